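"""Full-field baseline testing strategies: ZEST, DTS and TOP.

All three baselines test every location of the grid at least once:

* ``zest_field`` — Bayesian ZEST at every location, visited in a seeded
  random order, each location's prior centred on its normative value.
* ``dts_field`` — Dynamic Test Strategy: adaptive staircases; four anchor
  locations (the innermost point of each quadrant) start at the normative
  value, the remaining locations are visited breadth-first from the anchors
  and start at the mean of their already-estimated 8-neighbors.
* ``top_field`` — Tendency Oriented Perimetry: exactly one presentation per
  location; the grid is split into four interleaved subgrids tested group by
  group, with deterministic up/down adjustments and neighbor averaging
  propagating information to untested locations.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .estimators import (
    StaircaseConfig,
    ZestConfig,
    ZestState,
    build_prior_pmf,
    staircase_estimate,
    staircase_start,
    staircase_step,
    staircase_update,
    zest_estimate,
    zest_step,
    zest_update,
)
from .grid import GridSpec, LocationSequence, NormativeModel, VisualField, clamp_db
from .patient import ResponderProfile, respond
from .records import ExaminationRecord, Presentation

__all__ = ["run_zest_location", "run_staircase_location",
           "zest_field", "dts_field", "top_field"]


def run_zest_location(location, prior, responder, cfg: ZestConfig, rng, log):
    """Drive one ZEST location to termination; returns (estimate, n_presentations)."""
    state = ZestState(pmf=prior)
    while not state.done:
        stim = zest_step(state, cfg)
        resp = respond(stim, location, responder, rng)
        log.append(Presentation(location, resp.stimulus_db, resp.seen))
        state = zest_update(state, stim, resp.seen, cfg)
    return zest_estimate(state), state.presentations


def run_staircase_location(location, start_db, responder, cfg: StaircaseConfig,
                           rng, log):
    """Drive one staircase to termination; returns (estimate, n_presentations)."""
    state = staircase_start(start_db, cfg)
    n = 0
    while not state.done:
        stim = staircase_step(state, cfg)
        resp = respond(stim, location, responder, rng)
        log.append(Presentation(location, resp.stimulus_db, resp.seen))
        state = staircase_update(state, stim, resp.seen, cfg)
        n += 1
    return staircase_estimate(state), n


def zest_field(responder: ResponderProfile, grid: GridSpec,
               normative: NormativeModel, cfg: ZestConfig,
               rng: np.random.Generator) -> ExaminationRecord:
    """Full-field ZEST: every location once, in a seeded random order."""
    M = grid.M
    order = rng.permutation(M)
    estimates = np.zeros(M)
    counts = np.zeros(M, dtype=int)
    log = []
    for loc in order:
        prior = build_prior_pmf(normative.nv[loc], cfg)
        estimates[loc], counts[loc] = run_zest_location(
            int(loc), prior, responder, cfg, rng, log)
    return ExaminationRecord(
        strategy="zest",
        estimated_field=VisualField(estimates),
        tested_locations=LocationSequence(tuple(int(i) for i in order)),
        presentations_per_location=counts,
        log=log,
    )


def _quadrant_anchors(grid: GridSpec):
    """Innermost location of each quadrant (by eccentricity, ties to index)."""
    xy = np.asarray(grid.locations, dtype=float)
    ecc = grid.eccentricity()
    anchors = []
    for sx, sy in ((1, 1), (-1, 1), (-1, -1), (1, -1)):
        in_quad = np.flatnonzero((np.sign(xy[:, 0]) == sx) & (np.sign(xy[:, 1]) == sy))
        anchors.append(int(in_quad[np.argmin(ecc[in_quad])]))
    return anchors


def dts_field(responder: ResponderProfile, grid: GridSpec,
              normative: NormativeModel, cfg: StaircaseConfig,
              rng: np.random.Generator) -> ExaminationRecord:
    """Dynamic Test Strategy: staircases seeded by already-tested neighbors."""
    M = grid.M
    estimates = np.full(M, np.nan)
    counts = np.zeros(M, dtype=int)
    log = []
    order = []

    anchors = _quadrant_anchors(grid)
    queue = deque(anchors)
    enqueued = set(anchors)
    while queue:
        loc = queue.popleft()
        tested_nb = [n for n in sorted(grid.neighbor_sets[loc])
                     if not np.isnan(estimates[n])]
        if loc in anchors or not tested_nb:
            start = normative.nv[loc]
        else:
            start = float(np.mean([estimates[n] for n in tested_nb]))
        estimates[loc], counts[loc] = run_staircase_location(
            loc, start, responder, cfg, rng, log)
        order.append(loc)
        for n in sorted(grid.neighbor_sets[loc]):
            if n not in enqueued:
                enqueued.add(n)
                queue.append(n)
        if not queue:  # disconnected leftovers fall back to index order
            remaining = [i for i in range(M) if i not in enqueued]
            if remaining:
                enqueued.add(remaining[0])
                queue.append(remaining[0])

    return ExaminationRecord(
        strategy="dts",
        estimated_field=VisualField(estimates),
        tested_locations=LocationSequence(tuple(order)),
        presentations_per_location=counts,
        log=log,
    )


def _top_subgrids(grid: GridSpec):
    """Four interleaved subgrids by parity of the 6-degree row/column index."""
    groups = [[] for _ in range(4)]
    for i, (x, y) in enumerate(grid.locations):
        gx = ((x + 27) // 6) % 2
        gy = ((y + 21) // 6) % 2
        groups[2 * gy + gx].append(i)
    return groups


# deterministic adjustment fractions of nv_l for groups 1..4
TOP_STEP_FRACTIONS = (4 / 8, 3 / 8, 2 / 8, 1 / 8)


def top_field(responder: ResponderProfile, grid: GridSpec,
              normative: NormativeModel, rng: np.random.Generator,
              step_fractions=TOP_STEP_FRACTIONS) -> ExaminationRecord:
    """Tendency Oriented Perimetry: one presentation per location."""
    M = grid.M
    running = normative.nv / 2.0  # start estimates at half-normal
    tested = np.zeros(M, dtype=bool)
    counts = np.zeros(M, dtype=int)
    log = []
    order = []

    for g, group in enumerate(_top_subgrids(grid)):
        for loc in group:
            stim = float(clamp_db(running[loc]))
            resp = respond(stim, loc, responder, rng)
            log.append(Presentation(loc, resp.stimulus_db, resp.seen))
            step = normative.nv[loc] * step_fractions[g]
            running[loc] += step if resp.seen else -step
            tested[loc] = True
            counts[loc] = 1
            order.append(loc)
        # propagate to untested locations via tested-neighbor averaging
        updated = running.copy()
        for loc in range(M):
            if tested[loc]:
                continue
            nb = [n for n in grid.neighbor_sets[loc] if tested[n]]
            if nb:
                updated[loc] = float(np.mean(running[list(nb)]))
        running = updated

    return ExaminationRecord(
        strategy="top",
        estimated_field=VisualField(clamp_db(running)),
        tested_locations=LocationSequence(tuple(order)),
        presentations_per_location=counts,
        log=log,
    )
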