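"""Sequentially Optimized Reconstruction Strategy (SORS).

Training
--------
Given a training matrix X (M locations x N fields), SORS greedily builds an
ordered sequence of test locations.  At step k it evaluates every remaining
candidate location l by fitting the least-squares reconstruction basis

    D = X Y^T (Y Y^T)^{-1},   Y = I_seq X

for the prefix extended with l, and keeps the location whose basis minimizes
the Frobenius reconstruction error ||X - D Y||^2 (ties broken toward the
lowest index).  The per-prefix bases are stored: bases[k-1] maps the first k
measurements to a full M-location field estimate.

Because the optimal residual depends on X only through its Gram matrix
G = X X^T, the greedy search is carried out on G:

    ||X - D Y||^2 = tr(G) - tr(G[:, w] G[w, w]^{-1} G[w, :])

for a prefix w, which makes training cost independent of N.

Examination
-----------
Locations are tested in the trained order with a local estimator (ZEST or
the dynamic staircase).  After each tested location the whole field is
reconstructed from all measurements so far, and the reconstruction seeds the
next location: the ZEST variant recentres the prior's healthy mode on the
reconstructed value; the dynamic variant starts the staircase ``tau`` dB
below it (brighter), tau = 4 dB by default.  The final reported field keeps
the measured estimates at tested locations and fills untested ones from the
last reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import List, Optional

import numpy as np

from .estimators import (
    StaircaseConfig,
    ZestConfig,
    build_prior_pmf,
    shift_prior_pmf,
)
from .baselines import run_staircase_location, run_zest_location
from .grid import (
    GridSpec,
    LocationSequence,
    NormativeModel,
    PopulationMatrix,
    VisualField,
    clamp_db,
    selection_matrix,
)
from .patient import ResponderProfile
from .records import ExaminationRecord

__all__ = [
    "SorsModel",
    "SorsExamConfig",
    "least_squares_basis",
    "train_sors",
    "train_rs",
    "train_ors",
    "reconstruct",
    "examine_sors",
    "examine_noreconstruct",
]

RIDGE_SCALE = 1e-8


@dataclass
class SorsModel:
    """Trained location order plus per-prefix reconstruction bases."""

    sequence: LocationSequence
    bases: List[np.ndarray]          # bases[k-1] is M x k
    training_errors: np.ndarray      # squared Frobenius residual per prefix

    def __post_init__(self):
        if len(self.bases) != self.sequence.S:
            raise ValueError("one basis per prefix length required")
        for k, D in enumerate(self.bases, start=1):
            if D.shape[1] != k:
                raise ValueError(f"basis {k} must have {k} columns")

    @property
    def S(self) -> int:
        return self.sequence.S

    @property
    def M(self) -> int:
        return self.bases[-1].shape[0]


@dataclass
class SorsExamConfig:
    S: int
    local_method: str = "dynamic"          # "zest" | "dynamic"
    tau: float = 4.0                       # dB offset below the reconstructed start
    zest: ZestConfig = dc_field(default_factory=ZestConfig)
    staircase: StaircaseConfig = dc_field(default_factory=StaircaseConfig)

    def __post_init__(self):
        if self.local_method not in ("zest", "dynamic"):
            raise ValueError(f"unknown local method {self.local_method!r}")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")


def _solve_basis(XYt: np.ndarray, YYt: np.ndarray) -> np.ndarray:
    """Solve D = X Y^T (Y Y^T)^{-1} with a ridge fallback when singular."""
    try:
        np.linalg.cholesky(YYt)  # singularity probe: fails on PSD-singular Y Y^T
        return np.linalg.solve(YYt, XYt.T).T
    except np.linalg.LinAlgError:
        warnings.warn("measurement Gram matrix is singular; using ridge fallback",
                      RuntimeWarning, stacklevel=2)
        lam = RIDGE_SCALE * np.trace(YYt)
        if lam <= 0:
            lam = RIDGE_SCALE
        reg = YYt + lam * np.eye(YYt.shape[0])
        return np.linalg.solve(reg, XYt.T).T


def least_squares_basis(X: PopulationMatrix, seq: LocationSequence) -> np.ndarray:
    """Optimal M x k basis reconstructing X from its rows indexed by ``seq``.

    Minimizes ||X - D Y||_F^2 over D, with Y the measured sub-matrix of X.
    """
    if seq.S == 0:
        raise ValueError("sequence must contain at least one location")
    seq.validate(X.M)
    Y = selection_matrix(seq, X.M) @ X.X
    return _solve_basis(X.X @ Y.T, Y @ Y.T)


def _prefix_residual(G: np.ndarray, prefix: list) -> float:
    """tr(G) - tr(G[:,w] G[w,w]^{-1} G[w,:]) — optimal-basis residual."""
    w = list(prefix)
    Gww = G[np.ix_(w, w)]
    Gw = G[:, w]
    try:
        sol = np.linalg.solve(Gww, Gw.T)
    except np.linalg.LinAlgError:
        lam = RIDGE_SCALE * np.trace(Gww)
        sol = np.linalg.solve(Gww + max(lam, RIDGE_SCALE) * np.eye(len(w)), Gw.T)
    return float(np.trace(G) - np.trace(Gw @ sol))


def _fit_prefix_bases(X: PopulationMatrix, indices: list):
    """Store the per-prefix optimal bases and their residuals."""
    bases, errors = [], []
    for k in range(1, len(indices) + 1):
        prefix = LocationSequence(tuple(indices[:k]))
        D = least_squares_basis(X, prefix)
        Y = selection_matrix(prefix, X.M) @ X.X
        errors.append(float(np.sum((X.X - D @ Y) ** 2)))
        bases.append(D)
    return bases, np.asarray(errors)


def train_sors(X: PopulationMatrix, S: int) -> SorsModel:
    """Greedy selection of the S most reconstruction-effective locations."""
    if not (1 <= S <= X.M):
        raise ValueError(f"S must lie in [1, {X.M}]")
    G = X.X @ X.X.T
    chosen: list = []
    for _ in range(S):
        best_loc, best_err = None, np.inf
        for l in range(X.M):
            if l in chosen:
                continue
            err = _prefix_residual(G, chosen + [l])
            if err < best_err - 1e-12 or best_loc is None:
                best_loc, best_err = l, err
        chosen.append(best_loc)
    bases, errors = _fit_prefix_bases(X, chosen)
    return SorsModel(sequence=LocationSequence(tuple(chosen)), bases=bases,
                     training_errors=errors)


def train_rs(X: PopulationMatrix, S: int, rng: np.random.Generator) -> SorsModel:
    """Reconstruction Strategy baseline: a uniformly random location subset."""
    indices = list(rng.choice(X.M, size=S, replace=False))
    bases, errors = _fit_prefix_bases(X, indices)
    return SorsModel(sequence=LocationSequence(tuple(int(i) for i in indices)),
                     bases=bases, training_errors=errors)


def train_ors(X: PopulationMatrix, S: int, rng: np.random.Generator,
              n_candidates: int = 50) -> SorsModel:
    """Optimized Reconstruction Strategy: best of ``n_candidates`` random subsets.

    Unlike the greedy training, the whole sequence is drawn in one step; the
    candidate with the lowest full-S training residual wins.
    """
    G = X.X @ X.X.T
    best, best_err = None, np.inf
    for _ in range(n_candidates):
        cand = [int(i) for i in rng.choice(X.M, size=S, replace=False)]
        err = _prefix_residual(G, cand)
        if err < best_err:
            best, best_err = cand, err
    bases, errors = _fit_prefix_bases(X, best)
    return SorsModel(sequence=LocationSequence(tuple(best)), bases=bases,
                     training_errors=errors)


def reconstruct(model: SorsModel, k: int, measurements: np.ndarray) -> VisualField:
    """Estimate the full field from the first k measurements (Ω*_1..k order)."""
    if not (1 <= k <= model.S):
        raise ValueError(f"k must lie in [1, {model.S}]")
    y = np.asarray(measurements, dtype=float)
    if y.shape != (k,):
        raise ValueError(f"expected {k} measurements, got shape {y.shape}")
    return VisualField(clamp_db(model.bases[k - 1] @ y))


def examine_sors(model: SorsModel, responder: ResponderProfile,
                 normative: NormativeModel, cfg: SorsExamConfig,
                 rng: np.random.Generator) -> ExaminationRecord:
    """Run a SORS examination (ZEST or dynamic local estimation)."""
    return _examine(model, responder, normative, cfg, rng, reconstruct_each_step=True)


def examine_noreconstruct(model: SorsModel, responder: ResponderProfile,
                          normative: NormativeModel, cfg: SorsExamConfig,
                          rng: np.random.Generator) -> ExaminationRecord:
    """Ablation: test S locations seeded from normative values only.

    No information is shared between locations during the examination; a
    single reconstruction with the full-S basis fills untested locations at
    the end (the RS/ORS "v1" testing scheme).  The "v2" scheme with
    intermediate reconstructions is ``examine_sors`` run on an RS/ORS model.
    """
    return _examine(model, responder, normative, cfg, rng, reconstruct_each_step=False)


def _examine(model, responder, normative, cfg, rng, reconstruct_each_step):
    if cfg.S > model.S:
        raise ValueError(f"S={cfg.S} exceeds trained sequence length {model.S}")
    M = model.M
    seq = model.sequence.indices[: cfg.S]
    measurements = np.zeros(cfg.S)
    counts = np.zeros(M, dtype=int)
    log: list = []
    recon: Optional[VisualField] = None

    for k, loc in enumerate(seq, start=1):
        if cfg.local_method == "zest":
            if reconstruct_each_step and recon is not None:
                prior = shift_prior_pmf(recon.values[loc], normative.nv[loc], cfg.zest)
            else:
                prior = build_prior_pmf(normative.nv[loc], cfg.zest)
            est, n = run_zest_location(loc, prior, responder, cfg.zest, rng, log)
        else:
            if reconstruct_each_step and recon is not None:
                start = recon.values[loc] - cfg.tau
            else:
                start = normative.nv[loc]
            est, n = run_staircase_location(loc, start, responder, cfg.staircase,
                                            rng, log)
        measurements[k - 1] = est
        counts[loc] = n
        if reconstruct_each_step:
            recon = reconstruct(model, k, measurements[:k])

    if recon is None or not reconstruct_each_step:
        recon = reconstruct(model, cfg.S, measurements)

    final = recon.values.copy()
    final[list(seq)] = clamp_db(measurements)
    name = "sors-z" if cfg.local_method == "zest" else "sors-d"
    if not reconstruct_each_step:
        name += "-v1"
    return ExaminationRecord(
        strategy=name,
        estimated_field=VisualField(final),
        tested_locations=LocationSequence(seq),
        presentations_per_location=counts,
        log=log,
    )
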