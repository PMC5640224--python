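"""Simulated patient responses via a probability-of-seeing curve (POSC).

A responder is a true visual field plus reliability parameters.  The
probability of a "seen" response to a stimulus of intensity s (dB of
attenuation; higher dB = dimmer light) at a location with true sensitivity t
is a cumulative-Gaussian psychometric function in the dB domain, floored and
capped by the false-positive and false-negative rates:

    p(seen | s, t) = fp + (1 - fp - fn) * (1 - Phi((s - t) / sigma(t)))

with a threshold-dependent spread sigma(t) = min(exp(A*t + B), cap).  With
the Henson-style defaults A = -0.081, B = 3.27, cap = 6 dB the curve becomes
more gradual as sensitivity drops, so damaged locations answer less
consistently — the behaviour perimetry simulators are built around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .grid import VisualField, clamp_db

__all__ = ["ResponderProfile", "Response", "posc_spread", "prob_of_seeing", "respond"]

DEFAULT_FP = 0.03
DEFAULT_FN = 0.01
DEFAULT_SPREAD_A = -0.081
DEFAULT_SPREAD_B = 3.27
DEFAULT_SPREAD_CAP = 6.0


@dataclass
class ResponderProfile:
    """True field plus response-reliability parameters of a simulated patient."""

    true_field: VisualField
    fp: float = DEFAULT_FP
    fn: float = DEFAULT_FN
    spread_A: float = DEFAULT_SPREAD_A
    spread_B: float = DEFAULT_SPREAD_B
    spread_cap: float = DEFAULT_SPREAD_CAP

    def __post_init__(self):
        if not (0.0 <= self.fp < 1.0 and 0.0 <= self.fn < 1.0):
            raise ValueError("fp and fn must lie in [0, 1)")
        if self.fp + self.fn >= 1.0:
            raise ValueError("fp + fn must be < 1")


@dataclass(frozen=True)
class Response:
    seen: bool
    stimulus_db: float
    location: int


def posc_spread(threshold_db, spread_A=DEFAULT_SPREAD_A, spread_B=DEFAULT_SPREAD_B,
                spread_cap=DEFAULT_SPREAD_CAP):
    """Spread sigma(t) of the POSC at true sensitivity t, in dB."""
    return np.minimum(np.exp(spread_A * np.asarray(threshold_db, dtype=float)
                             + spread_B), spread_cap)


def prob_of_seeing(stimulus_db, threshold_db, profile: ResponderProfile):
    """Probability that the responder reports seeing the stimulus.

    Strictly decreasing in ``stimulus_db`` (dimmer stimuli are seen less
    often) and bounded in [fp, 1 - fn].
    """
    sigma = posc_spread(threshold_db, profile.spread_A, profile.spread_B,
                        profile.spread_cap)
    s = np.asarray(stimulus_db, dtype=float)
    t = np.asarray(threshold_db, dtype=float)
    p_see = 1.0 - ndtr((s - t) / sigma)  # ndtr = standard normal CDF
    return profile.fp + (1.0 - profile.fp - profile.fn) * p_see


def respond(stimulus_db: float, location: int, profile: ResponderProfile,
            rng: np.random.Generator) -> Response:
    """Draw one seen/unseen response at ``location`` for the given stimulus."""
    stimulus_db = float(clamp_db(stimulus_db))
    t = profile.true_field.values[location]
    p = float(prob_of_seeing(stimulus_db, t, profile))
    return Response(seen=bool(rng.random() < p), stimulus_db=stimulus_db,
                    location=location)
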