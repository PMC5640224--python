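"""Per-location sensitivity estimators: ZEST and a dynamic adaptive staircase.

ZEST maintains a probability mass function (PMF) over candidate sensitivities
(integer dB, 0..40), presents the posterior mean, and multiplies in the
psychometric likelihood of each response.  The prior is a mixture of a
"healthy" Gaussian centred on the normative value nv_l, an "abnormal"
Gaussian at 0 dB weighted by alpha, and a small floor epsilon so no
sensitivity is ever assigned zero probability:

    PMF_l  ∝  G(nv_l, sigma_l) + alpha * G(0, 1) + epsilon_l

Testing at a location stops when the posterior SD drops below ``stop_sd``
or the presentation cap is reached.

The dynamic staircase steps the stimulus brighter (lower dB) after an unseen
response and dimmer (higher dB) after a seen one, with larger steps in
depressed dB ranges where the psychometric curve is shallower.  One reversal
(or being pinned at a range bound twice) terminates the location; the
estimate is the midpoint of the two stimuli straddling the reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.stats import norm

from .grid import DB_MAX, DB_MIN
from .patient import ResponderProfile, prob_of_seeing

__all__ = [
    "Pmf",
    "ZestConfig",
    "ZestState",
    "build_prior_pmf",
    "shift_prior_pmf",
    "zest_step",
    "zest_update",
    "zest_estimate",
    "StaircaseConfig",
    "StaircaseState",
    "staircase_start",
    "staircase_step",
    "staircase_update",
    "staircase_estimate",
]

PMF_SUPPORT = np.arange(int(DB_MIN), int(DB_MAX) + 1, dtype=float)


@dataclass(frozen=True)
class Pmf:
    """Discrete distribution over candidate sensitivities (integer dB)."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        total = probs.sum()
        if total <= 0:
            raise ValueError("pmf weights must have positive mass")
        object.__setattr__(self, "probs", probs / total)
        object.__setattr__(self, "support", np.asarray(self.support, dtype=float))

    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))

    def sd(self) -> float:
        m = self.mean()
        return float(np.sqrt(np.dot((self.support - m) ** 2, self.probs)))


@dataclass(frozen=True)
class ZestConfig:
    sigma_l: float = 5.0          # healthy-mode SD (dB)
    alpha: float = 0.1            # weight of the abnormal component
    epsilon_l: float = 0.001      # floor bias (no zero-probability dB value)
    stop_sd: float = 2.0          # posterior-SD stopping threshold (dB)
    max_presentations: int = 4    # per-location presentation cap
    # POSC parameters assumed by the likelihood (defaults match the simulator).
    likelihood_fp: float = 0.03
    likelihood_fn: float = 0.01
    likelihood_spread_A: float = -0.081
    likelihood_spread_B: float = 3.27
    likelihood_spread_cap: float = 6.0

    def likelihood_profile(self) -> "ResponderProfile":
        from .grid import VisualField  # local import to avoid cycle at module load

        return ResponderProfile(
            true_field=VisualField(np.zeros(1)),
            fp=self.likelihood_fp,
            fn=self.likelihood_fn,
            spread_A=self.likelihood_spread_A,
            spread_B=self.likelihood_spread_B,
            spread_cap=self.likelihood_spread_cap,
        )


@dataclass
class ZestState:
    pmf: Pmf
    presentations: int = 0
    done: bool = False


def _mixture_pmf(center: float, cfg: ZestConfig) -> Pmf:
    healthy = norm.pdf(PMF_SUPPORT, loc=center, scale=cfg.sigma_l)
    abnormal = norm.pdf(PMF_SUPPORT, loc=0.0, scale=1.0)
    weights = healthy + cfg.alpha * abnormal + cfg.epsilon_l
    return Pmf(support=PMF_SUPPORT, probs=weights)


def build_prior_pmf(nv_l: float, cfg: ZestConfig) -> Pmf:
    """Standard prior: healthy mode at the normative value nv_l."""
    return _mixture_pmf(float(nv_l), cfg)


def shift_prior_pmf(estimate: float, nv_l: float, cfg: ZestConfig) -> Pmf:
    """Prior with the healthy mode shifted to a reconstructed estimate.

    Used when a field reconstruction already predicts the sensitivity at a
    not-yet-tested location: the healthy Gaussian is recentred on that
    prediction while the abnormal component and floor are unchanged.
    """
    return _mixture_pmf(float(estimate), cfg)


def zest_step(state: ZestState, cfg: ZestConfig) -> float:
    """Next stimulus: the posterior mean, rounded to the dB support."""
    if state.done:
        raise RuntimeError("zest_step called on a finished location")
    mean = state.pmf.mean()
    idx = int(np.argmin(np.abs(state.pmf.support - mean)))
    return float(state.pmf.support[idx])


def zest_update(state: ZestState, stimulus_db: float, seen: bool,
                cfg: ZestConfig) -> ZestState:
    """Multiply the psychometric likelihood of the response into the PMF."""
    if state.done:
        raise RuntimeError("zest_update called on a finished location")
    profile = cfg.likelihood_profile()
    p_seen = prob_of_seeing(stimulus_db, state.pmf.support, profile)
    like = p_seen if seen else 1.0 - p_seen
    posterior = Pmf(support=state.pmf.support, probs=state.pmf.probs * like)
    presentations = state.presentations + 1
    done = posterior.sd() < cfg.stop_sd or presentations >= cfg.max_presentations
    return ZestState(pmf=posterior, presentations=presentations, done=done)


def zest_estimate(state: ZestState) -> float:
    """Final estimate: posterior mean, clamped to the dB range."""
    return float(np.clip(state.pmf.mean(), DB_MIN, DB_MAX))


# ---------------------------------------------------------------------------
# Dynamic adaptive staircase
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseConfig:
    # (upper-exclusive dB bound of range, step size in that range); larger
    # steps at depressed values where the psychometric curve is shallower.
    step_table: tuple = ((10.0, 10.0), (20.0, 6.0), (np.inf, 4.0))
    max_reversals: int = 1
    stimulus_min: float = DB_MIN
    stimulus_max: float = DB_MAX

    def step_for(self, level_db: float) -> float:
        for bound, step in self.step_table:
            if level_db < bound:
                return step
        return self.step_table[-1][1]


@dataclass
class StaircaseState:
    current_stimulus: float
    last_response: Optional[bool] = None   # None before the first response
    reversals: int = 0
    pinned: int = 0                        # consecutive presentations stuck at a bound
    history: list = field(default_factory=list)
    done: bool = False
    _estimate: Optional[float] = None


def staircase_start(start_db: float, cfg: StaircaseConfig) -> StaircaseState:
    start = float(np.clip(start_db, cfg.stimulus_min, cfg.stimulus_max))
    return StaircaseState(current_stimulus=start)


def staircase_step(state: StaircaseState, cfg: StaircaseConfig) -> float:
    if state.done:
        raise RuntimeError("staircase_step called on a finished location")
    return state.current_stimulus


def staircase_update(state: StaircaseState, stimulus_db: float, seen: bool,
                     cfg: StaircaseConfig) -> StaircaseState:
    """Record a response, move the stimulus, and detect reversals/pinning."""
    if state.done:
        raise RuntimeError("staircase_update called on a finished location")
    history = state.history + [(float(stimulus_db), bool(seen))]
    reversals = state.reversals
    done = False
    estimate = None

    if state.last_response is not None and seen != state.last_response:
        reversals += 1
        if reversals >= cfg.max_reversals:
            # midpoint of the two stimuli straddling the reversal
            prev_stim = history[-2][0]
            estimate = float(np.clip((stimulus_db + prev_stim) / 2.0,
                                     cfg.stimulus_min, cfg.stimulus_max))
            done = True

    # seen -> dimmer (higher dB); unseen -> brighter (lower dB)
    direction = 1.0 if seen else -1.0
    step = cfg.step_for(float(stimulus_db))
    nxt = float(np.clip(stimulus_db + direction * step,
                        cfg.stimulus_min, cfg.stimulus_max))
    pinned = state.pinned + 1 if nxt == stimulus_db else 0
    if not done and pinned >= 2:
        done = True
        estimate = float(stimulus_db)

    return StaircaseState(
        current_stimulus=nxt,
        last_response=seen,
        reversals=reversals,
        pinned=pinned,
        history=history,
        done=done,
        _estimate=estimate,
    )


def staircase_estimate(state: StaircaseState) -> float:
    if not state.done or state._estimate is None:
        raise RuntimeError("staircase_estimate requires a finished staircase")
    return state._estimate
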