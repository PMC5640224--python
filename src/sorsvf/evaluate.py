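"""Metrics and experiment drivers for benchmarking testing strategies.

Accuracy is summarized by the per-field RMSE between true and estimated
sensitivities; examination time by the total number of stimulus
presentations.  Medians are reported throughout (perimetric error
distributions are heavy-tailed), and strategy comparisons use the
Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .grid import GridSpec, NormativeModel, PopulationMatrix, VisualField
from .patient import ResponderProfile
from .records import ExaminationRecord

__all__ = [
    "rmse",
    "mean_deviation",
    "scotoma_delta",
    "signed_error_summary",
    "crossval_split",
    "test_retest",
    "BenchmarkResult",
    "benchmark",
    "compare_strategies",
]


def rmse(true_field: np.ndarray, est_field: np.ndarray,
         grid: Optional[GridSpec] = None, include_blind_spot: bool = True) -> float:
    """Root mean square per-location error between two fields, in dB."""
    t = np.asarray(true_field, dtype=float)
    e = np.asarray(est_field, dtype=float)
    if t.shape != e.shape:
        raise ValueError("field length mismatch")
    if not include_blind_spot:
        if grid is None:
            raise ValueError("grid required to exclude blind-spot locations")
        mask = grid.non_blind_spot_mask()
        t, e = t[mask], e[mask]
    return float(np.sqrt(np.mean((t - e) ** 2)))


def mean_deviation(field: np.ndarray, normative: NormativeModel,
                   grid: Optional[GridSpec] = None) -> float:
    """Mean departure from normative values (dB); MD < -2 suggests abnormality.

    Blind-spot locations are excluded when a grid is given, as in clinical MD.
    """
    f = np.asarray(field, dtype=float)
    diff = f - normative.nv
    if grid is not None:
        diff = diff[grid.non_blind_spot_mask()]
    return float(np.mean(diff))


def scotoma_delta(field: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Scotoma-border sharpness: max absolute difference to any 8-neighbor."""
    f = np.asarray(field, dtype=float)
    out = np.zeros(grid.M)
    for l in range(grid.M):
        nb = list(grid.neighbor_sets[l])
        if nb:
            out[l] = np.max(np.abs(f[l] - f[nb]))
    return out


def signed_error_summary(records: Iterable[ExaminationRecord],
                         truths: Iterable[VisualField],
                         split_tested_untested: bool = False) -> pd.DataFrame:
    """Per-location signed errors (true - estimate; positive = underestimate).

    Returns mean, SD and N, optionally split into tested vs untested
    locations (relevant for sparse strategies that infer part of the field).
    """
    groups: Dict[str, List[float]] = {}
    for rec, truth in zip(records, truths):
        err = truth.values - rec.estimated_field.values
        if split_tested_untested:
            mask = rec.tested_mask(truth.M)
            groups.setdefault("tested", []).extend(err[mask].tolist())
            groups.setdefault("untested", []).extend(err[~mask].tolist())
        else:
            groups.setdefault("all", []).extend(err.tolist())
    rows = []
    for name, errs in groups.items():
        arr = np.asarray(errs)
        rows.append({"group": name, "mean": float(arr.mean()) if arr.size else np.nan,
                     "sd": float(arr.std()) if arr.size else np.nan,
                     "n": int(arr.size)})
    return pd.DataFrame(rows)


def crossval_split(X: PopulationMatrix, k_folds: int = 10,
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Patient-wise fold assignment (length N): no patient spans folds.

    Patients are assigned greedily, largest field count first, to the
    currently smallest fold, which balances fold sizes to within one
    patient's field count.
    """
    ids = np.asarray(X.patient_ids)
    unique, counts = np.unique(ids, return_counts=True)
    if k_folds > unique.size:
        raise ValueError("more folds than distinct patients")
    order = np.argsort(-counts, kind="stable")
    if rng is not None:  # shuffle among equal counts for randomized folds
        perm = rng.permutation(unique.size)
        unique, counts = unique[perm], counts[perm]
        order = np.argsort(-counts, kind="stable")
    fold_sizes = np.zeros(k_folds, dtype=int)
    assignment = {}
    for i in order:
        f = int(np.argmin(fold_sizes))
        assignment[unique[i]] = f
        fold_sizes[f] += counts[i]
    return np.asarray([assignment[pid] for pid in ids], dtype=int)


def test_retest(run_exam: Callable[[np.random.Generator], ExaminationRecord],
                n_repeats: int = 5, seed: int = 0) -> dict:
    """Repeat the same examination with fresh response noise.

    ``run_exam`` maps an RNG to an ExaminationRecord for the same responder.
    Returns per-location SDs of the estimates across repeats and their median.
    """
    rng = np.random.default_rng(seed)
    estimates = np.stack([
        run_exam(np.random.default_rng(rng.integers(2 ** 31))).estimated_field.values
        for _ in range(n_repeats)
    ])
    sds = estimates.std(axis=0, ddof=0)
    return {"per_location_sd": sds, "median_sd": float(np.median(sds)),
            "n_repeats": n_repeats}


@dataclass
class BenchmarkResult:
    """Per-examination rows plus per-strategy median aggregates."""

    rows: pd.DataFrame
    aggregates: pd.DataFrame


def benchmark(strategies: Dict[str, Callable], cohort: PopulationMatrix,
              grid: GridSpec, normative: NormativeModel,
              seed: int = 0, max_fields: Optional[int] = None,
              responder_kwargs: Optional[dict] = None) -> BenchmarkResult:
    """Run each strategy on every field of a test cohort.

    ``strategies`` maps a name to ``f(responder, rng) -> ExaminationRecord``.
    Each examination gets an independent child RNG of ``seed`` so strategies
    see identical responder streams per field index.
    """
    responder_kwargs = responder_kwargs or {}
    n = cohort.N if max_fields is None else min(cohort.N, max_fields)
    root = np.random.default_rng(seed)
    field_seeds = root.integers(2 ** 31, size=n)
    rows = []
    for i in range(n):
        truth = cohort.field(i)
        responder = ResponderProfile(true_field=truth, **responder_kwargs)
        for name, run in strategies.items():
            rng = np.random.default_rng(field_seeds[i])
            rec = run(responder, rng)
            rows.append({
                "strategy": name,
                "field_index": i,
                "patient_id": truth.patient_id,
                "rmse": rmse(truth.values, rec.estimated_field.values),
                "total_presentations": rec.total_presentations,
                "n_tested_locations": rec.tested_locations.S,
                "md_true": mean_deviation(truth.values, normative, grid),
                "md_est": mean_deviation(rec.estimated_field.values, normative, grid),
            })
    df = pd.DataFrame(rows)
    agg = (df.groupby("strategy")
             .agg(median_rmse=("rmse", "median"),
                  median_presentations=("total_presentations", "median"),
                  n=("rmse", "size"))
             .reset_index())
    return BenchmarkResult(rows=df, aggregates=agg)


def compare_strategies(result: BenchmarkResult, strategy_a: str, strategy_b: str,
                       metric: str = "rmse") -> dict:
    """Two-sided Mann-Whitney U test between two strategies' per-field metric."""
    df = result.rows
    a = df.loc[df.strategy == strategy_a, metric].to_numpy()
    b = df.loc[df.strategy == strategy_b, metric].to_numpy()
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return {"U": float(stat), "p_value": float(p),
            "median_a": float(np.median(a)), "median_b": float(np.median(b))}
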