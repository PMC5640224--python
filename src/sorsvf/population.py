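"""Synthetic visual-field cohorts with glaucoma-like spatial structure.

The generator emulates the statistical features a reconstruction-based
strategy relies on in real perimetric datasets: strong positive correlation
between nearby locations, healthy fields scattered tightly around normative
values, and glaucomatous fields with spatially coherent depressions
(arcuate bundles, nasal steps, diffuse loss) spanning a wide mean-deviation
range.

Spatially correlated variation is sampled in a truncated eigenbasis of a
squared-exponential covariance over the grid coordinates; components whose
eigenvalue falls below a relative cutoff are dropped (or an explicit
``gp_rank`` budget is enforced), so the generated population matrix has
numerical rank well below the number of locations — the low-dimensional
structure that field reconstruction exploits.  Repeat examinations of a
patient are independent redraws of correlated measurement noise around the
patient's base field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .grid import GridSpec, NormativeModel, PopulationMatrix, clamp_db

__all__ = ["CohortConfig", "archetype_masks", "generate_cohort"]

DEFAULT_ARCHETYPES = ("superior_arcuate", "inferior_arcuate", "nasal_step", "diffuse")


@dataclass
class CohortConfig:
    """Cohort shape mirrors a mixed clinical population (mostly glaucomatous).

    ``severity_mean`` is the mean (dB) of the exponential severity draw per
    sampled defect archetype; glaucomatous patients additionally receive a
    small diffuse depression so their mean deviation spans a wide range.
    """

    n_patients: int = 160
    fields_per_patient: int = 32
    fraction_glaucoma: float = 0.86
    archetypes: Sequence[str] = DEFAULT_ARCHETYPES
    severity_mean: float = 10.0
    global_depression_mean: float = 2.0
    global_noise_sd: float = 2.0              # patient-level correlated variation, dB
    visit_noise_sd: float = 1.0               # per-visit correlated redraw, dB
    spatial_correlation_scale: float = 10.0   # degrees
    gp_rank: Optional[int] = None             # cap on correlated-noise components
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fraction_glaucoma <= 1.0):
            raise ValueError("fraction_glaucoma must lie in [0, 1]")
        if self.severity_mean < 0:
            raise ValueError("severity_mean must be nonnegative")


def archetype_masks(grid: GridSpec) -> dict:
    """Stylized defect masks over the grid, respecting the horizontal midline.

    Nerve-fiber-bundle defects do not cross the horizontal raphe, so the
    arcuate masks carry zero weight in the opposite hemifield.  Weights are
    in [0, 1]; geometry is deliberately schematic — only the induced
    inter-location correlation structure matters for simulation.
    """
    xy = np.asarray(grid.locations, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    ecc = grid.eccentricity()

    band = np.exp(-(((ecc - 15.0) / 7.0) ** 2))  # arcuate band around 15 deg
    superior = np.where(y > 0, band, 0.0)
    inferior = np.where(y < 0, band, 0.0)
    # nasal step: superior nasal wedge (nasal = negative x on this grid)
    nasal = np.where((x <= -9) & (y > 0), 1.0, 0.0)
    diffuse = np.ones(grid.M)
    return {
        "superior_arcuate": superior,
        "inferior_arcuate": inferior,
        "nasal_step": nasal,
        "diffuse": diffuse,
    }


def _correlated_basis(grid: GridSpec, sd: float, scale: float,
                      gp_rank: Optional[int], rel_cutoff: float = 1e-9):
    """Truncated eigenbasis of the squared-exponential covariance (sd^2 K)."""
    xy = np.asarray(grid.locations, dtype=float)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-d2 / (2.0 * scale ** 2))
    lam, V = np.linalg.eigh(K)
    lam, V = lam[::-1], V[:, ::-1]
    keep = lam > rel_cutoff * lam[0]
    if gp_rank is not None:
        keep &= np.arange(lam.size) < gp_rank
    return sd * V[:, keep] * np.sqrt(lam[keep])


def generate_cohort(cfg: CohortConfig, grid: GridSpec,
                    normative: NormativeModel) -> PopulationMatrix:
    """Draw a cohort; columns are fields, repeat visits share a patient id."""
    rng = np.random.default_rng(cfg.seed)
    masks = archetype_masks(grid)
    A_patient = _correlated_basis(grid, cfg.global_noise_sd,
                                  cfg.spatial_correlation_scale, cfg.gp_rank)
    A_visit = _correlated_basis(grid, cfg.visit_noise_sd,
                                cfg.spatial_correlation_scale, cfg.gp_rank)

    n_glauc = int(round(cfg.fraction_glaucoma * cfg.n_patients))
    columns, ids = [], []
    for p in range(cfg.n_patients):
        glaucomatous = p < n_glauc
        base = normative.nv + A_patient @ rng.standard_normal(A_patient.shape[1])
        if glaucomatous:
            n_defects = int(rng.integers(1, 4))
            names = rng.choice(len(cfg.archetypes), size=n_defects, replace=False)
            for idx in names:
                severity = rng.exponential(cfg.severity_mean)
                base = base - severity * masks[cfg.archetypes[int(idx)]]
            base = base - rng.exponential(cfg.global_depression_mean)
        pid = f"P{p:04d}"
        for _ in range(cfg.fields_per_patient):
            visit = base + A_visit @ rng.standard_normal(A_visit.shape[1])
            columns.append(clamp_db(visit))
            ids.append(pid)

    X = np.column_stack(columns)
    return PopulationMatrix(X=X, patient_ids=ids)
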