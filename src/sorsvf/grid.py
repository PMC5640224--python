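"""Visual-field grid geometry, field containers and measurement selection.

A visual field is a vector of perceived sensitivities (PS, in dB) on a fixed
grid of test locations in visual degrees.  The default grid is the standard
24-2 pattern with M = 54 locations (including the two blind-spot points over
the optic nerve head).  All strategies in this package address locations by
their 0-based position in the fixed grid ordering defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DB_MIN = 0.0
DB_MAX = 40.0

__all__ = [
    "DB_MIN",
    "DB_MAX",
    "GridSpec",
    "VisualField",
    "PopulationMatrix",
    "LocationSequence",
    "NormativeModel",
    "clamp_db",
    "selection_matrix",
    "default_grid",
    "default_normative",
]


def clamp_db(values):
    """Clamp sensitivities to the instrument's dynamic range [0, 40] dB."""
    return np.clip(np.asarray(values, dtype=float), DB_MIN, DB_MAX)


@dataclass(frozen=True)
class GridSpec:
    """A fixed test-location layout.

    Attributes
    ----------
    locations : list of (x_deg, y_deg)
        Integer coordinates in visual degrees, in the canonical ordering.
    blind_spot_indices : tuple of int
        0-based indices of the locations over the optic nerve head.
    neighbor_sets : tuple of frozenset
        For each location, the indices of its 8-neighbors (locations at
        Chebyshev distance of one grid step, i.e. within 6 degrees on both
        axes).
    """

    locations: tuple
    blind_spot_indices: tuple
    neighbor_sets: tuple = field(default=None)

    def __post_init__(self):
        if len(set(self.locations)) != len(self.locations):
            raise ValueError("grid locations must be unique")
        if self.neighbor_sets is None:
            object.__setattr__(
                self, "neighbor_sets", _compute_neighbor_sets(self.locations)
            )

    @property
    def M(self) -> int:
        return len(self.locations)

    def eccentricity(self) -> np.ndarray:
        """Euclidean distance of each location from fixation, in degrees."""
        xy = np.asarray(self.locations, dtype=float)
        return np.hypot(xy[:, 0], xy[:, 1])

    def non_blind_spot_mask(self) -> np.ndarray:
        mask = np.ones(self.M, dtype=bool)
        mask[list(self.blind_spot_indices)] = False
        return mask


def _compute_neighbor_sets(locations, step: float = 6.0):
    xy = np.asarray(locations, dtype=float)
    sets = []
    for i in range(len(locations)):
        d = np.abs(xy - xy[i])
        mask = (d[:, 0] <= step) & (d[:, 1] <= step)
        mask[i] = False
        sets.append(frozenset(np.flatnonzero(mask).tolist()))
    return tuple(sets)


@dataclass
class VisualField:
    """One eye's map of perceived sensitivities on a grid."""

    values: np.ndarray
    patient_id: str = ""
    eye: str = "right"

    def __post_init__(self):
        self.values = clamp_db(self.values)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    @property
    def M(self) -> int:
        return self.values.size


@dataclass
class PopulationMatrix:
    """An M x N matrix whose columns are visual fields.

    ``patient_ids[n]`` labels column ``n``; repeated labels mark repeat
    examinations of the same patient and drive patient-wise fold splits.
    """

    X: np.ndarray
    patient_ids: list

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (M locations x N fields)")
        if self.X.shape[1] != len(self.patient_ids):
            raise ValueError("one patient id per column required")
        if self.X.shape[1] < 1:
            raise ValueError("need at least one field")

    @property
    def M(self) -> int:
        return self.X.shape[0]

    @property
    def N(self) -> int:
        return self.X.shape[1]

    def field(self, n: int) -> VisualField:
        return VisualField(self.X[:, n].copy(), patient_id=str(self.patient_ids[n]))


@dataclass(frozen=True)
class LocationSequence:
    """An ordered sequence of distinct 0-based location indices."""

    indices: tuple

    def __post_init__(self):
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("location sequence must not repeat indices")

    @property
    def S(self) -> int:
        return len(self.indices)

    def validate(self, M: int) -> None:
        if any(i < 0 or i >= M for i in self.indices):
            raise ValueError(f"location index out of range for M={M}")


@dataclass(frozen=True)
class NormativeModel:
    """Age-matched normal sensitivities nv_l for every grid location."""

    nv: np.ndarray

    def __post_init__(self):
        nv = np.asarray(self.nv, dtype=float)
        if np.any(nv < DB_MIN) or np.any(nv > DB_MAX):
            raise ValueError("normative values must lie in [0, 40] dB")
        object.__setattr__(self, "nv", nv)


def selection_matrix(seq: LocationSequence, M: int) -> np.ndarray:
    """Binary S x M measurement matrix selecting rows ``seq`` of a field matrix.

    Row i carries a single 1 in column ``seq.indices[i]``, so that
    ``selection_matrix(seq, M) @ X`` stacks the measured rows of ``X`` in
    sequence order.
    """
    seq.validate(M)
    I = np.zeros((seq.S, M))
    I[np.arange(seq.S), list(seq.indices)] = 1.0
    return I


# 24-2 pattern, right-eye orientation: row-major from the superior-left corner.
# The y = +/-3 rows extend nasally to x = -27; blind spot temporal at (15, +/-3).
_GRID_24_2_ROWS = [
    (21, (-9, -3, 3, 9)),
    (15, (-15, -9, -3, 3, 9, 15)),
    (9, (-21, -15, -9, -3, 3, 9, 15, 21)),
    (3, (-27, -21, -15, -9, -3, 3, 9, 15, 21)),
    (-3, (-27, -21, -15, -9, -3, 3, 9, 15, 21)),
    (-9, (-21, -15, -9, -3, 3, 9, 15, 21)),
    (-15, (-15, -9, -3, 3, 9, 15)),
    (-21, (-9, -3, 3, 9)),
]


def default_grid() -> GridSpec:
    """The standard 54-point 24-2 grid (6 degree spacing, 2 blind-spot points)."""
    locations = tuple(
        (x, y) for y, xs in _GRID_24_2_ROWS for x in xs
    )
    blind = tuple(i for i, (x, y) in enumerate(locations) if x == 15 and abs(y) == 3)
    return GridSpec(locations=locations, blind_spot_indices=blind)


def default_normative(grid: GridSpec) -> NormativeModel:
    """Smooth hill-of-vision normative model.

    Sensitivity decays linearly with eccentricity from ~34 dB near fixation:
    nv_l = clamp(34 - 0.5 * ecc_l / 6, 0, 40), rounded to 0.1 dB.  Any smooth
    normative surface suffices for simulation; real deployments would load a
    device-specific table instead.
    """
    ecc = grid.eccentricity()
    nv = clamp_db(34.0 - 0.5 * ecc / 6.0)
    return NormativeModel(nv=np.round(nv, 1))
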