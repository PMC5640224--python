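"""Examination bookkeeping shared by all testing strategies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import LocationSequence, VisualField, clamp_db

__all__ = ["Presentation", "ExaminationRecord"]


@dataclass(frozen=True)
class Presentation:
    location: int
    stimulus_db: float
    seen: bool


@dataclass
class ExaminationRecord:
    """Full log of one simulated examination.

    ``estimated_field`` holds the strategy's final field estimate;
    ``tested_locations`` the order in which locations were actually measured
    (for sparse strategies this is a strict subset of the grid).
    """

    strategy: str
    estimated_field: VisualField
    tested_locations: LocationSequence
    presentations_per_location: np.ndarray
    log: list = field(default_factory=list)

    def __post_init__(self):
        self.estimated_field.values = clamp_db(self.estimated_field.values)
        if len(self.log) != int(self.presentations_per_location.sum()):
            raise ValueError("log length must equal total presentation count")

    @property
    def total_presentations(self) -> int:
        return int(self.presentations_per_location.sum())

    def tested_mask(self, M: int) -> np.ndarray:
        mask = np.zeros(M, dtype=bool)
        mask[list(self.tested_locations.indices)] = True
        return mask
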