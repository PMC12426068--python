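"""Experimental design bookkeeping shared by simulation and likelihood code."""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = ["ResponseClasses", "DesignSpec"]


class ResponseClasses(enum.Enum):
    """Which old-response classes enter the frequency tables."""

    REMEMBER_ONLY = "remember_only"
    REMEMBER_PLUS_KNOW = "remember_plus_know"


@dataclass(frozen=True)
class DesignSpec:
    """Cohort and stimulus counts.

    Defaults mirror the study: 82 participants; 9 study statements per source
    combination (36 studied in total); 18 distractors, giving 54 test items.
    """

    n_participants: int = 82
    items_per_source: int = 9
    n_distractors: int = 18
    response_classes: ResponseClasses = ResponseClasses.REMEMBER_ONLY

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.items_per_source < 1 or self.n_distractors < 0:
            raise ValueError("design counts must be positive")

    @property
    def n_study_items(self) -> int:
        return 4 * self.items_per_source

    @property
    def n_test_items(self) -> int:
        return self.n_study_items + self.n_distractors

    @property
    def items_per_type(self) -> np.ndarray:
        """Test items per item type in (TI, TU, FI, FU, distractor) order."""
        return np.array([self.items_per_source] * 4 + [self.n_distractors], dtype=np.int64)
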