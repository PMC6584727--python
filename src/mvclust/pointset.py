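"""Point sets with per-entry missingness masks.

A :class:`PointSet` is an n x d table of real features with a boolean
``observed`` mask; missing entries (mask False) are stored as NaN and are
never read by any computation in the package.  All clusterers — the
Bayes-optimal ones and the baselines — consume the same masked object, so
nothing downstream can peek at hidden values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["PointSet"]


@dataclass
class PointSet:
    values: np.ndarray  # (n, d) float64; NaN at unobserved entries
    observed: np.ndarray  # (n, d) bool

    def __init__(self, values, observed: Optional[np.ndarray] = None):
        values = np.array(values, dtype=np.float64, copy=True)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("values must be a nonempty 2-D array")
        if observed is None:
            observed = np.isfinite(values)
        observed = np.asarray(observed, dtype=bool)
        if observed.shape != values.shape:
            raise ValueError("mask shape must match values shape")
        if not np.all(np.isfinite(values[observed])):
            raise ValueError("observed entries must be finite")
        values[~observed] = np.nan
        self.values = values
        self.observed = observed

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return bool(self.observed.all())

    def observed_pattern(self, row: int) -> tuple:
        """Sorted indices of the observed features of one row (0-based)."""
        return tuple(np.flatnonzero(self.observed[row]))

    def subset(self, rows) -> "PointSet":
        rows = np.asarray(rows)
        return PointSet(self.values[rows], self.observed[rows])

    def missing_fraction(self) -> float:
        return float(1.0 - self.observed.mean())
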