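"""Time-budget accounting and reconstruction-quality scoring.

All internal times are seconds; hour/day formatting lives only in the
report layer (:func:`format_duration`).  Per-point motor/readout overhead is
tracked separately from dwell so that dwell-only budgets (the quantity scan
planning reasons about) are directly comparable across strategies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .instrument import AcquisitionLog
from .reconstruction import ElementMap

__all__ = [
    "TimeBudget",
    "raster_time",
    "log_time",
    "time_fraction",
    "fraction_acquired",
    "nrmse",
    "format_duration",
]


@dataclass(frozen=True)
class TimeBudget:
    """Decomposed scan-time account; ``grand_total`` is always the sum."""

    n_points: int
    dwell_total: float
    stxm_total: float = 0.0
    overhead_total: float = 0.0

    @property
    def grand_total(self) -> float:
        return self.dwell_total + self.stxm_total + self.overhead_total

    def __post_init__(self) -> None:
        if min(self.n_points, self.dwell_total, self.stxm_total, self.overhead_total) < 0:
            raise ValueError("time-budget components must be non-negative")


def raster_time(n_rows: int, n_cols: int, dwell: float, overhead_per_point: float = 0.0) -> TimeBudget:
    """Budget of a traditional constant-dwell raster: ``rows * cols * dwell``."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if dwell <= 0:
        raise ValueError("dwell must be > 0")
    if overhead_per_point < 0:
        raise ValueError("overhead must be >= 0")
    n = n_rows * n_cols
    return TimeBudget(n_points=n, dwell_total=n * dwell, overhead_total=n * overhead_per_point)


def log_time(log: AcquisitionLog) -> TimeBudget:
    """Budget actually consumed by a scan log: dwell + STXM charges + overhead."""
    return TimeBudget(
        n_points=log.n_points,
        dwell_total=log.dwell_total,
        stxm_total=log.stxm_total,
        overhead_total=log.n_points * log.overhead,
    )


def time_fraction(reduced: TimeBudget, full: TimeBudget) -> float:
    """``100 * reduced.grand_total / full.grand_total`` (percent)."""
    if full.grand_total <= 0:
        raise ValueError("full budget must be positive")
    return 100.0 * reduced.grand_total / full.grand_total


def fraction_acquired(log: AcquisitionLog) -> float:
    """XRF-acquired points over total grid points, in [0, 1]."""
    rows, cols = log.shape
    return log.n_points / (rows * cols)


def nrmse(values: ElementMap | np.ndarray, reference: ElementMap | np.ndarray) -> float:
    """Root-mean-square error normalised by the reference range (max - min)."""
    a = values.values if isinstance(values, ElementMap) else np.asarray(values, float)
    b = reference.values if isinstance(reference, ElementMap) else np.asarray(reference, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    span = float(b.max() - b.min())
    if span <= 0:
        raise ValueError("reference map is constant; NRMSE undefined")
    return float(np.sqrt(np.mean((a - b) ** 2)) / span)


def format_duration(seconds: float) -> str:
    """Human-readable duration: seconds, then hours or days to one decimal."""
    if seconds < 3600:
        return f"{seconds:.0f} s"
    if seconds < 2 * 86400:
        return f"{seconds / 3600:.1f} hours"
    return f"{seconds / 86400:.1f} days"
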