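"""Simulated per-point acquisition and the scan log.

XRF acquisition draws each channel's count independently from a Poisson
distribution with mean ``expected_rate * dwell``; the STXM (transmission)
channel returns the phantom's transmission field, optionally with Gaussian
read noise, and is charged at its own (much shorter) dwell per point.

Two testing affordances are built in:

* ``expected_mode`` substitutes real-valued expected counts (rate x dwell)
  for the Poisson draw, so decision logic can be tested without noise;
* STXM read noise defaults to zero so transmission gating is deterministic.

A scan run consumes a single ``numpy.random.Generator`` stream in acquisition
order; strategy decisions never consume randomness, which keeps conditional
branches reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import IntegrityError
from .phantom import DetectorModel, ElementSpec, Phantom, expected_xrf_rate

__all__ = [
    "ROIWindow",
    "AcquiredPoint",
    "AcquisitionLog",
    "roi_sum",
    "roi_for_element",
    "acquire_xrf_point",
    "acquire_stxm_map",
]


@dataclass(frozen=True)
class ROIWindow:
    """Inclusive channel range covering one emission line."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise ValueError(f"invalid ROI window [{self.lo}, {self.hi}]")

    def validate_for(self, n_channels: int) -> None:
        if self.hi >= n_channels:
            raise ValueError(
                f"ROI window [{self.lo}, {self.hi}] outside spectrum of {n_channels} channels"
            )


def roi_sum(spectrum: np.ndarray, roi: ROIWindow) -> float:
    """Sum of counts over channels ``roi.lo .. roi.hi`` inclusive."""
    roi.validate_for(len(spectrum))
    return spectrum[roi.lo : roi.hi + 1].sum()


def roi_for_element(detector: DetectorModel, element: ElementSpec, k_sigma: float = 3.0) -> ROIWindow:
    """ROI window covering ``element``'s line within +/- ``k_sigma`` sigma, clipped to the axis."""
    e = detector.channel_energies()
    lo_e = element.line_energy - k_sigma * element.peak_sigma
    hi_e = element.line_energy + k_sigma * element.peak_sigma
    inside = np.nonzero((e >= lo_e) & (e <= hi_e))[0]
    if len(inside) == 0:
        ch = int(np.argmin(np.abs(e - element.line_energy)))
        return ROIWindow(ch, ch)
    return ROIWindow(int(inside[0]), int(inside[-1]))


@dataclass
class AcquiredPoint:
    """One acquired scan position.

    ``spectrum`` holds non-negative integer counts per channel (real-valued
    expected counts in expected mode); ``transmission`` is the concurrent
    STXM reading where the strategy collected one.
    """

    row: int
    col: int
    dwell: float
    spectrum: np.ndarray
    transmission: float | None = None
    order_index: int = 0

    def __post_init__(self) -> None:
        if self.dwell <= 0:
            raise ValueError("dwell must be > 0")
        if np.any(self.spectrum < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class AcquisitionLog:
    """Ordered record of everything a scan acquired, with time accounting.

    ``stxm_total`` carries the seconds spent on transmission readings (the
    strategy charges ``stxm_dwell`` per visited point); ``overhead`` is a
    constant per-XRF-point cost.  ``strategy``/``params``/``seed`` hold
    enough metadata to regenerate the log from scratch for parameter-only
    strategies.
    """

    shape: tuple[int, int]
    points: list[AcquiredPoint] = field(default_factory=list)
    overhead: float = 0.0
    seed: int | None = None
    stxm_total: float = 0.0
    transmission_map: np.ndarray | None = None
    expected_mode: bool = False
    strategy: str | None = None
    params: dict | None = None

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def dwell_total(self) -> float:
        return float(sum(p.dwell for p in self.points))

    def positions(self) -> list[tuple[int, int]]:
        return [(p.row, p.col) for p in self.points]

    def __iter__(self) -> Iterator[AcquiredPoint]:
        return iter(self.points)

    def validate(self) -> None:
        rows, cols = self.shape
        seen: set[tuple[int, int]] = set()
        last = -1
        for p in self.points:
            if not (0 <= p.row < rows and 0 <= p.col < cols):
                raise IntegrityError(f"point ({p.row}, {p.col}) outside grid {self.shape}")
            if (p.row, p.col) in seen:
                raise IntegrityError(f"duplicate position ({p.row}, {p.col}) in log")
            seen.add((p.row, p.col))
            if p.order_index <= last:
                raise IntegrityError("order_index must be strictly increasing")
            last = p.order_index


def acquire_xrf_point(
    phantom: Phantom,
    pos: tuple[int, int],
    dwell: float,
    rng: np.random.Generator | None = None,
    *,
    expected_mode: bool = False,
    transmission: float | None = None,
    order_index: int = 0,
) -> AcquiredPoint:
    """Simulate one XRF exposure of ``dwell`` seconds at ``pos``.

    Counts are independent Poisson draws with mean ``rate * dwell`` per
    channel; in expected mode the real-valued means themselves are recorded.
    """
    if dwell <= 0:
        raise ValueError("dwell must be > 0")
    rate = expected_xrf_rate(phantom, pos)
    if expected_mode:
        spectrum = rate * dwell
    else:
        if rng is None:
            raise ValueError("rng is required unless expected_mode is set")
        spectrum = rng.poisson(rate * dwell)
    return AcquiredPoint(
        row=pos[0], col=pos[1], dwell=dwell, spectrum=spectrum,
        transmission=transmission, order_index=order_index,
    )


def acquire_stxm_map(
    phantom: Phantom,
    stxm_dwell: float,
    rng: np.random.Generator | None = None,
    noise_sigma: float = 0.0,
) -> np.ndarray:
    """Full-grid transmission map; time cost is ``rows * cols * stxm_dwell``.

    Read noise is Gaussian with standard deviation ``noise_sigma`` (default
    0, i.e. the exact transmission field) and the result is clipped to
    [0, 1].  The caller charges the elapsed time to the log.
    """
    if stxm_dwell <= 0:
        raise ValueError("stxm_dwell must be > 0")
    t = phantom.transmission.copy()
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("rng is required for noisy STXM acquisition")
        t = np.clip(t + rng.normal(0.0, noise_sigma, t.shape), 0.0, 1.0)
    return t
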