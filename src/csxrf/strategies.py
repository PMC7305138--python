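"""Scan controllers: full raster, sparse+mask, conditional, dynamic, priority, combined.

All strategies share conventions:

* scan order is plain row-major raster;
* threshold comparisons use ``>=`` for "above" and ``<`` for "below", so
  ties fire the "above" branch;
* a single RNG stream is consumed in acquisition order and strategy
  decisions never consume randomness;
* each grid point appears at most once in the resulting log — the dynamic
  and priority scans merge their fast probe and top-up exposure into one
  record whose dwell is the selected total (Poisson additivity makes the
  merged spectrum statistically identical to a single long exposure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import PlanError
from .instrument import (
    AcquiredPoint,
    AcquisitionLog,
    ROIWindow,
    acquire_stxm_map,
    acquire_xrf_point,
    roi_sum,
)
from .phantom import Phantom

__all__ = [
    "Mask",
    "ScanPlan",
    "DecisionRule",
    "PriorityRule",
    "mask_from_preview",
    "full_raster_plan",
    "plan_sparse_masked",
    "run_plan",
    "run_full_raster",
    "run_conditional_scan",
    "run_dynamic_scan",
    "run_priority_scan",
    "run_combined_scan",
]

Mask = np.ndarray  # boolean grid, True = region of interest (dense scanning)


@dataclass(frozen=True)
class DecisionRule:
    """Per-point acquire/skip decision on a scalar signal.

    ``source`` is ``"transmission"`` or ``"roi"`` (with ``roi`` set);
    ``side`` is ``"above"`` (fire when signal >= threshold) or ``"below"``
    (fire when signal < threshold).  ``threshold`` may be ``+/-inf`` as a
    degenerate always/never sentinel.
    """

    source: str
    threshold: float
    side: str = "above"
    roi: ROIWindow | None = None

    def __post_init__(self) -> None:
        if self.source not in ("transmission", "roi"):
            raise ValueError(f"unknown signal source {self.source!r}")
        if self.side not in ("above", "below"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.source == "roi" and self.roi is None:
            raise ValueError("roi source requires an ROIWindow")
        if np.isnan(self.threshold):
            raise ValueError("threshold must not be NaN")

    def fires(self, value: float) -> bool:
        return value >= self.threshold if self.side == "above" else value < self.threshold


@dataclass(frozen=True)
class PriorityRule:
    """Ordered (ROI, count threshold, dwell) triples plus a default dwell.

    Rules are evaluated in order against the fast probe's ROI sums; the
    first rule whose ROI count reaches its threshold selects that rule's
    dwell, otherwise ``default_dwell`` applies.  An empty rule list
    degenerates to a constant-dwell scan.
    """

    rules: tuple[tuple[ROIWindow, float, float], ...]
    default_dwell: float

    def __post_init__(self) -> None:
        if self.default_dwell <= 0:
            raise ValueError("default_dwell must be > 0")
        for roi, _thr, dwell in self.rules:
            if dwell <= 0:
                raise ValueError("rule dwells must be > 0")

    def min_dwell(self) -> float:
        return min([self.default_dwell] + [d for _, _, d in self.rules])

    def select(self, spectrum: np.ndarray) -> float:
        for roi, threshold, dwell in self.rules:
            if roi_sum(spectrum, roi) >= threshold:
                return dwell
        return self.default_dwell


def mask_from_preview(
    preview: np.ndarray, threshold: float, side: str = "below", dilation_radius: int = 0
) -> Mask:
    """Threshold a preview map into a region-of-interest mask, then dilate.

    ``side="below"`` marks pixels with ``preview < threshold`` (the usual
    case for transmission previews: dense objects absorb); ``"above"`` marks
    ``preview >= threshold``.  Dilation uses a square structuring element of
    half-width ``dilation_radius``, deliberately widening the mask e.g. to
    tolerate specimen drift during the scan.
    """
    if side not in ("above", "below"):
        raise ValueError(f"unknown side {side!r}")
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be >= 0")
    preview = np.asarray(preview)
    if preview.ndim != 2:
        raise ValueError("preview must be a 2-D map")
    mask = preview >= threshold if side == "above" else preview < threshold
    if dilation_radius > 0 and mask.any():
        size = 2 * dilation_radius + 1
        mask = ndimage.binary_dilation(mask, structure=np.ones((size, size), bool))
    return mask


@dataclass
class ScanPlan:
    """Ordered (row, col, dwell) positions to visit."""

    shape: tuple[int, int]
    points: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        if not self.points:
            raise PlanError("scan plan is empty")
        rows, cols = self.shape
        seen: set[tuple[int, int]] = set()
        for r, c, dwell in self.points:
            if not (0 <= r < rows and 0 <= c < cols):
                raise PlanError(f"planned point ({r}, {c}) outside grid {self.shape}")
            if dwell <= 0:
                raise PlanError(f"planned dwell at ({r}, {c}) must be > 0")
            if (r, c) in seen:
                raise PlanError(f"duplicate planned point ({r}, {c})")
            seen.add((r, c))

    def __len__(self) -> int:
        return len(self.points)


def full_raster_plan(shape: tuple[int, int], dwell: float) -> ScanPlan:
    """Every grid point at constant ``dwell``, row-major."""
    rows, cols = shape
    return ScanPlan(shape, [(r, c, dwell) for r in range(rows) for c in range(cols)])


def _sparse_selector(
    shape: tuple[int, int],
    stride: int | None,
    phase: int,
    density: float | None,
    pattern_seed: int,
) -> np.ndarray:
    """Boolean grid of sparse sample positions (before masking)."""
    rows, cols = shape
    if (stride is None) == (density is None):
        raise PlanError("specify exactly one of stride or density")
    if stride is not None:
        if stride < 1:
            raise PlanError("stride must be >= 1")
        sel = np.zeros(shape, bool)
        sel[phase % stride :: stride, phase % stride :: stride] = True
        return sel
    if not (0 < density <= 1):
        raise PlanError("density must be in (0, 1]")
    rng = np.random.default_rng(pattern_seed)
    return rng.random(shape) < density


def plan_sparse_masked(
    mask: Mask,
    dense_dwell: float,
    sparse_dwell: float,
    *,
    stride: int | None = None,
    phase: int = 0,
    density: float | None = None,
    pattern_seed: int = 0,
) -> ScanPlan:
    """Dense raster inside the mask, sparse sampling outside.

    Every masked-true point enters the plan at ``dense_dwell``.  Outside the
    mask, points on the stride-``k`` sublattice (rows and cols congruent to
    ``phase`` mod ``k``) or an independent Bernoulli(``density``) draw
    (seeded by ``pattern_seed``) enter at ``sparse_dwell``.  Row-major order.
    """
    mask = np.asarray(mask, bool)
    sel = _sparse_selector(mask.shape, stride, phase, density, pattern_seed)
    points: list[tuple[int, int, float]] = []
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c]:
                points.append((r, c, dense_dwell))
            elif sel[r, c]:
                points.append((r, c, sparse_dwell))
    if not points:
        raise PlanError("sparse plan selected no points (all-false mask, empty pattern)")
    return ScanPlan(mask.shape, points)


def _as_rng(rng: np.random.Generator | int | None) -> tuple[np.random.Generator, int | None]:
    if isinstance(rng, np.random.Generator):
        return rng, None
    seed = rng
    return np.random.default_rng(seed), seed


def run_plan(
    phantom: Phantom,
    plan: ScanPlan,
    rng: np.random.Generator | int | None = None,
    *,
    overhead: float = 0.0,
    expected_mode: bool = False,
) -> AcquisitionLog:
    """Acquire one XRF point per planned position, in plan order."""
    gen, seed = _as_rng(rng)
    log = AcquisitionLog(
        shape=plan.shape, overhead=overhead, seed=seed,
        expected_mode=expected_mode, strategy="plan",
        params={"overhead": overhead, "expected_mode": expected_mode},
    )
    for i, (r, c, dwell) in enumerate(plan.points):
        log.points.append(
            acquire_xrf_point(phantom, (r, c), dwell, gen,
                              expected_mode=expected_mode, order_index=i)
        )
    return log


def run_full_raster(
    phantom: Phantom,
    dwell: float,
    rng: np.random.Generator | int | None = None,
    *,
    overhead: float = 0.0,
    expected_mode: bool = False,
) -> AcquisitionLog:
    """Traditional constant-dwell raster of the whole grid."""
    log = run_plan(phantom, full_raster_plan(phantom.shape, dwell), rng,
                   overhead=overhead, expected_mode=expected_mode)
    log.strategy = "full"
    log.params = {"dwell": dwell, "overhead": overhead, "expected_mode": expected_mode}
    return log


def run_conditional_scan(
    phantom: Phantom,
    rule: DecisionRule,
    stxm_dwell: float,
    xrf_dwell: float,
    rng: np.random.Generator | int | None = None,
    *,
    overhead: float = 0.0,
    stxm_noise_sigma: float = 0.0,
    expected_mode: bool = False,
) -> AcquisitionLog:
    """STXM-gated scan: transmission everywhere, XRF only where the rule fires.

    The fast transmission channel is read at every grid point (charged at
    ``stxm_dwell`` each); the far slower XRF exposure (``xrf_dwell``) is
    spent only where the transmission satisfies the decision rule.
    """
    if rule.source != "transmission":
        raise ValueError("conditional scan gates on the transmission signal")
    gen, seed = _as_rng(rng)
    tmap = acquire_stxm_map(phantom, stxm_dwell, gen, noise_sigma=stxm_noise_sigma)
    rows, cols = phantom.shape
    log = AcquisitionLog(
        shape=phantom.shape, overhead=overhead, seed=seed,
        stxm_total=rows * cols * stxm_dwell, transmission_map=tmap,
        expected_mode=expected_mode, strategy="conditional",
        params={
            "threshold": rule.threshold, "side": rule.side,
            "stxm_dwell": stxm_dwell, "xrf_dwell": xrf_dwell,
            "overhead": overhead, "stxm_noise_sigma": stxm_noise_sigma,
            "expected_mode": expected_mode,
        },
    )
    i = 0
    for r in range(rows):
        for c in range(cols):
            t = float(tmap[r, c])
            if rule.fires(t):
                log.points.append(
                    acquire_xrf_point(phantom, (r, c), xrf_dwell, gen,
                                      expected_mode=expected_mode,
                                      transmission=t, order_index=i)
                )
                i += 1
    return log


def run_dynamic_scan(
    phantom: Phantom,
    roi: ROIWindow,
    count_threshold: float,
    fast_dwell: float,
    slow_dwell: float,
    rng: np.random.Generator | int | None = None,
    *,
    overhead: float = 0.0,
    expected_mode: bool = False,
) -> AcquisitionLog:
    """Adaptive-dwell scan driven by a fast XRF probe.

    Every point is first exposed for ``fast_dwell``; if the probe's ROI
    count reaches ``count_threshold``, an additional ``slow_dwell -
    fast_dwell`` exposure is taken and merged, so the recorded point carries
    the full ``slow_dwell`` and the summed spectrum.  Otherwise the fast
    record stands.  Every grid point appears exactly once.
    """
    if fast_dwell <= 0 or slow_dwell <= 0:
        raise ValueError("dwells must be > 0")
    if fast_dwell >= slow_dwell:
        raise ValueError("fast_dwell must be < slow_dwell")
    roi.validate_for(phantom.detector.n_channels)
    gen, seed = _as_rng(rng)
    rows, cols = phantom.shape
    log = AcquisitionLog(
        shape=phantom.shape, overhead=overhead, seed=seed,
        expected_mode=expected_mode, strategy="dynamic",
        params={
            "roi_lo": roi.lo, "roi_hi": roi.hi,
            "count_threshold": count_threshold,
            "fast_dwell": fast_dwell, "slow_dwell": slow_dwell,
            "overhead": overhead, "expected_mode": expected_mode,
        },
    )
    i = 0
    for r in range(rows):
        for c in range(cols):
            fast = acquire_xrf_point(phantom, (r, c), fast_dwell, gen,
                                     expected_mode=expected_mode, order_index=i)
            if roi_sum(fast.spectrum, roi) >= count_threshold:
                top = acquire_xrf_point(phantom, (r, c), slow_dwell - fast_dwell, gen,
                                        expected_mode=expected_mode)
                fast = AcquiredPoint(r, c, slow_dwell, fast.spectrum + top.spectrum,
                                     order_index=i)
            log.points.append(fast)
            i += 1
    return log


def run_priority_scan(
    phantom: Phantom,
    rules: PriorityRule,
    probe_dwell: float,
    rng: np.random.Generator | int | None = None,
    *,
    overhead: float = 0.0,
    expected_mode: bool = False,
) -> AcquisitionLog:
    """Multi-element priority scan: first matching ROI rule sets the dwell.

    Generalises the dynamic scan to an ordered list of (ROI, threshold,
    dwell) rules — e.g. expose 1.2 s where a high-priority trace element's
    line is present, 0.6 s where a secondary element's is, and 0.2 s on bare
    substrate.  The fast probe is merged into the selected total dwell as in
    :func:`run_dynamic_scan`.
    """
    if probe_dwell <= 0:
        raise ValueError("probe_dwell must be > 0")
    if probe_dwell > rules.min_dwell():
        raise ValueError("probe_dwell must not exceed any selectable dwell")
    for roi, _thr, _d in rules.rules:
        roi.validate_for(phantom.detector.n_channels)
    gen, seed = _as_rng(rng)
    rows, cols = phantom.shape
    log = AcquisitionLog(
        shape=phantom.shape, overhead=overhead, seed=seed,
        expected_mode=expected_mode, strategy="priority",
        params={
            "rules": [[roi.lo, roi.hi, thr, dwell] for roi, thr, dwell in rules.rules],
            "default_dwell": rules.default_dwell, "probe_dwell": probe_dwell,
            "overhead": overhead, "expected_mode": expected_mode,
        },
    )
    i = 0
    for r in range(rows):
        for c in range(cols):
            probe = acquire_xrf_point(phantom, (r, c), probe_dwell, gen,
                                      expected_mode=expected_mode, order_index=i)
            dwell = rules.select(probe.spectrum)
            if dwell > probe_dwell:
                top = acquire_xrf_point(phantom, (r, c), dwell - probe_dwell, gen,
                                        expected_mode=expected_mode)
                probe = AcquiredPoint(r, c, dwell, probe.spectrum + top.spectrum,
                                      order_index=i)
            log.points.append(probe)
            i += 1
    return log


def run_combined_scan(
    phantom: Phantom,
    mask: Mask,
    rule: DecisionRule,
    stxm_dwell: float,
    dense_dwell: float,
    sparse_dwell: float,
    rng: np.random.Generator | int | None = None,
    *,
    stride: int | None = None,
    phase: int = 0,
    density: float | None = None,
    pattern_seed: int = 0,
    overhead: float = 0.0,
    stxm_noise_sigma: float = 0.0,
    expected_mode: bool = False,
) -> AcquisitionLog:
    """Mask + conditional combination.

    Masked-true points are scanned densely at ``dense_dwell``
    unconditionally (the mask is typically drawn wider than the feature to
    tolerate drift).  Outside the mask only the sparse sublattice is
    visited, and XRF is acquired there (at ``sparse_dwell``) only where the
    transmission rule fires.  STXM is read on every visited point.
    """
    if rule.source != "transmission":
        raise ValueError("combined scan gates on the transmission signal")
    mask = np.asarray(mask, bool)
    if mask.shape != phantom.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {phantom.shape}")
    gen, seed = _as_rng(rng)
    tfield = acquire_stxm_map(phantom, stxm_dwell, gen, noise_sigma=stxm_noise_sigma)
    sel = _sparse_selector(mask.shape, stride, phase, density, pattern_seed)
    rows, cols = mask.shape
    tmap = np.full(mask.shape, np.nan)
    log = AcquisitionLog(
        shape=mask.shape, overhead=overhead, seed=seed,
        expected_mode=expected_mode, strategy="combined",
        params={
            "threshold": rule.threshold, "side": rule.side,
            "stxm_dwell": stxm_dwell, "dense_dwell": dense_dwell,
            "sparse_dwell": sparse_dwell, "stride": stride, "phase": phase,
            "density": density, "pattern_seed": pattern_seed,
            "overhead": overhead, "expected_mode": expected_mode,
        },
    )
    i = 0
    n_visited = 0
    for r in range(rows):
        for c in range(cols):
            if not (mask[r, c] or sel[r, c]):
                continue
            n_visited += 1
            t = float(tfield[r, c])
            tmap[r, c] = t
            if mask[r, c]:
                dwell = dense_dwell
            elif rule.fires(t):
                dwell = sparse_dwell
            else:
                continue
            log.points.append(
                acquire_xrf_point(phantom, (r, c), dwell, gen,
                                  expected_mode=expected_mode,
                                  transmission=t, order_index=i)
            )
            i += 1
    log.stxm_total = n_visited * stxm_dwell
    log.transmission_map = tmap
    return log
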