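# Methods

## Forward model and its assumptions

A specimen is a regular grid of pixels (0-based row/col indices, row-major;
physical step size is metadata only and never enters the math). Each element
*e* contributes one Gaussian emission line. The expected fluorescence rate at
pixel *(r, c)* in MCA channel *ch* is

    rate[ch] = b + Σ_e c_e(r, c) · y_e · g_e[ch]

where *b* is a flat continuum (counts/s/channel), *c_e* ≥ 0 the concentration
field, *y_e* ≥ 0 the yield scale (counts/s per unit concentration at unit
dwell) and *g_e* the line profile. *g_e* is the Gaussian evaluated at
channel-centre energies and renormalised by its discrete sum, so
Σ_ch g_e = 1 exactly and the summed line rate equals *c_e · y_e* regardless
of peak width versus channel width; this makes ROI-sum expectations
closed-form and lets tests assert conservation to 1e-6 relative tolerance.
A line falling entirely off the energy axis degenerates to its nearest
channel rather than vanishing.

Deliberate omissions: attenuation physics, fluorescence yields, solid angle,
pile-up, escape peaks and dead time are not modelled. Transmission is an
independent stored field in [0, 1] because the methods use it only as a
gating signal, not as a physical observable to be predicted.

## Acquisition and randomness

XRF counts are independent Poisson draws with mean rate × dwell per channel.
The STXM channel returns the transmission field with optional Gaussian read
noise (σ default 0, clipped to [0, 1]) and is charged at its own dwell per
visited point. One `numpy.random.Generator` stream per scan run is consumed
strictly in acquisition order; decision logic never consumes randomness, so
a conditional branch cannot shift subsequent draws and identical seed +
request sequence gives a bit-identical log.

`expected_mode` replaces every Poisson draw by its real-valued mean. It
exists to separate decision-logic testing from counting noise: with
well-separated thresholds the dwell maps it produces are exact, and the
merged-exposure invariant (below) holds to machine precision.

## Strategies

Threshold convention everywhere: "above" fires when signal ≥ threshold,
"below" when signal < threshold; ties go to "above". ±inf thresholds are the
degenerate always/never sentinels and every strategy collapses to a full
raster or to zero acquisitions under them (tested).

* **Sparse + mask** — every masked-true pixel is planned at the dense dwell;
  outside the mask either a stride-k sublattice (rows and cols ≡ phase mod
  k; the default pattern) or an independent Bernoulli(p) draw with its own
  pattern seed is planned at the sparse dwell. Masks come from thresholded
  preview maps with optional square-structuring-element dilation
  (half-width = radius); dilation is an explicit user choice, typically used
  to widen a mask against specimen drift.
* **Conditional** — transmission is read at every grid point
  (rows·cols·stxm_dwell charged); XRF is acquired only where the rule fires.
* **Dynamic** — every pixel gets a fast probe; if the probe's ROI count
  reaches the threshold, a top-up of (slow − fast) seconds is acquired and
  merged: the recorded point carries dwell = slow and the summed spectrum.
  Merging rather than double-recording keeps each grid point unique in the
  log, and Poisson additivity makes the merged spectrum distributed exactly
  as a single slow exposure. "Slow" is interpreted as the *total* dwell of a
  fired pixel, not an additional exposure on top of the fast one.
* **Priority** — generalises dynamic to an ordered rule list
  (ROI, count threshold, dwell); first match wins, otherwise the default
  dwell. The probe dwell must not exceed any selectable dwell so the top-up
  is never negative.
* **Combined** — masked pixels are dense and unconditional; outside the mask
  only the sparse sublattice is visited and the conditional rule gates XRF
  there. STXM is charged on visited points only (unlike the pure conditional
  scan, the skipped sublattice complement is never approached).

## Reconstruction

`densify` scatters the point list into a (rows × cols × channels) cube with
per-pixel dwell and an explicit boolean missing mask (missing pixels store
0 counts and 0 dwell — never NaN, since raw counts are integers). Duplicate
positions are an integrity error. `normalize_to_cps` divides by dwell and
flips the units flag; normalising twice is an error because the operation is
not idempotent on the stored values. ROI integration requires counts/s.

**Biharmonic in-painting.** Missing pixels are the unknowns of a sparse
linear system. Interior unknowns (full 13-point neighbourhood in-grid) use
the standard bilaplacian stencil

        1
     2 -8  2
  1 -8 20 -8  1          = 0
     2 -8  2
        1

and any unknown whose 13-point stencil would leave the grid falls back to
the 5-point Laplace stencil restricted to in-grid orthogonal neighbours
(centre coefficient = neighbour count, a zero-flux closure). Known pixels
are moved to the right-hand side. This dialect keeps the system square and
nonsingular for edge-adjacent holes, degenerates to a constant fill when a
single pixel is known, is linear in the data, and leaves known pixels
bit-identical. The solve uses `scipy.sparse.linalg.spsolve`; the test suite
checks it against an independently written dense brute-force solve of the
same stencil equations on random grids up to 12 × 12 at 1e-8 relative
tolerance, and exact recovery of linear fields (which are biharmonic). A
nearest-known-pixel fill is provided as a cheap alternative.

Cube in-painting defaults to per-ROI-map (integrate first, then in-paint
each 2-D map — cheaper, and what is displayed), with per-channel in-painting
available for downstream spectral-fitting workflows; linearity makes the two
routes commute with ROI integration (tested numerically at 1e-8). A
per-channel-in-painted cube keeps its measured dwell map, so synthesised
pixels are identifiable as those with dwell 0.

## Time accounting

All internal times are seconds; `TimeBudget` decomposes a scan into dwell,
STXM and per-point overhead totals with grand_total their sum, and
hours/days formatting lives only in the report layer. Overhead (motor
settling, readout) is a constant per XRF point, default 0, and is reported
separately so dwell-only budgets remain comparable; real instruments show
large and unmodelled overheads (a scan whose dwell budget is ~2 h can take
6 h wall-clock), which is why no attempt is made to predict wall-clock time.
The dynamic-scan arithmetic is reported exactly: 32% of pixels at 7 s plus
68% at 1 s is 41.71% of the full 7 s budget (58.29% saved); rounded
summaries of the same scenario sometimes quote 43%/57%, which would
correspond to a slow fraction near 32.6%.

## Synthetic-data scope

The phantom generator emulates what the strategies respond to: compact
regions of distinct elemental composition on a uniform substrate, with
transmission contrast co-located with concentration, optional multiplicative
log-normal texture, and spectrally separable lines. It does not emulate
spectral overlap between lines, spatially varying background, detector
artefacts, or specimen drift during the scan. Passing tests therefore
demonstrate the correctness of decision logic, time accounting and
reconstruction — not robustness to overlapping peaks or drifting samples,
which on a real instrument are handled by spectral fitting and by widening
masks respectively.

The built-in 5 × 5 three-element specimen (grey substrate everywhere, a
6-pixel red rectangle, a 5-pixel blue disk, disjoint, with non-overlapping
±3σ ROI windows) is the canonical fixture for the priority scan; its
standard rules (thresholds of 2 counts on a 0.2 s probe) separate the
regions deterministically in expected mode because the expected probe ROI
counts are ≈6 (red), ≈4 (blue) and ≈0 (substrate).

Problem sizes used by the test suite and the acceptance script (100 × 100
for the dynamic scenario, 50 × 50 conditional, 64 × 64 sparse/in-painting
with 10–20 random sampling patterns per density, ≤12 × 12 oracle instances)
were chosen as the smallest grids on which the measured fractions are exact
or the stochastic comparisons are well-resolved.

## Numerical choices and degenerate inputs

* ROI windows are inclusive channel ranges; `roi_for_element` clips ±kσ
  windows to the energy axis and falls back to the single nearest channel
  for off-axis lines.
* Empty scan plans are rejected at planning time; empty *logs* are legal in
  memory (a conditional scan may never fire) but cannot be persisted.
* NRMSE is RMSE divided by the reference range; a constant reference is an
  error rather than a silent 0/0.
* Scan files store spectra as uint32 (float64 for expected-mode logs, which
  are real-valued by construction), positions as int32 grid indices, dwell
  and transmission as float64; a schema_version attribute guards layout
  changes. Regeneration from embedded metadata is supported for the
  parameter-only strategies (full, conditional, dynamic, priority); sparse
  and combined scans depend on an externally supplied mask, which scalar
  metadata cannot reconstruct.

## Known limitations

Acquisition is simulated point-by-point in Python — adequate for the grid
sizes above, not for megapixel simulation (megapixel *budgets* are computed
analytically). Fly scans, variable-velocity scans, phase-contrast gating,
spectral fitting as a decision signal and learned in-painting are out of
scope. The biharmonic edge fallback is a documented dialect choice: other
software may use different boundary closures and produce slightly different
fills near the grid edge.
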