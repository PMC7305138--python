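"""Why reduced acquisition matters: raster time budgets at realistic dwells.

A typical 100x100 low-energy XRF map at 3 s/pixel already costs a working
day; a megapixel map is infeasible even at 1 s/pixel.  Sparse sampling at
15% with sub-second dwells brings it back into a beamtime shift.
"""

from csxrf import format_duration, raster_time

cases = [
    ("100 x 100 @ 3 s (typical)", raster_time(100, 100, 3.0)),
    ("1000 x 1000 @ 1 s (megapixel)", raster_time(1000, 1000, 1.0)),
]
for label, budget in cases:
    print(f"{label:35s} {budget.grand_total:>12,.0f} s = {format_duration(budget.grand_total)}")

n_sparse = int(0.15 * 1000 * 1000)
for dwell in (0.5, 1.0):
    total = n_sparse * dwell
    print(f"{'1000 x 1000 sparse 15% @ ' + format(dwell, '.1f') + ' s':35s} "
          f"{total:>12,.0f} s = {format_duration(total)}")
# Sparse sampling turns an 11.6-day megapixel scan into of order a day of
# dwell time; masking and conditional gating reduce it further.
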