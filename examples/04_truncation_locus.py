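"""Calibrating the under-determined parameters of a truncated APC protein.

A truncation changes two parameters at once -- Axin binding (KD1 fold) and
the destruction complex's beta-catenin binding (k6 fraction) -- but a single
measured TCF level constrains only one degree of freedom.  The calibration
therefore returns a one-dimensional locus of equivalent parameter pairs; a
line is fitted in both abscissa conventions and the better one reported.
Here: the moderate truncation paired with a near-null allele, matched to a
4.9-fold activity elevation.
"""

import numpy as np

import wntapc as w

base = w.KineticParameters()
ctx = w.standard_context()

points = w.calibrate_locus(
    target_tcf=4.9, ctx=ctx, base=base,
    partner=w.build_allele("1638N"),
    kd1_grid=np.geomspace(1.0, 20.0, 10),
)
print("KD1 fold   k6 fraction   achieved TCF")
for p in points:
    if p.feasible:
        print(f"{p.kd1_fold:8.2f}   {p.k6_fraction:11.4f}   {p.achieved_tcf:12.3f}")
    else:
        print(f"{p.kd1_fold:8.2f}   {'infeasible':>11}   (target unreachable with k6 <= 1)")

primary, secondary = w.fit_locus_both(points)
print(f"\nbest-fitting line ({primary.x_convention}):")
print(f"  k6/k6_WT = {primary.slope:.3f} * (KD1/KD1_WT) + {primary.intercept:.3f}")
print(f"  rms residual {primary.rms_residual:.2e} over {primary.n_points} points")
print(f"(alternative convention {secondary.x_convention}: rms {secondary.rms_residual:.2e})")
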