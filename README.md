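# densewall

Circumferential wall-stretch analysis of the ascending aorta from
displacement-encoded (DENSE) MR phase images.

Aortic stiffness predicts cardiovascular events, but the standard imaging
measures (pulse-wave velocity, distensibility from cross-sectional area
change) integrate stiffness around the whole circumference. Aortic disease
— bicuspid-valve aortopathy in particular — is often *asymmetric*, so a
regional measure is needed. DENSE encodes tissue displacement in the MR
signal phase, `phi = 2*pi*k_e*(u . e)`, which makes the displacement of a
wall only 2-3 mm thick measurable without resolving anatomical features.
`densewall` implements the full post-processing chain:

1. spline delineation of the wall with low-magnitude pixel exclusion;
2. certainty-weighted normalized averaging of the wrapped phases and
   least-squares (Poisson) phase unwrapping;
3. decoding of 3-D displacement from balanced multi-point encodings;
4. tracking of 100 equidistant mid-wall points from diastole to systole,
   regularized with a 5-piece periodic spline;
5. per-segment stretch `lambda = L_systolic / L_diastolic` and quadrant
   statistics: mean stretch per anterior/right/posterior/left sector and
   the relative stretch difference `(S_quadrant - S_overall)/S_overall`;
6. cohort statistics: cine cross-sectional area change
   `(A_max - A_min)/A_min`, Pearson correlation, and a group x quadrant
   two-way ANOVA with Tukey ranges.

Because no patient DENSE data is publicly deposited, the package includes
a first-class synthetic phantom: a deforming annulus with an analytic
circumferential stretch pattern `s(theta) = s0 + sum a_k cos(k*theta +
phi_k)`, rigid motion, through-plane shift, partial-volume rendering and
complex Gaussian noise, providing exact ground truth for every stage.
See `docs/methods.md` for the model and numerical choices.

## Worked example

```python
import numpy as np
import densewall as dw

# anterior-peaked stretch: s(theta) = 1.05 + 0.03 cos(theta)
spec = dw.PhantomSpec(stretch_pattern=dw.StretchPattern(1.05, ((0.03, 0.0),)))
acq, truth, delin = dw.make_phantom(spec)

field = dw.process_acquisition(acq, delin.mask)          # phase -> displacement
seeds = dw.seed_points(delin.mid, 100)                   # diastolic mid-wall
tracked = dw.track_points(seeds, field)                  # systolic positions
profile = dw.stretch_profile(tracked, center=delin.center)
summary = dw.quadrant_summary(profile)

print(f"overall stretch: {summary.overall_percent:.2f}%")
for q in dw.QUADRANT_LABELS:
    print(f"  {q}: {100*summary.per_quadrant[q]:6.2f}%  "
          f"rel. diff {100*summary.rel_diff[q]:+5.2f}%")
```

prints

```
overall stretch: 104.92%
  A: 107.39%  rel. diff +2.36%
  R: 105.02%  rel. diff +0.09%
  P: 102.43%  rel. diff -2.37%
  L: 104.93%  rel. diff +0.02%
```

i.e. the pipeline recovers the imposed asymmetry: the anterior quadrant
stretches ~5% more than average (true value 107.7%), the posterior ~2.4%
less, and the overall stretch is within 0.1 percentage points of the
analytic circumferential mean. The `examples/` directory holds one short
script per capability (phantom synthesis, phase processing, quadrant
stretch, cohort statistics).

A thin CLI mirrors the library: `densewall simulate | convert | validate |
process | stretch | report | run`, with `run` executing the whole chain
from one YAML config and writing a manifest with config hash, seed and
per-file checksums (re-running an identical config is bit-identical).

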