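"""Cohort-level statistics: area change, correlation, two-way ANOVA.

Builds a small synthetic cohort of phantoms in three groups with different
stretch levels, measures each subject end-to-end, and runs the statistics
layer: cine relative area change (A_max - A_min)/A_min, the Pearson
correlation between stretch and area change, and the group x quadrant
two-way ANOVA with Tukey ranges.
"""

import numpy as np

import densewall as dw

groups = {
    "volunteer": 1.06,        # compliant young aorta
    "bav_nondilated": 1.03,   # bicuspid valve, non-dilated
    "dilated": 1.01,          # stiff dilated aorta
}

rows, stretches, area_changes = [], [], []
for gi, (g, s0) in enumerate(groups.items()):
    for subject in range(4):
        spec = dw.PhantomSpec(
            stretch_pattern=dw.StretchPattern(s0, ((0.01, 0.0),)),
            snr=25.0, seed=100 * gi + subject,
        )
        acq, truth, delin = dw.make_phantom(spec)
        field = dw.process_acquisition(acq, delin.mask)
        tracked = dw.track_points(dw.seed_points(delin.mid, 100), field)
        summary = dw.quadrant_summary(
            dw.stretch_profile(tracked, center=delin.center)
        )
        for q in dw.QUADRANT_LABELS:
            rows.append((f"{g}{subject}", g, q, summary.per_quadrant[q]))
        stretches.append(summary.overall)
        area_changes.append(
            dw.relative_area_change(dw.make_cine_series(spec, n_frames=10))
        )

r = dw.pearson_r(stretches, area_changes)
print(f"stretch vs relative area change: r = {r:.3f} over {len(stretches)} subjects")

res = dw.stretch_anova(dw.cohort_table(rows))
print("\ntwo-way ANOVA (factors: group, quadrant):")
print(res.effects.round(6).to_string())
print("\nTukey ranges between groups:")
print(res.tukey_group.summary())
# The group effect dominates (different stretch levels), the quadrant
# effect reflects the common 1% anterior-peaked asymmetry, and stretch
# correlates almost perfectly with area change because both are driven by
# the same imposed deformation.
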