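"""Compute EH ratios from ground-truth masks and summarize agreement.

On a noiseless cohort the ground-truth-mask EH ratio recovers the true
endolymph fraction to within one pixel per organ. The agreement block
reports the single-score two-way ICC, Pearson r, and Bland-Altman limits
of agreement, overall and per organ type.
"""

import numpy as np

import hydroseg as hs

subjects, manifest = hs.generate_cohort(
    20,
    hs.PhantomSpec(noise_sd=0.0),
    hs.CohortRanges(endolymph_fraction=(0.1, 0.6), noise_sd=(0.0, 0.0)),
    seed=5,
)
report = hs.cohort_eh_report(subjects)
merged = report.merge(
    manifest[["subject_id", "label", "requested_fraction"]], on=["subject_id", "label"]
)
err_px = (merged.gt_ratio - merged.requested_fraction).abs() * merged.gt_total_pixels
print(f"{len(merged)} organ measurements; max |error| = {err_px.max():.2f} pixels")

blocks = hs.agreement_report(
    merged.gt_ratio, merged.requested_fraction, merged.organ_type
)
for name, st in blocks.items():
    ba = st.bland_altman
    print(
        f"{name:>9}: n={st.n_pairs:3d}  ICC={st.icc:.4f} "
        f"CI={st.icc_ci}  r={st.pearson_r:.4f}  "
        f"LoA=[{ba.loa_lower:+.4f}, {ba.loa_upper:+.4f}]"
    )
# ICC ~= 1 and limits of agreement within a pixel's worth of ratio: the
# measurement pipeline itself adds no error beyond rasterization.
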