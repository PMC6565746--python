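"""Quantify nuclear DNA content from a synthetic confocal z-stack.

Builds a small scene of 40 nuclei (70 % diploid, 30 % tetraploid) plus 12
known-diploid reference nuclei, segments the DAPI channel, computes the
widest-plane FI statistic (mean intensity x ROI pixel area) per nucleus,
calibrates the diploid reference, classifies each nucleus, and prints the
recovered composition next to the ground truth.
"""

import numpy as np

from ploidykit.imaging import match_labels, measure_nuclei, segment_nuclei
from ploidykit.ploidy import calibrate_reference, classify_ploidy, compose
from ploidykit.synth import layout_scene, simulate_confocal_scene

rng = np.random.default_rng(0)
ploidies = [2] * 28 + [4] * 12          # 70 / 30 target mixture
rng.shuffle(ploidies)
ploidies += [2] * 12                     # known-diploid calibration anchors
spec = layout_scene(ploidies, voxel_size_um=(0.4, 0.2, 0.2), n_slices=16, seed=0)
stack, true_labels, truth = simulate_confocal_scene(spec)

labels = segment_nuclei(stack)
meas = measure_nuclei(stack, labels)
print(f"segmented {labels.max()} of {len(truth)} nuclei")

# identify the planted diploid anchors among the segmented nuclei
matched = meas.merge(
    match_labels(labels, true_labels), left_on="nucleus_id", right_on="seg_id"
)
is_anchor = matched["true_id"] > 40      # anchors were placed last
model = calibrate_reference(
    matched.loc[is_anchor, "fi"], method="median", anchor="2n"
)
calls = classify_ploidy(matched.loc[~is_anchor, "fi"].to_numpy(), model)
comp = compose(calls)[0]

print(f"diploid reference FI: {model.reference:,.0f} (arbitrary units)")
for cls in ("2n", "4n", ">4n"):
    print(f"  {cls:>3}: {100 * comp.fractions[cls]:5.1f} %")
print("truth was 70.0 / 30.0 / 0.0 — agreement within a few points is the")
print("expected recovery accuracy of the widest-plane FI statistic.")
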