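"""Enumerate the three augmentation scales for one patch.

Low augmentation is purely geometric: 2 flip states x 9 directional shift
states x 8 sampled offsets = 144 variants. Moderate and high add brightness
offsets in -50..50 at step 10 (11 offsets) or step 1 (101 offsets), giving
1,584 and 14,544 variants per original patch.
"""

import hydroseg as hs
from hydroseg.augment import AugmentationPolicy, enumerate_brightness_offsets

spec = hs.PhantomSpec(noise_sd=0.0, seed=0)
subject = hs.generate_subject(spec)
policy = AugmentationPolicy(seed=0)

for scale in ("low", "moderate", "high"):
    variants = hs.augment_patch(
        subject.mrc[1], subject.masks[1], "left", spec.crop, policy, scale=scale
    )
    print(f"{scale:>8}: {len(variants):6d} variants per original patch")

print("brightness offsets, step 10:", enumerate_brightness_offsets(50, 10))
img, mask = variants[10]
print(f"one variant: image {img.shape} {img.dtype}, "
      f"mask labels {sorted(int(v) for v in set(mask.ravel()))}")
# The counts are exact by construction: geometric states x brightness
# offsets; masks are never touched by brightness changes.
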