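"""Head-movement rejection: static vs moving subject.

The AND of per-frame skin masks shrinks when the head translates during the
clip; clips whose overlap covers < 35% of the frame are rejected.
"""

import pulsemap as pm
from pulsemap.skin_segmentation import motion_filter, per_frame_skin_masks

model = pm.SyntheticSkinModel(noise_sd=0.5)
for label, shift in [("static", (0, 0)), ("moving", (30, 22))]:
    geo = pm.SceneGeometry(height=80, width=80, motion_shift=shift)
    clip, _ = pm.generate_synthetic_clip(model, geo, 120, 30.0, seed=1)
    masks, _ = per_frame_skin_masks(clip, seed=0)
    keep, ratio = motion_filter(masks, clip.height, clip.width)
    verdict = "keep" if keep else "reject"
    print(f"{label:7s} subject: overlap ratio = {ratio:.3f} -> {verdict}")
# The moving subject's mask overlap falls below the 0.35 threshold, so that
# recording would be excluded from analysis, as in dataset curation.
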