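"""Extract tCENTRIST texture features from spectrogram images.

The descriptor is 512 histogram bins (upper+lower LTP codes) per block
over a 21-block spatial pyramid -> 10752 values per image, each 256-bin
sub-histogram summing to 1. It is invariant to global intensity shifts,
which the last lines demonstrate.
"""

import numpy as np

import eegspect as es

rec = es.generate_cohort(es.separable_spec(subjects_per_class=1, duration=14, seed=3))[0]
seg = es.preprocess_recording(rec)[0]
img = es.segment_to_image(seg)

fv = es.extract_tcentrist(img.pixels)
print(f"feature vector length: {fv.values.size} (= 512 x {len(fv.block_layout)} blocks)")
sums = fv.values.reshape(-1, 256).sum(axis=1)
print(f"sub-histogram sums: min {sums.min():.6f}, max {sums.max():.6f} (all 1)")

shifted = np.clip(img.pixels.astype(int) + 20, 0, 255)
fv2 = es.extract_tcentrist(shifted.astype(np.uint8))
print(f"max |difference| after +20 intensity shift: "
      f"{np.abs(fv.values - fv2.values).max():.1f} (shift-invariant where unclipped)")
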