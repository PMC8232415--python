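"""Render spectrogram images from EEG segments and check where the energy
sits.

Each 3.5-s segment becomes a 128x128 8-bit image of |STFT| in dB
(0-50 Hz, row 0 = 50 Hz). For a case-class segment the alpha rows
(8-13 Hz) should be visibly darker than for a control segment; the mean
row brightness around alpha is printed for one segment of each class.
"""

import numpy as np

import eegspect as es

cohort = es.generate_cohort(es.separable_spec(subjects_per_class=1, duration=14, seed=5))
for rec in cohort:
    seg = es.preprocess_recording(rec)[0]
    img = es.segment_to_image(seg)
    alpha_rows = (img.freq_axis >= 8) & (img.freq_axis <= 13)
    theta_rows = (img.freq_axis >= 4) & (img.freq_axis <= 8)
    print(f"{rec.class_label.value:8s} image {img.pixels.shape}, "
          f"alpha-row mean {img.pixels[alpha_rows].mean():6.1f}, "
          f"theta-row mean {img.pixels[theta_rows].mean():6.1f}")

# frame-count contract: floor((896 - 64)/16) + 1 = 53 frames
mag, freqs, times = es.compute_stft(seg)
print(f"STFT: {mag.shape[0]} frequency bins x {mag.shape[1]} frames "
      f"({freqs[1] - freqs[0]:g} Hz bins, frames {times[0]:.2f}-{times[-1]:.2f} s)")
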