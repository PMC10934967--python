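"""Run the five-stage preprocessing chain and count the windows it yields.

Interpolation to a fixed length, per-channel centering, modality scaling,
trailing moving-average smoothing, and sliding-window segmentation.  At the
reference geometry (3700-sample segments, 740-sample windows, stride 150)
every segment yields exactly 20 windows.
"""

import numpy as np

from imuaug.preprocess import PreprocessConfig, preprocess_segment, slide_windows
from imuaug.profiles import desk_spec
from imuaug.synthdata import generate_cohort

# reference geometry: the analytic window count
print("windows per 3700-sample segment at 740/150:",
      len(slide_windows(np.zeros((3700, 30)), 740, 150)))

# full chain on a synthetic segment (desk geometry: 640 -> 5 windows of 128)
spec = desk_spec(seed=1)
segments, _ = generate_cohort(spec)
cfg = PreprocessConfig(target_len=640, window_len=128, stride=128,
                       smooth_len=4, divisor_mode="fixed",
                       accel_divisor=2.537, gyro_divisor=0.478)
seg = segments[0]
windows = preprocess_segment(seg, cfg)
print(f"segment {seg.signal.shape} -> {len(windows)} windows of "
      f"{windows[0].signal.shape}, label class {windows[0].class_id}, "
      f"subject {windows[0].subject_id}")
# centering acts on the full segment, before smoothing and windowing
from imuaug.preprocess import center_channels, interpolate_to_length

centered = center_channels(interpolate_to_length(seg.signal, cfg.target_len))
print(f"full-segment channel means after centering: "
      f"max |mean| = {np.abs(centered.mean(axis=0)).max():.1e}")
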