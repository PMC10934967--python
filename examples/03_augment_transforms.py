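"""Apply the three stochastic window transforms and verify their invariants.

Rotation re-orients each sensor's 3-vector streams (norms preserved),
permutation shuffles four variable-length subsegments (rows preserved),
and time-warping distorts the time axis smoothly (endpoints preserved).
"""

import numpy as np

from imuaug.augment import (
    sample_permutation, sample_rotation, sample_time_warp,
    permute_window, rotate_window, time_warp_window,
)
from imuaug.layout import SensorLayout

layout = SensorLayout()
rng = np.random.default_rng(7)
window = rng.normal(size=(128, 30))

rot = rotate_window(window, layout, [sample_rotation(rng) for _ in layout.triads])
norm_err = max(
    np.abs(np.linalg.norm(rot[:, t.channels], axis=1)
           - np.linalg.norm(window[:, t.channels], axis=1)).max()
    for t in layout.triads
)
print(f"rotation: per-triad vector norms preserved to {norm_err:.1e}")

perm_params = sample_permutation(128, rng)
perm = permute_window(window, perm_params)
print(f"permutation: pieces of lengths {perm_params.cut_lengths} reordered as "
      f"{perm_params.order}; row multiset identical: "
      f"{np.array_equal(np.sort(perm, axis=0), np.sort(window, axis=0))}")

warp_params = sample_time_warp(128, seed=3, sigma=0.2)
warped = time_warp_window(window, warp_params)
print(f"time-warp: mean |displacement| {np.abs(warp_params.warp - np.arange(128)).mean():.1f} "
      f"samples; endpoints unchanged: "
      f"{np.allclose(warped[[0, -1]], window[[0, -1]])}")
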