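"""Shared independent oracles and tiny training helpers for the suite."""

import numpy as np

from imuaug.evaluate import TrainConfig
from imuaug.models import Conv1DConfig, build_conv1d


def brute_rodrigues(v, axis, angle_deg):
    """Rodrigues formula written out directly:
    v' = v cos(t) + (k x v) sin(t) + k (k . v)(1 - cos(t))."""
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    t = np.deg2rad(angle_deg)
    v = np.asarray(v, dtype=float)
    return v * np.cos(t) + np.cross(k, v) * np.sin(t) + k * np.dot(k, v) * (1 - np.cos(t))


TINY_MODEL = Conv1DConfig(
    conv_channels=(4, 8), dense_units=(16, 8, 3), dropout_p=0.2,
    input_len=40, input_channels=30,
)


def tiny_factory(seed: int):
    return build_conv1d(TINY_MODEL, seed=seed)


def fast_config(**kw):
    base = dict(batch_size=16, total_iterations=12, eval_window=(3, 12),
                eval_every=100, seed=1)
    base.update(kw)
    return TrainConfig(**base)
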