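"""Study-scale and desk-scale experiment profiles.

``full_scale_*`` mirror the reference study conditions exactly (42
subjects, 52 classes, 3700-sample segments, 740/150 windows, batch 256,
~5200 iterations scored at the 5000-5009 median window).  ``desk_*`` is a
proportionally scaled profile for CPU-sized experiments: everything —
segment and window geometry, class and subject counts, classifier widths
and the iteration budget — shrinks together, so protocol-level behaviour
(fold structure, augmentation accounting, scoring) is unchanged.
"""

from __future__ import annotations

from .evaluate import TrainConfig
from .models import Conv1DConfig, InceptionConfig
from .preprocess import PreprocessConfig
from .synthdata import CohortSpec


def full_scale_spec(seed: int = 0) -> CohortSpec:
    return CohortSpec(seed=seed)


def full_scale_preprocess() -> PreprocessConfig:
    return PreprocessConfig()


def full_scale_train(seed: int = 0) -> TrainConfig:
    return TrainConfig(seed=seed)


def full_scale_conv1d() -> Conv1DConfig:
    return Conv1DConfig()


def full_scale_inception() -> InceptionConfig:
    return InceptionConfig()


# --- desk scale -----------------------------------------------------------

#: Desk cohort: 8 classes, 6 ND + 6 stroke subjects, 640-sample segments.
def desk_spec(seed: int = 0, n_nd: int = 6, n_stroke: int = 6) -> CohortSpec:
    return CohortSpec(
        n_nd=n_nd,
        n_stroke=n_stroke,
        n_classes=8,
        n_reps=5,
        segment_len=640,
        seed=seed,
    )


def desk_preprocess() -> PreprocessConfig:
    """640 -> 5 windows of 128 at stride 128; divisors estimated per cohort."""
    return PreprocessConfig(
        target_len=640,
        window_len=128,
        stride=128,
        smooth_len=4,
        divisor_mode="estimate",
    )


def desk_train(seed: int = 0) -> TrainConfig:
    return TrainConfig(
        batch_size=64,
        total_iterations=600,
        eval_window=(550, 559),
        eval_every=100,
        seed=seed,
    )


def desk_conv1d(n_classes: int = 8) -> Conv1DConfig:
    # no dropout at desk scale: with a 600-iteration budget dropout acts as
    # a substitute regularizer and masks the marginal value of augmentation
    return Conv1DConfig(
        conv_channels=(16, 32, 64, 128),
        dense_units=(256, 128, n_classes),
        dropout_p=0.0,
        input_len=128,
    )


def desk_inception(n_classes: int = 8) -> InceptionConfig:
    return InceptionConfig(
        n_modules=3,
        n_filters=8,
        kernel_sizes=(5, 10, 20),
        bottleneck_channels=8,
        n_classes=n_classes,
    )
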