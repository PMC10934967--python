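import numpy as np
import pytest
from dataclasses import replace

from imuaug.layout import SensorLayout
from imuaug.preprocess import PreprocessConfig, WindowSample, preprocess_cohort
from imuaug.synthdata import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def layout() -> SensorLayout:
    return SensorLayout()


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """2 ND + 2 stroke subjects, 3 classes, short segments — fast everywhere."""
    return CohortSpec(
        n_nd=2, n_stroke=2, n_classes=3, n_reps=5, segment_len=120, seed=11
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_preprocess() -> PreprocessConfig:
    return PreprocessConfig(
        target_len=120, window_len=40, stride=20, smooth_len=3, divisor_mode="estimate"
    )


@pytest.fixture(scope="session")
def tiny_windows(tiny_cohort, tiny_preprocess):
    segments, _ = tiny_cohort
    return preprocess_cohort(segments, tiny_preprocess)


def make_windows(n_per_class, n_classes, width=16, n_ch=30, groups=None, seed=0):
    """Hand-built window lists for dataset-level tests."""
    rng = np.random.default_rng(seed)
    out = []
    groups = groups or ["StrokeRH"]
    i = 0
    for cls in range(1, n_classes + 1):
        for k in range(n_per_class):
            g = groups[i % len(groups)]
            out.append(
                WindowSample(
                    signal=rng.normal(size=(width, n_ch)),
                    class_id=cls,
                    subject_id=f"s{i % 4}",
                    group=g,
                    window_idx=k,
                )
            )
            i += 1
    return out
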