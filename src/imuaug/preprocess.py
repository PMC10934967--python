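"""Segment-to-window preprocessing chain.

Raw annotated segments are turned into fixed-length training windows in
five stages, applied in this order per segment:

1. linear interpolation of every channel to a common length ``L``
   (reference value 3700 samples),
2. per-segment, per-channel mean removal,
3. modality scaling — all accelerometer channels divided by one constant
   and all gyroscope channels by another, matching only the between-sensor
   scales (reference constants 2.537 and 0.478, the pooled standard
   deviations of the respective modalities over the reference recordings;
   ``divisor_mode='estimate'`` recomputes them from the cohort at hand),
4. trailing moving-average smoothing over the last ``m`` points (causal;
   the first ``m - 1`` points average over the shorter available prefix),
5. sliding-window segmentation with window length ``W`` and stride ``S``
   (reference 740 / 150, giving 20 windows per 3700-sample segment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layout import ACCEL, GYRO, SensorLayout
from .synthdata import SegmentRecord

ORIGINAL = "original"


@dataclass(frozen=True)
class PreprocessConfig:
    target_len: int = 3700
    window_len: int = 740
    stride: int = 150
    smooth_len: int = 10
    accel_divisor: float = 2.537
    gyro_divisor: float = 0.478
    divisor_mode: str = "fixed"  # 'fixed' or 'estimate'

    def __post_init__(self) -> None:
        if self.window_len > self.target_len:
            raise ValueError("window_len must be <= target_len")
        if self.stride < 1 or self.smooth_len < 1:
            raise ValueError("stride and smooth_len must be >= 1")
        if self.accel_divisor <= 0 or self.gyro_divisor <= 0:
            raise ValueError("divisors must be > 0")
        if self.divisor_mode not in ("fixed", "estimate"):
            raise ValueError("divisor_mode must be 'fixed' or 'estimate'")

    @property
    def n_windows(self) -> int:
        """Windows produced per segment: floor((L - W) / S) + 1."""
        return (self.target_len - self.window_len) // self.stride + 1


@dataclass
class WindowSample:
    """One fixed-length training window with label and provenance."""

    signal: np.ndarray  # W x C
    class_id: int
    subject_id: str
    group: str
    window_idx: int
    provenance: str = ORIGINAL  # original / rotation / permutation / timewarp
    seed: int | None = None

    def with_signal(self, signal: np.ndarray, provenance: str, seed: int) -> "WindowSample":
        return WindowSample(
            signal=signal,
            class_id=self.class_id,
            subject_id=self.subject_id,
            group=self.group,
            window_idx=self.window_idx,
            provenance=provenance,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# stages


def interpolate_to_length(signal: np.ndarray, target_len: int) -> np.ndarray:
    """Linearly resample each channel onto ``target_len`` equispaced points.

    The new time grid spans the original range, so the first and last
    samples are preserved exactly; ``T == target_len`` is the identity.
    """
    signal = np.asarray(signal, dtype=float)
    T = signal.shape[0]
    if T < 2:
        raise ValueError("need at least 2 time points to interpolate")
    if T == target_len:
        return signal.copy()
    x_new = np.linspace(0.0, T - 1.0, target_len)
    x_old = np.arange(T, dtype=float)
    return np.column_stack(
        [np.interp(x_new, x_old, signal[:, c]) for c in range(signal.shape[1])]
    )


def center_channels(signal: np.ndarray) -> np.ndarray:
    """Subtract each channel's mean."""
    signal = np.asarray(signal, dtype=float)
    return signal - signal.mean(axis=0, keepdims=True)


def compute_divisors(
    segments: list[SegmentRecord] | list[np.ndarray], layout: SensorLayout
) -> tuple[float, float]:
    """Pooled standard deviation per modality over all segments.

    Pooled means: one standard deviation over every time point of every
    channel of that modality of every segment, computed around the pooled
    mean.  Homogeneous of degree one in the signals.
    """
    if not segments:
        raise ValueError("need at least one segment")
    accel_cols = layout.channels_of(ACCEL)
    gyro_cols = layout.channels_of(GYRO)
    accel_vals = np.concatenate(
        [np.asarray(getattr(s, "signal", s))[:, accel_cols].ravel() for s in segments]
    )
    gyro_vals = np.concatenate(
        [np.asarray(getattr(s, "signal", s))[:, gyro_cols].ravel() for s in segments]
    )
    accel_sd = float(accel_vals.std())
    gyro_sd = float(gyro_vals.std())
    if accel_sd < 1e-12 or gyro_sd < 1e-12:
        raise ValueError("degenerate input: zero variance in a modality")
    return accel_sd, gyro_sd


def apply_scaling(
    signal: np.ndarray,
    layout: SensorLayout,
    accel_divisor: float,
    gyro_divisor: float,
) -> np.ndarray:
    """Divide accelerometer columns and gyroscope columns by their divisors."""
    if accel_divisor <= 0 or gyro_divisor <= 0:
        raise ValueError("divisors must be positive")
    out = np.asarray(signal, dtype=float).copy()
    out[:, layout.channels_of(ACCEL)] /= accel_divisor
    out[:, layout.channels_of(GYRO)] /= gyro_divisor
    return out


def smooth_trailing_mean(signal: np.ndarray, smooth_len: int) -> np.ndarray:
    """Causal moving average over the last ``smooth_len`` points per channel.

    output[t] = mean(input[max(0, t - m + 1) .. t]); the first ``m - 1``
    points average over the shorter available prefix (no padding).
    """
    if smooth_len < 1:
        raise ValueError("smooth_len must be >= 1")
    signal = np.asarray(signal, dtype=float)
    if smooth_len == 1:
        return signal.copy()
    csum = np.cumsum(signal, axis=0)
    T = signal.shape[0]
    out = np.empty_like(signal)
    m = min(smooth_len, T)
    out[:m] = csum[:m] / np.arange(1, m + 1)[:, None]
    if T > smooth_len:
        out[smooth_len:] = (csum[smooth_len:] - csum[:-smooth_len]) / smooth_len
    return out


def slide_windows(signal: np.ndarray, window_len: int, stride: int) -> list[np.ndarray]:
    """All windows starting at offsets 0, S, 2S, ... with offset + W <= L."""
    signal = np.asarray(signal)
    L = signal.shape[0]
    if window_len > L:
        raise ValueError(f"window_len {window_len} exceeds signal length {L}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return [
        signal[off : off + window_len].copy()
        for off in range(0, L - window_len + 1, stride)
    ]


# ---------------------------------------------------------------------------
# full chain


def preprocess_segment(
    segment: SegmentRecord, config: PreprocessConfig,
    accel_divisor: float | None = None, gyro_divisor: float | None = None,
) -> list[WindowSample]:
    """Run the five-stage chain on one segment."""
    ad = accel_divisor if accel_divisor is not None else config.accel_divisor
    gd = gyro_divisor if gyro_divisor is not None else config.gyro_divisor
    x = interpolate_to_length(segment.signal, config.target_len)
    x = center_channels(x)
    x = apply_scaling(x, segment.layout, ad, gd)
    x = smooth_trailing_mean(x, config.smooth_len)
    windows = slide_windows(x, config.window_len, config.stride)
    return [
        WindowSample(
            signal=w,
            class_id=segment.class_id,
            subject_id=segment.subject_id,
            group=segment.group,
            window_idx=i,
        )
        for i, w in enumerate(windows)
    ]


def preprocess_cohort(
    segments: list[SegmentRecord], config: PreprocessConfig
) -> list[WindowSample]:
    """Preprocess every segment; ``floor((L-W)/S)+1`` windows per segment.

    In ``divisor_mode='estimate'`` the modality divisors are the pooled
    standard deviations of the interpolated, centered cohort, so that the
    scaled accelerometer and gyroscope blocks each have pooled unit sd.
    """
    if not segments:
        return []
    if config.divisor_mode == "estimate":
        centered = [
            center_channels(interpolate_to_length(s.signal, config.target_len))
            for s in segments
        ]
        ad, gd = compute_divisors(centered, segments[0].layout)
    else:
        ad, gd = config.accel_divisor, config.gyro_divisor
    out: list[WindowSample] = []
    for seg in segments:
        out.extend(preprocess_segment(seg, config, ad, gd))
    return out


def stack_windows(windows: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    """(N, W, C) signal tensor and (N,) zero-based label vector."""
    X = np.stack([w.signal for w in windows]).astype(np.float64)
    y = np.array([w.class_id - 1 for w in windows], dtype=np.int64)
    return X, y
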