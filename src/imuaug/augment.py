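"""Stochastic time-series transformations for training-set augmentation.

Three label-preserving window transforms, with full seed control:

- **rotation** — each (sensor, modality) triad's 3-vector is rotated by a
  random axis/angle (axis components uniform on [-1, 1] then normalized,
  angle uniform on [-90°, +90°]), the same rotation at every time point;
- **permutation** — the window is cut into four subsegments of different
  random lengths whose temporal order is shuffled;
- **time-warping** — the time axis is distorted by a smooth, strictly
  increasing warp with fixed endpoints, built from the cumulative sum of a
  positive random speed curve.

Dataset-level helpers add one or two transformed copies of a target
group's windows (single/double augmentation, disjoint seed streams) and
top up under-represented classes to a target count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from ._seeds import child_seed
from .geometry import rotation_matrix
from .layout import SensorLayout
from .preprocess import WindowSample

METHODS = ("rotation", "permutation", "timewarp")

#: Offset between the seed streams of the two copies in double augmentation.
_COPY_SEED_STRIDE = 1_000_003  # large prime


# ---------------------------------------------------------------------------
# parameter types


@dataclass(frozen=True)
class RotationParams:
    axis: tuple[float, float, float]  # unit vector
    angle_deg: float  # in [-90, 90]

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector")
        if abs(self.angle_deg) > 90.0 + 1e-12:
            raise ValueError("|angle| must be <= 90 degrees")


@dataclass(frozen=True)
class PermutationParams:
    cut_lengths: tuple[int, ...]  # lengths of the subsegments, summing to W
    order: tuple[int, ...]  # permutation of 0..n_subsegments-1

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(len(self.cut_lengths))):
            raise ValueError("order must be a permutation of the subsegments")
        if any(l < 1 for l in self.cut_lengths):
            raise ValueError("every subsegment must be non-empty")


@dataclass(frozen=True)
class TimeWarpParams:
    warp: np.ndarray  # strictly increasing, warp[0] = 0, warp[-1] = W - 1

    def __post_init__(self) -> None:
        w = np.asarray(self.warp, dtype=float)
        if w.ndim != 1 or len(w) < 2:
            raise ValueError("warp must be a 1-D map of length >= 2")
        if np.any(np.diff(w) <= 0):
            raise ValueError("warp must be strictly increasing")
        if abs(w[0]) > 1e-9 or abs(w[-1] - (len(w) - 1)) > 1e-9:
            raise ValueError("warp endpoints must be fixed at 0 and W-1")
        object.__setattr__(self, "warp", w)


@dataclass(frozen=True)
class AugmentPlan:
    """Dataset-level augmentation: which transform, how many copies, on whom."""

    method: str  # rotation / permutation / timewarp
    n_copies: int = 1  # 1 = single, 2 = double augmentation
    base_seed: int = 0
    target_groups: tuple[str, ...] = ("StrokeRH", "StrokeLH")
    shared_rotation_per_window: bool = False  # one rotation for all triads

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")

    @property
    def seed_set(self) -> tuple[int, ...]:
        """One disjoint seed stream per copy."""
        return tuple(self.base_seed + k * _COPY_SEED_STRIDE for k in range(self.n_copies))


# ---------------------------------------------------------------------------
# parameter sampling


def sample_rotation(seed: int | np.random.Generator) -> RotationParams:
    """Axis uniform on the cube then normalized; angle uniform on [-90, 90]."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    while True:
        axis = rng.uniform(-1.0, 1.0, size=3)
        norm = np.linalg.norm(axis)
        if norm > 1e-12:
            break
    angle = float(rng.uniform(-90.0, 90.0))
    return RotationParams(axis=tuple(axis / norm), angle_deg=angle)


def sample_permutation(
    window_len: int,
    seed: int | np.random.Generator,
    n_subsegments: int = 4,
    min_len: int | None = None,
) -> PermutationParams:
    """Random cuts into ``n_subsegments`` pieces of different lengths.

    Cut points are drawn uniformly, redrawn until every piece has at least
    ``min_len`` points (default ``max(2, W // 20)``) and the piece lengths
    are not all equal.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if min_len is None:
        min_len = max(2, window_len // 20)
    if n_subsegments * min_len > window_len:
        raise ValueError("window too short for the requested subsegments")
    for _ in range(10_000):
        cuts = np.sort(rng.choice(np.arange(1, window_len), size=n_subsegments - 1, replace=False))
        lengths = np.diff(np.concatenate([[0], cuts, [window_len]]))
        if lengths.min() >= min_len and len(set(lengths.tolist())) > 1:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to draw valid permutation cuts")
    order = tuple(int(i) for i in rng.permutation(n_subsegments))
    return PermutationParams(cut_lengths=tuple(int(l) for l in lengths), order=order)


def sample_time_warp(
    window_len: int,
    seed: int | np.random.Generator,
    n_knots: int = 4,
    sigma: float = 0.2,
    min_speed: float = 0.1,
) -> TimeWarpParams:
    """Smooth random warp from a positive knot-interpolated speed curve.

    ``n_knots`` speed multipliers are drawn from N(1, sigma), clipped below
    at ``min_speed``, cubically interpolated over the window, clipped again
    (cubic interpolation can undershoot), cumulated and renormalized so the
    warp maps [0, W-1] onto itself.  ``sigma = 0`` gives the identity warp.
    """
    if n_knots < 2 or sigma < 0:
        raise ValueError("need n_knots >= 2 and sigma >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    knots_x = np.linspace(0, window_len - 1, n_knots)
    knots_v = np.clip(rng.normal(1.0, sigma, size=n_knots), min_speed, None)
    if sigma == 0:
        return TimeWarpParams(warp=np.arange(window_len, dtype=float))
    speed = CubicSpline(knots_x, knots_v)(np.arange(window_len))
    speed = np.clip(speed, min_speed / 2, None)
    cum = np.concatenate([[0.0], np.cumsum(speed[:-1])])
    warp = cum * (window_len - 1) / cum[-1]
    return TimeWarpParams(warp=warp)


# ---------------------------------------------------------------------------
# window transforms


def rotate_window(
    window: np.ndarray,
    layout: SensorLayout,
    params_per_triad: list[RotationParams] | RotationParams,
) -> np.ndarray:
    """Rotate each triad's 3-vector time series by its rotation.

    ``params_per_triad`` is either one :class:`RotationParams` per layout
    triad (independent rotations, the default sampling granularity) or a
    single shared rotation applied to every triad.  Per-time-point triad
    norms are preserved to machine precision.
    """
    window = np.asarray(window, dtype=float)
    triads = layout.triads
    if window.shape[1] != layout.n_channels:
        raise ValueError("window channel count does not match layout")
    if isinstance(params_per_triad, RotationParams):
        params = [params_per_triad] * len(triads)
    else:
        params = list(params_per_triad)
        if len(params) != len(triads):
            raise ValueError(f"need {len(triads)} rotation params, got {len(params)}")
    out = window.copy()
    for triad, p in zip(triads, params):
        R = rotation_matrix(np.asarray(p.axis), p.angle_deg)
        out[:, triad.channels] = out[:, triad.channels] @ R.T
    return out


def permute_window(window: np.ndarray, params: PermutationParams) -> np.ndarray:
    """Concatenate the window's subsegments in permuted temporal order."""
    window = np.asarray(window)
    if sum(params.cut_lengths) != window.shape[0]:
        raise ValueError("cut lengths do not partition the window")
    bounds = np.concatenate([[0], np.cumsum(params.cut_lengths)])
    pieces = [window[bounds[i] : bounds[i + 1]] for i in range(len(params.cut_lengths))]
    return np.concatenate([pieces[i] for i in params.order], axis=0)


def time_warp_window(window: np.ndarray, params: TimeWarpParams) -> np.ndarray:
    """Resample the window at the warped time points (linear interpolation)."""
    window = np.asarray(window, dtype=float)
    W = window.shape[0]
    if len(params.warp) != W:
        raise ValueError("warp length does not match the window")
    t = np.arange(W, dtype=float)
    return np.column_stack(
        [np.interp(params.warp, t, window[:, c]) for c in range(window.shape[1])]
    )


def transform_window(
    window: np.ndarray,
    method: str,
    layout: SensorLayout,
    seed: int,
    shared_rotation: bool = False,
) -> np.ndarray:
    """Apply one named transform with parameters drawn from ``seed``."""
    rng = np.random.default_rng(seed)
    if method == "rotation":
        if shared_rotation:
            return rotate_window(window, layout, sample_rotation(rng))
        params = [sample_rotation(rng) for _ in layout.triads]
        return rotate_window(window, layout, params)
    if method == "permutation":
        return permute_window(window, sample_permutation(window.shape[0], rng))
    if method == "timewarp":
        return time_warp_window(window, sample_time_warp(window.shape[0], rng))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# dataset-level operations


def augment_dataset(
    windows: list[WindowSample], plan: AugmentPlan, layout: SensorLayout
) -> list[WindowSample]:
    """Originals plus ``n_copies`` transformed copies of the target group.

    Labels are inherited; provenance records the method and the per-window
    seed; non-target windows pass through untouched.  Bitwise deterministic
    given the plan.
    """
    targets = [w for w in windows if w.group in plan.target_groups]
    if not targets:
        raise ValueError(f"no windows of target group(s) {plan.target_groups}")
    out = list(windows)
    for copy_seed in plan.seed_set:
        for idx, w in enumerate(targets):
            seed = child_seed(copy_seed, idx)
            sig = transform_window(
                w.signal, plan.method, layout, seed,
                shared_rotation=plan.shared_rotation_per_window,
            )
            out.append(w.with_signal(sig, provenance=plan.method, seed=seed))
    return out


def transformed_only(
    windows: list[WindowSample], plan: AugmentPlan, layout: SensorLayout
) -> list[WindowSample]:
    """Only the transformed copies (the training set of a TSTR run)."""
    full = augment_dataset(windows, plan, layout)
    return [w for w in full if w.provenance == plan.method]


def balance_by_augmentation(
    windows: list[WindowSample],
    target_count: int,
    method: str,
    layout: SensorLayout,
    seed: int = 0,
) -> list[WindowSample]:
    """Top up every class below ``target_count`` with transformed copies.

    Source windows of a class are cycled; each copy gets a fresh transform
    seed.  Classes at or above ``target_count`` are left unchanged.
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    by_class: dict[int, list[WindowSample]] = {}
    for w in windows:
        by_class.setdefault(w.class_id, []).append(w)
    out = list(windows)
    for class_id in sorted(by_class):
        pool = by_class[class_id]
        if not pool:
            raise ValueError(f"class {class_id} has no windows")
        deficit = target_count - len(pool)
        for j in range(max(deficit, 0)):
            src = pool[j % len(pool)]
            s = child_seed(seed, class_id, j)
            sig = transform_window(src.signal, method, layout, s)
            out.append(src.with_signal(sig, provenance=method, seed=s))
    return out
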