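"""Synthetic multi-subject, multi-class IMU cohorts.

The generator emulates the statistical structure of an upper-extremity ADL
recording study comparing non-disabled (ND) volunteers with hemiparetic
stroke patients: per-class latent movement templates, subject-specific
deviations whose size is controlled by a target inter-subject signal
coherence, severity-coupled amplitude attenuation and slowing on the
affected side, per-sensor mounting-orientation offsets, and white sensor
noise.  Nothing here claims biomechanical realism — the goal is a cohort on
which window segmentation, augmentation and subject-wise cross-validation
behave the way they do on real data.

Model of one rendered segment (channel-wise)::

    x = rotate( resample_time( a * warp( env * ( sqrt(c)*T + sqrt(1-c)*P ) ) ) ) + noise
    P = s_subj * P_subj + s_rep * P_rep,   s_subj^2 + s_rep^2 = 1

where ``T`` is the class template, ``P_subj`` is a smooth additive
perturbation fixed per (subject, class), ``P_rep`` varies per repetition,
``env`` is a smooth positive subject-specific amplitude envelope, ``warp``
a subject-specific monotone time distortion, and ``rotate`` a whole-body
orientation offset (facing direction / posture, shared by all sensors)
composed with small per-sensor mounting jitter.  Inter-subject
decorrelation is therefore
split between an additive component and *nuisance transforms* — timing,
orientation and amplitude-envelope variability — mirroring how impaired
movement differs across patients while remaining class-recognizable.  The
convex mixing keeps total variance independent of ``c`` (group amplitude
contrast is controlled only by the attenuation ``a``); the measured
pairwise correlation of repetition-averaged signals is ``sqrt(c_i*c_j)``
times a nuisance attenuation factor, inverted analytically (additive part)
and by frozen Monte-Carlo constants (nuisance part) so that the measured
cohort coherence hits the configured targets.  Stroke subjects map an
FMA-like severity score to ``c``, warp strength, amplitude and tempo,
making coherence, peak amplitude and downstream classification difficulty
all severity-graded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._seeds import child_rng
from .geometry import rotation_matrix, rotate_columns
from .layout import ACCEL, GYRO, DEFAULT_SITES, SensorLayout

logger = logging.getLogger(__name__)

ND = "ND"
STROKE_RH = "StrokeRH"
STROKE_LH = "StrokeLH"
STROKE_GROUPS = (STROKE_RH, STROKE_LH)

#: Fraction of the repetition-varying perturbation sd relative to the
#: subject-level perturbation sd.  Kept < 1 so that averaging the (default
#: five) repetitions of a subject changes the measured coherence only
#: marginally; the residual bias is absorbed analytically below.
_REP_SD_RATIO = 0.5

#: Share (in sd) of the subject-level additive perturbation that is a
#: class-independent "subject style" curve, identical in every class the
#: subject performs.  Both parts decorrelate subjects equally in the
#: per-class Pearson sense, but the shared part leaves within-subject
#: between-class contrasts untouched — emulating how real inter-subject
#: variability suppresses raw signal correlations far more than it
#: suppresses class discriminability.
_STYLE_SD_SHARE = np.sqrt(0.75)

#: Gaussian length-scales (as a fraction of segment length) of the additive
#: perturbations; both sit below the template bump band (bump widths are
#: 0.04-0.15 of the segment).
_PERT_LS_CLASS = 1.0 / 12.0
_PERT_LS_STYLE = 1.0 / 8.0

#: Repetition count assumed when converting a coherence target into a
#: perturbation scale (the study design's repetitions per movement).
_CAL_N_REPS = 5

#: Multiplicative attenuation of the measured coherence caused by the
#: nuisance transforms (time-warp, orientation offsets, amplitude envelope,
#: noise, length realignment), per group.  Fixed once by Monte-Carlo
#: calibration of the default generator — measuring the cohort coherence
#: with the additive component switched off — then frozen.
_NUISANCE_CAL = {ND: 1.03, STROKE_RH: 0.193, STROKE_LH: 0.193}


def _rep_corrected_coherence(target: float, n_reps: int, nuisance_cal: float) -> float:
    """Internal mixing coefficient whose *measured* coherence hits ``target``.

    Accounts for two effects: repetition averaging shrinks the additive
    perturbation variance from 1 to ``k = s_subj^2 + s_rep^2 / R``, and the
    nuisance transforms attenuate the measured correlation by
    ``nuisance_cal``.  Inverts ``measured = cal * c / (c + (1 - c) * k)``.
    """
    if target >= 1.0:
        return 1.0
    t = min(target / nuisance_cal, 0.995)
    s_subj_sq = 1.0 / (1.0 + _REP_SD_RATIO**2)
    k = s_subj_sq + (1.0 - s_subj_sq) / max(n_reps, 1)
    return float(np.clip(k * t / (1.0 - t + k * t), 1e-4, 1.0))


# ---------------------------------------------------------------------------
# specs and records


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a synthetic cohort.

    Defaults reproduce the reference study conditions: 28 ND + 14 stroke
    subjects, 52 ADL classes x 5 repetitions, 5 six-channel IMUs, raw
    segment lengths around 3700 samples, inter-subject coherence targets
    0.226 (ND) and 0.048 (stroke), and stroke severity uniform over an
    FMA-like 33..66 range (66 = ceiling, carried by ND subjects).
    """

    n_nd: int = 28
    n_stroke: int = 14
    n_classes: int = 52
    n_reps: int = 5
    segment_len: int = 3700
    n_sensors: int = 5
    coherence_nd: float = 0.226
    coherence_stroke: float = 0.048
    amplitude_ratio_stroke: float = 0.6
    severity_range: tuple[float, float] = (33.0, 66.0)
    seed: int = 0
    # --- structural knobs with study-condition defaults ---
    n_stroke_rh: int | None = None  # default: 9/14 of n_stroke, rounded
    noise_sd: float = 0.05  # white noise, relative to channel template sd
    coherence_severity_spread: float = 0.8  # spread of sqrt(c) across severity
    amplitude_severity_spread: float = 0.4
    tempo_slope: float = 0.3  # max fractional slowing at worst severity
    tempo_jitter: float = 0.03
    orientation_sd_deg: float = 10.0  # ND whole-body orientation offset angle sd
    orientation_sd_deg_stroke: float = 90.0  # larger: posture/facing varies widely
    orientation_jitter_deg: float = 10.0  # extra per-sensor mounting jitter
    duration_jitter: float = 0.2  # raw lengths uniform in [1-j, 1+j] * nominal
    gyro_scale: float = 0.4  # gyro channel sd relative to accel channels
    warp_sd_nd: float = 0.12  # sd of the subject time-warp speed multipliers
    warp_sd_stroke: float = 0.3
    warp_severity_spread: float = 0.6  # fractional spread of warp sd with severity
    envelope_sd_nd: float = 0.15  # sd of the smooth amplitude envelope
    envelope_sd_stroke: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_nd", "n_stroke", "n_classes", "n_reps", "segment_len", "n_sensors"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("coherence_nd", "coherence_stroke"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 < self.amplitude_ratio_stroke <= 1.0:
            raise ValueError("amplitude_ratio_stroke must be in (0, 1]")
        lo, hi = self.severity_range
        if not lo <= hi:
            raise ValueError("severity_range must be (min, max) with min <= max")

    @property
    def n_subjects(self) -> int:
        return self.n_nd + self.n_stroke

    def stroke_subgroup_sizes(self) -> tuple[int, int]:
        """(right-hemiparetic, left-hemiparetic) subject counts."""
        if self.n_stroke_rh is not None:
            rh = int(self.n_stroke_rh)
            if not 0 <= rh <= self.n_stroke:
                raise ValueError("n_stroke_rh out of range")
        else:
            rh = int(round(self.n_stroke * 9.0 / 14.0))
            rh = min(max(rh, 1), self.n_stroke) if self.n_stroke > 1 else self.n_stroke
        return rh, self.n_stroke - rh

    def layout(self) -> SensorLayout:
        if self.n_sensors == 5:
            return SensorLayout(DEFAULT_SITES)
        sites = []
        for i in range(self.n_sensors):
            side = "left" if i % 2 == 0 else "right"
            sites.append(f"{side}_s{i // 2}")
        return SensorLayout(tuple(sites))


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one synthetic subject."""

    subject_id: str
    group: str  # ND / StrokeRH / StrokeLH
    severity: float  # FMA-like, severity_range[1] = ceiling (ND value)
    amplitude_scale: float
    noise_sd: float  # relative to per-channel template sd
    orientation: tuple[tuple[tuple[float, float, float], float], ...] | None
    tempo_factor: float
    coherence: float  # target per-subject coherence parameter c
    duration_jitter: float
    seed: int
    affected_side: str | None = None  # 'left'/'right' -> strongest attenuation there
    warp_sd: float = 0.0  # subject time-warp speed-multiplier sd (0 = off)
    envelope_sd: float = 0.0  # smooth amplitude-envelope sd (0 = off)
    nuisance_attenuation: float = 1.0  # frozen Monte-Carlo coherence factor

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be > 0")
        if not 0.0 < self.coherence <= 1.0:
            raise ValueError("coherence must be in (0, 1]")


@dataclass
class SegmentRecord:
    """One annotated movement segment: a T x n_channels signal matrix."""

    subject_id: str
    group: str
    class_id: int
    rep_idx: int
    signal: np.ndarray
    layout: SensorLayout

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2 or sig.shape[1] != self.layout.n_channels:
            raise ValueError(
                f"signal must be T x {self.layout.n_channels}, got {sig.shape}"
            )
        if sig.shape[0] < 2:
            raise ValueError("segment must have at least 2 time points")
        if not np.all(np.isfinite(sig)):
            raise ValueError("segment contains non-finite values")
        self.signal = sig


# ---------------------------------------------------------------------------
# templates


def _smooth_bumps(rng: np.random.Generator, length: int) -> np.ndarray:
    """One smooth multi-peak curve: 3-6 Gaussian bumps, unit sd."""
    n_bumps = int(rng.integers(3, 7))
    t = np.arange(length, dtype=float)
    curve = np.zeros(length)
    for _ in range(n_bumps):
        center = rng.uniform(0.1, 0.9) * (length - 1)
        width = rng.uniform(0.04, 0.15) * length
        amp = rng.normal(0.0, 1.0)
        curve += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    sd = curve.std()
    if sd < 1e-12:  # essentially flat draw; fall back to a single bump
        curve = np.exp(-0.5 * ((t - 0.5 * (length - 1)) / (0.1 * length)) ** 2)
        sd = curve.std()
    return (curve - curve.mean()) / sd


def make_class_templates(
    n_classes: int,
    template_len: int,
    n_channels: int,
    seed: int,
    max_mean_corr: float = 0.5,
    max_redraws: int = 20,
) -> list[np.ndarray]:
    """Smooth per-class latent movement templates.

    Each channel is an independent sum of 3-6 random-amplitude Gaussian
    bumps, centred and scaled to unit standard deviation — a band-limited
    stand-in for multi-peak ADL traces.  A candidate class is redrawn if the
    mean absolute correlation of its flattened template with any existing
    class exceeds ``max_mean_corr``.  Deterministic given ``seed``.
    """
    if n_classes < 1 or template_len < 2 or n_channels < 1:
        raise ValueError("n_classes, n_channels must be >= 1 and template_len >= 2")
    templates: list[np.ndarray] = []
    for k in range(n_classes):
        for attempt in range(max_redraws + 1):
            rng = child_rng(seed, 101, k, attempt)
            tpl = np.column_stack(
                [_smooth_bumps(rng, template_len) for _ in range(n_channels)]
            )
            flat = tpl.ravel()
            ok = all(
                abs(np.corrcoef(flat, other.ravel())[0, 1]) <= max_mean_corr
                for other in templates
            )
            if ok:
                break
        templates.append(tpl)
    return templates


def assemble_imu_template(
    accel_template: np.ndarray, layout: SensorLayout, gyro_scale: float = 0.4
) -> np.ndarray:
    """Full-layout template from accelerometer-like channels.

    ``accel_template`` holds one column per accelerometer channel of the
    layout; gyroscope channels are built as the time-derivatives of the
    matching accelerometer channels, rescaled to ``gyro_scale`` times unit
    sd, giving the two modalities deliberately different scales.
    """
    accel_cols = layout.channels_of(ACCEL)
    gyro_cols = layout.channels_of(GYRO)
    if accel_template.shape[1] != len(accel_cols):
        raise ValueError(
            f"expected {len(accel_cols)} accel channels, got {accel_template.shape[1]}"
        )
    full = np.zeros((accel_template.shape[0], layout.n_channels))
    full[:, accel_cols] = accel_template
    deriv = np.gradient(accel_template, axis=0)
    sd = deriv.std(axis=0)
    sd[sd < 1e-12] = 1.0
    full[:, gyro_cols] = deriv / sd * gyro_scale
    return full


# ---------------------------------------------------------------------------
# rendering


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], length_scale: float) -> np.ndarray:
    """Unit-sd smooth noise per column (Gaussian-filtered white noise)."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter1d(raw, sigma=length_scale, axis=0, mode="nearest")
    sd = sm.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (sm - sm.mean(axis=0)) / sd


def _monotone_warp(
    rng_subj: np.random.Generator,
    rng_rep: np.random.Generator,
    length: int,
    warp_sd: float,
    rep_ratio: float = 0.35,
    n_knots: int = 6,
) -> np.ndarray:
    """Strictly increasing time map with fixed endpoints.

    Built as the normalized cumulative sum of a positive speed curve:
    log-normal speed multipliers at ``n_knots`` knots (a subject-level and
    a weaker repetition-level draw), interpolated shape-preservingly
    (PCHIP, so positivity is kept) over the segment.
    """
    from scipy.interpolate import PchipInterpolator

    v = np.exp(rng_subj.normal(0.0, warp_sd, n_knots))
    v *= np.exp(rng_rep.normal(0.0, warp_sd * rep_ratio, n_knots))
    knots = np.linspace(0.0, length - 1.0, n_knots)
    speed = PchipInterpolator(knots, v)(np.arange(length))
    cum = np.concatenate([[0.0], np.cumsum(speed[:-1])])
    return cum * (length - 1.0) / cum[-1]


def _resample(signal: np.ndarray, new_len: int) -> np.ndarray:
    old_len = signal.shape[0]
    if new_len == old_len:
        return signal.copy()
    x_new = np.linspace(0.0, old_len - 1.0, new_len)
    x_old = np.arange(old_len, dtype=float)
    return np.column_stack([np.interp(x_new, x_old, signal[:, c]) for c in range(signal.shape[1])])


def render_subject_segment(
    template: np.ndarray,
    profile: SubjectProfile,
    rep_idx: int,
    seed: int,
    class_id: int = 1,
    layout: SensorLayout | None = None,
    n_reps_assumed: int = _CAL_N_REPS,
) -> SegmentRecord:
    """Render one repetition of one movement class for one subject.

    Applies, in order: coherence-controlled smooth perturbation (subject-
    and repetition-level), amplitude scaling (whole signal, or only the
    affected-side sensors when ``profile.affected_side`` is set), time
    rescaling by tempo and duration jitter, per-sensor orientation rotation
    (shared by the accelerometer and gyroscope triads of a sensor, as a
    physical mounting offset would be), and white noise.  With the identity
    profile (coherence 1, scale 1, no offsets, no jitter, no noise) the
    output equals the template exactly.
    """
    template = np.asarray(template, dtype=float)
    if layout is None:
        if template.shape[1] % 6:
            raise ValueError("cannot infer layout: channel count not a multiple of 6")
        layout = SensorLayout(tuple(f"s{i}" for i in range(template.shape[1] // 6))) \
            if template.shape[1] != 30 else SensorLayout()
    if template.shape[1] != layout.n_channels:
        raise ValueError(
            f"template has {template.shape[1]} channels, layout expects {layout.n_channels}"
        )
    rng_rep = child_rng(profile.seed, 211, class_id, rep_idx, seed)

    x = template.copy()
    sd_ch = template.std(axis=0)
    sd_ch = np.where(sd_ch < 1e-12, 1.0, sd_ch)

    c = _rep_corrected_coherence(
        profile.coherence, n_reps_assumed, profile.nuisance_attenuation
    )
    if c < 1.0:
        # unit-variance perturbation split between a subject-level part
        # (fixed across repetitions) and a repetition-level part
        s_subj = 1.0 / np.sqrt(1.0 + _REP_SD_RATIO**2)
        s_rep = _REP_SD_RATIO * s_subj
        shape = template.shape
        # perturbations are smoother than the narrowest template bumps, so
        # they dominate the low-frequency band that drives raw-signal Pearson
        # correlations while sparing the mid-band class signatures
        ls = max(template.shape[0] * _PERT_LS_CLASS, 2.0)
        ls_style = max(template.shape[0] * _PERT_LS_STYLE, 2.0)
        w_style = _STYLE_SD_SHARE
        w_class = np.sqrt(1.0 - w_style**2)
        p_style = _smooth_noise(child_rng(profile.seed, 205), shape, ls_style)
        p_class = _smooth_noise(child_rng(profile.seed, 202, class_id), shape, ls)
        p_rep = _smooth_noise(rng_rep, shape, ls)
        pert = s_subj * (w_style * p_style + w_class * p_class) + s_rep * p_rep
        x = np.sqrt(c) * x + np.sqrt(1.0 - c) * sd_ch * pert

    if profile.envelope_sd > 0:
        env = _smooth_noise(
            child_rng(profile.seed, 203, class_id), (template.shape[0], 1),
            max(template.shape[0] / 12.0, 2.0),
        )[:, 0]
        # vigor fluctuations are predominantly downward (weak phases rather
        # than super-bursts), so the envelope's upside is capped
        x = x * np.clip(
            1.0 + profile.envelope_sd * env, 0.2, 1.0 + 0.5 * profile.envelope_sd
        )[:, None]

    if profile.warp_sd > 0:
        warp = _monotone_warp(
            child_rng(profile.seed, 204, class_id), rng_rep,
            template.shape[0], profile.warp_sd,
        )
        t_grid = np.arange(template.shape[0], dtype=float)
        x = np.column_stack(
            [np.interp(warp, t_grid, x[:, ch]) for ch in range(x.shape[1])]
        )

    if profile.affected_side is None:
        x *= profile.amplitude_scale
    else:
        # the affected limb drives the movement, so attenuation shows on all
        # sensors, strongest on the affected side (structural asymmetry)
        a = profile.amplitude_scale
        x *= 0.5 * (1.0 + a)
        cols = layout.channels_of_side(profile.affected_side)
        x[:, cols] *= a / (0.5 * (1.0 + a))

    j = profile.duration_jitter
    stretch = profile.tempo_factor * (rng_rep.uniform(1.0 - j, 1.0 + j) if j > 0 else 1.0)
    new_len = max(int(round(template.shape[0] * stretch)), 2)
    x = _resample(x, new_len)

    if profile.orientation is not None:
        for sensor_idx, (axis, angle_deg) in enumerate(profile.orientation):
            if angle_deg == 0.0:
                continue
            R = rotation_matrix(np.asarray(axis), angle_deg)
            for triad in layout.triads:
                if triad.sensor == layout.sites[sensor_idx]:
                    rotate_columns(x, triad.channels, R)

    if profile.noise_sd > 0:
        x = x + rng_rep.normal(0.0, profile.noise_sd, size=x.shape) * sd_ch

    return SegmentRecord(
        subject_id=profile.subject_id,
        group=profile.group,
        class_id=class_id,
        rep_idx=rep_idx,
        signal=x,
        layout=layout,
    )


# ---------------------------------------------------------------------------
# cohort assembly


def _axis_angle(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (unit) and angle in degrees of a rotation matrix."""
    cos = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.degrees(np.arccos(cos))
    if angle < 1e-9 or angle > 180 - 1e-9:
        return np.array([0.0, 0.0, 1.0]), float(angle)
    v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    return v / np.linalg.norm(v), float(angle)


def _severity_deficit(severity: float, spec: CohortSpec) -> float:
    lo, hi = spec.severity_range
    if hi == lo:
        return 0.0
    return float(np.clip((hi - severity) / (hi - lo), 0.0, 1.0))


def _subject_coherence(spec: CohortSpec, group: str, severity: float) -> float:
    """Severity-graded coherence parameter with group-level mean preserved.

    sqrt(c) is affine in the severity deficit so that the mean pairwise
    correlation E[sqrt(c_i)] * E[sqrt(c_j)] over a uniform severity draw
    stays at the configured group target.
    """
    if group == ND:
        return float(np.clip(spec.coherence_nd, 1e-3, 1.0))
    u = _severity_deficit(severity, spec)
    root = np.sqrt(spec.coherence_stroke) * (1.0 + spec.coherence_severity_spread * (0.5 - u))
    return float(np.clip(root**2, 1e-3, 1.0))


def build_profiles(spec: CohortSpec) -> list[SubjectProfile]:
    """Draw per-subject generative parameters for a cohort spec."""
    layout = spec.layout()
    profiles: list[SubjectProfile] = []
    n_rh, _ = spec.stroke_subgroup_sizes()
    lo, hi = spec.severity_range
    for i in range(spec.n_subjects):
        rng = child_rng(spec.seed, 301, i)
        is_nd = i < spec.n_nd
        if is_nd:
            group, severity, side = ND, hi, None
            amp = 1.0
            tempo = 1.0
            warp_sd = spec.warp_sd_nd
            envelope_sd = spec.envelope_sd_nd
        else:
            k = i - spec.n_nd
            group = STROKE_RH if k < n_rh else STROKE_LH
            side = "right" if group == STROKE_RH else "left"
            severity = float(rng.uniform(lo, hi))
            u = _severity_deficit(severity, spec)
            amp = spec.amplitude_ratio_stroke * (
                1.0 + spec.amplitude_severity_spread * (0.5 - u)
            )
            tempo = 1.0 + spec.tempo_slope * u
            warp_sd = spec.warp_sd_stroke * (
                1.0 + spec.warp_severity_spread * (u - 0.5)
            )
            envelope_sd = spec.envelope_sd_stroke
            # posture/facing deviation grows with impairment severity, so
            # the orientation offset is severity-graded too (mean factor 1)
            orient_factor = 0.6 + 0.8 * u
        if spec.tempo_jitter > 0:
            tempo *= float(rng.uniform(1 - spec.tempo_jitter, 1 + spec.tempo_jitter))
        if is_nd:
            orient_sd = spec.orientation_sd_deg
        else:
            orient_sd = spec.orientation_sd_deg_stroke * orient_factor
        if orient_sd > 0:
            # one whole-body orientation offset (facing direction / posture)
            # shared by all sensors, plus small per-sensor mounting jitter
            def _unit(v):
                n = np.linalg.norm(v)
                return v / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])

            g_axis = _unit(rng.normal(size=3))
            g_angle = float(rng.normal(0.0, orient_sd))
            offsets = []
            for _ in range(layout.n_sensors):
                j_axis = _unit(rng.normal(size=3))
                j_angle = float(rng.normal(0.0, spec.orientation_jitter_deg))
                R = rotation_matrix(g_axis, g_angle) @ rotation_matrix(j_axis, j_angle)
                axis, angle = _axis_angle(R)
                offsets.append((tuple(axis), float(angle)))
            orientation = tuple(offsets)
        else:
            orientation = None
        profiles.append(
            SubjectProfile(
                subject_id=f"{'nd' if is_nd else 'st'}{i:03d}",
                group=group,
                severity=severity,
                amplitude_scale=float(max(amp, 1e-3)),
                noise_sd=spec.noise_sd,
                orientation=orientation,
                tempo_factor=float(tempo),
                coherence=_subject_coherence(spec, group, severity),
                duration_jitter=spec.duration_jitter,
                seed=int(child_rng(spec.seed, 302, i).integers(0, 2**31 - 1)),
                affected_side=side,
                warp_sd=float(max(warp_sd, 0.0)),
                envelope_sd=float(max(envelope_sd, 0.0)),
                nuisance_attenuation=_NUISANCE_CAL[group],
            )
        )
    return profiles


def generate_cohort(spec: CohortSpec) -> tuple[list[SegmentRecord], list[SubjectProfile]]:
    """Generate the full synthetic cohort for ``spec``.

    Returns ``n_subjects * n_classes * n_reps`` segment records plus the
    subject profiles used to render them.  Bitwise deterministic given the
    spec (including its seed).
    """
    layout = spec.layout()
    accel_templates = make_class_templates(
        spec.n_classes, spec.segment_len, len(layout.channels_of(ACCEL)), seed=spec.seed
    )
    templates = [
        assemble_imu_template(t, layout, gyro_scale=spec.gyro_scale) for t in accel_templates
    ]
    profiles = build_profiles(spec)
    segments: list[SegmentRecord] = []
    for s_idx, profile in enumerate(profiles):
        for class_id in range(1, spec.n_classes + 1):
            for rep_idx in range(1, spec.n_reps + 1):
                segments.append(
                    render_subject_segment(
                        templates[class_id - 1],
                        profile,
                        rep_idx,
                        seed=0,
                        class_id=class_id,
                        layout=layout,
                        n_reps_assumed=spec.n_reps,
                    )
                )
    return segments, profiles


# ---------------------------------------------------------------------------
# cohort statistics


def measure_coherence(
    segments: list[SegmentRecord], class_id: int, channel: int
) -> float:
    """Mean pairwise Pearson correlation across subjects for one channel.

    Each subject contributes the mean of their repetitions of ``class_id``
    (after linear length alignment to the median segment length).  Pairs in
    which either signal has zero variance are excluded with a warning.
    """
    by_subject: dict[str, list[np.ndarray]] = {}
    for seg in segments:
        if seg.class_id == class_id:
            by_subject.setdefault(seg.subject_id, []).append(seg.signal[:, channel])
    if len(by_subject) < 2:
        raise ValueError("need segments of at least 2 subjects for this class")
    lengths = [len(s) for sigs in by_subject.values() for s in sigs]
    target_len = int(np.median(lengths))
    means = []
    for sigs in by_subject.values():
        aligned = [
            np.interp(
                np.linspace(0, len(s) - 1, target_len), np.arange(len(s)), s
            )
            for s in sigs
        ]
        means.append(np.mean(aligned, axis=0))
    rs = []
    n = len(means)
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = means[i].std(), means[j].std()
            if si < 1e-12 or sj < 1e-12:
                warnings.warn("zero-variance signal; pair excluded from coherence")
                continue
            rs.append(float(np.corrcoef(means[i], means[j])[0, 1]))
    if not rs:
        raise ValueError("no valid subject pairs (all zero-variance)")
    return float(np.mean(rs))


def mean_cohort_coherence(
    segments: list[SegmentRecord],
    group: str | tuple[str, ...],
    class_ids: list[int] | None = None,
    channels: list[int] | None = None,
) -> float:
    """Coherence averaged over classes and channels within one group."""
    groups = (group,) if isinstance(group, str) else tuple(group)
    segs = [s for s in segments if s.group in groups]
    if not segs:
        raise ValueError(f"no segments for group(s) {groups}")
    if class_ids is None:
        class_ids = sorted({s.class_id for s in segs})
    if channels is None:
        channels = list(range(segs[0].layout.n_channels))
    vals = [measure_coherence(segs, k, ch) for k in class_ids for ch in channels]
    return float(np.mean(vals))


def mean_peak_amplitude(
    segments: list[SegmentRecord], group: str | tuple[str, ...], channels: list[int] | None = None
) -> float:
    """Mean per-segment peak |signal| over the given group and channels."""
    groups = (group,) if isinstance(group, str) else tuple(group)
    segs = [s for s in segments if s.group in groups]
    if not segs:
        raise ValueError(f"no segments for group(s) {groups}")
    if channels is None:
        channels = list(range(segs[0].layout.n_channels))
    return float(np.mean([np.abs(s.signal[:, channels]).max() for s in segs]))
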