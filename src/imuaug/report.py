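"""Post-hoc analyses: severity correlations, relative gains, feature export.

The individual-level analyses relate each stroke subject's clinical
severity score (FMA-like, higher = better function) and their classifier
F1: severity and F1 are expected to correlate positively, while the
*relative* benefit of augmentation concentrates on subjects with low
baseline performance (negative gain-vs-baseline correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import ConditionResult
from .models import ClassifierHandle
from .preprocess import WindowSample, stack_windows
from .synthdata import STROKE_GROUPS, SubjectProfile


@dataclass
class CorrelationReport:
    pairs: list[tuple[str, float, float]]  # (subject, x, y)
    pearson_r: float
    p_value: float
    n: int


def correlate_severity_f1(
    profiles: list[SubjectProfile], result: ConditionResult
) -> CorrelationReport:
    """Pearson correlation between stroke subjects' severity and their F1.

    The p-value is the two-sided t-transform of r with n - 2 degrees of
    freedom.  Raises on fewer than 3 matched subjects or zero variance.
    """
    sev = {p.subject_id: p.severity for p in profiles if p.group in STROKE_GROUPS}
    pairs = [
        (s, sev[s], f1) for s, f1 in sorted(result.per_subject_f1.items()) if s in sev
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 stroke subjects with severity and F1")
    x = np.array([p[1] for p in pairs])
    y = np.array([p[2] for p in pairs])
    if x.std() < 1e-12 or y.std() < 1e-12:
        raise ValueError("zero variance in severity or F1")
    r, p = stats.pearsonr(x, y)
    return CorrelationReport(pairs=pairs, pearson_r=float(r), p_value=float(p), n=len(pairs))


@dataclass
class GainReport:
    per_subject_gain: dict[str, float]  # percent
    pearson_r: float | None  # gain vs. baseline; None if undefined
    p_value: float | None
    excluded: list[str]


def relative_gain(
    baseline_f1s: dict[str, float], augmented_f1s: dict[str, float]
) -> GainReport:
    """Per-subject percentage F1 increase and its correlation with baseline.

    gain_i = 100 * (aug_i - base_i) / base_i.  Subjects with a zero
    baseline are excluded with a warning; if the gains (or baselines) are
    constant the correlation is reported as undefined (None).
    """
    subjects = sorted(set(baseline_f1s) & set(augmented_f1s))
    if not subjects:
        raise ValueError("no matched subjects")
    gains: dict[str, float] = {}
    excluded: list[str] = []
    for s in subjects:
        base = baseline_f1s[s]
        if base == 0:
            warnings.warn(f"subject {s} has zero baseline F1; excluded from gains")
            excluded.append(s)
            continue
        gains[s] = 100.0 * (augmented_f1s[s] - base) / base
    r = p = None
    if len(gains) >= 3:
        x = np.array([baseline_f1s[s] for s in gains])
        y = np.array([gains[s] for s in gains])
        if x.std() > 1e-12 and y.std() > 1e-12:
            r_, p_ = stats.pearsonr(x, y)
            r, p = float(r_), float(p_)
    return GainReport(per_subject_gain=gains, pearson_r=r, p_value=p, excluded=excluded)


def export_penultimate(
    handle: ClassifierHandle, windows: list[WindowSample]
) -> pd.DataFrame:
    """One penultimate-feature row per window, inference mode.

    Columns ``f0..f{d-1}`` plus ``class_id``, ``subject_id``, ``group`` and
    ``provenance``.  Deterministic (dropout off).
    """
    X, _ = stack_windows(windows)
    feats = handle.penultimate(X)
    if feats.shape[1] != handle.penultimate_dim:
        raise ValueError("penultimate dimension mismatch")
    df = pd.DataFrame(feats, columns=[f"f{i}" for i in range(feats.shape[1])])
    df["class_id"] = [w.class_id for w in windows]
    df["subject_id"] = [w.subject_id for w in windows]
    df["group"] = [w.group for w in windows]
    df["provenance"] = [w.provenance for w in windows]
    return df


def embed_features(feature_matrix: pd.DataFrame, seed: int = 0) -> np.ndarray:
    """2-D embedding of exported features via UMAP (library defaults).

    Integration-only: one 2-vector per row; the embedding geometry itself
    is not part of any contract here.
    """
    import umap  # deferred; optional extra

    cols = [c for c in feature_matrix.columns if c.startswith("f") and c[1:].isdigit()]
    reducer = umap.UMAP(n_components=2, random_state=seed)
    return np.asarray(reducer.fit_transform(feature_matrix[cols].to_numpy()))
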