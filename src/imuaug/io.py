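"""Cohort and window-set persistence.

A cohort on disk is a CSV metadata table (subject, group, class,
repetition, severity, array key) next to one HDF5 container holding the
per-segment signal matrices; subject profiles go to a second CSV.  The
round trip is lossless (float64 throughout).  An optional delimited-text
reader ingests externally produced segment tables of the same shape.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .layout import SensorLayout
from .preprocess import WindowSample
from .synthdata import SegmentRecord, SubjectProfile

_META = "segments.csv"
_PROFILES = "profiles.csv"
_ARRAYS = "signals.h5"
_LAYOUT = "layout.json"


def write_cohort(
    out_dir: str | Path,
    segments: list[SegmentRecord],
    profiles: list[SubjectProfile] | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    with h5py.File(out / _ARRAYS, "w") as h5:
        for i, seg in enumerate(segments):
            key = f"seg{i:06d}"
            h5.create_dataset(key, data=seg.signal, dtype="f8")
            rows.append(
                dict(
                    key=key, subject_id=seg.subject_id, group=seg.group,
                    class_id=seg.class_id, rep_idx=seg.rep_idx,
                    n_samples=seg.signal.shape[0],
                )
            )
    pd.DataFrame(rows).to_csv(out / _META, index=False)
    layout = segments[0].layout if segments else SensorLayout()
    (out / _LAYOUT).write_text(json.dumps({"sites": list(layout.sites)}))
    if profiles is not None:
        prows = []
        for p in profiles:
            prows.append(
                dict(
                    subject_id=p.subject_id, group=p.group, severity=p.severity,
                    amplitude_scale=p.amplitude_scale, noise_sd=p.noise_sd,
                    tempo_factor=p.tempo_factor, coherence=p.coherence,
                    duration_jitter=p.duration_jitter, seed=p.seed,
                    affected_side=p.affected_side or "",
                    warp_sd=p.warp_sd, envelope_sd=p.envelope_sd,
                    nuisance_attenuation=p.nuisance_attenuation,
                    orientation=json.dumps(p.orientation),
                )
            )
        pd.DataFrame(prows).to_csv(out / _PROFILES, index=False)
    return out


def read_cohort(
    in_dir: str | Path,
) -> tuple[list[SegmentRecord], list[SubjectProfile] | None]:
    src = Path(in_dir)
    layout = SensorLayout(tuple(json.loads((src / _LAYOUT).read_text())["sites"]))
    meta = pd.read_csv(src / _META)
    segments = []
    with h5py.File(src / _ARRAYS, "r") as h5:
        for row in meta.itertuples():
            segments.append(
                SegmentRecord(
                    subject_id=row.subject_id, group=row.group,
                    class_id=int(row.class_id), rep_idx=int(row.rep_idx),
                    signal=np.asarray(h5[row.key]), layout=layout,
                )
            )
    profiles = None
    ppath = src / _PROFILES
    if ppath.exists():
        profiles = []
        for row in pd.read_csv(ppath, keep_default_na=False).itertuples():
            orientation = json.loads(row.orientation)
            if orientation is not None:
                orientation = tuple((tuple(a), float(ang)) for a, ang in orientation)
            profiles.append(
                SubjectProfile(
                    subject_id=row.subject_id, group=row.group,
                    severity=float(row.severity),
                    amplitude_scale=float(row.amplitude_scale),
                    noise_sd=float(row.noise_sd), orientation=orientation,
                    tempo_factor=float(row.tempo_factor),
                    coherence=float(row.coherence),
                    duration_jitter=float(row.duration_jitter),
                    seed=int(row.seed),
                    affected_side=row.affected_side or None,
                    warp_sd=float(row.warp_sd),
                    envelope_sd=float(row.envelope_sd),
                    nuisance_attenuation=float(row.nuisance_attenuation),
                )
            )
    return segments, profiles


def read_segment_table(
    csv_path: str | Path, layout: SensorLayout | None = None
) -> list[SegmentRecord]:
    """Optional ingestion of a long-format delimited segment table.

    Expected columns: ``subject_id, group, class_id, rep_idx, t, ch0..chN``
    (one row per time point).  Useful for bringing externally recorded
    segments into the pipeline.
    """
    df = pd.read_csv(csv_path)
    ch_cols = [c for c in df.columns if c.startswith("ch")]
    if layout is None:
        if len(ch_cols) % 6:
            raise ValueError("channel count must be a multiple of 6")
        layout = SensorLayout() if len(ch_cols) == 30 else SensorLayout(
            tuple(f"s{i}" for i in range(len(ch_cols) // 6))
        )
    segments = []
    keys = ["subject_id", "group", "class_id", "rep_idx"]
    for (subj, group, cls, rep), sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("t")
        segments.append(
            SegmentRecord(
                subject_id=str(subj), group=str(group), class_id=int(cls),
                rep_idx=int(rep), signal=sub[ch_cols].to_numpy(dtype=float),
                layout=layout,
            )
        )
    return segments


def write_windows(out_path: str | Path, windows: list[WindowSample]) -> Path:
    """Windowed dataset to one HDF5 file with label/provenance columns."""
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    X = np.stack([w.signal for w in windows])
    with h5py.File(out, "w") as h5:
        h5.create_dataset("signals", data=X, dtype="f8")
        h5.create_dataset("class_id", data=[w.class_id for w in windows])
        h5.create_dataset("window_idx", data=[w.window_idx for w in windows])
        h5.create_dataset(
            "subject_id", data=[w.subject_id.encode() for w in windows]
        )
        h5.create_dataset("group", data=[w.group.encode() for w in windows])
        h5.create_dataset("provenance", data=[w.provenance.encode() for w in windows])
        h5.create_dataset(
            "seed", data=[-1 if w.seed is None else w.seed for w in windows]
        )
    return out


def read_windows(path: str | Path) -> list[WindowSample]:
    with h5py.File(path, "r") as h5:
        X = np.asarray(h5["signals"])
        out = []
        for i in range(X.shape[0]):
            seed = int(h5["seed"][i])
            out.append(
                WindowSample(
                    signal=X[i],
                    class_id=int(h5["class_id"][i]),
                    subject_id=h5["subject_id"][i].decode(),
                    group=h5["group"][i].decode(),
                    window_idx=int(h5["window_idx"][i]),
                    provenance=h5["provenance"][i].decode(),
                    seed=None if seed == -1 else seed,
                )
            )
    return out
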