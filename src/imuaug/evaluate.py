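"""Training and evaluation protocols.

All experiments share one recipe: AdamW (lr 1e-3, betas (0.9, 0.999),
eps 1e-8, weight decay 0.01) minimizing cross-entropy over uniformly
shuffled batches, a fixed *iteration* budget (so enlarging the training set
by augmentation does not grant extra updates), and scoring by the median of
the validation macro-F1 recorded at a fixed late-iteration window
(reference: batch size 256, ~5200 iterations, median over iterations
5000-5009).

Protocols, all subject-wise to rule out identity leakage:

- ``run_losocv`` — leave-one-subject-out over the test group's subjects,
  optionally pooling the other group's data into training and optionally
  adding one or two transformed copies of the stroke training data;
- ``run_tstr`` — train on transformed copies only, test on the held-out
  subject's original windows (train-on-synthetic-test-on-real);
- ``run_transfer`` — pretrain on ND data once, re-instantiate the softmax
  head, fine-tune per fold on stroke data;
- ``run_subsets`` — train on random n-subject stroke subsets and evaluate
  every excluded stroke subject.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import f1_score

from ._seeds import child_rng, child_seed
from .augment import AugmentPlan, augment_dataset, transformed_only
from .layout import SensorLayout
from .models import ClassifierHandle, reinit_final_dense
from .nn import AdamW, softmax_cross_entropy
from .preprocess import ORIGINAL, WindowSample, stack_windows
from .synthdata import ND, STROKE_GROUPS

ModelFactory = Callable[[int], ClassifierHandle]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.01
    batch_size: int = 256
    total_iterations: int = 5200
    eval_window: tuple[int, int] = (5000, 5009)
    eval_every: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.eval_window
        if not (1 <= lo <= hi <= self.total_iterations):
            raise ValueError("eval_window must lie within total_iterations")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class Condition:
    """One experimental condition of the study grid."""

    name: str
    train_groups: tuple[str, ...] = ("Stroke",)  # 'ND' and/or 'Stroke'
    augment_plan: AugmentPlan | None = None
    model: str = "conv1d"
    transfer: bool = False
    tstr: bool = False
    subset_n: int | None = None

    def __post_init__(self) -> None:
        if self.tstr and self.augment_plan is None:
            raise ValueError("a TSTR condition needs an augmentation plan")


@dataclass
class ConditionResult:
    condition: str
    per_subject_f1: dict[str, float]
    trajectories: dict[str, dict[int, float]]
    subject_groups: dict[str, str]
    seed: int

    def group_mean(self, groups: str | tuple[str, ...]) -> float:
        if isinstance(groups, str):
            groups = (groups,) if groups != "Stroke" else STROKE_GROUPS
        vals = [f1 for s, f1 in self.per_subject_f1.items() if self.subject_groups[s] in groups]
        if not vals:
            raise ValueError(f"no subjects in group(s) {groups}")
        return float(np.mean(vals))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(list(self.per_subject_f1.values())))


# ---------------------------------------------------------------------------
# metrics


def macro_f1(predictions: Sequence[int], truths: Sequence[int], n_classes: int) -> float:
    """Unweighted mean of per-class F1 scores.

    Classes absent from both the predictions and the truths do not
    contribute to the mean.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.size == 0 or predictions.shape != truths.shape:
        raise ValueError("predictions and truths must be equal-length and nonempty")
    if predictions.max() >= n_classes or truths.max() >= n_classes or min(
        predictions.min(), truths.min()
    ) < 0:
        raise ValueError("labels out of range")
    labels = np.union1d(predictions, truths)
    return float(f1_score(truths, predictions, labels=labels, average="macro", zero_division=0))


def median_window_f1(trajectory: dict[int, float], eval_window: tuple[int, int]) -> float:
    """Median of the F1 values recorded at every iteration of the window."""
    lo, hi = eval_window
    vals = []
    for it in range(lo, hi + 1):
        if it not in trajectory:
            raise ValueError(f"iteration {it} missing from the trajectory")
        vals.append(trajectory[it])
    return float(statistics.median(vals))


# ---------------------------------------------------------------------------
# training loop


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple):
        return data
    return stack_windows(data)


def train_model(
    handle: ClassifierHandle,
    train_data,
    valid_data,
    config: TrainConfig,
) -> tuple[ClassifierHandle, dict[int, float]]:
    """Train in place; returns the handle and the validation-F1 trajectory.

    ``train_data``/``valid_data`` are window lists or ``(X, y)`` tuples.
    Validation macro-F1 is recorded at every iteration inside
    ``eval_window`` and every ``eval_every`` iterations elsewhere.
    Deterministic given ``config.seed``.
    """
    from .nn import core as _nn_core

    X, y = _as_arrays(train_data)
    if len(X) == 0:
        raise ValueError("empty training set")
    X = np.ascontiguousarray(X, dtype=_nn_core.DTYPE)
    Xv, yv = _as_arrays(valid_data) if valid_data is not None else (None, None)
    if Xv is not None:
        Xv = np.ascontiguousarray(Xv, dtype=_nn_core.DTYPE)
    rng = np.random.default_rng(child_seed(config.seed, 7001))
    opt = AdamW(
        _HandleRoot(handle), lr=config.lr, betas=config.betas,
        eps=config.eps, weight_decay=config.weight_decay,
    )
    n = len(X)
    order = rng.permutation(n)
    pos = 0
    trajectory: dict[int, float] = {}
    lo, hi = config.eval_window
    for it in range(1, config.total_iterations + 1):
        if pos + config.batch_size > n:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos : pos + config.batch_size]
        pos += config.batch_size
        logits = handle.logits(X[idx], train=True, rng=rng)
        loss, dlogits, _ = softmax_cross_entropy(logits, y[idx])
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged: non-finite loss at iteration {it}")
        handle.backward(dlogits)
        opt.step()
        if Xv is not None and (lo <= it <= hi or it % config.eval_every == 0 or it == config.total_iterations):
            preds = handle.predict(Xv)
            trajectory[it] = macro_f1(preds, yv, handle.n_classes)
    return handle, trajectory


class _HandleRoot:
    """Adapter presenting a ClassifierHandle as a single layer tree."""

    def __init__(self, handle: ClassifierHandle) -> None:
        self._handle = handle

    def sublayers(self):
        return self._handle.sublayers()


# ---------------------------------------------------------------------------
# protocols


def _split_groups(windows: list[WindowSample]) -> tuple[list[WindowSample], list[WindowSample]]:
    nd = [w for w in windows if w.group == ND]
    stroke = [w for w in windows if w.group in STROKE_GROUPS]
    return nd, stroke


def _subjects(windows: list[WindowSample]) -> list[str]:
    return sorted({w.subject_id for w in windows})


def _assert_no_leakage(train: list[WindowSample], held_out: str) -> None:
    leaked = [w for w in train if w.subject_id == held_out]
    if leaked:
        raise AssertionError(
            f"leakage: {len(leaked)} training windows belong to held-out subject {held_out}"
        )


def _fold_plan(plan: AugmentPlan | None, fold_idx: int) -> AugmentPlan | None:
    if plan is None:
        return None
    return replace(plan, base_seed=child_seed(plan.base_seed, 9001, fold_idx))


def run_losocv(
    windows: list[WindowSample],
    condition: Condition,
    train_config: TrainConfig,
    model_factory: ModelFactory,
    layout: SensorLayout,
    test_group: str = "Stroke",
) -> ConditionResult:
    """Leave-one-subject-out cross-validation over the test group.

    Each fold trains on all other test-group subjects (plus every subject
    of the other training groups named by the condition), with transformed
    copies of the stroke training windows added per the condition's plan,
    and evaluates every window of the held-out subject.
    """
    nd, stroke = _split_groups(windows)
    test_pool = stroke if test_group == "Stroke" else nd
    subjects = _subjects(test_pool)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects in the test group")
    if any(w.provenance != ORIGINAL for w in windows):
        raise ValueError("protocol input must be original-provenance windows")
    groups_map = {w.subject_id: w.group for w in windows}
    per_subject: dict[str, float] = {}
    trajectories: dict[str, dict[int, float]] = {}
    for fold_idx, held in enumerate(subjects):
        train = [w for w in test_pool if w.subject_id != held]
        if "ND" in condition.train_groups and test_group == "Stroke":
            train = nd + train
        elif test_group != "Stroke" and "Stroke" in condition.train_groups:
            train = train + stroke
        test = [w for w in test_pool if w.subject_id == held]
        if not test:
            raise ValueError(f"subject {held} has no windows")
        plan = _fold_plan(condition.augment_plan, fold_idx)
        if plan is not None:
            if condition.tstr:
                train = transformed_only(train, plan, layout)
            else:
                train = augment_dataset(train, plan, layout)
        _assert_no_leakage(train, held)
        handle = model_factory(child_seed(train_config.seed, 8101, fold_idx))
        fold_cfg = replace(train_config, seed=child_seed(train_config.seed, 8102, fold_idx))
        _, traj = train_model(handle, train, test, fold_cfg)
        per_subject[held] = median_window_f1(traj, train_config.eval_window)
        trajectories[held] = traj
    return ConditionResult(
        condition=condition.name,
        per_subject_f1=per_subject,
        trajectories=trajectories,
        subject_groups=groups_map,
        seed=train_config.seed,
    )


def run_losocv_repeats(
    windows: list[WindowSample],
    condition: Condition,
    train_config: TrainConfig,
    model_factory: ModelFactory,
    layout: SensorLayout,
    n_repeats: int = 3,
) -> list[ConditionResult]:
    """Repeat a LOSOCV condition with fresh transform and training seeds.

    Augmented results depend on the specific transformed-data instance, so
    augmented conditions are run several times (default 3) and summarized
    by their mean; each repetition re-derives the augmentation plan seed
    and the training seed.
    """
    out = []
    for r in range(n_repeats):
        cond = condition
        if condition.augment_plan is not None:
            cond = replace(
                condition,
                augment_plan=replace(
                    condition.augment_plan,
                    base_seed=child_seed(condition.augment_plan.base_seed, 8500, r),
                ),
            )
        cfg = replace(train_config, seed=child_seed(train_config.seed, 8501, r))
        out.append(run_losocv(windows, cond, cfg, model_factory, layout))
    return out


def average_results(results: Sequence[ConditionResult]) -> ConditionResult:
    """Per-subject mean over repeated runs of one condition."""
    if not results:
        raise ValueError("no results to average")
    subjects = results[0].per_subject_f1.keys()
    per_subject = {
        s: float(np.mean([r.per_subject_f1[s] for r in results])) for s in subjects
    }
    return ConditionResult(
        condition=results[0].condition,
        per_subject_f1=per_subject,
        trajectories={},
        subject_groups=results[0].subject_groups,
        seed=results[0].seed,
    )


def run_tstr(
    windows: list[WindowSample],
    method: str,
    train_config: TrainConfig,
    model_factory: ModelFactory,
    layout: SensorLayout,
    n_copies: int = 1,
    base_seed: int = 0,
    shared_rotation: bool = False,
) -> ConditionResult:
    """Train on transformed stroke windows only; test on original windows."""
    condition = Condition(
        name=f"tstr-{method}",
        train_groups=("Stroke",),
        augment_plan=AugmentPlan(
            method=method, n_copies=n_copies, base_seed=base_seed,
            shared_rotation_per_window=shared_rotation,
        ),
        tstr=True,
    )
    return run_losocv(windows, condition, train_config, model_factory, layout)


def run_transfer(
    windows: list[WindowSample],
    augment_plan: AugmentPlan | None,
    train_config: TrainConfig,
    model_factory: ModelFactory,
    layout: SensorLayout,
    pretrain_config: TrainConfig | None = None,
) -> ConditionResult:
    """ND-pretrained fine-tuning over stroke LOSOCV folds.

    Stage 1 trains one model on every ND subject's windows (computed once).
    Stage 2, per fold, clones it, re-instantiates the final dense layer and
    trains on the stroke training windows (plus any augmentation).
    """
    nd, stroke = _split_groups(windows)
    if not nd:
        raise ValueError("transfer learning needs ND subjects for pretraining")
    pre_cfg = pretrain_config or train_config
    pretrained = model_factory(child_seed(pre_cfg.seed, 8201))
    train_model(pretrained, nd, None, pre_cfg)
    subjects = _subjects(stroke)
    groups_map = {w.subject_id: w.group for w in windows}
    per_subject: dict[str, float] = {}
    trajectories: dict[str, dict[int, float]] = {}
    for fold_idx, held in enumerate(subjects):
        train = [w for w in stroke if w.subject_id != held]
        test = [w for w in stroke if w.subject_id == held]
        plan = _fold_plan(augment_plan, fold_idx)
        if plan is not None:
            train = augment_dataset(train, plan, layout)
        _assert_no_leakage(train, held)
        handle = pretrained.clone()
        reinit_final_dense(handle, seed=child_seed(train_config.seed, 8202, fold_idx))
        fold_cfg = replace(train_config, seed=child_seed(train_config.seed, 8203, fold_idx))
        _, traj = train_model(handle, train, test, fold_cfg)
        per_subject[held] = median_window_f1(traj, train_config.eval_window)
        trajectories[held] = traj
    name = "transfer" if augment_plan is None else f"transfer+{augment_plan.method}x{augment_plan.n_copies}"
    return ConditionResult(
        condition=name,
        per_subject_f1=per_subject,
        trajectories=trajectories,
        subject_groups=groups_map,
        seed=train_config.seed,
    )


@dataclass
class SubsetResult:
    n_subjects: int
    plan_name: str
    draw_f1s: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.draw_f1s))

    @property
    def sd(self) -> float:
        return float(np.std(self.draw_f1s))


def percentage_increase(baseline: float, value: float) -> float:
    """100 * (value - baseline) / baseline."""
    if baseline == 0:
        raise ValueError("baseline is zero; percentage increase undefined")
    return 100.0 * (value - baseline) / baseline


def results_to_frame(results: Sequence[ConditionResult]):
    """Tidy per-subject summary: one row per (condition, subject)."""
    import pandas as pd

    rows = []
    for res in results:
        for subj, f1 in sorted(res.per_subject_f1.items()):
            rows.append(
                dict(condition=res.condition, subject_id=subj,
                     group=res.subject_groups[subj], seed=res.seed, f1=f1)
            )
    return pd.DataFrame(rows)


def trajectories_to_frame(result: ConditionResult):
    """Long-format learning curves: (subject, iteration, f1)."""
    import pandas as pd

    rows = [
        dict(condition=result.condition, subject_id=s, iteration=it, f1=f1)
        for s, traj in sorted(result.trajectories.items())
        for it, f1 in sorted(traj.items())
    ]
    return pd.DataFrame(rows)


#: Default draw counts per subset size: smaller subsets are re-drawn more
#: often to tame the variance of the random selection.
DEFAULT_SUBSET_DRAWS = {2: 6, 4: 4, 6: 2, 8: 1, 10: 1, 12: 1}


def run_subsets(
    windows: list[WindowSample],
    n_list: Sequence[int],
    draws_per_n: dict[int, int] | None,
    augment_plans: Sequence[AugmentPlan | None],
    train_config: TrainConfig,
    model_factory: ModelFactory,
    layout: SensorLayout,
    seed: int = 0,
) -> list[SubsetResult]:
    """Random n-subject stroke training subsets, evaluated on the excluded.

    For every ``n`` and every draw, each plan (None = no augmentation)
    trains one model on the subset's windows (transformed copies added per
    plan) and scores the mean over every excluded stroke subject.  Draws
    are shared across plans so augmented and original results are paired.
    """
    if draws_per_n is None:
        draws_per_n = DEFAULT_SUBSET_DRAWS
    _, stroke = _split_groups(windows)
    subjects = _subjects(stroke)
    results: dict[tuple[int, str], SubsetResult] = {}
    for n in n_list:
        if n >= len(subjects):
            raise ValueError(f"subset size {n} must be < {len(subjects)} stroke subjects")
        for draw in range(draws_per_n.get(n, 1)):
            rng = child_rng(seed, 8301, n, draw)
            chosen = set(rng.choice(subjects, size=n, replace=False).tolist())
            excluded = [s for s in subjects if s not in chosen]
            base_train = [w for w in stroke if w.subject_id in chosen]
            for plan in augment_plans:
                plan_name = "original" if plan is None else f"{plan.method}x{plan.n_copies}"
                train = base_train
                if plan is not None:
                    fold_plan = replace(plan, base_seed=child_seed(plan.base_seed, n, draw))
                    train = augment_dataset(base_train, fold_plan, layout)
                for s in excluded:
                    _assert_no_leakage(train, s)
                handle = model_factory(child_seed(train_config.seed, 8302, n, draw))
                cfg = replace(train_config, seed=child_seed(train_config.seed, 8303, n, draw))
                test = [w for w in stroke if w.subject_id in excluded]
                _, traj = train_model(handle, train, test, cfg)
                # per-subject medians, then mean across excluded subjects
                Xv, yv = stack_windows(test)
                subj_arr = np.array([w.subject_id for w in test])
                preds = handle.predict(Xv)
                f1s = [
                    macro_f1(preds[subj_arr == s], yv[subj_arr == s], handle.n_classes)
                    for s in excluded
                ]
                key = (n, plan_name)
                results.setdefault(key, SubsetResult(n, plan_name, [])).draw_f1s.append(
                    float(np.mean(f1s))
                )
    return list(results.values())
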