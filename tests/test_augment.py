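"""Transform invariants and dataset-level augmentation accounting."""

import numpy as np
import pytest

from imuaug.augment import (
    AugmentPlan,
    PermutationParams,
    RotationParams,
    TimeWarpParams,
    augment_dataset,
    balance_by_augmentation,
    permute_window,
    rotate_window,
    sample_permutation,
    sample_rotation,
    sample_time_warp,
    time_warp_window,
    transform_window,
    transformed_only,
)
from conftest import make_windows


def brute_rodrigues(v, axis, angle_deg):
    """Independent Rodrigues oracle: v cosθ + (k x v) sinθ + k (k.v)(1-cosθ)."""
    k = np.asarray(axis) / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    return (
        v * np.cos(th)
        + np.cross(k, v) * np.sin(th)
        + k * np.dot(k, v) * (1 - np.cos(th))
    )


class TestRotation:
    def test_sampling_deterministic(self):
        assert sample_rotation(42) == sample_rotation(42)

    def test_angle_distribution(self):
        rng = np.random.default_rng(0)
        draws = [sample_rotation(rng) for _ in range(10_000)]
        angles = np.array([d.angle_deg for d in draws])
        assert np.all(np.abs(angles) <= 90.0)
        se = 90 / np.sqrt(3) / np.sqrt(len(angles))
        assert abs(angles.mean()) < 3 * se

    def test_axis_always_unit(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = sample_rotation(rng)
            assert np.linalg.norm(p.axis) == pytest.approx(1.0, abs=1e-12)

    def test_zero_angle_is_identity(self, layout):
        w = np.random.default_rng(2).normal(size=(20, 30))
        p = RotationParams(axis=(0.0, 0.0, 1.0), angle_deg=0.0)
        np.testing.assert_allclose(rotate_window(w, layout, p), w)

    def test_right_handed_quarter_turn(self, layout):
        w = np.zeros((1, 30))
        w[0, :3] = [1.0, 0.0, 0.0]
        p = RotationParams(axis=(0.0, 0.0, 1.0), angle_deg=90.0)
        out = rotate_window(w, layout, [p] + [RotationParams((0, 0, 1.0), 0.0)] * 9)
        np.testing.assert_allclose(out[0, :3], [0.0, 1.0, 0.0], atol=1e-12)

    def test_matches_brute_force_rodrigues(self, layout):
        rng = np.random.default_rng(3)
        w = rng.normal(size=(100, 30))
        params = [sample_rotation(rng) for _ in layout.triads]
        out = rotate_window(w, layout, params)
        for triad, p in zip(layout.triads, params):
            for t in range(0, 100, 7):
                expect = brute_rodrigues(w[t, list(triad.channels)], p.axis, p.angle_deg)
                np.testing.assert_allclose(out[t, list(triad.channels)], expect, atol=1e-10)

    def test_triad_norms_preserved(self, layout):
        rng = np.random.default_rng(4)
        w = rng.normal(size=(50, 30))
        out = rotate_window(w, layout, [sample_rotation(rng) for _ in layout.triads])
        for triad in layout.triads:
            n_in = np.linalg.norm(w[:, triad.channels], axis=1)
            n_out = np.linalg.norm(out[:, triad.channels], axis=1)
            assert np.abs(n_in - n_out).max() < 1e-9


class TestPermutation:
    def test_identity_order_unchanged(self):
        w = np.arange(16.0)[:, None]
        p = PermutationParams(cut_lengths=(4, 5, 3, 4), order=(0, 1, 2, 3))
        np.testing.assert_array_equal(permute_window(w, p), w)

    def test_enumerated_rearrangement(self):
        w = np.arange(1, 9.0)[:, None]
        p = PermutationParams(cut_lengths=(2, 2, 2, 2), order=(2, 0, 1, 3))
        np.testing.assert_array_equal(
            permute_window(w, p)[:, 0], [5, 6, 1, 2, 3, 4, 7, 8]
        )

    def test_row_multiset_preserved(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=(64, 6))
        p = sample_permutation(64, rng)
        out = permute_window(w, p)
        np.testing.assert_array_equal(
            np.sort(out, axis=0), np.sort(w, axis=0)
        )

    def test_sampled_pieces_have_different_lengths(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = sample_permutation(128, rng)
            assert len(p.cut_lengths) == 4
            assert sum(p.cut_lengths) == 128
            assert len(set(p.cut_lengths)) > 1
            assert min(p.cut_lengths) >= max(2, 128 // 20)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PermutationParams(cut_lengths=(4, 4), order=(0, 0))
        w = np.zeros((10, 1))
        with pytest.raises(ValueError):
            permute_window(w, PermutationParams(cut_lengths=(4, 4), order=(1, 0)))


class TestTimeWarp:
    def test_sigma_zero_is_identity(self):
        w = np.random.default_rng(7).normal(size=(50, 4))
        p = sample_time_warp(50, seed=1, sigma=0.0)
        np.testing.assert_allclose(time_warp_window(w, p), w)

    def test_constant_channel_invariant(self):
        w = np.full((64, 3), 2.5)
        p = sample_time_warp(64, seed=2, sigma=0.4)
        np.testing.assert_allclose(time_warp_window(w, p), 2.5)

    def test_monotone_input_stays_monotone(self):
        ramp = np.linspace(0, 1, 100)[:, None]
        p = sample_time_warp(100, seed=3, sigma=0.3)
        out = time_warp_window(ramp, p)[:, 0]
        assert np.all(np.diff(out) >= -1e-12)

    def test_endpoints_fixed(self):
        w = np.random.default_rng(8).normal(size=(40, 2))
        p = sample_time_warp(40, seed=4, sigma=0.3)
        out = time_warp_window(w, p)
        np.testing.assert_allclose(out[0], w[0])
        np.testing.assert_allclose(out[-1], w[-1])

    def test_sampling_deterministic(self):
        a = sample_time_warp(64, seed=5, sigma=0.2)
        b = sample_time_warp(64, seed=5, sigma=0.2)
        np.testing.assert_array_equal(a.warp, b.warp)

    def test_displacement_grows_with_sigma(self):
        disp = {}
        for sigma in (0.1, 0.4):
            rng = np.random.default_rng(9)
            d = [
                np.abs(sample_time_warp(128, rng, sigma=sigma).warp - np.arange(128)).mean()
                for _ in range(1000)
            ]
            disp[sigma] = np.mean(d)
        assert disp[0.4] > disp[0.1]

    def test_non_monotone_warp_rejected(self):
        with pytest.raises(ValueError):
            TimeWarpParams(warp=np.array([0.0, 2.0, 1.0, 3.0]))


class TestDatasetLevel:
    def test_single_augmentation_counts(self, layout):
        stroke = make_windows(25, 4, groups=["StrokeRH"])  # 100 windows
        nd = make_windows(50, 4, groups=["ND"], seed=1)  # 200 windows
        plan = AugmentPlan(method="rotation", n_copies=1, base_seed=3)
        out = augment_dataset(stroke + nd, plan, layout)
        assert len(out) == 400
        assert sum(w.provenance == "rotation" for w in out) == 100

    def test_double_augmentation_distinct_copies(self, layout):
        stroke = make_windows(25, 4, groups=["StrokeRH"])
        nd = make_windows(50, 4, groups=["ND"], seed=1)
        plan = AugmentPlan(method="rotation", n_copies=2, base_seed=3)
        out = augment_dataset(stroke + nd, plan, layout)
        assert len(out) == 500
        copies = [w for w in out if w.provenance == "rotation"]
        first, second = copies[:100], copies[100:]
        assert not any(
            np.allclose(a.signal, b.signal) for a, b in zip(first, second)
        )
        assert set(w.seed for w in first).isdisjoint(w.seed for w in second)

    def test_labels_inherited(self, layout):
        stroke = make_windows(10, 3, groups=["StrokeLH"])
        plan = AugmentPlan(method="timewarp", n_copies=1, base_seed=7)
        out = augment_dataset(stroke, plan, layout)
        originals = out[: len(stroke)]
        copies = out[len(stroke):]
        for src, cp in zip(originals, copies):
            assert (cp.class_id, cp.subject_id, cp.group) == (
                src.class_id, src.subject_id, src.group,
            )

    def test_bitwise_deterministic(self, layout):
        stroke = make_windows(10, 2, groups=["StrokeRH"])
        plan = AugmentPlan(method="permutation", n_copies=2, base_seed=5)
        a = augment_dataset(stroke, plan, layout)
        b = augment_dataset(stroke, plan, layout)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.signal, y.signal)

    def test_transformed_only_has_no_originals(self, layout):
        stroke = make_windows(10, 2, groups=["StrokeRH"])
        plan = AugmentPlan(method="rotation", n_copies=1, base_seed=5)
        out = transformed_only(stroke, plan, layout)
        assert len(out) == len(stroke)
        assert all(w.provenance == "rotation" for w in out)

    def test_empty_target_group_rejected(self, layout):
        nd = make_windows(10, 2, groups=["ND"])
        with pytest.raises(ValueError):
            augment_dataset(nd, AugmentPlan(method="rotation"), layout)

    def test_all_methods_shape_and_label_preserving(self, layout):
        w = np.random.default_rng(11).normal(size=(64, 30))
        for method in ("rotation", "permutation", "timewarp"):
            out = transform_window(w, method, layout, seed=13)
            assert out.shape == w.shape
            assert np.all(np.isfinite(out))


class TestBalance:
    def test_class_at_target_unchanged(self, layout):
        ws = make_windows(20, 2, groups=["StrokeRH"])
        out = balance_by_augmentation(ws, target_count=20, method="rotation", layout=layout)
        assert len(out) == len(ws)

    def test_deficit_filled_exactly(self, layout):
        ws = make_windows(5, 3, groups=["StrokeRH"])  # 5 per class
        out = balance_by_augmentation(ws, target_count=12, method="rotation", layout=layout)
        from collections import Counter

        counts = Counter(w.class_id for w in out)
        assert all(v == 12 for v in counts.values())
        added = [w for w in out if w.provenance == "rotation"]
        assert len(added) == 3 * 7

    def test_class_above_target_untouched(self, layout):
        ws = make_windows(30, 1, groups=["StrokeRH"])
        out = balance_by_augmentation(ws, target_count=25, method="timewarp", layout=layout)
        assert len(out) == 30
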