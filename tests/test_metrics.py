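import math

import numpy as np
import pytest

from xaibench3d.core import AttributionMap, BaselineSpec, Sample3D, ValidationError
from xaibench3d.fixtures import LinearAdapter
from xaibench3d.metrics import (
    CompactnessConfig,
    PerturbationSchedule,
    apply_preservation,
    apply_removal,
    compute_aopc,
    compute_aupc,
    compute_compactness_adaptive,
    compute_compactness_fixed,
    evaluate_sample,
    rank_elements,
)


# --- independent brute-force oracle -----------------------------------------
# deliberately re-derives ranking, element counts, perturbation and the
# trapezoid from first principles, without calling the library internals


def oracle_aopc_aupc(adapter, sample, values, K, baseline_kind):
    data = sample.data
    flat = values.ravel()
    order = sorted(range(flat.size), key=lambda i: (-flat[i], i))
    if baseline_kind == "mean":
        base = np.full_like(data, data.mean())
    else:
        base = np.zeros_like(data)
    cls = sample.predicted_label
    conf0 = float(adapter.score(data)[cls])
    is_points = sample.modality == "pointcloud"
    m = data.shape[0] if is_points else data.size
    drops, prescurve = [], [0.0]
    for k in range(1, K + 1):
        n_sel = math.ceil(k / K * m)
        sel = order[:n_sel]
        removed = data.copy()
        kept = base.copy()
        if is_points:
            removed[sel] = base[sel]
            kept[sel] = data[sel]
        else:
            removed.ravel()[sel] = base.ravel()[sel]
            kept.ravel()[sel] = data.ravel()[sel]
        drops.append(conf0 - float(adapter.score(removed)[cls]))
        prescurve.append(float(adapter.score(kept)[cls]))
    # trapezoid by hand over fractions 0, 1/K, ..., 1
    aopc = sum((([0.0] + drops)[i] + ([0.0] + drops)[i + 1]) / 2.0 / K
               for i in range(K))
    aupc = sum((prescurve[i] + prescurve[i + 1]) / 2.0 / K for i in range(K))
    return aopc, aupc


def _random_case(rng, modality):
    if modality == "pointcloud":
        n = int(rng.integers(10, 40))
        data = rng.standard_normal((n, 3))
        w = rng.standard_normal((n, 3))
        values = rng.uniform(size=n)
    else:
        shape = tuple(rng.integers(3, 7, size=3))
        data = (
            (rng.uniform(size=shape) < 0.4).astype(float)
            if modality == "voxel"
            else rng.standard_normal(shape)
        )
        w = rng.standard_normal(shape)
        values = rng.uniform(size=shape)
    sample = Sample3D("r", modality, data, 0, 0)
    return LinearAdapter(w), sample, values


class TestRanking:
    def test_tie_breaks_by_flat_index(self):
        amap = AttributionMap(np.array([0.2, 0.9, 0.9]), "custom", normalized=True)
        np.testing.assert_array_equal(rank_elements(amap), [1, 2, 0])

    def test_strictly_decreasing_is_identity(self):
        amap = AttributionMap(np.linspace(1, 0, 9), "custom", normalized=True)
        np.testing.assert_array_equal(rank_elements(amap), np.arange(9))

    def test_agrees_with_stable_sort_oracle(self, rng):
        vals = rng.choice(np.linspace(0, 1, 17), size=100)
        amap = AttributionMap(vals, "custom", normalized=True)
        expected = sorted(range(100), key=lambda i: (-vals[i], i))
        np.testing.assert_array_equal(rank_elements(amap), expected)


class TestRemovalPreservation:
    @pytest.mark.parametrize("n, frac, expected", [(4, 0.25, 1), (10, 0.25, 3),
                                                   (8, 1.0, 8)])
    def test_ceil_rounding(self, n, frac, expected):
        data = np.ones((1, 1, n))
        s = Sample3D("s", "volumetric", data, 0, 0)
        order = np.arange(n)
        out = apply_removal(s, order, frac, BaselineSpec("zero"))
        assert int((out.data == 0).sum()) == expected

    def test_full_removal_zero_baseline(self, rng):
        s = Sample3D("s", "volumetric", rng.standard_normal((3, 3, 3)), 0, 0)
        out = apply_removal(s, rank_elements(
            AttributionMap(rng.uniform(size=(3, 3, 3)), "custom", True)),
            1.0, BaselineSpec("zero"))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_preservation_at_full_fraction_is_identity(self, rng):
        data = rng.standard_normal((3, 3, 3))
        s = Sample3D("s", "volumetric", data, 0, 0)
        order = np.argsort(-data.ravel(), kind="stable")
        out = apply_preservation(s, order, 1.0, BaselineSpec("zero"))
        np.testing.assert_array_equal(out.data, data)

    @pytest.mark.parametrize("modality", ["volumetric", "pointcloud"])
    @pytest.mark.parametrize("frac", [0.1, 0.3, 0.5, 0.99])
    def test_duality_partition(self, rng, modality, frac):
        """Removed set of removal == kept set of preservation at equal fraction."""
        adapter, sample, values = _random_case(rng, modality)
        order = rank_elements(AttributionMap(values, "custom", True))
        base = BaselineSpec("zero")
        removed = apply_removal(sample, order, frac, base).data
        kept = apply_preservation(sample, order, frac, base).data
        # every element comes from exactly one branch of the partition
        np.testing.assert_allclose(removed + kept,
                                   sample.data + base.values(sample.data))

    def test_linearity_identity_on_linear_adapter(self, rng):
        adapter, sample, values = _random_case(rng, "volumetric")
        order = rank_elements(AttributionMap(values, "custom", True))
        base = BaselineSpec("zero")
        for frac in (0.2, 0.6):
            c_pres = adapter.score(apply_preservation(sample, order, frac, base).data)[0]
            c_rem = adapter.score(apply_removal(sample, order, frac, base).data)[0]
            c_base = adapter.score(base.values(sample.data))[0]
            c_full = adapter.score(sample.data)[0]
            assert c_pres + c_rem - c_base == pytest.approx(c_full, abs=1e-10)

    def test_fraction_out_of_range_rejected(self, rng):
        s = Sample3D("s", "volumetric", rng.standard_normal((2, 2, 2)), 0, 0)
        with pytest.raises(ValidationError):
            apply_removal(s, np.arange(8), 0.0, BaselineSpec("zero"))


class TestAOPCAUPC:
    def test_constant_model_gives_zero_aopc(self):
        class Const:
            def score(self, x):
                return np.array([0.8])
        s = Sample3D("s", "volumetric", np.ones((2, 2, 2)), 0, 0)
        amap = AttributionMap(np.linspace(0, 1, 8).reshape(2, 2, 2), "custom", True)
        aopc, drops, _ = compute_aopc(Const(), s, amap, PerturbationSchedule(4),
                                      BaselineSpec("zero"))
        assert aopc == 0.0
        np.testing.assert_array_equal(drops, 0.0)

    def test_hand_trapezoid_linear_example(self):
        adapter = LinearAdapter(np.array([4.0, 3.0, 2.0, 1.0]).reshape(1, 1, 4))
        s = Sample3D("s", "volumetric", np.ones((1, 1, 4)), 0, 0)
        amap = AttributionMap(np.array([[[0.9, 0.8, 0.7, 0.6]]]), "custom", True)
        aopc, drops, conf_init = compute_aopc(adapter, s, amap,
                                              PerturbationSchedule(4),
                                              BaselineSpec("zero"))
        assert conf_init == 10.0
        np.testing.assert_allclose(drops, [4.0, 7.0, 9.0, 10.0])
        assert aopc == pytest.approx(6.25)

    def test_constant_confidence_aupc(self):
        class Const:
            def score(self, x):
                return np.array([0.8])
        s = Sample3D("s", "volumetric", np.ones((2, 2, 2)), 0, 0)
        amap = AttributionMap(np.linspace(0, 1, 8).reshape(2, 2, 2), "custom", True)
        aupc, curve = compute_aupc(Const(), s, amap, PerturbationSchedule(4),
                                   BaselineSpec("zero"))
        np.testing.assert_allclose(curve, [0.0, 0.8, 0.8, 0.8, 0.8])
        assert aupc == pytest.approx(0.7)

    @pytest.mark.parametrize("modality", ["volumetric", "voxel", "pointcloud"])
    def test_oracle_equivalence_random_fixtures(self, modality):
        rng = np.random.default_rng(99)
        for trial in range(20):
            adapter, sample, values = _random_case(rng, modality)
            amap = AttributionMap(values, "custom", normalized=True)
            K = int(rng.integers(2, 8))
            kind = "mean" if modality == "volumetric" else "zero"
            aopc, _, _ = compute_aopc(adapter, sample, amap,
                                      PerturbationSchedule(K), BaselineSpec(kind))
            aupc, _ = compute_aupc(adapter, sample, amap,
                                   PerturbationSchedule(K), BaselineSpec(kind))
            o_aopc, o_aupc = oracle_aopc_aupc(adapter, sample, values, K, kind)
            assert abs(aopc - o_aopc) <= 1e-12 * max(1, abs(o_aopc))
            assert abs(aupc - o_aupc) <= 1e-12 * max(1, abs(o_aupc))

    def test_drop_curve_monotone_for_positive_linear_model(self, rng):
        w = np.abs(rng.standard_normal((3, 3, 3)))
        x = np.abs(rng.standard_normal((3, 3, 3)))
        adapter = LinearAdapter(w)
        s = Sample3D("s", "volumetric", x, 0, 0)
        amap = AttributionMap(rng.uniform(size=(3, 3, 3)), "custom", True)
        _, drops, _ = compute_aopc(adapter, s, amap, PerturbationSchedule(9),
                                   BaselineSpec("zero"))
        assert np.all(np.diff(drops) >= -1e-12)


class TestCompactness:
    def test_fixed_hand_count(self):
        amap = AttributionMap(np.array([[[0.9, 0.6, 0.4, 0.1]]]), "custom", True)
        s = Sample3D("s", "volumetric", np.array([[[1.0, 1.0, 1.0, 0.0]]]), 0, 0)
        out = compute_compactness_fixed(amap, s, thresholds=(0.5,))
        assert out[0.5] == pytest.approx(2.0 / 3.0)

    def test_all_above_threshold_ratio_one(self):
        amap = AttributionMap(np.full((2, 2, 2), 0.9), "custom", True)
        s = Sample3D("s", "volumetric", np.ones((2, 2, 2)), 0, 0)
        assert compute_compactness_fixed(amap, s, (0.5,))[0.5] == 1.0

    def test_fixed_monotone_nonincreasing_in_threshold(self, rng):
        for _ in range(10):
            vals = rng.uniform(size=(4, 4, 4))
            amap = AttributionMap(vals, "custom", True)
            s = Sample3D("s", "volumetric", rng.standard_normal((4, 4, 4)), 0, 0)
            out = compute_compactness_fixed(amap, s, (0.1, 0.3, 0.5, 0.7, 0.9))
            ratios = [out[t] for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
            assert all(a >= b for a, b in zip(ratios, ratios[1:]))

    def test_adaptive_top_fraction_count(self):
        vals = np.linspace(0.1, 0.8, 8).reshape(2, 2, 2)
        amap = AttributionMap(vals, "custom", True)
        data = np.zeros((2, 2, 2))
        data.flat[:2] = 1.0  # two non-zero elements
        s = Sample3D("s", "volumetric", data, 0, 0)
        # ceil(0.1 * 8) = 1 top element -> ratio 1/2
        assert compute_compactness_adaptive(amap, s, 0.1) == pytest.approx(0.5)

    def test_adaptive_degenerate_equal_values(self):
        amap = AttributionMap(np.full((2, 2, 2), 0.4), "custom", True)
        data = np.zeros((2, 2, 2))
        data.flat[:4] = 1.0
        s = Sample3D("s", "volumetric", data, 0, 0)
        assert compute_compactness_adaptive(amap, s, 0.1) == pytest.approx(8 / 4)

    def test_sparse_grid_ratio_exceeds_one(self, rng):
        # dense attribution on a nearly empty occupancy grid
        occ = np.zeros((8, 8, 8))
        occ.flat[:5] = 1.0
        vals = rng.uniform(0.6, 1.0, size=(8, 8, 8))
        amap = AttributionMap(vals, "custom", True)
        s = Sample3D("s", "voxel", occ, 0, 0)
        assert compute_compactness_fixed(amap, s, (0.5,))[0.5] > 1.0
        assert compute_compactness_adaptive(amap, s, 0.1) > 1.0

    def test_all_zero_sample_rejected(self):
        amap = AttributionMap(np.full((2, 2, 2), 0.4), "custom", True)
        s = Sample3D("s", "volumetric", np.zeros((2, 2, 2)), 0, 0)
        with pytest.raises(ValidationError):
            compute_compactness_fixed(amap, s)


class TestFaithfulnessSanity:
    def test_ground_truth_mask_beats_random_attribution(self):
        """On blob volumes scored by a matched filter, attributing the true
        blob support yields higher mean AOPC than random attribution in
        >= 95% of 50 seeded trials."""
        from xaibench3d.fixtures import FixtureSpec, gen_blob_volumes

        wins = 0
        for seed in range(50):
            spec = FixtureSpec(modality="volumetric", n_classes=1,
                               samples_per_class=3, grid_shape=(12, 12, 12),
                               blob_sigma=1.5, seed=seed)
            samples, masks = gen_blob_volumes(spec)
            rng = np.random.default_rng(10_000 + seed)
            gt_scores, rand_scores = [], []
            for s, m in zip(samples, masks):
                adapter = LinearAdapter(m.astype(float))  # matched filter
                s.predicted_label = 0
                gt = AttributionMap(m.astype(float), "custom", True)
                rnd = AttributionMap(rng.uniform(size=m.shape), "custom", True)
                sched = PerturbationSchedule(5)
                gt_scores.append(compute_aopc(adapter, s, gt, sched,
                                              BaselineSpec("mean"))[0])
                rand_scores.append(compute_aopc(adapter, s, rnd, sched,
                                                BaselineSpec("mean"))[0])
            wins += np.mean(gt_scores) > np.mean(rand_scores)
        assert wins >= 48  # 95% of 50


def test_evaluate_sample_collects_all_metrics(rng, conv_adapter):
    s = Sample3D("s", "volumetric", rng.standard_normal((16, 16, 16)), 0, 1)
    amap = AttributionMap(rng.uniform(size=(16, 16, 16)), "custom", True)
    rec = evaluate_sample(conv_adapter, s, amap, PerturbationSchedule(5),
                          compactness=CompactnessConfig())
    assert rec.drop_curve.shape == (5,)
    assert rec.preservation_curve.shape == (6,) and rec.preservation_curve[0] == 0.0
    assert set(rec.compactness_fixed) == {0.5, 0.7, 0.9}
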