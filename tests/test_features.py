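"""The three relevant-voxel selection criteria and cross-subject aggregation."""

import itertools

import numpy as np
import pytest
from scipy import stats

import fnirs_deception as fd
from fnirs_deception.epochs import ClassMeans
from fnirs_deception.features import (
    VoxelMask,
    aggregate_masks,
    class_samples,
    heuristic_select,
    nonparametric_select,
    parametric_select,
    quartiles,
    select_voxels,
)


def cm_from_diffs(diffs):
    """ClassMeans whose (m=1, m=2) blood-volume difference equals ``diffs``."""
    diffs = np.asarray(diffs, dtype=float)
    return ClassMeans(
        subject_id="S",
        mean_dB={1: diffs, 2: np.zeros_like(diffs)},
        mean_dO={1: diffs * 0, 2: diffs * 0},
        counts={1: 10, 2: 10},
    )


class TestHeuristic:
    def test_direct_threshold(self):
        mask = heuristic_select(cm_from_diffs([0.5, 1.2, 0.3, 2.0]))
        assert mask.voxels.tolist() == [2, 4]

    def test_fallback_no_qualifier_takes_top_two(self):
        mask = heuristic_select(cm_from_diffs([0.2, 0.9, 0.5]))
        assert mask.voxels.tolist() == [2, 3]

    def test_fallback_single_qualifier_adds_runner_up(self):
        mask = heuristic_select(cm_from_diffs([1.5, 0.9, 0.3]))
        assert mask.voxels.tolist() == [1, 2]

    def test_sign_of_difference_irrelevant(self):
        mask = heuristic_select(cm_from_diffs([-2.0, 0.1, 1.1]))
        assert mask.voxels.tolist() == [1, 3]

    def test_always_at_least_two_voxels(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            diffs = rng.normal(0, rng.uniform(0.05, 3), size=rng.integers(2, 17))
            assert heuristic_select(cm_from_diffs(diffs)).flags.sum() >= 2

    def test_single_voxel_rejected(self):
        with pytest.raises(ValueError):
            heuristic_select(cm_from_diffs([5.0]))


def quartile_oracle(x):
    """Explicit linear-interpolation order-statistic quartiles."""
    x = np.sort(np.asarray(x, dtype=float))
    out = []
    for p in (0.25, 0.75):
        h = (x.size - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, x.size - 1)
        out.append(x[lo] + (h - lo) * (x[hi] - x[lo]))
    return out


class TestNonparametric:
    def test_degenerate_disjoint_samples_selected(self):
        a = np.zeros((4, 1))
        b = np.full((4, 1), 5.0)
        assert nonparametric_select(a, b).flags.tolist() == [True]

    def test_identical_samples_not_selected(self):
        a = np.arange(8.0)[:, None]
        assert nonparametric_select(a, a.copy()).flags.tolist() == [False]

    def test_shift_thresholds(self):
        base = np.arange(1.0, 11.0)[:, None]
        assert nonparametric_select(base, base + 20.0).flags[0]
        assert not nonparametric_select(base, base + 0.1).flags[0]

    def test_quartiles_match_order_statistic_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            x = rng.normal(size=rng.integers(4, 30))
            q1, q3 = quartiles(x[:, None])
            want = quartile_oracle(x)
            assert q1[0] == pytest.approx(want[0], rel=1e-12)
            assert q3[0] == pytest.approx(want[1], rel=1e-12)

    def test_disjointness_matches_interval_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            a = rng.normal(0, 1, rng.integers(4, 15))
            b = rng.normal(rng.uniform(-2, 2), 1, rng.integers(4, 15))
            got = nonparametric_select(a[:, None], b[:, None]).flags[0]
            q1a, q3a = quartile_oracle(a)
            q1b, q3b = quartile_oracle(b)
            want = (q3a < q1b) or (q3b < q1a)
            assert got == want

    def test_selection_implies_median_separation(self):
        """A selected voxel's medians differ in the direction of the IQR gap."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            a = rng.normal(0, 1, 10)
            b = rng.normal(rng.uniform(-4, 4), 1, 10)
            if nonparametric_select(a[:, None], b[:, None]).flags[0]:
                assert np.median(a) != np.median(b)
                q1a, q3a = quartile_oracle(a)
                q1b, _ = quartile_oracle(b)
                if q3a < q1b:
                    assert np.median(a) < np.median(b)
                else:
                    assert np.median(a) > np.median(b)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="quartiles"):
            nonparametric_select(np.zeros((3, 1)), np.zeros((4, 1)))


class TestParametric:
    def _samples(self, a, b):
        return {1: np.atleast_2d(a).T, 2: np.atleast_2d(b).T,
                3: np.atleast_2d(a).T, 4: np.atleast_2d(b).T}

    def test_identical_groups_not_selected(self):
        s = self._samples([1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5])
        union, per = parametric_select(s, contrasts=(((1,), (2,)),))
        assert not union.flags.any()

    def test_strongly_separated_groups_selected(self):
        s = self._samples([0.0, 0, 0, 0, 0], [9.0, 9.1, 8.9, 9.05, 8.95])
        union, _ = parametric_select(s, contrasts=(((1,), (2,)),), alpha=0.1)
        assert union.flags.all()
        # cross-check against the reference t computation
        t, p = stats.ttest_ind([0.0, 0, 0, 0, 0], [9.0, 9.1, 8.9, 9.05, 8.95])
        assert p < 0.1

    def test_zero_variance_rule(self):
        same = self._samples([2.0, 2, 2, 2], [2.0, 2, 2, 2])
        union, _ = parametric_select(same, contrasts=(((1,), (2,)),))
        assert not union.flags.any()  # equal means -> p = 1
        diff = self._samples([2.0, 2, 2, 2], [3.0, 3, 3, 3])
        union, _ = parametric_select(diff, contrasts=(((1,), (2,)),))
        assert union.flags.all()  # different means -> p = 0

    def test_pooled_contrast_uses_merged_groups(self, default_features):
        qf, _ = default_features
        samples = class_samples(qf)
        _, per = parametric_select(samples)
        name = "m12-vs-m34"
        ga = np.vstack([samples[1], samples[2]])
        gb = np.vstack([samples[3], samples[4]])
        _, p = stats.ttest_ind(ga, gb, axis=0)
        assert np.array_equal(per[name].flags, p < 0.1)

    def test_null_calibration_rate_quick(self):
        """Under H0 the per-voxel selection rate tracks alpha (quick check;
        the full 10k-replicate calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(9)
        reps = 2000
        s = {
            1: rng.normal(size=(10, reps)),
            2: rng.normal(size=(10, reps)),
            3: rng.normal(size=(10, reps)),
            4: rng.normal(size=(10, reps)),
        }
        union, _ = parametric_select(s, contrasts=(((1,), (2,)),), alpha=0.1)
        rate = union.flags.mean()
        assert abs(rate - 0.10) < 0.02


def mask(sid, voxels, V=16):
    flags = np.zeros(V, dtype=bool)
    flags[np.asarray(voxels, dtype=int) - 1] = True
    return VoxelMask(sid, "combined", flags)


def brute_minimum_cover_size(flag_mat):
    V = flag_mat.shape[1]
    for k in range(1, V + 1):
        for comb in itertools.combinations(range(V), k):
            if flag_mat[:, list(comb)].any(axis=1).all():
                return k
    return None


class TestAggregate:
    def test_single_common_voxel(self):
        agg = aggregate_masks([mask("A", [8]), mask("B", [8]), mask("C", [8])])
        assert agg.voxels.tolist() == [8]

    def test_worked_three_subject_cover(self):
        agg = aggregate_masks([mask("A", [1, 8]), mask("B", [8]), mask("C", [3])])
        assert sorted(agg.voxels.tolist()) == [3, 8]

    def test_frequency_counts(self):
        agg = aggregate_masks([mask("A", [1, 8]), mask("B", [8]), mask("C", [3])])
        assert agg.frequency[7] == 2 and agg.frequency[0] == 1

    def test_all_zero_subject_excluded_with_cover_of_rest(self):
        masks = [mask("A", [2]), mask("B", []), mask("C", [2])]
        agg = aggregate_masks(masks)
        assert agg.subjects_excluded == ["B"]
        assert agg.voxels.tolist() == [2]

    def test_valid_and_minimal_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(150):
            ns, nv = rng.integers(2, 9), rng.integers(3, 13)
            fm = rng.random((ns, nv)) < rng.uniform(0.15, 0.5)
            fm[fm.sum(axis=1) == 0, rng.integers(0, nv)] = True
            masks = [VoxelMask(f"S{j}", "combined", fm[j]) for j in range(ns)]
            agg = aggregate_masks(masks)
            assert fm[:, agg.flags].any(axis=1).all(), "must cover every subject"
            assert agg.flags.sum() == brute_minimum_cover_size(fm)

    def test_informative_voxel_recovery_on_cohort(self, small_cohort):
        cfg, cohort = small_cohort
        masks = [select_voxels(qf)["combined"] for qf, _ in cohort]
        agg = aggregate_masks(masks)
        informative = {v + 1 for v in cfg.informative_voxels}
        assert set(agg.voxels.tolist()) <= informative


class TestSelectVoxels:
    def test_informative_voxels_flagged(self, default_features):
        qf, truth = default_features
        masks = select_voxels(qf)
        informative = set(truth.informative_voxels)
        for crit in ("heuristic", "nonparametric", "parametric", "combined"):
            assert informative <= set(np.flatnonzero(masks[crit].flags)), crit

    def test_all_mask_is_everything(self, default_features):
        qf, _ = default_features
        assert select_voxels(qf)["all"].flags.all()

    def test_combined_is_union(self, default_features):
        qf, _ = default_features
        m = select_voxels(qf)
        want = m["heuristic"].flags | m["nonparametric"].flags | m["parametric"].flags
        assert np.array_equal(m["combined"].flags, want)
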