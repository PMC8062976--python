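"""Scaled-MAE metric, Spearman quality bins and rank-sum comparison."""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oral2gut as og
from oral2gut.evaluate import assign_quality_bin

FAMILIES13 = [*og.DEFAULT_FAMILIES, "Other"]


def _closed(mat):
    mat = np.asarray(mat, dtype=float)
    mat = np.clip(mat, 0, None)
    mat = mat * (100.0 / mat.sum(axis=1, keepdims=True))
    mat[:, -1] += 100.0 - mat.sum(axis=1)
    return mat


def _pair(truth, pred):
    ids = [f"s{i}" for i in range(truth.shape[0])]
    return (
        og.FamilyTable(ids, FAMILIES13, pred),
        og.FamilyTable(ids, FAMILIES13, truth),
    )


class TestComputeMaes:
    def test_perfect_prediction_gives_zero(self):
        rng = np.random.default_rng(0)
        truth = _closed(rng.uniform(1, 10, (5, 13)))
        pred_t, true_t = _pair(truth, truth.copy())
        report = og.compute_maes(pred_t, true_t)
        np.testing.assert_allclose(report.per_family_maes, 0, atol=1e-12)
        assert report.mean_maes == pytest.approx(0.0)

    def test_closed_form_example(self):
        """Truth column sd 10, constant error 2 -> maes 0.2."""
        truth = np.zeros((3, 13))
        truth[:, 0] = [10, 20, 30]
        truth[:, -1] = [90, 80, 70]
        pred = truth.copy()
        pred[:, 0] = [12, 22, 32]
        pred[:, -1] = [88, 78, 68]
        pred_t, true_t = _pair(truth, pred)
        report = og.compute_maes(pred_t, true_t)
        assert report.per_family_maes[0] == pytest.approx(0.2)

    def test_zero_sd_family_excluded_from_mean(self):
        truth = np.zeros((3, 13))
        truth[:, 0] = 40.0  # constant family: sd 0, maes undefined
        truth[:, 1] = [10, 20, 30]
        truth[:, -1] = [50, 40, 30]
        pred = truth.copy()
        pred[:, 1] = [15, 25, 35]
        ids = ["s0", "s1", "s2"]
        report = og.compute_maes(
            og.FamilyTable(ids, FAMILIES13, pred, closed=False),
            og.FamilyTable(ids, FAMILIES13, truth, closed=False),
        )
        assert FAMILIES13[0] in report.undefined_families
        assert math.isnan(report.per_family_maes[0])
        assert not math.isnan(report.mean_maes)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), scale=st.sampled_from([0.5, 2.0, 7.3]))
    def test_scale_invariance_and_naive_oracle(self, seed, scale):
        """maes is invariant to joint positive scaling and matches a
        double-loop re-implementation to 1e-12."""
        rng = np.random.default_rng(seed)
        truth = rng.uniform(0, 10, (5, 13))
        pred = rng.uniform(0, 10, (5, 13))
        ids = [f"s{i}" for i in range(5)]
        t1 = og.FamilyTable(ids, FAMILIES13, truth, closed=False)
        p1 = og.FamilyTable(ids, FAMILIES13, pred, closed=False)
        report = og.compute_maes(p1, t1)

        # naive per-family oracle
        for j in range(13):
            errs = [abs(pred[i, j] - truth[i, j]) for i in range(5)]
            mean_err = sum(errs) / 5
            mu = sum(truth[i, j] for i in range(5)) / 5
            sd = math.sqrt(
                sum((truth[i, j] - mu) ** 2 for i in range(5)) / 4
            )
            assert report.per_family_maes[j] == pytest.approx(
                mean_err / sd, abs=1e-12
            )

        t2 = og.FamilyTable(ids, FAMILIES13, truth * scale / 10, closed=False)
        p2 = og.FamilyTable(ids, FAMILIES13, pred * scale / 10, closed=False)
        scaled = og.compute_maes(p2, t2)
        np.testing.assert_allclose(
            scaled.per_family_maes, report.per_family_maes, atol=1e-10
        )

    def test_misaligned_samples_rejected(self):
        rng = np.random.default_rng(1)
        truth = _closed(rng.uniform(1, 10, (3, 13)))
        pred_t, true_t = _pair(truth, truth)
        other = og.FamilyTable(["x", "y", "z"], FAMILIES13, truth)
        with pytest.raises(ValueError):
            og.compute_maes(pred_t, other)


class TestSpearmanPerSample:
    def test_identical_profiles_are_excellent(self):
        rng = np.random.default_rng(2)
        truth = _closed(rng.uniform(1, 10, (2, 13)))
        pred_t, true_t = _pair(truth, truth.copy())
        quals = og.spearman_per_sample(pred_t, true_t)
        assert all(q.r == pytest.approx(1.0) for q in quals)
        assert all(q.bin == "excellent" for q in quals)

    def test_reversed_ranking_is_incorrect(self):
        truth = _closed(np.arange(1.0, 14.0)[None, :])
        pred = _closed(np.arange(13.0, 0.0, -1.0)[None, :])
        pred_t, true_t = _pair(truth, pred)
        (q,) = og.spearman_per_sample(pred_t, true_t)
        assert q.r == pytest.approx(-1.0)
        assert q.bin == "incorrect"

    def test_matches_brute_force_rank_formula_with_ties(self):
        """Adjacent swap + ties: r equals the average-rank Pearson formula."""
        truth_row = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 12.0])
        pred_row = truth_row.copy()
        pred_row[[0, 1]] = pred_row[[1, 0]]  # swap two adjacent ranks
        t = _closed(truth_row[None, :])
        p = _closed(pred_row[None, :])
        pred_t, true_t = _pair(t, p)
        (q,) = og.spearman_per_sample(pred_t, true_t)

        def average_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        ra, rb = average_ranks(t[0]), average_ranks(p[0])
        expected = np.corrcoef(ra, rb)[0, 1]
        assert q.r == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_is_nan_and_incorrect(self, caplog):
        truth = _closed(np.arange(1.0, 14.0)[None, :])
        pred = np.full((1, 13), 100.0 / 13)
        pred[:, -1] += 100.0 - pred.sum(axis=1)
        pred_t, true_t = _pair(truth, pred)
        with caplog.at_level(logging.WARNING, logger="oral2gut.evaluate"):
            (q,) = og.spearman_per_sample(pred_t, true_t)
        assert math.isnan(q.r)
        assert q.bin == "incorrect"
        assert "constant" in caplog.text

    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.95, "excellent"),
            (0.8, "good"),  # boundary is right-closed
            (0.75, "good"),
            (0.7, "discrete"),
            (0.5, "discrete"),
            (0.4, "incorrect"),
            (-0.2, "incorrect"),
        ],
    )
    def test_bin_boundaries_right_closed(self, r, expected):
        assert assign_quality_bin(r) == expected


class TestSummarizeBins:
    def test_all_excellent(self):
        quals = [og.SampleQuality(f"s{i}", 0.9, "excellent") for i in range(4)]
        bins = og.summarize_bins(quals)
        assert bins == {
            "excellent": 1.0,
            "good": 0.0,
            "discrete": 0.0,
            "incorrect": 0.0,
        }

    def test_counting(self):
        quals = [
            og.SampleQuality("a", 0.9, "excellent"),
            og.SampleQuality("b", 0.9, "excellent"),
            og.SampleQuality("c", 0.1, "incorrect"),
            og.SampleQuality("d", 0.1, "incorrect"),
        ]
        bins = og.summarize_bins(quals)
        assert bins["excellent"] == 0.5
        assert bins["incorrect"] == 0.5
        assert sum(bins.values()) == pytest.approx(1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            og.summarize_bins([])


class TestWilcoxonFamilyCompare:
    def _group(self, col, n_extra=12):
        """Closed tables where the first family carries the signal."""
        col = np.asarray(col, dtype=float)
        mat = np.column_stack([col, 100.0 - col])
        return og.FamilyTable(
            [f"g{i}" for i in range(len(col))],
            ["Bacteroidaceae", "Other"],
            mat,
        )

    def test_identical_groups_give_p_near_one(self):
        a = self._group([10, 20, 30, 40])
        pvals = og.wilcoxon_family_compare(a, a)
        assert (pvals >= 0.99).all()

    def test_complete_separation_exact_tail(self):
        """{1,2,3} vs {10,11,12}: two-sided exact p = 2/20 = 0.1."""
        a = self._group([1, 2, 3])
        b = self._group([10, 11, 12])
        pvals = og.wilcoxon_family_compare(a, b)
        assert pvals["Bacteroidaceae"] == pytest.approx(0.1, abs=1e-12)

        # oracle: enumerate all C(6,3)=20 rank assignments
        ranks = range(1, 7)
        observed = sum([1, 2, 3])
        stats_all = [sum(c) for c in itertools.combinations(ranks, 3)]
        tail = sum(
            1
            for s in stats_all
            if abs(s - 10.5) >= abs(observed - 10.5)  # 10.5 = mean rank sum
        )
        assert tail / len(stats_all) == pytest.approx(0.1)

    def test_constant_equal_family_has_p_one(self):
        a = self._group([50, 50, 50])
        b = self._group([50, 50, 50])
        pvals = og.wilcoxon_family_compare(a, b)
        assert (pvals == 1.0).all()

    def test_group_size_below_two_rejected(self):
        a = self._group([10])
        b = self._group([20, 30])
        with pytest.raises(ValueError):
            og.wilcoxon_family_compare(a, b)
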