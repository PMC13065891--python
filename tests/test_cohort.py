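from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from miredit.cohort import (
    EditingMatrix,
    compare_groups,
    impute_missing,
    rank_sum_test,
    run_pca,
    select_sites,
)
from miredit.simulate import simulate_editing_matrix


def matrix(data, samples, conditions, sites=None):
    sites = sites or [f"site{i}" for i in range(len(data))]
    levels = pd.DataFrame(data, index=sites, columns=samples)
    return EditingMatrix(levels=levels, conditions=pd.Series(conditions))


@pytest.fixture
def small_matrix():
    samples = [f"h{i}" for i in range(5)] + [f"c{i}" for i in range(5)]
    conditions = {s: ("healthy" if s.startswith("h") else "cancer") for s in samples}
    rng = np.random.default_rng(1)
    data = rng.uniform(0.1, 0.3, size=(4, 10))
    data[0, 5:] += 0.5  # site0 shifted in cancer
    return matrix(np.clip(data, 0, 1), samples, conditions)


class TestEditingMatrix:
    def test_rejects_out_of_range_levels(self):
        with pytest.raises(ValueError):
            matrix([[1.5, 0.2], [0.1, 0.0]], ["a", "b"], {"a": "x", "b": "x"})

    def test_rejects_unlabeled_samples(self):
        with pytest.raises(ValueError):
            matrix([[0.5, 0.2]], ["a", "b"], {"a": "x"})


class TestImputeMissing:
    def test_no_missing_returned_unchanged(self, small_matrix):
        out = impute_missing(small_matrix, seed=0)
        pd.testing.assert_frame_equal(out.levels, small_matrix.levels)

    def test_constant_site_imputed_to_constant(self):
        samples = ["a", "b", "c", "d"]
        conditions = {s: "x" for s in samples}
        data = np.array(
            [[0.2, 0.2, 0.2, np.nan], [0.4, 0.5, 0.6, 0.7], [0.3, 0.1, 0.2, 0.5]]
        )
        m = matrix(data, samples, conditions)
        out = impute_missing(m, seed=0)
        assert out.levels.loc["site0", "d"] == pytest.approx(0.2)

    def test_observed_cells_never_altered(self):
        m, _ = simulate_editing_matrix(seed=3, missing_fraction=0.2)
        out = impute_missing(m, seed=5)
        observed = ~m.levels.isna()
        assert out.levels.where(observed).equals(m.levels.where(observed))
        assert not out.levels.isna().any().any()

    def test_bitwise_deterministic(self):
        m, _ = simulate_editing_matrix(seed=4, missing_fraction=0.2)
        a = impute_missing(m, seed=9)
        b = impute_missing(m, seed=9)
        assert a.levels.equals(b.levels)

    def test_site_missing_in_whole_condition_gets_global_mean(self, caplog):
        import logging

        samples = ["a", "b", "c", "d"]
        conditions = {"a": "x", "b": "x", "c": "y", "d": "y"}
        data = np.array([[np.nan, np.nan, 0.4, 0.2], [0.1, 0.2, 0.3, 0.4]])
        m = matrix(data, samples, conditions)
        with caplog.at_level(logging.WARNING, logger="miredit.cohort"):
            out = impute_missing(m, seed=0)
        assert out.levels.loc["site0", "a"] == pytest.approx(0.3)  # global mean
        assert any("global mean" in r.message for r in caplog.records)

    def test_values_clipped_to_unit_interval(self):
        m, _ = simulate_editing_matrix(seed=6, missing_fraction=0.3)
        out = impute_missing(m, seed=0)
        assert ((out.levels >= 0) & (out.levels <= 1)).all().all()


class TestRankSumTest:
    def test_exact_enumeration_oracle_disjoint_5v5(self):
        # Exhaustive-permutation oracle: 2 most-extreme splits of 252.
        x = [0.0] * 5
        y = [0.5, 0.6, 0.5, 0.7, 0.6]
        assert rank_sum_test(x, y) == pytest.approx(2 / comb(10, 5))

    def test_identical_groups_p_one(self):
        assert rank_sum_test([0.2] * 5, [0.2] * 5) == 1.0

    def test_exact_matches_independent_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = rng.uniform(0, 1, size=6)
            y = rng.uniform(0, 1, size=5)
            combined = np.concatenate([x, y])
            ranks = rankdata(combined)
            mu = x.size * (combined.size + 1) / 2
            dev = abs(ranks[: x.size].sum() - mu)
            count = sum(
                1
                for idx in combinations(range(combined.size), x.size)
                if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9
            )
            assert rank_sum_test(x, y) == pytest.approx(count / comb(11, 6))

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0.3, 0.05, size=20)
        y = rng.normal(0.5, 0.05, size=20)
        p = rank_sum_test(np.clip(x, 0, 1), np.clip(y, 0, 1))
        assert p < 1e-6


class TestSelectSites:
    def test_identical_site_excluded(self):
        samples = [f"h{i}" for i in range(5)] + [f"c{i}" for i in range(5)]
        conditions = {s: ("healthy" if s.startswith("h") else "cancer") for s in samples}
        m = matrix([[0.2] * 10], samples, conditions)
        assert select_sites(m, "healthy") == []

    def test_strong_shift_included(self):
        samples = [f"h{i}" for i in range(5)] + [f"c{i}" for i in range(5)]
        conditions = {s: ("healthy" if s.startswith("h") else "cancer") for s in samples}
        m = matrix([[0.0] * 5 + [0.9] * 5], samples, conditions)
        # Exact rank-sum: p = 2/252 < 0.1.
        assert select_sites(m, "healthy") == ["site0"]

    def test_no_cancer_conditions_selects_nothing(self):
        samples = ["h0", "h1", "h2"]
        m = matrix([[0.1, 0.5, 0.9]], samples, {s: "healthy" for s in samples})
        assert select_sites(m, "healthy") == []

    def test_missing_healthy_label_is_error(self, small_matrix):
        with pytest.raises(ValueError):
            select_sites(small_matrix, "nope")

    def test_invariant_to_sample_order(self, small_matrix):
        sel_a = select_sites(small_matrix, "healthy")
        perm = list(reversed(small_matrix.samples))
        m2 = EditingMatrix(
            levels=small_matrix.levels[perm], conditions=small_matrix.conditions
        )
        assert select_sites(m2, "healthy") == sel_a


class TestRunPCA:
    def test_rank_one_fixture_pc1_explains_all(self):
        samples = [f"s{i}" for i in range(8)]
        conditions = {s: "x" for s in samples}
        v = np.array([0.0, 0.0, 0.0, 0.0, 0.6, 0.6, 0.6, 0.6])
        data = np.vstack([v, 0.5 * v + 0.1])
        m = matrix(data, samples, conditions)
        scores, loadings, evr = run_pca(m)
        assert evr[0] == pytest.approx(1.0)
        # Two point-clouds collapse to exactly two distinct PC1 scores.
        assert len(np.unique(np.round(scores["PC1"], 9))) == 2
        assert scores["PC1"].iloc[:4].max() != scores["PC1"].iloc[4:].min()

    def test_duplicate_samples_identical_scores(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(0, 1, size=(4, 5))
        data[:, 4] = data[:, 0]
        samples = [f"s{i}" for i in range(5)]
        m = matrix(data, samples, {s: "x" for s in samples})
        scores, _, _ = run_pca(m)
        assert np.allclose(scores.loc["s4"], scores.loc["s0"])

    def test_score_covariance_diagonal(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(0, 1, size=(6, 12))
        samples = [f"s{i}" for i in range(12)]
        m = matrix(data, samples, {s: "x" for s in samples})
        scores, _, _ = run_pca(m)
        cov = np.cov(scores.to_numpy().T)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-8

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0, 1, size=(5, 9))
        samples = [f"s{i}" for i in range(9)]
        m = matrix(data, samples, {s: "x" for s in samples})
        _, loadings, _ = run_pca(m)
        for col in loadings.columns:
            assert loadings[col].iloc[np.argmax(np.abs(loadings[col].to_numpy()))] > 0

    def test_reconstruction_error_decreases_with_components(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(0, 1, size=(6, 15))
        samples = [f"s{i}" for i in range(15)]
        m = matrix(data, samples, {s: "x" for s in samples})
        centered = data.T - data.T.mean(axis=0)
        errors = []
        for k in range(1, 6):
            scores, loadings, _ = run_pca(m, n_components=k)
            recon = scores.to_numpy() @ loadings.to_numpy().T
            errors.append(np.linalg.norm(centered - recon))
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))

    def test_constant_matrix_is_error(self):
        samples = ["a", "b", "c"]
        m = matrix(np.full((3, 3), 0.5), samples, {s: "x" for s in samples})
        with pytest.raises(ValueError, match="zero variance"):
            run_pca(m)

    def test_missing_values_rejected(self):
        samples = ["a", "b", "c"]
        data = np.array([[0.1, np.nan, 0.3], [0.2, 0.4, 0.5]])
        m = matrix(data, samples, {s: "x" for s in samples})
        with pytest.raises(ValueError, match="impute"):
            run_pca(m)


class TestCompareGroups:
    def test_identical_groups_tier_none(self):
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        conditions = {s: s[0] for s in samples}
        m = matrix([[0.3] * 8], samples, conditions)
        g = compare_groups(m, "site0", "a", "b")
        assert g.p_value == 1.0 and g.significance_tier == "none"

    def test_strong_difference_two_stars(self):
        samples = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        conditions = {s: s[0] for s in samples}
        m = matrix([[0, 0, 0, 0, 0, 0.5, 0.6, 0.5, 0.7, 0.6]], samples, conditions)
        g = compare_groups(m, "site0", "a", "b")
        assert g.p_value == pytest.approx(2 / 252)
        assert g.significance_tier == "**" and g.direction == "up"

    def test_direction_fallback_to_mean_when_medians_tie(self):
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        conditions = {s: s[0] for s in samples}
        # Same median (0.3) but higher mean in b.
        m = matrix([[0.3, 0.3, 0.2, 0.3, 0.3, 0.3, 0.9, 0.3]], samples, conditions)
        g = compare_groups(m, "site0", "a", "b")
        assert g.direction == "up"

    def test_undersized_group_is_error(self):
        samples = ["a0", "a1", "b0"]
        conditions = {s: s[0] for s in samples}
        m = matrix([[0.1, 0.2, 0.3]], samples, conditions)
        with pytest.raises(ValueError):
            compare_groups(m, "site0", "a", "b")
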