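"""Bray-Curtis, PERMANOVA, Pareto PCA, Spearman+BH, alpha diversity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from salivaflux import (
    alpha_diversity,
    bh_qvalues,
    bray_curtis,
    bray_curtis_matrix,
    pareto_pca,
    permanova,
    spearman_bh,
)


class TestBrayCurtis:
    def test_examples(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([1, 0], [0, 1]) == 1.0
        assert bray_curtis([2, 1], [1, 1]) == pytest.approx(0.2)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    @given(
        st.lists(st.floats(0, 1e3, allow_nan=False), min_size=2, max_size=12),
        st.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_symmetry_and_bounds(self, u, data):
        v = data.draw(st.lists(st.floats(0, 1e3, allow_nan=False),
                               min_size=len(u), max_size=len(u)))
        if sum(u) == 0 and sum(v) == 0:
            return
        d_uv = bray_curtis(u, v)
        assert d_uv == bray_curtis(v, u)
        assert 0.0 <= d_uv <= 1.0

    def test_matrix_min_shift_for_negatives(self):
        df = pd.DataFrame([[1.0, -0.5], [2.0, 0.5]], index=["a", "b"])
        with pytest.warns(UserWarning, match="min-shifted"):
            D = bray_curtis_matrix(df)
        assert D.loc["a", "a"] == 0.0
        assert D.loc["a", "b"] == D.loc["b", "a"] > 0


def _perfect_separation_matrix():
    # two groups of two; zero within, one between
    D = np.ones((4, 4)) - np.eye(4)
    D[0, 1] = D[1, 0] = 0.0
    D[2, 3] = D[3, 2] = 0.0
    return D


def _group_form_r2(D, labels):
    """Independent oracle: classical within/total sum-of-squares formulas."""
    labels = np.asarray(labels)
    n = len(labels)
    ss_total = (D[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = D[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    return 1.0 - ss_within / ss_total


class TestPermanova:
    def test_zero_within_distance_gives_r2_one(self):
        res = permanova(_perfect_separation_matrix(), ["a", "a", "b", "b"],
                        n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)

    def test_equidistant_two_by_two_gives_one_third(self):
        D = 3.0 * (np.ones((4, 4)) - np.eye(4))
        res = permanova(D, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0 / 3.0)
        assert res.pseudo_f == pytest.approx(1.0)

    def test_hat_form_equals_group_form_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.random((9, 4))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = permanova(D, labels, n_perm=9, seed=0)
        assert res.r_squared == pytest.approx(_group_form_r2(D, labels), abs=1e-10)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        X = rng.random((6, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(D, labels, n_perm=999, seed=1)

        def f_stat(lab):
            r2 = _group_form_r2(D, lab)
            return (r2 / 1) / ((1 - r2) / 4)

        f_obs = f_stat(labels)
        fs = [f_stat(labels[list(p)]) for p in itertools.permutations(range(6))]
        p_exact = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert abs(res.p_value - p_exact) < 3 * np.sqrt(p_exact * (1 - p_exact) / 999) + 1e-3

    def test_invariances(self):
        rng = np.random.default_rng(8)
        X = rng.random((8, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        labels = ["a"] * 4 + ["b"] * 4
        base = permanova(D, labels, n_perm=49, seed=3)
        renamed = permanova(D, ["ctrl" if l == "a" else "case" for l in labels],
                            n_perm=49, seed=3)
        scaled = permanova(5.0 * D, labels, n_perm=49, seed=3)
        assert base.r_squared == pytest.approx(renamed.r_squared, abs=1e-12)
        assert base.r_squared == pytest.approx(scaled.r_squared, abs=1e-12)
        assert base.p_value == scaled.p_value

    def test_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(11)
        X = rng.random((10, 4))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        labels = ["a"] * 5 + ["b"] * 5
        mine = permanova(D, labels, n_perm=99, seed=0)
        dm = skbio_stats.DistanceMatrix(D)
        theirs = skbio_stats.permanova(dm, grouping=labels, permutations=99)
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-8)

    def test_continuous_covariate_model(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=10)
        profile = np.outer(x, [1.0, -1.0, 0.5]) + 0.05 * rng.normal(size=(10, 3))
        D = np.sqrt(((profile[:, None, :] - profile[None, :, :]) ** 2).sum(-1))
        res = permanova(D, x, n_perm=199, seed=0, grouping_name="biomarker")
        assert 0.8 < res.r_squared <= 1.0
        assert res.p_value < 0.05

    def test_null_p_uniformity(self):
        """Under shuffled labels the permutation p-value is uniform."""
        rng = np.random.default_rng(13)
        X = rng.random((12, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        pvals = []
        for i in range(400):
            perm = rng.permutation(12)
            pvals.append(permanova(D[np.ix_(perm, perm)], labels,
                                   n_perm=99, seed=1000 + i).p_value)
        from scipy.stats import kstest
        stat, _ = kstest(pvals, "uniform")
        # allow for the discrete p-grid (multiples of 1/100)
        assert stat < 1.63 / np.sqrt(len(pvals)) + 0.01

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            permanova(D, ["a", "b"], n_perm=9)


class TestParetoPCA:
    def test_scaling_by_sqrt_sd(self):
        rng = np.random.default_rng(0)
        col = rng.normal(0, 1, 30)
        col = (col - col.mean()) / col.std(ddof=1) * 4.0  # sd exactly 4
        df = pd.DataFrame({"a": col, "b": rng.normal(size=30)})
        res = pareto_pca(df)
        # reconstruct: scores @ loadings.T equals the Pareto-scaled matrix
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        expected_a = (col - col.mean()) / 2.0
        np.testing.assert_allclose(recon[:, 0], expected_a, atol=1e-10)

    def test_duplicate_sample_rows_coincide(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((6, 4)), index=[f"s{i}" for i in range(6)])
        df.loc["s5"] = df.loc["s0"]
        res = pareto_pca(df)
        np.testing.assert_allclose(res.scores.loc["s0"], res.scores.loc["s5"],
                                   atol=1e-10)

    def test_pc1_fraction_matches_eigensolver_oracle(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((5, 3)))
        res = pareto_pca(df)
        X = df.to_numpy()
        Xs = (X - X.mean(0)) / np.sqrt(X.std(0, ddof=1))
        eig = np.sort(np.linalg.eigvalsh(Xs.T @ Xs))[::-1]
        assert res.explained_variance_ratio[0] == pytest.approx(eig[0] / eig.sum(),
                                                                abs=1e-10)
        assert res.explained_variance_ratio.sum() <= 1.0 + 1e-12

    def test_zero_variance_feature_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5], "c": [0.0, 1, 0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pareto_pca(df)
        assert res.dropped_features == ["b"]


class TestSpearmanBH:
    def test_perfect_monotone_pairs(self):
        x = pd.DataFrame(
            {f"s{i}": [i, 10 - i] for i in range(6)},
            index=["up", "down"],
        )
        res = spearman_bh(x, np.arange(6, dtype=float))
        assert res.loc["up", "rho"] == pytest.approx(1.0)
        assert res.loc["down", "rho"] == pytest.approx(-1.0)

    def test_bh_step_up_oracle(self):
        q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_constant_feature_reported_missing(self):
        x = pd.DataFrame(
            {f"s{i}": [1.0, i] for i in range(6)}, index=["const", "var"]
        )
        res = spearman_bh(x, np.arange(6, dtype=float))
        assert np.isnan(res.loc["const", "rho"])
        assert np.isfinite(res.loc["var", "q_value"])

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_bh_matches_brute_force(self, pvals):
        p = np.asarray(pvals)
        q = bh_qvalues(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = m - rank_from_top
            running = min(running, p[idx] * m / rank)
            brute[idx] = running
        np.testing.assert_allclose(q, brute, atol=1e-12)


class TestAlphaDiversity:
    def test_uniform_distribution(self):
        assert alpha_diversity([1, 1, 1, 1], "shannon") == pytest.approx(np.log(4))
        assert alpha_diversity([1, 1, 1, 1], "inverse_simpson") == pytest.approx(4.0)

    def test_single_component(self):
        assert alpha_diversity([0, 5, 0], "shannon") == 0.0
        assert alpha_diversity([0, 5, 0], "inverse_simpson") == pytest.approx(1.0)

    def test_hand_computed_inverse_simpson(self):
        assert alpha_diversity([0.5, 0.25, 0.25], "inverse_simpson") == pytest.approx(
            1 / 0.375
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity([0.0, 0.0])
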