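import numpy as np
import pandas as pd
import pytest

import molaric as m
from molaric.phylo import _phylo_mean_and_resid

from conftest import star_tree

# Values cross-validated against independent R implementations
# (picante::Kcalc, nlme::gls with Brownian correlation, ape::ace) on the
# five_taxon_tree / five_taxon_trait fixture.
R_ORACLE_K = 1.6503829956
R_ORACLE_PGLS_SLOPE = 1.2847278522
R_ORACLE_PGLS_INTERCEPT = 0.9119216684
R_ORACLE_PGLS_SE_SLOPE = 0.3565835852
R_ORACLE_ANCESTRAL_ROOT = 1.722316  # ape::ace root estimate


class TestBMCovariance:
    def test_hand_computed_three_taxa(self, balanced_tree):
        cov = m.bm_covariance(balanced_tree, ["A", "B", "C"])
        np.testing.assert_allclose(cov.C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_diagonal(self):
        cov = m.bm_covariance(star_tree(4, depth=2.5))
        np.testing.assert_allclose(cov.C, 2.5 * np.eye(4))

    def test_cherry(self):
        cov = m.bm_covariance(m.PhyloTree.from_newick("(A:3,B:3);"), ["A", "B"])
        np.testing.assert_allclose(cov.C, [[3, 0], [0, 3]])

    def test_properties(self, five_taxon_tree):
        cov = m.bm_covariance(five_taxon_tree)
        C = cov.C
        assert np.allclose(C, C.T)
        assert np.all(np.linalg.eigvalsh(C) > -1e-12)
        for i in range(cov.n):
            for j in range(cov.n):
                assert C[i, j] <= min(C[i, i], C[j, j]) + 1e-12


class TestOLS:
    def test_perfect_line(self):
        r = m.ols_fit([0, 1, 2], [-1, 1, 3])
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(-1.0)
        assert r.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_identity_line(self):
        r = m.ols_fit([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.r2 == pytest.approx(1.0)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        x = rng.normal(size=20)
        y = 1.5 * x - 0.3 + rng.normal(size=20)
        ours = m.ols_fit(x, y)
        sm_fit = statsmodels.OLS(y, statsmodels.add_constant(x)).fit()
        assert ours.slope == pytest.approx(sm_fit.params[1], abs=1e-12)
        assert ours.intercept == pytest.approx(sm_fit.params[0], abs=1e-12)
        assert ours.se_slope == pytest.approx(sm_fit.bse[1], abs=1e-12)
        lo, hi = sm_fit.conf_int()[1]
        assert ours.ci95_slope == pytest.approx((lo, hi), abs=1e-10)
        assert ours.r2 == pytest.approx(sm_fit.rsquared, abs=1e-12)

    def test_constant_predictor_errors(self):
        with pytest.raises(m.ValidationError):
            m.ols_fit([1, 1, 1], [1, 2, 3])


class TestPGLS:
    def test_identity_covariance_equals_ols(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        y = 0.7 * x + rng.normal(size=15)
        cov = m.BMCovariance(tuple(f"t{i}" for i in range(15)), np.eye(15))
        a, b = m.pgls_fit(x, y, cov), m.ols_fit(x, y)
        for attr in ("slope", "intercept", "se_slope", "se_intercept", "r2", "sigma2"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-10)

    def test_perfect_fit_any_covariance(self, five_taxon_tree):
        cov = m.bm_covariance(five_taxon_tree)
        x = np.array([0.1, 0.3, 1.0, 1.3, 0.8])
        r = m.pgls_fit(x, 2 * x - 1, cov)
        assert r.slope == pytest.approx(2.0, abs=1e-10)
        assert r.intercept == pytest.approx(-1.0, abs=1e-10)
        assert r.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_matches_explicit_inverse_oracle(self):
        # brute-force GLS with explicit matrix inverses, computed from
        # first principles on a random 6-taxon instance
        rng = np.random.default_rng(7)
        tree = m.gen_random_tree(6, seed=7)
        cov = m.bm_covariance(tree)
        x = rng.normal(size=6)
        y = 1.2 * x + rng.multivariate_normal(np.zeros(6), 0.3 * cov.C)
        Cinv = np.linalg.inv(cov.C)
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.inv(X.T @ Cinv @ X) @ X.T @ Cinv @ y
        e = y - X @ beta
        sigma2 = e @ Cinv @ e / 4
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ Cinv @ X)))
        ours = m.pgls_fit(x, y, cov)
        assert ours.intercept == pytest.approx(beta[0], abs=1e-10)
        assert ours.slope == pytest.approx(beta[1], abs=1e-10)
        assert ours.sigma2 == pytest.approx(sigma2, abs=1e-10)
        assert ours.se_slope == pytest.approx(se[1], abs=1e-10)

    def test_matches_r_gls_oracle(self, five_taxon_tree, five_taxon_trait):
        x = pd.Series({"A": 0.1, "B": 0.3, "C": 1.0, "D": 1.3, "E": 0.8})
        cov = m.bm_covariance(five_taxon_tree)
        r = m.pgls_fit(x, five_taxon_trait, cov)
        assert r.slope == pytest.approx(R_ORACLE_PGLS_SLOPE, abs=1e-9)
        assert r.intercept == pytest.approx(R_ORACLE_PGLS_INTERCEPT, abs=1e-9)
        assert r.se_slope == pytest.approx(R_ORACLE_PGLS_SE_SLOPE, abs=1e-9)

    def test_invariant_to_covariance_rescaling(self, five_taxon_tree, five_taxon_trait):
        x = np.array([0.1, 0.3, 1.0, 1.3, 0.8])
        cov = m.bm_covariance(five_taxon_tree)
        scaled = m.BMCovariance(cov.labels, 7.3 * cov.C)
        a = m.pgls_fit(x, five_taxon_trait.to_numpy(), cov)
        b = m.pgls_fit(x, five_taxon_trait.to_numpy(), scaled)
        assert a.slope == pytest.approx(b.slope, abs=1e-12)
        assert a.ci95_slope == pytest.approx(b.ci95_slope, abs=1e-10)


class TestBlombergK:
    def test_star_tree_k_is_one_exactly(self):
        rng = np.random.default_rng(3)
        tree = star_tree(10, depth=1.7)
        for _ in range(5):
            y = rng.normal(size=10)
            assert m.blomberg_k(tree, y) == pytest.approx(1.0, abs=1e-10)

    def test_matches_picante_oracle(self, five_taxon_tree, five_taxon_trait):
        assert m.blomberg_k(five_taxon_tree, five_taxon_trait) == pytest.approx(
            R_ORACLE_K, abs=1e-9
        )

    def test_constant_trait_errors(self, five_taxon_tree):
        with pytest.raises(m.ValidationError, match="degenerate"):
            m.blomberg_k(five_taxon_tree, np.ones(5))

    def test_bm_traits_give_mean_k_near_one(self):
        # BM expectation: K averages ~1 when the trait evolves on the
        # same tree the statistic assumes
        tree = m.gen_random_tree(32, seed=11)
        ks = [
            m.blomberg_k(tree, m.simulate_bm(tree, 1.0, seed=500 + i))
            for i in range(200)
        ]
        assert np.mean(ks) == pytest.approx(1.0, abs=0.1)


class TestPhylosignalTest:
    def test_deterministic_under_seed(self, five_taxon_tree, five_taxon_trait):
        k1, p1 = m.phylosignal_test(five_taxon_tree, five_taxon_trait, 199, seed=1)
        k2, p2 = m.phylosignal_test(five_taxon_tree, five_taxon_trait, 199, seed=1)
        assert (k1, p1) == (k2, p2)

    def test_clade_structured_trait_is_significant(self):
        # two deep clades with very different trait values
        tree = m.PhyloTree.from_newick(
            "((a1:0.1,a2:0.1,a3:0.1,a4:0.1):2,(b1:0.1,b2:0.1,b3:0.1,b4:0.1):2);"
        )
        trait = pd.Series(
            {"a1": 0.0, "a2": 0.1, "a3": -0.1, "a4": 0.05,
             "b1": 5.0, "b2": 5.1, "b3": 4.9, "b4": 5.05}
        )
        _, p = m.phylosignal_test(tree, trait, n_perm=999, seed=2)
        assert p <= 0.05

    def test_requires_seed_and_enough_permutations(self, five_taxon_tree, five_taxon_trait):
        with pytest.raises(m.ValidationError):
            m.phylosignal_test(five_taxon_tree, five_taxon_trait, 199, seed=None)
        with pytest.raises(m.ValidationError):
            m.phylosignal_test(five_taxon_tree, five_taxon_trait, 10, seed=1)


class TestAncestralStates:
    def test_star_tree_root_is_arithmetic_mean(self):
        tree = star_tree(6, depth=1.0)
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        anc = m.ancestral_states(tree, y)
        assert len(anc) == 1
        assert anc.iloc[0] == pytest.approx(y.mean())

    def test_cherry_symmetry(self):
        tree = m.PhyloTree.from_newick("(A:1,B:1);")
        anc = m.ancestral_states(tree, pd.Series({"A": 0.0, "B": 2.0}))
        assert anc.iloc[0] == pytest.approx(1.0)

    def test_matches_joint_gaussian_oracle(self, five_taxon_tree, five_taxon_trait):
        # brute-force conditional expectation of internal states given
        # tips under the joint BM Gaussian, built from scratch here
        tree = five_taxon_tree
        y = five_taxon_trait.to_numpy()
        cov = m.bm_covariance(tree, list(five_taxon_trait.index))
        C = cov.C
        ones = np.ones(5)
        Cinv = np.linalg.inv(C)
        a_hat = (ones @ Cinv @ y) / (ones @ Cinv @ ones)
        anc = m.ancestral_states(tree, five_taxon_trait)
        # cross-covariance vectors computed by hand from the fixture
        # topology ((A,B),((C,D),E)) with depths: root 0, (A,B) at 0.5,
        # ((C,D),E) at 0.4, (C,D) at 0.9
        hand_cov = {
            "node1": np.array([0.5, 0.5, 0.0, 0.0, 0.0]),   # (A,B)
            "node4": np.array([0.0, 0.0, 0.4, 0.4, 0.4]),   # ((C,D),E)
            "node5": np.array([0.0, 0.0, 0.9, 0.9, 0.4]),   # (C,D)
        }
        for node_id, ck in hand_cov.items():
            expected = a_hat + ck @ Cinv @ (y - a_hat)
            assert anc.loc[node_id] == pytest.approx(expected, abs=1e-8)
        root_id = anc.index[0]
        assert anc.loc[root_id] == pytest.approx(a_hat, abs=1e-12)
        assert anc.loc[root_id] == pytest.approx(R_ORACLE_ANCESTRAL_ROOT, abs=1e-5)


class TestSimulateBM:
    def test_zero_rate_returns_root_value(self, five_taxon_tree):
        y = m.simulate_bm(five_taxon_tree, 0.0, root_value=3.5, seed=1)
        np.testing.assert_allclose(y.to_numpy(), 3.5)

    def test_seed_reproducibility(self, five_taxon_tree):
        a = m.simulate_bm(five_taxon_tree, 1.0, seed=9)
        b = m.simulate_bm(five_taxon_tree, 1.0, seed=9)
        pd.testing.assert_series_equal(a, b)

    def test_monte_carlo_covariance_matches_bm(self, balanced_tree):
        cov = m.bm_covariance(balanced_tree, ["A", "B", "C"])
        sims = np.array(
            [
                m.simulate_bm(balanced_tree, 2.0, seed=10_000 + i)[["A", "B", "C"]]
                for i in range(4000)
            ]
        )
        np.testing.assert_allclose(
            np.cov(sims.T), 2.0 * cov.C, atol=0.25
        )


def test_phylo_mean_matches_gls_formula(five_taxon_tree, five_taxon_trait):
    C = m.bm_covariance(five_taxon_tree).C
    y = five_taxon_trait.to_numpy()
    a_hat, resid, denom = _phylo_mean_and_resid(y, C)
    Cinv = np.linalg.inv(C)
    ones = np.ones(5)
    assert a_hat == pytest.approx((ones @ Cinv @ y) / (ones @ Cinv @ ones), abs=1e-12)
    d = y - a_hat
    assert resid == pytest.approx(d @ Cinv @ d, abs=1e-12)
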