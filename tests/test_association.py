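"""Founder association scan: kinship, REML null model, Wald scan, blocks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ilqtl import association, simulate
from ilqtl.association import (
    association_scan,
    declare_qtl_blocks,
    fit_null_model,
    kinship_from_indicators,
    pve,
)
from ilqtl.core import founder_indicators


@pytest.fixture
def toy_Z(rng):
    """Valid founder indicators for 6 lines x 8 loci, 4 founders."""
    Z = np.zeros((8, 6, 4))
    for k in range(8):
        for j in range(6):
            donor = 1 + (j % 3)
            d = rng.integers(0, 3)  # dosage 0/1/2
            Z[k, j, 0] = 2 - d
            Z[k, j, donor] = d
    return Z


class TestKinship:
    def test_matches_brute_force_double_loop(self, toy_Z):
        K = kinship_from_indicators(toy_Z)
        m, n, _ = toy_Z.shape
        brute = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                brute[i, j] = sum(toy_Z[k, i] @ toy_Z[k, j] for k in range(m)) / (2 * m)
        assert np.allclose(K, brute, atol=1e-12)

    def test_identical_lines_have_equal_self_and_cross_terms(self, toy_Z):
        Z = toy_Z.copy()
        Z[:, 1, :] = Z[:, 0, :]
        K = kinship_from_indicators(Z)
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_all_recurrent_gives_rank_one_constant_matrix(self):
        Z = np.zeros((5, 4, 4))
        Z[:, :, 0] = 2.0
        K = kinship_from_indicators(Z)
        assert np.allclose(K, 2.0)
        assert np.linalg.matrix_rank(K) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kinship_from_indicators(np.zeros((0, 5, 4)))


class TestNullModel:
    def test_identity_kinship_reduces_to_ols(self, rng):
        n = 80
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 2.0]) + rng.normal(0, 1.5, n)
        fit = fit_null_model(y, X, np.eye(n))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.beta, beta_ols, atol=1e-6)
        resid = y - X @ beta_ols
        s2 = resid @ resid / (n - 2)
        assert fit.sigma2_g + fit.sigma2_e == pytest.approx(s2, rel=1e-4)
        # restricted log-likelihood closed form at V = sigma2 * I:
        # -1/2 [(n-p)(log(2 pi s2) + 1) + log|X'X|]  (scale-invariant profile)
        sign, logdet_xx = np.linalg.slogdet(X.T @ X)
        ll = -0.5 * ((n - 2) * (np.log(2 * np.pi * s2) + 1.0) + logdet_xx)
        assert fit.reml_loglik == pytest.approx(ll, rel=1e-6)

    def test_pure_noise_shrinks_genetic_variance(self, rng):
        n = 100
        u = rng.standard_normal((n, 5))
        K = u @ u.T / 5 + np.eye(n) * 0.01
        ratios = []
        for _ in range(200):
            y = rng.standard_normal(n)
            fit = fit_null_model(y, np.ones((n, 1)), K)
            ratios.append(fit.sigma2_g / max(fit.sigma2_e, 1e-12))
        assert np.median(ratios) < 0.05

    def test_variance_component_recovery(self, rng):
        n = 300
        G = rng.standard_normal((n, 40))
        K = G @ G.T / 40
        L = np.linalg.cholesky(K + 1e-9 * np.eye(n))
        rel_err = []
        for _ in range(100):
            y = 2.0 * (L @ rng.standard_normal(n)) + rng.standard_normal(n)
            fit = fit_null_model(y, np.ones((n, 1)), K)
            rel_err.append(abs(fit.sigma2_g - 4.0) / 4.0)
        assert np.median(rel_err) < 0.25

    def test_reproducible_to_tolerance(self, rng):
        n = 60
        K = np.eye(n)
        y = rng.standard_normal(n)
        f1 = fit_null_model(y, np.ones((n, 1)), K)
        f2 = fit_null_model(y.copy(), np.ones((n, 1)), K)
        assert abs(f1.sigma2_g - f2.sigma2_g) < 1e-6

    def test_nonfinite_phenotype_rejected(self):
        y = np.array([1.0, np.nan, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            fit_null_model(y, np.ones((6, 1)), np.eye(6))

    def test_singular_design_rejected(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError):
            fit_null_model(rng.standard_normal(n), X, np.eye(n))


def _one_pop(seed=3, n=120, markers_per_chrom=10):
    cfg = simulate.SimConfig(
        n_chromosomes=2,
        n_markers_per_chrom=markers_per_chrom,
        n_lines=(n,),
        donors=("Teqing",),
        selection=None,
        n_selected=None,
        seed=seed,
    )
    m = simulate.build_marker_map(cfg)
    pop, _ = simulate.breed_population(cfg, "Teqing", np.random.default_rng(seed), markers=m)
    return pop, m


class TestScan:
    def test_constant_phenotype_gives_zero_statistics(self):
        pop, markers = _one_pop()
        Z, founders, line_ids = founder_indicators([pop])
        y = np.full(len(line_ids), 5.0)
        scan = association_scan(
            y, np.ones((len(y), 1)), None, Z, markers, founders, loco=False
        )
        assert np.allclose(scan["W"], 0.0, atol=1e-8)

    def test_agrees_with_ols_dosage_regression_when_kinship_off(self, rng):
        """With the polygenic weight at zero and one founder contrast, the
        scan Wald statistic equals the squared t of an ordinary dosage
        regression and the p-values agree on the same reference."""
        pop, markers = _one_pop(seed=4)
        Z, founders, line_ids = founder_indicators([pop])
        n = len(line_ids)
        y = rng.standard_normal(n) + 0.3 * pop.genotypes[:, 0]
        X = np.ones((n, 1))
        fit = fit_null_model(y, X, np.zeros((n, n)))
        scan = association_scan(
            y, X, np.zeros((n, n)), Z, markers, founders, null_fit=fit, loco=False
        )
        # null-model residual variance (REML with intercept only)
        s2_null = np.sum((y - y.mean()) ** 2) / (n - 1)
        Q = np.eye(n) - np.ones((n, n)) / n
        for k in [0, 3, 15]:
            d = pop.genotypes[:, k].astype(float)
            if d.std() == 0:
                continue
            # independent OLS route to the same score-type quadratic form
            w_oracle = (d @ Q @ y) ** 2 / ((d @ Q @ d) * s2_null)
            assert scan.iloc[k]["W"] == pytest.approx(w_oracle, rel=1e-6)
            assert scan.iloc[k]["p_value"] == pytest.approx(
                float(stats.chi2.sf(w_oracle, 1)), rel=1e-6
            )
            assert scan.iloc[k]["df"] == 1
            # ties to the classical regression t-test up to the O(1/n)
            # difference between null- and model-based variance estimates
            Xk = np.column_stack([np.ones(n), d])
            beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
            resid = y - Xk @ beta
            t2 = (d @ Q @ y) ** 2 / ((d @ Q @ d) * (resid @ resid / (n - 2)))
            assert scan.iloc[k]["W"] == pytest.approx(t2, rel=0.1)

    def test_founder_relabeling_permutes_effects(self, rng):
        pop, markers = _one_pop(seed=5)
        Z, founders, line_ids = founder_indicators([pop])
        n = len(line_ids)
        y = rng.standard_normal(n) + 0.5 * pop.genotypes[:, 2]
        X = np.ones((n, 1))
        scan = association_scan(y, X, None, Z, markers, founders, loco=False)
        Zp = Z[:, :, ::-1]  # swap founder slots
        scan_p = association_scan(
            y, X, None, Zp, markers, founders[::-1], loco=False
        )
        assert np.allclose(scan["W"], scan_p["W"], atol=1e-8)
        assert np.allclose(
            scan["effect_HHZ"], scan_p["effect_HHZ"], atol=1e-8
        )

    def test_skips_monomorphic_marker(self, tiny_map):
        from ilqtl.core import Population

        g = np.zeros((30, 10), dtype=np.int8)
        g[:, 1] = np.resize([0, 1, 2], 30)
        pop = Population(
            population_id="p",
            recurrent_id="HHZ",
            donor_id="Teqing",
            scheme=(1, 3),
            line_ids=[f"L{i}" for i in range(30)],
            genotypes=g,
            markers=tiny_map,
        )
        Z, founders, _ = founder_indicators([pop])
        y = np.random.default_rng(0).standard_normal(30)
        scan = association_scan(
            y, np.ones((30, 1)), None, Z, tiny_map, founders, loco=False
        )
        assert bool(scan.iloc[0]["skipped"])  # all recurrent
        assert not bool(scan.iloc[1]["skipped"])


class TestPve:
    def test_zero_effect(self, rng):
        Z = rng.integers(0, 3, size=(50, 4)).astype(float)
        y = rng.standard_normal(50)
        assert pve(Z, np.zeros(4), y) == 0.0

    def test_exact_fit_is_100(self, rng):
        Z = rng.integers(0, 3, size=(50, 4)).astype(float)
        gamma = np.array([0.0, 1.0, -0.5, 2.0])
        y = Z @ gamma
        assert pve(Z, gamma, y) == pytest.approx(100.0)

    def test_invariant_to_affine_rescaling_of_y(self, rng):
        Z = rng.integers(0, 3, size=(50, 4)).astype(float)
        gamma = np.array([0.0, 1.0, -0.5, 2.0])
        y = Z @ gamma + rng.standard_normal(50)
        v1 = pve(Z, gamma, y)
        # rescaling y rescales the fitted effects by the same factor
        v2 = pve(Z, gamma * 3.0, y * 3.0 + 7.0)
        assert v1 == pytest.approx(v2)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            pve(np.ones((10, 4)), np.ones(4), np.ones(10))


class TestBlocks:
    def _scan(self, rows):
        cols = [
            "marker_id", "chrom", "pos_bp", "bin_100kb", "W", "df",
            "p_value", "pve", "favorable_source", "significant", "skipped",
            "effect_HHZ", "effect_Teqing",
        ]
        return pd.DataFrame(rows, columns=cols)

    def test_empty_when_nothing_significant(self):
        scan = self._scan(
            [("m1", 1, 150_000, 2, 1.0, 3, 0.5, 1.0, "HHZ", False, False, 0.1, -0.1)]
        )
        assert declare_qtl_blocks(scan, np.zeros((10, 1))) == []

    def test_perfect_ld_neighbors_merge(self, rng):
        d = rng.integers(0, 3, size=20).astype(float)
        dosage = np.column_stack([d, d])
        scan = self._scan(
            [
                ("m1", 1, 150_000, 2, 30.0, 3, 1e-6, 10.0, "Teqing", True, False, -0.5, 0.5),
                ("m2", 1, 350_000, 4, 28.0, 3, 1e-5, 9.0, "Teqing", True, False, -0.4, 0.4),
            ]
        )
        blocks = declare_qtl_blocks(scan, dosage)
        assert len(blocks) == 1
        assert (blocks[0].bin_start, blocks[0].bin_end) == (2, 4)
        assert blocks[0].favorable_source == ["Teqing"]

    def test_different_chromosomes_stay_separate(self, rng):
        d = rng.integers(0, 3, size=20).astype(float)
        dosage = np.column_stack([d, d])
        scan = self._scan(
            [
                ("m1", 1, 150_000, 2, 30.0, 3, 1e-6, 10.0, "Teqing", True, False, -0.5, 0.5),
                ("m2", 2, 150_000, 2, 28.0, 3, 1e-5, 9.0, "HHZ", True, False, 0.4, -0.4),
            ]
        )
        blocks = declare_qtl_blocks(scan, dosage)
        assert [b.name for b in blocks] == ["qGY1.1", "qGY2.1"]

    def test_uncorrelated_significant_markers_split(self, rng):
        a = rng.integers(0, 3, size=400).astype(float)
        b = rng.permutation(a)
        dosage = np.column_stack([a, b])
        scan = self._scan(
            [
                ("m1", 1, 150_000, 2, 30.0, 3, 1e-6, 10.0, "Teqing", True, False, -0.5, 0.5),
                ("m2", 1, 250_000, 3, 28.0, 3, 1e-5, 9.0, "Teqing", True, False, -0.4, 0.4),
            ]
        )
        blocks = declare_qtl_blocks(scan, dosage)
        assert len(blocks) == 2
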