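"""Kinship, mixed-model fitting, association scan and heritability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from traitarch.datamodel import GenotypeMatrix
from traitarch.lmm import (
    LMMError,
    _eigen,
    _optimize_lambda,
    _scan_stats,
    assoc_scan,
    broad_sense_h2,
    centered_kinship,
    fit_null_lmm,
    loglik_dense,
)

from conftest import random_genotypes, toy_variants


def gm(values, prefix="l"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return GenotypeMatrix(values, [f"{prefix}{i}" for i in range(n)],
                          [f"1:{1000 + 500 * j}:A:T" for j in range(m)])


class TestCenteredKinship:
    def test_hand_computed_three_lines(self):
        """K from columns [0,1,1] and [0,0,1]: outer-product arithmetic."""
        K = centered_kinship(gm([[0, 0], [1, 0], [1, 1]]))
        assert K[0, 0] == pytest.approx(5 / 18)
        assert K[0, 1] == pytest.approx(-1 / 18)

    def test_constant_column_contributes_nothing(self):
        K1 = centered_kinship(gm([[0, 1], [1, 1], [1, 1]]))
        K2 = centered_kinship(gm([[0], [1], [1]]))
        np.testing.assert_allclose(K1, K2)

    def test_identical_lines_symmetric_entries(self):
        K = centered_kinship(gm([[0, 1, 1], [0, 1, 1], [1, 0, 0]]))
        assert K[0, 0] == pytest.approx(K[1, 1])
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_missing_entries_mean_imputed(self):
        vals = np.array([[0, 1], [1, np.nan], [1, 0]])
        K = centered_kinship(gm(vals))
        assert np.isfinite(K).all()

    def test_monomorphic_only_rejected(self):
        with pytest.raises(LMMError):
            centered_kinship(gm([[1, 0], [1, 0], [1, 0]]))

    def test_centered_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        g, _ = random_genotypes(rng, 8, 30)
        K = centered_kinship(g)
        np.testing.assert_allclose(K.sum(axis=1), 0.0, atol=1e-10)
        assert np.linalg.eigvalsh(K).min() > -1e-10


class TestNullFit:
    def test_matches_dense_likelihood_on_random_instances(self):
        """Eigen-trick (RE)ML equals the dense no-trick evaluation to 1e-8."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = rng.integers(5, 9)
            g, _ = random_genotypes(rng, n, 20)
            K = centered_kinship(g)
            y = rng.normal(size=n)
            W = np.ones((n, 1))
            d, U = _eigen(K)
            for reml in (False, True):
                lam = float(rng.uniform(0.1, 10.0))
                from traitarch.lmm import _loglik_rotated

                ll_rot = _loglik_rotated(lam, d, U.T @ y, U.T @ W, reml)
                ll_dense = loglik_dense(lam, y, W, K, reml=reml)
                assert ll_rot == pytest.approx(ll_dense, abs=1e-8)

    def test_pve_near_one_without_noise(self):
        rng = np.random.default_rng(2)
        g, _ = random_genotypes(rng, 100, 300)
        K = centered_kinship(g)
        # y drawn from N(0, K): pure genetic signal
        L = np.linalg.cholesky(K + 1e-8 * np.eye(100))
        y = L @ rng.normal(size=100)
        fit = fit_null_lmm(y, np.ones((100, 1)), K)
        assert fit.pve >= 0.99

    def test_pve_near_zero_for_independent_noise(self):
        rng = np.random.default_rng(3)
        pves = []
        for s in range(10):
            g, _ = random_genotypes(np.random.default_rng(s), 60, 150)
            K = centered_kinship(g)
            y = rng.normal(size=60)
            pves.append(fit_null_lmm(y, np.ones((60, 1)), K).pve)
        assert np.mean(pves) < 0.25

    def test_pve_invariant_to_shift_and_scale(self):
        rng = np.random.default_rng(4)
        g, _ = random_genotypes(rng, 40, 100)
        K = centered_kinship(g)
        y = rng.normal(size=40) + (K @ rng.normal(size=40))
        W = np.ones((40, 1))
        base = fit_null_lmm(y, W, K).pve
        assert fit_null_lmm(y + 100.0, W, K).pve == pytest.approx(base, abs=1e-6)
        assert fit_null_lmm(y * 3.5, W, K).pve == pytest.approx(base, abs=1e-6)

    def test_zero_variance_phenotype_rejected(self):
        g = gm([[0, 1], [1, 0], [1, 1]])
        K = centered_kinship(g)
        with pytest.raises(LMMError, match="variance"):
            fit_null_lmm(np.ones(3), np.ones((3, 1)), K)


class TestAssocScan:
    def test_ols_reduction_group_mean_difference(self):
        """With K = I and intercept-only W, beta is the group-mean contrast."""
        g = gm([[0], [0], [1], [1]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = assoc_scan(y, g, np.ones((4, 1)), np.eye(4), maf_min=0.0)
        assert res["beta"][0] == pytest.approx(2.0, abs=1e-6)

    def test_scaled_identity_kinship_equals_ols(self):
        """With K = cI the scan reproduces OLS beta and LRT p exactly."""
        rng = np.random.default_rng(5)
        n, m = 30, 12
        g, _ = random_genotypes(rng, n, m)
        y = rng.normal(size=n) + g.values[:, 0]
        W = np.ones((n, 1))
        for c in (0.5, 1.0, 4.0):
            res = assoc_scan(y, g, W, c * np.eye(n), maf_min=0.0)
            for j in range(m):
                x = g.values[:, j]
                X = np.column_stack([np.ones(n), x])
                beta_ols = np.linalg.lstsq(X, y, rcond=None)[0][1]
                rss1 = np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
                rss0 = np.sum((y - y.mean()) ** 2)
                stat = n * np.log(rss0 / rss1)
                p_ols = stats.chi2.sf(stat, 1)
                assert res["beta"][j] == pytest.approx(beta_ols, abs=1e-6)
                assert res["p_lrt"][j] == pytest.approx(p_ols, rel=1e-4, abs=1e-12)

    def test_identical_columns_identical_results(self):
        rng = np.random.default_rng(6)
        vals = (rng.random((20, 3)) < 0.4).astype(float)
        vals[:, 2] = vals[:, 0]
        g = gm(vals)
        y = rng.normal(size=20) + vals[:, 0]
        K = centered_kinship(g)
        res = assoc_scan(y, g, np.ones((20, 1)), K, maf_min=0.0)
        assert res["beta"][0] == pytest.approx(res["beta"][2], abs=1e-9)
        assert res["p_lrt"][0] == pytest.approx(res["p_lrt"][2], abs=1e-9)

    def test_fixed_lambda_matches_dense_gls(self):
        """Per-marker beta at fixed lambda equals closed-form dense GLS."""
        rng = np.random.default_rng(7)
        n = 5
        g = gm([[0, 1, 0, 1], [1, 0, 1, 1], [0, 1, 1, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        K = centered_kinship(g)
        y = rng.normal(size=n)
        W = np.ones((n, 1))
        d, U = _eigen(K)
        lam = 2.3
        ll, beta, se, ok = _scan_stats(
            np.full(4, lam), d, U.T @ y, U.T @ W, U.T @ g.values
        )
        V = lam * K + np.eye(n)
        Vinv = np.linalg.inv(V)
        for j in range(4):
            X = np.column_stack([W, g.values[:, j]])
            coef = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
            assert beta[j] == pytest.approx(coef[1], abs=1e-8)

    def test_covariate_variant_returns_na(self):
        rng = np.random.default_rng(8)
        g, _ = random_genotypes(rng, 25, 6)
        y = rng.normal(size=25)
        K = centered_kinship(g)
        vid = g.variant_ids[2]
        res = assoc_scan(y, g, np.ones((25, 1)), K, covariate_variants=[vid])
        assert np.isnan(res.set_index("id").loc[vid, "p_lrt"])

    def test_below_maf_flagged_untested(self):
        vals = np.zeros((20, 1))
        vals[0, 0] = 1.0  # maf 0.05 - epsilon? maf = 1/20 = 0.05
        g = gm(vals)
        y = np.random.default_rng(9).normal(size=20)
        res = assoc_scan(y, g, np.ones((20, 1)), np.eye(20), maf_min=0.1)
        assert not res["tested"][0] and np.isnan(res["p_lrt"][0])

    def test_null_p_values_approximately_uniform(self):
        """Permuted phenotypes give ~uniform LRT p-values (KS < 0.05)."""
        rng = np.random.default_rng(10)
        g, _ = random_genotypes(rng, 60, 100)
        K = centered_kinship(g)
        base = rng.normal(size=60)
        W = np.ones((60, 1))
        ps = []
        for _ in range(20):
            y = rng.permutation(base)
            res = assoc_scan(y, g, W, K, maf_min=0.0)
            ps.extend(res["p_lrt"].dropna())
        ps = np.asarray(ps)
        ks = stats.kstest(ps, "uniform").statistic
        assert len(ps) >= 2000
        assert ks < 0.05


class TestBroadSenseH2:
    def test_identical_replicates_give_one(self):
        df = pd.DataFrame(
            {
                "line": ["a", "a", "b", "b"],
                "rep": [0, 1, 0, 1],
                "block": ["B0"] * 4,
                "flowering_days": [10.0, 10.0, 20.0, 20.0],
                "seed_count": [1.0] * 4,
            }
        )
        assert broad_sense_h2(df) > 0.999

    def test_balanced_anova_closed_form(self):
        """2 lines x 2 reps, A = {1,3}, B = {5,7}: H2 = 7/9 exactly."""
        df = pd.DataFrame(
            {
                "line": ["A", "A", "B", "B"],
                "rep": [0, 1, 0, 1],
                "block": ["B0"] * 4,
                "flowering_days": [1.0, 3.0, 5.0, 7.0],
                "seed_count": [1.0] * 4,
            }
        )
        assert broad_sense_h2(df) == pytest.approx(7 / 9, abs=1e-6)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(11)
        est = []
        for s in range(10):
            df = pd.DataFrame(
                {
                    "line": np.repeat([f"l{i}" for i in range(40)], 3),
                    "rep": list(range(3)) * 40,
                    "block": ["B0"] * 120,
                    "flowering_days": rng.normal(50, 5, size=120),
                    "seed_count": 1.0,
                }
            )
            est.append(broad_sense_h2(df))
        assert np.mean(est) < 0.1

    def test_agrees_with_statsmodels_mixedlm(self):
        """Independent REML route: statsmodels MixedLM variance components."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(12)
        n_lines, reps = 30, 4
        g = rng.normal(0, 2.0, size=n_lines)
        rows = []
        for i in range(n_lines):
            for r in range(reps):
                rows.append(
                    dict(line=f"l{i}", rep=r, block=f"B{r % 2}",
                         flowering_days=50 + g[i] + 0.4 * (r % 2)
                         + rng.normal(0, 1.0),
                         seed_count=1.0)
                )
        df = pd.DataFrame(rows)
        ours = broad_sense_h2(df)
        md = smf.mixedlm("flowering_days ~ C(block)", df, groups=df["line"]).fit(reml=True)
        var_line = float(md.cov_re.iloc[0, 0])
        var_res = float(md.scale)
        theirs = var_line / (var_line + var_res)
        assert ours == pytest.approx(theirs, abs=1e-3)

    def test_single_replicate_lines_rejected(self):
        df = pd.DataFrame(
            {
                "line": ["a", "b", "c"],
                "rep": [0, 0, 0],
                "block": ["B0"] * 3,
                "flowering_days": [1.0, 2.0, 3.0],
                "seed_count": [1.0] * 3,
            }
        )
        with pytest.raises(LMMError):
            broad_sense_h2(df)
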