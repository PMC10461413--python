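"""Linear mixed-model machinery for association mapping in inbred lines.

The model is the standard single-kinship LMM

    y = W alpha + x beta + u + eps,   u ~ N(0, sigma_g^2 K),  eps ~ N(0, sigma_e^2 I)

profiled over the variance ratio lambda = sigma_g^2 / sigma_e^2 via a single
eigendecomposition of the kinship matrix K.  After rotating y, W and x by
the eigenvectors, the covariance becomes diagonal with weights
lambda * d_i + 1, so every likelihood evaluation is a weighted least
squares at O(n) cost.  The per-marker test is a likelihood-ratio test
against the no-marker null on one degree of freedom, matching the choice
of reporting beta (trait units per derived allele) plus an LRT p-value.

lambda is maximized on a 100-point log grid over [1e-5, 1e5] followed by
local refinement: Brent for the single null fit, a vectorized
golden-section pass for the genome scan (one bracket per marker).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import GenotypeMatrix

LAMBDA_BOUNDS = (1e-5, 1e5)
N_GRID = 100

_LOG2PI = np.log(2.0 * np.pi)


class LMMError(ValueError):
    pass


def centered_kinship(genotypes: GenotypeMatrix) -> np.ndarray:
    """Centered kinship K = (1/m) sum_j (x_j - xbar_j 1)(x_j - xbar_j 1)^T.

    Missing dosages are mean-imputed per variant (only here — stored
    matrices keep their missing entries).  Monomorphic variants are
    skipped; m counts the retained variants.
    """
    X = genotypes.values.copy()
    n = X.shape[0]
    if n < 2:
        raise LMMError("kinship needs at least two lines")
    mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(mean, np.nonzero(nan_mask)[1])
    centered = X - X.mean(axis=0)
    poly = centered.std(axis=0) > 0
    m = int(poly.sum())
    if m == 0:
        raise LMMError("no polymorphic variants; kinship undefined")
    C = centered[:, poly]
    return (C @ C.T) / m


@dataclass
class LMMFit:
    """Null-model fit: variance ratio, residual variance, REML loglik, PVE."""

    lambda_hat: float
    sigma_e2: float
    loglik: float
    pve: float


def _eigen(K: np.ndarray):
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)  # K is PSD up to round-off
    return d, U


def _wls(y, W, weights_inv):
    """Weighted LS of y on W with per-observation inverse variances.

    Returns (coef, rss, logdet_XtWX)."""
    Ww = W * weights_inv[:, None]
    A = W.T @ Ww
    b = Ww.T @ y
    coef = np.linalg.solve(A, b)
    resid = y - W @ coef
    rss = float(np.sum(resid * resid * weights_inv))
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        raise LMMError("covariate matrix not full rank")
    return coef, rss, logdet


def _loglik_rotated(lam, d, y_r, W_r, reml):
    """Profile (RE)ML log-likelihood at variance ratio ``lam``.

    Works on eigen-rotated data; sigma_e^2 is profiled out.
    """
    n, c = W_r.shape
    v = lam * d + 1.0
    winv = 1.0 / v
    _, rss, logdet_A = _wls(y_r, W_r, winv)
    sum_log_v = float(np.sum(np.log(v)))
    if not np.isfinite(rss) or rss <= 0:
        return -np.inf
    if reml:
        df = n - c
        s2 = rss / df
        return -0.5 * (df * _LOG2PI + sum_log_v + logdet_A + df * np.log(s2) + df)
    s2 = rss / n
    return -0.5 * (n * _LOG2PI + sum_log_v + n * np.log(s2) + n)


def loglik_dense(lam, y, W, K, reml=False):
    """Reference (RE)ML log-likelihood via dense V = lam*K + I (no eigen trick).

    Kept deliberately independent of the rotated path; used to validate it.
    """
    n, c = W.shape
    V = lam * K + np.eye(n)
    Vinv = np.linalg.inv(V)
    A = W.T @ Vinv @ W
    alpha = np.linalg.solve(A, W.T @ Vinv @ y)
    r = y - W @ alpha
    rss = float(r @ Vinv @ r)
    _, logdet_V = np.linalg.slogdet(V)
    if reml:
        df = n - c
        s2 = rss / df
        _, logdet_A = np.linalg.slogdet(A)
        return -0.5 * (df * _LOG2PI + logdet_V + logdet_A + df * np.log(s2) + df)
    s2 = rss / n
    return -0.5 * (n * _LOG2PI + logdet_V + n * np.log(s2) + n)


def _optimize_lambda(d, y_r, W_r, reml):
    """Grid + Brent maximization of the profile likelihood over lambda."""
    grid = np.logspace(np.log10(LAMBDA_BOUNDS[0]), np.log10(LAMBDA_BOUNDS[1]), N_GRID)
    lls = np.array([_loglik_rotated(l, d, y_r, W_r, reml) for l in grid])
    if not np.isfinite(lls).any():
        raise LMMError(
            f"non-finite likelihood everywhere on lambda grid {LAMBDA_BOUNDS}"
        )
    i = int(np.nanargmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, N_GRID - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_loglik_rotated(np.exp(t), d, y_r, W_r, reml),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    ll = -float(res.fun)
    if ll < lls[i]:  # refinement should never lose to the grid
        lam, ll = float(grid[i]), float(lls[i])
    return lam, ll


def fit_null_lmm(y, W, K) -> LMMFit:
    """REML fit of the no-marker LMM; PVE uses trace(K)/n scaling.

    pve = lambda_hat * kbar / (lambda_hat * kbar + 1) with
    kbar = trace(K)/n, the mean diagonal of the (uncentered-scale)
    kinship: the fraction of phenotypic variance attributable to
    relatedness under the fitted variance ratio.
    """
    y = np.asarray(y, dtype=float)
    W = np.asarray(W, dtype=float)
    n = y.shape[0]
    if W.ndim != 2 or W.shape[0] != n or K.shape != (n, n):
        raise LMMError("dimension mismatch between y, W and K")
    if np.std(y) == 0:
        raise LMMError("phenotype has zero variance")
    d, U = _eigen(K)
    y_r = U.T @ y
    W_r = U.T @ W
    lam, ll = _optimize_lambda(d, y_r, W_r, reml=True)
    v = lam * d + 1.0
    _, rss, _ = _wls(y_r, W_r, 1.0 / v)
    sigma_e2 = rss / (n - W.shape[1])
    kbar = float(np.trace(K)) / n
    pve = lam * kbar / (lam * kbar + 1.0)
    return LMMFit(lambda_hat=lam, sigma_e2=sigma_e2, loglik=ll, pve=pve)


def _scan_stats(lam_vec, d, y_r, W_r, X_r):
    """Per-marker ML quantities at per-marker lambda values (vectorized).

    Returns (loglik, beta, se, ok) arrays over markers.  X_r is n x m.
    """
    n, c = W_r.shape
    m = X_r.shape[1]
    V = lam_vec[:, None] * d[None, :] + 1.0  # (m, n)
    Winv = 1.0 / V
    Xm = X_r.T  # (m, n)
    # normal equations blocks, batched over markers
    WtW = np.einsum("mn,nc,nk->mck", Winv, W_r, W_r)
    WtX = np.einsum("mn,nc->mc", Winv * Xm, W_r)
    XtX = np.sum(Winv * Xm * Xm, axis=1)
    Wty = np.einsum("mn,nc->mc", Winv * y_r[None, :], W_r)
    Xty = np.sum(Winv * Xm * y_r[None, :], axis=1)
    yty = np.sum(Winv * y_r[None, :] ** 2, axis=1)

    A = np.empty((m, c + 1, c + 1))
    A[:, :c, :c] = WtW
    A[:, :c, c] = WtX
    A[:, c, :c] = WtX
    A[:, c, c] = XtX
    rhs = np.concatenate([Wty, Xty[:, None]], axis=1)

    ok = np.ones(m, dtype=bool)
    coef = np.zeros((m, c + 1))
    Ainv = np.zeros_like(A)
    for j in range(m):  # batched solve with per-marker singularity guard
        try:
            Ainv[j] = np.linalg.inv(A[j])
            coef[j] = Ainv[j] @ rhs[j]
        except np.linalg.LinAlgError:
            ok[j] = False
    # near-collinear markers: unstable Schur complement
    ok &= np.abs(np.diagonal(Ainv, axis1=1, axis2=2)[:, c]) < 1e12

    rss = yty - np.einsum("mk,mk->m", coef, rhs)
    ok &= rss > 1e-12
    rss = np.where(ok, rss, np.nan)
    sum_log_v = np.sum(np.log(V), axis=1)
    ll = -0.5 * (n * _LOG2PI + sum_log_v + n * np.log(rss / n) + n)
    s2 = rss / n
    beta = coef[:, c]
    se = np.sqrt(s2 * np.diagonal(Ainv, axis1=1, axis2=2)[:, c])
    return ll, beta, se, ok


def assoc_scan(
    y,
    genotypes: GenotypeMatrix,
    W,
    K,
    covariate_variants=(),
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Univariate LMM scan: per-marker ML beta, se and LRT p-value.

    lambda is re-optimized per marker (grid + vectorized golden-section);
    the LRT compares against the no-marker ML null on 1 df.  Variants in
    ``covariate_variants`` are appended (0/1 dosage) to the covariates W;
    their own tests return NA by collinearity.  Monomorphic or
    below-``maf_min`` variants return NA with ``tested = False``.
    Missing dosages are mean-imputed for testing only; ``n_used`` counts
    the genotyped lines per marker.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if genotypes.n_lines != n:
        raise LMMError("phenotype and genotype line counts differ")
    W = np.asarray(W, dtype=float)
    X = genotypes.values.copy()
    nan_mask = np.isnan(X)
    n_used = (~nan_mask).sum(axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.where(nan_mask, 0.0, X).sum(axis=0)
        mean = np.where(n_used > 0, sums / np.maximum(n_used, 1), 0.0)
    X[nan_mask] = np.take(mean, np.nonzero(nan_mask)[1])

    freq = mean
    maf = np.minimum(freq, 1.0 - freq)
    testable = (maf >= maf_min) & (X.std(axis=0) > 0) & (n_used >= 2)

    if covariate_variants:
        idx = {v: i for i, v in enumerate(genotypes.variant_ids)}
        missing_ids = [v for v in covariate_variants if v not in idx]
        if missing_ids:
            raise LMMError(f"covariate variant(s) not found: {missing_ids}")
        cov_cols = [idx[v] for v in covariate_variants]
        W = np.hstack([W, X[:, cov_cols]])
        testable[cov_cols] = False  # exactly collinear with itself

    d, U = _eigen(K)
    y_r = U.T @ y
    W_r = U.T @ W
    X_r = U.T @ X[:, testable]
    m = X_r.shape[1]

    beta = np.full(genotypes.n_variants, np.nan)
    se = np.full(genotypes.n_variants, np.nan)
    p = np.full(genotypes.n_variants, np.nan)

    if m > 0:
        _, ll_null = _optimize_lambda(d, y_r, W_r, reml=False)
        grid = np.logspace(
            np.log10(LAMBDA_BOUNDS[0]), np.log10(LAMBDA_BOUNDS[1]), N_GRID
        )
        best_ll = np.full(m, -np.inf)
        best_i = np.zeros(m, dtype=int)
        for i, lam in enumerate(grid):
            ll, _, _, ok = _scan_stats(np.full(m, lam), d, y_r, W_r, X_r)
            ll = np.where(ok, ll, -np.inf)
            better = ll > best_ll
            best_ll[better] = ll[better]
            best_i[better] = i
        # golden-section refinement in log-lambda, one bracket per marker
        lo = np.log(grid[np.maximum(best_i - 1, 0)])
        hi = np.log(grid[np.minimum(best_i + 1, N_GRID - 1)])
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c1 = b - invphi * (b - a)
        c2 = a + invphi * (b - a)
        f1 = _scan_stats(np.exp(c1), d, y_r, W_r, X_r)[0]
        f2 = _scan_stats(np.exp(c2), d, y_r, W_r, X_r)[0]
        for _ in range(30):
            take1 = f1 >= f2  # maximize
            b = np.where(take1, c2, b)
            a = np.where(take1, a, c1)
            c1 = b - invphi * (b - a)
            c2 = a + invphi * (b - a)
            f1 = _scan_stats(np.exp(c1), d, y_r, W_r, X_r)[0]
            f2 = _scan_stats(np.exp(c2), d, y_r, W_r, X_r)[0]
        lam_hat = np.exp((a + b) / 2.0)
        ll_alt, b_hat, se_hat, ok = _scan_stats(lam_hat, d, y_r, W_r, X_r)
        ll_alt = np.maximum(ll_alt, best_ll)  # never worse than the grid
        stat = np.clip(2.0 * (ll_alt - ll_null), 0.0, None)
        p_vals = stats.chi2.sf(stat, df=1)
        p_vals = np.clip(p_vals, np.finfo(float).tiny, 1.0)
        p_vals[~ok] = np.nan
        b_hat[~ok] = np.nan
        se_hat[~ok] = np.nan
        sel = np.flatnonzero(testable)
        beta[sel] = b_hat
        se[sel] = se_hat
        p[sel] = p_vals

    return pd.DataFrame(
        {
            "id": genotypes.variant_ids,
            "maf": maf,
            "beta": beta,
            "se": se,
            "p_lrt": p,
            "n_used": n_used,
            "tested": testable & ~np.isnan(p),
        }
    )


def broad_sense_h2(phenotypes: pd.DataFrame, trait: str = "flowering_days") -> float:
    """Broad-sense heritability from replicated lines: var_line / (var_line + var_res).

    REML fit of trait = block (fixed) + line (random) + residual, done with
    the same eigen-LMM core using the line-incidence kinship K = Z Z^T at
    replicate level; H2 = lambda_hat / (1 + lambda_hat).  For balanced
    designs this agrees with the ANOVA method-of-moments closed form.
    """
    from .datamodel import make_phenotype_table

    df = make_phenotype_table(phenotypes).dropna(subset=[trait])
    reps_per_line = df.groupby("line")[trait].count()
    if (reps_per_line >= 2).sum() < 2:
        raise LMMError("need >= 2 lines with >= 2 replicates for H2")
    y = df[trait].to_numpy(dtype=float)
    n = len(y)
    lines = pd.Categorical(df["line"])
    Z = np.zeros((n, len(lines.categories)))
    Z[np.arange(n), lines.codes] = 1.0
    K = Z @ Z.T
    blocks = pd.Categorical(df["block"])
    W = np.ones((n, 1))
    if len(blocks.categories) > 1:
        B = np.zeros((n, len(blocks.categories) - 1))
        sel = blocks.codes > 0
        B[np.flatnonzero(sel), blocks.codes[sel] - 1] = 1.0
        W = np.hstack([W, B])
    d, U = _eigen(K)
    y_r = U.T @ y
    W_r = U.T @ W
    if np.std(y) == 0:
        return 0.0
    lam, _ = _optimize_lambda(d, y_r, W_r, reml=True)
    return float(lam / (1.0 + lam))
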