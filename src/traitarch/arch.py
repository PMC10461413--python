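"""Genetic-architecture statistics.

The centerpiece is the maximum-likelihood comparison of two one-parameter
families for the absolute effect sizes of candidate loci: an exponential
distribution (the expectation for an adaptive walk toward a shifted
optimum, where a few early large-effect substitutions dominate) against a
uniform distribution on (0, theta] (the expectation under an
infinitesimal-style architecture maintained by stabilizing selection).
Model choice is by AIC with one parameter each:

    exponential: lambda_hat = 1/mean, loglik = n (ln lambda_hat - 1)
    uniform:     theta_hat = max,     loglik = -n ln theta_hat

Also here: rank and correlation tests between populations, Watterson's
theta and the derived effective population size, and a closed-form
neutral expectation for allele age given frequency — an explicit
stand-in for genealogy-based age estimation, not a reimplementation of
it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FitComparison:
    """Exponential-vs-uniform ML fit of absolute effect sizes."""

    n: int
    lambda_hat: float  # exponential rate, 1/days
    theta_hat: float  # uniform upper bound, days
    loglik_exp: float
    loglik_unif: float
    aic_exp: float
    aic_unif: float
    chosen: str  # "exponential" | "uniform"
    tie: bool = False


def fit_effect_distributions(abs_betas, unbiased_uniform: bool = False) -> FitComparison:
    """ML fit + AIC comparison of exponential vs uniform on |beta| > 0.

    Both families carry one free parameter (the uniform lower bound is
    fixed at 0), so AIC = 2 - 2*loglik for each.  Ties go to uniform and
    are flagged.  ``unbiased_uniform`` swaps the uniform MLE (sample max)
    for the (n+1)/n * max variant.
    """
    x = np.asarray(list(abs_betas), dtype=float)
    if x.size == 0:
        raise ValueError("need at least one effect size")
    if (x <= 0).any() or not np.isfinite(x).all():
        raise ValueError("effect sizes must be positive and finite (use |beta|)")
    n = x.size
    lam = 1.0 / x.mean()
    theta = x.max() * ((n + 1) / n if unbiased_uniform else 1.0)
    ll_exp = n * (np.log(lam) - 1.0)
    ll_unif = -n * np.log(theta)
    aic_exp = 2.0 - 2.0 * ll_exp
    aic_unif = 2.0 - 2.0 * ll_unif
    tie = np.isclose(aic_exp, aic_unif, rtol=0.0, atol=1e-12)
    chosen = "uniform" if (tie or aic_unif < aic_exp) else "exponential"
    return FitComparison(
        n=n,
        lambda_hat=float(lam),
        theta_hat=float(theta),
        loglik_exp=float(ll_exp),
        loglik_unif=float(ll_unif),
        aic_exp=float(aic_exp),
        aic_unif=float(aic_unif),
        chosen=chosen,
        tie=bool(tie),
    )


def mann_whitney(x, y):
    """Mann-Whitney U with exact p for small tie-free samples.

    Exact enumeration when min(n1, n2) < 8 and the pooled sample has no
    ties; otherwise the tie-corrected normal approximation.  Identical
    constant samples return p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) < 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_cor(x, y):
    """Pearson correlation with the usual t-based two-sided p (n-2 df)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson denominator."""
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(S: int, n: int, L: float = 1.0) -> float:
    """Watterson's theta per site: S / (a_n * L)."""
    if n < 2 or L < 1:
        raise ValueError("need sample size >= 2 and L >= 1")
    return S / (harmonic_number(n) * L)


def ne_from_theta(theta_per_site: float, mu: float) -> float:
    """Long-term diploid N_e = theta_W / (4 mu)."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    return theta_per_site / (4.0 * mu)


def expected_allele_age(p: float, N_e: float) -> float:
    """Mean age (generations) of a neutral derived allele at frequency p.

    Closed-form diffusion expectation t = -4 N_e p ln(p) / (1 - p).  This
    is a neutral-expectation stand-in used to relate frequency to age; it
    is not a genealogy-based age estimate and carries no per-locus
    uncertainty.
    """
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError("frequency must be strictly between 0 and 1")
    return -4.0 * N_e * p * np.log(p) / (1.0 - p)


@dataclass
class PopulationReport:
    """Per-population architecture summary."""

    population: str
    n_zones: int
    n_clumps: int
    n_loci: int
    broad_sense_h2: float
    pve: float
    fit: FitComparison | None
    cor_daf_beta: tuple | None  # (r, p) over representative loci
    cor_daf_beta_positive: tuple | None  # loci delaying the trait
    cor_daf_beta_negative: tuple | None  # loci reducing the trait
    cor_age_daf: tuple | None
    theta_w: float | None = None
    n_e: float | None = None


def _safe_pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return pearson_cor(x, y)


def population_report(
    population: str,
    loci: pd.DataFrame,
    n_zones: int,
    n_clumps: int,
    h2: float,
    pve: float,
    ages=None,
    theta_w: float | None = None,
    n_e: float | None = None,
    include_fixed_in_fit: bool = True,
) -> PopulationReport:
    """Assemble the per-population architecture report.

    Distribution fits use |beta| of the representative loci (optionally
    excluding manually added fixed loci); correlations use
    derived-allele-polarized frequencies only (daf = NA rows drop out).
    """
    df = loci.copy()
    fit_df = df if include_fixed_in_fit else df[~df["fixed"].astype(bool)]
    absb = pd.to_numeric(fit_df["beta"], errors="coerce").abs()
    absb = absb[np.isfinite(absb) & (absb > 0)]
    fit = fit_effect_distributions(absb) if len(absb) >= 1 else None
    cor_all = _safe_pearson(df["daf"], df["beta"])
    pos = df[df["beta"] > 0]
    neg = df[df["beta"] < 0]
    cor_pos = _safe_pearson(pos["daf"], pos["beta"])
    cor_neg = _safe_pearson(neg["daf"], neg["beta"])
    cor_age = None
    if ages is not None:
        merged = df.merge(ages, on="id", how="inner")
        if len(merged) >= 3:
            cor_age = _safe_pearson(merged["age"], merged["daf"])
    return PopulationReport(
        population=population,
        n_zones=int(n_zones),
        n_clumps=int(n_clumps),
        n_loci=int(len(df)),
        broad_sense_h2=float(h2),
        pve=float(pve),
        fit=fit,
        cor_daf_beta=cor_all,
        cor_daf_beta_positive=cor_pos,
        cor_daf_beta_negative=cor_neg,
        cor_age_daf=cor_age,
        theta_w=theta_w,
        n_e=n_e,
    )


def compare_populations(reports: dict[str, PopulationReport], loci: dict[str, pd.DataFrame]):
    """Pairwise Mann-Whitney tests on |beta| between populations."""
    names = sorted(reports)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa = loci[a]["beta"].abs().dropna()
            xb = loci[b]["beta"].abs().dropna()
            if len(xa) and len(xb):
                U, p = mann_whitney(xa, xb)
                rows.append(dict(pop_a=a, pop_b=b, U=U, p=p))
    return pd.DataFrame(rows, columns=["pop_a", "pop_b", "U", "p"])


def report_to_dict(report: PopulationReport) -> dict:
    d = asdict(report)
    return d


def write_report(reports, comparisons: pd.DataFrame, path) -> None:
    payload = {
        "populations": {name: report_to_dict(r) for name, r in reports.items()},
        "comparisons": comparisons.to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
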