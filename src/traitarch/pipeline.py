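"""End-to-end orchestration: simulate -> GWAS -> loci -> architecture report.

Two preset study conditions mirror the contrast the package exists to
analyze:

* :func:`continent_config` — a large, long-established, highly selfing
  population under weak stabilizing selection on flowering time (high
  diversity, many small/moderate-effect trait variants);
* :func:`island_config` — the same ancestral process interrupted by a
  colonization bottleneck and a shift of the trait optimum toward
  earlier flowering (strong directional selection, few large-effect
  variants arising largest-first).

Both are desk-scale emulations: population sizes, genome length and time
depth are orders of magnitude below the natural populations they imitate,
with the mutation rate raised so that diversity stays informative; see
docs/methods.md for the scaling argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import arch, ld, localscore
from .datamodel import GenotypeMatrix, median_phenotype, polarize
from .lmm import assoc_scan, broad_sense_h2, centered_kinship, fit_null_lmm
from .sim import SimConfig, simulate_phenotypes, simulate_population


def selfing_ne_factor(selfing: float) -> float:
    """Effective-size reduction 1/(1+F) under partial selfing, F = s/(2-s)."""
    F = selfing / (2.0 - selfing)
    return 1.0 / (1.0 + F)


def continent_config(seed: int = 0, **overrides) -> SimConfig:
    """Forward-simulation preset: stable population under stabilizing selection.

    Used for the stabilizing-regime property checks (trait alleles held
    rare, no sign bias).  The continental *study* population itself is
    generated by :func:`traitarch.sim.simulate_coalescent_lines` (see
    CONTINENT_STUDY), because the continental time depth is beyond any
    forward burn-in.
    """
    params = dict(
        N=160,
        generations=1000,
        L=100_000,
        n_chrom=25,
        mu_per_site=4e-6,
        rec_per_site=1.2e-5,
        selfing=0.95,
        p_null=0.9,
        sigma_effect=3.0,
        regime="stabilizing",
        opt0=0.0,
        omega=8.0,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def island_config(seed: int = 0, **overrides) -> SimConfig:
    """Colonization bottleneck plus optimum shift toward earlier flowering.

    Burn-in of 300 generations, then an extreme founder event (16
    individuals for 3 generations) with the optimum displaced 15 days
    earlier, recovery to the island census of 300, and sampling 400
    generations later — after the first large walk steps have fixed and
    while later small-effect variants segregate.  The trait-mutation
    supply is mutation-limited (10% of mutations causal).  Because the
    founder event destroys almost all standing variation, the short
    burn-in costs little realism.
    """
    params = dict(
        N=300,
        generations=700,
        t_shift=300,
        N_bottleneck=16,
        bottleneck_generations=3,
        L=100_000,
        n_chrom=50,
        mu_per_site=2e-6,
        rec_per_site=2e-5,
        selfing=0.95,
        p_null=0.90,
        sigma_effect=10.0,
        regime="shifted_optimum",
        opt0=0.0,
        opt1=-15.0,
        omega=6.0,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


#: Study conditions for the coalescent-backed continental sample.
CONTINENT_STUDY = dict(
    n_lines=250,
    Ne=5000.0,
    L=100_000,
    n_chrom=50,
    mu_per_site=9e-8,
    rec_per_site=1e-7,
    p_null=0.97,
    sigma_effect=3.5,
)

#: Sample size drawn from the island population (census 300 after recovery).
ISLAND_SAMPLE = 144


def neutral_config(seed: int = 0, **overrides) -> SimConfig:
    params = dict(
        N=100,
        generations=1000,
        L=100_000,
        n_chrom=1,
        mu_per_site=1.25e-7,  # theta = 4 N mu L = 5 per locus at N = 100
        rec_per_site=1e-6,
        selfing=0.0,
        p_null=1.0,
        sigma_effect=0.0,
        regime="neutral",
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@dataclass
class GwasResult:
    trait: pd.Series  # per-line median flowering
    genotypes: GenotypeMatrix  # derived-coded, line-aligned to trait
    variants: pd.DataFrame
    daf: np.ndarray
    kinship: np.ndarray
    null_fit: object
    assoc: pd.DataFrame
    h2: float


def run_gwas(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariate_variants=(),
    covariates: np.ndarray | None = None,
    maf_min: float = 0.05,
) -> GwasResult:
    """Median aggregation -> polarization -> kinship -> null fit -> scan."""
    per_line = median_phenotype(phenotypes)
    common = [l for l in genotypes.line_ids if l in per_line.index]
    if not common:
        only_geno = [l for l in genotypes.line_ids if l not in per_line.index]
        only_phen = [l for l in per_line.index if l not in set(genotypes.line_ids)]
        raise ValueError(
            "no overlap between genotyped and phenotyped lines; "
            f"genotype-only examples: {only_geno[:5]}, "
            f"phenotype-only examples: {only_phen[:5]}"
        )
    G = genotypes.subset_lines(common)
    y = per_line.loc[common, "flowering_days"].to_numpy()
    pol = polarize(G, variants)
    K = centered_kinship(pol.genotypes)
    W = np.ones((len(common), 1))
    if covariates is not None:
        W = np.hstack([W, np.asarray(covariates, dtype=float)])
    fit = fit_null_lmm(y, W, K)
    assoc = assoc_scan(
        y, pol.genotypes, W, K,
        covariate_variants=covariate_variants, maf_min=maf_min,
    )
    h2 = broad_sense_h2(phenotypes[phenotypes["line"].isin(common)])
    return GwasResult(
        trait=pd.Series(y, index=common, name="flowering_days"),
        genotypes=pol.genotypes,
        variants=variants,
        daf=pol.daf,
        kinship=K,
        null_fit=fit,
        assoc=assoc,
        h2=h2,
    )


@dataclass
class ArchitectureResult:
    tracks: dict
    zones: list
    clumps: list
    loci: pd.DataFrame
    n_zones: int = field(init=False)
    n_clumps: int = field(init=False)

    def __post_init__(self):
        self.n_zones = len(self.zones)
        self.n_clumps = len(self.clumps)


def run_architecture(
    gwas: GwasResult,
    xi: float = 2.0,
    alpha: float = 0.05,
    n_resample: int = 1000,
    seed: int = 0,
    clump_p1: float = 0.01,
    clump_window_kb: float = 1000.0,
    clump_r2: float = 0.8,
    rep_r2max: float = 0.5,
    manual_loci: pd.DataFrame | None = None,
    null_calibration: str = "gc",
) -> ArchitectureResult:
    """Local score -> zones -> clumps -> representative loci.

    ``null_calibration`` sets how the per-chromosome significance
    thresholds are built: "uniform" (i.i.d. uniform p-values), "gc"
    (uniform rescaled by the signal-robust genomic-control inflation
    factor of the observed scan — the default, guarding against a
    conservative or inflated association test), or "empirical"
    (resampling the observed p-value marginal directly).
    """
    tracks = localscore.lindley_scores(gwas.assoc, gwas.variants, xi=xi)
    p_obs = gwas.assoc["p_lrt"].dropna().to_numpy()
    p_pool = p_obs if null_calibration == "empirical" else None
    lambda_gc = (
        localscore.genomic_control_lambda(p_obs)
        if null_calibration == "gc" and len(p_obs)
        else 1.0
    )
    zones = []
    for chrom, track in sorted(tracks.items()):
        track.threshold = localscore.significance_threshold(
            len(track.scores), xi, alpha=alpha, n_resample=n_resample, seed=seed,
            p_pool=p_pool, lambda_gc=lambda_gc,
        )
        zones.extend(localscore.call_zones(track))
    clumps = ld.clump(
        gwas.assoc, gwas.genotypes, gwas.variants,
        p1=clump_p1, window_kb=clump_window_kb, r2=clump_r2,
    )
    loci = ld.representative_loci(
        zones, tracks, gwas.assoc, gwas.genotypes, gwas.variants,
        daf=gwas.daf, r2max=rep_r2max, manual_loci=manual_loci,
    )
    return ArchitectureResult(tracks=tracks, zones=zones, clumps=clumps, loci=loci)


def run_regime(
    config: SimConfig,
    n_sample: int,
    population: str,
    h2_target: float = 0.8,
    xi: float = 2.0,
    alpha: float = 0.05,
    n_resample: int = 500,
    maf_min: float = 0.05,
    mu_true: float | None = None,
    manual_loci: pd.DataFrame | None = None,
):
    """Simulate one forward regime and push it through the whole pipeline.

    Returns (PopulationReport, GwasResult, ArchitectureResult, truth)."""
    genotypes, variants, truth, state = simulate_population(config, n_sample=n_sample)
    phen = simulate_phenotypes(
        genotypes, truth, h2_target=h2_target, seed=config.seed + 2
    )
    gwas = run_gwas(genotypes, variants, phen, maf_min=maf_min)
    archres = run_architecture(
        gwas, xi=xi, alpha=alpha, n_resample=n_resample, seed=config.seed + 3,
        manual_loci=manual_loci if manual_loci is None else manual_loci,
    )
    report = _report_for(
        population, gwas, archres, n_sample, config.L,
        mu_true if mu_true is not None else config.mu_per_site,
    )
    return report, gwas, archres, truth


def _report_for(population, gwas, archres, n_sample, L, mu):
    freq = np.nanmean(gwas.genotypes.values, axis=0)
    S = int(np.sum((freq > 0) & (freq < 1)))  # segregating in the sample
    theta = arch.watterson_theta(S, n_sample, L)
    n_e = arch.ne_from_theta(theta, mu)
    return arch.population_report(
        population,
        archres.loci,
        n_zones=archres.n_zones,
        n_clumps=archres.n_clumps,
        h2=gwas.h2,
        pve=gwas.null_fit.pve,
        theta_w=theta,
        n_e=n_e,
    )


def fixed_walk_locus(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame | None:
    """Known fixed causal locus for manual addition to the island locus set.

    Mirrors the treatment of a large-effect variant fixed during
    colonization, which cannot surface in GWAS: the mutation with the
    largest |effect| among those that fixed after the optimum shift in the
    adaptive direction, carried with its externally known effect size.
    Returns a one-row manual-locus table, or None when nothing fixed.
    """
    if config.t_shift is None:
        return None
    direction = np.sign(config.opt1 - config.opt0)
    cand = truth[
        truth["fixed"]
        & (truth["fixation_generation"] > config.t_shift)
        & (np.sign(truth["effect"]) == direction)
        & (truth["effect"] != 0)
    ]
    if not len(cand):
        return None
    row = cand.loc[cand["effect"].abs().idxmax()]
    chrom = row["id"].split(":")[0]
    return pd.DataFrame(
        [
            dict(
                id=row["id"], chrom=chrom, pos=int(row["pos"]),
                beta=float(row["effect"]), p_lrt=np.nan, daf=1.0,
                impact="HIGH", fixed=True,
            )
        ]
    )


def run_study(
    regime: str,
    seed: int,
    h2_target: float = 0.8,
    xi: float = 1.0,
    alpha: float = 0.05,
    n_resample: int = 500,
    maf_min: float = 0.05,
):
    """One replicate of the two-regime study for one regime.

    ``regime`` is "continent" (coalescent-backed large-N_e sample, weak
    stabilizing selection) or "island" (forward colonization +
    optimum-shift simulation with the fixed walk locus added manually).
    The experiment-level xi defaults to 1: desk-scale marginal signals
    are weaker than genome-scale ones and a smaller tuning constant is
    the local-score recommendation in that setting.
    Returns (PopulationReport, GwasResult, ArchitectureResult, truth).
    """
    if regime == "continent":
        from .sim import simulate_coalescent_lines

        params = dict(CONTINENT_STUDY)
        genotypes, variants, truth = simulate_coalescent_lines(seed=seed, **params)
        phen = simulate_phenotypes(genotypes, truth, h2_target=h2_target,
                                   seed=seed + 2, sigma_floor=1.0)
        gwas = run_gwas(genotypes, variants, phen, maf_min=maf_min)
        archres = run_architecture(gwas, xi=xi, alpha=alpha,
                                   n_resample=n_resample, seed=seed + 3)
        report = _report_for("continent", gwas, archres,
                             params["n_lines"], params["L"], params["mu_per_site"])
        return report, gwas, archres, truth
    if regime == "island":
        config = island_config(seed)
        genotypes, variants, truth, state = simulate_population(
            config, n_sample=ISLAND_SAMPLE
        )
        phen = simulate_phenotypes(genotypes, truth, h2_target=h2_target,
                                   seed=seed + 2, sigma_floor=1.0)
        gwas = run_gwas(genotypes, variants, phen, maf_min=maf_min)
        manual = fixed_walk_locus(truth, config)
        archres = run_architecture(gwas, xi=xi, alpha=alpha,
                                   n_resample=n_resample, seed=seed + 3,
                                   manual_loci=manual)
        report = _report_for("island", gwas, archres, ISLAND_SAMPLE,
                             config.L, config.mu_per_site)
        return report, gwas, archres, truth
    raise ValueError(f"unknown regime {regime!r}")


def two_regime_experiment(n_reps: int, base_seed: int = 0, **study_kwargs) -> pd.DataFrame:
    """Replicated island-vs-continent comparison.

    Returns one row per replicate with zone/clump/locus counts and the
    chosen effect-size family per regime.
    """
    rows = []
    for r in range(n_reps):
        seed = base_seed + 1000 * r
        out = {}
        for regime in ("continent", "island"):
            report, gwas, archres, truth = run_study(regime, seed, **study_kwargs)
            out[f"{regime}_zones"] = report.n_zones
            out[f"{regime}_clumps"] = report.n_clumps
            out[f"{regime}_loci"] = report.n_loci
            out[f"{regime}_chosen"] = report.fit.chosen if report.fit else None
            out[f"{regime}_h2"] = report.broad_sense_h2
            out[f"{regime}_pve"] = report.pve
        rows.append(out)
    return pd.DataFrame(rows)
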