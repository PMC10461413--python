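"""Forward Wright-Fisher simulation of a quantitative trait in a selfer.

The simulator produces the synthetic study populations: a discrete-
generation diploid Wright-Fisher population with partial selfing, an
infinite-sites mutation model over a finite genome split into freely
assorting chromosomes, uniform crossovers within the genome, and a single
additive trait under Gaussian stabilizing selection whose optimum (and
population size) can shift once — the colonization event.  Three regimes
are supported:

* ``neutral`` — no selection, all mutations trait-neutral; used for
  diversity calibration against coalescent expectations;
* ``stabilizing`` — a large, long-established population sitting at its
  trait optimum, the "continent" emulation;
* ``shifted_optimum`` — a stabilizing burn-in followed by a bottleneck
  and an optimum displacement, the "island colonization" emulation in
  which an adaptive walk toward the new optimum unfolds.

Every mutation's true effect, origin generation and final frequency are
recorded (:class:`SimTruth` rows), so allele-age and effect-size analyses
downstream can be checked against ground truth.  An origin-fixation walk
(:func:`simulate_origin_fixation_walk`) provides the mutation-limited
adaptive-walk oracle independent of the population simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, make_phenotype_table, make_variant_table

REGIMES = ("neutral", "stabilizing", "shifted_optimum")


@dataclass
class SimConfig:
    N: int
    generations: int
    L: int = 100_000
    n_chrom: int = 5
    mu_per_site: float = 4e-6
    rec_per_site: float = 4e-6
    selfing: float = 0.95
    p_null: float = 0.9
    sigma_effect: float = 3.0
    regime: str = "stabilizing"
    opt0: float = 0.0
    opt1: float = 0.0
    omega: float = 8.0
    t_shift: int | None = None
    N_bottleneck: int | None = None
    bottleneck_generations: int | None = None  # None: size stays at N_bottleneck
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not 0.0 <= self.selfing <= 1.0:
            raise ValueError("selfing must lie in [0, 1]")
        if self.mu_per_site < 0 or self.rec_per_site < 0:
            raise ValueError("rates must be non-negative")
        if self.regime != "neutral" and self.omega <= 0:
            raise ValueError("omega must be positive under selection")
        if self.N_bottleneck is not None and self.N_bottleneck > self.N:
            raise ValueError("N_bottleneck cannot exceed N")
        if self.N_bottleneck is not None and self.N_bottleneck < 2:
            raise ValueError("N_bottleneck must be >= 2")
        if self.t_shift is not None and not 0 < self.t_shift <= self.generations:
            raise ValueError("t_shift must lie in (0, generations]")
        if self.bottleneck_generations is not None and self.bottleneck_generations < 1:
            raise ValueError("bottleneck_generations must be >= 1 when set")
        if self.L < self.n_chrom:
            raise ValueError("genome shorter than chromosome count")
        return self


@dataclass
class PopulationState:
    """Final state of a forward run plus per-mutation ground truth."""

    config: SimConfig
    haplotypes: np.ndarray  # (2N, m) uint8, segregating sites only
    positions: np.ndarray  # (m,) int bp, unsorted
    effects: np.ndarray  # (m,) float trait units
    origins: np.ndarray  # (m,) int generation of origin
    mut_ids: np.ndarray  # (m,) int
    fixed: list = field(default_factory=list)  # dicts for fixed mutations
    trait_mean: np.ndarray = None  # per-generation mean trait value
    z_base: float = 0.0

    @property
    def pop_size(self) -> int:
        return self.haplotypes.shape[0] // 2

    def frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def _selection_probs(z: np.ndarray, opt: float, omega: float) -> np.ndarray:
    logw = -((z - opt) ** 2) / (2.0 * omega**2)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def _draw_position(rng, L, used: set) -> int:
    while True:
        p = int(rng.integers(1, L + 1))
        if p not in used:
            used.add(p)
            return p


def _make_gametes(rng, H, parents, pos, chrom_idx, n_chrom, cx_rate, L):
    """Build one gamete per entry of ``parents`` (diploid indices).

    Chromosomes assort freely; within the genome, crossovers fall
    uniformly at ``cx_rate`` expected per gamete.  Gametes with at most
    one crossover (the vast majority at desk scale) are built in one
    vectorized pass; rarer multi-crossover gametes individually.
    """
    k = len(parents)
    m = H.shape[1]
    n_cx = rng.poisson(cx_rate, size=k)
    flips = rng.integers(0, 2, size=(k, n_chrom)).astype(bool)
    h1 = H[2 * parents]
    h2 = H[2 * parents + 1]
    src = flips[:, chrom_idx].copy()  # (k, m) source haplotype per site
    rec = np.flatnonzero(n_cx > 0)
    if rec.size and m:
        max_cx = int(n_cx.max())
        bps = rng.uniform(0, L, size=(rec.size, max_cx))
        live = np.arange(max_cx)[None, :] < n_cx[rec][:, None]
        bps[~live] = np.inf  # padding beyond each gamete's crossover count
        # crossover parity at each site: count of breakpoints to its left
        parity = (
            (bps[:, :, None] < pos[None, None, :]).sum(axis=1) & 1
        ).astype(bool)
        src[rec] ^= parity
    return np.where(src, h2, h1)


def run_forward(config: SimConfig) -> PopulationState:
    """Run the forward simulation and return the final population state."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    N = cfg.N
    H = np.zeros((2 * N, 0), dtype=np.uint8)
    pos = np.empty(0, dtype=np.int64)
    eff = np.empty(0, dtype=float)
    origin = np.empty(0, dtype=np.int64)
    mut_ids = np.empty(0, dtype=np.int64)
    next_id = 0
    used_positions: set = set()
    fixed: list = []
    z_base = 0.0
    chrom_len = cfg.L / cfg.n_chrom
    opt = cfg.opt0
    mu_per_gamete = cfg.mu_per_site * cfg.L
    cx_rate = cfg.rec_per_site * cfg.L
    trait_mean = np.empty(cfg.generations)
    neutral_trait = cfg.regime == "neutral"

    def target_size(t: int) -> int:
        if (
            cfg.regime == "shifted_optimum"
            and cfg.t_shift is not None
            and cfg.N_bottleneck is not None
            and t >= cfg.t_shift
        ):
            dur = cfg.bottleneck_generations
            if dur is None or t < cfg.t_shift + dur:
                return cfg.N_bottleneck
        return cfg.N

    for t in range(1, cfg.generations + 1):
        if cfg.regime == "shifted_optimum" and cfg.t_shift is not None and t == cfg.t_shift:
            opt = cfg.opt1
        shrink = target_size(t)
        if shrink < N:  # founder event: sample survivors without replacement
            keep = rng.choice(N, size=shrink, replace=False)
            rows = np.empty(2 * shrink, dtype=np.int64)
            rows[0::2] = 2 * keep
            rows[1::2] = 2 * keep + 1
            H = H[rows]
            N = shrink

        m = H.shape[1]
        if m:
            dosage = H[0::2].astype(np.float64) + H[1::2]
            z = dosage @ eff + z_base
        else:
            z = np.full(N, z_base)
        trait_mean[t - 1] = z.mean()

        if cfg.regime == "neutral":
            probs = np.full(N, 1.0 / N)
        else:
            probs = _selection_probs(z, opt, cfg.omega)

        N_next = target_size(t + 1) if t < cfg.generations else N
        selfer = rng.random(N_next) < cfg.selfing
        p1 = rng.choice(N, size=N_next, p=probs)
        p2 = np.where(selfer, p1, rng.choice(N, size=N_next, p=probs))
        chrom_idx = np.minimum((pos - 1) // chrom_len, cfg.n_chrom - 1).astype(np.int64)
        g1 = _make_gametes(rng, H, p1, pos, chrom_idx, cfg.n_chrom, cx_rate, cfg.L)
        g2 = _make_gametes(rng, H, p2, pos, chrom_idx, cfg.n_chrom, cx_rate, cfg.L)
        N = N_next
        H_next = np.empty((2 * N, m), dtype=np.uint8)
        H_next[0::2] = g1
        H_next[1::2] = g2

        n_new = rng.poisson(2 * N * mu_per_gamete)
        if n_new:
            new_cols = np.zeros((2 * N, n_new), dtype=np.uint8)
            targets = rng.integers(0, 2 * N, size=n_new)
            new_cols[targets, np.arange(n_new)] = 1
            new_pos = np.array(
                [_draw_position(rng, cfg.L, used_positions) for _ in range(n_new)],
                dtype=np.int64,
            )
            if neutral_trait:
                new_eff = np.zeros(n_new)
            else:
                nulls = rng.random(n_new) < cfg.p_null
                new_eff = np.where(
                    nulls, 0.0, rng.normal(0.0, cfg.sigma_effect, size=n_new)
                )
            H_next = np.concatenate([H_next, new_cols], axis=1)
            pos = np.concatenate([pos, new_pos])
            eff = np.concatenate([eff, new_eff])
            origin = np.concatenate([origin, np.full(n_new, t, dtype=np.int64)])
            mut_ids = np.concatenate(
                [mut_ids, np.arange(next_id, next_id + n_new, dtype=np.int64)]
            )
            next_id += n_new

        counts = H_next.sum(axis=0)
        lost = counts == 0
        is_fixed = counts == 2 * N
        if is_fixed.any():
            for j in np.flatnonzero(is_fixed):
                fixed.append(
                    dict(
                        mut_id=int(mut_ids[j]),
                        pos=int(pos[j]),
                        effect=float(eff[j]),
                        origin_generation=int(origin[j]),
                        fixation_generation=t,
                    )
                )
            z_base += eff[is_fixed].sum()
        keep_cols = ~(lost | is_fixed)
        if not keep_cols.all():
            for j in np.flatnonzero(lost):
                used_positions.discard(int(pos[j]))
            H_next = H_next[:, keep_cols]
            pos = pos[keep_cols]
            eff = eff[keep_cols]
            origin = origin[keep_cols]
            mut_ids = mut_ids[keep_cols]
        H = np.ascontiguousarray(H_next)

    return PopulationState(
        config=cfg,
        haplotypes=H,
        positions=pos,
        effects=eff,
        origins=origin,
        mut_ids=mut_ids,
        fixed=fixed,
        trait_mean=trait_mean,
        z_base=z_base,
    )


def _impact_labels(effects: np.ndarray) -> np.ndarray:
    """Annotation-class emulation: label by |effect| quantile.

    Zero effects are MODIFIER; nonzero effects split at the 50th and 90th
    percentile of |effect| into LOW / MODERATE / HIGH.
    """
    labels = np.full(effects.shape, "MODIFIER", dtype=object)
    nz = effects != 0
    if nz.any():
        a = np.abs(effects[nz])
        q50, q90 = np.quantile(a, [0.5, 0.9])
        lab = np.where(a >= q90, "HIGH", np.where(a >= q50, "MODERATE", "LOW"))
        labels[nz] = lab
    return labels


def _chrom_of(state: PopulationState, positions) -> np.ndarray:
    chrom_len = state.config.L / state.config.n_chrom
    return (
        np.minimum(
            (np.asarray(positions) - 1) // chrom_len, state.config.n_chrom - 1
        ).astype(int)
        + 1
    )


def truth_table(state: PopulationState, include_fixed: bool = True) -> pd.DataFrame:
    """Per-mutation ground truth: effect, origin, final frequency, fixed flag.

    ``age_gen`` is the allele age at sampling (generations since origin);
    ``fixation_generation`` is NaN for segregating mutations.
    """
    T = state.config.generations
    freqs = state.frequencies()
    chroms = _chrom_of(state, state.positions)
    order = np.argsort(state.positions, kind="stable")
    rows = [
        dict(
            id=f"{chroms[j]}:{int(state.positions[j])}:A:T",
            mut_id=int(state.mut_ids[j]),
            pos=int(state.positions[j]),
            effect=float(state.effects[j]),
            origin_generation=int(state.origins[j]),
            age_gen=T - int(state.origins[j]),
            fixation_generation=np.nan,
            final_freq=float(freqs[j]),
            fixed=False,
        )
        for j in order
    ]
    if include_fixed:
        fixed_chroms = _chrom_of(state, [f["pos"] for f in state.fixed])
        rows += [
            dict(
                id=f"{fixed_chroms[k]}:{f['pos']}:A:T",
                mut_id=f["mut_id"],
                pos=f["pos"],
                effect=f["effect"],
                origin_generation=f["origin_generation"],
                age_gen=T - f["origin_generation"],
                fixation_generation=f["fixation_generation"],
                final_freq=1.0,
                fixed=True,
            )
            for k, f in enumerate(state.fixed)
        ]
    df = pd.DataFrame(
        rows,
        columns=["id", "mut_id", "pos", "effect", "origin_generation", "age_gen",
                 "fixation_generation", "final_freq", "fixed"],
    )
    return df.sort_values("pos", kind="stable").reset_index(drop=True)


def _variant_table_for(state: PopulationState, positions, effects):
    chroms = _chrom_of(state, positions)
    impacts = _impact_labels(np.asarray(effects))
    recs = [
        dict(
            id=f"{c}:{p}:A:T",
            chrom=str(c),
            pos=int(p),
            ref="A",
            alt="T",
            ancestral="ref",  # founder state is ancestral by construction
            impact=impacts[j],
        )
        for j, (c, p) in enumerate(zip(chroms, positions))
    ]
    recs_sorted = sorted(recs, key=lambda r: (r["chrom"], r["pos"]))
    return make_variant_table(recs_sorted)


def sample_accessions(state: PopulationState, n: int, seed: int):
    """Sample n individuals without replacement, one gamete each.

    Each sampled individual collapses to a fully homozygous line (a
    single-seed-descent emulation), giving a {0,1} dosage matrix.
    Returns (GenotypeMatrix, variant table) with variants sorted by
    (chrom, pos).
    """
    if n > state.pop_size:
        raise ValueError(f"cannot sample {n} from population of {state.pop_size}")
    rng = np.random.default_rng(seed)
    inds = rng.choice(state.pop_size, size=n, replace=False)
    gametes = rng.integers(0, 2, size=n)
    rows = 2 * inds + gametes
    values = state.haplotypes[rows].astype(float)
    variants = _variant_table_for(state, state.positions, state.effects)
    # variant table is (chrom, pos) sorted; align the matrix columns
    chrom_len = state.config.L / state.config.n_chrom
    chroms = (
        np.minimum((state.positions - 1) // chrom_len, state.config.n_chrom - 1)
        .astype(int) + 1
    )
    ids_unsorted = [
        f"{c}:{p}:A:T" for c, p in zip(chroms, state.positions)
    ]
    col_by_id = {v: j for j, v in enumerate(ids_unsorted)}
    order = [col_by_id[v] for v in variants["id"]]
    line_ids = [f"line_{i:04d}" for i in range(n)]
    genotypes = GenotypeMatrix(values[:, order], line_ids, list(variants["id"]))
    return genotypes, variants


def simulate_population(config: SimConfig, n_sample: int | None = None):
    """Forward-simulate and sample lines.

    Returns (GenotypeMatrix of sampled inbred lines, variant table,
    SimTruth DataFrame, PopulationState).  ``n_sample`` defaults to the
    whole final population.
    """
    state = run_forward(config)
    n = state.pop_size if n_sample is None else n_sample
    genotypes, variants = sample_accessions(state, n, seed=config.seed + 1)
    truth = truth_table(state)
    return genotypes, variants, truth, state


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: pd.DataFrame,
    h2_target: float = 0.8,
    n_blocks: int = 4,
    n_reps: int = 4,
    beta_seed_slope: float = 2.0,
    seed: int = 0,
    block_sd: float = 0.5,
    sigma_floor: float = 0.0,
    baseline_days: float = 60.0,
    seed_intercept: float = 200.0,
    seed_noise_sd: float = 15.0,
) -> pd.DataFrame:
    """Replicate-level phenotypes from true effects.

    Line genetic value g = sum(dosage * effect) + baseline; environmental
    noise is scaled so var(g)/(var(g)+sigma_e^2) equals ``h2_target``
    (broad-sense, since lines are clones).  Replicates are laid out in a
    randomized block design (rep i sits in block i mod n_blocks) with
    Gaussian block effects.  Seed count declines linearly in flowering
    time (slope ``beta_seed_slope`` seeds/day) with truncation at zero —
    the fitness-proxy relationship.
    """
    if not 0.0 < h2_target <= 1.0:
        raise ValueError("h2_target must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    eff_by_id = dict(zip(truth["id"], truth["effect"]))
    missing = [v for v in genotypes.variant_ids if v not in eff_by_id]
    if missing:
        raise ValueError(f"truth table lacks effects for {missing[:3]}...")
    effects = np.array([eff_by_id[v] for v in genotypes.variant_ids])
    X = np.nan_to_num(genotypes.values, nan=0.0)
    g = X @ effects + baseline_days
    var_g = g.var()
    if var_g == 0 and h2_target == 1.0:
        raise ValueError("h2_target = 1 with zero genetic variance")
    if h2_target == 1.0:
        sigma_e = 0.0
    elif var_g == 0:
        sigma_e = max(0.5, sigma_floor)  # pure micro-environmental noise
    else:
        # sigma_floor models absolute measurement/micro-environmental noise
        # (days); when genetic variance is small the realized heritability
        # falls below h2_target accordingly
        sigma_e = max(np.sqrt(var_g * (1.0 - h2_target) / h2_target), sigma_floor)
    block_effects = rng.normal(0.0, block_sd, size=n_blocks) if n_blocks > 1 else np.zeros(1)
    rows = []
    for i, line in enumerate(genotypes.line_ids):
        for rep in range(n_reps):
            block = rep % n_blocks
            flowering = g[i] + block_effects[block] + rng.normal(0.0, sigma_e)
            flowering = max(flowering, 0.0)
            seeds = seed_intercept - beta_seed_slope * flowering + rng.normal(
                0.0, seed_noise_sd
            )
            rows.append(
                dict(
                    line=line,
                    rep=rep,
                    block=f"B{block}",
                    flowering_days=flowering,
                    seed_count=max(seeds, 0.0),
                )
            )
    return make_phenotype_table(pd.DataFrame(rows))


@dataclass
class WalkStep:
    step: int
    effect: float
    s: float
    dist_before: float
    dist_after: float


def simulate_origin_fixation_walk(
    z0: float,
    omega: float,
    effect_sigma: float = 1.0,
    max_steps: int = 1000,
    max_tries: int = 100_000,
    eps: float = 0.5,
    seed: int = 0,
) -> list[WalkStep]:
    """Mutation-limited origin-fixation adaptive walk toward an optimum at 0.

    Candidate effects r ~ N(0, effect_sigma) arise one at a time; the
    selection coefficient is s = w(z + r)/w(z) - 1 under Gaussian fitness
    w(z) = exp(-z^2 / (2 omega^2)), and beneficial candidates fix with
    the classic weak-selection probability min(1, 2s).  Accepted steps
    strictly reduce |z|; the walk stops within ``eps`` of the optimum.
    Under this model early steps are expected to be larger than later
    ones, with roughly exponentially distributed accepted effects.
    """
    rng = np.random.default_rng(seed)
    z = float(z0)
    steps: list[WalkStep] = []
    tries = 0
    while abs(z) >= eps and len(steps) < max_steps and tries < max_tries:
        tries += 1
        r = rng.normal(0.0, effect_sigma)
        s = np.exp((z**2 - (z + r) ** 2) / (2.0 * omega**2)) - 1.0
        if s > 0 and rng.random() < min(1.0, 2.0 * s):
            steps.append(
                WalkStep(
                    step=len(steps) + 1,
                    effect=r,
                    s=float(s),
                    dist_before=abs(z),
                    dist_after=abs(z + r),
                )
            )
            z += r
    return steps


def simulate_coalescent_lines(
    n_lines: int,
    Ne: float,
    L: int = 100_000,
    n_chrom: int = 50,
    mu_per_site: float = 9e-8,
    rec_per_site: float = 1e-7,
    p_null: float = 0.9,
    sigma_effect: float = 2.0,
    seed: int = 0,
):
    """Coalescent-backed sample of inbred lines from a deep, stable population.

    This is the generator for the large-N_e "continental" study condition,
    where the population's time depth (N_e in the hundreds of thousands,
    even rescaled) is far beyond what a forward simulation can burn in:
    each of ``n_chrom`` freely assorting blocks is an independent msprime
    coalescent tree sequence over ``n_lines`` haploid genomes (one genome
    per fully inbred line) with diploid effective size ``Ne``; mutation
    ages are the true node times in generations.  Trait effects are
    assigned i.i.d. from the usual null/Normal mixture, independent of
    frequency — the weak-stabilizing limit in which per-locus selection
    (N_e s << 1) leaves allele frequencies effectively neutral.

    Returns (GenotypeMatrix, variant table, truth DataFrame) with the
    same layout as the forward simulator's outputs.
    """
    import msprime

    if n_lines < 2:
        raise ValueError("need at least two lines")
    rng = np.random.default_rng(seed)
    block_len = L // n_chrom
    line_ids = [f"line_{i:04d}" for i in range(n_lines)]
    cols = []
    recs = []
    truth_rows = []
    for b in range(1, n_chrom + 1):
        ts = msprime.sim_ancestry(
            samples=n_lines,
            ploidy=1,
            population_size=2.0 * Ne,  # haploid-sample scaling of diploid Ne
            sequence_length=block_len,
            recombination_rate=rec_per_site,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        ts = msprime.sim_mutations(
            ts,
            rate=mu_per_site,
            random_seed=int(rng.integers(1, 2**31 - 1)),
            discrete_genome=False,  # infinite sites: one mutation per site
        )
        seen = set()
        offset = (b - 1) * block_len
        for var in ts.variants():
            pos = int(np.floor(var.site.position)) + 1
            if pos in seen or pos > block_len:
                continue
            seen.add(pos)
            geno = var.genotypes.astype(float)
            if geno.min() == geno.max():
                continue
            mut_time = var.site.mutations[0].time
            if rng.random() < p_null:
                effect = 0.0
            else:
                effect = float(rng.normal(0.0, sigma_effect))
            vid = f"{b}:{offset + pos}:A:T"
            cols.append((b, pos, geno))
            recs.append(
                dict(id=vid, chrom=str(b), pos=offset + pos, ref="A", alt="T",
                     ancestral="ref", impact=None, effect=effect)
            )
            truth_rows.append(
                dict(
                    id=vid,
                    mut_id=len(truth_rows),
                    pos=offset + pos,
                    effect=effect,
                    origin_generation=np.nan,
                    age_gen=float(mut_time),
                    fixation_generation=np.nan,
                    final_freq=float(geno.mean()),
                    fixed=False,
                )
            )
    effects = np.array([r["effect"] for r in recs])
    impacts = _impact_labels(effects)
    for r, lab in zip(recs, impacts):
        r["impact"] = lab
        del r["effect"]
    recs_sorted = sorted(
        range(len(recs)), key=lambda i: (recs[i]["chrom"], recs[i]["pos"])
    )
    variants = make_variant_table([recs[i] for i in recs_sorted])
    values = (
        np.column_stack([cols[i][2] for i in recs_sorted])
        if recs
        else np.empty((n_lines, 0))
    )
    genotypes = GenotypeMatrix(values, line_ids, list(variants["id"]))
    truth = (
        pd.DataFrame(truth_rows)
        .sort_values("pos", kind="stable")
        .reset_index(drop=True)
    )
    return genotypes, variants, truth
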