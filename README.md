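# traitarch

How does population history shape the genetic architecture of a
quantitative trait?  A large, long-established population under
stabilizing selection is expected to carry many trait-affecting variants
of individually small effect (Fisher's infinitesimal picture), while a
small population recently founded through an extreme bottleneck and
pushed toward a new phenotypic optimum adapts through an **adaptive
walk** in the sense of the Fisher–Orr geometric model: a few large-effect
mutations fix first, followed by progressively smaller refinements, so
that the effect sizes of its trait loci are approximately exponentially
distributed rather than uniform.

`traitarch` implements the full inference chain needed to test this
contrast on highly selfing inbred plant lines (flowering time in days is
the motivating trait, seed count the fitness proxy), together with the
synthetic-data generators that emulate both demographic regimes, so that
every stage can be exercised and validated without any external data:

* **Simulation** — a forward Wright–Fisher simulator with partial
  selfing (default 95%), infinite-sites mutation, recombination with
  freely assorting chromosome blocks, Gaussian stabilizing selection
  `w(z) = exp(−(z−opt)²/2ω²)`, and a one-time optimum shift plus
  founder bottleneck (the island colonization); a coalescent-backed
  generator (msprime) for the deep-`N_e` continental sample; an
  origin-fixation adaptive-walk oracle; and a replicate/block phenotype
  generator calibrated to a target broad-sense heritability.
* **Association** — centered kinship `K = (1/m) Σ_j (x_j − x̄_j)(x_j − x̄_j)ᵀ`,
  the single-kinship linear mixed model `y = Wα + xβ + u + ε` with
  `u ~ N(0, σ_g²K)` profiled over `λ = σ_g²/σ_e²` by one
  eigendecomposition, per-marker likelihood-ratio tests, PVE
  (chip heritability), and replicate-based broad-sense `H² =
  σ²_line/(σ²_line + σ²_res)` by REML.
* **Locus discovery** — Lindley local scores `L_i = max(0, L_{i−1} −
  log10 p_i − ξ)` with resampling-calibrated significance thresholds
  (uniform, genomic-control-scaled, or empirical-marginal nulls), greedy
  LD clumping (p < 0.01, 1 Mb, r² > 0.8), sliding-window LD pruning
  (50/10/0.3), and one representative SNP per significant zone pruned at
  r² > 0.5.
* **Architecture inference** — maximum-likelihood exponential
  (`λ̂ = 1/mean`) versus uniform (`θ̂ = max`) fits of absolute effect
  sizes compared by AIC, Mann–Whitney tests between populations, Pearson
  frequency–effect and age–frequency correlations, Watterson's
  `θ_W = S/(a_n L)`, `N_e = θ_W/4μ`, and the neutral expectation
  `t̄(p) = −4N_e p ln p/(1−p)` for allele age given frequency.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts (all outputs under `results/`):

```bash
python analysis/01_simulate_cohorts.py   # simulate both populations
python analysis/02_gwas.py               # mixed-model association
python analysis/03_candidate_loci.py     # local score -> zones -> loci
python analysis/04_architecture_report.py
python analysis/05_walk_and_replicates.py
```

A typical run prints:

```
continent: tested 525 variants; H2=0.81 PVE=0.90; top hit 21:41744:A:T (beta=-5.59 d, p=7.15e-09)
island:    tested 132 variants; H2=0.41 PVE=0.82; top hit 40:79905:A:T (beta=2.80 d, p=1.21e-03)
continent: 12 zones / 9 clumps / 12 loci; N_e~5171; effect sizes fit uniform     (AIC exp 55.85 vs unif 43.30)
island:     6 zones / 2 clumps /  6 loci; N_e~102;  effect sizes fit exponential (AIC exp 25.67 vs unif 26.99)
Mann-Whitney |beta| continent vs island: U=55.0, p=0.0831
```

Read: the continental cohort is highly heritable (H² = 0.81) with most
phenotypic variance tracking relatedness (PVE = 0.90); its twelve
candidate loci have effect sizes spread evenly up to ~6 days, so the
uniform distribution wins the AIC comparison, and its diversity-based
`N_e` estimate (~5200) recovers the simulated effective size of 5000.
The island cohort carries one large fixed variant from the colonization
walk (added manually, as it cannot appear in GWAS) plus a handful of
small segregating refinements — an exponential-shaped set — and fewer
loci overall, with `N_e` two orders of magnitude smaller.  The replicated
experiment (script 05) repeats this whole pipeline across seeds and
tabulates how often each signature is recovered, and `walk_steps.tsv`
shows the mean fixed-effect size declining along the adaptive walk
(step 1 ≈ 3.5 days down to ≈ 1.1 by step 6).

The same stages are available as a command-line tool for external data
(VCF + phenotype TSV): `traitarch sim`, `traitarch gwas`,
`traitarch architecture`, `traitarch compare`, `traitarch run-all`.

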