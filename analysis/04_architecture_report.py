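#!/usr/bin/env python
"""Architecture inference: effect-size distributions, tests, correlations.

For each cohort's representative loci: maximum-likelihood exponential vs
uniform fits of |beta| compared by AIC, Mann-Whitney tests between the
cohorts, Pearson correlations of derived allele frequency with effect
size and with the neutral-expectation allele age, plus Watterson theta
and the implied N_e.  Writes results/architecture/report.json and the
pairwise comparison table.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from traitarch import arch, vcfio  # noqa: E402
from traitarch.pipeline import CONTINENT_STUDY, island_config  # noqa: E402

SEED = 55


def main():
    reports, loci_by_pop = {}, {}
    mus = {"continent": CONTINENT_STUDY["mu_per_site"],
           "island": island_config(SEED).mu_per_site}
    for name in ("continent", "island"):
        locidir = ROOT / "results" / "loci" / name
        if not locidir.exists():
            sys.exit("run analysis/03_candidate_loci.py first")
        loci = pd.read_csv(locidir / "loci.tsv", sep="\t")
        zones = pd.read_csv(locidir / "zones.tsv", sep="\t")
        clumps = pd.read_csv(locidir / "clumps.tsv", sep="\t")
        fit = json.loads((ROOT / "results" / "gwas" / name / "fit.json").read_text())
        genotypes, _ = vcfio.read_vcf(
            ROOT / "results" / "cohorts" / name / "genotypes.vcf"
        )
        freq = np.nanmean(genotypes.values, axis=0)
        S = int(((freq > 0) & (freq < 1)).sum())
        theta = arch.watterson_theta(S, genotypes.n_lines, 100_000)
        ages = pd.DataFrame(
            {
                "id": loci["id"],
                "age": [
                    arch.expected_allele_age(p, arch.ne_from_theta(theta, mus[name]))
                    if 0 < p < 1 else np.nan
                    for p in loci["daf"]
                ],
            }
        ).dropna()
        reports[name] = arch.population_report(
            name, loci, n_zones=len(zones), n_clumps=len(clumps),
            h2=fit["broad_sense_h2"], pve=fit["pve"], ages=ages,
            theta_w=theta, n_e=arch.ne_from_theta(theta, mus[name]),
        )
        loci_by_pop[name] = loci
    comparisons = arch.compare_populations(reports, loci_by_pop)
    out = ROOT / "results" / "architecture"
    out.mkdir(parents=True, exist_ok=True)
    arch.write_report(reports, comparisons, out / "report.json")
    comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    for name, rep in reports.items():
        fit = rep.fit
        print(f"{name}: {rep.n_zones} zones / {rep.n_clumps} clumps / "
              f"{rep.n_loci} loci; H2={rep.broad_sense_h2:.2f} "
              f"PVE={rep.pve:.2f}; N_e~{rep.n_e:.0f}; "
              f"effect sizes fit {fit.chosen} "
              f"(AIC exp {fit.aic_exp:.2f} vs unif {fit.aic_unif:.2f})")
    for _, row in comparisons.iterrows():
        print(f"Mann-Whitney |beta| {row['pop_a']} vs {row['pop_b']}: "
              f"U={row['U']:.1f}, p={row['p']:.3g}")


if __name__ == "__main__":
    main()
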