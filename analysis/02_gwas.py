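#!/usr/bin/env python
"""Mixed-model GWAS on both simulated cohorts.

Reads the cohorts written by 01_simulate_cohorts.py, aggregates replicate
phenotypes to per-line medians, builds the centered kinship, fits the
null LMM (variance ratio, PVE) and scans every variant (LRT).  Writes
assoc.tsv, kinship.tsv and fit.json per cohort under results/gwas/<name>/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd  # noqa: E402

from traitarch import vcfio  # noqa: E402
from traitarch.pipeline import run_gwas  # noqa: E402


def main():
    for name in ("continent", "island"):
        cohort = ROOT / "results" / "cohorts" / name
        if not cohort.exists():
            sys.exit(f"run analysis/01_simulate_cohorts.py first ({cohort} missing)")
        genotypes, variants = vcfio.read_vcf(cohort / "genotypes.vcf")
        phen = vcfio.read_phenotypes(cohort / "phenotypes.tsv")
        res = run_gwas(genotypes, variants, phen)
        out = ROOT / "results" / "gwas" / name
        out.mkdir(parents=True, exist_ok=True)
        assoc = res.assoc.merge(variants[["id", "chrom", "pos"]], on="id")
        assoc["daf"] = res.daf
        assoc.to_csv(out / "assoc.tsv", sep="\t", index=False, float_format="%.8g")
        pd.DataFrame(res.kinship, index=res.genotypes.line_ids,
                     columns=res.genotypes.line_ids).to_csv(
            out / "kinship.tsv", sep="\t", float_format="%.8g")
        fit = dict(lambda_hat=res.null_fit.lambda_hat,
                   sigma_e2=res.null_fit.sigma_e2,
                   loglik=res.null_fit.loglik, pve=res.null_fit.pve,
                   broad_sense_h2=res.h2)
        (out / "fit.json").write_text(json.dumps(fit, indent=2))
        n_tested = int(assoc["tested"].sum())
        best = assoc.dropna(subset=["p_lrt"]).sort_values("p_lrt").iloc[0]
        print(f"{name}: tested {n_tested} variants; H2={res.h2:.2f} "
              f"PVE={res.null_fit.pve:.2f}; top hit {best['id']} "
              f"(beta={best['beta']:.2f} d, p={best['p_lrt']:.2e})")


if __name__ == "__main__":
    main()
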