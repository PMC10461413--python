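"""VCF and TSV input/output for inbred-line dosage matrices.

Reading goes through cyvcf2.  Only biallelic sites are used; multiallelic
rows are skipped and counted.  The optional INFO keys understood are
``AA`` (ancestral allele; recorded as ref/alt/unknown) and ``IMPACT``
(functional annotation class).  Writing emits a minimal VCF 4.2 text file
with homozygous GT calls, which round-trips through :func:`read_vcf`.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .datamodel import (
    DataFormatError,
    GenotypeMatrix,
    IMPACT_CLASSES,
    PHENOTYPE_COLUMNS,
    default_variant_id,
    make_phenotype_table,
    make_variant_table,
)

logger = logging.getLogger(__name__)

HET_POLICIES = ("missing", "half")


def read_vcf(path, het_policy: str = "missing", exclude=None):
    """Read a VCF into a (GenotypeMatrix, variant table) pair.

    Heterozygous calls are handled per ``het_policy``: ``"missing"``
    (default; residual hets in selfing lines are treated as call errors)
    or ``"half"`` (dosage 0.5).  The AA INFO tag is parsed into the
    ancestral field when it equals ref or alt; anything else (including
    absence) yields ``"unknown"``.  Multiallelic rows are skipped with a
    logged count.  ``exclude`` is an optional collection of variant ids
    to drop — the hook for externally curated exclusion lists (e.g.,
    sites adjacent to complex structural variants).
    """
    import cyvcf2

    if het_policy not in HET_POLICIES:
        raise ValueError(f"het_policy must be one of {HET_POLICIES}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:  # cyvcf2 raises plain OSError on bad headers
        raise DataFormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vcf.samples)
    excluded = set(exclude) if exclude is not None else set()
    columns = []
    records = []
    seen_ids = set()
    n_multi = 0
    n_excluded = 0
    for row_number, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        vid = v.ID if v.ID not in (None, ".") else default_variant_id(
            v.CHROM, v.POS, ref, alt
        )
        if vid in seen_ids:
            raise DataFormatError(
                f"duplicate variant id {vid!r} at body row {row_number} of {path}"
            )
        seen_ids.add(vid)
        if vid in excluded:
            n_excluded += 1
            continue
        aa = v.INFO.get("AA")
        if aa == ref:
            ancestral = "ref"
        elif aa == alt:
            ancestral = "alt"
        else:
            ancestral = "unknown"
        impact = v.INFO.get("IMPACT")
        if impact not in IMPACT_CLASSES:
            impact = "NA"
        # cyvcf2 gt_types: 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        gt = np.asarray(v.gt_types)
        col = np.full(len(samples), np.nan)
        col[gt == 0] = 0.0
        col[gt == 3] = 1.0
        if het_policy == "half":
            col[gt == 1] = 0.5
        columns.append(col)
        records.append(
            dict(id=vid, chrom=v.CHROM, pos=v.POS, ref=ref, alt=alt,
                 ancestral=ancestral, impact=impact)
        )
    vcf.close()
    if n_multi:
        logger.info("skipped %d multiallelic row(s) in %s", n_multi, path)
    if n_excluded:
        logger.info("dropped %d excluded variant(s) in %s", n_excluded, path)
    variants = make_variant_table(records)
    values = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    genotypes = GenotypeMatrix(values, samples, list(variants["id"]))
    return genotypes, variants


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##INFO=<ID=IMPACT,Number=1,Type=String,Description="Predicted functional impact class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(genotypes: GenotypeMatrix, variants: pd.DataFrame, path) -> None:
    """Write a GT-only VCF; inverse of :func:`read_vcf` on its output.

    Dosage 1 becomes ``1/1``, 0 becomes ``0/0``, 0.5 becomes ``0/1`` and
    missing becomes ``./.``.  The ancestral state is emitted as an AA tag
    (the actual allele string) and the impact class as IMPACT.
    """
    if list(variants["id"]) != list(genotypes.variant_ids):
        raise DataFormatError("variant table and genotype matrix ids disagree")
    gt_map = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}
    try:
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for chrom in dict.fromkeys(variants["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(map(str, genotypes.line_ids))
                + "\n"
            )
            for j, rec in enumerate(variants.itertuples(index=False)):
                info = []
                if rec.ancestral == "ref":
                    info.append(f"AA={rec.ref}")
                elif rec.ancestral == "alt":
                    info.append(f"AA={rec.alt}")
                if rec.impact != "NA":
                    info.append(f"IMPACT={rec.impact}")
                info_str = ";".join(info) if info else "."
                calls = [
                    gt_map.get(x, "./.") if np.isfinite(x) else "./."
                    for x in genotypes.values[:, j]
                ]
                fh.write(
                    f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}"
                    f"\t.\tPASS\t{info_str}\tGT\t" + "\t".join(calls) + "\n"
                )
    except OSError as exc:
        raise OSError(f"cannot write VCF to {path}: {exc}") from exc


def read_phenotypes(path) -> pd.DataFrame:
    """Read a replicate-level phenotype TSV (line, rep, block, flowering_days,
    seed_count).  ``NA`` / empty seed counts become missing."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"line": str, "block": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise DataFormatError(f"cannot read phenotype TSV {path}: {exc}") from exc
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"phenotype TSV {path} missing column(s) {missing}; "
            f"expected header {PHENOTYPE_COLUMNS}"
        )
    return make_phenotype_table(df)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    make_phenotype_table(phenotypes).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_covariates(path, line_ids) -> np.ndarray:
    """Read a covariate TSV (line + numeric columns) aligned to ``line_ids``.

    Returns an n x c float array (no intercept column)."""
    df = pd.read_csv(path, sep="\t", dtype={"line": str})
    if "line" not in df.columns:
        raise DataFormatError(f"covariate TSV {path} must have a 'line' column")
    df = df.set_index("line")
    missing = [l for l in line_ids if l not in df.index]
    if missing:
        raise DataFormatError(f"covariate TSV missing lines {missing[:5]}")
    return df.loc[list(line_ids)].to_numpy(dtype=float)
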