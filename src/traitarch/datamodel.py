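"""Core data containers for inbred-line genotype/phenotype analysis.

Genotypes are carried as a lines x variants dosage matrix over {0, 1,
missing}.  The single-dose coding reflects highly selfing, effectively
homozygous accessions: each line contributes one allele per site, and a
residual heterozygous call is treated according to an explicit policy
(missing by default) rather than as a half dose.

Variant metadata live in a plain pandas DataFrame (``VARIANT_COLUMNS``),
phenotypes in a replicate-level DataFrame (``PHENOTYPE_COLUMNS``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns of a variant table, one row per biallelic variant.
VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "ancestral", "impact"]

#: Columns of a replicate-level phenotype table.
PHENOTYPE_COLUMNS = ["line", "rep", "block", "flowering_days", "seed_count"]

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER", "NA")
ANCESTRAL_STATES = ("ref", "alt", "unknown")


class DataFormatError(ValueError):
    """Raised for malformed input files or inconsistent tables."""


def default_variant_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def make_variant_table(records) -> pd.DataFrame:
    """Build and validate a variant table from an iterable of dicts.

    Enforces: pos >= 1, ref != alt, unique ids, sorted by (chrom, pos).
    """
    df = pd.DataFrame(list(records), columns=VARIANT_COLUMNS)
    if len(df) == 0:
        return df
    df["pos"] = df["pos"].astype(np.int64)
    if (df["pos"] < 1).any():
        raise DataFormatError("variant positions must be >= 1 (1-based)")
    if (df["ref"] == df["alt"]).any():
        bad = df.loc[df["ref"] == df["alt"], "id"].iloc[0]
        raise DataFormatError(f"ref == alt for variant {bad!r}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise DataFormatError(f"duplicate variant id {dup!r}")
    keys = list(zip(df["chrom"], df["pos"]))
    if keys != sorted(keys):
        raise DataFormatError("variant table must be sorted by (chrom, pos)")
    bad_anc = ~df["ancestral"].isin(ANCESTRAL_STATES)
    if bad_anc.any():
        raise DataFormatError(
            f"ancestral must be one of {ANCESTRAL_STATES}, got "
            f"{df.loc[bad_anc, 'ancestral'].iloc[0]!r}"
        )
    return df.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Lines x variants dosage matrix for inbred lines.

    ``values`` is float64 with entries in {0.0, 1.0, nan}; nan marks a
    missing call.  A value of 1 is one copy of the alt (or, after
    :func:`polarize`, the derived) allele in the line's homozygous genome.
    """

    values: np.ndarray
    line_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = list(self.line_ids)
        self.variant_ids = list(self.variant_ids)
        if self.values.ndim != 2:
            raise DataFormatError("genotype values must be 2-D")
        n, m = self.values.shape
        if n != len(self.line_ids) or m != len(self.variant_ids):
            raise DataFormatError(
                f"genotype shape {self.values.shape} inconsistent with "
                f"{len(self.line_ids)} lines / {len(self.variant_ids)} variants"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 0.5, 1.0)).all():
            raise DataFormatError("dosages must lie in {0, 0.5, 1, missing}")
        if len(set(self.line_ids)) != n:
            raise DataFormatError("duplicate line ids")
        if len(set(self.variant_ids)) != m:
            raise DataFormatError("duplicate variant ids")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def missingness(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return np.isnan(self.values).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Per-variant mean dosage over non-missing lines (nan if none)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)

    def subset_variants(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, (list, tuple, set)):
            keep = [i for i, v in enumerate(self.variant_ids) if v in set(mask_or_ids)]
        else:
            keep = np.flatnonzero(np.asarray(mask_or_ids))
        return GenotypeMatrix(
            self.values[:, keep],
            self.line_ids,
            [self.variant_ids[i] for i in keep],
        )

    def subset_lines(self, line_ids) -> "GenotypeMatrix":
        index = {l: i for i, l in enumerate(self.line_ids)}
        rows = [index[l] for l in line_ids]
        return GenotypeMatrix(self.values[rows, :], list(line_ids), self.variant_ids)


@dataclass
class PolarizedGenotypes:
    """Result of :func:`polarize`: derived-allele coding plus frequencies."""

    genotypes: GenotypeMatrix
    daf: np.ndarray  # derived allele frequency; nan where undefined
    unknown_ancestral: np.ndarray  # bool; excluded from polarity analyses
    flipped: np.ndarray = field(default=None)  # bool; ancestral == alt


def polarize(genotypes: GenotypeMatrix, variants: pd.DataFrame) -> PolarizedGenotypes:
    """Recode alt dosages to derived-allele dosages using ancestral states.

    Where the ancestral allele is the alt allele the dosages flip 0 <-> 1.
    Variants with unknown ancestral state are flagged (they stay in the
    matrix, unflipped, for association use, but carry ``daf = nan`` so
    frequency-polarity analyses skip them).  All-missing columns get
    ``daf = nan`` as a degenerate case.
    """
    if list(variants["id"]) != list(genotypes.variant_ids):
        raise DataFormatError("variant table and genotype matrix ids disagree")
    values = genotypes.values.copy()
    anc = variants["ancestral"].to_numpy()
    flipped = anc == "alt"
    unknown = anc == "unknown"
    values[:, flipped] = 1.0 - values[:, flipped]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        daf = np.nanmean(values, axis=0)
    daf[unknown] = np.nan
    out = GenotypeMatrix(values, genotypes.line_ids, genotypes.variant_ids)
    return PolarizedGenotypes(out, daf, unknown, flipped)


def make_phenotype_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a replicate-level phenotype table.

    flowering_days must be non-negative; (line, rep) pairs unique;
    seed_count may be missing.
    """
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataFormatError(f"phenotype table missing columns {missing_cols}")
    df = df[PHENOTYPE_COLUMNS].copy()
    df["flowering_days"] = pd.to_numeric(df["flowering_days"], errors="raise")
    df["seed_count"] = pd.to_numeric(df["seed_count"], errors="coerce")
    if (df["flowering_days"].dropna() < 0).any():
        raise DataFormatError("flowering_days must be non-negative")
    dup = df.duplicated(subset=["line", "rep"])
    if dup.any():
        pair = df.loc[dup, ["line", "rep"]].iloc[0]
        raise DataFormatError(f"duplicate (line, rep) pair {tuple(pair)}")
    return df.reset_index(drop=True)


def median_phenotype(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replicates to one row per line.

    Returns a DataFrame indexed by line with columns ``flowering_days``
    (median over non-missing replicate values; even counts use the
    midpoint) and ``seed_count`` (total over non-missing replicates, nan
    if all replicates missing).  Lines with no non-missing flowering value
    are dropped with a warning.
    """
    phenotypes = make_phenotype_table(phenotypes)
    grouped = phenotypes.groupby("line", sort=True)
    med = grouped["flowering_days"].median()
    n_obs = grouped["flowering_days"].count()
    seed = grouped["seed_count"].sum(min_count=1)
    empty = n_obs == 0
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} line(s) with no non-missing "
            "flowering values",
            stacklevel=2,
        )
    out = pd.DataFrame({"flowering_days": med, "seed_count": seed})
    return out.loc[~empty]
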