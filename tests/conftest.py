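import numpy as np
import pandas as pd
import pytest

from traitarch.datamodel import GenotypeMatrix, make_variant_table


def toy_variants(n, chrom="1", start=1000, step=500, ancestral="ref"):
    return make_variant_table(
        [
            dict(
                id=f"{chrom}:{start + i * step}:A:T",
                chrom=chrom,
                pos=start + i * step,
                ref="A",
                alt="T",
                ancestral=ancestral,
                impact="NA",
            )
            for i in range(n)
        ]
    )


@pytest.fixture
def small_genotypes():
    """5 lines x 4 variants with one missing call."""
    values = np.array(
        [
            [0, 1, 0, 1],
            [0, 1, 1, 0],
            [1, 0, 0, 1],
            [1, np.nan, 1, 0],
            [0, 0, 1, 1],
        ],
        dtype=float,
    )
    variants = toy_variants(4)
    return GenotypeMatrix(values, [f"l{i}" for i in range(5)], list(variants["id"])), variants


@pytest.fixture
def phenotype_frame():
    return pd.DataFrame(
        {
            "line": ["a", "a", "b", "b"],
            "rep": [0, 1, 0, 1],
            "block": ["B0", "B1", "B0", "B1"],
            "flowering_days": [30.0, 34.0, 50.0, 52.0],
            "seed_count": [100.0, np.nan, 80.0, 70.0],
        }
    )


def random_genotypes(rng, n_lines, n_variants, chrom="1", missing=0.0):
    freqs = rng.uniform(0.1, 0.9, size=n_variants)
    values = (rng.random((n_lines, n_variants)) < freqs).astype(float)
    if missing:
        mask = rng.random(values.shape) < missing
        values[mask] = np.nan
    variants = toy_variants(n_variants, chrom=chrom)
    return (
        GenotypeMatrix(values, [f"l{i}" for i in range(n_lines)], list(variants["id"])),
        variants,
    )
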