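"""Lindley local-score aggregation of association p-values.

Per-variant p-values along a chromosome are turned into scores
s_i = -log10(p_i) - xi, whose cumulative Lindley process
L_i = max(0, L_{i-1} + s_i) accumulates over runs of associated variants
and resets at zero elsewhere.  Maximal positive excursions whose peak
exceeds a resampling-calibrated threshold are the significant zones, each
treated as one candidate locus.  The tuning constant xi must exceed the
null mean of -log10(p) (log10 e ~ 0.4343) so the process drifts downward
under no association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

XI_MIN = np.log10(np.e)  # null E[-log10 p] under uniform p


@dataclass
class LindleyTrack:
    """Lindley process for one chromosome."""

    chrom: str
    variant_ids: list[str]
    positions: np.ndarray
    scores: np.ndarray  # s_i = -log10(p_i) - xi
    lindley: np.ndarray  # L_i
    xi: float
    threshold: float = field(default=np.nan)


@dataclass
class SignificantZone:
    chrom: str
    start_index: int  # 0-based, inclusive
    end_index: int
    start_bp: int
    end_bp: int
    peak_score: float
    peak_id: str


def _lindley(scores: np.ndarray) -> np.ndarray:
    L = np.empty_like(scores)
    acc = 0.0
    for i, s in enumerate(scores):
        acc = max(0.0, acc + s)
        L[i] = acc
    return L


def lindley_scores(assoc: pd.DataFrame, variants: pd.DataFrame, xi: float = 2.0):
    """Compute per-chromosome Lindley tracks from an association table.

    ``assoc`` needs columns id/p_lrt; positions come from ``variants``
    (id/chrom/pos).  Untested variants (p = NA) are dropped from the
    track.  p = 0 is clamped to the smallest positive float with a
    warning.  Returns a dict chrom -> LindleyTrack.
    """
    if xi <= XI_MIN:
        raise ValueError(f"xi must exceed log10(e) ~ {XI_MIN:.4f} for negative drift")
    merged = assoc[["id", "p_lrt"]].merge(
        variants[["id", "chrom", "pos"]], on="id", how="inner"
    )
    merged = merged.dropna(subset=["p_lrt"]).sort_values(["chrom", "pos"])
    if (merged["p_lrt"] <= 0).any():
        warnings.warn("p-values of 0 clamped to the smallest positive float")
        merged["p_lrt"] = merged["p_lrt"].clip(lower=np.finfo(float).tiny)
    if (merged["p_lrt"] > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    tracks = {}
    for chrom, sub in merged.groupby("chrom", sort=True):
        s = -np.log10(sub["p_lrt"].to_numpy()) - xi
        tracks[str(chrom)] = LindleyTrack(
            chrom=str(chrom),
            variant_ids=list(sub["id"]),
            positions=sub["pos"].to_numpy(),
            scores=s,
            lindley=_lindley(s),
            xi=xi,
        )
    return tracks


def genomic_control_lambda(p_values) -> float:
    """Genomic-control inflation factor: median observed chi2 / median chi2(1).

    Robust to a minority of true signals; lambda > 1 flags test-statistic
    inflation, lambda < 1 a conservative test.
    """
    from scipy import stats

    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    chi = stats.chi2.isf(np.clip(p, np.finfo(float).tiny, 1.0), df=1)
    return float(np.median(chi) / stats.chi2.median(df=1))


def significance_threshold(
    m: int,
    xi: float,
    alpha: float = 0.05,
    n_resample: int = 1000,
    seed: int = 0,
    p_pool=None,
    lambda_gc: float = 1.0,
) -> float:
    """Empirical (1 - alpha) quantile of the max Lindley score under the null.

    The null is m i.i.d. p-values: uniform by default; scaled by the
    genomic-control factor ``lambda_gc`` (null chi-squared statistics
    multiplied by lambda, so the threshold tracks an inflated or
    conservative association test); or drawn from ``p_pool`` (an observed
    p-value marginal).  Each resample contributes its maximum Lindley
    score.  Deterministic under a fixed seed.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if xi <= XI_MIN:
        raise ValueError(
            f"E[s] >= 0 under the uniform null (xi <= {XI_MIN:.4f}); "
            "threshold undefined — increase xi"
        )
    if p_pool is not None:
        p_pool = np.asarray(p_pool, dtype=float)
        p_pool = np.clip(p_pool[np.isfinite(p_pool)], np.finfo(float).tiny, 1.0)
        if p_pool.size == 0:
            raise ValueError("empty p-value pool")
        if np.mean(-np.log10(p_pool)) >= xi:
            raise ValueError(
                "E[s] >= 0 under the empirical marginal; increase xi"
            )
    rng = np.random.default_rng(seed)
    if p_pool is not None:
        P = rng.choice(p_pool, size=(m, n_resample), replace=True)
    else:
        P = rng.uniform(size=(m, n_resample))
        if lambda_gc != 1.0:
            from scipy import stats

            chi = stats.chi2.isf(P, df=1) * lambda_gc
            P = stats.chi2.sf(chi, df=1)
            P = np.clip(P, np.finfo(float).tiny, 1.0)
    L = np.zeros(n_resample)
    best = np.zeros(n_resample)
    for i in range(m):  # vectorized over resamples, sequential over sites
        s = -np.log10(P[i]) - xi
        L = np.maximum(0.0, L + s)
        np.maximum(best, L, out=best)
    return float(np.quantile(best, 1.0 - alpha))


def call_zones(track: LindleyTrack) -> list[SignificantZone]:
    """Significant zones: maximal runs of L > 0 whose peak exceeds the threshold.

    Zone boundaries are the zero-resets of the Lindley process; the peak
    is the leftmost argmax within the run.
    """
    if not np.isfinite(track.threshold):
        raise ValueError("track threshold not set")
    L = track.lindley
    zones = []
    i = 0
    n = len(L)
    while i < n:
        if L[i] > 0:
            j = i
            while j + 1 < n and L[j + 1] > 0:
                j += 1
            peak_rel = int(np.argmax(L[i : j + 1]))  # argmax is leftmost on ties
            peak = i + peak_rel
            if L[peak] > track.threshold:
                zones.append(
                    SignificantZone(
                        chrom=track.chrom,
                        start_index=i,
                        end_index=j,
                        start_bp=int(track.positions[i]),
                        end_bp=int(track.positions[j]),
                        peak_score=float(L[peak]),
                        peak_id=track.variant_ids[peak],
                    )
                )
            i = j + 1
        else:
            i += 1
    return zones


def zones_table(zones) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                chrom=z.chrom,
                start_bp=z.start_bp,
                end_bp=z.end_bp,
                peak_score=z.peak_score,
                peak_id=z.peak_id,
            )
            for z in zones
        ],
        columns=["chrom", "start_bp", "end_bp", "peak_score", "peak_id"],
    )
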