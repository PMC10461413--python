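"""Linkage-disequilibrium reduction of association results.

Three complementary reductions of LD redundancy:

* :func:`clump` — greedy index-variant clumping (best p first, members
  within a physical window and above an r-squared bound), the clump count
  being one polygenicity estimate;
* :func:`ld_prune` — sliding-window pairwise pruning (window/step/r2,
  keeping the earlier-positioned member of each offending pair), used to
  build near-independent genome-wide variant sets;
* :func:`representative_loci` — one representative (lowest-p) variant per
  significant zone, with a final pairwise prune among representatives.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix


def pairwise_r2(genotypes: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete lines.

    Returns nan when fewer than two complete pairs exist or either column
    is constant among them.
    """
    x = genotypes.values[:, i]
    y = genotypes.values[:, j]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return np.nan
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def _r2_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs r2 with pairwise-complete handling (nan where undefined)."""
    m = values.shape[1]
    R = np.full((m, m), np.nan)
    finite = np.isfinite(values)
    if finite.all():
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(values.T)
        R = C * C
        np.fill_diagonal(R, 1.0)
        return R
    for i in range(m):
        R[i, i] = 1.0
        for j in range(i + 1, m):
            x, y = values[:, i], values[:, j]
            ok = finite[:, i] & finite[:, j]
            if ok.sum() < 2:
                continue
            xs, ys = x[ok], y[ok]
            sx, sy = xs.std(), ys.std()
            if sx == 0 or sy == 0:
                continue
            r = np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy)
            R[i, j] = R[j, i] = r * r
    return R


def clump(
    assoc: pd.DataFrame,
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    p1: float = 0.01,
    window_kb: float = 1000.0,
    r2: float = 0.8,
) -> list[dict]:
    """Greedy LD clumping around index variants significant at ``p1``.

    The best (lowest-p) unassigned variant with p < p1 becomes an index;
    every unassigned variant on the same chromosome within ``window_kb``
    kilobases and with r-squared > ``r2`` with the index joins its clump.
    Repeats until no unassigned significant variant remains.  Returns a
    list of {"index": id, "members": [ids]}; the list length is the clump
    polygenicity count.
    """
    merged = assoc[["id", "p_lrt"]].merge(
        variants[["id", "chrom", "pos"]], on="id", how="inner"
    )
    order = {v: k for k, v in enumerate(genotypes.variant_ids)}
    merged = merged.dropna(subset=["p_lrt"])
    sig = merged[merged["p_lrt"] < p1].sort_values(["p_lrt", "chrom", "pos"])
    assigned = set()
    clumps = []
    window_bp = window_kb * 1000.0
    for row in sig.itertuples(index=False):
        if row.id in assigned:
            continue
        assigned.add(row.id)
        i = order[row.id]
        members = []
        near = merged[
            (merged["chrom"] == row.chrom)
            & (np.abs(merged["pos"] - row.pos) <= window_bp)
        ]
        for other in near.itertuples(index=False):
            if other.id in assigned:
                continue
            r2_ij = pairwise_r2(genotypes, i, order[other.id])
            if np.isfinite(r2_ij) and r2_ij > r2:
                members.append(other.id)
                assigned.add(other.id)
        clumps.append({"index": row.id, "members": members})
    return clumps


def ld_prune(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    window: int = 50,
    step: int = 10,
    r2: float = 0.3,
) -> list[str]:
    """Sliding-window pairwise LD pruning (window/step in variant counts).

    Within each window of ``window`` position-sorted variants, while any
    retained pair has r-squared above ``r2`` the later-positioned member
    is removed; the window then slides by ``step``.  Removals accumulate
    globally per chromosome; the retained ids are returned in position
    order.
    """
    if list(variants["id"]) != list(genotypes.variant_ids):
        raise ValueError("variant table and genotype matrix ids disagree")
    retained = []
    for _, sub in variants.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()  # position-sorted within chrom by contract
        removed = np.zeros(len(idx), dtype=bool)
        start = 0
        while True:
            stop = min(start + window, len(idx))
            win = np.arange(start, stop)
            win = win[~removed[win]]
            if len(win) > 1:
                vals = genotypes.values[:, idx[win]]
                R = _r2_matrix(vals)
                # repeatedly drop the later member of the worst pair
                alive = np.ones(len(win), dtype=bool)
                while True:
                    sub_R = np.where(
                        np.outer(alive, alive), R, np.nan
                    )
                    np.fill_diagonal(sub_R, np.nan)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        offending = np.argwhere(sub_R > r2)
                    if len(offending) == 0:
                        break
                    later = int(offending[:, 1].max())  # max index = later position
                    pairs = offending[offending.max(axis=1) == later]
                    later = int(pairs[0].max())
                    alive[later] = False
                removed[win[~alive]] = True
            if stop >= len(idx):
                break
            start += step
        retained.extend(variants.loc[idx[~removed], "id"])
    return retained


def representative_loci(
    zones,
    tracks,
    assoc: pd.DataFrame,
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    daf=None,
    r2max: float = 0.5,
    manual_loci: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One representative variant per significant zone, LD-pruned at ``r2max``.

    ``tracks`` is the chrom -> LindleyTrack dict the zones were called
    from (zone indices refer to track order).  Per zone the lowest-p
    variant wins (ties go leftmost); among the representatives, while any
    pair exceeds ``r2max`` the larger-p member is dropped.
    ``manual_loci`` rows (id, chrom, pos, beta, daf, impact, fixed) are
    appended untouched — the route for known causal loci fixed in a
    population, which cannot surface in GWAS.  Returns the locus table
    (id, chrom, pos, beta, p_lrt, daf, impact, fixed).
    """
    p_by_id = dict(zip(assoc["id"], assoc["p_lrt"]))
    order = {v: k for k, v in enumerate(genotypes.variant_ids)}
    reps = []
    for z in zones:
        track = tracks[z.chrom]
        ids = [
            v
            for v in track.variant_ids[z.start_index : z.end_index + 1]
            if np.isfinite(p_by_id.get(v, np.nan))
        ]
        if not ids:
            warnings.warn(f"zone on {z.chrom} has no testable variant; dropped")
            continue
        best = min(ids, key=lambda v: (p_by_id[v], order[v]))
        reps.append(best)
    # final pairwise prune among representatives: drop the weaker (larger p)
    reps = list(dict.fromkeys(reps))
    changed = True
    while changed:
        changed = False
        for a in list(reps):
            for b in list(reps):
                if a == b or a not in reps or b not in reps:
                    continue
                r2_ab = pairwise_r2(genotypes, order[a], order[b])
                if np.isfinite(r2_ab) and r2_ab > r2max:
                    drop = a if p_by_id[a] >= p_by_id[b] else b
                    reps.remove(drop)
                    changed = True
    vinfo = variants.set_index("id")
    daf_by_id = (
        dict(zip(genotypes.variant_ids, daf)) if daf is not None else {}
    )
    beta_by_id = dict(zip(assoc["id"], assoc["beta"]))
    rows = [
        dict(
            id=v,
            chrom=vinfo.loc[v, "chrom"],
            pos=int(vinfo.loc[v, "pos"]),
            beta=beta_by_id.get(v, np.nan),
            p_lrt=p_by_id.get(v, np.nan),
            daf=daf_by_id.get(v, np.nan),
            impact=vinfo.loc[v, "impact"],
            fixed=False,
        )
        for v in reps
    ]
    out = pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "beta", "p_lrt", "daf", "impact", "fixed"]
    )
    if manual_loci is not None and len(manual_loci):
        manual = manual_loci.copy()
        if "fixed" not in manual:
            manual["fixed"] = True
        if "p_lrt" not in manual:
            manual["p_lrt"] = np.nan
        manual = manual.reindex(columns=out.columns)
        out = manual.copy() if out.empty else pd.concat([out, manual],
                                                        ignore_index=True)
    return out
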