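"""Lineage inference, threshold detection, trees, ranks, and dN/dS."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from repseq.io import Clonotype, Repertoire
from repseq.lineage import (
    ClonalLineage,
    build_lineages,
    build_tree,
    compare_tree_sets,
    detect_threshold,
    dnds,
    hamming_distance,
    make_outgroup,
    mutation_count,
    nearest_distances,
    rank_by_root_distance,
)


def clone(nt, v="V1", j="J1", sample="s", aa=None, gm=None):
    return Clonotype(
        cdr3_nt=nt, v_gene=v, j_gene=j, cdr3_aa=aa, sample_id=sample,
        umi_count=1, frequency=0.0, germline_mutations=gm,
    )


def lineage_of(seqs, outgroup=None, threshold=0.2):
    members = tuple(clone(s, sample=f"s{i}") for i, s in enumerate(seqs))
    return ClonalLineage(
        lineage_id="L0",
        members=members,
        v_gene="V1",
        j_gene="J1",
        cdr3_len=len(seqs[0]),
        threshold_used=threshold,
        germline_outgroup=outgroup,
    )


class TestHamming:
    def test_masked_positions_excluded(self):
        assert hamming_distance("ACGT", "ANGT") == 0.0
        assert hamming_distance("ACGT", "TNGT") == pytest.approx(1 / 3)

    def test_unnormalized_counts_substitutions(self):
        assert hamming_distance("AAAA", "AATT", normalize=False) == 2.0


class TestDetectThreshold:
    def mixture(self, rng, n=2000, mu1=0.05, mu2=0.30):
        half = n // 2
        d = np.concatenate(
            [rng.normal(mu1, 0.02, half), rng.normal(mu2, 0.05, n - half)]
        )
        return np.clip(d, 0.0, 1.0)

    @staticmethod
    def analytic_minimum(mu1=0.05, s1=0.02, mu2=0.30, s2=0.05):
        from scipy.stats import norm

        grid = np.linspace(mu1, mu2, 20001)
        dens = 0.5 * norm.pdf(grid, mu1, s1) + 0.5 * norm.pdf(grid, mu2, s2)
        return grid[np.argmin(dens)]

    def test_bimodal_mixture_recovers_density_minimum(self):
        target = self.analytic_minimum()
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            res = detect_threshold(self.mixture(rng))
            assert not res.flagged
            hits += abs(res.threshold - target) <= 0.03
        assert hits >= 0.9 * n_seeds

    def test_shift_consistency(self):
        """Shifting both modes up by delta moves the threshold by about
        delta."""
        rng = np.random.default_rng(1)
        base = detect_threshold(self.mixture(rng, mu1=0.05, mu2=0.30)).threshold
        rng = np.random.default_rng(1)
        shifted = detect_threshold(self.mixture(rng, mu1=0.10, mu2=0.35)).threshold
        assert shifted - base == pytest.approx(0.05, abs=0.03)

    def test_unimodal_falls_back(self):
        rng = np.random.default_rng(0)
        res = detect_threshold(np.clip(rng.normal(0.3, 0.05, 500), 0, 1))
        assert res.flagged and res.threshold == 0.15

    def test_too_few_distances_falls_back(self):
        res = detect_threshold(np.array([0.1, 0.2, 0.3]))
        assert res.flagged and res.threshold == 0.15

    def test_constant_distances_fall_back(self):
        res = detect_threshold(np.full(100, 0.2))
        assert res.flagged


class TestBuildLineages:
    def rep(self, seqs):
        return Repertoire(tuple(clone(s, sample=f"s{i}") for i, s in enumerate(seqs)))

    def test_single_linkage_chain(self):
        # pairwise distances 0.1, 0.1, 0.2 on length-10 sequences
        seqs = ["AAAAAAAAAA", "CAAAAAAAAA", "CAAAAAAAAC"]
        lins, _ = build_lineages(self.rep(seqs), threshold=0.15)
        assert len(lins) == 1 and lins[0].size == 3

    def test_all_distant_gives_singletons(self):
        seqs = ["AAAAAAAAAA", "CCCCCAAAAA", "GGGGGGGGGG"]
        lins, _ = build_lineages(self.rep(seqs), threshold=0.15)
        assert len(lins) == 3 and all(l.size == 1 for l in lins)

    def test_partition_respects_v_j_length(self):
        members = (
            clone("AAAAAAAAA", v="V1"),
            clone("AAAAAAAAA", v="V2"),
            clone("AAAAAAAAAAAA", v="V1"),
        )
        lins, _ = build_lineages(Repertoire(members), threshold=0.5)
        assert len(lins) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_connected_components_oracle(self, seed):
        """Single-linkage clustering at the threshold equals the connected
        components of the distance graph (networkx oracle)."""
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(20, 120)), 12
        seqs = list({"".join(rng.choice(list("AC"), L)) for _ in range(n)})
        threshold = 0.25
        lins, _ = build_lineages(self.rep(seqs), threshold=threshold)
        got = {frozenset(m.cdr3_nt for m in l.members) for l in lins}
        g = nx.Graph()
        g.add_nodes_from(seqs)
        for a, b in itertools.combinations(seqs, 2):
            if hamming_distance(a, b) <= threshold:
                g.add_edge(a, b)
        expect = {frozenset(cc) for cc in nx.connected_components(g)}
        assert got == expect

    def test_order_invariance(self, rng):
        seqs = list({"".join(rng.choice(list("ACG"), 9)) for _ in range(40)})
        a, _ = build_lineages(self.rep(seqs), threshold=0.25)
        b, _ = build_lineages(self.rep(seqs[::-1]), threshold=0.25)
        assert {frozenset(m.cdr3_nt for m in l.members) for l in a} == {
            frozenset(m.cdr3_nt for m in l.members) for l in b
        }


class TestOutgroup:
    def test_masked_middle(self):
        og = make_outgroup(12, "TGTGCG", "TGG")
        assert og == "TGTGCG" + "NNN" + "TGG"

    def test_no_germline_returns_none(self):
        assert make_outgroup(12, None, None) is None

    def test_overlapping_germline_trimmed(self):
        og = make_outgroup(9, "TGTGCGAGA", "TTTGACTGG")
        assert len(og) == 9


class TestBuildTree:
    def test_three_taxon_closed_form(self):
        """Two members + outgroup: NJ reproduces the exact additive
        distances, so distance to root equals the observed Hamming distance
        to the outgroup."""
        og = "AAAAAAAAAA"
        b, c = "CAAAAAAAAA", "CCCAAAAAAA"
        lin = lineage_of([b, c], outgroup=og)
        tree = build_tree(lin, min_size=2)
        assert tree.distance_to_root[(b, "V1", "J1")] == pytest.approx(
            hamming_distance(b, og), abs=1e-9
        )
        assert tree.distance_to_root[(c, "V1", "J1")] == pytest.approx(
            hamming_distance(c, og), abs=1e-9
        )

    def test_star_topology_equal_root_distances(self):
        og = "A" * 12
        members = ["C" + "A" * 11, "A" * 3 + "C" + "A" * 8, "A" * 6 + "C" + "A" * 5,
                   "A" * 9 + "C" + "A" * 2, "A" * 11 + "C"]
        tree = build_tree(lineage_of(members, outgroup=og), min_size=5)
        vals = list(tree.distance_to_root.values())
        assert np.allclose(vals, vals[0], atol=1e-9)

    def test_member_order_invariance(self, rng):
        og = "A" * 12
        members = ["".join(rng.choice(list("AC"), 12)) for _ in range(6)]
        members = list(dict.fromkeys(members))
        t1 = build_tree(lineage_of(members, outgroup=og), min_size=2)
        t2 = build_tree(lineage_of(members[::-1], outgroup=og), min_size=2)
        for k in t1.distance_to_root:
            assert t1.distance_to_root[k] == pytest.approx(t2.distance_to_root[k], abs=1e-9)

    def test_root_distances_nonnegative(self, rng):
        og = "A" * 15
        members = list({"".join(rng.choice(list("ACGT"), 15)) for _ in range(8)})
        tree = build_tree(lineage_of(members, outgroup=og), min_size=2)
        assert all(v >= 0 for v in tree.distance_to_root.values())

    def test_small_lineage_rejected(self):
        with pytest.raises(ValueError):
            build_tree(lineage_of(["AAAA", "AAAC"], outgroup="AAAA"), min_size=5)


class TestMutationCount:
    def test_identical_to_reference_is_zero(self):
        assert mutation_count(clone("AAAGGG"), "AAAGGG") == 0

    def test_planted_substitutions(self):
        assert mutation_count(clone("TTAGGA"), "AAAGGG") == 3

    def test_precomputed_field_wins(self):
        assert mutation_count(clone("TTTTTT", gm=7), "AAAAAA") == 7

    def test_masked_reference_positions_ignored(self):
        assert mutation_count(clone("AAATTT"), "AAANNN") == 0


class TestRanks:
    def test_chain_ranks(self):
        og = "A" * 10
        members = ["C" + "A" * 9, "CC" + "A" * 8, "CCC" + "A" * 7, "CCCC" + "A" * 6,
                   "CCCCC" + "A" * 5]
        tree = build_tree(lineage_of(members, outgroup=og), min_size=5)
        table = rank_by_root_distance([tree])
        ranks = dict(zip(table.cdr3_aa, table.avg_rank))
        # members sorted by mutation load get ranks 1..5
        got = [tree.ranks[(m, "V1", "J1")] for m in members]
        assert got == [1, 2, 3, 4, 5]

    def test_all_equal_distances_share_mean_rank(self):
        og = "A" * 12
        members = ["C" + "A" * 11, "A" * 5 + "C" + "A" * 6, "A" * 11 + "C",
                   "A" * 3 + "C" + "A" * 8, "A" * 7 + "C" + "A" * 4]
        tree = build_tree(lineage_of(members, outgroup=og), min_size=5)
        assert all(r == 3.0 for r in tree.ranks.values())

    def test_compare_identical_rank_tables(self):
        df = pd.DataFrame(
            {
                "cdr3_aa": list("ABCDEFG"),
                "v_gene": "V1",
                "j_gene": "J1",
                "avg_rank": [1.0, 2, 3, 4, 5, 6, 7],
            }
        )
        r, p, n = compare_tree_sets(df, df)
        assert r == pytest.approx(1.0) and n == 7

    def test_compare_reversed_rank_tables(self):
        df = pd.DataFrame(
            {"cdr3_aa": list("ABCDE"), "v_gene": "V1", "j_gene": "J1",
             "avg_rank": [1.0, 2, 3, 4, 5]}
        )
        rev = df.assign(avg_rank=df.avg_rank.iloc[::-1].to_numpy())
        r, _, _ = compare_tree_sets(df, rev)
        assert r == pytest.approx(-1.0)

    def test_independent_ranks_uncorrelated(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = {"cdr3_aa": [f"A{i}" for i in range(100)], "v_gene": "V1", "j_gene": "J1"}
            a = pd.DataFrame({**base, "avg_rank": rng.permutation(100).astype(float)})
            b = pd.DataFrame({**base, "avg_rank": rng.permutation(100).astype(float)})
            r, _, _ = compare_tree_sets(a, b)
            hits += abs(r) < 0.3
        assert hits >= 19


class TestDnDs:
    def test_single_synonymous_change_is_zero(self):
        ref = "TTTGGGAAA"  # F G K
        obs = "TTCGGGAAA"  # TTT->TTC synonymous (both F)
        res = dnds(lineage_of([obs], outgroup=ref), reference=ref)
        assert res.dnds == 0.0 and res.sd == 1.0

    def test_single_nonsynonymous_change_is_undefined(self):
        ref = "TTTGGGAAA"
        obs = "TGTGGGAAA"  # F->C
        res = dnds(lineage_of([obs], outgroup=ref), reference=ref)
        assert res.undefined and res.nd == 1.0

    def test_neutral_codon_evolution_near_one(self, rng):
        """Uniform substitutions with no selection give dN/dS ~ 1."""
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                  if a + b + c not in {"TAA", "TAG", "TGA"}]
        ref = "".join(rng.choice(codons, 60))
        members = []
        total_subs = 0
        for _ in range(120):
            seq = list(ref)
            n_mut = rng.poisson(2.5)
            total_subs += n_mut
            for _ in range(n_mut):
                pos = int(rng.integers(len(seq)))
                seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            members.append("".join(seq))
        assert total_subs >= 200
        res = dnds(lineage_of(members, outgroup=ref), reference=ref)
        assert not res.undefined
        assert 0.7 <= res.dnds <= 1.3
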