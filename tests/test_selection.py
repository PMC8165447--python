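import math
from itertools import product

import numpy as np
import pytest

import oracles
from famscan import synthgen
from famscan.io import FormatError, GeneModel, PhyloTree, SequenceRecord, TreeNode
from famscan.selection import (
    SENSE_CODONS,
    CodonAlignment,
    WindowConfig,
    _jukes_cantor,
    classify_duplications,
    kaks_pair,
    map_protein_alignment_to_codons,
    ng86_count_differences,
    ng86_count_sites,
    sister_leaf_pairs,
    sliding_window_kaks,
)


class TestSiteCounting:
    @pytest.mark.parametrize("codon,s,n", [
        ("TTT", 1 / 3, 8 / 3),    # only TTT->TTC is synonymous
        ("ATG", 0.0, 3.0),        # Met is a singleton codon
        ("GGG", 1.0, 2.0),        # fourfold-degenerate third position
    ])
    def test_worked_examples(self, codon, s, n):
        got_s, got_n = ng86_count_sites(codon)
        assert got_s == pytest.approx(s, abs=1e-12)
        assert got_n == pytest.approx(n, abs=1e-12)

    def test_sites_partition_to_three_for_every_sense_codon(self):
        for codon in SENSE_CODONS:
            s, n = ng86_count_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)
            assert oracles.brute_sites(codon) == pytest.approx((s, n), abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_count_sites("TAA")


class TestDifferenceCounting:
    @pytest.mark.parametrize("a,b,sd,nd", [
        ("GGA", "GGG", 1.0, 0.0),       # Gly->Gly
        ("TTT", "GTA", 0.5, 1.5),       # two pathways, one syn step in one
        ("AAA", "AAA", 0.0, 0.0),
    ])
    def test_worked_examples(self, a, b, sd, nd):
        assert ng86_count_differences(a, b) == pytest.approx((sd, nd))

    def test_pathway_averaging_conserves_hamming_distance(self):
        for a, b in product(SENSE_CODONS[::7], SENSE_CODONS[::5]):
            sd, nd = ng86_count_differences(a, b)
            ham = sum(x != y for x, y in zip(a, b))
            assert sd + nd == pytest.approx(ham, abs=1e-12)
            assert (sd, nd) == pytest.approx(oracles.brute_differences(a, b),
                                             abs=1e-12)


class TestKaKsPair:
    def test_identical_sequences_undefined_ratio(self):
        cds = "ATGGCTGCA"
        res = kaks_pair(CodonAlignment(cds, cds))
        assert res.sd == res.nd == 0.0
        assert res.ka == res.ks == 0.0
        assert res.ratio is None and res.selection_call == "undefined"

    def test_jukes_cantor_worked_value(self):
        assert _jukes_cantor(0.1) == pytest.approx(0.107326, abs=1e-6)
        assert _jukes_cantor(0.75) is None

    def test_symmetric_in_rows(self, rng):
        a, b, _ = synthgen.evolve_codon_pair(
            60, synthgen.EvolutionConfig(0.5, 40, 5))
        r1 = kaks_pair(CodonAlignment(a.residues, b.residues))
        r2 = kaks_pair(CodonAlignment(b.residues, a.residues))
        assert r1.sd == pytest.approx(r2.sd)
        assert r1.nd == pytest.approx(r2.nd)
        assert r1.s_sites == pytest.approx(r2.s_sites)

    def test_matches_brute_force_oracle_on_random_pairs(self):
        """S, N, Sd, Nd agree with a no-shared-code enumerator to 1e-9."""
        for seed in range(50):
            a, b, _ = synthgen.evolve_codon_pair(
                50, synthgen.EvolutionConfig(1.0, 30, seed))
            res = kaks_pair(CodonAlignment(a.residues, b.residues))
            S, N, Sd, Nd = oracles.brute_pair_counts(a.residues, b.residues)
            assert res.s_sites == pytest.approx(S, abs=1e-9)
            assert res.n_sites == pytest.approx(N, abs=1e-9)
            assert res.sd == pytest.approx(Sd, abs=1e-9)
            assert res.nd == pytest.approx(Nd, abs=1e-9)

    def test_invariants_rejected(self):
        with pytest.raises(FormatError):
            CodonAlignment("ATGA", "ATGA")                 # not codon-sized
        with pytest.raises(FormatError):
            CodonAlignment("ATG---", "ATGA-A")             # ragged gap triplet
        with pytest.raises(FormatError):
            CodonAlignment("ATGTAAGCT", "ATGGCAGCT")       # internal stop


class TestSlidingWindows:
    def test_window_bookkeeping_300_150_9(self):
        a, b, _ = synthgen.evolve_codon_pair(
            100, synthgen.EvolutionConfig(0.5, 60, 3))
        aln = CodonAlignment(a.residues, b.residues)
        wins = sliding_window_kaks(aln, WindowConfig(150, 9))
        assert len(wins) == 17
        assert (wins[0][0], wins[0][1]) == (1, 150)
        assert (wins[-1][0], wins[-1][1]) == (145, 294)

    def test_disjoint_tiling_sums_to_whole_gene(self):
        a, b, _ = synthgen.evolve_codon_pair(
            100, synthgen.EvolutionConfig(0.8, 80, 11))
        aln = CodonAlignment(a.residues, b.residues)
        whole = kaks_pair(aln)
        tiles = sliding_window_kaks(aln, WindowConfig(30, 30))
        assert sum(w[2].sd for w in tiles) == pytest.approx(whole.sd, abs=1e-9)
        assert sum(w[2].nd for w in tiles) == pytest.approx(whole.nd, abs=1e-9)
        assert sum(w[2].s_sites for w in tiles) == pytest.approx(
            whole.s_sites, abs=1e-9)

    def test_identical_alignment_all_windows_undefined(self):
        cds = "".join(SENSE_CODONS[i % 60] for i in range(60))
        wins = sliding_window_kaks(CodonAlignment(cds, cds), WindowConfig(90, 9))
        assert all(w[2].ratio is None for w in wins)

    def test_window_larger_than_alignment(self):
        with pytest.raises(FormatError):
            sliding_window_kaks(CodonAlignment("ATG" * 10, "ATG" * 10),
                                WindowConfig(150, 9))

    def test_window_config_validation(self):
        with pytest.raises(ValueError):
            WindowConfig(100, 9)     # not a multiple of 3
        with pytest.raises(ValueError):
            WindowConfig(150, 0)


class TestBackTranslation:
    def test_gapless_pair_roundtrips(self):
        cds_a = SequenceRecord("a", "ATGGCTAAAGTTTGC")
        cds_b = SequenceRecord("b", "ATGGCAAAAGTATGT")
        aln = map_protein_alignment_to_codons("MAKVC", "MAKVC", cds_a, cds_b)
        assert aln.row_a == cds_a.residues
        assert aln.row_b == cds_b.residues

    def test_protein_gap_becomes_aligned_triplet(self):
        cds_a = SequenceRecord("a", "ATGGCTGTT")       # MAV
        cds_b = SequenceRecord("b", "ATGGCTAAAGTT")    # MAKV
        aln = map_protein_alignment_to_codons("MA-V", "MAKV", cds_a, cds_b)
        assert aln.row_a[6:9] == "---"
        assert aln.row_a.replace("-", "") == cds_a.residues

    def test_trailing_stop_trimmed(self):
        cds_a = SequenceRecord("a", "ATGGCTGTTTAA")
        cds_b = SequenceRecord("b", "ATGGCTGTT")
        aln = map_protein_alignment_to_codons("MAV", "MAV", cds_a, cds_b)
        assert len(aln.row_a) == 9

    def test_length_mismatch_reports_expectation(self):
        with pytest.raises(FormatError, match="9 nt expected"):
            map_protein_alignment_to_codons(
                "MAV", "MAV",
                SequenceRecord("a", "ATGGCT"), SequenceRecord("b", "ATGGCTGTT"),
            )

    def test_internal_stop_reports_codon_index(self):
        with pytest.raises(FormatError, match="codon 2"):
            map_protein_alignment_to_codons(
                "MAV", "MAV",
                SequenceRecord("a", "ATGTAAGTT"), SequenceRecord("b", "ATGGCTGTT"),
            )


def _pair_fixture(rng):
    """Hand-built members: sister pairs with controlled identity and
    coordinates covering every duplication outcome."""
    aa = "ACDEFGHIKLMNPQRSTVWY"

    def protein(n):
        return "M" + "".join(aa[i] for i in rng.integers(0, 20, n - 1))

    def cds_for(prot):
        return synthgen._back_translate(prot, rng)[:-3]

    def mutate(prot, frac):
        chars = list(prot)
        sites = 1 + rng.permutation(len(prot) - 1)[:int(frac * len(prot))]
        for s in sites:
            chars[s] = aa[(aa.index(chars[s]) + 7) % 20]
        return "".join(chars)

    proteins, cds, models = {}, {}, {}

    def add(gid, prot, chrom, start):
        proteins[gid] = SequenceRecord(gid, prot)
        c = cds_for(prot)
        cds[gid] = SequenceRecord(gid, c)
        models[gid] = GeneModel(gid, chrom, "+", start, start + len(c) - 1,
                                cds_parts=((start, start + len(c) - 1),))

    p1 = protein(120)
    add("t1", p1, "chr1", 10_000)
    add("t2", mutate(p1, 0.05), "chr1", 60_000)          # 50 kb apart -> tandem
    p2 = protein(120)
    add("s1", p2, "chr3", 10_000)
    add("s2", mutate(p2, 0.05), "chr9", 40_000)          # -> segmental
    p3 = protein(120)
    add("x1", p3, "chr2", 10_000)
    add("x2", mutate(p3, 0.30), "chr2", 20_000)          # 70% identity -> dropped
    p4 = protein(120)
    add("f1", p4, "chr4", 10_000)
    add("f2", mutate(p4, 0.05), "chr4", 310_000)         # 300 kb -> unclassified
    p5 = protein(120)
    add("u1", p5, "chr5", 10_000)
    add("u2", mutate(p5, 0.05), "scaffold9.0", 5_000)    # unplaced

    def cherry(a, b):
        return TreeNode(children=[TreeNode(name=a, length=0.1),
                                  TreeNode(name=b, length=0.1)], length=0.2)

    tree = PhyloTree(TreeNode(children=[
        cherry("t1", "t2"), cherry("s1", "s2"), cherry("x1", "x2"),
        cherry("f1", "f2"), cherry("u1", "u2"),
    ]))
    return models, proteins, cds, tree


class TestDuplicationClassifier:
    def test_typing_follows_coordinates_and_identity(self, rng):
        models, proteins, cds, tree = _pair_fixture(rng)
        events = {(e.gene_a, e.gene_b): e
                  for e in classify_duplications(models, proteins, cds, tree)}
        assert ("x1", "x2") not in events            # below 80% identity
        t = events[("t1", "t2")]
        assert t.dup_type == "tandem"
        assert t.chromosomal_relation == "same_chromosome"
        assert t.separation_bp == 50_000
        assert t.identity_pct > 80
        s = events[("s1", "s2")]
        assert s.dup_type == "segmental"
        assert s.chromosomal_relation == "different_chromosome"
        f = events[("f1", "f2")]
        assert f.dup_type == "unclassified" and f.separation_bp == 300_000
        u = events[("u1", "u2")]
        assert u.dup_type == "unclassified"
        assert u.chromosomal_relation == "unplaced"
        for ev in events.values():
            assert ev.kaks.selection_call in (
                "positive", "purifying", "neutral", "undefined")

    def test_missing_gene_model_named(self, rng):
        models, proteins, cds, tree = _pair_fixture(rng)
        del models["t2"]
        with pytest.raises(KeyError, match="t2"):
            classify_duplications(models, proteins, cds, tree)

    def test_sister_pairs_are_immediate_cherries_only(self):
        tree = PhyloTree(TreeNode(children=[
            TreeNode(children=[
                TreeNode(name="a"), TreeNode(name="b"),
                TreeNode(children=[TreeNode(name="c"), TreeNode(name="d")]),
            ]),
            TreeNode(name="e"),
        ]))
        assert set(sister_leaf_pairs(tree)) == {("a", "b"), ("c", "d")}
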