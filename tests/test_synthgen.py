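import numpy as np
import pytest

from famscan import synthgen
from famscan.io import parse_fasta, parse_gff3
from famscan.promoter import default_motif_table, extract_promoters, scan_cis_elements
from famscan.selection import STOP_CODONS
from famscan.synthgen import (
    DesignError,
    EvolutionConfig,
    FamilySpec,
    ParameterError,
    PlanError,
    SpecError,
    evolve_codon_pair,
    generate_ct_table,
    generate_family_genome,
    plant_promoter_elements,
    random_promoter_plan,
)


class TestEvolveCodonPair:
    def test_zero_events_identical_copies(self):
        a, b, counts = evolve_codon_pair(20, EvolutionConfig(0.5, 0, 1))
        assert a.residues == b.residues
        assert counts["synonymous"] == counts["nonsynonymous"] == 0

    def test_omega_zero_forbids_nonsynonymous_acceptance(self):
        _, _, counts = evolve_codon_pair(50, EvolutionConfig(0.0, 50, 2))
        assert counts["nonsynonymous"] == 0

    def test_no_stop_codons_ever_created(self):
        for seed in range(5):
            _, b, _ = evolve_codon_pair(40, EvolutionConfig(2.0, 100, seed))
            codons = {b.residues[i:i + 3] for i in range(0, len(b.residues), 3)}
            assert not codons & STOP_CODONS

    def test_reproducible_from_seed(self):
        r1 = evolve_codon_pair(30, EvolutionConfig(0.4, 60, 9))
        r2 = evolve_codon_pair(30, EvolutionConfig(0.4, 60, 9))
        assert r1[0].residues == r2[0].residues
        assert r1[1].residues == r2[1].residues
        assert r1[2] == r2[2]

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            EvolutionConfig(-0.1, 10, 0)
        with pytest.raises(ParameterError):
            evolve_codon_pair(5, EvolutionConfig(0.5, 10, 0))


class TestFamilyGenome:
    def test_member_bookkeeping(self, small_family):
        fam = small_family
        # 3 PCF + 2 CIN + 1 CYC + 2x2 duplicate pairs + 1x2 decoy pair
        assert len(fam.truth.members) == 12
        labels = list(fam.truth.members.values())
        assert labels.count("PCF") == 3 and labels.count("CYC") == 1
        emitted = {p.id for p in fam.proteins}
        assert set(fam.truth.members) <= emitted
        assert set(fam.truth.background) <= emitted
        for gid, (s, e) in fam.truth.domain_intervals.items():
            prot = next(p for p in fam.proteins if p.id == gid)
            assert 1 <= s <= e <= len(prot)

    def test_tandem_pair_separation_and_chromosome(self, small_family):
        genes = {g.gene_id: g for g in small_family.genes}
        pair = next(p for p in small_family.truth.duplicate_pairs
                    if p.dup_type == "tandem")
        ga, gb = genes[pair.gene_a], genes[pair.gene_b]
        assert ga.chromosome == gb.chromosome
        assert abs(gb.start - ga.start) == pair.separation_bp == 50_000

    def test_segmental_pair_on_different_chromosomes(self, small_family):
        genes = {g.gene_id: g for g in small_family.genes}
        pair = next(p for p in small_family.truth.duplicate_pairs
                    if p.dup_type == "segmental" and p.expect_retained)
        assert genes[pair.gene_a].chromosome != genes[pair.gene_b].chromosome

    def test_genome_carries_the_annotated_cds(self, small_family):
        fam = small_family
        genome = {r.id: r for r in fam.genome}
        cds = {c.id: c for c in fam.cds}
        from famscan.io import reverse_complement
        for g in fam.genes[:5]:
            embedded = genome[g.chromosome].residues[g.start - 1:g.end]
            if g.strand == "-":
                embedded = reverse_complement(embedded)
            assert embedded == cds[g.gene_id].residues

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        spec = FamilySpec(n_pcf=2, n_cin=1, n_cyc=1, n_background=2,
                          tandem_separations_bp=(30_000,),
                          n_segmental_pairs=1, low_identity_fractions=(),
                          chromosome_length=120_000)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_family_genome(2, spec, 5).write(d1)
        generate_family_genome(2, spec, 5).write(d2)
        for name in ("genome.fna", "genes.gff3", "proteins.faa", "cds.fna",
                     "truth_members.tsv", "truth_pairs.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_written_fixture_reparses(self, tmp_path, small_family):
        paths = small_family.write(tmp_path)
        genome = parse_fasta(paths["genome"], "dna")
        assert len(genome) == 3
        models = parse_gff3(paths["gff"])
        assert {m.gene_id for m in models} == {g.gene_id for g in small_family.genes}

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(SpecError):
            generate_family_genome(1, FamilySpec(n_segmental_pairs=1), 0)
        with pytest.raises(SpecError):
            generate_family_genome(
                2, FamilySpec(tandem_separations_bp=(500_000,)), 0)


class TestPromoterPlanting:
    def test_offset_outside_window_rejected(self, small_family):
        motifs = default_motif_table()
        plan = [(sorted(small_family.truth.members)[0], "ABRE", 1499, "+")]
        with pytest.raises(PlanError, match="offset"):
            plant_promoter_elements(small_family.genome, small_family.genes,
                                    motifs, plan, seed=1)

    def test_overlapping_plan_rejected(self, small_family):
        motifs = default_motif_table()
        g = sorted(small_family.truth.members)[0]
        plan = [(g, "ABRE", 100, "+"), (g, "G-box", 103, "+")]
        with pytest.raises(PlanError, match="overlap"):
            plant_promoter_elements(small_family.genome, small_family.genes,
                                    motifs, plan, seed=1)

    def test_empty_plan_scrubs_background_clean(self, small_family):
        motifs = default_motif_table()
        genome, truth = plant_promoter_elements(
            small_family.genome, small_family.genes, motifs, [], seed=3)
        assert truth == []
        gmap = {r.id: r for r in genome}
        proms = extract_promoters(gmap, small_family.genes, 1500)
        assert scan_cis_elements(proms, motifs, "given_only") == []


class TestCtGenerator:
    def test_calibrator_must_be_designed(self):
        with pytest.raises(DesignError):
            generate_ct_table({"s": {"g": 2.0}}, "ref", "cal", 0.1)

    def test_replicate_and_noise_validation(self):
        design = {"cal": {"g": 1.0}}
        with pytest.raises(DesignError):
            generate_ct_table(design, "ref", "cal", 0.1, replicates=1)
        with pytest.raises(DesignError):
            generate_ct_table(design, "ref", "cal", -0.5)

    def test_reference_fixed_at_fold_one(self):
        design = {"cal": {"g": 1.0}, "s": {"g": 8.0}}
        tbl, _ = generate_ct_table(design, "ref", "cal", 0.0, seed=3)
        ref = tbl.data[tbl.data["gene"] == "ref"]
        assert ref["ct"].nunique() == 1


class TestRandomPromoterPlan:
    def test_requested_counts_and_no_overlaps(self, rng):
        motifs = default_motif_table()
        genes = [f"g{i}" for i in range(10)]
        plan = random_promoter_plan(genes, {"ABRE": 30, "MBS": 10}, motifs, rng)
        assert sum(1 for p in plan if p[1] == "ABRE") == 30
        assert sum(1 for p in plan if p[1] == "MBS") == 10
        by_gene: dict[str, list[tuple[int, int]]] = {}
        for g, el, off, _ in plan:
            k = len(motifs[el].consensus)
            iv = (off, off + k - 1)
            for s, e in by_gene.setdefault(g, []):
                assert iv[1] < s or iv[0] > e
            by_gene[g].append(iv)
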