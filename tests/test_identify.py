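import math

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from famscan import synthgen
from famscan._align import AlignmentError, align_local
from famscan.identify import (
    KYTE_DOOLITTLE,
    PKA_TABLE,
    ScanConfig,
    WATER_MASS,
    classify_subfamily,
    default_class_references,
    default_domain_reference,
    karlin_altschul_evalue,
    net_charge,
    physicochemical_profile,
    scan_for_domain,
    smith_waterman,
    ProfileError,
    ClassificationError,
)
from famscan.io import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def _biopython_local_aligner():
    """Independent quadratic-space reference for local affine alignment."""
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -12.0       # open + extend on the first gap residue
    a.extend_gap_score = -1.0
    return a


class TestSmithWaterman:
    def test_matches_independent_reference_on_random_pairs(self, rng):
        oracle = _biopython_local_aligner()
        cfg = ScanConfig()
        for _ in range(100):
            a = "".join(AA[i] for i in rng.integers(0, 20, 30))
            b = "".join(AA[i] for i in rng.integers(0, 20, 30))
            aln = smith_waterman(SequenceRecord("q", a), SequenceRecord("s", b), cfg)
            assert aln.score == pytest.approx(oracle.score(a, b), abs=1e-9)

    def test_self_alignment_covers_full_length(self):
        cfg = ScanConfig()
        seq = "MKRQWLEDVHAGF"
        mat = substitution_matrices.load("BLOSUM62")
        expected = sum(mat[c, c] for c in seq)
        aln = smith_waterman(SequenceRecord("a", seq), SequenceRecord("b", seq), cfg)
        assert aln.score == pytest.approx(expected)
        assert (aln.a_start, aln.a_end) == (1, len(seq))
        assert (aln.b_start, aln.b_end) == (1, len(seq))

    def test_all_nonpositive_scores_give_empty_alignment(self):
        # A vs T scores 0 under BLOSUM62, so nothing can rise above the floor
        aln, ra, rb = align_local("AAA", "TTTT")
        assert aln.score == 0.0 and aln.is_empty and ra == "" == rb

    def test_score_symmetric_for_symmetric_matrix(self, rng):
        for _ in range(20):
            a = "".join(AA[i] for i in rng.integers(0, 20, 25))
            b = "".join(AA[i] for i in rng.integers(0, 20, 25))
            fwd, _, _ = align_local(a, b)
            rev, _, _ = align_local(b, a)
            assert fwd.score == pytest.approx(rev.score)

    def test_unknown_residue_named(self):
        with pytest.raises(AlignmentError, match="'J'.*position 2"):
            align_local("AJA", "AAA")


class TestScan:
    def test_planted_domain_accepted_with_tiny_evalue(self):
        dom = default_domain_reference()
        prot = SequenceRecord("hit", "M" + "A" * 30 + dom.residues + "G" * 50)
        decoys = [SequenceRecord(f"d{i}", "LVIF" * 50) for i in range(5)]
        hits = scan_for_domain([prot] + decoys, ScanConfig())
        assert [h.protein_id for h in hits] == ["hit"]
        assert hits[0].e_value < 1e-10
        assert hits[0].hit_start == 32
        assert hits[0].hit_end == 31 + len(dom)

    def test_evalue_strictly_decreasing_in_score(self):
        cfg = ScanConfig()
        scores = [50.0, 100.0, 200.0, 400.0]
        es = [karlin_altschul_evalue(s, 59, 10_000, cfg) for s in scores]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_empty_protein_set(self):
        assert scan_for_domain([], ScanConfig()) == []

    def test_sensitivity_and_specificity_on_synthetic_families(self):
        """Planted members recovered and background excluded, >=95% each."""
        tp = fn = tn = fp = 0
        for seed in range(10):
            spec = synthgen.FamilySpec(
                n_pcf=2, n_cin=2, n_cyc=1, n_background=6,
                tandem_separations_bp=(), n_segmental_pairs=0,
                low_identity_fractions=(), chromosome_length=100_000,
            )
            fam = synthgen.generate_family_genome(2, spec, seed)
            hits = {h.protein_id for h in scan_for_domain(fam.proteins, ScanConfig())}
            for gid in fam.truth.members:
                tp += gid in hits
                fn += gid not in hits
            for gid in fam.truth.background:
                fp += gid in hits
                tn += gid not in hits
        assert tp / (tp + fn) >= 0.95
        assert tn / (tn + fp) >= 0.95


class TestClassify:
    def test_planted_subfamilies_recovered(self, small_family):
        fam = small_family
        hits = scan_for_domain(fam.proteins, ScanConfig())
        c1, c2 = default_class_references()
        prot = {p.id: p for p in fam.proteins}
        calls = {
            h.protein_id: classify_subfamily(h, prot[h.protein_id], c1, c2)
            for h in hits
        }
        pcf = next(c for g, c in calls.items() if g.startswith("pcf"))
        cyc = next(c for g, c in calls.items() if g.startswith("cyc"))
        assert pcf.class_label == "PCF" and pcf.basic_region_gap
        assert cyc.class_label == "CYC" and cyc.r_domain_found
        assert cyc.r_domain_interval is not None

    def test_mixed_family_agreement_at_least_95pct(self):
        agree = total = 0
        for seed in range(3):
            spec = synthgen.FamilySpec(
                n_pcf=8, n_cin=6, n_cyc=4, n_background=0,
                tandem_separations_bp=(), n_segmental_pairs=0,
                low_identity_fractions=(), chromosome_length=150_000,
            )
            fam = synthgen.generate_family_genome(2, spec, 100 + seed)
            hits = scan_for_domain(fam.proteins, ScanConfig())
            c1, c2 = default_class_references()
            prot = {p.id: p for p in fam.proteins}
            for h in hits:
                call = classify_subfamily(h, prot[h.protein_id], c1, c2)
                agree += call.class_label == fam.truth.members[h.protein_id]
                total += 1
        assert total >= 50
        assert agree / total >= 0.95

    def test_short_region_rejected(self):
        from famscan.identify import DomainHit
        hit = DomainHit("p", 1, 10, 50.0, 1e-6, 0.2)
        with pytest.raises(ClassificationError):
            classify_subfamily(
                hit, SequenceRecord("p", "MKRQWLEDVHAGFKRQW"),
                *default_class_references()
            )


class TestPhysicochemistry:
    def test_gravy_of_ala_tripeptide(self):
        prof = physicochemical_profile(SequenceRecord("a", "AAA"))
        assert prof.gravy == pytest.approx(1.8)

    def test_pi_matches_two_group_closed_form(self):
        # glycylglycine: no ionizable side chains -> pI = (9.6 + 2.34) / 2
        prof = physicochemical_profile(SequenceRecord("gg", "GG"))
        expected = (PKA_TABLE["N_term"] + PKA_TABLE["C_term"]) / 2.0
        assert prof.isoelectric_point == pytest.approx(expected, abs=0.01)

    def test_net_charge_strictly_decreasing(self, rng):
        for _ in range(100):
            seq = "".join(AA[i] for i in rng.integers(0, 20, 30))
            phs = np.linspace(0.5, 13.5, 27)
            qs = [net_charge(seq, p) for p in phs]
            assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_gravy_reversal_invariant_and_mw_additivity(self, rng):
        a = "".join(AA[i] for i in rng.integers(0, 20, 17))
        b = "".join(AA[i] for i in rng.integers(0, 20, 23))
        pa = physicochemical_profile(SequenceRecord("a", a))
        pr = physicochemical_profile(SequenceRecord("r", a[::-1]))
        assert pa.gravy == pytest.approx(pr.gravy)
        pb = physicochemical_profile(SequenceRecord("b", b))
        pab = physicochemical_profile(SequenceRecord("ab", a + b))
        joined = pa.molecular_weight_kda + pb.molecular_weight_kda \
            - WATER_MASS / 1000.0
        assert pab.molecular_weight_kda == pytest.approx(joined)

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ProfileError):
            physicochemical_profile(SequenceRecord("x", "AAXA"))
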