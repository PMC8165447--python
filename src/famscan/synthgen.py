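"""Synthetic genomes, gene families, codon pairs, promoters and Ct tables
with machine-readable truth.

Every generator is a pure function of (spec, seed). Defaults emulate the
statistical shape of a mid-size Rosaceae transcription-factor family: a
34-member family (14 PCF, 12 CIN, 8 CYC) scattered over multi-100-kb
chromosomes, tandem duplicates within 200 kb on one chromosome, segmental
duplicates across chromosomes diverged under a known omega, promoters with
planted cis-element occurrences, and triplicated qPCR Ct tables with known
fold changes.

Codon evolution is an acceptance-rejection scheme rather than a full
Markov codon model: each proposal round draws one uniform random
single-nucleotide change; stop-creating proposals are rejected, synonymous
proposals are accepted with probability 1 and nonsynonymous ones with
probability min(omega, 1) (for omega > 1 the synonymous acceptance drops
to 1/omega instead). The realized synonymous/nonsynonymous event ratio is
therefore directly controllable, which is what validating NG86 against
realized counts requires.

Backgrounds are actively scrubbed of confounders so truth is exact: the
C-terminal tails of non-CYC members are re-drawn until no window mimics an
R domain, and promoter backgrounds are re-drawn until no accidental motif
matches remain outside the planted occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from famscan.expression import CtTable
from famscan.identify import POLAR_RESIDUES, default_class_references
from famscan.io import (
    GeneModel,
    PhyloTree,
    SequenceRecord,
    TreeNode,
    reverse_complement,
    write_fasta,
    write_gff3,
    write_tsv,
)
from famscan.phylo import DistanceMatrix, leaf_path_distances
from famscan.promoter import MotifTable, promoter_genomic_window, scan_cis_elements
from famscan.selection import SENSE_CODONS, STOP_CODONS, translate_codon

__all__ = [
    "ParameterError", "SpecError", "PlanError", "DesignError",
    "EvolutionConfig", "FamilySpec", "FamilyTruth", "SyntheticFamily",
    "DuplicatePairTruth", "PlantedElement",
    "evolve_codon_pair", "generate_family_genome",
    "plant_promoter_elements", "generate_ct_table", "random_additive_tree",
    "R_DOMAIN",
]


class ParameterError(ValueError):
    pass


class SpecError(ValueError):
    pass


class PlanError(ValueError):
    pass


class DesignError(ValueError):
    pass


AA20 = "ACDEFGHIKLMNPQRSTVWY"
R_DOMAIN = "KKDRESSTNQSDKRSQNSES"   # hydrophilic, polar-rich 20-mer

_CODONS_FOR_AA: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _CODONS_FOR_AA.setdefault(translate_codon(_c), []).append(_c)
_STOPS = sorted(STOP_CODONS)
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# codon-pair evolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolutionConfig:
    """True omega target, number of proposal rounds, and the seed."""

    omega: float
    n_events: int
    seed: int

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ParameterError("omega must be non-negative")
        if self.n_events < 0:
            raise ParameterError("n_events must be non-negative")


def _evolve_codons(codons: list[str], omega: float, n_events: int,
                   rng: np.random.Generator) -> dict[str, int]:
    """Mutate a codon list in place by acceptance-rejection rounds."""
    counts = {"synonymous": 0, "nonsynonymous": 0,
              "rejected_stop": 0, "rejected_selection": 0}
    L = len(codons)
    if omega <= 1.0:
        p_syn, p_non = 1.0, omega
    else:
        p_syn, p_non = 1.0 / omega, 1.0
    for _ in range(n_events):
        site = int(rng.integers(0, 3 * L))
        ci, off = divmod(site, 3)
        cur = codons[ci]
        alts = [b for b in _BASES if b != cur[off]]
        base = alts[int(rng.integers(0, 3))]
        new = cur[:off] + base + cur[off + 1:]
        if new in STOP_CODONS:
            counts["rejected_stop"] += 1
            continue
        syn = translate_codon(cur) == translate_codon(new)
        p = p_syn if syn else p_non
        if p >= 1.0 or rng.random() < p:
            codons[ci] = new
            counts["synonymous" if syn else "nonsynonymous"] += 1
        else:
            counts["rejected_selection"] += 1
    return counts


def evolve_codon_pair(ancestor_length_codons: int, cfg: EvolutionConfig
                      ) -> tuple[SequenceRecord, SequenceRecord, dict[str, int]]:
    """Draw a random stop-free ancestor CDS and evolve one copy.

    Returns (cds_a, cds_b, realized counts); fully reproducible from
    ``cfg.seed``.
    """
    if ancestor_length_codons < 10:
        raise ParameterError("ancestor must be at least 10 codons")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, len(SENSE_CODONS), ancestor_length_codons)
    ancestor = [SENSE_CODONS[i] for i in idx]
    copy = list(ancestor)
    counts = _evolve_codons(copy, cfg.omega, cfg.n_events, rng)
    return (
        SequenceRecord("cds_a", "".join(ancestor)),
        SequenceRecord("cds_b", "".join(copy)),
        counts,
    )


# ---------------------------------------------------------------------------
# family genome generation
# ---------------------------------------------------------------------------

@dataclass
class FamilySpec:
    """What to plant: member counts per subfamily, duplicate pairs, decoys.

    ``tandem_separations_bp`` lists one start-to-start separation per
    planted tandem pair (same chromosome); segmental pairs land on
    different chromosomes. ``low_identity_fractions`` plants extra
    cross-chromosome pairs at the given amino-acid identity so the >80%
    retention rule has something to reject.
    """

    n_pcf: int = 14
    n_cin: int = 12
    n_cyc: int = 8
    tandem_separations_bp: tuple[int, ...] = (50_000, 120_000)
    n_segmental_pairs: int = 2
    low_identity_fractions: tuple[float, ...] = (0.70,)
    n_background: int = 30
    chromosome_length: int = 400_000
    dup_omega: float = 0.2
    dup_n_events: int = 60
    flank_n_range: tuple[int, int] = (30, 60)
    flank_c_range: tuple[int, int] = (80, 120)
    min_gene_spacing: int = 2_500


@dataclass(frozen=True)
class DuplicatePairTruth:
    gene_a: str
    gene_b: str
    dup_type: str                # tandem | segmental
    omega: float
    separation_bp: int | None
    expect_retained: bool        # False for low-identity decoy pairs
    target_identity: float | None = None


@dataclass(frozen=True)
class PlantedElement:
    gene_id: str
    element: str
    offset: int
    strand: str


@dataclass
class FamilyTruth:
    members: dict[str, str] = field(default_factory=dict)
    domain_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    duplicate_pairs: list[DuplicatePairTruth] = field(default_factory=list)
    promoter_plants: list[PlantedElement] = field(default_factory=list)
    fold_changes: dict[tuple[str, str], float] = field(default_factory=dict)
    background: list[str] = field(default_factory=list)


@dataclass
class SyntheticFamily:
    genome: list[SequenceRecord]
    genes: list[GeneModel]
    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    truth: FamilyTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fna",
            "gff": outdir / "genes.gff3",
            "proteins": outdir / "proteins.faa",
            "cds": outdir / "cds.fna",
            "truth_members": outdir / "truth_members.tsv",
            "truth_pairs": outdir / "truth_pairs.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_gff3(self.genes, paths["gff"])
        write_fasta(self.proteins, paths["proteins"])
        write_fasta(self.cds, paths["cds"])
        write_tsv(pd.DataFrame(
            [{"gene_id": g, "subfamily": s,
              "domain_start": self.truth.domain_intervals[g][0],
              "domain_end": self.truth.domain_intervals[g][1]}
             for g, s in self.truth.members.items()]
        ), paths["truth_members"])
        write_tsv(pd.DataFrame(
            [{"gene_a": p.gene_a, "gene_b": p.gene_b, "dup_type": p.dup_type,
              "omega": p.omega, "separation_bp": p.separation_bp,
              "expect_retained": p.expect_retained}
             for p in self.truth.duplicate_pairs]
        ), paths["truth_pairs"])
        return paths


def _rand_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, len(AA20), n))


def _scrub_polar_windows(seq: str, rng: np.random.Generator,
                         window: int = 20, threshold: float = 0.6,
                         max_rounds: int = 500) -> str:
    """Re-draw residues until no window is polar-rich enough to mimic an
    R domain."""
    chars = list(seq)
    for _ in range(max_rounds):
        bad = None
        for i in range(0, len(chars) - window + 1):
            frac = sum(c in POLAR_RESIDUES for c in chars[i:i + window]) / window
            if frac >= threshold:
                bad = i
                break
        if bad is None:
            return "".join(chars)
        for j in range(bad, bad + window):
            chars[j] = AA20[int(rng.integers(0, len(AA20)))]
    raise SpecError("could not scrub polar-rich windows from a decoy tail")


def _member_protein(subfamily: str, rng: np.random.Generator,
                    spec: FamilySpec) -> tuple[str, tuple[int, int]]:
    """Protein string and the 1-based domain interval for one member."""
    class1, class2 = default_class_references()
    dom = class1.residues if subfamily == "PCF" else class2.residues
    fn = int(rng.integers(*spec.flank_n_range))
    fc = int(rng.integers(*spec.flank_c_range))
    flank_n = _rand_aa(rng, fn)
    flank_c = _rand_aa(rng, fc)
    if subfamily == "CYC":
        spacer = _rand_aa(rng, int(rng.integers(8, 13)))
        tail = spacer + R_DOMAIN + flank_c
    else:
        tail = _scrub_polar_windows(flank_c, rng)
    protein = "M" + flank_n + dom + tail
    dstart = 2 + fn
    return protein, (dstart, dstart + len(dom) - 1)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS_FOR_AA[aa][int(rng.integers(0, len(_CODONS_FOR_AA[aa])))]
        for aa in protein
    ]
    codons.append(_STOPS[int(rng.integers(0, len(_STOPS)))])
    return "".join(codons)


def _translate_cds(cds: str) -> str:
    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


def _place_interval(occupied: list[tuple[int, int]], L: int, glen: int,
                    margin: int, rng: np.random.Generator,
                    start: int | None = None) -> int:
    lo, hi = margin + 1, L - glen - margin
    if hi <= lo:
        raise SpecError("chromosome too short for the requested genes")
    for _ in range(2000):
        s = start if start is not None else int(rng.integers(lo, hi))
        e = s + glen - 1
        if all(e + margin < s2 or s - margin > e2 for s2, e2 in occupied):
            occupied.append((s, e))
            return s
        if start is not None:
            raise SpecError("fixed placement overlaps an existing gene")
    raise SpecError("could not place gene; chromosome too crowded")


def generate_family_genome(n_chromosomes: int, spec: FamilySpec, seed: int
                           ) -> SyntheticFamily:
    """Emit genome + annotation + proteins + CDS with full planted truth.

    Deterministic: the same (spec, seed) yields byte-identical outputs.
    """
    if n_chromosomes < 1:
        raise SpecError("need at least one chromosome")
    if spec.n_segmental_pairs > 0 and n_chromosomes < 2:
        raise SpecError("segmental pairs need at least 2 chromosomes")
    if spec.tandem_separations_bp:
        worst = max(spec.tandem_separations_bp)
        if worst + 4 * spec.min_gene_spacing >= spec.chromosome_length:
            raise SpecError(
                f"tandem separation {worst} does not fit a "
                f"{spec.chromosome_length} bp chromosome"
            )
    rng = np.random.default_rng(seed)
    truth = FamilyTruth()
    # gene_id -> (cds string, chromosome index or None, fixed start or None)
    entries: list[dict] = []

    def add_member(gene_id: str, subfamily: str) -> None:
        protein, dom = _member_protein(subfamily, rng, spec)
        entries.append({"gene_id": gene_id, "cds": _back_translate(protein, rng)})
        truth.members[gene_id] = subfamily
        truth.domain_intervals[gene_id] = dom

    for i in range(spec.n_pcf):
        add_member(f"pcf{i + 1:02d}", "PCF")
    for i in range(spec.n_cin):
        add_member(f"cin{i + 1:02d}", "CIN")
    for i in range(spec.n_cyc):
        add_member(f"cyc{i + 1:02d}", "CYC")

    def add_pair(prefix: str, dup_type: str, separation: int | None
                 ) -> tuple[str, str]:
        ga, gb = f"{prefix}a", f"{prefix}b"
        protein, dom = _member_protein("CIN", rng, spec)
        cds_a = _back_translate(protein, rng)
        codons = [cds_a[k:k + 3] for k in range(0, len(cds_a) - 3, 3)]
        _evolve_codons(codons, spec.dup_omega, spec.dup_n_events, rng)
        cds_b = "".join(codons) + cds_a[-3:]
        entries.append({"gene_id": ga, "cds": cds_a})
        entries.append({"gene_id": gb, "cds": cds_b})
        for g in (ga, gb):
            truth.members[g] = "CIN"
            truth.domain_intervals[g] = dom
        truth.duplicate_pairs.append(DuplicatePairTruth(
            ga, gb, dup_type, spec.dup_omega, separation, True
        ))
        return ga, gb

    tandem_ids = []
    for t, sep in enumerate(spec.tandem_separations_bp, start=1):
        tandem_ids.append((add_pair(f"dup_t{t}", "tandem", int(sep)), int(sep)))
    segmental_ids = []
    for s in range(1, spec.n_segmental_pairs + 1):
        segmental_ids.append(add_pair(f"dup_s{s}", "segmental", None))

    low_ids = []
    for k, ident in enumerate(spec.low_identity_fractions, start=1):
        ga, gb = f"low{k}a", f"low{k}b"
        protein, dom = _member_protein("CIN", rng, spec)
        cds_a = _back_translate(protein, rng)
        n_res = len(protein)
        n_mut = int(round((1.0 - ident) * n_res))
        # never touch the initiator Met
        sites = 1 + rng.permutation(n_res - 1)[:n_mut]
        codons = [cds_a[j:j + 3] for j in range(0, len(cds_a) - 3, 3)]
        nonpolar = [a for a in AA20 if a not in POLAR_RESIDUES]
        for site in sites:
            old_aa = protein[site]
            # keep the scrubbed tail free of fake R-domain windows
            pool = nonpolar if site + 1 > dom[1] else AA20
            choices = [a for a in pool if a != old_aa]
            new_aa = choices[int(rng.integers(0, len(choices)))]
            opts = _CODONS_FOR_AA[new_aa]
            codons[site] = opts[int(rng.integers(0, len(opts)))]
        cds_b = "".join(codons) + cds_a[-3:]
        entries.append({"gene_id": ga, "cds": cds_a})
        entries.append({"gene_id": gb, "cds": cds_b})
        for g in (ga, gb):
            truth.members[g] = "CIN"
            truth.domain_intervals[g] = dom
        truth.duplicate_pairs.append(DuplicatePairTruth(
            ga, gb, "segmental", 0.0, None, False, target_identity=ident
        ))
        low_ids.append((ga, gb))

    for i in range(spec.n_background):
        gid = f"bg{i + 1:03d}"
        prot = _rand_aa(rng, int(rng.integers(100, 300)))
        entries.append({"gene_id": gid, "cds": _back_translate("M" + prot, rng)})
        truth.background.append(gid)

    # --- placement -------------------------------------------------------
    by_id = {e["gene_id"]: e for e in entries}
    occupied: dict[int, list[tuple[int, int]]] = {c: [] for c in range(n_chromosomes)}
    margin = spec.min_gene_spacing
    L = spec.chromosome_length
    placement: dict[str, tuple[int, int]] = {}   # gene -> (chrom idx, start)

    for (ga, gb), sep in tandem_ids:
        glen_a = len(by_id[ga]["cds"])
        glen_b = len(by_id[gb]["cds"])
        chrom = int(rng.integers(0, n_chromosomes))
        lo, hi = margin + 1, L - sep - glen_b - margin
        if hi <= lo:
            raise SpecError(f"tandem separation {sep} does not fit")
        for _ in range(2000):
            s = int(rng.integers(lo, hi))
            iv_a = (s, s + glen_a - 1)
            iv_b = (s + sep, s + sep + glen_b - 1)
            occ = occupied[chrom]
            if all(iv[1] + margin < s2 or iv[0] - margin > e2
                   for iv in (iv_a, iv_b) for s2, e2 in occ):
                occ.extend([iv_a, iv_b])
                placement[ga] = (chrom, iv_a[0])
                placement[gb] = (chrom, iv_b[0])
                break
        else:
            raise SpecError("could not place tandem pair")

    for ga, gb in segmental_ids + low_ids:
        ca = int(rng.integers(0, n_chromosomes))
        cb = int(rng.integers(0, n_chromosomes - 1))
        if cb >= ca:
            cb += 1
        placement[ga] = (ca, _place_interval(
            occupied[ca], L, len(by_id[ga]["cds"]), margin, rng))
        placement[gb] = (cb, _place_interval(
            occupied[cb], L, len(by_id[gb]["cds"]), margin, rng))

    for e in entries:
        gid = e["gene_id"]
        if gid in placement:
            continue
        chrom = int(rng.integers(0, n_chromosomes))
        placement[gid] = (chrom, _place_interval(
            occupied[chrom], L, len(e["cds"]), margin, rng))

    # --- assemble chromosomes -------------------------------------------
    base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    chrom_seqs = [
        bytearray(base_lut[rng.integers(0, 4, L)].tobytes())
        for _ in range(n_chromosomes)
    ]
    genes: list[GeneModel] = []
    proteins: list[SequenceRecord] = []
    cds_records: list[SequenceRecord] = []
    for e in entries:
        gid = e["gene_id"]
        cds = e["cds"]
        chrom, start = placement[gid]
        strand = "+" if rng.random() < 0.5 else "-"
        end = start + len(cds) - 1
        genomic = cds if strand == "+" else reverse_complement(cds)
        chrom_seqs[chrom][start - 1:end] = genomic.encode()
        genes.append(GeneModel(
            gene_id=gid, chromosome=f"chr{chrom + 1}", strand=strand,
            start=start, end=end, cds_parts=((start, end),),
            coding_complete=True,
        ))
        proteins.append(SequenceRecord(gid, _translate_cds(cds)))
        cds_records.append(SequenceRecord(gid, cds))

    genome = [
        SequenceRecord(f"chr{c + 1}", chrom_seqs[c].decode())
        for c in range(n_chromosomes)
    ]
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return SyntheticFamily(genome, genes, proteins, cds_records, truth)


# ---------------------------------------------------------------------------
# promoter planting
# ---------------------------------------------------------------------------

def _promoter_coords(gene: GeneModel, chrom_len: int, length_bp: int
                     ) -> tuple[int, int]:
    start, end, truncated = promoter_genomic_window(gene, length_bp)
    if truncated or end > chrom_len:
        raise PlanError(
            f"gene {gene.gene_id}: promoter window does not fit the chromosome"
        )
    return start, end

def _read_promoter(chrom: bytearray, gene: GeneModel, length_bp: int) -> str:
    s, e = _promoter_coords(gene, len(chrom), length_bp)
    seq = chrom[s - 1:e].decode()
    return reverse_complement(seq) if gene.strand == "-" else seq


def _write_promoter(chrom: bytearray, gene: GeneModel, length_bp: int,
                    promoter: str) -> None:
    s, e = _promoter_coords(gene, len(chrom), length_bp)
    if gene.strand == "-":
        promoter = reverse_complement(promoter)
    chrom[s - 1:e] = promoter.encode()


def _realize_iupac(consensus: str, rng: np.random.Generator) -> str:
    out = []
    for ch in consensus.upper():
        opts = ambiguous_dna_values[ch]
        out.append(opts[int(rng.integers(0, len(opts)))])
    return "".join(out)


def plant_promoter_elements(genome: Sequence[SequenceRecord],
                            genes: Iterable[GeneModel],
                            motifs: MotifTable,
                            plan: Sequence[tuple[str, str, int, str]],
                            seed: int,
                            promoter_length: int = 1500,
                            max_rescan_rounds: int = 50
                            ) -> tuple[list[SequenceRecord], list[PlantedElement]]:
    """Substitute motif occurrences into promoters; truth is exact.

    ``plan`` entries are (gene_id, element_name, offset, strand) with the
    offset 1-based inside the promoter window. Planted motifs replace
    bases. After planting, all listed genes' promoters are re-scanned and
    any accidental match of a table motif outside the planted set has its
    free bases re-drawn, so a subsequent scan recovers exactly the planted
    occurrences (given-strand policy).
    """
    rng = np.random.default_rng(seed)
    gene_list = list(genes)
    models = {g.gene_id: g for g in gene_list}
    chrom = {r.id: bytearray(r.residues, "ascii") for r in genome}

    planted_iv: dict[str, list[tuple[int, int]]] = {}
    realized: list[tuple[str, str, int, str, str]] = []
    for gene_id, element, offset, strand in plan:
        if gene_id not in models:
            raise PlanError(f"plan references unknown gene {gene_id!r}")
        motif = motifs[element]
        k = len(motif.consensus)
        if not 1 <= offset <= promoter_length - k + 1:
            raise PlanError(
                f"{gene_id}/{element}: offset {offset} outside the "
                f"{promoter_length} bp promoter window"
            )
        iv = (offset, offset + k - 1)
        for s2, e2 in planted_iv.get(gene_id, []):
            if iv[0] <= e2 and s2 <= iv[1]:
                raise PlanError(
                    f"{gene_id}: planted elements overlap at offsets "
                    f"{s2}-{e2} and {iv[0]}-{iv[1]}"
                )
        planted_iv.setdefault(gene_id, []).append(iv)
        realized.append((gene_id, element, offset, strand,
                         _realize_iupac(motif.consensus, rng)))

    for gene_id, element, offset, strand, concrete in realized:
        gene = models[gene_id]
        prom = list(_read_promoter(chrom[gene.chromosome], gene, promoter_length))
        ins = concrete if strand == "+" else reverse_complement(concrete)
        prom[offset - 1:offset - 1 + len(ins)] = ins
        _write_promoter(chrom[gene.chromosome], gene, promoter_length,
                        "".join(prom))

    expected = {
        (g, el, off) for g, el, off, strand, _ in realized if strand == "+"
    }
    scannable = [
        g for g in gene_list
        if not promoter_genomic_window(g, promoter_length)[2]
        and promoter_genomic_window(g, promoter_length)[1]
        <= len(chrom[g.chromosome])
    ]
    for _ in range(max_rescan_rounds):
        proms = {
            g.gene_id: SequenceRecord(
                g.gene_id, _read_promoter(chrom[g.chromosome], g, promoter_length))
            for g in scannable
        }
        bad = [
            h for h in scan_cis_elements(proms, motifs, "given_only")
            if (h.gene_id, h.element_name, h.offset) not in expected
        ]
        if not bad:
            break
        for h in bad:
            gene = models[h.gene_id]
            k = len(motifs[h.element_name].consensus)
            protected = planted_iv.get(h.gene_id, [])
            prom = list(_read_promoter(chrom[gene.chromosome], gene,
                                       promoter_length))
            free = [
                p for p in range(h.offset, h.offset + k)
                if not any(s <= p <= e for s, e in protected)
            ]
            for p in free:
                prom[p - 1] = _BASES[int(rng.integers(0, 4))]
            _write_promoter(chrom[gene.chromosome], gene, promoter_length,
                            "".join(prom))
    else:
        raise PlanError(
            "could not scrub accidental motif matches from promoters"
        )

    new_genome = [
        SequenceRecord(r.id, chrom[r.id].decode(), r.description)
        for r in genome
    ]
    truth = [PlantedElement(g, el, off, strand)
             for g, el, off, strand, _ in realized]
    return new_genome, truth


def random_promoter_plan(gene_ids: Sequence[str],
                         element_counts: Mapping[str, int],
                         motifs: MotifTable,
                         rng: np.random.Generator,
                         promoter_length: int = 1500
                         ) -> list[tuple[str, str, int, str]]:
    """Distribute the requested number of occurrences of each element over
    random genes and offsets, avoiding overlaps between planted motifs."""
    plan: list[tuple[str, str, int, str]] = []
    iv_by_gene: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}
    for element in sorted(element_counts):
        k = len(motifs[element].consensus)
        for _ in range(element_counts[element]):
            for _attempt in range(2000):
                g = gene_ids[int(rng.integers(0, len(gene_ids)))]
                off = int(rng.integers(1, promoter_length - k + 2))
                iv = (off, off + k - 1)
                if all(iv[1] < s or iv[0] > e for s, e in iv_by_gene[g]):
                    iv_by_gene[g].append(iv)
                    plan.append((g, element, off, "+"))
                    break
            else:
                raise PlanError(
                    f"could not place {element} occurrences without overlap"
                )
    return plan


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def generate_ct_table(design: Mapping[str, Mapping[str, float]],
                      reference_gene: str,
                      calibrator_sample: str,
                      noise_sd: float,
                      replicates: int = 3,
                      seed: int = 0,
                      target_baseline_ct: float = 24.0,
                      reference_ct: float = 20.0
                      ) -> tuple[CtTable, dict[tuple[str, str], float]]:
    """Replicated Ct table with known fold changes.

    ``design[sample][gene]`` is the true abundance fold; Ct values are
    baseline - log2(fold) + N(0, noise_sd) per replicate and the reference
    gene is fixed at fold 1 in every sample. The returned truth maps
    (sample, gene) to the fold relative to the calibrator sample.
    """
    if calibrator_sample not in design:
        raise DesignError(
            f"calibrator sample {calibrator_sample!r} not in the design"
        )
    if replicates < 2:
        raise DesignError("need at least 2 replicates")
    if noise_sd < 0:
        raise DesignError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[tuple[str, str], float] = {}
    for sample in design:
        genes = design[sample]
        for rep in range(1, replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({"sample": sample, "gene": reference_gene,
                         "replicate": rep, "ct": reference_ct + noise})
        for gene, fold in genes.items():
            if fold <= 0:
                raise DesignError(f"fold for {gene!r} must be positive")
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append({
                    "sample": sample, "gene": gene, "replicate": rep,
                    "ct": target_baseline_ct - np.log2(fold) + noise,
                })
            truth[(sample, gene)] = fold / design[calibrator_sample][gene]
    tbl = CtTable(pd.DataFrame(rows), reference_gene, calibrator_sample)
    return tbl, truth


# ---------------------------------------------------------------------------
# random additive trees (NJ consistency harness)
# ---------------------------------------------------------------------------

def random_additive_tree(n_leaves: int, rng: np.random.Generator,
                         edge_length_range: tuple[float, float] = (0.1, 2.0)
                         ) -> tuple[PhyloTree, DistanceMatrix]:
    """Random binary topology with uniform edge lengths and its exact
    patristic distance matrix."""
    if n_leaves < 3:
        raise ParameterError("need at least 3 leaves")
    lo, hi = edge_length_range
    nodes = [TreeNode(name=f"t{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        a.length = float(rng.uniform(lo, hi))
        b.length = float(rng.uniform(lo, hi))
        nodes.append(TreeNode(children=[a, b]))
    a, b = nodes
    a.length = float(rng.uniform(lo, hi))
    b.length = float(rng.uniform(lo, hi))
    tree = PhyloTree(TreeNode(children=[a, b]))
    return tree, leaf_path_distances(tree)
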