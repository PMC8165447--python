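"""Family-member identification by conserved-domain scanning, subfamily
classification and physicochemical profiling.

The scan replaces a heuristic database search with exact Smith-Waterman
local alignment against a single domain reference: databases at this scale
are small and exactness gives a testable contract. Significance uses the
Karlin-Altschul form E = kappa * m * n * exp(-lambda * s) with configured
lambda/kappa constants (defaults are the classic ungapped BLOSUM62 values).

Subfamilies follow the standard Class I / Class II split of plant
TCP-like families: Class I (PCF) members lack four residues in the basic
region of the domain, and within Class II the CYC-type members carry a
hydrophilic, polar-rich R domain C-terminal of the main domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

from famscan._align import (
    AlignmentError,
    align_global,
    align_local,
)
from famscan.io import SequenceRecord, parse_fasta

__all__ = [
    "ScanConfig", "DomainHit", "SubfamilyCall", "PhysicochemicalProfile",
    "RDomainConfig", "smith_waterman", "scan_for_domain",
    "classify_subfamily", "physicochemical_profile", "net_charge",
    "default_domain_reference", "default_class_references",
    "KYTE_DOOLITTLE", "AVERAGE_RESIDUE_MASS", "PKA_TABLE", "POLAR_RESIDUES",
]


class ClassificationError(ValueError):
    """Domain region unusable for subfamily typing."""


class ProfileError(ValueError):
    """Sequence unusable for physicochemical profiling."""


def default_domain_reference() -> SequenceRecord:
    """The shipped Class II domain reference used as the scan query."""
    path = resources.files("famscan.data") / "domain_class2.faa"
    return parse_fasta(str(path), "protein")[0]


def default_class_references() -> tuple[SequenceRecord, SequenceRecord]:
    """(class1_ref, class2_ref) domain references for subfamily typing."""
    d1 = resources.files("famscan.data") / "domain_class1.faa"
    d2 = resources.files("famscan.data") / "domain_class2.faa"
    return parse_fasta(str(d1), "protein")[0], parse_fasta(str(d2), "protein")[0]


@dataclass
class ScanConfig:
    """Parameters of the domain scan.

    ``e_threshold`` defaults to 0.001; accepted hits must also span a
    domain-sized region, 55-60 aa widened by +/-20% to tolerate alignment
    fraying at the domain edges.
    """

    domain_reference: SequenceRecord = field(default_factory=default_domain_reference)
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_kappa: float = 0.041
    e_threshold: float = 0.001
    min_domain_len: int = 55
    max_domain_len: int = 60

    def __post_init__(self) -> None:
        if self.e_threshold <= 0:
            raise ValueError("e_threshold must be positive")
        if self.min_domain_len > self.max_domain_len:
            raise ValueError("min_domain_len > max_domain_len")


@dataclass(frozen=True)
class DomainHit:
    """An accepted local-alignment hit of the domain on one protein."""

    protein_id: str
    hit_start: int          # 1-based inclusive, on the protein
    hit_end: int
    raw_score: float
    e_value: float
    aligned_domain_fraction: float

    def __post_init__(self) -> None:
        if self.hit_start > self.hit_end:
            raise ValueError("hit_start > hit_end")
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")


@dataclass(frozen=True)
class SubfamilyCall:
    protein_id: str
    class_label: str        # PCF | CIN | CYC
    basic_region_gap: bool
    r_domain_found: bool
    r_domain_interval: tuple[int, int] | None = None


@dataclass(frozen=True)
class PhysicochemicalProfile:
    length_aa: int
    molecular_weight_kda: float
    isoelectric_point: float
    gravy: float


@dataclass
class RDomainConfig:
    window_len: int = 20
    polar_fraction_threshold: float = 0.6


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def smith_waterman(query: SequenceRecord, subject: SequenceRecord,
                   cfg: ScanConfig):
    """Exact local alignment of query vs subject under the scan config.

    Returns the :class:`famscan._align.LocalAlignment`; coordinates
    ``a_*`` index the query, ``b_*`` the subject (1-based inclusive).
    """
    aln, _, _ = align_local(
        query.residues, subject.residues,
        cfg.substitution_matrix, cfg.gap_open, cfg.gap_extend,
    )
    return aln


def karlin_altschul_evalue(score: float, m: int, n: int, cfg: ScanConfig) -> float:
    return cfg.karlin_kappa * m * n * math.exp(-cfg.karlin_lambda * score)


def scan_for_domain(proteins: list[SequenceRecord], cfg: ScanConfig
                    ) -> list[DomainHit]:
    """Scan proteins with the domain reference; return accepted hits only.

    E-values use m = domain length and n = total residues in the scanned
    set; acceptance requires E <= threshold and a domain-sized hit region.
    Hits are sorted by ascending E (ties by protein id).
    """
    if not proteins:
        return []
    domain = cfg.domain_reference
    m = len(domain)
    n_db = sum(len(p) for p in proteins)
    lo = 0.8 * cfg.min_domain_len
    hi = 1.2 * cfg.max_domain_len
    hits: list[DomainHit] = []
    for prot in proteins:
        aln = smith_waterman(domain, prot, cfg)
        if aln.is_empty:
            continue
        e = karlin_altschul_evalue(aln.score, m, n_db, cfg)
        span = aln.b_end - aln.b_start + 1
        if e <= cfg.e_threshold and lo <= span <= hi:
            hits.append(DomainHit(
                protein_id=prot.id,
                hit_start=aln.b_start, hit_end=aln.b_end,
                raw_score=aln.score,
                e_value=max(e, 5e-324),
                aligned_domain_fraction=(aln.a_end - aln.a_start + 1) / m,
            ))
    hits.sort(key=lambda h: (h.e_value, h.protein_id))
    return hits


# ---------------------------------------------------------------------------
# subfamily classification
# ---------------------------------------------------------------------------

POLAR_RESIDUES = frozenset("STNQKRHDE")


def _basic_region_gap(region: str, class2_ref: str, matrix: str,
                      gap_open: float, gap_extend: float) -> bool:
    """True when the region-vs-ClassII alignment opens a 3-5 residue gap in
    the region row inside the first (basic) quarter of the reference."""
    _, row_region, row_ref = align_global(
        region, class2_ref, matrix, gap_open, gap_extend
    )
    quarter = math.ceil(len(class2_ref) / 4)
    ref_pos = 0
    run_len = 0
    run_ref_start = 0
    for cr, cf in zip(row_region, row_ref):
        if cf != "-":
            ref_pos += 1
        if cr == "-" and cf != "-":
            if run_len == 0:
                run_ref_start = ref_pos
            run_len += 1
        else:
            if 3 <= run_len <= 5 and run_ref_start <= quarter:
                return True
            run_len = 0
    return 3 <= run_len <= 5 and run_ref_start <= quarter


def classify_subfamily(hit: DomainHit, protein: SequenceRecord,
                       class1_ref: SequenceRecord,
                       class2_ref: SequenceRecord,
                       r_cfg: RDomainConfig | None = None,
                       matrix: str = "BLOSUM62",
                       gap_open: float = 11.0,
                       gap_extend: float = 1.0) -> SubfamilyCall:
    """Assign PCF / CIN / CYC from the domain hit region.

    Class I (PCF) is called when the alignment to the Class II reference
    opens a 3-5 residue deletion in the basic quarter of the domain, or when
    the Class I reference scores strictly higher. Within Class II, CYC is
    called when a 20-aa window C-terminal of the domain is polar-rich.
    """
    r_cfg = r_cfg or RDomainConfig()
    region = protein.residues[hit.hit_start - 1:hit.hit_end]
    if len(region) < 20:
        raise ClassificationError(
            f"{protein.id}: domain region of {len(region)} aa is too short to type"
        )
    s1, _, _ = align_global(region, class1_ref.residues, matrix, gap_open, gap_extend)
    s2, _, _ = align_global(region, class2_ref.residues, matrix, gap_open, gap_extend)
    gap_evidence = _basic_region_gap(
        region, class2_ref.residues, matrix, gap_open, gap_extend
    )
    if gap_evidence or s1 > s2:
        return SubfamilyCall(
            protein_id=protein.id, class_label="PCF",
            basic_region_gap=gap_evidence, r_domain_found=False,
        )
    tail = protein.residues[hit.hit_end:]
    w = r_cfg.window_len
    for i in range(0, len(tail) - w + 1):
        window = tail[i:i + w]
        frac = sum(c in POLAR_RESIDUES for c in window) / w
        if frac >= r_cfg.polar_fraction_threshold:
            start = hit.hit_end + i + 1
            return SubfamilyCall(
                protein_id=protein.id, class_label="CYC",
                basic_region_gap=False, r_domain_found=True,
                r_domain_interval=(start, start + w - 1),
            )
    return SubfamilyCall(
        protein_id=protein.id, class_label="CIN",
        basic_region_gap=False, r_domain_found=False,
    )


# ---------------------------------------------------------------------------
# physicochemical profile
# ---------------------------------------------------------------------------

# Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# average residue masses (Da); one water is added per chain
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# side-chain and terminal pKa values
PKA_TABLE = {
    "N_term": 9.6, "C_term": 2.34,
    "K": 10.53, "R": 12.48, "H": 6.0,
    "D": 3.65, "E": 4.25, "C": 8.33, "Y": 10.07,
}
_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")


def net_charge(residues: str, ph: float, pka: dict | None = None) -> float:
    """Net protein charge at a given pH (Henderson-Hasselbalch per group),
    including both termini. Strictly decreasing in pH."""
    pka = pka or PKA_TABLE
    q = 1.0 / (1.0 + 10 ** (ph - pka["N_term"]))
    q -= 1.0 / (1.0 + 10 ** (pka["C_term"] - ph))
    for aa in _BASIC:
        n = residues.count(aa)
        if n:
            q += n / (1.0 + 10 ** (ph - pka[aa]))
    for aa in _ACIDIC:
        n = residues.count(aa)
        if n:
            q -= n / (1.0 + 10 ** (pka[aa] - ph))
    return q


def physicochemical_profile(protein: SequenceRecord,
                            pka_table: dict | None = None,
                            hydropathy_table: dict | None = None,
                            mass_table: dict | None = None
                            ) -> PhysicochemicalProfile:
    """Length, molecular weight (kDa), isoelectric point and GRAVY.

    The pI is located by bisection on the net-charge curve over pH (0, 14)
    to |Q| < 1e-4; the curve is strictly decreasing so the root is unique.
    """
    seq = protein.residues
    if not seq:
        raise ProfileError("empty sequence")
    hydro = hydropathy_table or KYTE_DOOLITTLE
    masses = mass_table or AVERAGE_RESIDUE_MASS
    pka = pka_table or PKA_TABLE
    bad = set(seq) - set(masses)
    if bad:
        raise ProfileError(
            f"{protein.id}: nonstandard residue(s) {sorted(bad)} not profiled"
        )
    mw = (sum(masses[c] for c in seq) + WATER_MASS) / 1000.0
    gravy = sum(hydro[c] for c in seq) / len(seq)

    # bisect to a 1e-6 pH interval; |Q| at the returned point is far below
    # the 1e-4 target even where the charge curve is nearly flat
    lo, hi = 0.0, 14.0
    mid = 7.0
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return PhysicochemicalProfile(
        length_aa=len(seq),
        molecular_weight_kda=mw,
        isoelectric_point=mid,
        gravy=gravy,
    )
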