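"""Duplication-event typing and Nei-Gojobori (1986) Ka/Ks machinery.

Site counting assigns each codon position the fraction of its three
single-nucleotide changes that are synonymous; stop-creating changes count
as nonsynonymous. Differences between codons are averaged over all k!
substitution orderings, discarding pathways that pass through a stop codon
(falling back to all pathways, stop steps counted nonsynonymous, when every
pathway is blocked). Proportions are Jukes-Cantor corrected, and
Ka/Ks = 1 discriminates positive from purifying selection. An undefined
ratio (Ks = 0 or an out-of-range correction) is a first-class sentinel
(None), never 0 or infinity.

Duplicate candidates are sister-leaf pairs of the family tree retained at
>80% global-alignment identity; a retained pair on one chromosome within
200 kb (start-to-start) is tandem, a cross-chromosome pair is segmental.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Mapping

from Bio.Data import CodonTable
from Bio.Seq import Seq

from famscan._align import align_global
from famscan.io import FormatError, GeneModel, PhyloTree, SequenceRecord, TreeNode

__all__ = [
    "CodonAlignment", "KaKsResult", "WindowConfig", "DuplicationEvent",
    "ng86_count_sites", "ng86_count_differences", "kaks_pair",
    "sliding_window_kaks", "map_protein_alignment_to_codons",
    "classify_duplications", "sister_leaf_pairs", "alignment_identity_pct",
    "SENSE_CODONS", "translate_codon",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_BASES = "ACGT"


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon; None for a stop codon."""
    return _TABLE.forward_table.get(codon)


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def ng86_count_sites(codon: str) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) of one sense codon.

    s + n = 3 exactly; stop-creating changes count as nonsynonymous.
    """
    if codon in STOP_CODONS or codon not in _TABLE.forward_table:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = _TABLE.forward_table[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if _TABLE.forward_table.get(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=4096)
def ng86_count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all substitution pathways; sd + nd equals the Hamming
    distance of the codons."""
    for c in (codon_a, codon_b):
        if c not in _TABLE.forward_table:
            raise ValueError(f"not a sense codon: {c!r}")
    diff_pos = [p for p in range(3) if codon_a[p] != codon_b[p]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0

    def path_counts(order: tuple[int, ...], allow_stops: bool
                    ) -> tuple[float, float] | None:
        cur = codon_a
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                if not allow_stops:
                    return None
                nd += 1.0
            elif _TABLE.forward_table[cur] == _TABLE.forward_table[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    valid = [r for order in permutations(diff_pos)
             if (r := path_counts(order, allow_stops=False)) is not None]
    if not valid:
        valid = [path_counts(order, allow_stops=True)
                 for order in permutations(diff_pos)]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------

_GAP_CODON = "---"


@dataclass(frozen=True)
class CodonAlignment:
    """Two gapped CDS rows; gaps occur only as whole aligned codon triplets
    and neither de-gapped frame contains an internal stop."""

    row_a: str
    row_b: str
    id_a: str = "a"
    id_b: str = "b"

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise FormatError("codon alignment rows differ in length")
        if len(self.row_a) % 3 != 0:
            raise FormatError("codon alignment length is not a multiple of 3")
        for rid, row in ((self.id_a, self.row_a), (self.id_b, self.row_b)):
            for i in range(0, len(row), 3):
                tri = row[i:i + 3]
                if "-" in tri and tri != _GAP_CODON:
                    raise FormatError(
                        f"row {rid}: gap not aligned to a whole codon at "
                        f"column {i + 1}"
                    )
            degapped = row.replace("-", "")
            for ci in range(0, len(degapped), 3):
                if degapped[ci:ci + 3] in STOP_CODONS:
                    raise FormatError(
                        f"row {rid}: internal stop codon at codon "
                        f"{ci // 3 + 1}"
                    )

    @property
    def n_columns(self) -> int:
        return len(self.row_a)

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Comparable (gap-free in both rows) codon pairs, in order."""
        out = []
        for i in range(0, len(self.row_a), 3):
            ca, cb = self.row_a[i:i + 3], self.row_b[i:i + 3]
            if "-" not in ca and "-" not in cb:
                out.append((ca, cb))
        return out

    def window(self, start_nt: int, end_nt: int) -> "CodonAlignment":
        """Sub-alignment over 1-based inclusive column range."""
        return CodonAlignment(
            self.row_a[start_nt - 1:end_nt],
            self.row_b[start_nt - 1:end_nt],
            self.id_a, self.id_b,
        )


@dataclass(frozen=True)
class KaKsResult:
    s_sites: float            # S: synonymous sites
    n_sites: float            # N: nonsynonymous sites
    sd: float                 # synonymous differences
    nd: float                 # nonsynonymous differences
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    ratio: float | None
    selection_call: str       # positive | purifying | neutral | undefined
    n_codons: int


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * __import__("math").log(1.0 - 4.0 * p / 3.0)


_CALL_TOL = 1e-9


def kaks_pair(aln: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks for one codon alignment (whole gene or window)."""
    pairs = aln.codon_pairs()
    if not pairs:
        raise FormatError("no comparable codon columns")
    s_a = s_b = sd = nd = 0.0
    for ca, cb in pairs:
        sa, _ = ng86_count_sites(ca)
        sb, _ = ng86_count_sites(cb)
        s_a += sa
        s_b += sb
        d_s, d_n = ng86_count_differences(ca, cb)
        sd += d_s
        nd += d_n
    n_codons = len(pairs)
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_codons - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    if ks is None or ka is None or ks == 0.0:
        ratio = None
    else:
        ratio = ka / ks
    if ratio is None:
        call = "undefined"
    elif ratio > 1.0 + _CALL_TOL:
        call = "positive"
    elif ratio < 1.0 - _CALL_TOL:
        call = "purifying"
    else:
        call = "neutral"
    return KaKsResult(
        s_sites=S, n_sites=N, sd=sd, nd=nd, ps=ps, pn=pn,
        ks=ks, ka=ka, ratio=ratio, selection_call=call, n_codons=n_codons,
    )


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: 150 nt windows stepping 9 nt by default."""

    window_nt: int = 150
    step_nt: int = 9

    def __post_init__(self) -> None:
        for name, v in (("window_nt", self.window_nt), ("step_nt", self.step_nt)):
            if v <= 0 or v % 3 != 0:
                raise ValueError(f"{name} must be a positive multiple of 3")


def sliding_window_kaks(aln: CodonAlignment, cfg: WindowConfig | None = None
                        ) -> list[tuple[int, int, KaKsResult]]:
    """Ka/Ks per overlapping window; (start, end) are 1-based inclusive.

    Windows start at 1, 1+step, ... while they fit inside the alignment;
    windows with Ks = 0 carry an undefined ratio (gaps in a plot, not 0)."""
    cfg = cfg or WindowConfig()
    L = aln.n_columns
    if cfg.window_nt > L:
        raise FormatError(
            f"window {cfg.window_nt} exceeds alignment length {L}"
        )
    out = []
    start = 1
    while start + cfg.window_nt - 1 <= L:
        end = start + cfg.window_nt - 1
        out.append((start, end, kaks_pair(aln.window(start, end))))
        start += cfg.step_nt
    return out


# ---------------------------------------------------------------------------
# protein alignment -> codon alignment
# ---------------------------------------------------------------------------

def _check_cds(protein: str, cds: str, name: str) -> str:
    """Validate a CDS against its de-gapped protein row; returns the CDS
    trimmed of a trailing stop codon if present."""
    if len(cds) == 3 * len(protein) + 3 and cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    if len(cds) != 3 * len(protein):
        raise FormatError(
            f"{name}: CDS length {len(cds)} does not match protein "
            f"({3 * len(protein)} nt expected)"
        )
    observed = str(Seq(cds).translate())
    star = observed.find("*")
    if star != -1:
        raise FormatError(f"{name}: internal stop at codon {star + 1}")
    if observed != protein:
        mism = next(i for i, (x, y) in enumerate(zip(observed, protein)) if x != y)
        raise FormatError(
            f"{name}: CDS translation mismatches protein at residue {mism + 1}"
        )
    return cds


def map_protein_alignment_to_codons(row_a: str, row_b: str,
                                    cds_a: SequenceRecord,
                                    cds_b: SequenceRecord) -> CodonAlignment:
    """Back-translate an aligned protein pair onto its CDS pair.

    Each residue column becomes its source codon and each protein gap a
    3-nt gap; a trailing stop codon on either CDS is trimmed."""
    if len(row_a) != len(row_b):
        raise FormatError("protein alignment rows differ in length")
    a = _check_cds(row_a.replace("-", ""), cds_a.residues.upper(), cds_a.id)
    b = _check_cds(row_b.replace("-", ""), cds_b.residues.upper(), cds_b.id)
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for ra, rb in zip(row_a, row_b):
        if ra == "-":
            out_a.append(_GAP_CODON)
        else:
            out_a.append(a[3 * ia:3 * ia + 3])
            ia += 1
        if rb == "-":
            out_b.append(_GAP_CODON)
        else:
            out_b.append(b[3 * ib:3 * ib + 3])
            ib += 1
    return CodonAlignment("".join(out_a), "".join(out_b), cds_a.id, cds_b.id)


# ---------------------------------------------------------------------------
# duplication events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicationEvent:
    gene_a: str
    gene_b: str
    identity_pct: float
    same_clade: bool
    chromosomal_relation: str       # same_chromosome | different_chromosome | unplaced
    separation_bp: int | None
    dup_type: str                   # tandem | segmental | unclassified
    kaks: KaKsResult


def sister_leaf_pairs(tree: PhyloTree) -> list[tuple[str, str]]:
    """Leaf pairs sharing an immediate parent (the strictest reading of
    'located in the same branch')."""
    pairs: list[tuple[str, str]] = []
    for node in tree.root.walk():
        leaf_children = sorted(
            (c.name or "" for c in node.children if c.is_leaf)
        )
        pairs.extend(combinations(leaf_children, 2))
    return pairs


def alignment_identity_pct(row_a: str, row_b: str) -> float:
    """Percent identical columns over all alignment columns (gaps count as
    mismatches)."""
    n = len(row_a)
    if n == 0:
        return 0.0
    same = sum(a == b and a != "-" for a, b in zip(row_a, row_b))
    return 100.0 * same / n


def classify_duplications(models: Mapping[str, GeneModel],
                          proteins: Mapping[str, SequenceRecord],
                          cds: Mapping[str, SequenceRecord],
                          tree: PhyloTree,
                          identity_threshold_pct: float = 80.0,
                          tandem_max_separation_bp: int = 200_000,
                          matrix: str = "BLOSUM62",
                          gap_open: float = 11.0,
                          gap_extend: float = 1.0) -> list[DuplicationEvent]:
    """Type duplicate gene pairs from the family tree and coordinates.

    Candidates are sister-leaf pairs; pairs are retained above the identity
    threshold and typed tandem (same chromosome, close), segmental
    (different chromosomes), or unclassified (same chromosome but distant,
    or either gene unplaced). Each retained pair carries its NG86 result.
    """
    events: list[DuplicationEvent] = []
    for ga, gb in sister_leaf_pairs(tree):
        for g in (ga, gb):
            if g not in models:
                raise KeyError(f"tree leaf {g!r} has no gene model")
            if g not in proteins or g not in cds:
                raise KeyError(f"tree leaf {g!r} has no sequence record")
        _, row_a, row_b = align_global(
            proteins[ga].residues, proteins[gb].residues,
            matrix, gap_open, gap_extend,
        )
        identity = alignment_identity_pct(row_a, row_b)
        if identity <= identity_threshold_pct:
            continue
        ma, mb = models[ga], models[gb]
        separation: int | None = None
        if not (ma.is_placed and mb.is_placed):
            relation, dup_type = "unplaced", "unclassified"
        elif ma.chromosome == mb.chromosome:
            relation = "same_chromosome"
            separation = abs(ma.start - mb.start)
            dup_type = ("tandem" if separation <= tandem_max_separation_bp
                        else "unclassified")
        else:
            relation, dup_type = "different_chromosome", "segmental"
        codon_aln = map_protein_alignment_to_codons(
            row_a, row_b, cds[ga], cds[gb]
        )
        events.append(DuplicationEvent(
            gene_a=ga, gene_b=gb, identity_pct=identity, same_clade=True,
            chromosomal_relation=relation, separation_bp=separation,
            dup_type=dup_type, kaks=kaks_pair(codon_aln),
        ))
    return events
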