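"""Strand-aware promoter extraction and cis-element census.

Promoters are the 1,500-2,000 bp immediately upstream of the translation
start (the first CDS base), returned 5'->3' on the gene's coding
orientation. Element scanning matches IUPAC consensus strings exactly at
every position (overlaps included); the default policy scans the given
strand only because palindrome-partner motifs (e.g. CGTCA / TGACG) are
separate table entries and both-strand scanning would double-count them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from famscan.io import (
    FormatError,
    GeneModel,
    SequenceRecord,
    read_tsv,
    reverse_complement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Motif", "MotifTable", "CisElementHit", "load_motif_table",
    "default_motif_table", "extract_promoters", "scan_cis_elements",
    "census_by_category", "CATEGORIES",
]

CATEGORIES = ("growth_development", "stress", "hormone")


@dataclass(frozen=True)
class Motif:
    element_name: str
    consensus: str
    category: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise FormatError(f"motif {self.element_name}: empty consensus")
        bad = set(self.consensus.upper()) - set(ambiguous_dna_values)
        if bad:
            raise FormatError(
                f"motif {self.element_name}: invalid IUPAC code(s) {sorted(bad)}"
            )
        if self.category not in CATEGORIES:
            raise FormatError(
                f"motif {self.element_name}: unknown category {self.category!r}"
            )

    def regex(self) -> re.Pattern:
        parts = []
        for ch in self.consensus.upper():
            opts = ambiguous_dna_values[ch]
            parts.append(opts if len(opts) == 1 else f"[{opts}]")
        # lookahead so overlapping matches are all reported
        return re.compile(f"(?=({''.join(parts)}))")


@dataclass
class MotifTable:
    entries: list[Motif]

    def __post_init__(self) -> None:
        names = [m.element_name for m in self.entries]
        if len(names) != len(set(names)):
            raise FormatError("duplicate element names in motif table")

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> Motif:
        for m in self.entries:
            if m.element_name == name:
                return m
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [m.element_name for m in self.entries]


def load_motif_table(path: str | Path) -> MotifTable:
    df = read_tsv(path)
    required = {"element", "consensus_iupac", "category"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"motif table must have columns {sorted(required)}"
        )
    return MotifTable([
        Motif(str(r.element), str(r.consensus_iupac), str(r.category))
        for r in df.itertuples()
    ])


def default_motif_table() -> MotifTable:
    """The shipped PlantCARE-style motif table (editable config)."""
    return load_motif_table(str(resources.files("famscan.data") / "motifs.tsv"))


@dataclass(frozen=True)
class CisElementHit:
    gene_id: str
    element_name: str
    offset: int             # 1-based within the promoter, coding orientation
    strand_of_match: str    # + or -, relative to the promoter string


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def promoter_genomic_window(gene: GeneModel, length_bp: int
                            ) -> tuple[int, int, bool]:
    """(start, end, truncated) genomic window of the promoter, 1-based
    inclusive, before strand orientation. Truncation clips at position 1;
    clipping at the chromosome 3' end is applied by the caller."""
    if not gene.cds_parts:
        raise FormatError(f"gene {gene.gene_id}: no CDS to anchor the promoter")
    if gene.strand == "+":
        anchor = gene.cds_parts[0][0]          # first CDS base
        start = anchor - length_bp
        end = anchor - 1
        truncated = start < 1
        return max(start, 1), end, truncated
    anchor = gene.cds_parts[-1][1]             # genomic end = first coding base
    return anchor + 1, anchor + length_bp, False


def extract_promoters(genome: Mapping[str, SequenceRecord] | Iterable[SequenceRecord],
                      genes: Iterable[GeneModel],
                      length_bp: int = 1500) -> dict[str, SequenceRecord]:
    """Promoter sequence per gene, reading 5'->3' toward the ATG.

    Minus-strand promoters are reverse-complemented. Windows clipped at a
    chromosome edge are flagged 'truncated' in the record description (a
    fully clipped window yields a flagged empty record).
    """
    if not 1500 <= length_bp <= 2000:
        raise ValueError("promoter length must be in [1500, 2000] bp")
    if not isinstance(genome, Mapping):
        genome = {r.id: r for r in genome}
    out: dict[str, SequenceRecord] = {}
    n_truncated = 0
    for gene in genes:
        chrom = genome.get(gene.chromosome)
        if chrom is None:
            raise FormatError(
                f"gene {gene.gene_id}: chromosome {gene.chromosome!r} "
                "not in genome"
            )
        start, end, truncated = promoter_genomic_window(gene, length_bp)
        if end > len(chrom.residues):
            end = len(chrom.residues)
            truncated = True
        seq = chrom.residues[start - 1:end] if start <= end else ""
        if gene.strand == "-":
            seq = reverse_complement(seq)
        if truncated or not seq:
            n_truncated += 1
        desc = "truncated" if truncated else ""
        if not seq:
            desc = "empty"
        out[gene.gene_id] = SequenceRecord(gene.gene_id, seq, desc)
    if n_truncated:
        logger.info("extract_promoters: %d promoter(s) truncated", n_truncated)
    return out


# ---------------------------------------------------------------------------
# scanning & census
# ---------------------------------------------------------------------------

def scan_cis_elements(promoters: Mapping[str, SequenceRecord],
                      motifs: MotifTable,
                      strand_policy: str = "given_only"
                      ) -> list[CisElementHit]:
    """All exact IUPAC-consensus matches in the promoters.

    Offsets are 1-based on the promoter string; with ``strand_policy
    'both'`` the reverse complement is also scanned and hits mapped back to
    promoter coordinates with strand '-'.
    """
    if strand_policy not in ("given_only", "both"):
        raise ValueError(f"unknown strand_policy {strand_policy!r}")
    hits: list[CisElementHit] = []
    for gene_id in sorted(promoters):
        seq = promoters[gene_id].residues.upper()
        if not seq:
            continue
        for motif in motifs:
            pat = motif.regex()
            k = len(motif.consensus)
            for m in pat.finditer(seq):
                hits.append(CisElementHit(
                    gene_id, motif.element_name, m.start() + 1, "+"
                ))
            if strand_policy == "both":
                rc = reverse_complement(seq)
                L = len(seq)
                for m in pat.finditer(rc):
                    offset = L - m.start() - k + 1
                    hits.append(CisElementHit(
                        gene_id, motif.element_name, offset, "-"
                    ))
    return hits


def census_by_category(hits: list[CisElementHit], motifs: MotifTable
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-gene x per-element counts, per-category totals).

    Exact tallies; the category totals are sums of member-element counts
    and the grand total equals ``len(hits)``.
    """
    known = set(motifs.names)
    for h in hits:
        if h.element_name not in known:
            raise FormatError(f"hit references unknown element {h.element_name!r}")
    genes = sorted({h.gene_id for h in hits})
    per_gene = pd.DataFrame(
        0, index=pd.Index(genes, name="gene_id"), columns=motifs.names
    )
    for h in hits:
        per_gene.loc[h.gene_id, h.element_name] += 1
    element_totals = per_gene.sum(axis=0) if genes else pd.Series(
        0, index=motifs.names
    )
    cat_rows = []
    for cat in CATEGORIES:
        members = [m.element_name for m in motifs if m.category == cat]
        cat_rows.append({
            "category": cat,
            "total": int(element_totals[members].sum()) if members else 0,
        })
    return per_gene, pd.DataFrame(cat_rows)
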