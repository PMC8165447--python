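"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates in the public API are 1-based inclusive (the GFF3
convention); any half-open arithmetic is internal to a function. FASTA is
wrapped at 60 columns on write and read tolerantly at any width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

Molecule = Literal["dna", "protein"]


class FormatError(ValueError):
    """An input file or in-memory object violates its format contract."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence (DNA or protein), residues stored uppercase."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


def validate_record(rec: SequenceRecord, molecule: Molecule) -> None:
    if not rec.id:
        raise FormatError("sequence record with empty id")
    if not rec.residues:
        raise FormatError(f"empty sequence for id {rec.id!r}")
    alphabet = DNA_ALPHABET if molecule == "dna" else PROTEIN_ALPHABET
    bad = set(rec.residues) - alphabet
    if bad:
        ch = sorted(bad)[0]
        pos = rec.residues.index(ch) + 1
        raise FormatError(
            f"illegal {molecule} character {ch!r} at position {pos} "
            f"of record {rec.id!r}"
        )


def parse_fasta(path: str | Path, molecule: Molecule) -> list[SequenceRecord]:
    """Read a FASTA file, validating ids and the declared alphabet.

    Residues are uppercased and concatenated across wrapped lines; record
    order is preserved. Duplicate ids, an empty file, or characters outside
    the declared alphabet raise :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out = SequenceRecord(rec.id, residues, desc)
        validate_record(out, molecule)
        records.append(out)
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# gene models / GFF3
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: strand, span and ordered CDS parts.

    ``cds_parts`` are (start, end) pairs, 1-based inclusive, sorted by start
    and non-overlapping regardless of strand. When ``coding_complete`` the
    total CDS length must be a positive multiple of 3.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    cds_parts: tuple[tuple[int, int], ...] = ()
    coding_complete: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        prev_end = 0
        for s, e in self.cds_parts:
            if s > e:
                raise FormatError(f"gene {self.gene_id}: CDS part end {e} < start {s}")
            if s <= prev_end:
                raise FormatError(
                    f"gene {self.gene_id}: CDS parts unsorted or overlapping"
                )
            if s < self.start or e > self.end:
                raise FormatError(
                    f"gene {self.gene_id}: CDS part [{s},{e}] outside gene span"
                )
            prev_end = e
        if self.coding_complete:
            n = self.cds_length
            if n == 0 or n % 3 != 0:
                raise FormatError(
                    f"gene {self.gene_id}: coding-complete CDS length {n} "
                    "is not a positive multiple of 3"
                )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_parts)

    @property
    def is_placed(self) -> bool:
        """True when the gene sits on a named chromosome (``chr*`` token)
        rather than an unplaced scaffold."""
        return self.chromosome.lower().startswith("chr")


_KNOWN_FEATURES = {"gene", "mRNA", "CDS"}


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3, grouping gene features with CDS children.

    CDS features may point at the gene directly or through an mRNA. Unknown
    feature types are ignored with a logged count; a CDS whose Parent chain
    does not reach a gene is a :class:`FormatError`.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    skipped = sum(
        1 for f in db.all_features() if f.featuretype not in _KNOWN_FEATURES
    )
    if skipped:
        logger.info("parse_gff3: ignored %d features of unknown types", skipped)

    for feat in db.all_features():
        if feat.end < feat.start:
            raise FormatError(
                f"feature {feat.id}: end {feat.end} < start {feat.start}"
            )

    for cds in db.features_of_type("CDS"):
        gene_parents = list(db.parents(cds.id, featuretype="gene"))
        if not gene_parents:
            parents = cds.attributes.get("Parent", ["<missing>"])
            raise FormatError(
                f"CDS {cds.id} has no gene ancestor "
                f"(Parent={','.join(parents)})"
            )

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        parts = tuple(sorted(
            (c.start, c.end) for c in db.children(gene.id, featuretype="CDS")
        ))
        total = sum(e - s + 1 for s, e in parts)
        models.append(GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            start=gene.start,
            end=gene.end,
            cds_parts=parts,
            coding_complete=bool(parts) and total % 3 == 0,
        ))
    return models


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append("\t".join([
            g.chromosome, "famscan", "gene", str(g.start), str(g.end),
            ".", g.strand, ".", f"ID={g.gene_id}",
        ]))
        for i, (s, e) in enumerate(g.cds_parts, start=1):
            lines.append("\t".join([
                g.chromosome, "famscan", "CDS", str(s), str(e),
                ".", g.strand, "0",
                f"ID={g.gene_id}.cds{i};Parent={g.gene_id}",
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trees / Newick
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A rooted-tree node; ``length`` is the branch to the parent."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaves(self) -> Iterator["TreeNode"]:
        for n in self.walk():
            if n.is_leaf:
                yield n


@dataclass
class PhyloTree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [n.name or "" for n in self.root.leaves()]

    def validate(self) -> None:
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise FormatError("duplicate leaf labels in tree")
        for n in self.root.walk():
            if n.length < 0:
                raise FormatError("negative branch length in tree")


def serialize_newick(tree: PhyloTree) -> str:
    """Render a tree as Newick with branch lengths to 6 decimals."""
    tree.validate()

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            if not node.name:
                raise FormatError("unlabeled leaf cannot be serialized")
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}){node.name or ''}:{node.length:.6f}"

    root = tree.root
    if root.is_leaf:
        raise FormatError("cannot serialize a single-leaf tree")
    inner = ",".join(fmt(c) for c in root.children)
    return f"({inner}){root.name or ''};"


def parse_newick(text: str) -> PhyloTree:
    dtree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )

    def conv(nd: dendropy.Node) -> TreeNode:
        name = nd.taxon.label if nd.taxon is not None else nd.label
        length = nd.edge.length if nd.edge.length is not None else 0.0
        return TreeNode(
            name=name, length=float(length),
            children=[conv(c) for c in nd.child_nodes()],
        )

    root = conv(dtree.seed_node)
    root.length = 0.0
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())
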