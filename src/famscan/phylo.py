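"""Multiple protein alignment, pairwise distances, and Neighbor-Joining.

The MSA is a deliberately simple progressive aligner: a UPGMA guide tree on
3-mer count distances, then profile-profile Needleman-Wunsch merges with
sum-of-pairs column scoring. Distances use pairwise deletion with either
p-distance (default) or a Poisson correction. NJ is the Saitou-Nei
algorithm with rate-corrected branch lengths, negative lengths clamped to
zero, deterministic tie-breaking by smallest index pair, and an unrooted
trifurcation at the end.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from famscan._align import _matrix_arrays, gotoh_global
from famscan.io import FormatError, PhyloTree, SequenceRecord, TreeNode

__all__ = [
    "Alignment", "DistanceMatrix", "progressive_msa",
    "protein_distance_matrix", "build_nj_tree", "leaf_path_distances",
    "bipartitions",
]


@dataclass
class Alignment:
    """Ordered gapped rows of equal length; de-gapping recovers inputs."""

    rows: list[tuple[str, str]]   # (id, gapped residues)

    def __post_init__(self) -> None:
        if self.rows:
            ncol = len(self.rows[0][1])
            for rid, row in self.rows:
                if len(row) != ncol:
                    raise FormatError(f"row {rid} has unequal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.matrix, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise FormatError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise FormatError("distance matrix is not symmetric")
        if (d < 0).any():
            raise FormatError("distance matrix has negative entries")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise FormatError("distance matrix diagonal is not zero")
        self.matrix = d


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ca, cb = Counter(a[i:i + k] for i in range(len(a) - k + 1)), \
        Counter(b[i:i + k] for i in range(len(b) - k + 1))
    shared = sum((ca & cb).values())
    denom = min(len(a), len(b)) - k + 1
    if denom <= 0:
        return 1.0
    return 1.0 - shared / denom


def _upgma_merge_order(d: np.ndarray) -> list[tuple[int, int]]:
    """UPGMA agglomeration; returns merge pairs over a growing node list
    where new clusters get indices n, n+1, ... Ties pick the smallest
    (i, j) pair."""
    n = d.shape[0]
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    dist = {(min(i, j), max(i, j)): d[i, j]
            for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int]] = []
    nxt = n
    while len(active) > 1:
        best = None
        for i, j in combinations(active, 2):
            key = (min(i, j), max(i, j))
            cur = dist[key]
            if best is None or cur < best[0] - 1e-15 or (
                    abs(cur - best[0]) <= 1e-15 and key < best[1]):
                best = (cur, key)
        i, j = best[1]
        merges.append((i, j))
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(nxt, k), max(nxt, k))] = (
                sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        sizes[nxt] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return merges


_GAP = "-"


def _profile_counts(rows: list[str], alphabet: str) -> np.ndarray:
    lut = {c: i for i, c in enumerate(alphabet)}
    ncol = len(rows[0])
    counts = np.zeros((ncol, len(alphabet) + 1), dtype=float)
    gap_idx = len(alphabet)
    for row in rows:
        for j, ch in enumerate(row):
            counts[j, lut.get(ch, gap_idx) if ch != _GAP else gap_idx] += 1
    return counts


def _align_profiles(rows_a: list[str], rows_b: list[str], matrix_name: str,
                    gap_open: float, gap_extend: float
                    ) -> tuple[list[str], list[str]]:
    alphabet, M = _matrix_arrays(matrix_name)
    # extend with a zero-scoring gap symbol
    Mx = np.zeros((len(alphabet) + 1, len(alphabet) + 1))
    Mx[:len(alphabet), :len(alphabet)] = M
    ca = _profile_counts(rows_a, alphabet)
    cb = _profile_counts(rows_b, alphabet)
    S = (ca @ Mx @ cb.T) / (len(rows_a) * len(rows_b))
    _, ops = gotoh_global(S, gap_open, gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    for op in ops:
        if op == "D":
            for r, row in enumerate(rows_a):
                out_a[r] += row[i]
            for r, row in enumerate(rows_b):
                out_b[r] += row[j]
            i += 1
            j += 1
        elif op == "U":
            for r, row in enumerate(rows_a):
                out_a[r] += row[i]
            for r in range(len(rows_b)):
                out_b[r] += _GAP
            i += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += _GAP
            for r, row in enumerate(rows_b):
                out_b[r] += row[j]
            j += 1
    return out_a, out_b


def progressive_msa(seqs: list[SequenceRecord], matrix: str = "BLOSUM62",
                    gap_open: float = 11.0, gap_extend: float = 1.0
                    ) -> Alignment:
    """Progressive multiple alignment; deterministic, ties by input order."""
    if not seqs:
        raise FormatError("no sequences to align")
    if len(seqs) == 1:
        return Alignment([(seqs[0].id, seqs[0].residues)])
    ids = {s.id for s in seqs}
    if len(ids) != len(seqs):
        raise FormatError("duplicate sequence ids in MSA input")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[i].residues, seqs[j].residues)
    merges = _upgma_merge_order(d)
    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([s.id], [s.residues]) for i, s in enumerate(seqs)
    }
    nxt = n
    for i, j in merges:
        ids_a, rows_a = profiles.pop(i)
        ids_b, rows_b = profiles.pop(j)
        new_a, new_b = _align_profiles(rows_a, rows_b, matrix, gap_open, gap_extend)
        profiles[nxt] = (ids_a + ids_b, new_a + new_b)
        nxt += 1
    final_ids, final_rows = profiles.popitem()[1]
    by_id = dict(zip(final_ids, final_rows))
    return Alignment([(s.id, by_id[s.id]) for s in seqs])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def protein_distance_matrix(aln: Alignment, model: str = "p_distance"
                            ) -> DistanceMatrix:
    """Pairwise-deletion distances: p-distance or Poisson -ln(1 - p)."""
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(aln.rows) < 2:
        raise FormatError("need at least 2 rows for a distance matrix")
    n = len(aln.rows)
    d = np.zeros((n, n))
    for i in range(n):
        id_i, row_i = aln.rows[i]
        for j in range(i + 1, n):
            id_j, row_j = aln.rows[j]
            comp = 0
            diff = 0
            for a, b in zip(row_i, row_j):
                if a != _GAP and b != _GAP:
                    comp += 1
                    if a != b:
                        diff += 1
            if comp == 0:
                raise FormatError(
                    f"rows {id_i!r} and {id_j!r} share no comparable columns"
                )
            p = diff / comp
            if model == "p_distance":
                dij = p
            else:
                if p >= 1.0:
                    raise FormatError(
                        f"Poisson correction undefined for rows "
                        f"{id_i!r}/{id_j!r} (p = {p})"
                    )
                dij = -math.log(1.0 - p)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(tuple(aln.ids), d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def build_nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei NJ; consistent on additive inputs.

    For n >= 3 the result is unrooted with a trifurcation at the root node;
    computed negative branch lengths are clamped to zero; the Q-criterion
    minimum breaks ties toward the smallest (i, j) index pair.
    """
    n = len(dm.ids)
    if n < 2:
        raise FormatError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.ids]
    d = dm.matrix.copy()

    if n == 2:
        half = d[0, 1] / 2.0
        nodes[0].length = half
        nodes[1].length = half
        return PhyloTree(TreeNode(children=nodes))

    active = list(range(n))
    D = {(i, j): d[i, j] for i in range(n) for j in range(n)}

    def dist(i: int, j: int) -> float:
        return D[(min(i, j), max(i, j))] if i != j else 0.0

    node_of: dict[int, TreeNode] = dict(enumerate(nodes))
    nxt = n
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(dist(i, k) for k in active) for i in active}
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                i, j = active[ii], active[jj]
                q = (r - 2) * dist(i, j) - sums[i] - sums[j]
                key = (min(i, j), max(i, j))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key)
        i, j = best[1]
        dij = dist(i, j)
        li = dij / 2.0 + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        li = max(li, 0.0)
        lj = max(lj, 0.0)
        child_i, child_j = node_of.pop(i), node_of.pop(j)
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])
        node_of[nxt] = new
        for k in active:
            if k in (i, j):
                continue
            dk = max((dist(i, k) + dist(j, k) - dij) / 2.0, 0.0)
            D[(min(nxt, k), max(nxt, k))] = dk
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    a, b, c = active
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    la = max((dab + dac - dbc) / 2.0, 0.0)
    lb = max((dab + dbc - dac) / 2.0, 0.0)
    lc = max((dac + dbc - dab) / 2.0, 0.0)
    na, nb, nc = node_of[a], node_of[b], node_of[c]
    na.length, nb.length, nc.length = la, lb, lc
    return PhyloTree(TreeNode(children=[na, nb, nc]))


# ---------------------------------------------------------------------------
# tree utilities
# ---------------------------------------------------------------------------

def leaf_path_distances(tree: PhyloTree) -> DistanceMatrix:
    """Patristic (path-length) distances between all leaf pairs."""
    paths: dict[str, list[TreeNode]] = {}

    def walk(node: TreeNode, trail: list[TreeNode]) -> None:
        trail = trail + [node]
        if node.is_leaf:
            paths[node.name or ""] = trail
        for ch in node.children:
            walk(ch, trail)

    walk(tree.root, [])
    names = sorted(paths)
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[names[i]], paths[names[j]]
            common = 0
            for a, b in zip(pi, pj):
                if a is b:
                    common += 1
                else:
                    break
            total = sum(nd.length for nd in pi[common:]) + \
                sum(nd.length for nd in pj[common:])
            d[i, j] = d[j, i] = total
    return DistanceMatrix(tuple(names), d)


def bipartitions(tree: PhyloTree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial unrooted splits of the leaf set, as canonical pairs."""
    all_leaves = frozenset(tree.leaf_names())
    splits: set[frozenset[frozenset[str]]] = set()

    def clade(node: TreeNode) -> frozenset[str]:
        return frozenset(n.name or "" for n in node.leaves())

    for node in tree.root.walk():
        if node is tree.root:
            continue
        side = clade(node)
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset((side, other)))
    return splits
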