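"""Alignment filtering, p-distances, neighbor-joining trees, and
nearest-taxon reporting.

The NJ agglomeration (Saitou & Nei Q-criterion) is implemented here with a
deterministic lexicographic tie-break and negative branch-length clamping;
trees are carried as :class:`skbio.TreeNode`, so Newick I/O and path-length
queries come from scikit-bio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix, TreeNode

GAP = "-"


@dataclass
class Alignment:
    ids: list[str]
    matrix: np.ndarray  # (n_seqs, n_cols) of single characters

    def __post_init__(self):
        if self.matrix.ndim != 2 or len(self.ids) != self.matrix.shape[0]:
            raise ValueError("ids/matrix shape mismatch")

    @classmethod
    def from_sequences(cls, pairs: list[tuple[str, str]]) -> "Alignment":
        lengths = {len(s) for _, s in pairs}
        if len(lengths) > 1:
            raise ValueError("aligned rows must have equal length")
        ids = [i for i, _ in pairs]
        mat = np.array([list(s.upper()) for _, s in pairs])
        return cls(ids, mat)

    @classmethod
    def read_fasta(cls, path) -> "Alignment":
        return cls.from_sequences([(r.id, str(r.seq))
                                   for r in SeqIO.parse(str(path), "fasta")])

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]


def filter_gap_columns(aln: Alignment, max_gap_frac: float = 0.05,
                       ) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction strictly exceeds ``max_gap_frac``.

    A column at exactly the threshold is retained. Returns the filtered
    alignment and the removed column indices; removing everything is an error.
    """
    if aln.n_cols == 0:
        raise ValueError("empty alignment")
    gap_frac = (aln.matrix == GAP).mean(axis=0)
    keep = gap_frac <= max_gap_frac
    if not keep.any():
        raise ValueError("all columns removed by gap filter")
    removed = np.flatnonzero(~keep).tolist()
    return Alignment(aln.ids, aln.matrix[:, keep]), removed


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise fraction of differing positions, gapped positions excluded
    pairwise; a pair with no comparable positions is an error."""
    n = len(aln.ids)
    d = np.zeros((n, n))
    gap = aln.matrix == GAP
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            if not ok.any():
                raise ValueError(
                    f"no comparable positions for {aln.ids[i]!r}/{aln.ids[j]!r}")
            d[i, j] = d[j, i] = (aln.matrix[i, ok] != aln.matrix[j, ok]).mean()
    return DistanceMatrix(d, ids=aln.ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining with deterministic tie-breaks.

    Standard Saitou-Nei agglomeration: at each step join the pair minimizing
    Q(i, j) = (r - 2) d(i, j) - row_i - row_j; ties go to the lexicographically
    smallest (taxon, taxon) pair. Branch lengths come from the two-point
    formulas; negative estimates are clamped to 0 and flagged on the node
    (``node.clamped``). Input must be symmetric with a zero diagonal (enforced
    by skbio's DistanceMatrix); at least three taxa are required.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("need at least three taxa")
    d = {a: {b: float(dm[a, b]) for b in ids} for a in ids}
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in ids}
    active = sorted(ids)
    counter = 0

    def clamp(node: TreeNode, length: float) -> None:
        node.length = max(0.0, length)
        node.clamped = length < 0

    while len(active) > 3:
        r = len(active)
        rowsum = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                a, b = active[ai], active[bi]
                q = (r - 2) * d[a][b] - rowsum[a] - rowsum[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * d[a][b] + (rowsum[a] - rowsum[b]) / (2 * (r - 2))
        lb = d[a][b] - la
        parent = TreeNode(name=f"_nj{counter}")
        counter += 1
        clamp(nodes[a], la)
        clamp(nodes[b], lb)
        parent.extend([nodes[a], nodes[b]])
        new = parent.name
        d[new] = {}
        for c in active:
            if c in (a, b):
                continue
            dist = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[new][c] = dist
            d[c][new] = dist
        nodes[new] = parent
        active = sorted([c for c in active if c not in (a, b)] + [new])

    a, b, c = active
    root = TreeNode()
    clamp(nodes[a], 0.5 * (d[a][b] + d[a][c] - d[b][c]))
    clamp(nodes[b], 0.5 * (d[a][b] + d[b][c] - d[a][c]))
    clamp(nodes[c], 0.5 * (d[a][c] + d[b][c] - d[a][b]))
    root.extend([nodes[a], nodes[b], nodes[c]])
    for node in root.non_tips(include_self=True):
        node.name = None  # placeholder join labels are not taxa
    return root


def tree_splits(tree: TreeNode) -> set[frozenset]:
    """Nontrivial bipartitions (unrooted sense) induced by the tree's edges.

    Each split is canonicalized as the side not containing the
    lexicographically smallest taxon; trivial splits (single leaf or its
    complement) are dropped.
    """
    tips_all = frozenset(t.name for t in tree.tips())
    anchor = min(tips_all)
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        side = tips_all - below if anchor in below else below
        if 2 <= len(side) <= len(tips_all) - 2:
            splits.add(side)
    return splits


def robinson_foulds(a: TreeNode, b: TreeNode) -> int:
    """Unweighted Robinson-Foulds distance (symmetric split difference)."""
    return len(tree_splits(a) ^ tree_splits(b))


def nearest_taxon(tree: TreeNode, query: str) -> str:
    """Leaf minimizing path-length distance to ``query``; ties broken
    lexicographically."""
    tips = {t.name for t in tree.tips()}
    if query not in tips:
        raise KeyError(f"unknown taxon {query!r}")
    qnode = tree.find(query)
    best: tuple[float, str] | None = None
    for tip in tree.tips():
        if tip.name == query:
            continue
        dist = qnode.distance(tip)
        key = (dist, tip.name)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("tree has a single leaf")
    return best[1]
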