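"""Neighbour joining over PM distances, cluster extraction, consensus, CA.

Profiles are clustered by building a neighbour-joining tree from the
pairwise mismatch-count matrix.  Candidate clusters are read off the tree
as the two sides of every internal bipartition; downstream redundancy
removal keeps a disjoint subset.  Each cluster's stacked member profiles
form a multiple profile alignment (MPA); its positionwise-majority string
is the consensus profile, and the consensus agreement

    CA = 1 - mean over members of PM(member, consensus) / L

measures cluster coherence on a [0, 1] scale (1 = all members identical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .profiles import ProfileMatrix


class ClusteringError(ValueError):
    """Raised for invalid clustering inputs."""


class TreeNode:
    """Node of an (unrooted, root-at-trifurcation) NJ tree."""

    __slots__ = ("label", "children")

    def __init__(self, label: Optional[str] = None):
        self.label = label
        self.children: list[tuple["TreeNode", float]] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class NJTree:
    """Neighbour-joining tree; the root is the final trifurcating join.

    Branch lengths may be negative, as neighbour joining can produce.
    """

    root: TreeNode
    leaf_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.leaf_names)

    def _postorder(self):
        """Iterative post-order traversal (trees can be deep caterpillars)."""
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            for child, _ in node.children:
                stack.append(child)
        return reversed(out)

    def leaf_sets(self) -> dict:
        """Map node -> frozenset of leaf labels below it."""
        sets: dict[TreeNode, frozenset] = {}
        for node in self._postorder():
            if node.is_leaf:
                sets[node] = frozenset([node.label])
            else:
                sets[node] = frozenset().union(*(sets[c] for c, _ in node.children))
        return sets

    def internal_bipartitions(self) -> list[frozenset]:
        """Leaf sets of internal edges (edges between two internal nodes).

        Each frozenset is one side of the bipartition; the other side is its
        complement in the leaf set.
        """
        sets = self.leaf_sets()
        out = []
        for node in self._postorder():
            if node is self.root or node.is_leaf:
                continue
            out.append(sets[node])
        return out

    def leaf_branch_lengths(self) -> dict:
        """Map leaf label -> length of its pendant branch."""
        out = {}
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child, length in node.children:
                if child.is_leaf:
                    out[child.label] = length
                else:
                    stack.append(child)
        return out

    def to_newick(self) -> str:
        parts: dict[TreeNode, str] = {}
        for node in self._postorder():
            if node.is_leaf:
                parts[node] = node.label
            else:
                inner = ",".join(
                    f"{parts[c]}:{length:.10g}" for c, length in node.children
                )
                parts[node] = f"({inner})"
        return parts[self.root] + ";"


def neighbor_joining(d: np.ndarray, labels: Sequence[str]) -> NJTree:
    """Canonical Saitou-Nei neighbour joining on a symmetric distance matrix.

    At each step the pair minimizing ``Q(i,j) = (m-2) d(i,j) - r_i - r_j``
    is joined, with limb lengths from the standard formulas.  Ties in Q are
    broken by the smallest (row, column) index pair in the current matrix,
    making the output fully deterministic.  O(n^3) time, O(n^2) memory.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ClusteringError("distance matrix must be square")
    if n < 3:
        raise ClusteringError("neighbour joining requires at least 3 taxa")
    if len(labels) != n:
        raise ClusteringError("one label required per row")
    if not np.allclose(d, d.T, rtol=0, atol=1e-9):
        raise ClusteringError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ClusteringError("distance matrix must be non-negative")
    if np.any(np.diag(d) != 0):
        raise ClusteringError("distance matrix must have a zero diagonal")

    D = d.copy()
    nodes: list[TreeNode] = [TreeNode(label) for label in labels]
    m = n
    while m > 2:
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        Q[np.tril_indices(m)] = np.inf
        # row-major argmin = smallest (row, column) pair among ties
        i, j = divmod(int(np.argmin(Q)), m)
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        parent.children = [(nodes[i], li), (nodes[j], lj)]
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k != i and k != j]
        sub = D[np.ix_(keep, keep)]
        row = dnew[keep]
        D = np.empty((m - 1, m - 1))
        D[:-1, :-1] = sub
        D[-1, :-1] = row
        D[:-1, -1] = row
        D[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        m -= 1

    a, b = nodes
    root = a if not a.is_leaf else b
    other = b if root is a else a
    root.children.append((other, float(D[0, 1])))
    return NJTree(root=root, leaf_names=tuple(labels))


@dataclass(frozen=True, order=True)
class CandidateCluster:
    """A bipartition side of the NJ tree proposed as a profile cluster."""

    cluster_id: str
    members: frozenset = field(compare=False)

    @property
    def size(self) -> int:
        return len(self.members)


def candidate_clusters(tree: NJTree, min_size: int = 2) -> list[CandidateCluster]:
    """Both sides of every internal bipartition, size-filtered and deduplicated.

    A side is emitted when its size lies in ``[min_size, n - min_size]``.
    Ordering is deterministic: size descending, then sorted member list.
    """
    if min_size < 2:
        raise ClusteringError("min_size must be >= 2")
    n = len(tree)
    all_leaves = frozenset(tree.leaf_names)
    seen: set[frozenset] = set()
    for side in tree.internal_bipartitions():
        for s in (side, all_leaves - side):
            if min_size <= len(s) <= n - min_size:
                seen.add(s)
    ordered = sorted(seen, key=lambda s: (-len(s), tuple(sorted(s))))
    width = max(4, len(str(len(ordered))))
    return [
        CandidateCluster(cluster_id=f"C{i + 1:0{width}d}", members=s)
        for i, s in enumerate(ordered)
    ]


def consensus(mpa: np.ndarray) -> np.ndarray:
    """Positionwise majority bit of a multiple profile alignment.

    Exact ties go to 0 (absence) -- conservative against inflating apparent
    conservation, and deterministic.
    """
    mpa = np.asarray(mpa, dtype=np.uint8)
    if mpa.ndim != 2 or mpa.shape[0] < 1:
        raise ClusteringError("consensus requires a non-empty 2-D profile stack")
    ones = mpa.sum(axis=0, dtype=np.int64)
    return (2 * ones > mpa.shape[0]).astype(np.uint8)


def consensus_agreement(mpa: np.ndarray, cons: np.ndarray) -> float:
    """CA = 1 - mean mismatch fraction of members to the consensus."""
    mpa = np.asarray(mpa, dtype=np.uint8)
    cons = np.asarray(cons, dtype=np.uint8)
    if mpa.shape[1] != cons.shape[0]:
        raise ClusteringError("consensus length must match profile length")
    return float(1.0 - (mpa != cons[None, :]).mean())


@dataclass(frozen=True)
class MPAConsensus:
    """A cluster's multiple profile alignment, consensus profile and CA."""

    cluster_id: str
    member_ids: tuple[str, ...]
    mpa: np.ndarray
    consensus: np.ndarray
    ca: float


def cluster_consensus(matrix: ProfileMatrix, cluster: CandidateCluster) -> MPAConsensus:
    """Build the MPA, consensus and CA for one candidate cluster.

    Member order follows the profile-matrix row order for determinism.
    """
    member_ids = tuple(p for p in matrix.protein_ids if p in cluster.members)
    if len(member_ids) != len(cluster.members):
        missing = sorted(cluster.members - set(member_ids))
        raise ClusteringError(f"cluster members missing from matrix: {missing}")
    mpa = matrix.rows(member_ids)
    cons = consensus(mpa)
    return MPAConsensus(
        cluster_id=cluster.cluster_id,
        member_ids=member_ids,
        mpa=mpa,
        consensus=cons,
        ca=consensus_agreement(mpa, cons),
    )


def write_mpa(mc: MPAConsensus, path) -> None:
    """One line per member: protein_id and its 0/1 string; consensus last."""
    with open(path, "w") as fh:
        for pid, bits in zip(mc.member_ids, mc.mpa):
            fh.write(f"{pid}\t{''.join(str(int(b)) for b in bits)}\n")
        fh.write(f"consensus\t{''.join(str(int(b)) for b in mc.consensus)}\n")


def write_newick(tree: NJTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
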