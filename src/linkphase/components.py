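"""Shared-SNP fragment graph and normalized-cut partitioning.

Assembly gaps and sequencing/mapping errors leave weakly bridged regions in
the fragment overlap graph: a single spurious or lone fragment can connect
two otherwise independent groups and corrupt the phasing of both.  This
stage builds a graph whose edge weights count the SNPs shared by two
fragments and recursively bipartitions it along the Fiedler vector of the
normalized Laplacian

    L_N = D^{-1/2} (D - W) D^{-1/2},

stopping when the normalized-cut value of the best split exceeds a
threshold ``t`` (default 0.03).  The resulting leaves are the strongly
connected components of fragments that are phased independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc
from scipy.sparse.linalg import ArpackNoConvergence, eigsh

from .fragio import Fragment

#: Below this vertex count the eigenproblem is solved densely.
_DENSE_LIMIT = 200


@dataclass
class FragmentGraph:
    """Weighted undirected graph over fragments.

    ``weights`` is a symmetric nonnegative CSR matrix with zero diagonal;
    entry (i, j) counts the variant indices covered by both fragments.
    """

    ids: list[str]
    weights: sp.csr_matrix

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()


@dataclass
class PartitionNode:
    """Node of the recursive bipartition tree."""

    members: list[str]
    nc_value: float | None = None
    children: tuple["PartitionNode", "PartitionNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list["PartitionNode"]:
        if self.is_leaf:
            return [self]
        return self.children[0].leaves() + self.children[1].leaves()


def build_share_graph(fragments: Sequence[Fragment]) -> FragmentGraph:
    """Edge weight = number of variant indices covered by both fragments."""
    ids = [f.id for f in fragments]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate fragment ids")
    by_site: dict[int, list[int]] = {}
    for i, frag in enumerate(fragments):
        for c in frag.calls:
            by_site.setdefault(c.variant_index, []).append(i)
    counts: dict[tuple[int, int], int] = {}
    for members in by_site.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                key = (members[a], members[b])
                counts[key] = counts.get(key, 0) + 1
    n = len(ids)
    if counts:
        rows, cols, vals = [], [], []
        for (i, j), w in counts.items():
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n), dtype=float)
    else:
        W = sp.csr_matrix((n, n), dtype=float)
    return FragmentGraph(ids=ids, weights=W)


def normalized_laplacian(W: sp.spmatrix | np.ndarray) -> np.ndarray:
    """Dense L_N = D^{-1/2}(D - W)D^{-1/2}; requires all degrees positive."""
    W = sp.csr_matrix(W)
    d = np.asarray(W.sum(axis=1)).ravel()
    if np.any(d <= 0):
        raise ValueError("zero-degree vertex: remove isolated vertices first")
    dinv = 1.0 / np.sqrt(d)
    Wd = W.toarray() * dinv[:, None] * dinv[None, :]
    L = np.eye(W.shape[0]) - Wd
    return (L + L.T) / 2.0


def _fiedler_vector(L: np.ndarray) -> np.ndarray:
    n = L.shape[0]
    if n <= _DENSE_LIMIT:
        _, vecs = scipy.linalg.eigh(L, subset_by_index=[0, 1])
        return vecs[:, 1]
    try:
        v0 = np.ones(n) / np.sqrt(n)
        _, vecs = eigsh(sp.csr_matrix(L), k=2, which="SA", v0=v0)
        return vecs[:, 1]
    except ArpackNoConvergence:
        _, vecs = scipy.linalg.eigh(L, subset_by_index=[0, 1])
        return vecs[:, 1]


def spectral_bipartition(
    W: sp.spmatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a connected graph by the sign of the Fiedler vector.

    Zero entries join the positive side; if the sign split degenerates
    (all entries one sign, numerically), the split falls back to the
    median of the Fiedler vector.  Returns two index arrays, both
    non-empty.
    """
    W = sp.csr_matrix(W)
    n = W.shape[0]
    if n < 2:
        raise ValueError("bipartition needs >= 2 vertices")
    if n == 2:
        return np.array([0]), np.array([1])
    L = normalized_laplacian(W)
    e2 = _fiedler_vector(L)
    pos = e2 >= 0
    if pos.all() or not pos.any():
        pos = e2 >= np.median(e2)
        if pos.all() or not pos.any():  # fully degenerate vector
            pos = np.arange(n) < n // 2
    idx = np.arange(n)
    return idx[pos], idx[~pos]


def ncut_value(
    W: sp.spmatrix | np.ndarray,
    members_1: Sequence[int],
    members_2: Sequence[int],
) -> float:
    """Normalized-cut value of a bipartition: cut/assoc_1 + cut/assoc_2.

    ``cut`` sums weights crossing the split; ``assoc_k`` sums all weights
    incident to side k.  A side with zero association yields the maximal
    value 2 (a split that isolates disconnected mass should be refused).
    """
    W = sp.csr_matrix(W)
    m1 = np.asarray(members_1, dtype=int)
    m2 = np.asarray(members_2, dtype=int)
    if m1.size == 0 or m2.size == 0:
        raise ValueError("both sides must be non-empty")
    if np.intersect1d(m1, m2).size or m1.size + m2.size != W.shape[0]:
        raise ValueError("members must partition the vertex set")
    cut = W[m1][:, m2].sum()
    assoc1 = W[m1].sum()
    assoc2 = W[m2].sum()
    if assoc1 <= 0 or assoc2 <= 0:
        return 2.0
    return float(cut / assoc1 + cut / assoc2)


def recursive_partition(
    graph: FragmentGraph,
    t: float = 0.03,
    min_size: int = 4,
    return_tree: bool = False,
):
    """Recursively bipartition the fragment graph into phasing components.

    Connected components are extracted first (a disconnected graph makes
    the Fiedler vector degenerate); each component is then split along the
    Fiedler vector while the candidate split's normalized-cut value stays
    at or below ``t`` and the component holds at least ``min_size``
    members.  Isolated (zero-degree) fragments are excluded.  Returns the
    list of leaf id-sets (and the partition forest when ``return_tree``).
    """
    W = graph.weights
    deg = graph.degrees
    active = np.where(deg > 0)[0]
    roots: list[PartitionNode] = []

    def descend(idx: np.ndarray) -> list[PartitionNode]:
        """Split idx into connected components, each becoming a node."""
        sub = W[idx][:, idx]
        ncomp, labels = _cc(sub, directed=False)
        nodes = []
        for c in range(ncomp):
            comp_idx = idx[labels == c]
            nodes.append(grow(comp_idx))
        return nodes

    def grow(idx: np.ndarray) -> PartitionNode:
        """idx is connected; attempt a spectral split."""
        node = PartitionNode(members=[graph.ids[i] for i in idx])
        if idx.size < max(min_size, 2):
            return node
        sub = W[idx][:, idx]
        s1, s2 = spectral_bipartition(sub)
        nc = ncut_value(sub, s1, s2)
        node.nc_value = nc
        if nc > t:
            return node
        left = descend(idx[s1])
        right = descend(idx[s2])

        def bundle(nodes: list[PartitionNode], members: list[str]) -> PartitionNode:
            if len(nodes) == 1:
                return nodes[0]
            # a side that fell apart into several components: chain them
            head = nodes[0]
            rest = bundle(nodes[1:], [m for nd in nodes[1:] for m in nd.members])
            return PartitionNode(
                members=members, nc_value=0.0, children=(head, rest)
            )

        node.children = (
            bundle(left, [graph.ids[i] for i in idx[s1]]),
            bundle(right, [graph.ids[i] for i in idx[s2]]),
        )
        return node

    roots = descend(active)
    leaves = [leaf.members for root in roots for leaf in root.leaves()]
    if return_tree:
        return leaves, roots
    return leaves
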