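"""Distances for benchmarking reconstruction results against the truth.

Variant clusterings are compared with the variation of information (VI),
the entropy-based metric VI(A, B) = H(A) + H(B) - 2 I(A; B) in nats;
0 iff the partitions are identical up to relabeling, and lower values
mean greater similarity.

Clonal evolution trees are compared with a discrete spectral distance
(DSD): each directed tree (germline root included) is symmetrized to an
undirected adjacency matrix, the sorted eigenvalue spectra are zero-padded
to equal length, and their Euclidean distance is returned. The directed
adjacency of a tree is nilpotent (every eigenvalue 0), so the spectra are
taken after symmetrization; a graph-Laplacian variant is exposed as an
option.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping, Sequence

import networkx as nx
import numpy as np

from .phylogeny import GERMLINE, Phylogeny


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# variation of information

def variation_of_information(a: Mapping[object, object],
                             b: Mapping[object, object]) -> float:
    """VI between two clusterings given as element -> label mappings.

    Labels are arbitrary (comparison is label-invariant); both clusterings
    must cover the identical element set.
    """
    if set(a) != set(b):
        raise MetricError(
            f"clusterings cover different element sets "
            f"({len(set(a) ^ set(b))} elements differ)")
    n = len(a)
    if n == 0:
        raise MetricError("empty clusterings")
    joint = Counter((a[x], b[x]) for x in a)
    ca = Counter(a.values())
    cb = Counter(b.values())
    h_a = -sum((c / n) * np.log(c / n) for c in ca.values())
    h_b = -sum((c / n) * np.log(c / n) for c in cb.values())
    mi = sum((c / n) * np.log(c * n / (ca[la] * cb[lb]))
             for (la, lb), c in joint.items())
    return max(h_a + h_b - 2.0 * mi, 0.0)


# ---------------------------------------------------------------------------
# clone trees

def tree_to_adjacency(
    tree: Phylogeny | Mapping[int, int] | Sequence[tuple[int, int]],
) -> np.ndarray:
    """Directed adjacency matrix of a clone tree, germline included.

    Accepts a :class:`Phylogeny`, a child -> parent mapping, or an
    iterable of (parent, child) edges; node ids are sorted, the germline
    (id 0) is always present, and ``A[i, j] = 1`` iff node i is the
    parent of node j. Raises on cycles or multiple roots.
    """
    if isinstance(tree, Phylogeny):
        edges = [(p, c) for c, p in tree.parents.items()]
    elif isinstance(tree, Mapping):
        edges = [(p, c) for c, p in tree.items()]
    else:
        edges = [(int(p), int(c)) for p, c in tree]
    if not edges:
        raise MetricError("empty tree")

    g = nx.DiGraph(edges)
    g.add_node(GERMLINE)
    if not nx.is_directed_acyclic_graph(g):
        raise MetricError("clone tree contains a cycle")
    roots = [n for n in g.nodes if g.in_degree(n) == 0]
    if roots != [GERMLINE]:
        raise MetricError(f"expected the germline (0) as single root, found roots {sorted(roots)}")
    bad = [n for n in g.nodes if g.in_degree(n) > 1]
    if bad:
        raise MetricError(f"node(s) {bad} have more than one parent")

    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)))
    for p, c in g.edges:
        adj[index[p], index[c]] = 1.0
    return adj


def _spectrum(adj: np.ndarray, kind: str) -> np.ndarray:
    sym = np.clip(adj + adj.T, 0.0, 1.0)
    if kind == "laplacian":
        sym = np.diag(sym.sum(axis=1)) - sym
    elif kind != "adjacency":
        raise MetricError(f"unknown spectrum kind {kind!r}")
    return np.sort(np.linalg.eigvalsh(sym))


def discrete_spectral_distance(a: np.ndarray, b: np.ndarray,
                               spectrum: str = "adjacency") -> float:
    """Euclidean distance between the sorted (symmetrized) spectra of two
    directed clone-tree adjacency matrices; sizes may differ (the shorter
    spectrum is zero-padded). 0 for isomorphic trees of equal size."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MetricError("empty graph")
    sa = _spectrum(a, spectrum)
    sb = _spectrum(b, spectrum)
    k = max(len(sa), len(sb))
    sa = np.sort(np.concatenate([sa, np.zeros(k - len(sa))]))
    sb = np.sort(np.concatenate([sb, np.zeros(k - len(sb))]))
    return float(np.linalg.norm(sa - sb))


def average_tree_distance(truth: np.ndarray,
                          reported: Sequence[np.ndarray],
                          spectrum: str = "adjacency") -> float:
    """Mean DSD between the truth and each reported tree (tools that
    report several candidate trees are scored by the average)."""
    reported = list(reported)
    if not reported:
        raise MetricError("no reported trees")
    return float(np.mean([
        discrete_spectral_distance(truth, r, spectrum=spectrum) for r in reported]))
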