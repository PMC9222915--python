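"""Distance-based phylogeny over HVR peptides.

A deliberately lightweight tree-building stage: normalized global-alignment
distances between peptides, canonical Saitou-Nei neighbor joining, optional
rooting on an outgroup's pendant edge, newick output. It supports a
qualitative look at allele relatedness; it makes no claim to model-based
(maximum-likelihood) inference.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Sequence

import dendropy
import edlib
import numpy as np


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.isfinite(self.d).all() or (self.d < 0).any():
            raise ValueError("distances must be finite and non-negative")

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.d):
            lines.append(lab + "  " + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def pairwise_distance(a: str, b: str) -> float:
    """Normalized global-alignment distance between two peptides.

    Global (Needleman-Wunsch) alignment with match 0, mismatch 1, gap 1,
    no free end gaps; the unit-cost optimum equals the Levenshtein
    distance, normalized by the number of alignment columns, giving a
    p-distance-like value in [0, 1].
    """
    if not a or not b:
        raise ValueError("peptides must be non-empty")
    if a == b:
        return 0.0
    # several co-optimal alignments may differ in column count depending on
    # argument order; canonicalize the order so the distance is symmetric
    if b < a:
        a, b = b, a
    res = edlib.align(a, b, mode="NW", task="path")
    columns = sum(int(n) for n in re.findall(r"(\d+)", res["cigar"]))
    return res["editDistance"] / columns


def distance_matrix(labels: Sequence[str], peptides: Sequence[str]) -> DistanceMatrix:
    if len(labels) != len(peptides):
        raise ValueError("labels and peptides differ in length")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(peptides[i], peptides[j])
    return DistanceMatrix(list(labels), d)


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Canonical Saitou-Nei neighbor joining.

    Deterministic: when several pairs minimize the Q criterion, the pair
    with the lexicographically smallest (label_i, label_j) wins, where an
    internal node carries the smallest leaf label beneath it. Negative
    branch lengths (possible on non-additive input) are clamped to zero;
    the count of clamped edges is stored on the returned tree as
    ``negative_lengths_clamped``.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError(f"need at least 3 labels, got {n}")
    if len(set(matrix.labels)) != n:
        raise ValueError("labels must be unique")

    tns = dendropy.TaxonNamespace(list(matrix.labels))
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in matrix.labels]
    labels = list(matrix.labels)  # sort key per active node
    d = matrix.d.astype(float).copy()
    active = list(range(n))
    clamped = 0

    def join(i: int, j: int, li: float, lj: float) -> dendropy.Node:
        nonlocal clamped
        parent = dendropy.Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            if length < 0:
                length = 0.0
                clamped += 1
            parent.add_child(child)
            child.edge.length = length
        return parent

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                key = (q[ai, aj], *sorted((labels[active[ai]], labels[active[aj]])))
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        li = 0.5 * sub[ai, aj] + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = sub[ai, aj] - li
        parent = join(i, j, li, lj)
        # distances from the new node to the remaining ones
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        k = len(nodes)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[k, :k] = new_row
        d[:k, k] = new_row
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    root = dendropy.Node()
    lengths = (
        0.5 * (d[i, j] + d[i, k] - d[j, k]),
        0.5 * (d[i, j] + d[j, k] - d[i, k]),
        0.5 * (d[i, k] + d[j, k] - d[i, j]),
    )
    for idx, length in zip((i, j, k), lengths):
        if length < 0:
            length = 0.0
            clamped += 1
        root.add_child(nodes[idx])
        nodes[idx].edge.length = length
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.negative_lengths_clamped = clamped
    return tree


def root_on_outgroup(tree: dendropy.Tree, label: str) -> dendropy.Tree:
    """Root the tree at the midpoint of the outgroup's pendant edge."""
    node = tree.find_node_with_taxon_label(label)
    if node is None:
        raise ValueError(f"outgroup label {label!r} not found in tree")
    parent = node.parent_node
    pendant = node.edge.length if node.edge.length is not None else 0.0
    mid = dendropy.Node()
    parent.remove_child(node)
    parent.add_child(mid)
    mid.edge.length = pendant / 2.0
    mid.add_child(node)
    node.edge.length = pendant / 2.0
    tree.reroot_at_node(mid, update_bipartitions=False, suppress_unifurcations=False)
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(file=io.StringIO(text), schema="newick")
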