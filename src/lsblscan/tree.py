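"""Neighbor-joining trees from allele-sharing distance matrices.

Implements Saitou-Nei neighbor joining with the PHYLIP-style handling of
negative branch estimates (clamped to zero, deficit moved to the sister
branch) and deterministic tie-breaking, producing an unrooted tree as a
:class:`dendropy.Tree` (trifurcating seed node). Newick serialization and
distance-matrix TSV I/O round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over ordered, named taxa."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate taxon labels")
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.matrix < 0).any():
            raise ValueError("distances must be non-negative")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.columns], matrix=df.values)


def _clamped_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sister."""
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei NJ on a distance matrix; returns an unrooted tree.

    At each step the pair minimizing Q(i, j) = (m-2) d_ij - r_i - r_j is
    joined (ties: smallest (i, j) in input order). Branch lengths follow
    the standard NJ formulas; negatives are clamped to 0 with the deficit
    moved to the sister branch. The final three nodes attach to a
    trifurcating seed node, so the tree is unrooted.
    """
    m = len(dm.labels)
    if m < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {m}")

    tns = dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = [
        dendropy.Node(taxon=tns.get_taxon(lab)) for lab in dm.labels
    ]
    d = dm.matrix.astype(float).copy()
    active = list(range(m))  # indices into rows of d / entries of nodes

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        # only the upper triangle is searched (Q is symmetric up to float
        # rounding); ties resolve to the smallest (i, j) position pair
        q[np.tril_indices(k)] = np.inf
        best = np.argwhere(q == q.min())
        i_loc, j_loc = min(tuple(x) for x in best)
        i, j = active[i_loc], active[j_loc]

        dij = sub[i_loc, j_loc]
        li = dij / 2.0 + (r[i_loc] - r[j_loc]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = _clamped_pair(li, lj)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj

        # distances from the new node to every remaining node
        new_row = np.zeros(d.shape[0] + 1)
        for loc, idx in enumerate(active):
            if idx in (i, j):
                continue
            new_row[idx] = (sub[i_loc, loc] + sub[j_loc, loc] - dij) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    # terminal trifurcation: solve the three leaf-branch equations
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    root = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write Newick with branch lengths; labels are quoted as needed."""
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
        )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def is_population_clade(tree: dendropy.Tree, labels) -> bool:
    """True if the labelled leaves form a connected subtree (unrooted sense).

    A leaf set is a clade of an unrooted tree iff some edge bipartition
    separates exactly that set from the rest; equivalently some node's leaf
    set, or its complement, equals the set.
    """
    want = set(labels)
    all_leaves = set(leaf_labels(tree))
    if not want <= all_leaves:
        raise ValueError(f"labels not in tree: {sorted(want - all_leaves)[:5]}")
    if len(want) in (1, len(all_leaves)):
        return True
    for node in tree.preorder_node_iter():
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == want or (all_leaves - below) == want:
            return True
    return False
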