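"""Nei genetic distances between populations and neighbor-joining trees.

Nei's standard genetic distance (the 1972 form) between populations X and Y
over loci ℓ with frequency vectors x, y:

    j_X(ℓ) = Σ_i x_i²   j_Y(ℓ) = Σ_i y_i²   j_XY(ℓ) = Σ_i x_i y_i
    J_• = arithmetic mean over loci;  I = J_XY / sqrt(J_X · J_Y);  D = −ln I.

I ≤ 1 by Cauchy–Schwarz, so D ≥ 0, with D = 0 iff the frequency profiles
are proportional. The DA distance (Nei et al. 1983),
DA = 1 − (1/L) Σ_ℓ Σ_i sqrt(x_i y_i), is provided for sensitivity checks.

Trees are built by the Saitou–Nei neighbor-joining agglomeration, which is
exact on additive distance matrices, and serialized as unrooted Newick via
dendropy.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .containers import LOCI, DistanceMatrix, FrequencyTable
from .errors import HlaPopgenError, InfiniteDistanceError
from .nomenclature import Locus

__all__ = [
    "nei_standard_distance",
    "da_distance",
    "distance_matrix",
    "neighbor_joining",
    "PhyloTree",
]


def _locus_vectors(
    x: FrequencyTable, y: FrequencyTable, locus: Locus, renormalize: bool
) -> tuple[np.ndarray, np.ndarray]:
    cats = sorted(
        set(x.freqs.get(locus, {})) | set(y.freqs.get(locus, {})), key=lambda c: c.code
    )
    if not cats:
        raise HlaPopgenError(f"neither population has frequencies at locus {locus}")
    xv = np.array([x.get(c) for c in cats])
    yv = np.array([y.get(c) for c in cats])
    if renormalize:
        xv = xv / xv.sum()
        yv = yv / yv.sum()
    return xv, yv


def nei_standard_distance(
    x: FrequencyTable,
    y: FrequencyTable,
    loci: Sequence[Locus] = LOCI,
    renormalize: bool = False,
) -> float:
    """Nei (1972) standard genetic distance D = −ln I over the given loci.

    Frequencies are used as stored (printed tables are left un-renormalized
    by default; ``renormalize`` first scales each locus column to sum to 1).
    """
    jX = jY = jXY = 0.0
    for locus in loci:
        xv, yv = _locus_vectors(x, y, locus, renormalize)
        jX += float(xv @ xv)
        jY += float(yv @ yv)
        jXY += float(xv @ yv)
    L = len(loci)
    identity = (jXY / L) / math.sqrt((jX / L) * (jY / L))
    if identity <= 0:
        raise InfiniteDistanceError(
            f"{x.population} and {y.population} share no alleles; D is infinite"
        )
    return -math.log(identity)


def da_distance(
    x: FrequencyTable,
    y: FrequencyTable,
    loci: Sequence[Locus] = LOCI,
    renormalize: bool = False,
) -> float:
    """DA distance of Nei, Tajima & Tateno (1983)."""
    acc = 0.0
    for locus in loci:
        xv, yv = _locus_vectors(x, y, locus, renormalize)
        acc += 1.0 - float(np.sqrt(xv * yv).sum())
    return acc / len(loci)


def distance_matrix(
    tables: Iterable[FrequencyTable],
    loci: Sequence[Locus] = LOCI,
    variant: str = "nei72",
    renormalize: bool = False,
) -> DistanceMatrix:
    """Pairwise distances between all populations, in input order."""
    tables = list(tables)
    labels = [t.population for t in tables]
    if len(set(labels)) != len(labels):
        raise HlaPopgenError("duplicate population labels")
    if len(tables) < 2:
        raise HlaPopgenError("at least two populations required")
    fn = {"nei72": nei_standard_distance, "da": da_distance}.get(variant)
    if fn is None:
        raise HlaPopgenError(f"unknown distance variant {variant!r}")
    n = len(tables)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(tables[i], tables[j], loci=loci, renormalize=renormalize)
    return DistanceMatrix(labels, d)


class PhyloTree:
    """An unrooted, leaf-labelled tree with branch lengths.

    Thin wrapper over a :class:`dendropy.Tree` exposing the operations the
    pipeline needs: Newick round trip and patristic (path) distances.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.tree.is_rooted = False

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    def to_newick(self) -> str:
        return (
            self.tree.as_string(schema="newick", suppress_rooting=True).strip()
        )

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    def patristic_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length distances (labels sorted)."""
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = self.leaf_labels
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        return DistanceMatrix(labels, d)


def neighbor_joining(d: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Repeatedly joins the pair (i, j) minimizing
    Q(i, j) = (n−2)·d(i, j) − Σ_k d(i, k) − Σ_k d(j, k),
    with ties broken on the lexicographically smallest cluster-label pair;
    the final three clusters are closed onto one internal node with the
    exact three-point formulas. Negative branch lengths are kept as computed
    unless ``clamp_negative`` sets them to 0. Exact on additive matrices.
    """
    n = len(d.labels)
    if n < 3:
        raise HlaPopgenError("neighbor joining requires at least 3 taxa")
    taxa = dendropy.TaxonNamespace(d.labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in d.labels]
    # Cluster tie-break label: the smallest leaf label inside the cluster.
    tags = list(d.labels)
    mat = d.values.copy()
    active = list(range(n))

    def _edge(length: float) -> float:
        return max(0.0, length) if clamp_negative else length

    while len(active) > 3:
        m = len(active)
        sub = mat[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                key = tuple(sorted((tags[active[ai]], tags[active[aj]])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, ai, aj)
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = mat[i, j]
        bi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        bj = dij - bi
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = _edge(bi)
        nj.edge.length = _edge(bj)
        # Distances from the new cluster to the remaining ones.
        new_row = np.zeros(mat.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (mat[i, k] + mat[j, k] - dij)
        mat = np.pad(mat, ((0, 1), (0, 1)))
        mat[-1, :-1] = new_row[:-1]
        mat[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        tags.append(min(tags[i], tags[j]))
        active = [k for k in active if k not in (i, j)] + [mat.shape[0] - 1]

    x, y, z = active
    # Exact closure: a + b = d_xy, a + c = d_xz, b + c = d_yz.
    a = 0.5 * (mat[x, y] + mat[x, z] - mat[y, z])
    b = mat[x, y] - a
    c = mat[x, z] - a
    center = dendropy.Node()
    for node, length in ((nodes[x], a), (nodes[y], b), (nodes[z], c)):
        center.add_child(node)
        node.edge.length = _edge(length)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=center)
    return PhyloTree(tree)
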