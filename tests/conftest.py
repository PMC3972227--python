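import collections

import numpy as np
import pytest

from hla_popgen import (
    AlleleCategory,
    DistanceMatrix,
    GenotypeDataset,
    GenotypeRecord,
    Haplotype,
    HaplotypeFrequencyTable,
    LOCI,
    Locus,
    default_serology_map,
    make_paper_fixtures,
)


def cat(code: str, locus: Locus | None = None) -> AlleleCategory:
    return AlleleCategory.from_code(code, locus)


def hap(a: str, b: str, d: str) -> Haplotype:
    return Haplotype(cat(a), cat(b), cat(d))


def record(sample_id, population, a_pair, b_pair, d_pair) -> GenotypeRecord:
    return GenotypeRecord(
        sample_id,
        population,
        {
            Locus.A: tuple(cat(x) for x in a_pair),
            Locus.B: tuple(cat(x) for x in b_pair),
            Locus.DRB1: tuple(cat(x) for x in d_pair),
        },
    )


@pytest.fixture(scope="session")
def serology_map():
    return default_serology_map()


@pytest.fixture(scope="session")
def paper_fixtures():
    return make_paper_fixtures()


@pytest.fixture()
def tiny_dataset():
    """Four donors, two populations, mixed zygosity."""
    return GenotypeDataset(
        [
            record("s1", "P1", ("A*01", "A*02"), ("B*07", "B*08"), ("DRB1*01", "DRB1*04")),
            record("s2", "P1", ("A*02", "A*02"), ("B*07", "B*07"), ("DRB1*04", "DRB1*04")),
            record("s3", "P1", ("A*02", "A*03"), ("B*08", "B*13"), ("DRB1*01", "DRB1*01")),
            record("s4", "P2", ("A*11", "A*11"), ("B*13", "B*13"), ("DRB1*09", "DRB1*09")),
        ]
    )


def le_truth_table(pa=(0.5, 0.3, 0.2)):
    """A linkage-equilibrium ground truth: three alleles per locus, the
    haplotype frequency of every combination is the product of its allele
    frequencies."""
    A = [cat(c) for c in ("A*01", "A*02", "A*03")]
    B = [cat(c) for c in ("B*07", "B*08", "B*13")]
    D = [cat(c) for c in ("DRB1*01", "DRB1*03", "DRB1*04")]
    freqs = {
        Haplotype(a, b, d): pa[i] * pa[j] * pa[k]
        for i, a in enumerate(A)
        for j, b in enumerate(B)
        for k, d in enumerate(D)
    }
    return HaplotypeFrequencyTable(freqs, population="Sim")


def random_additive_matrix(n_taxa: int, rng: np.random.Generator) -> DistanceMatrix:
    """Path-distance matrix of a random unrooted binary tree with positive
    branch lengths: the exactness oracle for neighbor joining."""
    labels = [f"T{i}" for i in range(n_taxa)]
    adj: dict[str, list[tuple[str, float]]] = {}

    def add_edge(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    center = "I0"
    for leaf in labels[:3]:
        add_edge(center, leaf, float(rng.uniform(0.1, 2.0)))
    nxt = 1
    for leaf in labels[3:]:
        edges = [(u, v, w) for u in adj for v, w in adj[u] if u < v]
        u, v, w = edges[rng.integers(len(edges))]
        mid = f"I{nxt}"
        nxt += 1
        adj[u] = [(x, ww) for x, ww in adj[u] if x != v]
        adj[v] = [(x, ww) for x, ww in adj[v] if x != u]
        t = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w * t)
        add_edge(mid, v, w * (1 - t))
        add_edge(mid, leaf, float(rng.uniform(0.1, 2.0)))

    n = len(labels)
    d = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        queue = collections.deque([src])
        while queue:
            x = queue.popleft()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    queue.append(y)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    return DistanceMatrix(labels, d)


def total_variation(table: HaplotypeFrequencyTable, truth: HaplotypeFrequencyTable) -> float:
    support = set(table) | set(truth)
    return 0.5 * sum(abs(table.get(h) - truth.get(h)) for h in support)
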