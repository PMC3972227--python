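"""Maximum-likelihood haplotype frequencies from unphased genotypes.

Phase across the three loci is unobserved: a donor heterozygous at h loci is
compatible with 2^(h−1) unordered haplotype pairs (diplotypes). Under random
mating the likelihood of a genotype is the sum of f(h1)·f(h2) over its
compatible diplotypes, with the factor 2 for heterozygous pairs, and the EM
algorithm maximizes it: the E-step distributes each donor over compatible
diplotypes in proportion to current frequencies, the M-step re-estimates
each haplotype's frequency as its expected share of the 2N chromosomes.

The estimator is exposed statsmodels-style: a :class:`HaplotypeFrequencyModel`
built from a dataset whose :meth:`~HaplotypeFrequencyModel.fit` returns an
:class:`EMResult` carrying the table, the log-likelihood trace and
convergence diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .allele_stats import DEFAULT_SEED
from .containers import (
    LOCI,
    GenotypeDataset,
    GenotypeRecord,
    Haplotype,
    HaplotypeFrequencyTable,
)
from .errors import HlaPopgenError

__all__ = [
    "enumerate_diplotypes",
    "HaplotypeFrequencyModel",
    "EMResult",
    "em_haplotype_frequencies",
    "filter_and_rank",
    "frequency_band_summary",
]

DiplotypePair = tuple[Haplotype, Haplotype]


def enumerate_diplotypes(record: GenotypeRecord) -> list[DiplotypePair]:
    """All unordered haplotype pairs whose locus-wise union reproduces the
    genotype; 2^(h−1) of them for h heterozygous loci (1 when h = 0).

    Pairs are returned sorted, each pair internally ordered, so the
    enumeration is deterministic.
    """
    pairs: set[DiplotypePair] = set()
    slots = [record.pair(locus) for locus in LOCI]
    for orientation in product((0, 1), repeat=len(LOCI)):
        h1 = Haplotype(*(slots[i][o] for i, o in enumerate(orientation)))
        h2 = Haplotype(*(slots[i][1 - o] for i, o in enumerate(orientation)))
        pairs.add((h1, h2) if h1.key <= h2.key else (h2, h1))
    return sorted(pairs, key=lambda p: (p[0].key, p[1].key))


@dataclass
class EMResult:
    """Fitted haplotype frequencies with optimization diagnostics."""

    table: HaplotypeFrequencyTable
    log_likelihood_trace: list[float]
    iterations: int
    converged: bool
    model: "HaplotypeFrequencyModel" = field(repr=False, default=None)

    @property
    def log_likelihood(self) -> float:
        return self.log_likelihood_trace[-1]

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.table.items(), key=lambda kv: (-kv[1], kv[0].key))
        return pd.DataFrame(
            {
                "A": [h.a.code for h, _ in rows],
                "B": [h.b.code for h, _ in rows],
                "DRB1": [h.drb1.code for h, _ in rows],
                "frequency": [v for _, v in rows],
            }
        )

    def summary(self, top_n: int = 20) -> str:
        df = self.to_frame().head(top_n)
        lines = [
            "EM haplotype frequency estimate",
            f"  population:     {self.table.population or '<all>'}",
            f"  individuals:    {self.table.n}",
            f"  haplotypes:     {len(self.table)} in support",
            f"  iterations:     {self.iterations} ({'converged' if self.converged else 'NOT converged'})",
            f"  log-likelihood: {self.log_likelihood:.6f}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class HaplotypeFrequencyModel:
    """EM estimator of three-locus haplotype frequencies for one population.

    The support is restricted to haplotypes compatible with at least one
    observed genotype; all others have maximum-likelihood frequency 0, so
    the restriction changes nothing but the state-space size. Identical
    genotypes are grouped and weighted for speed.
    """

    def __init__(self, dataset: GenotypeDataset, population: str | None = None):
        self.dataset = dataset.subset(population) if population is not None else dataset
        self.population = population if population is not None else ""
        self.nobs = len(self.dataset)
        self._build_support()

    def _build_support(self) -> None:
        hap_index: dict[Haplotype, int] = {}
        groups: dict[tuple, int] = {}
        group_pairs: list[list[tuple[int, int]]] = []
        self._group_weight: list[float] = []
        for rec in self.dataset:
            pairs = enumerate_diplotypes(rec)
            idx_pairs = []
            for h1, h2 in pairs:
                for h in (h1, h2):
                    if h not in hap_index:
                        hap_index[h] = len(hap_index)
                idx_pairs.append((hap_index[h1], hap_index[h2]))
            sig = tuple(idx_pairs)
            if sig in groups:
                self._group_weight[groups[sig]] += 1.0
            else:
                groups[sig] = len(group_pairs)
                group_pairs.append(idx_pairs)
                self._group_weight.append(1.0)
        self.haplotypes: list[Haplotype] = [h for h, _ in sorted(hap_index.items(), key=lambda kv: kv[1])]
        self.n_haplotypes = len(self.haplotypes)
        # Flattened (group, pair) arrays for vectorized E/M steps.
        g_idx, i_idx, j_idx = [], [], []
        for g, idx_pairs in enumerate(group_pairs):
            for i, j in idx_pairs:
                g_idx.append(g)
                i_idx.append(i)
                j_idx.append(j)
        self._g = np.array(g_idx, dtype=np.int64)
        self._i = np.array(i_idx, dtype=np.int64)
        self._j = np.array(j_idx, dtype=np.int64)
        self._mult = np.where(self._i != self._j, 2.0, 1.0)
        self._w = np.asarray(self._group_weight, dtype=float)
        self.n_groups = len(group_pairs)

    def _initial(self, init: str, rng: np.random.Generator) -> np.ndarray:
        if init == "uniform":
            f = np.ones(self.n_haplotypes)
        elif init == "allele_product":
            # Linkage-equilibrium start: product of single-locus frequencies
            # over the observed support.
            denom = 2.0 * self.nobs
            tables: dict = {}
            for locus in LOCI:
                counts: dict = {}
                for rec in self.dataset:
                    for cat in rec.pair(locus):
                        counts[cat] = counts.get(cat, 0) + 1
                tables[locus] = {cat: c / denom for cat, c in counts.items()}
            f = np.array(
                [
                    tables[LOCI[0]][h.a] * tables[LOCI[1]][h.b] * tables[LOCI[2]][h.drb1]
                    for h in self.haplotypes
                ]
            )
        elif init == "random":
            f = rng.dirichlet(np.ones(self.n_haplotypes))
        else:
            raise HlaPopgenError(f"unknown init {init!r}")
        return f / f.sum()

    def _run(self, f: np.ndarray, tol: float, max_iter: int):
        trace: list[float] = []
        converged = False
        iterations = 0
        total_w = self._w.sum()
        for iterations in range(1, max_iter + 1):
            w = self._mult * f[self._i] * f[self._j]
            s = np.bincount(self._g, weights=w, minlength=self.n_groups)
            ll = float(np.dot(self._w, np.log(np.maximum(s, 1e-300))))
            trace.append(ll)
            resp = self._w[self._g] * w / s[self._g]
            counts = np.bincount(self._i, weights=resp, minlength=self.n_haplotypes)
            counts += np.bincount(self._j, weights=resp, minlength=self.n_haplotypes)
            f_new = counts / (2.0 * total_w)
            delta = float(np.max(np.abs(f_new - f)))
            f = f_new
            if delta < tol:
                converged = True
                break
        # Log-likelihood at the final parameter value.
        w = self._mult * f[self._i] * f[self._j]
        s = np.bincount(self._g, weights=w, minlength=self.n_groups)
        trace.append(float(np.dot(self._w, np.log(np.maximum(s, 1e-300)))))
        return f, trace, iterations, converged

    def fit(
        self,
        tol: float = 1e-7,
        max_iter: int = 1000,
        init: str = "allele_product",
        restarts: int = 1,
        seed: int = DEFAULT_SEED,
    ) -> EMResult:
        """Run EM to convergence; with ``restarts`` > 1 the best of one
        ``init`` start and ``restarts − 1`` random starts is returned."""
        if tol <= 0 or max_iter <= 0:
            raise HlaPopgenError("tol and max_iter must be positive")
        if restarts < 1:
            raise HlaPopgenError("restarts must be >= 1")
        rng = np.random.default_rng(seed)
        best = None
        for r in range(restarts):
            f0 = self._initial(init if r == 0 else "random", rng)
            f, trace, iterations, converged = self._run(f0, tol, max_iter)
            if best is None or trace[-1] > best[1][-1]:
                best = (f, trace, iterations, converged)
        f, trace, iterations, converged = best
        for a, b in zip(trace, trace[1:]):
            if b < a - 1e-8:
                raise HlaPopgenError(
                    f"EM log-likelihood decreased ({a:.9f} -> {b:.9f}); "
                    "this indicates an implementation defect"
                )
        table = HaplotypeFrequencyTable(
            {h: float(v) for h, v in zip(self.haplotypes, f)},
            population=self.population,
            n=self.nobs,
        )
        return EMResult(table, trace, iterations, converged, model=self)


def em_haplotype_frequencies(
    dataset: GenotypeDataset,
    population: str | None = None,
    tol: float = 1e-7,
    max_iter: int = 1000,
    init: str = "allele_product",
    restarts: int = 1,
    seed: int = DEFAULT_SEED,
) -> EMResult:
    """Functional wrapper over :class:`HaplotypeFrequencyModel`."""
    return HaplotypeFrequencyModel(dataset, population).fit(
        tol=tol, max_iter=max_iter, init=init, restarts=restarts, seed=seed
    )


def filter_and_rank(
    table: HaplotypeFrequencyTable,
    min_freq: float = 0.0,
    top_n: int | None = None,
) -> HaplotypeFrequencyTable:
    """Keep haplotypes with frequency ≥ ``min_freq``, sorted descending by
    frequency with lexicographic tie-break, optionally truncated to
    ``top_n``."""
    if min_freq < 0:
        raise HlaPopgenError("min_freq must be non-negative")
    rows = [(h, v) for h, v in table.items() if v >= min_freq]
    rows.sort(key=lambda kv: (-kv[1], kv[0].key))
    if top_n is not None:
        rows = rows[:top_n]
    return HaplotypeFrequencyTable(dict(rows), population=table.population, n=table.n)


def frequency_band_summary(
    table: HaplotypeFrequencyTable,
    band_edges: list[float] = (0.01, 0.001, 0.0001),
) -> pd.DataFrame:
    """Count haplotypes per frequency band and sum their mass (as percent).

    Bands are ``> e1``, then half-open intervals ``(e_{i+1}, e_i]``, and a
    final ``(0, e_last]``; zero-frequency haplotypes fall in no band.
    """
    edges = list(band_edges)
    if any(a <= b for a, b in zip(edges, edges[1:])):
        raise HlaPopgenError("band edges must be strictly decreasing")
    bounds = [(edges[0], np.inf)] + [(lo, hi) for hi, lo in zip(edges, edges[1:])] + [(0.0, edges[-1])]
    labels = [f">{edges[0]:g}"] + [f"{hi:g}–{lo:g}" for hi, lo in zip(edges, edges[1:])] + [f"≤{edges[-1]:g}"]
    counts = [0] * len(bounds)
    mass = [0.0] * len(bounds)
    for _, v in table.items():
        if v <= 0:
            continue
        for b, (lo, hi) in enumerate(bounds):
            if lo < v <= hi or (np.isinf(hi) and v > lo):
                counts[b] += 1
                mass[b] += v
                break
    return pd.DataFrame(
        {"band": labels, "count": counts, "percent_of_total": [100.0 * m for m in mass]}
    )
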