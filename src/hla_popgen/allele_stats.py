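"""Direct-counting allele frequencies, Hardy–Weinberg testing, and
population composition summaries.

The HWE test is the classical multiallelic chi-square on genotype classes:
expected counts N·p_i² for homozygotes and 2N·p_i·p_j for heterozygotes,
with rare categories pooled first so the asymptotic approximation is not
applied to near-empty cells. A Monte-Carlo exact variant (permuting the 2N
allele copies into pairs) is available for sparse tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LOCI, FrequencyTable, GenotypeDataset
from .errors import DegenerateTestError, HlaPopgenError
from .nomenclature import AlleleCategory, Locus

__all__ = [
    "allele_frequencies",
    "hwe_test",
    "HWEResult",
    "population_composition",
    "composition_from_counts",
    "DEFAULT_SEED",
]

#: Package-wide default seed for every operation that uses randomness.
DEFAULT_SEED = 20140401


def _allele_counts(dataset: GenotypeDataset, locus: Locus) -> dict[AlleleCategory, int]:
    counts: dict[AlleleCategory, int] = {}
    for rec in dataset:
        for cat in rec.pair(locus):
            counts[cat] = counts.get(cat, 0) + 1
    return counts


def allele_frequencies(
    dataset: GenotypeDataset,
    population: str,
    loci: Iterable[Locus] = LOCI,
) -> FrequencyTable:
    """Direct counting: each of the 2N allele slots at a locus counts once."""
    sub = dataset.subset(population)
    freqs: dict[Locus, dict[AlleleCategory, float]] = {}
    denom = 2 * len(sub)
    for locus in loci:
        counts = _allele_counts(sub, locus)
        freqs[locus] = {cat: c / denom for cat, c in sorted(counts.items(), key=lambda kv: kv[0].code)}
    return FrequencyTable(population, freqs, sample_count=len(sub))


@dataclass
class HWEResult:
    """Outcome of a Hardy–Weinberg equilibrium test at one locus."""

    locus: Locus
    chi2: float
    df: int
    p_value: float
    method: str
    pooled_categories: list[AlleleCategory] = field(default_factory=list)
    n: int = 0

    def summary(self) -> str:
        pooled = ", ".join(c.code for c in self.pooled_categories) or "none"
        return (
            f"HWE test ({self.method}) at {self.locus.value}: "
            f"chi2 = {self.chi2:.4f}, df = {self.df}, p = {self.p_value:.4g} "
            f"(N = {self.n}; pooled: {pooled})"
        )


def _pool(counts: dict[AlleleCategory, int], min_expected: float):
    """Pool rarest-first every category whose allele count is below the
    validity threshold; returns (category -> class index, k)."""
    ordered = sorted(counts.items(), key=lambda kv: (kv[1], kv[0].code))
    pooled = [cat for cat, c in ordered if c < min_expected]
    kept = [cat for cat, c in sorted(counts.items(), key=lambda kv: kv[0].code) if c >= min_expected]
    # A pooled class only exists if it absorbs at least one category; if it
    # absorbs everything but one, the test is degenerate.
    classes: dict[AlleleCategory, int] = {cat: i for i, cat in enumerate(kept)}
    k = len(kept) + (1 if pooled else 0)
    for cat in pooled:
        classes[cat] = k - 1
    return classes, k, pooled


def _chi2_statistic(genotype_counts: np.ndarray, class_counts: np.ndarray, n: int) -> float:
    """Chi-square over all unordered genotype classes of k pooled alleles.

    ``genotype_counts`` is a k×k symmetric matrix of observed genotype
    counts (each heterozygote counted once, split across [i,j] and [j,i]).
    """
    k = len(class_counts)
    p = class_counts / class_counts.sum()
    chi2 = 0.0
    for i, j in combinations_with_replacement(range(k), 2):
        obs = genotype_counts[i, j] if i == j else genotype_counts[i, j] + genotype_counts[j, i]
        exp = n * p[i] ** 2 if i == j else 2 * n * p[i] * p[j]
        if exp > 0:
            chi2 += (obs - exp) ** 2 / exp
    return chi2


def _genotype_matrix(pairs: np.ndarray, k: int) -> np.ndarray:
    mat = np.zeros((k, k))
    np.add.at(mat, (pairs[:, 0], pairs[:, 1]), 1.0)
    return mat


def hwe_test(
    dataset: GenotypeDataset,
    population: str,
    locus: Locus,
    min_expected: float = 5.0,
    method: str = "chi2_pooled",
    seed: int = DEFAULT_SEED,
    n_permutations: int = 2000,
) -> HWEResult:
    """Test deviation from Hardy–Weinberg proportions at one locus.

    ``min_expected`` is a threshold on allele copies: categories carried by
    fewer copies are pooled into a joint rare class before the genotype
    classes are formed. df = k(k−1)/2 for k post-pooling categories.

    ``method="monte_carlo_exact"`` keeps the same statistic but replaces the
    asymptotic reference distribution with permutations of the 2N observed
    allele copies into random pairs (seeded, hence reproducible).
    """
    if method not in ("chi2_pooled", "monte_carlo_exact"):
        raise HlaPopgenError(f"unknown HWE method {method!r}")
    sub = dataset.subset(population)
    n = len(sub)
    counts = _allele_counts(sub, locus)
    classes, k, pooled = _pool(counts, min_expected)
    if k < 2:
        raise DegenerateTestError(
            f"{population}/{locus.value}: fewer than two allele classes after pooling"
        )
    pairs = np.array(
        [[classes[a], classes[b]] for rec in sub for (a, b) in [rec.pair(locus)]],
        dtype=int,
    )
    pairs.sort(axis=1)
    class_counts = np.bincount(pairs.ravel(), minlength=k).astype(float)
    chi2 = _chi2_statistic(_genotype_matrix(pairs, k), class_counts, n)
    df = k * (k - 1) // 2
    if method == "chi2_pooled":
        p_value = float(stats.chi2.sf(chi2, df))
    else:
        rng = np.random.default_rng(seed)
        copies = pairs.ravel().copy()
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(copies).reshape(-1, 2)
            perm.sort(axis=1)
            stat = _chi2_statistic(_genotype_matrix(perm, k), class_counts, n)
            if stat >= chi2 - 1e-12:
                hits += 1
        p_value = (hits + 1) / (n_permutations + 1)
    return HWEResult(locus, float(chi2), df, p_value, method, pooled, n)


def composition_from_counts(counts: dict[str, int]) -> pd.DataFrame:
    """Population → (count, percent of total), percents to full precision."""
    total = sum(counts.values())
    if total <= 0:
        raise HlaPopgenError("composition requires a positive total count")
    return pd.DataFrame(
        {
            "population": list(counts),
            "count": list(counts.values()),
            "percent": [100.0 * c / total for c in counts.values()],
        }
    )


def population_composition(dataset: GenotypeDataset) -> pd.DataFrame:
    """Sample counts and percent shares per population label."""
    counts: dict[str, int] = {}
    for rec in dataset:
        counts[rec.population] = counts.get(rec.population, 0) + 1
    return composition_from_counts(counts)
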