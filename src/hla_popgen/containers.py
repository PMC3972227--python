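"""In-memory containers shared across the pipeline stages.

All frequencies are stored as proportions in [0, 1]; percent is purely a
presentation concern of the readers and writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import HlaPopgenError, MalformedRecordError
from .nomenclature import AlleleCategory, Locus

__all__ = [
    "AllelePair",
    "GenotypeRecord",
    "GenotypeDataset",
    "FrequencyTable",
    "Haplotype",
    "HaplotypeFrequencyTable",
    "DistanceMatrix",
    "LOCI",
]

#: Canonical locus order used everywhere.
LOCI: tuple[Locus, ...] = (Locus.A, Locus.B, Locus.DRB1)

AllelePair = tuple[AlleleCategory, AlleleCategory]


def _canonical_pair(pair: Sequence[AlleleCategory], locus: Locus) -> AllelePair:
    if len(pair) != 2:
        raise MalformedRecordError(f"locus {locus}: expected exactly two alleles")
    a, b = pair
    for cat in (a, b):
        if cat.locus is not locus:
            raise MalformedRecordError(
                f"allele {cat.code!r} does not belong to locus {locus}"
            )
    return (a, b) if a.code <= b.code else (b, a)


@dataclass(frozen=True)
class GenotypeRecord:
    """One donor's unphased typing: an unordered allele pair per locus."""

    sample_id: str
    population: str
    alleles: Mapping[Locus, AllelePair]

    def __post_init__(self) -> None:
        if set(self.alleles) != set(LOCI):
            raise MalformedRecordError(
                f"record {self.sample_id!r}: exactly the loci {[l.value for l in LOCI]} required"
            )
        canon = {loc: _canonical_pair(self.alleles[loc], loc) for loc in LOCI}
        object.__setattr__(self, "alleles", canon)

    def pair(self, locus: Locus) -> AllelePair:
        return self.alleles[locus]

    def is_heterozygous(self, locus: Locus) -> bool:
        a, b = self.alleles[locus]
        return a != b


class GenotypeDataset:
    """A non-empty collection of donors with unique sample ids."""

    def __init__(self, records: Sequence[GenotypeRecord]):
        records = list(records)
        if not records:
            raise MalformedRecordError("genotype dataset may not be empty")
        seen: set[str] = set()
        for rec in records:
            if rec.sample_id in seen:
                raise MalformedRecordError(f"duplicate sample_id {rec.sample_id!r}")
            seen.add(rec.sample_id)
        self.records: list[GenotypeRecord] = records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GenotypeRecord]:
        return iter(self.records)

    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        out: list[str] = []
        for rec in self.records:
            if rec.population not in out:
                out.append(rec.population)
        return out

    def subset(self, population: str) -> "GenotypeDataset":
        recs = [r for r in self.records if r.population == population]
        if not recs:
            raise HlaPopgenError(f"no records with population label {population!r}")
        return GenotypeDataset(recs)


@dataclass
class FrequencyTable:
    """Per-locus allele-category frequencies for one population.

    ``sample_count`` is the number of diploid individuals behind the
    estimates (None for transcribed literature tables whose N is external).
    """

    population: str
    freqs: dict[Locus, dict[AlleleCategory, float]]
    sample_count: int | None = None

    #: Printed tables sum to 1 only within rounding; counted ones exactly.
    SUM_TOL = 0.005

    def __post_init__(self) -> None:
        for locus, fr in self.freqs.items():
            for cat, v in fr.items():
                if cat.locus is not locus:
                    raise HlaPopgenError(f"category {cat.code!r} filed under locus {locus}")
                if v < 0:
                    raise HlaPopgenError(f"negative frequency for {cat.code!r}: {v}")
            total = sum(fr.values())
            if fr and abs(total - 1.0) > self.SUM_TOL:
                raise HlaPopgenError(
                    f"{self.population}/{locus}: frequencies sum to {total:.6f}, not 1"
                )

    def get(self, cat: AlleleCategory, default: float | None = 0.0) -> float:
        """Frequency of a category; absent categories read as ``default``."""
        fr = self.freqs.get(cat.locus, {})
        if cat in fr:
            return fr[cat]
        if default is None:
            raise KeyError(cat)
        return default

    def loci(self) -> list[Locus]:
        return [l for l in LOCI if l in self.freqs]

    def categories(self, locus: Locus) -> list[AlleleCategory]:
        return sorted(self.freqs.get(locus, {}), key=lambda c: c.code)

    def nonzero_categories(self, locus: Locus) -> list[AlleleCategory]:
        return [c for c in self.categories(locus) if self.freqs[locus][c] > 0]


@dataclass(frozen=True, order=True)
class Haplotype:
    """An A–B–DRB1 allele combination carried on one chromosome."""

    a: AlleleCategory
    b: AlleleCategory
    drb1: AlleleCategory

    def __post_init__(self) -> None:
        for cat, locus in zip((self.a, self.b, self.drb1), LOCI):
            if cat.locus is not locus:
                raise HlaPopgenError(
                    f"haplotype slot {locus} holds {cat.code!r} of locus {cat.locus}"
                )

    def allele(self, locus: Locus) -> AlleleCategory:
        return {Locus.A: self.a, Locus.B: self.b, Locus.DRB1: self.drb1}[locus]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.a.code, self.b.code, self.drb1.code)

    def __str__(self) -> str:
        return f"{self.a.code}-{self.b.code}-{self.drb1.code}"


class HaplotypeFrequencyTable:
    """Ordered haplotype → frequency map for one population.

    A complete (unfiltered) estimate sums to 1; filtered tables may sum
    below 1 but never meaningfully above.
    """

    def __init__(
        self,
        freqs: Mapping[Haplotype, float],
        population: str = "",
        n: int | None = None,
        sum_tol: float = 1e-9,
    ):
        for h, v in freqs.items():
            if v < 0:
                raise HlaPopgenError(f"negative haplotype frequency for {h}: {v}")
        total = sum(freqs.values())
        # sum_tol is 1e-9 for estimates; readers of print-rounded tables
        # pass a looser bound since rounded rows can overshoot 1
        if total > 1 + sum_tol:
            raise HlaPopgenError(f"haplotype frequencies sum to {total:.9f} > 1")
        self.freqs: dict[Haplotype, float] = dict(freqs)
        self.population = population
        self.n = n

    def __len__(self) -> int:
        return len(self.freqs)

    def __iter__(self) -> Iterator[Haplotype]:
        return iter(self.freqs)

    def items(self) -> Iterator[tuple[Haplotype, float]]:
        return iter(self.freqs.items())

    def get(self, h: Haplotype, default: float = 0.0) -> float:
        return self.freqs.get(h, default)

    def total(self) -> float:
        return sum(self.freqs.values())

    def marginal(self, locus: Locus) -> dict[AlleleCategory, float]:
        """Single-locus allele frequencies implied by the haplotype mass."""
        out: dict[AlleleCategory, float] = {}
        for h, v in self.freqs.items():
            cat = h.allele(locus)
            out[cat] = out.get(cat, 0.0) + v
        return out


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between labelled populations."""

    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise HlaPopgenError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise HlaPopgenError("duplicate population labels in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise HlaPopgenError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise HlaPopgenError("distance matrix diagonal is not zero")

    def get(self, x: str, y: str) -> float:
        return float(self.values[self.labels.index(x), self.labels.index(y)])
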