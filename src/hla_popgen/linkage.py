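"""Three-locus linkage disequilibrium.

For a haplotype h = (a, b, d) the global disequilibrium is

    Δ(h) = HF(h) − p(a)·p(b)·p(d),

the excess of the haplotype's frequency over what independent assortment of
its three alleles would predict. This raw Δ (not a normalized D′) is what
registry haplotype reports tabulate; summed over the complete haplotype
space it vanishes identically, which serves as a closure diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .containers import LOCI, FrequencyTable, Haplotype, HaplotypeFrequencyTable
from .errors import InconsistentInputError

__all__ = ["LDRecord", "three_locus_delta", "delta_closure_check"]


@dataclass(frozen=True)
class LDRecord:
    """A haplotype with its frequency and disequilibrium."""

    haplotype: Haplotype
    hf: float
    delta: float

    @property
    def delta_percent(self) -> float:
        return 100.0 * self.delta


def _marginal_product(h: Haplotype, freqs: FrequencyTable) -> float:
    prod = 1.0
    for locus in LOCI:
        cat = h.allele(locus)
        try:
            prod *= freqs.get(cat, default=None)
        except KeyError:
            raise InconsistentInputError(
                f"allele {cat.code!r} of haplotype {h} is absent from the "
                f"{freqs.population!r} frequency table"
            ) from None
    return prod


def three_locus_delta(
    hf_table: HaplotypeFrequencyTable, freqs: FrequencyTable
) -> list[LDRecord]:
    """Δ for every haplotype of the table, in table order.

    Every allele of every haplotype must exist in the frequency table (a
    frequency of zero is fine; a missing category is an inconsistency).
    """
    return [
        LDRecord(h, hf, hf - _marginal_product(h, freqs))
        for h, hf in hf_table.items()
    ]


def delta_closure_check(
    full_hf_table: HaplotypeFrequencyTable, freqs: FrequencyTable
) -> float:
    """Σ Δ over the complete haplotype space implied by the frequency table.

    Analytically zero whenever the haplotype table sums to 1 and each locus's
    frequencies sum to 1; numerically ~1e-9. Haplotypes absent from the table
    enter with HF 0 (and hence negative Δ).
    """
    total = 0.0
    for a, b, d in product(
        freqs.categories(LOCI[0]), freqs.categories(LOCI[1]), freqs.categories(LOCI[2])
    ):
        h = Haplotype(a, b, d)
        total += full_hf_table.get(h, 0.0) - freqs.get(a) * freqs.get(b) * freqs.get(d)
    return total
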