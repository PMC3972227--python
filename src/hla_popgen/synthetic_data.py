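"""Registry-like genotype simulation with known ground truth.

The generative model is random mating at the haplotype level: each diploid
individual receives two haplotypes drawn i.i.d. from a specified three-locus
haplotype frequency vector, and only the per-locus unordered allele pairs
are recorded (phase is discarded, exactly the information loss the EM
estimator must undo). Within-haplotype linkage disequilibrium is carried
entirely by the generator frequencies; between an individual's two
haplotypes there is none, matching the Hardy–Weinberg assumption under
which the downstream estimators operate.

The module also exposes the packaged transcriptions of the study's printed
tables (donor composition, per-ethnicity allele frequencies, the top-50 Han
haplotypes with their disequilibria), checksum-guarded so silent fixture
corruption cannot propagate into analyses.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .allele_stats import DEFAULT_SEED
from .containers import (
    LOCI,
    FrequencyTable,
    GenotypeDataset,
    GenotypeRecord,
    Haplotype,
    HaplotypeFrequencyTable,
)
from .errors import FixtureChecksumError, HlaPopgenError
from .io import read_frequency_table, read_haplotype_table

__all__ = [
    "SimulationSpec",
    "sample_genotypes",
    "make_paper_fixtures",
    "PaperFixtures",
    "han_truth_table",
]

#: SHA-256 of the packaged reference tables (texts are versioned data).
_FIXTURE_SHA256 = {
    "liaoning_composition.tsv": "8da925e4c7b956210898571eff7e68e5c0a687478d01e03df6a20f7361bbbef7",
    "liaoning_allele_frequencies.tsv": "382921fda5178ef49f14ff1f11d9b8046bee4db31d094f65871d745603e57b40",
    "han_top50_haplotypes.tsv": "1b48c6f08ef98259d3c291f69b0f768910df4e0769e73c83a537f4a1268d5ee3",
}


@dataclass
class SimulationSpec:
    """Ground truth and sampling plan for one simulated registry sample.

    ``noise_floor`` moves that much total probability mass from the truth
    haplotypes onto a uniform cloud of extra rare haplotypes obtained by
    cyclically permuting alleles across loci of the truth set — a stress
    test for frequency filters that invents no new alleles.
    """

    haplotype_freqs: HaplotypeFrequencyTable
    n_individuals: int
    population_label: str = "Sim"
    seed: int = DEFAULT_SEED
    noise_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise HlaPopgenError("n_individuals must be >= 1")
        if len(self.haplotype_freqs) == 0:
            raise HlaPopgenError("generator haplotype table may not be empty")
        if not 0.0 <= self.noise_floor < 1.0:
            raise HlaPopgenError("noise_floor must lie in [0, 1)")


def _noise_haplotypes(truth: list[Haplotype]) -> list[Haplotype]:
    """Rare-haplotype cloud: shift the B column by 1 and the DRB1 column by
    2 across the sorted truth set; drop any collision with the truth."""
    k = len(truth)
    seen = set(truth)
    out = []
    for i in range(k):
        h = Haplotype(truth[i].a, truth[(i + 1) % k].b, truth[(i + 2) % k].drb1)
        if h not in seen:
            out.append(h)
            seen.add(h)
    return out


def _generator_distribution(spec: SimulationSpec) -> tuple[list[Haplotype], np.ndarray]:
    truth = sorted(spec.haplotype_freqs, key=lambda h: h.key)
    probs = np.array([spec.haplotype_freqs.get(h) for h in truth], dtype=float)
    if probs.sum() <= 0:
        raise HlaPopgenError("generator frequencies sum to zero")
    probs = probs / probs.sum()
    if spec.noise_floor > 0:
        noise = _noise_haplotypes(truth)
        if noise:
            probs = probs * (1.0 - spec.noise_floor)
            truth = truth + noise
            probs = np.concatenate([probs, np.full(len(noise), spec.noise_floor / len(noise))])
    return truth, probs


def sample_genotypes(spec: SimulationSpec) -> GenotypeDataset:
    """Draw 2·n haplotypes i.i.d. and record unphased genotypes.

    Sampling is inverse-CDF over the canonically sorted haplotype list, so a
    fixed seed gives a bit-stable dataset across platforms.
    """
    haps, probs = _generator_distribution(spec)
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    rng = np.random.default_rng(spec.seed)
    draws = np.searchsorted(cdf, rng.random(2 * spec.n_individuals), side="right")
    width = len(str(spec.n_individuals))
    records = []
    for i in range(spec.n_individuals):
        h1, h2 = haps[draws[2 * i]], haps[draws[2 * i + 1]]
        alleles = {locus: (h1.allele(locus), h2.allele(locus)) for locus in LOCI}
        records.append(
            GenotypeRecord(f"{spec.population_label}-{i + 1:0{width}d}", spec.population_label, alleles)
        )
    return GenotypeDataset(records)


@dataclass
class PaperFixtures:
    """The packaged study tables: composition counts, per-population allele
    frequencies, and the top-50 Han haplotypes with printed LD (percent)."""

    composition: dict[str, int]
    frequencies: dict[str, FrequencyTable]
    han_haplotypes: HaplotypeFrequencyTable
    han_ld_percent: dict[Haplotype, float]


def _fixture_path(name: str) -> Path:
    return resources.files("hla_popgen.data") / name


def _check_fixture(name: str) -> Path:
    path = _fixture_path(name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    expected = _FIXTURE_SHA256[name]
    if expected is not None and digest != expected:
        raise FixtureChecksumError(
            f"packaged table {name} has checksum {digest[:12]}…, expected {expected[:12]}…"
        )
    return Path(str(path))


def make_paper_fixtures() -> PaperFixtures:
    """Load (and checksum-verify) the packaged study tables."""
    comp_df = pd.read_csv(_check_fixture("liaoning_composition.tsv"), sep="\t")
    composition = dict(zip(comp_df["population"], comp_df["count"].astype(int)))

    frequencies = read_frequency_table(_check_fixture("liaoning_allele_frequencies.tsv"))
    sample_n = {k: v for k, v in composition.items() if k in frequencies}
    for pop, n in sample_n.items():
        frequencies[pop].sample_count = n

    hap_path = _check_fixture("han_top50_haplotypes.tsv")
    han = read_haplotype_table(hap_path, population="Han", n=composition.get("Han"))
    ld_df = pd.read_csv(hap_path, sep="\t")
    ld = {}
    for h, (_, row) in zip(han, ld_df.iterrows()):
        ld[h] = float(row["ld_percent"])
    return PaperFixtures(composition, frequencies, han, ld)


def han_truth_table(top_n: int = 20) -> HaplotypeFrequencyTable:
    """The top-``top_n`` Han haplotypes, renormalized to a proper
    distribution — the standard ground truth for recovery experiments."""
    fx = make_paper_fixtures()
    rows = sorted(fx.han_haplotypes.items(), key=lambda kv: (-kv[1], kv[0].key))[:top_n]
    total = sum(v for _, v in rows)
    return HaplotypeFrequencyTable(
        {h: v / total for h, v in rows}, population="Han", n=fx.han_haplotypes.n
    )
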