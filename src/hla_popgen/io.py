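"""Readers and writers for the pipeline's delimited-text formats.

Tab and comma delimiters are both accepted on input (auto-detected from the
header line); writers always emit tab-separated text. Frequency tables are
percent on disk and proportions in memory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    LOCI,
    DistanceMatrix,
    FrequencyTable,
    GenotypeDataset,
    GenotypeRecord,
    Haplotype,
    HaplotypeFrequencyTable,
)
from .errors import HlaPopgenError, MalformedRecordError
from .nomenclature import (
    UNKNOWN_CODE,
    AlleleCategory,
    Locus,
    SerologyMap,
    normalize_allele,
)

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_frequency_table",
    "write_frequency_table",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_phylip_lower_triangle",
]

GENOTYPE_COLUMNS = ["sample_id", "population", "A_1", "A_2", "B_1", "B_2", "DRB1_1", "DRB1_2"]


def _detect_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _fmt(x: float) -> str:
    """Compact float formatting that survives a read/write round trip."""
    return np.format_float_positional(x, precision=12, trim="-")


def read_genotype_table(path: str | Path, mapping: SerologyMap) -> GenotypeDataset:
    """Read donor typings; every allele cell goes through ``normalize_allele``.

    Row order is preserved. Duplicated sample ids, missing columns and empty
    cells are hard errors naming the offending row.
    """
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedRecordError(f"{path}: missing column(s) {missing}")
    records: list[GenotypeRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        alleles: dict[Locus, tuple[AlleleCategory, AlleleCategory]] = {}
        for locus in LOCI:
            pair = []
            for slot in (f"{locus.value}_1", f"{locus.value}_2"):
                raw = row[slot]
                if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                    raise MalformedRecordError(f"{path} line {idx}: empty cell in {slot}")
                raw = str(raw).strip()
                if raw == UNKNOWN_CODE:
                    pair.append(AlleleCategory.from_code(raw, locus))
                else:
                    pair.append(normalize_allele(raw, mapping))
            alleles[locus] = (pair[0], pair[1])
        try:
            records.append(
                GenotypeRecord(str(row["sample_id"]), str(row["population"]), alleles)
            )
        except MalformedRecordError as e:
            raise MalformedRecordError(f"{path} line {idx}: {e}") from e
    return GenotypeDataset(records)


def write_genotype_table(dataset: GenotypeDataset, path: str | Path) -> None:
    rows = []
    for rec in dataset:
        row = {"sample_id": rec.sample_id, "population": rec.population}
        for locus in LOCI:
            a, b = rec.pair(locus)
            row[f"{locus.value}_1"], row[f"{locus.value}_2"] = a.code, b.code
        rows.append(row)
    pd.DataFrame(rows, columns=GENOTYPE_COLUMNS).to_csv(path, sep="\t", index=False)


def _locus_of_label(label: str, previous: Locus | None) -> Locus:
    if label == UNKNOWN_CODE:
        # The registry table prints its single untypable allele in the HLA-A
        # block; an Unknown row inherits the locus of the preceding row.
        return previous if previous is not None else Locus.A
    return AlleleCategory.from_code(label).locus


def read_frequency_table(path: str | Path) -> dict[str, FrequencyTable]:
    """Read a percent-valued allele × population table.

    Absent (blank) cells read as frequency 0. Returns one table per
    population column, in column order.
    """
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    if df.columns[0] != "allele":
        raise HlaPopgenError(f"{path}: first column must be 'allele'")
    pops = list(df.columns[1:])
    freqs: dict[str, dict[Locus, dict[AlleleCategory, float]]] = {
        p: {l: {} for l in LOCI} for p in pops
    }
    prev: Locus | None = None
    for _, row in df.iterrows():
        label = str(row["allele"]).strip()
        locus = _locus_of_label(label, prev)
        prev = locus
        cat = AlleleCategory.from_code(label, locus)
        for p in pops:
            cell = row[p]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                value = 0.0
            else:
                value = float(cell) / 100.0
            if value < 0:
                raise HlaPopgenError(f"{path}: negative frequency for {label} in {p}")
            if cat in freqs[p][locus]:
                raise HlaPopgenError(f"{path}: duplicate category {label} for {p}")
            freqs[p][locus][cat] = value
    return {
        p: FrequencyTable(p, {l: fr for l, fr in freqs[p].items() if fr})
        for p in pops
    }


def write_frequency_table(tables: Mapping[str, FrequencyTable], path: str | Path) -> None:
    """Write tables as percent; rows are the union of categories, in locus
    order then code order."""
    pops = list(tables)
    rows: list[AlleleCategory] = []
    for locus in LOCI:
        cats: set[AlleleCategory] = set()
        for t in tables.values():
            cats.update(t.freqs.get(locus, {}))
        rows.extend(sorted(cats, key=lambda c: (c.code == UNKNOWN_CODE, c.code)))
    with open(path, "w") as fh:
        fh.write("allele\t" + "\t".join(pops) + "\n")
        for cat in rows:
            cells = [_fmt(tables[p].get(cat) * 100.0) for p in pops]
            fh.write(cat.code + "\t" + "\t".join(cells) + "\n")


def read_haplotype_table(path: str | Path, population: str = "", n: int | None = None) -> HaplotypeFrequencyTable:
    """Read an ``A B DRB1 frequency`` table (proportions); extra columns are
    ignored. Row order is preserved."""
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    for col in ("A", "B", "DRB1", "frequency"):
        if col not in df.columns:
            raise HlaPopgenError(f"{path}: missing column {col!r}")
    freqs: dict[Haplotype, float] = {}
    for _, row in df.iterrows():
        h = Haplotype(
            AlleleCategory.from_code(str(row["A"]).strip(), Locus.A),
            AlleleCategory.from_code(str(row["B"]).strip(), Locus.B),
            AlleleCategory.from_code(str(row["DRB1"]).strip(), Locus.DRB1),
        )
        if h in freqs:
            raise HlaPopgenError(f"{path}: duplicate haplotype {h}")
        freqs[h] = float(row["frequency"])
    return HaplotypeFrequencyTable(freqs, population=population, n=n, sum_tol=0.005)


def write_haplotype_table(table: HaplotypeFrequencyTable, path: str | Path, decimals: int = 4) -> None:
    """Write haplotype frequencies rounded to table precision (4 decimals by
    default, matching the print convention of registry reports)."""
    with open(path, "w") as fh:
        fh.write("A\tB\tDRB1\tfrequency\n")
        for h, v in table.items():
            fh.write(f"{h.a.code}\t{h.b.code}\t{h.drb1.code}\t{v:.{decimals}f}\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise HlaPopgenError(f"{path}: row and column labels differ")
    return DistanceMatrix(labels, df.to_numpy(dtype=float))


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(d.labels) + "\n")
        for i, lab in enumerate(d.labels):
            fh.write(lab + "\t" + "\t".join(_fmt(v) for v in d.values[i]) + "\n")


def write_phylip_lower_triangle(d: DistanceMatrix, path: str | Path) -> None:
    """Lower-triangle PHYLIP distance format (names padded to 10 columns)."""
    with open(path, "w") as fh:
        fh.write(f"{len(d.labels):5d}\n")
        for i, lab in enumerate(d.labels):
            name = (lab[:10]).ljust(10)
            cells = " ".join(f"{d.values[i, j]:.6f}" for j in range(i))
            fh.write(name + (" " + cells if cells else "") + "\n")
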