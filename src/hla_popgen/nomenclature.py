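"""HLA allele nomenclature at first-field ("allele group") resolution.

Registry typing at intermediate resolution is consolidated to allele groups
(``A*02``, ``DRB1*09``), except for the B14, B15 and B40 families, which are
kept at the level of their serological splits (``B*14(64)``, ``B*15(62)``,
``B*40(60)`` ...) because the groups lump serologically distinct antigens.
Split assignments are reference knowledge and ship as a user-extensible
table; a B14/B15/B40 allele absent from the table is an error, never a
silent truncation.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import AlleleFormatError, UnmappedAlleleError

__all__ = [
    "Locus",
    "AlleleCategory",
    "SerologyMap",
    "normalize_allele",
    "default_serology_map",
]


class Locus(str, Enum):
    """The three classical loci typed by donor registries."""

    A = "A"
    B = "B"
    DRB1 = "DRB1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: ``LOCUS*GG`` or ``LOCUS*GG(SS)``: two-digit allele group, optional
#: two-digit serological split.
_CATEGORY_RE = re.compile(r"^(A|B|DRB1)\*(\d{2})(?:\((\d{2})\))?$")

#: Full resolution, colon-delimited: ``B*15:01``, ``A*02:07:01`` ...
_FULLRES_RE = re.compile(r"^(A|B|DRB1)\*(\d{2,3}(?::\d{2,3})+)$")

#: Legacy concatenated-digit notation: ``B*1501``, ``DRB1*0301``.
_LEGACY_RE = re.compile(r"^(A|B|DRB1)\*(\d{4,5})$")

#: B groups kept at serological-split resolution.
SPLIT_GROUPS = frozenset({"14", "15", "40"})

UNKNOWN_CODE = "Unknown"


@dataclass(frozen=True, order=True)
class AlleleCategory:
    """One row label of a consolidated frequency table.

    ``code`` follows the grammar ``LOCUS*GG`` / ``LOCUS*GG(SS)``, or is the
    literal ``"Unknown"`` (a first-class category: the registry table prints
    one untypable allele).
    """

    locus: Locus
    code: str

    def __post_init__(self) -> None:
        if self.code == UNKNOWN_CODE:
            return
        m = _CATEGORY_RE.match(self.code)
        if m is None:
            raise AlleleFormatError(f"not a valid allele category: {self.code!r}")
        if m.group(1) != self.locus.value:
            raise AlleleFormatError(
                f"category {self.code!r} does not belong to locus {self.locus}"
            )

    @classmethod
    def from_code(cls, code: str, locus: Locus | None = None) -> "AlleleCategory":
        """Build a category from its code, inferring the locus when embedded.

        ``"Unknown"`` carries no locus of its own and requires an explicit one.
        Outside the serologically split B families, a redundant split equal
        to its own group (legacy ``B*51(51)``) is canonicalized to the bare
        group; inside them, ``B*40(40)`` and ``B*40`` are distinct
        categories (split-typed antigen vs. unresolved broad group).
        """
        code = code.strip()
        if code == UNKNOWN_CODE:
            if locus is None:
                raise AlleleFormatError("'Unknown' category requires an explicit locus")
            return cls(locus, UNKNOWN_CODE)
        m = _CATEGORY_RE.match(code)
        if m is None:
            raise AlleleFormatError(f"not a valid allele category: {code!r}")
        loc = Locus(m.group(1))
        if locus is not None and locus is not loc:
            raise AlleleFormatError(f"category {code!r} is not at locus {locus}")
        group, split = m.group(2), m.group(3)
        if (
            split is not None
            and split == group
            and not (loc is Locus.B and group in SPLIT_GROUPS)
        ):
            code = f"{loc.value}*{group}"
        return cls(loc, code)

    @property
    def group(self) -> str | None:
        """Two-digit allele group, or None for ``Unknown``."""
        m = _CATEGORY_RE.match(self.code)
        return m.group(2) if m else None

    def __str__(self) -> str:
        return self.code


def _looks_like_category(raw: str) -> bool:
    return raw == UNKNOWN_CODE or _CATEGORY_RE.match(raw) is not None


def _split_fullres(raw: str) -> tuple[Locus, str, str]:
    """Parse a full-resolution allele; returns (locus, group, two-field key)."""
    m = _FULLRES_RE.match(raw)
    if m is not None:
        locus = Locus(m.group(1))
        fields = m.group(2).split(":")
        group = fields[0][:2] if len(fields[0]) <= 3 else fields[0]
        key = f"{locus.value}*{fields[0]}:{fields[1]}"
        return locus, group, key
    m = _LEGACY_RE.match(raw)
    if m is not None:
        locus = Locus(m.group(1))
        digits = m.group(2)
        group = digits[:2]
        key = f"{locus.value}*{digits[:2]}:{digits[2:]}"
        return locus, group, key
    raise AlleleFormatError(f"unparseable allele string: {raw!r}")


@dataclass(frozen=True)
class SerologyMap:
    """Total map from B14/B15/B40 full-resolution alleles to split categories.

    Lookups outside the map fail loudly: serological equivalences are
    reference knowledge, and guessing a split would corrupt every downstream
    frequency.
    """

    entries: Mapping[str, AlleleCategory]

    def __post_init__(self) -> None:
        for raw, cat in self.entries.items():
            if not isinstance(cat, AlleleCategory):
                raise AlleleFormatError(f"mapping value for {raw!r} is not a category")

    def lookup(self, two_field_key: str) -> AlleleCategory:
        try:
            return self.entries[two_field_key]
        except KeyError:
            raise UnmappedAlleleError(
                f"{two_field_key!r} belongs to a serologically split B group but has "
                "no split assignment; extend the serology map rather than truncating"
            ) from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SerologyMap":
        entries: dict[str, AlleleCategory] = {}
        with open(path, newline="") as fh:
            rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
        header, *body = rows
        if header[:2] != ["allele", "category"]:
            raise AlleleFormatError(f"serology map {path}: expected header 'allele\\tcategory'")
        for row in body:
            entries[row[0].strip()] = AlleleCategory.from_code(row[1].strip())
        return cls(entries)


def default_serology_map() -> SerologyMap:
    """The packaged WHO split assignments for common B14/B15/B40 alleles."""
    with resources.as_file(resources.files("hla_popgen.data") / "serology_map.tsv") as p:
        return SerologyMap.from_tsv(p)


def normalize_allele(raw: str, mapping: SerologyMap) -> AlleleCategory:
    """Consolidate one allele call to its analysis category.

    Already-consolidated codes pass through unchanged (the operation is
    idempotent, modulo canonicalization of redundant splits). Full-resolution
    calls are truncated to their first field, except B14/B15/B40 alleles,
    which are resolved through ``mapping`` — the map is consulted before any
    truncation, and a missing entry raises rather than degrading silently.
    """
    raw = raw.strip()
    if _looks_like_category(raw):
        if raw == UNKNOWN_CODE:
            raise AlleleFormatError(
                "'Unknown' cannot be normalized without a locus; construct it directly"
            )
        return AlleleCategory.from_code(raw)
    locus, group, key = _split_fullres(raw)
    if locus is Locus.B and group in SPLIT_GROUPS:
        return mapping.lookup(key)
    return AlleleCategory.from_code(f"{locus.value}*{group}")
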