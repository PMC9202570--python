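"""Deterministic ICD-O-3 -> ICCC third-edition recoding.

ICCC (International Classification of Childhood Cancer) groups are not
abstracted directly by registries; they are recoded from the ICD-O-3
topography (site), morphology (histology), and behavior codes through
published lookup tables. This module implements that lookup: a rule table
maps (site, histology, behavior) triples to one of the 46 subgroups, with
"999" ("Not classified by SEER or in situ") as the fallback for triples no
rule covers. It also implements the CCDI eligibility filter that admits
age-20-39 cases of eight pediatric-type subgroups into training corpora.

A synthetic fixture table bundled with the package (not the licensed SEER
table) provides at least one rule per subgroup so the full pipeline runs
self-contained; a user-supplied table in the same CSV schema is accepted
everywhere a table is taken.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .reference import CCDI_AUGMENT_COUNTS, SUBGROUP_CODES

__all__ = [
    "ICDO3Code",
    "RecodeRule",
    "RecodeTable",
    "RecodeTableError",
    "CCDI_SUBGROUPS",
    "CCDI_AGE_MIN",
    "CCDI_AGE_MAX",
    "load_recode_table",
    "fixture_table_path",
    "recode",
    "main_group_of",
    "ccdi_filter",
]

_SITE_RE = re.compile(r"^C(\d{2})\.(\d)$")

#: The eight subgroups the CCDI advisory group regards as pediatric up to
#: age 39 (nephroblastoma, hepatoblastoma, the five malignant-bone-tumor
#: subgroups, rhabdomyosarcoma).
CCDI_SUBGROUPS: frozenset[str] = frozenset(CCDI_AUGMENT_COUNTS)
CCDI_AGE_MIN = 20
CCDI_AGE_MAX = 39

_ALL_BEHAVIORS = frozenset(range(7))


class RecodeTableError(ValueError):
    """Raised for malformed or (in strict mode) ambiguous rule tables."""


def _site_value(site: str) -> int:
    """Topography string "Cdd.d" -> integer tenths (C40.2 -> 402)."""
    m = _SITE_RE.match(site)
    if m is None:
        raise ValueError(f"invalid topography code {site!r}; expected 'Cdd.d'")
    value = int(m.group(1)) * 10 + int(m.group(2))
    if not 0 <= value <= 809:
        raise ValueError(f"topography {site!r} outside C00.0-C80.9")
    return value


def _site_string(value: int) -> str:
    return f"C{value // 10:02d}.{value % 10}"


@dataclass(frozen=True)
class ICDO3Code:
    """An ICD-O-3 coding triple: topography, 4-digit morphology, behavior."""

    site: str
    histology: int
    behavior: int

    def __post_init__(self) -> None:
        _site_value(self.site)  # validates the pattern and range
        if not 8000 <= int(self.histology) <= 9999:
            raise ValueError(f"histology {self.histology} outside 8000-9999")
        if not 0 <= int(self.behavior) <= 6:
            raise ValueError(f"behavior {self.behavior} outside 0-6")

    @property
    def site_value(self) -> int:
        return _site_value(self.site)


def _parse_int_spec(spec: str, what: str) -> tuple[tuple[int, int], ...]:
    """Parse "9180-9189;9250" into inclusive integer intervals."""
    intervals: list[tuple[int, int]] = []
    for part in spec.split(";"):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo_s, hi_s = part.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(part)
        if lo > hi:
            raise ValueError(f"{what} range {part!r} has low > high")
        intervals.append((lo, hi))
    if not intervals:
        raise ValueError(f"empty {what} specification")
    return tuple(intervals)


def _parse_site_spec(spec: str) -> tuple[tuple[int, int], ...]:
    """Parse "C40.0-C41.9;C76.0" into inclusive intervals of site tenths."""
    intervals: list[tuple[int, int]] = []
    for part in spec.split(";"):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo_s, hi_s = part.split("-", 1)
            lo, hi = _site_value(lo_s.strip()), _site_value(hi_s.strip())
        else:
            lo = hi = _site_value(part)
        if lo > hi:
            raise ValueError(f"site range {part!r} has low > high")
        intervals.append((lo, hi))
    if not intervals:
        raise ValueError("empty site specification")
    return tuple(intervals)


def _parse_behavior_spec(spec: str) -> frozenset[int]:
    spec = spec.strip()
    if not spec:
        return _ALL_BEHAVIORS
    values: set[int] = set()
    for lo, hi in _parse_int_spec(spec, "behavior"):
        if not (0 <= lo and hi <= 6):
            raise ValueError(f"behavior spec {spec!r} outside 0-6")
        values.update(range(lo, hi + 1))
    return frozenset(values)


def _in_intervals(value: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(lo <= value <= hi for lo, hi in intervals)


def _intervals_intersect(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> bool:
    return any(alo <= bhi and blo <= ahi for alo, ahi in a for blo, bhi in b)


@dataclass(frozen=True)
class RecodeRule:
    """One table row: the ICD-O-3 combinations assigned to one subgroup.

    ``histology_set`` and ``site_set`` are inclusive integer intervals
    (sites in tenths, C40.2 -> 402); an empty ``behavior_set`` in the CSV
    means any behavior 0-6.
    """

    iccc_subgroup: str
    histology_set: tuple[tuple[int, int], ...]
    site_set: tuple[tuple[int, int], ...]
    behavior_set: frozenset[int] = _ALL_BEHAVIORS

    def __post_init__(self) -> None:
        if self.iccc_subgroup not in SUBGROUP_CODES:
            raise ValueError(
                f"unknown ICCC subgroup {self.iccc_subgroup!r}"
            )

    def matches(self, code: ICDO3Code) -> bool:
        return (
            int(code.histology) in range(8000, 10000)
            and _in_intervals(int(code.histology), self.histology_set)
            and _in_intervals(code.site_value, self.site_set)
            and int(code.behavior) in self.behavior_set
        )

    # enumeration helpers used by the synthetic corpus generator
    def histology_values(self) -> list[int]:
        return [v for lo, hi in self.histology_set for v in range(lo, hi + 1)]

    def site_values(self) -> list[str]:
        return [
            _site_string(v)
            for lo, hi in self.site_set
            for v in range(lo, hi + 1)
        ]

    def behavior_values(self) -> list[int]:
        return sorted(self.behavior_set)


@dataclass
class RecodeTable:
    """Ordered rule list; first matching rule wins.

    In strict mode (checked at load time) no two rules carrying different
    subgroups may match the same triple, so first-match order is
    immaterial for the bundled fixture.
    """

    rules: list[RecodeRule]
    version_label: str = ""

    def __post_init__(self) -> None:
        if not self.rules:
            raise RecodeTableError("no rules")
        self._by_subgroup: dict[str, list[RecodeRule]] = {}
        for rule in self.rules:
            self._by_subgroup.setdefault(rule.iccc_subgroup, []).append(rule)

    def rules_for(self, subgroup: str) -> list[RecodeRule]:
        return list(self._by_subgroup.get(subgroup, []))

    @property
    def subgroups(self) -> list[str]:
        return sorted(self._by_subgroup)

    def validate_strict(self) -> None:
        """Reject tables where rules of different subgroups overlap."""
        for i, a in enumerate(self.rules):
            for j in range(i + 1, len(self.rules)):
                b = self.rules[j]
                if a.iccc_subgroup == b.iccc_subgroup:
                    continue
                if (
                    _intervals_intersect(a.histology_set, b.histology_set)
                    and _intervals_intersect(a.site_set, b.site_set)
                    and a.behavior_set & b.behavior_set
                ):
                    raise RecodeTableError(
                        f"rules {i + 1} ({a.iccc_subgroup}) and "
                        f"{j + 1} ({b.iccc_subgroup}) both match some "
                        "(site, histology, behavior) triple"
                    )


def load_recode_table(
    path: str | Path, *, strict: bool = True, version_label: str | None = None
) -> RecodeTable:
    """Load and validate a recode-rule CSV.

    Schema: header ``iccc_subgroup,histology_spec,site_spec,behavior_spec``
    where the specs are semicolon-separated values or inclusive ``lo-hi``
    ranges (sites written as ``C40.0-C41.9``); an empty behavior spec
    accepts any behavior.
    """
    path = Path(path)
    rules: list[RecodeRule] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) < {
            "iccc_subgroup",
            "histology_spec",
            "site_spec",
        }:
            raise RecodeTableError(
                f"{path}: no rules (missing or malformed header)"
            )
        for row in reader:
            line = reader.line_num
            try:
                rules.append(
                    RecodeRule(
                        iccc_subgroup=row["iccc_subgroup"].strip(),
                        histology_set=_parse_int_spec(
                            row["histology_spec"], "histology"
                        ),
                        site_set=_parse_site_spec(row["site_spec"]),
                        behavior_set=_parse_behavior_spec(
                            row.get("behavior_spec") or ""
                        ),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise RecodeTableError(f"{path}, line {line}: {exc}") from exc
    if not rules:
        raise RecodeTableError(f"{path}: no rules")
    table = RecodeTable(
        rules, version_label=version_label if version_label is not None else path.name
    )
    if strict:
        table.validate_strict()
    return table


def fixture_table_path() -> Path:
    """Path of the bundled synthetic fixture rule table."""
    return Path(resources.files("icccml.data") / "recode_fixture.csv")


_FIXTURE_CACHE: RecodeTable | None = None


def fixture_table() -> RecodeTable:
    """The bundled synthetic fixture table (cached)."""
    global _FIXTURE_CACHE
    if _FIXTURE_CACHE is None:
        _FIXTURE_CACHE = load_recode_table(fixture_table_path())
    return _FIXTURE_CACHE


def recode(code: ICDO3Code, table: RecodeTable) -> str:
    """Map an ICD-O-3 triple to its ICCC subgroup; "999" if no rule matches."""
    for rule in table.rules:
        if rule.matches(code):
            return rule.iccc_subgroup
    return "999"


def main_group_of(iccc_subgroup: str) -> str:
    """Main group of a subgroup ("011" -> "01"); "999" is its own group."""
    if iccc_subgroup == "999":
        return "999"
    if iccc_subgroup not in SUBGROUP_CODES:
        raise ValueError(f"unknown ICCC subgroup {iccc_subgroup!r}")
    return iccc_subgroup[:2]


def ccdi_filter(
    records: Iterable[tuple[str, int]]
) -> list[tuple[str, int]]:
    """Records (subgroup, age) eligible for CCDI training augmentation.

    Keeps, in order, records aged 20-39 whose subgroup is one of the eight
    CCDI pediatric-type codes.
    """
    return [
        (subgroup, age)
        for subgroup, age in records
        if subgroup in CCDI_SUBGROUPS and CCDI_AGE_MIN <= age <= CCDI_AGE_MAX
    ]
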