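"""Core domain types shared across the pipeline.

A spontaneous report (:class:`CaseReport`) carries the demographics, suspect
and concomitant drugs, MedDRA reaction preferred terms (PTs), and regulatory
outcomes of one submitted case. Disproportionality works on report-level
2x2 tables (:class:`ContingencyTable`), and screening decisions are recorded
per drug-PT pair in :class:`SignalRecord`.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

#: The five long-acting GnRH analogs under study (active-moiety keywords).
STUDY_DRUGS = ("leuprolide", "goserelin", "histrelin", "buserelin", "triptorelin")

AGE_GROUPS = ("<=18", "19-45", "46-60", "61-80", ">80", "unknown")
SEXES = ("female", "male", "unknown")
ROLE_CODES = ("primary_suspect", "secondary_suspect", "concomitant", "interacting")
OUTCOMES = (
    "death",
    "hospitalization",
    "life_threatening",
    "disability",
    "congenital_anomaly",
    "required_intervention",
    "other",
)

#: MedDRA system organ classes excluded from signal tables because their
#: members are generally unrelated to drug pharmacology or disease progression
#: (administration-site noise, procedural artifacts, lab-test terms, ...).
DEFAULT_EXCLUDED_SOCS = (
    "General disorders and administration site conditions",
    "Product issues",
    "Social circumstances",
    "Investigations",
    "Injury, poisoning and procedural complications",
    "Congenital, familial and genetic disorders",
    "Surgical and medical procedures",
)

EXCLUSION_REASONS = (
    "none",
    "below_min_n",
    "ci_includes_1",
    "ic025_nonpositive",
    "excluded_soc",
    "unmapped_soc",
    "duplicate_pt",
    "chi2_below_threshold",
)

_WS = re.compile(r"\s+")


def norm_term(term: str) -> str:
    """Whitespace-collapse and casefold a MedDRA term for matching."""
    return _WS.sub(" ", term.strip()).casefold()


def age_group_of(age_years: float | None) -> str:
    """Bin an age in years into the study's age strata.

    Bin edges follow the report-age strata used for spontaneous-report
    demographics: <=18, 19-45, 46-60, 61-80, >80, with missing age mapping
    to "unknown".
    """
    if age_years is None:
        return "unknown"
    if age_years < 0:
        raise ValueError(f"negative age: {age_years}")
    if age_years <= 18:
        return "<=18"
    if age_years <= 45:
        return "19-45"
    if age_years <= 60:
        return "46-60"
    if age_years <= 80:
        return "61-80"
    return ">80"


class AmbiguousDrugNameError(ValueError):
    """Raised when two distinct keywords both match one raw drug string."""


class DegenerateTableError(ValueError):
    """Raised when a 2x2 statistic is undefined without continuity correction."""


class EmptyExposureError(ValueError):
    """Raised when a drug has no exposed reports in the corpus."""


class ConflictingMappingError(ValueError):
    """Raised when one PT maps to more than one SOC."""


class UnmappedPtError(KeyError):
    """Raised when a PT is absent from a PT->SOC map."""


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report."""

    name_raw: str
    name_norm: str | None  # matched study keyword, or None if outside study set
    role_code: str = "primary_suspect"
    indication: str | None = None

    def __post_init__(self) -> None:
        if self.role_code not in ROLE_CODES:
            raise ValueError(f"unknown role code: {self.role_code!r}")


@dataclass
class CaseReport:
    """One spontaneous adverse-event report."""

    case_id: str
    receipt_date: _dt.date | None
    age_years: float | None
    sex: str
    country: str
    drugs: list[DrugEntry]
    reactions: list[str]
    outcomes: frozenset[str] = frozenset()
    off_label: bool | None = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if not self.reactions:
            raise ValueError(f"report {self.case_id}: reactions must be non-empty")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex: {self.sex!r}")
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcomes: {sorted(unknown)}")

    @property
    def age_group(self) -> str:
        return age_group_of(self.age_years)

    def has_drug(self, name_norm: str, roles: Iterable[str] | None = None) -> bool:
        roles = set(roles) if roles is not None else None
        for d in self.drugs:
            if d.name_norm == name_norm and (roles is None or d.role_code in roles):
                return True
        return False


class PtSocMap:
    """Total PT -> primary SOC mapping with case-insensitive lookup.

    Lookup of an unmapped PT raises :class:`UnmappedPtError`; use
    :meth:`get` for a None-returning probe.
    """

    def __init__(self, entries: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = entries.items() if isinstance(entries, Mapping) else entries
        self._entries: dict[str, str] = {}
        self._display: dict[str, str] = {}
        for pt, soc in items:
            key = norm_term(pt)
            if key in self._entries and self._entries[key] != soc:
                raise ConflictingMappingError(
                    f"PT {pt!r} mapped to both {self._entries[key]!r} and {soc!r}"
                )
            self._entries[key] = soc
            self._display[key] = pt.strip()

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pt: str) -> bool:
        return norm_term(pt) in self._entries

    def __getitem__(self, pt: str) -> str:
        key = norm_term(pt)
        if key not in self._entries:
            raise UnmappedPtError(pt)
        return self._entries[key]

    def get(self, pt: str, default: str | None = None) -> str | None:
        return self._entries.get(norm_term(pt), default)

    @property
    def pts(self) -> tuple[str, ...]:
        return tuple(self._display.values())

    @property
    def socs(self) -> tuple[str, ...]:
        return tuple(sorted(set(self._entries.values())))


class ImeList:
    """Set of important-medical-event PTs; membership is case/whitespace-insensitive."""

    def __init__(self, pts: Iterable[str]):
        self._display = tuple(dict.fromkeys(p.strip() for p in pts))
        self._keys = frozenset(norm_term(p) for p in self._display)

    def __contains__(self, pt: str) -> bool:
        return norm_term(pt) in self._keys

    def __len__(self) -> int:
        return len(self._keys)

    @property
    def pts(self) -> tuple[str, ...]:
        return self._display


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 table for one drug-event pair.

    a: reports with the target drug AND the target event;
    b: target drug, other events; c: other drugs, target event;
    d: other drugs, other events.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            v = getattr(self, cell)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {cell} must be a non-negative integer, got {v}")
        if self.n_total == 0:
            raise ValueError("empty table: N must be > 0")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalStat:
    """Disproportionality statistics for one drug-event pair."""

    n: int
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float


@dataclass(frozen=True)
class SignalCriteria:
    """Screening thresholds a drug-PT pair must meet to count as a signal."""

    min_n: int = 3
    require_ror_low_gt1: bool = True
    require_ic025_gt0: bool = True
    require_chi2_ge: float | None = None
    role_codes_included: frozenset[str] = frozenset(
        {"primary_suspect", "secondary_suspect"}
    )

    def __post_init__(self) -> None:
        if self.min_n < 1:
            raise ValueError("min_n must be >= 1")
        bad = set(self.role_codes_included) - set(ROLE_CODES)
        if bad:
            raise ValueError(f"unknown role codes: {sorted(bad)}")


@dataclass(frozen=True)
class SignalRecord:
    """Screening outcome for one drug-PT pair."""

    drug: str
    pt: str
    soc: str | None
    table: ContingencyTable
    stats: SignalStat
    passed: bool
    exclusion_reason: str

    def __post_init__(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason: {self.exclusion_reason!r}")
        if self.passed != (self.exclusion_reason == "none"):
            raise ValueError("passed must be equivalent to exclusion_reason == 'none'")
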