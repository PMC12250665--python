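"""Report ingestion and vocabulary loading.

Two on-disk dialects are supported:

``simple_table``
    One UTF-8 CSV, one row per case-drug-reaction, with the headered columns
    ``case_id, receipt_date, age, sex, country, drug, role_code, indication,
    reaction_pt, outcome, off_label``. Dates are ISO-8601; multiple outcomes
    are ``|``-joined; ``off_label`` is ``true``/``false``/empty.

``faers_multi_table``
    A directory of ``$``-delimited text tables in the style of FAERS
    quarterly ASCII: ``DEMO.txt`` (caseid, fda_dt, age, age_cod, sex,
    reporter_country, off_label), ``DRUG.txt`` (caseid, drug_seq, drugname,
    role_cod, indi_pt), ``REAC.txt`` (caseid, pt), ``OUTC.txt`` (caseid,
    outc_cod). Dates are YYYYMMDD; ages carry FAERS unit codes
    (DEC/YR/MON/WK/DY); role codes are PS/SS/C/I; outcome codes are
    DE/HO/LT/DS/CA/RI/OT; ``off_label`` is Y/N/blank.

Rows sharing a case key are merged into one :class:`~gnrha_pv.types.CaseReport`
(drugs and reactions unioned, first-seen order preserved). Malformed rows and
orphan drug/reaction rows are counted on the returned :class:`ReportList`,
not fatal, unless more than half the input is malformed.
"""

from __future__ import annotations

import datetime as _dt
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from gnrha_pv.types import (
    AmbiguousDrugNameError,
    CaseReport,
    DrugEntry,
    ImeList,
    PtSocMap,
    STUDY_DRUGS,
    norm_term,
)

SIMPLE_COLUMNS = (
    "case_id",
    "receipt_date",
    "age",
    "sex",
    "country",
    "drug",
    "role_code",
    "indication",
    "reaction_pt",
    "outcome",
    "off_label",
)

# FAERS age-unit codes -> multiplicative factor to years.
AGE_UNIT_FACTORS = {"DEC": 10.0, "YR": 1.0, "MON": 1.0 / 12.0, "WK": 1.0 / 52.0, "DY": 1.0 / 365.25}

_ROLE_FROM_FAERS = {
    "PS": "primary_suspect",
    "SS": "secondary_suspect",
    "C": "concomitant",
    "I": "interacting",
}
_ROLE_TO_FAERS = {v: k for k, v in _ROLE_FROM_FAERS.items()}

_OUTC_FROM_FAERS = {
    "DE": "death",
    "HO": "hospitalization",
    "LT": "life_threatening",
    "DS": "disability",
    "CA": "congenital_anomaly",
    "RI": "required_intervention",
    "OT": "other",
}
_OUTC_TO_FAERS = {v: k for k, v in _OUTC_FROM_FAERS.items()}

_SEX_FROM_FAERS = {"F": "female", "M": "male"}
_SEX_TO_FAERS = {"female": "F", "male": "M", "unknown": ""}


class MissingColumnError(ValueError):
    """A required column is absent from an input table."""


class ReportList(list):
    """A list of CaseReports annotated with ingestion diagnostics."""

    def __init__(self, reports: Iterable[CaseReport] = ()):
        super().__init__(reports)
        self.n_malformed: int = 0
        self.n_orphans: int = 0
        self.n_unparseable_dates: int = 0
        self.n_unparseable_ages: int = 0


def normalize_drug_name(
    name_raw: str, keywords: Sequence[str] = STUDY_DRUGS
) -> str | None:
    """Map a verbatim drug string to the study keyword it contains.

    Matching is case-insensitive substring search after trimming; brand
    names carry no keyword and return None (a synonym table, applied
    upstream, is the supported route for brands). Two distinct keywords
    matching one string is an error rather than a silent pick.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    raw = name_raw.strip().casefold()
    hits = [k for k in keywords if k.casefold() in raw]
    if len(hits) > 1:
        raise AmbiguousDrugNameError(
            f"drug string {name_raw!r} matches multiple keywords: {sorted(hits)}"
        )
    return hits[0].casefold() if hits else None


def _read_table(path: Path, sep: str, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, engine="python" if sep == "$" else "c")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path.name}: missing required column(s) {missing}")
    return df


def _parse_iso_date(s: str) -> _dt.date | None:
    try:
        return _dt.date.fromisoformat(s.strip())
    except ValueError:
        return None


def _parse_faers_date(s: str) -> _dt.date | None:
    s = s.strip()
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None


def _parse_bool(s: str) -> bool | None:
    t = s.strip().casefold()
    if t in {"true", "1", "yes", "y"}:
        return True
    if t in {"false", "0", "no", "n"}:
        return False
    return None


def read_reports(
    path: str | Path,
    dialect: str,
    keywords: Sequence[str] = STUDY_DRUGS,
) -> ReportList:
    """Read a report corpus, merging rows by case key.

    Returns one CaseReport per distinct case key; the returned
    :class:`ReportList` carries counts of malformed rows, orphan rows and
    unparseable dates/ages. More than 50% malformed rows is fatal.
    """
    path = Path(path)
    if dialect == "simple_table":
        return _read_simple(path, keywords)
    if dialect == "faers_multi_table":
        return _read_faers(path, keywords)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_simple(path: Path, keywords: Sequence[str]) -> ReportList:
    df = _read_table(path, ",", SIMPLE_COLUMNS)
    out = ReportList()
    cases: dict[str, dict] = {}
    n_rows = len(df)
    for row in df.itertuples(index=False):
        case_id = row.case_id.strip()
        pt = row.reaction_pt.strip()
        if not case_id or not pt:
            out.n_malformed += 1
            continue
        if case_id not in cases:
            date = _parse_iso_date(row.receipt_date) if row.receipt_date.strip() else None
            if row.receipt_date.strip() and date is None:
                out.n_unparseable_dates += 1
            age: float | None = None
            if row.age.strip():
                try:
                    age = float(row.age)
                    if age < 0:
                        raise ValueError
                except ValueError:
                    age = None
                    out.n_unparseable_ages += 1
            sex = row.sex.strip().casefold() or "unknown"
            if sex not in {"female", "male"}:
                sex = "unknown"
            cases[case_id] = {
                "receipt_date": date,
                "age_years": age,
                "sex": sex,
                "country": row.country.strip() or "unknown",
                "drugs": [],
                "drug_seen": set(),
                "reactions": [],
                "outcomes": set(),
                "off_label": _parse_bool(row.off_label),
            }
        rec = cases[case_id]
        drug_raw = row.drug.strip()
        role = row.role_code.strip() or "primary_suspect"
        if drug_raw and (drug_raw, role) not in rec["drug_seen"]:
            rec["drug_seen"].add((drug_raw, role))
            rec["drugs"].append(
                DrugEntry(
                    name_raw=drug_raw,
                    name_norm=normalize_drug_name(drug_raw, keywords),
                    role_code=role,
                    indication=row.indication.strip() or None,
                )
            )
        if pt not in rec["reactions"]:
            rec["reactions"].append(pt)
        for o in row.outcome.split("|"):
            o = o.strip()
            if o:
                rec["outcomes"].add(o)
    if n_rows and out.n_malformed > 0.5 * n_rows:
        raise ValueError(
            f"{path.name}: {out.n_malformed}/{n_rows} rows malformed (>50%)"
        )
    for case_id, rec in cases.items():
        out.append(
            CaseReport(
                case_id=case_id,
                receipt_date=rec["receipt_date"],
                age_years=rec["age_years"],
                sex=rec["sex"],
                country=rec["country"],
                drugs=rec["drugs"],
                reactions=rec["reactions"],
                outcomes=frozenset(rec["outcomes"]),
                off_label=rec["off_label"],
            )
        )
    return out


def _read_faers(dirpath: Path, keywords: Sequence[str]) -> ReportList:
    demo = _read_table(dirpath / "DEMO.txt", "$", ("caseid", "fda_dt", "age", "age_cod", "sex", "reporter_country", "off_label"))
    drug = _read_table(dirpath / "DRUG.txt", "$", ("caseid", "drug_seq", "drugname", "role_cod", "indi_pt"))
    reac = _read_table(dirpath / "REAC.txt", "$", ("caseid", "pt"))
    outc_path = dirpath / "OUTC.txt"
    outc = _read_table(outc_path, "$", ("caseid", "outc_cod")) if outc_path.exists() else None

    out = ReportList()
    cases: dict[str, dict] = {}
    for row in demo.itertuples(index=False):
        case_id = row.caseid.strip()
        if not case_id:
            out.n_malformed += 1
            continue
        date = _parse_faers_date(row.fda_dt)
        if row.fda_dt.strip() and date is None:
            out.n_unparseable_dates += 1
        age: float | None = None
        if row.age.strip():
            factor = AGE_UNIT_FACTORS.get(row.age_cod.strip().upper() or "YR")
            try:
                raw = float(row.age)
                if raw < 0 or factor is None:
                    raise ValueError
                age = raw * factor
            except ValueError:
                out.n_unparseable_ages += 1
        off = row.off_label.strip().upper()
        cases[case_id] = {
            "receipt_date": date,
            "age_years": age,
            "sex": _SEX_FROM_FAERS.get(row.sex.strip().upper(), "unknown"),
            "country": row.reporter_country.strip() or "unknown",
            "drugs": [],
            "drug_seen": set(),
            "reactions": [],
            "outcomes": set(),
            "off_label": {"Y": True, "N": False}.get(off),
        }

    drug = drug.sort_values("drug_seq", kind="stable") if "drug_seq" in drug.columns else drug
    for row in drug.itertuples(index=False):
        case_id = row.caseid.strip()
        if case_id not in cases:
            out.n_orphans += 1
            continue
        name = row.drugname.strip()
        if not name:
            out.n_malformed += 1
            continue
        role_raw = row.role_cod.strip().upper()
        indi = row.indi_pt.strip()
        sig = (name, role_raw, indi)
        if sig in cases[case_id]["drug_seen"]:
            continue
        cases[case_id]["drug_seen"].add(sig)
        cases[case_id]["drugs"].append(
            DrugEntry(
                name_raw=name,
                name_norm=normalize_drug_name(name, keywords),
                role_code=_ROLE_FROM_FAERS.get(row.role_cod.strip().upper(), "concomitant"),
                indication=row.indi_pt.strip() or None,
            )
        )
    for row in reac.itertuples(index=False):
        case_id = row.caseid.strip()
        if case_id not in cases:
            out.n_orphans += 1
            continue
        pt = row.pt.strip()
        if pt and pt not in cases[case_id]["reactions"]:
            cases[case_id]["reactions"].append(pt)
    if outc is not None:
        for row in outc.itertuples(index=False):
            case_id = row.caseid.strip()
            if case_id not in cases:
                out.n_orphans += 1
                continue
            mapped = _OUTC_FROM_FAERS.get(row.outc_cod.strip().upper())
            if mapped:
                cases[case_id]["outcomes"].add(mapped)

    for case_id, rec in cases.items():
        if not rec["reactions"]:  # a case with no reaction rows is not analyzable
            out.n_malformed += 1
            continue
        out.append(
            CaseReport(
                case_id=case_id,
                receipt_date=rec["receipt_date"],
                age_years=rec["age_years"],
                sex=rec["sex"],
                country=rec["country"],
                drugs=rec["drugs"],
                reactions=rec["reactions"],
                outcomes=frozenset(rec["outcomes"]),
                off_label=rec["off_label"],
            )
        )
    n_cases = len(demo)
    if n_cases and out.n_malformed > 0.5 * n_cases:
        raise ValueError(f"{dirpath}: {out.n_malformed}/{n_cases} cases malformed (>50%)")
    return out


def write_reports(reports: Iterable[CaseReport], path: str | Path, dialect: str) -> None:
    """Write a corpus in the given dialect (inverse of :func:`read_reports`)."""
    path = Path(path)
    if dialect == "simple_table":
        _write_simple(reports, path)
    elif dialect == "faers_multi_table":
        _write_faers(reports, path)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def _fmt_age(age: float | None) -> str:
    if age is None:
        return ""
    return repr(age) if age != int(age) else str(int(age))


def _write_simple(reports: Iterable[CaseReport], path: Path) -> None:
    rows = []
    for r in reports:
        date = r.receipt_date.isoformat() if r.receipt_date else ""
        age = _fmt_age(r.age_years)
        off = "" if r.off_label is None else str(r.off_label).lower()
        outcome = "|".join(sorted(r.outcomes))
        drugs = r.drugs if r.drugs else [None]
        for d in drugs:
            for pt in r.reactions:
                rows.append(
                    {
                        "case_id": r.case_id,
                        "receipt_date": date,
                        "age": age,
                        "sex": r.sex,
                        "country": r.country,
                        "drug": d.name_raw if d else "",
                        "role_code": d.role_code if d else "",
                        "indication": (d.indication or "") if d else "",
                        "reaction_pt": pt,
                        "outcome": outcome,
                        "off_label": off,
                    }
                )
    pd.DataFrame(rows, columns=list(SIMPLE_COLUMNS)).to_csv(path, index=False)


def _write_faers(reports: Iterable[CaseReport], dirpath: Path) -> None:
    dirpath.mkdir(parents=True, exist_ok=True)
    demo, drug, reac, outc = [], [], [], []
    for r in reports:
        demo.append(
            {
                "caseid": r.case_id,
                "fda_dt": r.receipt_date.strftime("%Y%m%d") if r.receipt_date else "",
                "age": _fmt_age(r.age_years),
                "age_cod": "YR" if r.age_years is not None else "",
                "sex": _SEX_TO_FAERS[r.sex],
                "reporter_country": "" if r.country == "unknown" else r.country,
                "off_label": {True: "Y", False: "N", None: ""}[r.off_label],
            }
        )
        for i, d in enumerate(r.drugs, start=1):
            drug.append(
                {
                    "caseid": r.case_id,
                    "drug_seq": i,
                    "drugname": d.name_raw,
                    "role_cod": _ROLE_TO_FAERS[d.role_code],
                    "indi_pt": d.indication or "",
                }
            )
        for pt in r.reactions:
            reac.append({"caseid": r.case_id, "pt": pt})
        for o in sorted(r.outcomes):
            outc.append({"caseid": r.case_id, "outc_cod": _OUTC_TO_FAERS[o]})
    pd.DataFrame(demo, columns=["caseid", "fda_dt", "age", "age_cod", "sex", "reporter_country", "off_label"]).to_csv(dirpath / "DEMO.txt", sep="$", index=False)
    pd.DataFrame(drug, columns=["caseid", "drug_seq", "drugname", "role_cod", "indi_pt"]).to_csv(dirpath / "DRUG.txt", sep="$", index=False)
    pd.DataFrame(reac, columns=["caseid", "pt"]).to_csv(dirpath / "REAC.txt", sep="$", index=False)
    pd.DataFrame(outc, columns=["caseid", "outc_cod"]).to_csv(dirpath / "OUTC.txt", sep="$", index=False)


def load_pt_soc_map(path: str | Path) -> PtSocMap:
    """Load a two-column (pt, soc) CSV; conflicting duplicate PT rows are fatal."""
    df = _read_table(Path(path), ",", ("pt", "soc"))
    pairs = [(r.pt.strip(), r.soc.strip()) for r in df.itertuples(index=False) if r.pt.strip()]
    return PtSocMap(pairs)


def load_ime_list(path: str | Path) -> ImeList:
    """Load a one-column (pt) CSV of important-medical-event terms."""
    df = _read_table(Path(path), ",", ("pt",))
    return ImeList(p.strip() for p in df["pt"] if p.strip())


def default_pt_soc_map() -> PtSocMap:
    """The packaged toy PT->SOC map (60 PTs across 12 SOCs)."""
    with resources.as_file(resources.files("gnrha_pv") / "data" / "pt_soc_map.csv") as p:
        return load_pt_soc_map(p)


def default_ime_list() -> ImeList:
    """The packaged toy IME term list."""
    with resources.as_file(resources.files("gnrha_pv") / "data" / "ime_list.csv") as p:
        return load_ime_list(p)
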