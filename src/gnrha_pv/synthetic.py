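"""Synthetic FAERS-like corpus generator with fully known ground truth.

The generator emulates the structure of spontaneous-report data — five
long-acting GnRH analogs plus a background drug pool, MedDRA-coded
reactions, demographic strata, regulatory outcomes, missingness and exact
duplicate submissions — while keeping every quantity the pipeline estimates
plantable and recoverable:

* drug-event associations are injected at the report level: a report
  exposed to the signal drug includes the signal PT with probability p1
  solving odds(p1)/odds(p0) = true ROR, so the report-level 2x2 odds ratio
  equals the planted ROR in expectation;
* important-medical-event (IME) reactions are attached with per-report
  probability logistic in the planted factor effects (drug, sex, off-label
  use, age group), so a logit fit on the corpus targets the planted odds
  ratios directly;
* exact duplicates are planted by copying finished reports (missingness is
  applied before copying so duplicates stay byte-equal on the dedup key);
* everything is reproducible from the seed.

IME-listed PTs have zero background rate and injected PTs are never
IME-listed, so neither mechanism contaminates the other's planted truth.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from gnrha_pv import io as _io
from gnrha_pv.types import CaseReport, DrugEntry, STUDY_DRUGS

#: Non-study drugs forming the comparator background.
BACKGROUND_DRUGS = (
    "tamoxifen",
    "metformin",
    "lisinopril",
    "omeprazole",
    "atorvastatin",
    "ibuprofen",
    "warfarin",
    "sertraline",
)

_RATE_CYCLE = (0.04, 0.025, 0.015, 0.01, 0.006, 0.004)

DEFAULT_INJECTED = (
    ("leuprolide", "Hot flush", 2.0),
    ("goserelin", "Malignant neoplasm progression", 5.0),
    ("triptorelin", "Ovarian hyperstimulation syndrome", 20.0),
)

#: Background reporting rate of each injected PT among unexposed reports.
_INJECTED_P0 = {
    "Hot flush": 0.02,
    "Malignant neoplasm progression": 0.02,
    "Ovarian hyperstimulation syndrome": 0.005,
}

DEFAULT_DRUG_WEIGHTS = {
    "leuprolide": 0.25,
    "goserelin": 0.08,
    "triptorelin": 0.06,
    "histrelin": 0.035,
    "buserelin": 0.025,
}

#: Planted multivariate IME odds ratios (reference: leuprolide, female,
#: on-label, age 19-45).
DEFAULT_IME_EFFECTS = (
    ("drug", "buserelin", 27.94),
    ("drug", "goserelin", 6.78),
    ("drug", "histrelin", 1.22),
    ("drug", "triptorelin", 3.58),
    ("sex", "male", 1.11),
    ("off_label", "yes", 1.40),
    ("age_group", "<=18", 0.29),
    ("age_group", ">80", 1.83),
    ("age_group", "46-60", 1.16),
    ("age_group", "61-80", 1.11),
)

_YEARS = tuple(range(2004, 2024))
_AGE_BOUNDS = {"<=18": (1, 18), "19-45": (19, 45), "46-60": (46, 60), "61-80": (61, 80), ">80": (81, 95)}


def _demo(age, sex_female, countries, role_secondary, indications, outcomes, off_label):
    return {
        "age_group": age,
        "sex": {"female": sex_female, "male": 1.0 - sex_female},
        "country": countries,
        "role_code": {
            "primary_suspect": 1.0 - role_secondary,
            "secondary_suspect": role_secondary,
        },
        "indication": indications,
        "outcome": outcomes,
        "off_label": off_label,
    }


def default_demographics() -> dict:
    """Per-drug demographic distributions emulating the study population:
    older, mostly male prostate-cancer reporting for leuprolide/goserelin;
    young, mostly female precocious-puberty reporting for histrelin and
    triptorelin; buserelin reported from Germany, as a secondary suspect,
    mostly in women aged 19-45."""
    us_mix = {"US": 0.6, "GB": 0.1, "CA": 0.08, "FR": 0.08, "JP": 0.07, "DE": 0.07}
    onc_out = {"other": 0.45, "hospitalization": 0.25, "death": 0.15, "life_threatening": 0.08, "disability": 0.07}
    mild_out = {"other": 0.65, "hospitalization": 0.2, "death": 0.03, "life_threatening": 0.05, "disability": 0.07}
    return {
        "leuprolide": _demo(
            {"<=18": 0.05, "19-45": 0.12, "46-60": 0.2, "61-80": 0.48, ">80": 0.15},
            0.35, us_mix, 0.1,
            {"Prostate cancer": 0.55, "Endometriosis": 0.15, "Breast cancer": 0.1, "Precocious puberty": 0.1, "Uterine leiomyoma": 0.1},
            onc_out, 0.15,
        ),
        "goserelin": _demo(
            {"<=18": 0.03, "19-45": 0.2, "46-60": 0.25, "61-80": 0.42, ">80": 0.1},
            0.45, us_mix, 0.1,
            {"Prostate cancer": 0.4, "Breast cancer": 0.35, "Endometriosis": 0.2, "Uterine leiomyoma": 0.05},
            {"other": 0.35, "hospitalization": 0.2, "death": 0.29, "life_threatening": 0.09, "disability": 0.07},
            0.1,
        ),
        "triptorelin": _demo(
            {"<=18": 0.2, "19-45": 0.45, "46-60": 0.2, "61-80": 0.12, ">80": 0.03},
            0.6, us_mix, 0.15,
            {"Precocious puberty": 0.35, "Endometriosis": 0.3, "Prostate cancer": 0.25, "Infertility": 0.1},
            mild_out, 0.25,
        ),
        "histrelin": _demo(
            {"<=18": 0.4, "19-45": 0.3, "46-60": 0.15, "61-80": 0.12, ">80": 0.03},
            0.6, us_mix, 0.05,
            {"Precocious puberty": 0.6, "Prostate cancer": 0.3, "Endometriosis": 0.1},
            mild_out, 0.2,
        ),
        "buserelin": _demo(
            {"<=18": 0.08, "19-45": 0.42, "46-60": 0.3, "61-80": 0.17, ">80": 0.03},
            0.7, {"DE": 0.6, "US": 0.15, "GB": 0.1, "FR": 0.1, "JP": 0.05}, 1.0,
            {"Endometriosis": 0.45, "Infertility": 0.3, "Prostate cancer": 0.25},
            mild_out, 0.3,
        ),
        "background": _demo(
            {"<=18": 0.08, "19-45": 0.3, "46-60": 0.27, "61-80": 0.27, ">80": 0.08},
            0.55, us_mix, 0.15,
            {"Hypertension": 0.3, "Diabetes mellitus": 0.25, "Depression": 0.2, "Pain": 0.25},
            mild_out, 0.1,
        ),
    }


def default_background_rates(
    injected: Sequence[tuple[str, str, float]] = DEFAULT_INJECTED,
) -> dict[str, float]:
    """Per-report background inclusion probability of every fixture PT.

    IME-listed PTs get rate 0 (they are attached only through the IME
    mechanism); injected PTs get their designated background rate; the
    remaining PTs cycle through a fixed grid of realistic reporting rates.
    """
    pt_map = _io.default_pt_soc_map()
    ime = set(_io.default_ime_list().pts)
    injected_pts = {pt for (_, pt, _) in injected}
    rates: dict[str, float] = {}
    i = 0
    for pt in pt_map.pts:
        if pt in ime:
            rates[pt] = 0.0
        elif pt in injected_pts:
            rates[pt] = _INJECTED_P0[pt]
        else:
            rates[pt] = _RATE_CYCLE[i % len(_RATE_CYCLE)]
            i += 1
    return rates


@dataclass
class SyntheticConfig:
    """Full generative specification of one synthetic corpus."""

    n_reports: int = 20_000
    seed: int = 0
    drug_weights: dict = field(default_factory=lambda: dict(DEFAULT_DRUG_WEIGHTS))
    background_pt_rates: dict = field(default_factory=default_background_rates)
    injected_signals: tuple = DEFAULT_INJECTED
    demographic_spec: dict = field(default_factory=default_demographics)
    ime_baseline_rate: float = 0.15
    ime_effects: tuple = DEFAULT_IME_EFFECTS
    duplicate_fraction: float = 0.02
    concomitant_rate: float = 0.3
    missing_rates: dict = field(
        default_factory=lambda: {"age": 0.2, "sex": 0.05, "country": 0.05, "off_label": 0.1}
    )

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        w = sum(self.drug_weights.values())
        if w > 1 + 1e-12 or any(v < 0 for v in self.drug_weights.values()):
            raise ValueError("drug_weights must be non-negative and sum to <= 1")
        for pt, p in self.background_pt_rates.items():
            if not 0 <= p <= 1:
                raise ValueError(f"background rate of {pt!r} outside [0,1]")
        pts = set(self.background_pt_rates)
        for drug, pt, ror in self.injected_signals:
            if ror <= 0:
                raise ValueError(f"injected signal ({drug}, {pt}): true ROR must be > 0")
            if pt not in pts:
                raise ValueError(f"injected PT {pt!r} not in the PT vocabulary")
            p0 = self.background_pt_rates[pt]
            if not 0 < p0 < 1:
                raise ValueError(
                    f"injected signal ({drug}, {pt}): background rate {p0} leaves the "
                    "target odds unreachable with p1 < 1"
                )
        for p in self.missing_rates.values():
            if not 0 <= p <= 1:
                raise ValueError("missing rates must be in [0,1]")


@dataclass
class InjectedTruth:
    drug: str
    pt: str
    true_ror: float
    p0: float
    p1: float
    expected_cells: tuple  # analytic (a, b, c, d) on the deduplicated corpus
    realized_cells: tuple  # exact counts as generated (pre-duplication)


@dataclass
class GroundTruth:
    n_unique: int
    n_duplicates: int
    injected: list
    ime_baseline_rate: float
    ime_effects: tuple
    mean_ime_rate: float
    drug_report_counts: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n"
        )


def _p1_for(p0: float, true_ror: float) -> float:
    odds = true_ror * p0 / (1.0 - p0)
    return odds / (1.0 + odds)


def _sample_levels(rng, dist: Mapping[str, float], size: int) -> np.ndarray:
    levels = list(dist)
    probs = np.array([dist[lv] for lv in levels], dtype=float)
    probs = probs / probs.sum()
    return np.array(levels, dtype=object)[rng.choice(len(levels), size=size, p=probs)]


_NAME_TEMPLATES = ("{U}", "{U} ACETATE", "{C} depot", "{U} 22.5MG DEPOT")


def _raw_name(drug: str, variant: int) -> str:
    t = _NAME_TEMPLATES[variant % len(_NAME_TEMPLATES)]
    return t.format(U=drug.upper(), C=drug.capitalize())


def generate(config: SyntheticConfig) -> tuple[list[CaseReport], GroundTruth]:
    """Generate one corpus and its ground truth. Deterministic in the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_reports
    k_dup = round(config.duplicate_fraction * n)
    n_u = n - k_dup

    drugs = list(config.drug_weights) + list(BACKGROUND_DRUGS)
    w_study = np.array([config.drug_weights[d] for d in config.drug_weights])
    w_bg = (1.0 - w_study.sum()) / len(BACKGROUND_DRUGS)
    weights = np.concatenate([w_study, np.full(len(BACKGROUND_DRUGS), w_bg)])
    weights = weights / weights.sum()
    drug_idx = rng.choice(len(drugs), size=n_u, p=weights)
    drug_of = np.array(drugs, dtype=object)[drug_idx]

    # --- demographics, sampled per drug group in fixed drug order ---
    spec_of = {
        d: config.demographic_spec.get(d, config.demographic_spec["background"])
        for d in drugs
    }
    age_group = np.empty(n_u, dtype=object)
    sex = np.empty(n_u, dtype=object)
    country = np.empty(n_u, dtype=object)
    role = np.empty(n_u, dtype=object)
    indication = np.empty(n_u, dtype=object)
    outcome = np.empty(n_u, dtype=object)
    off_label = np.zeros(n_u, dtype=bool)
    for gi, d in enumerate(drugs):
        idx = np.nonzero(drug_idx == gi)[0]
        if idx.size == 0:
            continue
        s = spec_of[d]
        age_group[idx] = _sample_levels(rng, s["age_group"], idx.size)
        sex[idx] = _sample_levels(rng, s["sex"], idx.size)
        country[idx] = _sample_levels(rng, s["country"], idx.size)
        role[idx] = _sample_levels(rng, s["role_code"], idx.size)
        indication[idx] = _sample_levels(rng, s["indication"], idx.size)
        outcome[idx] = _sample_levels(rng, s["outcome"], idx.size)
        off_label[idx] = rng.random(idx.size) < s["off_label"]

    age = np.empty(n_u, dtype=float)
    for grp, (lo, hi) in _AGE_BOUNDS.items():
        idx = np.nonzero(age_group == grp)[0]
        age[idx] = rng.integers(lo, hi + 1, size=idx.size)

    year_w = np.arange(1, len(_YEARS) + 1, dtype=float)
    year = np.array(_YEARS)[rng.choice(len(_YEARS), size=n_u, p=year_w / year_w.sum())]
    doy = rng.integers(0, 365, size=n_u)

    # --- reactions: independent inclusion with odds-exact injection ---
    pts = list(config.background_pt_rates)
    p0 = np.array([config.background_pt_rates[pt] for pt in pts])
    prob = np.tile(p0, (n_u, 1))
    pt_col = {pt: j for j, pt in enumerate(pts)}
    injected_truth: list[InjectedTruth] = []
    for drug, pt, true_ror in config.injected_signals:
        j = pt_col[pt]
        exposed = drug_of == drug
        p1 = _p1_for(p0[j], true_ror)
        prob[exposed, j] = p1
        injected_truth.append(
            InjectedTruth(
                drug=drug, pt=pt, true_ror=true_ror, p0=float(p0[j]), p1=p1,
                expected_cells=(), realized_cells=(),
            )
        )
    reac = rng.random((n_u, len(pts))) < prob

    # --- IME attachment: per-report logistic probability in the true factors ---
    effects = {(f, lv): math.log(orr) for f, lv, orr in config.ime_effects}
    lin = np.full(
        n_u,
        math.log(config.ime_baseline_rate / (1 - config.ime_baseline_rate)),
    )
    for (factor, level), beta in effects.items():
        if factor == "drug":
            lin += beta * (drug_of == level)
        elif factor == "sex":
            lin += beta * (sex == level)
        elif factor == "off_label":
            lin += beta * (off_label if level == "yes" else ~off_label)
        elif factor == "age_group":
            lin += beta * (age_group == level)
        else:
            raise ValueError(f"unknown IME factor {factor!r}")
    p_ime = 1.0 / (1.0 + np.exp(-lin))
    ime_pts = list(_io.default_ime_list().pts)
    ime_fire = rng.random(n_u) < p_ime
    ime_choice = rng.integers(0, len(ime_pts), size=n_u)

    # --- guarantee >= 1 reaction: fill from background-only vocabulary ---
    injected_pt_set = {pt for (_, pt, _) in config.injected_signals}
    fill_j = np.array(
        [j for j, pt in enumerate(pts) if p0[j] > 0 and pt not in injected_pt_set]
    )
    fill_w = p0[fill_j] / p0[fill_j].sum()
    empty = np.nonzero(~reac.any(axis=1) & ~ime_fire)[0]
    fill_choice = fill_j[rng.choice(len(fill_j), size=empty.size, p=fill_w)]
    reac[empty, fill_choice] = True

    # --- realized + expected cells for each injected signal ---
    for t in injected_truth:
        j = pt_col[t.pt]
        exposed = drug_of == t.drug
        has = reac[:, j]
        a = int((exposed & has).sum())
        b = int((exposed & ~has).sum())
        c = int((~exposed & has).sum())
        d = n_u - a - b - c
        t.realized_cells = (a, b, c, d)
        w = weights[drugs.index(t.drug)]
        t.expected_cells = (
            n_u * w * t.p1,
            n_u * w * (1 - t.p1),
            n_u * (1 - w) * t.p0,
            n_u * (1 - w) * (1 - t.p0),
        )

    # --- missingness (MCAR), before duplication so duplicates stay exact ---
    miss = {
        f: rng.random(n_u) < config.missing_rates.get(f, 0.0)
        for f in ("age", "sex", "country", "off_label")
    }

    conc = rng.random(n_u) < config.concomitant_rate
    conc_drug = rng.integers(0, len(BACKGROUND_DRUGS), size=n_u)
    name_variant = rng.integers(0, len(_NAME_TEMPLATES), size=n_u)

    reports: list[CaseReport] = []
    pts_arr = np.array(pts, dtype=object)
    for i in range(n_u):
        reactions = list(pts_arr[reac[i]])
        if ime_fire[i]:
            reactions.append(ime_pts[ime_choice[i]])
        d_name = drug_of[i]
        entries = [
            DrugEntry(
                name_raw=_raw_name(d_name, int(name_variant[i])),
                name_norm=d_name if d_name in STUDY_DRUGS else None,
                role_code=role[i],
                indication=indication[i],
            )
        ]
        if conc[i]:
            bg = BACKGROUND_DRUGS[conc_drug[i]]
            if bg != d_name:
                entries.append(
                    DrugEntry(name_raw=bg, name_norm=None, role_code="concomitant")
                )
        reports.append(
            CaseReport(
                case_id=f"C{i:07d}",
                receipt_date=_dt.date(int(year[i]), 1, 1) + _dt.timedelta(days=int(doy[i])),
                age_years=None if miss["age"][i] else float(age[i]),
                sex="unknown" if miss["sex"][i] else sex[i],
                country="unknown" if miss["country"][i] else country[i],
                drugs=entries,
                reactions=reactions,
                outcomes=frozenset([outcome[i]]),
                off_label=None if miss["off_label"][i] else bool(off_label[i]),
            )
        )

    # --- exact duplicates + shuffle ---
    dup_src = rng.integers(0, n_u, size=k_dup)
    for s in dup_src:
        src = reports[s]
        reports.append(
            CaseReport(
                case_id=src.case_id,
                receipt_date=src.receipt_date,
                age_years=src.age_years,
                sex=src.sex,
                country=src.country,
                drugs=list(src.drugs),
                reactions=list(src.reactions),
                outcomes=src.outcomes,
                off_label=src.off_label,
            )
        )
    order = rng.permutation(len(reports))
    reports = [reports[i] for i in order]

    counts: dict[str, int] = {}
    for d in drug_of:
        counts[d] = counts.get(d, 0) + 1
    truth = GroundTruth(
        n_unique=n_u,
        n_duplicates=k_dup,
        injected=injected_truth,
        ime_baseline_rate=config.ime_baseline_rate,
        ime_effects=tuple(config.ime_effects),
        mean_ime_rate=float(p_ime.mean()),
        drug_report_counts=counts,
    )
    return reports, truth


# ---------------------------------------------------------------------------
# fixture profiles

PROFILES = ("tiny", "null", "signals", "ime", "full")


def profile_config(profile: str, seed: int = 0) -> SyntheticConfig:
    """The generative conditions of each named validation corpus."""
    if profile == "tiny":
        return SyntheticConfig(
            n_reports=40,
            seed=seed,
            duplicate_fraction=0.05,
            missing_rates={"age": 0.1, "sex": 0.05, "country": 0.0, "off_label": 0.1},
        )
    if profile == "null":
        return SyntheticConfig(
            n_reports=20_000, seed=seed, injected_signals=(), ime_effects=()
        )
    if profile == "signals":
        return SyntheticConfig(n_reports=20_000, seed=seed, ime_effects=())
    if profile == "ime":
        return SyntheticConfig(n_reports=50_000, seed=seed, injected_signals=())
    if profile == "full":
        return SyntheticConfig(n_reports=50_000, seed=seed)
    raise ValueError(f"unknown profile: {profile!r} (choose from {PROFILES})")


def make_fixture(profile: str, out_dir: str | Path, seed: int = 0) -> Path:
    """Write a complete corpus fixture to disk.

    Emits the corpus in both dialects (``reports.csv`` and ``faers/``),
    the PT->SOC map, the IME list, ``truth.json`` and ``config.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = profile_config(profile, seed=seed)
    reports, truth = generate(config)
    _io.write_reports(reports, out / "reports.csv", "simple_table")
    _io.write_reports(reports, out / "faers", "faers_multi_table")
    pt_map = _io.default_pt_soc_map()
    with open(out / "pt_soc_map.csv", "w") as fh:
        fh.write("pt,soc\n")
        for pt in pt_map.pts:
            soc = pt_map[pt]
            fh.write(f'"{pt}","{soc}"\n')
    with open(out / "ime_list.csv", "w") as fh:
        fh.write("pt\n")
        for pt in _io.default_ime_list().pts:
            fh.write(pt + "\n")
    truth.to_json(out / "truth.json")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
    return out
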