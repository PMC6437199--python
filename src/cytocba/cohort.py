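"""Cohort-level analysis: patient-table parsing, myasthenia-gravis subtype
classification and the clinical/serological summaries.

The patient table is a CSV with one row per patient (the packaged example
table describes a 30-patient case series of myasthenia gravis with
myositis and/or myocarditis).  Column schema::

    patient_id, age, sex, subtype, mgfa_class, ck, achr_titer,
    myositis, myocarditis, outcome, titin_cba, kv14_cba,
    titin_former, kv14_former

``sex`` is M/F; ``subtype`` one of EOMG/LOMG/TMG; ``mgfa_class`` an MGFA
severity token (``3a``, ``4b``, ``5`` ...); ``ck`` creatine kinase in
IU/L; ``achr_titer`` an anti-AChR titre in nM, possibly left-censored as
``<x``; ``myositis``/``myocarditis`` and the four antibody columns use
``+``/``-`` with ``ND`` (no data) allowed in the former-method columns;
``outcome`` is Alive or Dead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError, SchemaError

SUBTYPES = ("EOMG", "LOMG", "TMG")
MGFA_TOKENS = {"1", "2", "2a", "2b", "3", "3a", "3b", "4", "4a", "4b", "5"}
ANTIBODIES = ("titin", "kv14")
METHODS = ("cba", "former")

REQUIRED_COLUMNS = (
    "patient_id", "age", "sex", "subtype", "mgfa_class", "ck", "achr_titer",
    "myositis", "myocarditis", "outcome",
    "titin_cba", "kv14_cba", "titin_former", "kv14_former",
)


@dataclass
class PatientRecord:
    """One patient row; antibody calls are 'positive' / 'negative' /
    'no_data'."""

    patient_id: str
    age: float
    sex: str
    subtype: str
    mgfa_class: str
    ck: float
    achr_titer: float
    achr_censored: bool
    myositis: bool
    myocarditis: bool
    outcome: str
    titin_cba: str
    kv14_cba: str
    titin_former: str
    kv14_former: str

    @property
    def thymoma(self) -> bool:
        return self.subtype == "TMG"

    @property
    def mgfa_group(self) -> int:
        """MGFA class rollup: '3a'/'3b' -> 3, '4b' -> 4, etc."""
        return int(self.mgfa_class[0])

    def call(self, antibody: str, method: str) -> str:
        if antibody not in ANTIBODIES:
            raise DomainError(f"unknown antibody {antibody!r}")
        if method not in METHODS:
            raise DomainError(f"unknown method {method!r}")
        return getattr(self, f"{antibody}_{method}")


def _parse_call(token: str, row: int, column: str, allow_nd: bool) -> str:
    token = token.strip()
    if token == "+":
        return "positive"
    if token in ("-", "−"):
        return "negative"
    if token.upper() == "ND" and allow_nd:
        return "no_data"
    raise ParseError(f"row {row}: bad value {token!r} in column {column!r}")


def _parse_flag(token: str, row: int, column: str) -> bool:
    return _parse_call(token, row, column, allow_nd=False) == "positive"


def parse_patient_table(path: str | Path) -> list[PatientRecord]:
    """Parse and validate the patient-table CSV.

    ``ND`` is accepted only in the former-method antibody columns and maps
    to ``no_data``; censored AChR titres (``<0.2``) keep their bound with
    the censoring flag set.  Unknown MGFA tokens and outcomes other than
    Alive/Dead are parse errors naming the row.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    records = []
    for i, raw in df.iterrows():
        row = i + 2  # 1-based with header
        age = float(raw["age"])
        if age <= 0:
            raise ParseError(f"row {row}: non-positive age {age}")
        sex = raw["sex"].strip().upper()
        if sex not in ("M", "F"):
            raise ParseError(f"row {row}: sex must be M or F, got {raw['sex']!r}")
        subtype = raw["subtype"].strip().upper()
        if subtype not in SUBTYPES:
            raise ParseError(f"row {row}: unknown subtype {raw['subtype']!r}")
        mgfa = raw["mgfa_class"].strip().lower()
        if mgfa not in MGFA_TOKENS:
            raise ParseError(f"row {row}: unknown MGFA token {raw['mgfa_class']!r}")
        ck = float(raw["ck"])
        if ck < 0:
            raise ParseError(f"row {row}: negative creatine kinase {ck}")
        titer_token = raw["achr_titer"].strip()
        censored = titer_token.startswith("<")
        achr = float(titer_token.lstrip("<"))
        outcome = raw["outcome"].strip().capitalize()
        if outcome not in ("Alive", "Dead"):
            raise ParseError(f"row {row}: outcome must be Alive or Dead, "
                             f"got {raw['outcome']!r}")
        records.append(PatientRecord(
            patient_id=str(raw["patient_id"]),
            age=age, sex=sex, subtype=subtype, mgfa_class=mgfa,
            ck=ck, achr_titer=achr, achr_censored=censored,
            myositis=_parse_flag(raw["myositis"], row, "myositis"),
            myocarditis=_parse_flag(raw["myocarditis"], row, "myocarditis"),
            outcome=outcome,
            titin_cba=_parse_call(raw["titin_cba"], row, "titin_cba", False),
            kv14_cba=_parse_call(raw["kv14_cba"], row, "kv14_cba", False),
            titin_former=_parse_call(raw["titin_former"], row, "titin_former", True),
            kv14_former=_parse_call(raw["kv14_former"], row, "kv14_former", True),
        ))
    return records


def example_patient_table_path() -> Path:
    """Path of the packaged 30-patient example table."""
    return Path(str(resources.files("cytocba.data").joinpath("patient_table.csv")))


def load_example_cohort() -> list[PatientRecord]:
    return parse_patient_table(example_patient_table_path())


def classify_subtype(onset_age: float, thymoma: bool,
                     age_cutoff: float = 50.0) -> str:
    """Myasthenia-gravis subtype: thymoma-associated dominates; otherwise
    onset before the cutoff (50 years) is early-onset, at or after it
    late-onset."""
    if onset_age <= 0:
        raise DomainError(f"onset age must be positive, got {onset_age}")
    if thymoma:
        return "TMG"
    return "EOMG" if onset_age < age_cutoff else "LOMG"


def round_percent(count: int, total: int) -> float | None:
    """Integer percent, half away from zero; None for an empty denominator."""
    if total == 0:
        return None
    return float(math.floor(100.0 * count / total + 0.5))


@dataclass
class CohortSummary:
    n: int
    n_male: int
    n_female: int
    age_mean: float
    age_sd: float | None
    age_min: float
    age_max: float
    ck_mean: float
    ck_sd: float | None
    ck_min: float
    ck_max: float
    subtype_counts: dict
    mgfa_group_counts: dict
    thymoma_count: int
    deaths: int
    myocarditis_n: int
    myocarditis_deaths: int
    myocarditis_mortality_pct: float | None
    seropositivity: dict          # (antibody, method) -> (n_pos, n_total, pct)
    dual_positive: int
    at_least_one_positive: int

    def to_dict(self) -> dict:
        out = dict(vars(self))
        out["seropositivity"] = {
            f"{antibody}_{method}": {"n_pos": v[0], "n_total": v[1], "pct": v[2]}
            for (antibody, method), v in self.seropositivity.items()
        }
        return out


def cohort_summary(records: list[PatientRecord], sd_ddof: int = 1) -> CohortSummary:
    """All cohort-level descriptive numbers in one pass.

    The standard deviation uses the sample (n-1) convention by default and
    is reported missing for a single record.  Censored AChR titres are
    excluded from any numeric mean (none is reported here, but the rule is
    applied wherever titres are aggregated).
    """
    if not records:
        raise DomainError("cohort_summary requires at least one record")
    ages = np.array([r.age for r in records], dtype=float)
    cks = np.array([r.ck for r in records], dtype=float)
    n = len(records)

    def sd(values: np.ndarray) -> float | None:
        return float(values.std(ddof=sd_ddof)) if len(values) > sd_ddof else None

    subtype_counts = {s: sum(r.subtype == s for r in records) for s in SUBTYPES}
    mgfa_groups = sorted({r.mgfa_group for r in records})
    mgfa_group_counts = {g: sum(r.mgfa_group == g for r in records)
                         for g in mgfa_groups}
    deaths = sum(r.outcome == "Dead" for r in records)
    myo_n = sum(r.myocarditis for r in records)
    myo_deaths = sum(r.myocarditis and r.outcome == "Dead" for r in records)

    seropositivity = {}
    for antibody in ANTIBODIES:
        for method in METHODS:
            calls = [r.call(antibody, method) for r in records]
            n_pos = calls.count("positive")
            n_total = len(calls) - calls.count("no_data")
            seropositivity[(antibody, method)] = (
                n_pos, n_total, round_percent(n_pos, n_total))

    n_both, n_any = dual_positivity(records)
    return CohortSummary(
        n=n,
        n_male=sum(r.sex == "M" for r in records),
        n_female=sum(r.sex == "F" for r in records),
        age_mean=float(ages.mean()), age_sd=sd(ages),
        age_min=float(ages.min()), age_max=float(ages.max()),
        ck_mean=float(cks.mean()), ck_sd=sd(cks),
        ck_min=float(cks.min()), ck_max=float(cks.max()),
        subtype_counts=subtype_counts,
        mgfa_group_counts=mgfa_group_counts,
        thymoma_count=sum(r.thymoma for r in records),
        deaths=deaths,
        myocarditis_n=myo_n,
        myocarditis_deaths=myo_deaths,
        myocarditis_mortality_pct=round_percent(myo_deaths, myo_n),
        seropositivity=seropositivity,
        dual_positive=n_both,
        at_least_one_positive=n_any,
    )


def seropositivity_table(records: list[PatientRecord],
                         grouping: dict | None = None) -> pd.DataFrame:
    """Long-format seropositivity: one row per (group, antibody, method)
    with counts, ``no_data``-excluded totals and integer-rounded percents.

    ``grouping`` maps patient_id -> group name; all patients fall in one
    ``all`` group by default.
    """
    grouping = grouping or {}
    rows = []
    groups: dict[str, list[PatientRecord]] = {}
    for r in records:
        groups.setdefault(grouping.get(r.patient_id, "all"), []).append(r)
    for group, members in groups.items():
        for antibody in ANTIBODIES:
            for method in METHODS:
                calls = [m.call(antibody, method) for m in members]
                n_pos = calls.count("positive")
                n_total = len(calls) - calls.count("no_data")
                rows.append({
                    "group": group, "antibody": antibody, "method": method,
                    "n_pos": n_pos, "n_total": n_total,
                    "pct": round_percent(n_pos, n_total),
                })
    return pd.DataFrame(rows)


def seropositivity_from_results(results, grouping: dict | None = None
                                ) -> pd.DataFrame:
    """Group-level seropositivity computed from assay
    :class:`~cytocba.index.IndexResult` objects rather than a patient
    table (used to recover simulated-cohort prevalences)."""
    grouping = grouping or {}
    rows = []
    groups: dict[tuple, list] = {}
    for res in results:
        key = (grouping.get(res.serum_id, "all"), res.antigen)
        groups.setdefault(key, []).append(res.call)
    for (group, antigen), calls in sorted(groups.items()):
        n_pos = calls.count("positive")
        rows.append({
            "group": group, "antibody": antigen, "method": "cba",
            "n_pos": n_pos, "n_total": len(calls),
            "pct": round_percent(n_pos, len(calls)),
        })
    return pd.DataFrame(rows)


def dual_positivity(records: list[PatientRecord]) -> tuple[int, int]:
    """(patients positive for both antibodies, patients positive for at
    least one), over the cytometric cell-based-assay calls."""
    n_both = sum(r.titin_cba == "positive" and r.kv14_cba == "positive"
                 for r in records)
    n_any = sum(r.titin_cba == "positive" or r.kv14_cba == "positive"
                for r in records)
    return n_both, n_any


@dataclass
class Concordance:
    antibody: str
    n_pos_former: int   # headline count over all records (no_data cannot be positive)
    n_pos_cba: int
    n_discordant: int   # over records with former-method data
    n_evaluable: int    # records with former-method data


def method_concordance(records: list[PatientRecord], antibody: str) -> Concordance:
    """Compare the cytometric assay's calls with the former detection
    method for one antibody.  Discordance is evaluated only where the
    former method has data; the headline former-positive count is over all
    records, since a no-data row cannot be positive."""
    former = [r.call(antibody, "former") for r in records]
    cba = [r.call(antibody, "cba") for r in records]
    evaluable = [(f, c) for f, c in zip(former, cba) if f != "no_data"]
    return Concordance(
        antibody=antibody,
        n_pos_former=former.count("positive"),
        n_pos_cba=cba.count("positive"),
        n_discordant=sum(f != c for f, c in evaluable),
        n_evaluable=len(evaluable),
    )


@dataclass
class OutcomeAnalysis:
    deaths: int
    myocarditis_n: int
    myocarditis_deaths: int
    mortality_pct: float | None   # deaths among myocarditis patients
    n_both: int                   # myositis and myocarditis
    n_myositis_only: int
    n_myocarditis_only: int


def outcome_analysis(records: list[PatientRecord]) -> OutcomeAnalysis:
    """Deaths, the myositis/myocarditis subgroup split and mortality among
    myocarditis patients (integer-rounded percent)."""
    myo_n = sum(r.myocarditis for r in records)
    myo_deaths = sum(r.myocarditis and r.outcome == "Dead" for r in records)
    return OutcomeAnalysis(
        deaths=sum(r.outcome == "Dead" for r in records),
        myocarditis_n=myo_n,
        myocarditis_deaths=myo_deaths,
        mortality_pct=round_percent(myo_deaths, myo_n),
        n_both=sum(r.myositis and r.myocarditis for r in records),
        n_myositis_only=sum(r.myositis and not r.myocarditis for r in records),
        n_myocarditis_only=sum(r.myocarditis and not r.myositis for r in records),
    )


REPORT_SCHEMA = {
    "summary": dict,
    "concordance": dict,
    "outcomes": dict,
}


def cohort_report(records: list[PatientRecord], sd_ddof: int = 1) -> dict:
    """Full JSON-ready cohort report: summary + per-antibody concordance +
    outcome analysis."""
    return {
        "summary": cohort_summary(records, sd_ddof).to_dict(),
        "concordance": {antibody: vars(method_concordance(records, antibody))
                        for antibody in ANTIBODIES},
        "outcomes": vars(outcome_analysis(records)),
    }


def validate_cohort_report(report: dict) -> None:
    """Structural check of a cohort report against the shipped schema."""
    for key, expected_type in REPORT_SCHEMA.items():
        if key not in report:
            raise SchemaError(f"cohort report missing section {key!r}")
        if not isinstance(report[key], expected_type):
            raise SchemaError(f"cohort report section {key!r} has wrong type")
    for section in ("n", "deaths", "seropositivity"):
        if section not in report["summary"]:
            raise SchemaError(f"cohort report summary missing {section!r}")
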