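"""Cohort construction from coded discharge records.

Builds one diagnosis cohort from an NIS-schema discharge table: applies the
inclusion rule (primary diagnosis code in the diagnosis's code set, plus an
optional secondary-code requirement), the single exclusion rule (missing
race/ethnicity), drops stays whose disease-specific surgery preceded
admission, and derives the treatment variables — whether surgery was
delivered, its invasiveness category, temporizing-only care, time to surgery
and postoperative length of stay — from procedure codes and their day
offsets.

Day convention: procedure days are 0-based offsets from the admission day;
negative days are pre-admission procedures.  Time to surgery is the first
disease-specific surgery day; postoperative LOS is total LOS minus that day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError
from .survey import assign_age_band

logger = logging.getLogger(__name__)

SURGERY_CATEGORIES = ("least", "intermediate", "most")
#: Precedence when one stay carries codes from several categories: the most
#: invasive category wins.
CATEGORY_PRECEDENCE = ("most", "intermediate", "least")

RACE_LEVELS = ("black", "white", "latinx", "api", "native_other")

REQUIRED_COLUMNS = [
    "record_id", "year", "age", "race_raw", "hispanic_flag",
    "diagnosis_codes", "procedure_codes", "los_days", "died",
    "hospital_id", "stratum_id", "discwt", "trendwt",
]


@dataclass
class CodeMap:
    """Diagnosis/procedure code configuration for one diagnosis.

    ``surgery`` maps invasiveness category (least/intermediate/most) to code
    sets; the categories are nominal labels, never ordered in computation.
    ``comorbidities`` maps comorbidity names to the flag columns (or code-
    derived columns) that enter the crude comorbidity score.
    """

    name: str
    primary_dx: frozenset
    surgery: dict
    temporizing: frozenset = frozenset()
    secondary_required: frozenset | None = None
    unusual: frozenset = frozenset()
    comorbidities: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.primary_dx = frozenset(self.primary_dx)
        self.surgery = {k: frozenset(v) for k, v in self.surgery.items()}
        self.temporizing = frozenset(self.temporizing)
        self.unusual = frozenset(self.unusual)
        if self.secondary_required is not None:
            self.secondary_required = frozenset(self.secondary_required)
        unknown = set(self.surgery) - set(SURGERY_CATEGORIES)
        if unknown:
            raise ConfigError(f"{self.name}: unknown surgery categories {sorted(unknown)}")
        seen: dict[str, str] = {}
        for cat in SURGERY_CATEGORIES:
            for code in self.surgery.get(cat, ()):
                if code in seen:
                    raise ConfigError(
                        f"{self.name}: surgery code {code!r} appears in both "
                        f"{seen[code]!r} and {cat!r}"
                    )
                seen[code] = cat
        overlap = set(seen) & self.temporizing
        if overlap:
            raise ConfigError(
                f"{self.name}: codes {sorted(overlap)} are both surgical and temporizing"
            )

    @property
    def all_surgery_codes(self) -> frozenset:
        return frozenset().union(*self.surgery.values()) if self.surgery else frozenset()

    def category_of(self, code: str) -> str | None:
        for cat in SURGERY_CATEGORIES:
            if code in self.surgery.get(cat, ()):
                return cat
        return None


def load_codemaps(path: str | Path | None = None) -> dict[str, CodeMap]:
    """Load code maps from YAML; default is the packaged illustrative map."""
    if path is None:
        text = resources.files("egsdisparity.data").joinpath("illustrative_codes.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    maps = {}
    for name, spec in raw.items():
        maps[name] = CodeMap(
            name=name,
            primary_dx=spec["primary_dx"],
            surgery=spec.get("surgery", {}),
            temporizing=spec.get("temporizing", ()),
            secondary_required=spec.get("secondary_required"),
            unusual=spec.get("unusual", ()),
            comorbidities=spec.get("comorbidities", {}),
        )
    return maps


def _split_codes(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return str(cell).split()


def _parse_procedures(cell) -> list[tuple[str, float]]:
    """Parse 'code:day code:day ...'; a missing day parses to NaN."""
    out = []
    for tok in _split_codes(cell):
        code, _, day = tok.partition(":")
        out.append((code, float(day) if day not in ("", "nan") else np.nan))
    return out


def assign_race_ethnicity(df: pd.DataFrame) -> pd.Series:
    """Combined race/ethnicity: Hispanic ethnicity maps to latinx regardless
    of the race field; otherwise the race field itself; unmappable values
    become missing (and are excluded downstream)."""
    if not {"race_raw", "hispanic_flag"} <= set(df.columns):
        raise SchemaError({"race_raw", "hispanic_flag"} - set(df.columns))
    race = df["race_raw"].astype(object).where(df["race_raw"].notna(), None)
    out = []
    for r, h in zip(race, df["hispanic_flag"].fillna(0).astype(int)):
        if h == 1:
            out.append("latinx")
        elif r in RACE_LEVELS:
            out.append(r)
        else:
            out.append(None)
    return pd.Series(out, index=df.index, dtype=object)


def classify_treatment(df: pd.DataFrame, codemap: CodeMap) -> pd.DataFrame:
    """Treatment variables from procedure codes.

    Returns columns ``any_surgery``, ``surgery_category`` (highest-precedence
    matched category, most > intermediate > least), ``temporizing_only``,
    ``first_surgery_day`` (minimum day over matched surgery codes; NaN when
    no day is recorded or no surgery) and ``unusual_steps``.
    """
    rows = []
    for cell in df["procedure_codes"]:
        procs = _parse_procedures(cell)
        cats = set()
        days = []
        any_day_missing = False
        temporizing = False
        unusual = False
        for code, day in procs:
            cat = codemap.category_of(code)
            if cat is not None:
                cats.add(cat)
                if np.isnan(day):
                    any_day_missing = True
                else:
                    days.append(day)
            if code in codemap.temporizing:
                temporizing = True
            if code in codemap.unusual:
                unusual = True
        if cats:
            category = next(c for c in CATEGORY_PRECEDENCE if c in cats)
            first_day = min(days) if days else np.nan
            if any_day_missing and not days:
                first_day = np.nan
            rows.append((1, category, 0, first_day, int(unusual)))
        else:
            rows.append((0, "none", int(temporizing), np.nan, int(unusual)))
    return pd.DataFrame(
        rows,
        columns=["any_surgery", "surgery_category", "temporizing_only",
                 "first_surgery_day", "unusual_steps"],
        index=df.index,
    )


def build_cohort(df: pd.DataFrame, codemap: CodeMap, diagnosis: str | None = None,
                 log: dict | None = None) -> pd.DataFrame:
    """Apply inclusion/exclusion rules and derive treatment variables.

    Inclusion: primary (first-listed) diagnosis code in the diagnosis's set,
    and, when configured, a required code among the secondary diagnoses.
    Exclusions: missing race/ethnicity (the study's only patient-level
    exclusion) and disease-specific surgery before admission
    (``first_surgery_day < 0``).

    ``log``, when given, receives row counts for every step so callers can
    verify row-count conservation.
    """
    if diagnosis is not None and diagnosis != codemap.name:
        raise ConfigError(f"codemap is for {codemap.name!r}, not {diagnosis!r}")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(missing, table="discharge")
    acc = {} if log is None else log
    acc["input_rows"] = len(df)

    dx_lists = df["diagnosis_codes"].map(_split_codes)
    primary_ok = dx_lists.map(lambda c: bool(c) and c[0] in codemap.primary_dx)
    if codemap.secondary_required is not None:
        secondary_ok = dx_lists.map(
            lambda c: any(x in codemap.secondary_required for x in c[1:])
        )
        include = primary_ok & secondary_ok
    else:
        include = primary_ok
    acc["excluded_not_diagnosis"] = int((~include).sum())
    out = df.loc[include].copy()

    out["race_ethnicity"] = assign_race_ethnicity(out)
    n0 = len(out)
    out = out.loc[out["race_ethnicity"].notna()]
    acc["excluded_missing_race"] = n0 - len(out)

    derived = ["any_surgery", "surgery_category", "temporizing_only",
               "first_surgery_day", "unusual_steps", "time_to_surgery",
               "postop_los", "age_band", "diagnosis"]
    out = out.drop(columns=[c for c in derived if c in out.columns])
    out = pd.concat([out, classify_treatment(out, codemap)], axis=1)
    pre_admission = out["first_surgery_day"] < 0
    acc["excluded_preadmission_surgery"] = int(pre_admission.sum())
    out = out.loc[~pre_admission].copy()

    operated = out["any_surgery"] == 1
    out["time_to_surgery"] = np.where(operated, out["first_surgery_day"], np.nan)
    out["postop_los"] = np.where(
        operated, out["los_days"] - out["first_surgery_day"], np.nan
    )
    # clip rare inconsistencies where the recorded LOS ends before the
    # procedure day (possible in messy claims data)
    out.loc[out["postop_los"] < 0, "postop_los"] = 0.0
    out["age_band"] = assign_age_band(out["age"])
    out["diagnosis"] = codemap.name
    acc["retained_rows"] = len(out)
    return out.reset_index(drop=True)
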