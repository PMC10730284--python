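"""Data-driven covariates: diagnosis mortality subgroups, the crude
comorbidity excess-risk score, and hospital-level aggregates.

These are the empirically derived covariates entering the mediation models:

* primary diagnosis codes are grouped into three severity subgroups
  (lowest / intermediate / highest) by their weighted in-hospital mortality;
* each comorbidity's excess mortality risk (weighted risk difference,
  with minus without, within the diagnosis cohort) is summed over a
  record's comorbidities into a crude additive score;
* hospitals contribute their weighted operative rate, mean LOS, percent
  black patients, and white-black operative-rate difference as contextual
  covariates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ClassificationError
from .survey import SurveyDesign, weighted_mean

logger = logging.getLogger(__name__)

SUBGROUP_LABELS = ("lowest", "intermediate", "highest")


def _primary_code(cell) -> str:
    return str(cell).split()[0] if cell else ""


@dataclass
class DxSubgroupMap:
    """Primary-code -> mortality-severity subgroup assignment.

    Fitted by exhaustive search over the two cut points (in code-level
    weighted mortality) minimizing total within-group weighted variance;
    groups are relabeled so mean mortality is strictly ordered
    lowest < intermediate < highest.
    """

    code_mortality: dict
    code_weight: dict
    assignment: dict

    def subgroup_of(self, code: str) -> str:
        return self.assignment[code]

    def assign(self, df: pd.DataFrame, dx_col: str = "diagnosis_codes") -> pd.Series:
        """Subgroup label per record from its primary diagnosis code."""
        return df[dx_col].map(lambda c: self.assignment.get(_primary_code(c)))

    def group_means(self) -> dict:
        """Weighted mean mortality per subgroup."""
        out = {}
        for label in SUBGROUP_LABELS:
            codes = [c for c, g in self.assignment.items() if g == label]
            if not codes:
                continue
            w = np.array([self.code_weight[c] for c in codes])
            m = np.array([self.code_mortality[c] for c in codes])
            out[label] = float(np.sum(w * m) / np.sum(w))
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "code_mortality": self.code_mortality,
            "code_weight": self.code_weight,
            "assignment": self.assignment,
        }, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DxSubgroupMap":
        return cls(**yaml.safe_load(Path(path).read_text()))


def fit_dx_subgroups(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    died_col: str = "died",
    dx_col: str = "diagnosis_codes",
    weighted: bool = True,
    allow_single_group: bool = False,
) -> DxSubgroupMap:
    """Partition primary codes into three mortality subgroups.

    Code-level mortality is the weighted (or unweighted) death proportion;
    the two cut points are chosen by exhaustive search over sorted codes,
    minimizing within-group variance weighted by code discharge totals.
    """
    codes = cohort[dx_col].map(_primary_code)
    wcol = cohort[design.weight] if weighted else pd.Series(1.0, index=cohort.index)
    tab = pd.DataFrame({"code": codes, "died": cohort[died_col], "w": wcol})
    stats = tab.groupby("code").apply(
        lambda g: pd.Series({
            "mortality": np.sum(g["w"] * g["died"]) / np.sum(g["w"]),
            "weight": np.sum(g["w"]),
        }),
        include_groups=False,
    )
    if len(stats) < 3:
        if len(stats) >= 1 and allow_single_group:
            assignment = {c: "intermediate" for c in stats.index}
            return DxSubgroupMap(
                stats["mortality"].to_dict(), stats["weight"].to_dict(), assignment
            )
        raise ClassificationError(
            f"need >=3 distinct primary codes to form subgroups (got {len(stats)})"
        )
    stats = stats.sort_values("mortality")
    if stats["mortality"].nunique() == 1:
        if allow_single_group:
            assignment = {c: "intermediate" for c in stats.index}
            return DxSubgroupMap(
                stats["mortality"].to_dict(), stats["weight"].to_dict(), assignment
            )
        raise ClassificationError("all codes have identical mortality")
    m = stats["mortality"].to_numpy()
    w = stats["weight"].to_numpy()
    k = len(m)
    best = None
    for i, j in itertools.combinations(range(1, k), 2):
        loss = 0.0
        for lo, hi in ((0, i), (i, j), (j, k)):
            ww, mm = w[lo:hi], m[lo:hi]
            mu = np.sum(ww * mm) / np.sum(ww)
            loss += float(np.sum(ww * (mm - mu) ** 2))
        if best is None or loss < best[0] - 1e-15:
            best = (loss, i, j)
    _, i, j = best
    assignment = {}
    for idx, code in enumerate(stats.index):
        assignment[code] = SUBGROUP_LABELS[0 if idx < i else (1 if idx < j else 2)]
    return DxSubgroupMap(
        stats["mortality"].to_dict(), stats["weight"].to_dict(), assignment
    )


@dataclass
class ComorbidityScore:
    """Per-comorbidity excess mortality risks and the additive crude score.

    ``excess_risk[c]`` is the weighted death-risk difference (with minus
    without comorbidity ``c``) within the diagnosis cohort; negative values
    are retained.  A record's score is the sum over its present
    comorbidities; no comorbidities means a score of exactly 0.
    """

    excess_risk: dict
    columns: dict = field(default_factory=dict)

    def score(self, df: pd.DataFrame) -> pd.Series:
        total = pd.Series(0.0, index=df.index)
        for name, risk in self.excess_risk.items():
            if risk is None:
                continue
            col = self.columns.get(name, name)
            total = total + df[col].fillna(0).astype(float) * risk
        return total

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {"excess_risk": self.excess_risk, "columns": self.columns},
            sort_keys=True,
        ))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ComorbidityScore":
        return cls(**yaml.safe_load(Path(path).read_text()))


def fit_comorbidity_score(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    comorbidity_columns: dict | list,
    died_col: str = "died",
) -> ComorbidityScore:
    """Weighted excess-risk per comorbidity within one diagnosis cohort.

    A comorbidity present in no (or all) records has undefined excess risk;
    it is recorded as missing, excluded from the score, and logged.
    """
    if isinstance(comorbidity_columns, list):
        comorbidity_columns = {c: c for c in comorbidity_columns}
    excess = {}
    for name, col in comorbidity_columns.items():
        flags = cohort[col].fillna(0).astype(int)
        if flags.nunique() < 2:
            logger.warning(
                "comorbidity %r has zero variation; excess risk set missing", name
            )
            excess[name] = None
            continue
        with_ = weighted_mean(cohort, died_col, design, subset=(flags == 1))
        without = weighted_mean(cohort, died_col, design, subset=(flags == 0))
        excess[name] = float(with_.value - without.value)
    return ComorbidityScore(excess_risk=excess, columns=dict(comorbidity_columns))


def compute_hospital_aggregates(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    los_col: str = "los_days",
) -> pd.DataFrame:
    """Weighted per-hospital statistics used as contextual covariates.

    Returns one row per hospital present in the cohort: ``operative_rate``
    (weighted share with any surgery), ``mean_los``, ``pct_black`` and
    ``white_black_oprate_diff`` (white minus black weighted operative rate;
    missing unless the hospital saw at least one discharge of each group).
    """
    rows = []
    for hid, sub in cohort.groupby(design.cluster, sort=True):
        w = sub[design.weight].to_numpy(dtype=float)
        sw = w.sum()
        op = float(np.sum(w * sub["any_surgery"].to_numpy(dtype=float)) / sw)
        mean_los = float(np.sum(w * sub[los_col].to_numpy(dtype=float)) / sw)
        is_black = sub["race_ethnicity"] == "black"
        is_white = sub["race_ethnicity"] == "white"
        pct_black = float(w[is_black].sum() / sw)
        if is_black.any() and is_white.any():
            rb = float(np.sum(w[is_black] * sub.loc[is_black, "any_surgery"]) / w[is_black].sum())
            rw = float(np.sum(w[is_white] * sub.loc[is_white, "any_surgery"]) / w[is_white].sum())
            diff = rw - rb
        else:
            diff = np.nan
        rows.append((hid, op, mean_los, pct_black, diff))
    return pd.DataFrame(
        rows,
        columns=[design.cluster, "hosp_operative_rate", "hosp_mean_los",
                 "hosp_pct_black", "hosp_wb_oprate_diff"],
    )


def join_hospital_aggregates(
    cohort: pd.DataFrame, aggregates: pd.DataFrame, design: SurveyDesign
) -> pd.DataFrame:
    """Attach each record's hospital aggregates as record-level covariates."""
    return cohort.merge(aggregates, on=design.cluster, how="left")
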