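"""Grouped multiple mediation by the difference-of-coefficients method.

The disparity in an outcome is summarized by the black-vs-white coefficient
of a weighted generalized linear model.  The *total* effect is that
coefficient adjusted only for age and year; the *direct* (unexplained)
effect is the coefficient after additionally adjusting for all mediator
groups (medical, treatment, hospital, socioeconomic); the *specific
indirect (unique)* effect of one group is the change in the coefficient
when that group alone is removed from the fully adjusted model; and the
*overlap* is the remainder,

    overlap = total - direct - sum_g unique_g,

the portion of the disparity attributable non-uniquely to several groups at
once.  The identity is exact by construction on the link (coefficient)
scale — which is why the decomposition is carried on the link scale, with
odds-ratio / rate-ratio transforms derived for reporting only (link-scale
effects are non-collapsible, so ratio-scale components do not add).

Binary outcomes (surgery delivered, in-hospital mortality) use a binomial
logit; day counts (length of stay, time to surgery) use a negative binomial
log link, whose race coefficient is reported as a discharge-per-day
incidence rate ratio exp(-beta): a longer stay means a lower daily
probability of discharge, hence a ratio below 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EstimationError, FitError
from .survey import SurveyDesign

logger = logging.getLogger(__name__)

RACE_COL = "race_ethnicity"
RACE_REFERENCE = "white"
RACE_OF_INTEREST = "black"

Term = tuple  # (column, "cat" | "num")


@dataclass
class OutcomeSpec:
    """How one outcome is modeled and reported."""

    name: str
    column: str
    family: str  # "binomial" | "negbin"
    is_treatment: bool = False
    operated_only: bool = False
    hospital_stat: str = "hosp_operative_rate"

    @property
    def scale(self) -> str:
        return "log-odds" if self.family == "binomial" else "log-rate"

    def ratio(self, coef: float) -> float:
        """Odds ratio for logit outcomes; discharge-per-day incidence rate
        ratio exp(-coef) for day-count outcomes."""
        return float(np.exp(coef)) if self.family == "binomial" else float(np.exp(-coef))


OUTCOMES = {
    "surgery_delivered": OutcomeSpec(
        "surgery_delivered", "any_surgery", "binomial",
        is_treatment=True, hospital_stat="hosp_operative_rate"),
    "mortality": OutcomeSpec(
        "mortality", "died", "binomial", hospital_stat="hosp_operative_rate"),
    "los": OutcomeSpec("los", "los_days", "negbin", hospital_stat="hosp_mean_los"),
    "time_to_surgery": OutcomeSpec(
        "time_to_surgery", "time_to_surgery", "negbin",
        is_treatment=True, operated_only=True, hospital_stat="hosp_mean_los"),
}


@dataclass
class FactorGroups:
    """Named, disjoint covariate groups plus the always-included base set.

    Age and year (the base) enter every model being compared, so they are
    excluded from the mediation itself.  The hospital group's statistical
    covariate is outcome-specific (mean LOS for stay-length models,
    operative rate for surgery-delivery and mortality models) and is
    resolved at fit time from :attr:`OutcomeSpec.hospital_stat`.
    """

    base: list = field(default_factory=lambda: [
        ("age_band", "cat"), ("age", "num"), ("year", "num"),
    ])
    groups: dict = field(default_factory=lambda: {
        "medical": [("comorb_score", "num"), ("dx_subgroup", "cat"),
                    ("unusual_steps", "num")],
        "treatment": [("any_surgery", "num"), ("time_to_surgery_filled", "num"),
                      ("surgery_category", "cat")],
        "hospital": [("hosp_size", "cat"), ("hosp_ownership", "cat"),
                     ("hosp_region", "cat"), ("__hospital_stat__", "num")],
        "socioeconomic": [("payer", "cat"), ("zip_income_quartile", "cat"),
                          ("weekend_admission", "num"), ("elective_admission", "num")],
    })
    treatment_group: str = "treatment"

    def __post_init__(self) -> None:
        seen = {}
        for g, terms in self.groups.items():
            for col, _ in terms:
                if col in seen:
                    raise EstimationError(
                        f"column {col!r} appears in groups {seen[col]!r} and {g!r}"
                    )
                seen[col] = g

    def resolved(self, outcome: OutcomeSpec) -> dict:
        """Groups with the outcome-specific hospital covariate substituted."""
        out = {}
        for g, terms in self.groups.items():
            out[g] = [
                (outcome.hospital_stat if col == "__hospital_stat__" else col, kind)
                for col, kind in terms
            ]
        return out

    def with_extended_covariates(self, comorbidity_columns: list) -> "FactorGroups":
        """Sensitivity variant: individual comorbidity flags instead of the
        crude score, and the against-medical-advice flag added."""
        groups = {g: list(t) for g, t in self.groups.items()}
        groups["medical"] = [
            t for t in groups["medical"] if t[0] != "comorb_score"
        ] + [(c, "num") for c in comorbidity_columns]
        groups["socioeconomic"] = groups["socioeconomic"] + [("ama_flag", "num")]
        return replace(self, groups=groups)


@dataclass
class ModelFit:
    """A fitted component GLM and its race coefficient."""

    label: str
    race_coef: float
    race_se: float
    params: pd.Series
    bse: pd.Series
    n_obs: int
    alpha: float | None = None


@dataclass
class MediationDecomposition:
    """Link-scale decomposition of one outcome's black-white disparity."""

    outcome: str
    scale: str
    total: float
    total_se: float
    direct: float
    direct_se: float
    unique: dict
    unique_se: dict
    overlap: float
    n_obs: int
    alpha: float | None = None

    def additivity_residual(self) -> float:
        return self.total - (self.direct + sum(self.unique.values()) + self.overlap)

    def ratios(self, spec: OutcomeSpec | None = None) -> dict:
        """Ratio-scale report (odds or discharge-per-day rate ratios).

        Derived from link-scale components; because the links are
        nonlinear, ratio components are non-collapsible and do not
        multiply/add exactly.
        """
        spec = spec or OUTCOMES[self.outcome]
        out = {"total": spec.ratio(self.total), "direct": spec.ratio(self.direct),
               "overlap": spec.ratio(self.overlap)}
        for g, v in self.unique.items():
            out[f"unique_{g}"] = spec.ratio(v)
        return out

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "scale": self.scale,
            "total": self.total, "total_se": self.total_se,
            "direct": self.direct, "direct_se": self.direct_se,
            "unique": dict(self.unique), "unique_se": dict(self.unique_se),
            "overlap": self.overlap, "n_obs": self.n_obs,
            "ratio_scale": self.ratios(),
        }


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    levels = sorted(series.astype(str).unique())
    cols = {}
    for lev in levels[1:]:  # first sorted level is the reference
        cols[f"{prefix}[{lev}]"] = (series.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=series.index)


def build_design_matrix(df: pd.DataFrame, terms: list) -> pd.DataFrame:
    """Intercept + race dummies (white reference) + requested terms.

    Categorical terms are dummy-coded against their first sorted level.
    Constant and linearly dependent columns (e.g. a surgery-category "none"
    dummy alongside the surgery indicator) are dropped with a warning, in
    left-to-right order, so every fitted model has a full-rank design.
    """
    parts = [pd.DataFrame({"const": np.ones(len(df))}, index=df.index)]
    race = df[RACE_COL].astype(str)
    for lev in sorted(race.unique()):
        if lev == RACE_REFERENCE:
            continue
        parts.append(pd.DataFrame(
            {f"race[{lev}]": (race == lev).astype(float)}, index=df.index))
    for col, kind in terms:
        if kind == "cat":
            parts.append(_dummies(df[col], col))
        else:
            parts.append(df[[col]].astype(float))
    X = pd.concat(parts, axis=1)
    cols = list(X.columns)
    G = X.to_numpy(dtype=float)
    G = G.T @ G
    kept: list[int] = []
    dropped: list[str] = []
    for j in range(len(cols)):
        if not kept:
            kept.append(j)
            continue
        gjj = G[j, j]
        if gjj <= 0:
            dropped.append(cols[j])
            continue
        sub = G[np.ix_(kept, kept)]
        cross = G[kept, j]
        try:
            resid = gjj - cross @ np.linalg.solve(sub, cross)
        except np.linalg.LinAlgError:  # pragma: no cover - kept set is full rank
            resid = 0.0
        if resid > 1e-8 * gjj:
            kept.append(j)
        else:
            dropped.append(cols[j])
    if dropped:
        logger.warning("dropping collinear/constant design columns %s", dropped)
    return X.iloc[:, kept]


def _estimate_alpha(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    """Moment estimate of negative-binomial dispersion from Poisson fit:
    weighted regression of ((y-mu)^2 - mu)/mu on mu (through the origin)."""
    z = ((y - mu) ** 2 - mu) / mu
    num = float(np.sum(w * z * mu))
    den = float(np.sum(w * mu**2))
    return float(min(max(num / den, 1e-6), 10.0))


def fit_outcome_model(
    cohort: pd.DataFrame,
    outcome: OutcomeSpec,
    terms: list,
    design: SurveyDesign,
    alpha: float | None = None,
    label: str = "model",
) -> ModelFit:
    """Weighted GLM of the outcome on race, base covariates and ``terms``,
    with design-based (cluster-robust by hospital) standard errors.

    Survey weights enter as frequency weights normalized to mean 1, so the
    effective sample size equals the number of observations; the sandwich
    covariance clusters on the design's PSU.  For negative-binomial
    outcomes the dispersion is the supplied ``alpha`` or a Pearson moment
    estimate from an initial Poisson fit.
    """
    cols = [outcome.column, RACE_COL, design.weight, design.cluster]
    cols += [c for c, _ in terms]
    data = cohort
    if outcome.operated_only:
        data = data.loc[data["any_surgery"] == 1]
    data = data.dropna(subset=[c for c in cols if c in data.columns])
    if len(data) == 0:
        raise EstimationError(f"empty data for outcome {outcome.name!r}")
    y = data[outcome.column].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise FitError(f"outcome {outcome.name!r} is constant")
    X = build_design_matrix(data, terms)
    w = data[design.weight].to_numpy(dtype=float)
    w = w / w.mean()
    groups = pd.factorize(data[design.cluster])[0]
    if outcome.family == "binomial":
        family = sm.families.Binomial()
    else:
        if alpha is None:
            pois = sm.GLM(y, X, family=sm.families.Poisson(), freq_weights=w).fit()
            alpha = _estimate_alpha(y, np.asarray(pois.mu), w)
        family = sm.families.NegativeBinomial(alpha=alpha)
    try:
        import warnings

        with warnings.catch_warnings():
            # statsmodels emits a generic advisory about freq_weights with
            # sandwich covariances; scores are weighted correctly for the
            # frequency interpretation used here
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=family, freq_weights=w).fit(
                cov_type="cluster", cov_kwds={"groups": groups}, maxiter=200,
            )
    except Exception as exc:  # pragma: no cover - defensive
        raise FitError(f"{label}: GLM fit failed for {outcome.name!r}: {exc}") from exc
    if not getattr(res, "converged", True):
        raise FitError(f"{label}: IRLS did not converge for {outcome.name!r}")
    if not np.all(np.isfinite(res.params)):
        raise FitError(f"{label}: non-finite coefficients for {outcome.name!r} "
                       "(possible separation)")
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    race_key = f"race[{RACE_OF_INTEREST}]"
    if race_key not in params.index:
        raise FitError(f"{label}: no {RACE_OF_INTEREST!r} rows in fitted data")
    return ModelFit(
        label=label,
        race_coef=float(params[race_key]),
        race_se=float(bse[race_key]),
        params=params,
        bse=bse,
        n_obs=len(data),
        alpha=alpha if outcome.family == "negbin" else None,
    )


def decompose(
    cohort: pd.DataFrame,
    outcome: OutcomeSpec | str,
    groups: FactorGroups,
    design: SurveyDesign,
) -> MediationDecomposition:
    """Difference-of-coefficients decomposition for one outcome.

    Fits the base model (total), the fully adjusted model (direct) and one
    leave-one-group-out model per mediator group; when the outcome is
    itself a treatment variable the treatment group is excluded from the
    mediators.  The negative-binomial dispersion is estimated once, on the
    fully adjusted model, and held fixed across the nested fits so that
    coefficient differences are comparable.

    The SE attached to each unique component is the conservative
    ``sqrt(se_loo^2 + se_direct^2)``, ignoring the positive correlation of
    the two race coefficients (no formal testing is attached to the
    components).
    """
    if isinstance(outcome, str):
        outcome = OUTCOMES[outcome]
    resolved = groups.resolved(outcome)
    if outcome.is_treatment:
        resolved = {g: t for g, t in resolved.items() if g != groups.treatment_group}
    group_names = list(resolved)
    all_terms = list(groups.base) + [t for g in group_names for t in resolved[g]]

    alpha = None
    full = fit_outcome_model(cohort, outcome, all_terms, design, label="full")
    alpha = full.alpha
    base = fit_outcome_model(cohort, outcome, list(groups.base), design,
                             alpha=alpha, label="base")
    unique = {}
    unique_se = {}
    for g in group_names:
        terms = list(groups.base) + [
            t for other in group_names if other != g for t in resolved[other]
        ]
        loo = fit_outcome_model(cohort, outcome, terms, design, alpha=alpha,
                                label=f"without_{g}")
        unique[g] = loo.race_coef - full.race_coef
        unique_se[g] = float(np.hypot(loo.race_se, full.race_se))
    total = base.race_coef
    direct = full.race_coef
    overlap = total - direct - sum(unique.values())
    return MediationDecomposition(
        outcome=outcome.name,
        scale=outcome.scale,
        total=total,
        total_se=base.race_se,
        direct=direct,
        direct_se=full.race_se,
        unique=unique,
        unique_se=unique_se,
        overlap=overlap,
        n_obs=full.n_obs,
        alpha=alpha,
    )


def sensitivity_suite(
    cohort: pd.DataFrame,
    outcome: OutcomeSpec | str,
    groups: FactorGroups,
    design: SurveyDesign,
    comorbidity_columns: list = ("cm_chf", "cm_diabetes", "cm_renal"),
    recent_years: tuple = (2016, 2017),
) -> dict:
    """The three robustness checks of the main decomposition.

    (a) excluding elective admissions; (b) restricting to the most recent
    years; (c) swapping the comorbidity score for individual comorbidity
    flags and adding the against-medical-advice flag.  A variant whose
    restricted subset is empty is skipped with a warning.
    """
    results: dict = {}
    non_elective = cohort.loc[cohort["elective_admission"] == 0]
    if len(non_elective):
        results["non_elective"] = decompose(non_elective, outcome, groups, design)
    else:
        logger.warning("sensitivity 'non_elective' skipped: no rows")
    recent = cohort.loc[cohort["year"].isin(recent_years)]
    if len(recent):
        results["recent_years"] = decompose(recent, outcome, groups, design)
    else:
        logger.warning("sensitivity 'recent_years' skipped: no rows in %s",
                       recent_years)
    extended = groups.with_extended_covariates(list(comorbidity_columns))
    results["extended_covariates"] = decompose(cohort, outcome, extended, design)
    return results
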