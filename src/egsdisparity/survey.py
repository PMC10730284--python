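"""Design-based estimation for stratified, clustered, weighted discharge samples.

The sampling design mirrors a national inpatient discharge sample: hospitals
are the primary sampling units (clusters), nested in design strata, and each
discharge carries a sampling weight.  Point estimates are Hajek ratio means
(sum(w*y)/sum(w)) and variances come from Taylor linearization of the ratio,
aggregating linearized scores to cluster totals and measuring their
between-cluster dispersion within strata.  This is the standard variance
estimator for such designs (the behaviour of R's ``survey`` package, without
finite-population corrections).

Age adjustment is direct standardization over five age bands against a
standard age distribution; treatment standardization reweights one group's
joint (age band x treatment stratum) distribution to a reference group's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, SchemaError

logger = logging.getLogger(__name__)

#: Critical value used for all normal-theory 95% intervals.
Z_95 = 1.96

AGE_BANDS = ["<40", "40-54", "55-69", "70-89", ">89"]


def assign_age_band(age: pd.Series) -> pd.Series:
    """Bin age in years into the five analysis bands."""
    return pd.cut(
        age,
        bins=[-np.inf, 40, 55, 70, 90, np.inf],
        right=False,
        labels=AGE_BANDS,
    ).astype(object)


@dataclass(frozen=True)
class SurveyDesign:
    """Column names defining the complex-survey design of a discharge table.

    Parameters
    ----------
    weight : discharge-level sampling weight column (``discwt`` for
        cross-sectional estimates, ``trendwt`` for across-year trends).
    stratum : design stratum identifier column.
    cluster : primary-sampling-unit (hospital) identifier column.
    """

    weight: str = "discwt"
    stratum: str = "stratum_id"
    cluster: str = "hospital_id"

    def validate(self, df: pd.DataFrame) -> None:
        missing = {self.weight, self.stratum, self.cluster} - set(df.columns)
        if missing:
            raise SchemaError(missing, table="design")
        w = df[self.weight].to_numpy(dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise EstimationError("survey weights must be positive and finite")


@dataclass
class Estimate:
    """A design-based point estimate with normal-theory uncertainty."""

    value: float
    se: float
    n_obs: int
    sum_weights: float

    @property
    def ci_low(self) -> float:
        return self.value - Z_95 * self.se

    @property
    def ci_high(self) -> float:
        return self.value + Z_95 * self.se

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Estimate(value={self.value:.6g}, se={self.se:.3g}, "
            f"95% CI [{self.ci_low:.6g}, {self.ci_high:.6g}], n={self.n_obs})"
        )


@dataclass
class AgeStandard:
    """A standard age distribution over the five analysis bands.

    Weights must sum to 1.  The default standard for a cohort is its pooled
    (all race/ethnicity groups) weighted age-band distribution, which is
    symmetric between the groups being compared.
    """

    weights: dict[str, float]

    def __post_init__(self) -> None:
        total = float(sum(self.weights.values()))
        if not np.isclose(total, 1.0, atol=1e-9):
            raise EstimationError(
                f"age-standard weights must sum to 1 (got {total:.12g})"
            )
        if any(v < 0 for v in self.weights.values()):
            raise EstimationError("age-standard weights must be nonnegative")

    @classmethod
    def from_cohort(
        cls, df: pd.DataFrame, design: SurveyDesign, band_col: str = "age_band"
    ) -> "AgeStandard":
        """Pooled weighted age-band distribution of a cohort."""
        w = df.groupby(band_col, observed=True)[design.weight].sum()
        return cls((w / w.sum()).to_dict())


def _taylor_variance(
    z: np.ndarray, strata: np.ndarray, clusters: np.ndarray
) -> float:
    """Between-cluster-within-stratum variance of a linearized score.

    ``z`` holds per-record linearized scores whose population total is the
    quantity of interest; the estimator sums, within each stratum ``h`` with
    ``n_h`` sampled clusters, ``n_h/(n_h-1)`` times the squared deviations of
    cluster score totals from their stratum mean.  A stratum with a single
    cluster (lonely PSU) cannot be centered internally; its cluster total is
    centered at the grand mean of all cluster totals, a conservative
    convention.
    """
    df = pd.DataFrame({"z": z, "h": strata, "c": clusters})
    totals = df.groupby(["h", "c"], observed=True, sort=True)["z"].sum()
    var = 0.0
    lonely = []
    grand_mean = float(totals.mean())
    for h, zh in totals.groupby(level="h", observed=True, sort=True):
        nh = len(zh)
        if nh == 1:
            lonely.append(h)
            var += float((zh.iloc[0] - grand_mean) ** 2)
        else:
            dev = zh.to_numpy() - zh.to_numpy().mean()
            var += nh / (nh - 1) * float(np.sum(dev**2))
    if lonely:
        logger.warning(
            "lonely PSU in strata %s: singleton cluster centered at grand mean",
            lonely,
        )
    return var


def weighted_mean(
    df: pd.DataFrame,
    column: str,
    design: SurveyDesign,
    subset: pd.Series | np.ndarray | None = None,
) -> Estimate:
    """Design-based (Hajek) mean of ``column`` with Taylor-linearized SE.

    Rows with missing values of ``column`` are excluded from the domain.
    Domain (subgroup) estimation keeps the full design structure of ``df``:
    rows outside the domain carry zero linearized scores but their clusters
    still anchor the between-cluster variance, the standard convention for
    design-based subgroup inference.
    """
    design.validate(df)
    if column not in df.columns:
        raise SchemaError({column})
    mask = df[column].notna().to_numpy()
    if subset is not None:
        mask = mask & np.asarray(subset, dtype=bool)
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise EstimationError(f"empty subset for weighted mean of {column!r}")
    y = np.where(mask, df[column].to_numpy(dtype=float, na_value=0.0), 0.0)
    w = df[design.weight].to_numpy(dtype=float)
    wm = np.where(mask, w, 0.0)
    sw = float(wm.sum())
    mean = float(np.sum(wm * y) / sw)
    # Linearized score of the ratio estimator sum(wy)/sum(w); zero outside
    # the domain.
    z = wm * (y - mean) / sw
    var = _taylor_variance(
        z, df[design.stratum].to_numpy(), df[design.cluster].to_numpy()
    )
    return Estimate(value=mean, se=float(np.sqrt(var)), n_obs=n_obs, sum_weights=sw)


def age_adjusted_mean(
    df: pd.DataFrame,
    column: str,
    design: SurveyDesign,
    standard: AgeStandard,
    subset: pd.Series | np.ndarray | None = None,
    band_col: str = "age_band",
) -> Estimate:
    """Directly age-standardized mean: sum_b s_b * mean(column | band b).

    Bands carrying standard weight but empty in the subset are dropped from
    both the standard (renormalized) and the estimate, with a log message.
    The SE treats band-specific estimates as independent:
    ``sqrt(sum_b s_b^2 se_b^2)``.
    """
    base = np.ones(len(df), dtype=bool) if subset is None else np.asarray(subset, dtype=bool)
    bands = {b: s for b, s in standard.weights.items() if s > 0}
    present = set(df.loc[base & df[column].notna().to_numpy(), band_col].unique())
    usable = {b: s for b, s in bands.items() if b in present}
    if not usable:
        raise EstimationError("no age band with data and positive standard weight")
    dropped = set(bands) - set(usable)
    if dropped:
        logger.warning("age bands %s empty in subset; dropped and renormalized", sorted(dropped))
    norm = sum(usable.values())
    value = 0.0
    var = 0.0
    n_obs = 0
    sw = 0.0
    for b, s in usable.items():
        sb = s / norm
        est = weighted_mean(df, column, design,
                            subset=base & (df[band_col] == b).to_numpy())
        value += sb * est.value
        var += sb**2 * est.se**2
        n_obs += est.n_obs
        sw += est.sum_weights
    return Estimate(value=value, se=float(np.sqrt(var)), n_obs=n_obs, sum_weights=sw)


@dataclass
class GroupComparison:
    """Age-adjusted estimates for two groups and their difference."""

    group_a: str
    group_b: str
    estimate_a: Estimate
    estimate_b: Estimate
    difference: Estimate
    p_value: float


def compare_groups(
    df: pd.DataFrame,
    column: str,
    design: SurveyDesign,
    standard: AgeStandard,
    group_col: str = "race_ethnicity",
    group_a: str = "black",
    group_b: str = "white",
    band_col: str = "age_band",
) -> GroupComparison:
    """Difference of age-adjusted means (a minus b) with a Wald z test."""
    est = {}
    for g in (group_a, group_b):
        mask = df[group_col] == g
        if not mask.any():
            raise EstimationError(f"group {g!r} empty in comparison of {column!r}")
        est[g] = age_adjusted_mean(df, column, design, standard, subset=mask, band_col=band_col)
    a, b = est[group_a], est[group_b]
    diff = a.value - b.value
    se = float(np.hypot(a.se, b.se))
    if se == 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(diff) / se))
    d = Estimate(value=diff, se=se, n_obs=a.n_obs + b.n_obs, sum_weights=a.sum_weights + b.sum_weights)
    return GroupComparison(group_a, group_b, a, b, d, p)


@dataclass
class TreatmentStandardization:
    """LOS disparity before and after standardizing for treatment factors.

    ``percent_change`` is (unadjusted - adjusted) / unadjusted * 100 — the
    share of the disparity explained by differential treatment.
    """

    outcome: str
    treatment_vars: list[str]
    unadjusted: Estimate
    adjusted: Estimate
    percent_change: float
    n_collapsed_strata: int = 0


def _stratum_means(
    data: pd.DataFrame,
    column: str,
    design: SurveyDesign,
    keys: list[str],
    group_mask: np.ndarray,
) -> pd.DataFrame:
    """Weighted mean, Taylor SE and weight share per stratum of ``keys``
    within one group, keeping the full design for variance estimation.

    Strata are keyed by a string join of the key values; the first key (the
    age band) is kept in its own column for the collapse rule.
    """
    labels = data[keys].astype(str).agg("|".join, axis=1).to_numpy()
    bands = data[keys[0]].astype(str).to_numpy()
    rows = []
    for label in sorted(set(labels[group_mask])):
        mask = group_mask & (labels == label)
        est = weighted_mean(data, column, design, subset=mask)
        rows.append((label, bands[mask.argmax()], est.value, est.se,
                     est.sum_weights))
    out = pd.DataFrame(rows, columns=["key", "band", "mean", "se", "sw"])
    out["share"] = out["sw"] / out["sw"].sum()
    return out.set_index("key")


def standardize_for_treatment(
    df: pd.DataFrame,
    design: SurveyDesign,
    treatment_vars: list[str],
    outcome: str = "los_days",
    group_col: str = "race_ethnicity",
    reference: str = "white",
    comparison: str = "black",
    band_col: str = "age_band",
) -> TreatmentStandardization:
    """Disparity in ``outcome`` with and without treatment standardization.

    Both estimates standardize to the reference group's distribution so that
    the only thing changing between them is the stratification:

    * unadjusted: comparison-group age-band means reweighted to the
      reference group's age distribution (direct age standardization);
    * adjusted: comparison-group means over joint (age band x treatment)
      strata reweighted to the reference group's joint distribution.

    Disparity is comparison minus reference.  Joint strata where the
    reference group has weight but the comparison group has no rows are
    collapsed: their reference weight is reallocated proportionally across
    the comparison-present strata of the same age band.
    """
    data = df.loc[df[outcome].notna()].copy()
    for v in treatment_vars:
        data = data.loc[data[v].notna()]
    data = data.reset_index(drop=True)
    ref_mask = (data[group_col] == reference).to_numpy()
    cmp_mask = (data[group_col] == comparison).to_numpy()
    if not ref_mask.any() or not cmp_mask.any():
        raise EstimationError("both groups must be nonempty for standardization")
    n_ref = int(ref_mask.sum())
    n_cmp = int(cmp_mask.sum())
    sw_total = float(data.loc[ref_mask | cmp_mask, design.weight].sum())

    def _disparity(keys: list[str]) -> tuple[Estimate, int]:
        mr = _stratum_means(data, outcome, design, keys, ref_mask)
        mc = _stratum_means(data, outcome, design, keys, cmp_mask)
        # collapse reference strata absent in comparison group within age band
        shares = mr["share"].copy()
        missing = [k for k in mr.index if k not in mc.index]
        n_collapsed = len(missing)
        if n_collapsed:
            logger.warning(
                "%d treatment strata empty in %s group; reference weight "
                "reallocated within age band", n_collapsed, comparison,
            )
            for key in missing:
                band = mr.at[key, "band"]
                peers = [
                    k for k in mr.index
                    if mr.at[k, "band"] == band and k in mc.index
                ]
                lost = shares.at[key]
                shares.at[key] = 0.0
                peer_total = shares.loc[peers].sum() if peers else 0.0
                if peers and peer_total > 0:
                    shares.loc[peers] += lost * shares.loc[peers] / peer_total
                elif peers:
                    shares.loc[peers] += lost / len(peers)
                # no peers in band: the band's weight is dropped entirely
        shares = shares / shares.sum()
        value = 0.0
        var = 0.0
        for key, s in shares.items():
            if s == 0 or key not in mc.index:
                continue
            value += s * (mc.at[key, "mean"] - mr.at[key, "mean"])
            var += s**2 * (mc.at[key, "se"] ** 2 + mr.at[key, "se"] ** 2)
        est = Estimate(
            value=float(value),
            se=float(np.sqrt(var)),
            n_obs=n_ref + n_cmp,
            sum_weights=sw_total,
        )
        return est, n_collapsed

    unadj, _ = _disparity([band_col])
    adj, n_collapsed = _disparity([band_col, *treatment_vars])
    if unadj.value == 0:
        pct = float("nan")
    else:
        pct = float((unadj.value - adj.value) / unadj.value * 100.0)
    return TreatmentStandardization(
        outcome=outcome,
        treatment_vars=list(treatment_vars),
        unadjusted=unadj,
        adjusted=adj,
        percent_change=pct,
        n_collapsed_strata=n_collapsed,
    )
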