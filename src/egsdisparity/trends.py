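"""Yearly disparity series, trend tests, and gap-closure extrapolation.

One age-adjusted black-white disparity is estimated per calendar year with
the trend weights; a simple (ordinary least squares) regression of the
yearly disparities on calendar year tests whether the gap is widening or
narrowing, and, when the gap is significantly shrinking, the years until
closure are extrapolated from the final observed year's disparity and the
fitted annual slope.

Year 2015 is always excluded: the sample's sampling methodology changed
mid-year, making that year's estimates incomparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import TrendError
from .survey import AgeStandard, SurveyDesign, compare_groups

logger = logging.getLogger(__name__)

EXCLUDED_YEAR = 2015


@dataclass
class DisparitySeries:
    """Per-year age-adjusted disparity estimates for one metric."""

    metric: str
    group_a: str
    group_b: str
    table: pd.DataFrame  # columns: year, disparity, se, p_value, n_obs

    @property
    def years(self) -> np.ndarray:
        return self.table["year"].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.table["disparity"].to_numpy()


@dataclass
class TrendFit:
    """OLS fit of disparity on calendar year with closure extrapolation.

    ``years_to_closure`` is |final-year disparity / slope|, present only
    when the slope is statistically significant (p < 0.05) and opposes the
    sign of the final-year disparity, i.e. the gap is closing.
    """

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    n_years: int
    final_year: int
    final_disparity: float
    years_to_closure: float | None

    @property
    def direction(self) -> str:
        if self.p_value >= 0.05:
            return "stable"
        closing = np.sign(self.final_disparity) == -np.sign(self.slope)
        return "closing" if closing else "widening"


def build_series(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    metric: str,
    standard: AgeStandard | None = None,
    group_col: str = "race_ethnicity",
    group_a: str = "black",
    group_b: str = "white",
    band_col: str = "age_band",
) -> DisparitySeries:
    """Age-adjusted yearly disparity (group_a minus group_b) with trendwt.

    Years where either group is absent are dropped with a log message; 2015
    is dropped unconditionally.  The standard population defaults to the
    pooled weighted age distribution of the full multi-year cohort.
    """
    if standard is None:
        standard = AgeStandard.from_cohort(cohort, design, band_col)
    rows = []
    years = sorted(int(y) for y in cohort["year"].unique())
    for year in years:
        if year == EXCLUDED_YEAR:
            logger.info("year 2015 excluded from trend series by convention")
            continue
        sub = cohort.loc[cohort["year"] == year]
        present = set(sub.loc[sub[metric].notna(), group_col])
        if not {group_a, group_b} <= present:
            logger.warning("year %d dropped: a comparison group is absent", year)
            continue
        cmp_ = compare_groups(
            sub, metric, design, standard,
            group_col=group_col, group_a=group_a, group_b=group_b,
            band_col=band_col,
        )
        rows.append((year, cmp_.difference.value, cmp_.difference.se,
                     cmp_.p_value, cmp_.difference.n_obs))
    if len(rows) < 2:
        raise TrendError("need at least 2 usable years for a disparity series")
    table = pd.DataFrame(rows, columns=["year", "disparity", "se", "p_value", "n_obs"])
    return DisparitySeries(metric=metric, group_a=group_a, group_b=group_b, table=table)


def fit_trend(series: DisparitySeries) -> TrendFit:
    """Simple regression of yearly disparity on calendar year.

    Unweighted OLS on the yearly point estimates; the closed-form slope
    Sxy/Sxx with a two-sided t test on n-2 degrees of freedom.  A perfectly
    linear series (zero residual) gets p = 0 for a nonzero slope and p = 1
    for a flat one.
    """
    x = series.years.astype(float)
    y = series.values.astype(float)
    n = len(x)
    if n < 3:
        raise TrendError(f"need >=3 yearly estimates to fit a trend (got {n})")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    ssr = float(np.sum(resid**2))
    if ssr <= 1e-300:
        slope_se = 0.0
        p = 1.0 if slope == 0 else 0.0
    else:
        s2 = ssr / (n - 2)
        slope_se = float(np.sqrt(s2 / sxx))
        t = slope / slope_se
        p = float(2 * sps.t.sf(abs(t), n - 2))
    final_year = int(x[-1])
    final_disp = float(y[-1])
    closing = (
        p < 0.05
        and slope != 0
        and final_disp != 0
        and np.sign(final_disp) == -np.sign(slope)
    )
    closure = abs(final_disp / slope) if closing else None
    return TrendFit(
        slope=slope, intercept=intercept, slope_se=slope_se, p_value=p,
        n_years=n, final_year=final_year, final_disparity=final_disp,
        years_to_closure=closure,
    )


def plot_series(series: DisparitySeries, fit: TrendFit | None = None,
                path=None):
    """Yearly disparity plot with 95% CIs and, optionally, the fitted
    trend line annotated with significance and years-to-closure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    t = series.table
    ax.errorbar(t["year"], t["disparity"], yerr=1.96 * t["se"],
                fmt="o-", capsize=3, lw=1)
    ax.axhline(0.0, color="gray", lw=0.8)
    if fit is not None:
        x = np.array([t["year"].min(), t["year"].max()], dtype=float)
        ax.plot(x, fit.intercept + fit.slope * x, "--", color="C3")
        note = f"slope {fit.slope:+.3g}/yr (p={fit.p_value:.3g})"
        if fit.years_to_closure is not None:
            note += f"; closure in {fit.years_to_closure:.0f} y"
        ax.set_title(note, fontsize=10)
    ax.set_xlabel("year")
    ax.set_ylabel(f"{series.group_a} - {series.group_b} {series.metric}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
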