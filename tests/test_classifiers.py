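"""Empirically derived covariates: diagnosis mortality subgroups, the crude
comorbidity excess-risk score, and hospital aggregates."""

import itertools

import numpy as np
import pandas as pd
import pytest

from egsdisparity import (
    ClassificationError,
    compute_hospital_aggregates,
    fit_comorbidity_score,
    fit_dx_subgroups,
    join_hospital_aggregates,
)


def frame_from_codes(code_mortality, n_per_code=200, weights=None):
    """Cohort whose code-level death proportions are exact by construction."""
    rows = []
    for j, (code, m) in enumerate(code_mortality.items()):
        k = int(round(m * n_per_code))
        for i in range(n_per_code):
            rows.append({
                "diagnosis_codes": code,
                "died": 1 if i < k else 0,
                "discwt": 1.0 if weights is None else weights[j],
                "stratum_id": "s",
                "hospital_id": f"h{j}",
            })
    return pd.DataFrame(rows)


class TestDxSubgroups:
    def test_exhaustive_search_oracle(self, design):
        """Partition of mortalities {.001,.002,.05,.06,.30} must match the
        brute-force minimum-within-group-variance split computed here by
        direct enumeration."""
        mort = {"c1": 0.005, "c2": 0.010, "c3": 0.050, "c4": 0.060, "c5": 0.300}
        df = frame_from_codes(mort)
        fitted = fit_dx_subgroups(df, design)
        # independent exhaustive enumeration over the two cut points
        codes = sorted(mort, key=mort.get)
        vals = np.array([mort[c] for c in codes])
        best, best_loss = None, np.inf
        for i, j in itertools.combinations(range(1, 5), 2):
            loss = sum(
                ((vals[lo:hi] - vals[lo:hi].mean()) ** 2).sum()
                for lo, hi in ((0, i), (i, j), (j, 5))
            )
            if loss < best_loss:
                best, best_loss = (i, j), loss
        i, j = best
        expected = {}
        for idx, c in enumerate(codes):
            expected[c] = ("lowest" if idx < i else
                           "intermediate" if idx < j else "highest")
        assert fitted.assignment == expected
        assert expected == {"c1": "lowest", "c2": "lowest",
                            "c3": "intermediate", "c4": "intermediate",
                            "c5": "highest"}

    def test_group_means_strictly_ordered(self, chole_cohort, design):
        fitted = fit_dx_subgroups(chole_cohort, design)
        means = fitted.group_means()
        assert means["lowest"] < means["intermediate"] < means["highest"]

    def test_too_few_codes_raises(self, design):
        df = frame_from_codes({"a": 0.1, "b": 0.2})
        with pytest.raises(ClassificationError):
            fit_dx_subgroups(df, design)

    def test_identical_mortalities_degenerate(self, design):
        df = frame_from_codes({"a": 0.1, "b": 0.1, "c": 0.1})
        with pytest.raises(ClassificationError):
            fit_dx_subgroups(df, design)
        single = fit_dx_subgroups(df, design, allow_single_group=True)
        assert set(single.assignment.values()) == {"intermediate"}

    def test_refit_deterministic_and_persistable(self, chole_cohort, design, tmp_path):
        a = fit_dx_subgroups(chole_cohort, design)
        b = fit_dx_subgroups(chole_cohort, design)
        assert a.assignment == b.assignment
        a.to_yaml(tmp_path / "map.yaml")
        from egsdisparity import DxSubgroupMap

        c = DxSubgroupMap.from_yaml(tmp_path / "map.yaml")
        assert c.assignment == a.assignment
        assert c.assign(chole_cohort).equals(a.assign(chole_cohort))


class TestComorbidityScore:
    @staticmethod
    def _cohort_with_flags(p_death_with=0.10, p_death_without=0.02, n=2000):
        rng = np.random.default_rng(8)
        flag = (rng.random(n) < 0.3).astype(int)
        died = np.where(flag == 1, rng.random(n) < p_death_with,
                        rng.random(n) < p_death_without).astype(int)
        return pd.DataFrame({
            "cm_a": flag, "cm_b": 0, "died": died, "discwt": 1.0,
            "stratum_id": "s", "hospital_id": rng.choice(list("xyzuv"), n),
        })

    def test_excess_risk_is_weighted_risk_difference(self, design):
        """Exact arithmetic: mortality 0.10 with vs 0.02 without gives
        excess risk 0.08 when proportions are exact by construction."""
        df = pd.DataFrame({
            "cm_a": [1] * 10 + [0] * 50,
            "died": [1] + [0] * 9 + [1] + [0] * 49,
            "discwt": 1.0, "stratum_id": "s",
            "hospital_id": list(range(60)),
        })
        score = fit_comorbidity_score(df, design, ["cm_a"])
        assert score.excess_risk["cm_a"] == pytest.approx(0.10 - 0.02, abs=1e-12)

    def test_score_is_additive_and_zero_without_comorbidities(self, design):
        df = self._cohort_with_flags()
        df["cm_b"] = 1 - df["cm_a"]  # disjoint second comorbidity
        score = fit_comorbidity_score(df, design, ["cm_a", "cm_b"])
        s = score.score(df)
        ra, rb = score.excess_risk["cm_a"], score.excess_risk["cm_b"]
        expected = df["cm_a"] * ra + df["cm_b"] * rb
        np.testing.assert_allclose(s, expected, atol=1e-12)
        none = df.assign(cm_a=0, cm_b=0)
        assert (score.score(none) == 0.0).all()

    def test_zero_prevalence_comorbidity_set_missing(self, design, caplog):
        import logging

        df = self._cohort_with_flags()
        with caplog.at_level(logging.WARNING, logger="egsdisparity.classifiers"):
            score = fit_comorbidity_score(df, design, ["cm_a", "cm_b"])
        assert score.excess_risk["cm_b"] is None
        assert any("zero variation" in r.message for r in caplog.records)
        assert np.isfinite(score.score(df)).all()

    def test_positive_excess_recovered_from_odds_doubling(self, design):
        """A comorbidity that raises mortality produces a positive excess
        risk well separated from zero at n=2000."""
        df = self._cohort_with_flags(p_death_with=0.08, p_death_without=0.04)
        score = fit_comorbidity_score(df, design, ["cm_a"])
        assert score.excess_risk["cm_a"] > 0


class TestHospitalAggregates:
    def test_hand_counted_rates(self, design):
        df = pd.DataFrame({
            "hospital_id": ["h1"] * 5 + ["h2"] * 4,
            "any_surgery": [1, 1, 1, 1, 0, 0, 0, 1, 1],
            "los_days": [2, 4, 6, 8, 10, 1, 3, 5, 7],
            "race_ethnicity": ["white", "white", "black", "black", "white",
                               "white", "white", "white", "white"],
            "discwt": 1.0, "stratum_id": "s",
        })
        agg = compute_hospital_aggregates(df, design).set_index("hospital_id")
        assert agg.loc["h1", "hosp_operative_rate"] == pytest.approx(0.8)
        assert agg.loc["h1", "hosp_mean_los"] == pytest.approx(6.0)
        assert agg.loc["h1", "hosp_pct_black"] == pytest.approx(0.4)
        # h1: white rate (1+1+0)/3, black rate 1.0 -> diff = 2/3 - 1
        assert agg.loc["h1", "hosp_wb_oprate_diff"] == pytest.approx(2 / 3 - 1.0)
        # h2 has no black discharges -> difference undefined
        assert np.isnan(agg.loc["h2", "hosp_wb_oprate_diff"])
        assert agg.loc["h2", "hosp_operative_rate"] == pytest.approx(0.5)

    def test_equal_weights_reduce_to_unweighted(self, chole_cohort, design):
        equal = chole_cohort.assign(discwt=1.0)
        agg = compute_hospital_aggregates(equal, design).set_index("hospital_id")
        manual = equal.groupby("hospital_id")["any_surgery"].mean()
        np.testing.assert_allclose(
            agg["hosp_operative_rate"].loc[manual.index], manual, atol=1e-12
        )

    def test_join_adds_record_level_covariates(self, chole_cohort, design):
        agg = compute_hospital_aggregates(chole_cohort, design)
        joined = join_hospital_aggregates(
            chole_cohort.drop(columns=[c for c in chole_cohort.columns
                                       if c.startswith("hosp_")]),
            agg, design)
        assert "hosp_operative_rate" in joined.columns
        assert len(joined) == len(chole_cohort)
        assert joined["hosp_operative_rate"].between(0, 1).all()
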