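"""Design-based estimation: Hajek means, Taylor variances, age and
treatment standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from egsdisparity import (
    AgeStandard,
    EstimationError,
    SurveyDesign,
    age_adjusted_mean,
    assign_age_band,
    compare_groups,
    standardize_for_treatment,
    weighted_mean,
)

from conftest import srs_mean_se


def brute_force_linearized_se(df, design):
    """Independent re-derivation of the stratified-cluster Taylor SE.

    Deliberately structured differently from the library: explicit python
    loops over strata and clusters, no pandas groupby.
    """
    y = df["y"].to_numpy(float)
    w = df[design.weight].to_numpy(float)
    mean = (w * y).sum() / w.sum()
    z = w * (y - mean) / w.sum()
    var = 0.0
    for h in sorted(set(df[design.stratum])):
        rows_h = [i for i in range(len(df)) if df[design.stratum].iloc[i] == h]
        clusters = sorted(set(df[design.cluster].iloc[i] for i in rows_h))
        totals = []
        for c in clusters:
            totals.append(sum(z[i] for i in rows_h if df[design.cluster].iloc[i] == c))
        nh = len(totals)
        zbar = sum(totals) / nh
        var += nh / (nh - 1) * sum((t - zbar) ** 2 for t in totals)
    return mean, np.sqrt(var)


class TestWeightedMean:
    def test_matches_independent_linearization_on_printed_fixture(self, toy_survey, design):
        """Taylor SE on the 12-row, 3-stratum fixture agrees with a brute
        force linearization coded independently, to 1e-10."""
        est = weighted_mean(toy_survey, "y", design)
        mean, se = brute_force_linearized_se(toy_survey, design)
        assert est.value == pytest.approx(mean, abs=1e-12)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_design_collapse_to_srs(self, design):
        """Equal weights, one stratum, one cluster per row reduce to the
        textbook SRS mean and SE."""
        rng = np.random.default_rng(4)
        y = rng.normal(10, 3, size=57)
        df = pd.DataFrame({
            "y": y, "discwt": 1.0, "stratum_id": "s",
            "hospital_id": [f"c{i}" for i in range(len(y))],
        })
        est = weighted_mean(df, "y", design)
        mean, se = srs_mean_se(y)
        assert est.value == pytest.approx(mean, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=40))
    def test_design_collapse_property(self, values):
        """The SRS collapse holds for arbitrary data, not just one draw."""
        design = SurveyDesign()
        df = pd.DataFrame({
            "y": values, "discwt": 1.0, "stratum_id": 1,
            "hospital_id": np.arange(len(values)),
        })
        est = weighted_mean(df, "y", design)
        mean, se = srs_mean_se(values)
        assert est.value == pytest.approx(mean, abs=1e-9)
        assert est.se == pytest.approx(se, abs=1e-9)

    def test_constant_outcome_has_zero_se(self, design):
        df = pd.DataFrame({
            "y": 7.0, "discwt": [1.0, 2.0, 3.0, 1.0],
            "stratum_id": ["A", "A", "B", "B"],
            "hospital_id": ["u", "v", "x", "z"],
        })
        est = weighted_mean(df, "y", design)
        assert est.value == pytest.approx(7.0)
        assert est.se == pytest.approx(0.0, abs=1e-14)

    def test_empty_subset_raises(self, toy_survey, design):
        with pytest.raises(EstimationError):
            weighted_mean(toy_survey, "y", design, subset=toy_survey["y"] > 100)

    def test_lonely_psu_handled_with_warning(self, design, caplog):
        df = pd.DataFrame({
            "y": [1.0, 2.0, 3.0, 4.0, 5.0],
            "discwt": 1.0,
            "stratum_id": ["A", "A", "A", "A", "B"],
            "hospital_id": ["a", "a", "b", "b", "c"],
        })
        import logging

        with caplog.at_level(logging.WARNING, logger="egsdisparity.survey"):
            est = weighted_mean(df, "y", design)
        assert np.isfinite(est.se)
        assert any("lonely" in r.message for r in caplog.records)


class TestAgeStandardization:
    @staticmethod
    def _cohort(rng, n=400):
        bands = rng.choice(["<40", "40-54", "55-69", "70-89", ">89"], size=n)
        return pd.DataFrame({
            "y": rng.normal(5, 2, size=n) + (bands == ">89") * 3,
            "age_band": bands,
            "discwt": rng.lognormal(1, 0.4, size=n),
            "stratum_id": rng.choice(["s1", "s2", "s3"], size=n),
            "hospital_id": rng.choice([f"h{i}" for i in range(12)], size=n),
        })

    def test_self_standardization_equals_crude_mean(self, design):
        """Standardizing a group to its own weighted age distribution must
        reproduce the crude weighted mean exactly."""
        df = self._cohort(np.random.default_rng(7))
        own = AgeStandard.from_cohort(df, design)
        adj = age_adjusted_mean(df, "y", design, own)
        crude = weighted_mean(df, "y", design)
        assert adj.value == pytest.approx(crude.value, abs=1e-12)

    def test_identical_band_means_give_zero_disparity(self, design):
        """Groups with identical band-specific means but different age
        structures have exactly zero age-adjusted disparity."""
        rows = []
        band_mean = {"<40": 2.0, "40-54": 4.0, "55-69": 6.0, "70-89": 8.0, ">89": 10.0}
        counts = {"black": [30, 10, 5, 3, 2], "white": [5, 10, 20, 30, 15]}
        for g, ns in counts.items():
            for band, k in zip(band_mean, ns):
                for i in range(k):
                    rows.append((g, band, band_mean[band], 1.0 + (i % 3)))
        df = pd.DataFrame(rows, columns=["race_ethnicity", "age_band", "y", "discwt"])
        df["stratum_id"] = "s"
        df["hospital_id"] = np.arange(len(df))
        standard = AgeStandard({b: 0.2 for b in band_mean})
        cmp_ = compare_groups(df, "y", design, standard)
        assert cmp_.difference.value == pytest.approx(0.0, abs=1e-12)

    def test_band_label_permutation_invariance(self, design):
        """Renaming bands consistently in data and standard leaves the
        estimate unchanged."""
        df = self._cohort(np.random.default_rng(9))
        standard = AgeStandard.from_cohort(df, design)
        base = age_adjusted_mean(df, "y", design, standard)
        perm = {b: f"band{i}" for i, b in enumerate(standard.weights)}
        df2 = df.assign(age_band=df["age_band"].map(perm))
        standard2 = AgeStandard({perm[b]: s for b, s in standard.weights.items()})
        permuted = age_adjusted_mean(df2, "y", design, standard2)
        assert permuted.value == pytest.approx(base.value, abs=1e-12)
        assert permuted.se == pytest.approx(base.se, abs=1e-12)

    def test_age_band_assignment_matches_band_edges(self):
        ages = pd.Series([18, 39, 40, 54, 55, 69, 70, 89, 90, 95])
        bands = assign_age_band(ages)
        assert list(bands) == ["<40", "<40", "40-54", "40-54", "55-69",
                               "55-69", "70-89", "70-89", ">89", ">89"]

    def test_empty_band_dropped_and_renormalized(self, design):
        df = self._cohort(np.random.default_rng(3))
        df = df.loc[df["age_band"] != ">89"]
        standard = AgeStandard({"<40": 0.3, "40-54": 0.3, "55-69": 0.2,
                                "70-89": 0.1, ">89": 0.1})
        est = age_adjusted_mean(df, "y", design, standard)
        assert np.isfinite(est.value)


class TestCompareGroups:
    def test_identical_groups_have_zero_difference(self, design):
        rng = np.random.default_rng(21)
        half = pd.DataFrame({
            "y": rng.normal(3, 1, 200),
            "age_band": rng.choice(["<40", "40-54"], 200),
            "discwt": rng.lognormal(0, 0.3, 200),
            "stratum_id": rng.choice(["A", "B"], 200),
            "hospital_id": rng.choice(list("abcdefgh"), 200),
        })
        df = pd.concat([half.assign(race_ethnicity="black"),
                        half.assign(race_ethnicity="white")], ignore_index=True)
        standard = AgeStandard.from_cohort(df, design)
        cmp_ = compare_groups(df, "y", design, standard)
        assert cmp_.difference.value == pytest.approx(0.0, abs=1e-12)
        assert cmp_.p_value == pytest.approx(1.0, abs=1e-9)

    def test_toy_difference_matches_hand_computation(self, design):
        """Two groups, two bands, hand-computed age-adjusted difference."""
        df = pd.DataFrame({
            "race_ethnicity": ["black"] * 4 + ["white"] * 4,
            "age_band": ["<40", "<40", "40-54", "40-54"] * 2,
            "y": [2.0, 4.0, 6.0, 8.0, 1.0, 3.0, 5.0, 7.0],
            "discwt": [1.0, 1.0, 1.0, 3.0, 2.0, 2.0, 1.0, 1.0],
            "stratum_id": "s",
            "hospital_id": list("abcdefgh"),
        })
        standard = AgeStandard({"<40": 0.5, "40-54": 0.5})
        cmp_ = compare_groups(df, "y", design, standard)
        # black: <40 mean 3.0; 40-54: (6 + 3*8)/4 = 7.5 -> adjusted 5.25
        # white: <40 mean 2.0; 40-54: 6.0 -> adjusted 4.0
        assert cmp_.difference.value == pytest.approx(5.25 - 4.0, abs=1e-12)


class TestTreatmentStandardization:
    def test_treatment_independent_of_race_changes_nothing(self, design):
        """When treatment allocation is identical across races and outcomes
        depend only on age band, adjusting for treatment leaves the
        disparity unchanged (percent change ~ 0)."""
        rng = np.random.default_rng(5)
        n = 4000
        race = rng.choice(["black", "white"], n)
        band = rng.choice(["<40", "40-54"], n)
        tts = rng.integers(0, 3, n)
        y = 3.0 + (band == "40-54") * 2.0 + 0.5 * tts + (race == "black") * 1.0
        df = pd.DataFrame({
            "race_ethnicity": race, "age_band": band, "tts": tts,
            "los_days": y, "discwt": 1.0, "stratum_id": "s",
            "hospital_id": rng.choice([f"h{i}" for i in range(20)], n),
        })
        res = standardize_for_treatment(df, design, ["tts"])
        assert res.unadjusted.value == pytest.approx(1.0, abs=0.05)
        assert abs(res.percent_change) < 5.0

    def test_two_stratum_fixture_matches_hand_standardization(self, design):
        """Hand-checked reweighting on a 2-band x 2-treatment fixture."""
        rows = [
            # group, band, treated, y, w
            ("white", "<40", 0, 2.0, 3.0),
            ("white", "<40", 1, 4.0, 1.0),
            ("white", "40-54", 0, 6.0, 1.0),
            ("white", "40-54", 1, 8.0, 1.0),
            ("black", "<40", 0, 3.0, 1.0),
            ("black", "<40", 1, 6.0, 1.0),
            ("black", "40-54", 0, 7.0, 1.0),
            ("black", "40-54", 1, 11.0, 3.0),
        ]
        df = pd.DataFrame(rows, columns=["race_ethnicity", "age_band",
                                         "treated", "los_days", "discwt"])
        df["stratum_id"] = "s"
        df["hospital_id"] = np.arange(len(df))
        res = standardize_for_treatment(df, design, ["treated"])
        # white age shares: <40 4/6, 40-54 2/6
        # unadjusted: black band means (4.5, 10.0), white (2.5, 7.0)
        #   -> 2/3*(4.5-2.5) + 1/3*(10-7) = 4/3 + 1 = 7/3
        assert res.unadjusted.value == pytest.approx(7.0 / 3.0, abs=1e-12)
        # joint white shares: (<40,0)=1/2, (<40,1)=1/6, (40-54,0)=1/6, (40-54,1)=1/6
        # diffs: 1.0, 2.0, 1.0, 3.0 -> 1/2 + 2/6 + 1/6 + 3/6 = 1.5
        assert res.adjusted.value == pytest.approx(1.5, abs=1e-12)
        expected_pct = (7.0 / 3.0 - 1.5) / (7.0 / 3.0) * 100.0
        assert res.percent_change == pytest.approx(expected_pct, abs=1e-9)
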