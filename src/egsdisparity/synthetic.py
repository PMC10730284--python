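"""Synthetic NIS-style discharge data with a known structural disparity model.

The generator emulates the schema and sampling design of a national
inpatient discharge sample — hospitals as clustered primary sampling units
within region-by-type strata, discharge-level sampling weights, coded
diagnoses and day-stamped procedures — under a configurable structural
model::

    race --> mediators (socioeconomic, medical, hospital)
    race, mediators --> treatment (surgery delivered, daily surgery rate,
                                   invasiveness category)
    race, mediators, treatment --> outcomes (in-hospital death, LOS)

All race effects are black-vs-white shifts on the link scale (log-odds for
binary nodes, log daily-surgery-rate for the delay process, log-mean for
LOS); other race/ethnicity groups are generated but carry no structural
effects by default.  Because every coefficient is configurable and recorded
in :class:`TruthParams`, downstream estimators can be tested against known
ground truth, including the marginal ("total") race effect obtained by a
brute-force fit on an arbitrarily large simulated population — the honest
definition for non-collapsible logit/log-link outcomes.

Covariate distributions are race-conditional and qualitatively mirror the
descriptive structure of real inpatient data: black patients are younger
and more often have Medicaid or self-pay coverage, live in lowest-income-
quartile ZIP codes, are admitted non-electively, and are seen at urban
teaching hospitals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

RACE_LEVELS = ("white", "black", "latinx", "api", "native_other")

#: Binary mediators with race-shiftable prevalence.  ``teaching`` acts on
#: hospital assignment and ``high_risk_dx`` tilts the primary-code draw
#: toward higher-mortality codes.
MEDIATORS = (
    "medicaid", "selfpay", "lowest_income", "elective", "weekend",
    "cm_chf", "cm_diabetes", "cm_renal", "teaching", "high_risk_dx",
)
TREATMENT_TARGETS = ("any_surgery", "surgery_delay", "most_invasive")
OUTCOME_TARGETS = ("died", "los")
DIRECT_EFFECT_KEYS = ("any_surgery", "surgery_delay", "died", "los")

_BASE_PREVALENCE = {
    "medicaid": 0.07, "selfpay": 0.07, "lowest_income": 0.20,
    "elective": 0.10, "weekend": 0.23,
    "cm_chf": 0.10, "cm_diabetes": 0.18, "cm_renal": 0.07,
}

_AGE_MEAN = {"white": 57.0, "black": 50.0, "latinx": 47.0, "api": 52.0,
             "native_other": 50.0}
_AGE_SD = 19.0

# Per-diagnosis baseline intercepts (link scale) and category mixes.
_DIAGNOSES = {
    # name: (mix, surgery logit, daily-surgery-rate logit, log postop-LOS
    #        mean, mortality logit, (least, intermediate, most) mix)
    "appendicitis": (0.20, 3.4, 1.4, np.log(2.3), -6.2, (0.90, 0.07, 0.03)),
    "cholecystitis": (0.31, 2.1, 0.0, np.log(3.0), -5.2, (0.86, 0.135, 0.005)),
    "gallstone_pancreatitis": (0.06, 0.5, -1.0, np.log(3.5), -4.4, (0.977, 0.016, 0.007)),
    "hernia": (0.14, 2.1, 0.8, np.log(3.6), -4.5, (0.72, 0.235, 0.045)),
    "obstruction": (0.20, -0.3, -0.3, np.log(5.2), -3.6, (0.83, 0.03, 0.14)),
    "perforation": (0.02, 2.0, 1.0, np.log(8.5), -1.9, (0.66, 0.33, 0.01)),
    "other": (0.07, None, None, np.log(3.0), -4.6, None),
}

# Primary codes per diagnosis, matching the packaged illustrative code map,
# with mortality log-odds offsets defining the empirical severity subgroups.
_DX_CODES = {
    "appendicitis": (["540.0", "540.1", "540.9"], [1.4, 0.7, 0.0], [0.25, 0.10, 0.65]),
    "cholecystitis": (["575.0", "575.1", "575.12"], [0.0, 1.0, 0.4], [0.75, 0.19, 0.06]),
    "gallstone_pancreatitis": (["577.0", "577.1", "577.2"], [0.7, 0.0, 1.4], [0.48, 0.02, 0.50]),
    "hernia": (["550.0", "550.1", "551.1", "552.21"], [0.0, 0.1, 0.9, 1.6], [0.30, 0.16, 0.52, 0.02]),
    "obstruction": (["560.1", "560.81", "560.9"], [1.5, 0.6, 0.0], [0.04, 0.93, 0.03]),
    "perforation": (["569.83", "531.1", "532.1"], [0.0, 0.6, 1.2], [0.52, 0.09, 0.39]),
    "other": (["799.9"], [0.0], [1.0]),
}

_GALLSTONE_SECONDARY = ["574.0", "574.2", "574.5"]

_SURGERY_CODES = {
    "appendicitis": {"least": ["47.01", "47.09"], "intermediate": ["47.11"], "most": ["45.62"]},
    "cholecystitis": {"least": ["51.23", "51.22"], "intermediate": ["51.21"], "most": ["51.32"]},
    "gallstone_pancreatitis": {"least": ["51.23", "51.22"], "intermediate": ["51.21"], "most": ["52.6"]},
    "hernia": {"least": ["53.05"], "intermediate": ["53.00"], "most": ["45.62"]},
    "obstruction": {"least": ["54.59"], "intermediate": ["46.01"], "most": ["45.62", "45.79"]},
    "perforation": {"least": ["44.42"], "intermediate": ["46.10"], "most": ["45.62"]},
}
_TEMPORIZING_CODES = {
    "appendicitis": ["54.91"], "cholecystitis": ["51.01", "51.10"],
    "gallstone_pancreatitis": ["51.10", "51.01"], "hernia": ["96.07"],
    "obstruction": ["96.08"], "perforation": ["54.91"],
}
_UNUSUAL_CODE = {
    "appendicitis": "54.59", "cholecystitis": "54.59",
    "gallstone_pancreatitis": "54.59", "hernia": "54.59",
    "obstruction": "54.21", "perforation": "54.59",
}

_HOSPITAL_ATTRS = {
    "region": (["northeast", "midwest", "south", "west"], [0.19, 0.23, 0.38, 0.20]),
    "type": (["rural", "urban_nonteaching", "urban_teaching"], [0.15, 0.50, 0.35]),
    "size": (["large", "medium", "small"], [0.59, 0.27, 0.14]),
    "ownership": (["for_profit", "government", "nonprofit", "unspecified_private"],
                  [0.12, 0.10, 0.44, 0.34]),
}

DISCHARGE_COLUMNS = [
    "record_id", "year", "age", "race_raw", "hispanic_flag",
    "diagnosis_codes", "procedure_codes", "los_days", "died", "payer",
    "zip_income_quartile", "weekend_admission", "elective_admission",
    "ama_flag", "cm_chf", "cm_diabetes", "cm_renal",
    "hospital_id", "stratum_id", "discwt", "trendwt",
]


def default_race_to_mediator() -> dict:
    return {
        "medicaid": 1.2, "selfpay": 0.8, "lowest_income": 1.3,
        "elective": -0.5, "weekend": 0.05,
        "cm_chf": 0.2, "cm_diabetes": 0.5, "cm_renal": 0.4,
        "teaching": 1.0, "high_risk_dx": 0.3,
    }


def default_mediator_to_treatment() -> dict:
    return {
        "medicaid:any_surgery": -0.20, "selfpay:any_surgery": -0.30,
        "lowest_income:any_surgery": -0.10, "elective:any_surgery": 0.30,
        "cm_chf:any_surgery": -0.30,
        "medicaid:surgery_delay": -0.15, "weekend:surgery_delay": -0.20,
        "cm_chf:surgery_delay": -0.10, "teaching:surgery_delay": -0.10,
        "cm_diabetes:most_invasive": 0.20,
    }


def default_to_outcome() -> dict:
    return {
        "cm_chf:died": 0.8, "cm_renal:died": 0.7, "cm_diabetes:died": 0.2,
        "any_surgery:died": -0.3,
        "medicaid:los": 0.05, "cm_chf:los": 0.15, "teaching:los": 0.05,
        "elective:los": -0.05, "time_to_surgery:los": 0.0,
    }


def default_direct_race_effects() -> dict:
    return {"any_surgery": -0.25, "surgery_delay": -0.20, "died": 0.15,
            "los": 0.08}


@dataclass
class GeneratorConfig:
    """Structural and design configuration of the synthetic sample.

    ``path_coefficients`` holds three flat maps keyed as ``source`` (for
    ``race_to_mediator``) or ``"source:target"`` strings:

    * ``race_to_mediator`` — black-vs-white link-scale shift of each mediator;
    * ``mediator_to_treatment`` — mediator effects on ``any_surgery`` (log
      odds), ``surgery_delay`` (log odds of surgery per hospital day; more
      negative means longer waits) and ``most_invasive`` (log odds);
    * ``to_outcome`` — mediator/treatment effects on ``died`` (log odds) and
      ``los`` (log mean days).

    ``direct_race_effects`` are black-vs-white effects remaining after all
    mediators, one per treatment/outcome node.
    """

    n_hospitals: int = 60
    n_discharges: int = 20_000
    years: tuple = tuple(range(2002, 2012))
    race_probs: dict = field(default_factory=lambda: {
        "white": 0.66, "black": 0.10, "latinx": 0.13, "api": 0.06,
        "native_other": 0.05,
    })
    diagnosis_mix: dict = field(default_factory=lambda: {
        name: spec[0] for name, spec in _DIAGNOSES.items()
    })
    race_to_mediator: dict = field(default_factory=default_race_to_mediator)
    mediator_to_treatment: dict = field(default_factory=default_mediator_to_treatment)
    to_outcome: dict = field(default_factory=default_to_outcome)
    direct_race_effects: dict = field(default_factory=default_direct_race_effects)
    weight_mean: float = 5.0
    weight_sigma: float = 0.3
    los_dispersion: float = 0.5
    missing_race_prob: float = 0.03
    preadmission_surgery_prob: float = 0.01
    missing_procday_prob: float = 0.005
    max_surgery_wait: int = 21
    allow_2015: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hospitals < 1:
            raise ConfigError("n_hospitals must be a positive integer")
        if self.n_discharges < self.n_hospitals:
            raise ConfigError("n_discharges must be >= n_hospitals")
        total = sum(self.race_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"race_probs must sum to 1 (got {total!r})")
        unknown = set(self.race_probs) - set(RACE_LEVELS)
        if unknown:
            raise ConfigError(f"unknown race levels {sorted(unknown)}")
        if 2015 in self.years and not self.allow_2015:
            raise ConfigError(
                "year 2015 is excluded from analyses by convention; pass "
                "allow_2015=True to generate it anyway"
            )
        bad = set(self.race_to_mediator) - set(MEDIATORS)
        if bad:
            raise ConfigError(f"unknown mediators in race_to_mediator: {sorted(bad)}")
        for key in self.mediator_to_treatment:
            src, _, tgt = key.partition(":")
            if src not in MEDIATORS or tgt not in TREATMENT_TARGETS:
                raise ConfigError(f"bad mediator_to_treatment key {key!r}")
        for key in self.to_outcome:
            src, _, tgt = key.partition(":")
            if (src not in MEDIATORS + ("any_surgery", "time_to_surgery")
                    or tgt not in OUTCOME_TARGETS):
                raise ConfigError(f"bad to_outcome key {key!r}")
        bad = set(self.direct_race_effects) - set(DIRECT_EFFECT_KEYS)
        if bad:
            raise ConfigError(f"unknown direct_race_effects keys: {sorted(bad)}")

    def null(self) -> "GeneratorConfig":
        """Copy with every race path and direct effect set to zero."""
        return dataclasses.replace(
            self,
            race_to_mediator={k: 0.0 for k in self.race_to_mediator},
            direct_race_effects={k: 0.0 for k in self.direct_race_effects},
        )


@dataclass
class TruthParams:
    """Realized structural coefficients, the recovery-test oracle.

    ``total_effects`` holds marginal (age- and year-adjusted) black-vs-white
    link-scale coefficients per outcome when they have been computed by
    :func:`true_total_effects`; for nonlinear links these are defined on an
    arbitrarily large simulated population rather than as path sums, because
    logit/log-link effects are non-collapsible.
    """

    race_to_mediator: dict
    mediator_to_treatment: dict
    to_outcome: dict
    direct_race_effects: dict
    seed: int
    total_effects: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthParams":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


def generate_hospitals(config: GeneratorConfig) -> pd.DataFrame:
    """Hospital frame with attributes and region-by-type design strata.

    Strata with a single hospital are merged into the modal stratum (the
    hospital adopts its region/type) whenever more than one hospital exists,
    so every stratum has at least two clusters when the count permits.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n = config.n_hospitals
    cols = {}
    for attr, (levels, probs) in _HOSPITAL_ATTRS.items():
        cols[attr] = rng.choice(levels, size=n, p=probs)
    df = pd.DataFrame(cols)
    df.insert(0, "hospital_id", [f"H{i:04d}" for i in range(1, n + 1)])
    df["stratum_id"] = df["region"].astype(str) + "/" + df["type"].astype(str)
    if n > 1:
        while True:
            counts = df["stratum_id"].value_counts()
            lonely = counts[counts == 1]
            if len(lonely) == 0 or len(counts) == 1:
                break
            modal = counts.index[0]
            idx = df.index[df["stratum_id"] == lonely.index[0]][0]
            region, htype = modal.split("/")
            df.loc[idx, ["region", "type", "stratum_id"]] = [region, htype, modal]
    return df


def _draw_negbin(rng, mu, alpha):
    """Negative binomial with mean mu and variance mu + alpha*mu^2."""
    if alpha <= 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    return rng.negative_binomial(size, size / (size + mu))


def generate_discharges(
    config: GeneratorConfig, hospitals: pd.DataFrame
) -> tuple[pd.DataFrame, TruthParams]:
    """One row per discharge under the configured structural model."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    n = config.n_discharges
    races = list(config.race_probs)
    race = rng.choice(races, size=n, p=[config.race_probs[r] for r in races])
    black = (race == "black").astype(float)
    years = np.array(sorted(config.years))
    year = rng.choice(years, size=n)
    age_mu = np.array([_AGE_MEAN[r] for r in race])
    age = np.clip(np.round(rng.normal(age_mu, _AGE_SD)), 18, 95)

    # --- mediators -------------------------------------------------------
    shift = {m: config.race_to_mediator.get(m, 0.0) for m in MEDIATORS}
    med = {}
    for m, p0 in _BASE_PREVALENCE.items():
        eta = _logit(p0) + shift[m] * black
        med[m] = (rng.random(n) < _sigmoid(eta)).astype(int)

    # hospital assignment: race-dependent preference for teaching hospitals
    base_teach = (hospitals["type"] == "urban_teaching").mean()
    base_teach = min(max(base_teach, 0.02), 0.98)
    p_teach = _sigmoid(_logit(base_teach) + shift["teaching"] * black)
    go_teaching = rng.random(n) < p_teach
    teach_ids = hospitals.loc[hospitals["type"] == "urban_teaching", "hospital_id"].to_numpy()
    other_ids = hospitals.loc[hospitals["type"] != "urban_teaching", "hospital_id"].to_numpy()
    all_ids = hospitals["hospital_id"].to_numpy()
    hosp = np.empty(n, dtype=object)
    pick_t = go_teaching & (len(teach_ids) > 0)
    if len(teach_ids):
        hosp[pick_t] = rng.choice(teach_ids, size=int(pick_t.sum()))
    rest = ~pick_t
    pool = other_ids if len(other_ids) else all_ids
    hosp[rest] = rng.choice(pool, size=int(rest.sum()))
    # guarantee every hospital at least one discharge
    used = set(hosp)
    empty_hospitals = [h for h in all_ids if h not in used]
    if empty_hospitals:
        repl = rng.choice(n, size=len(empty_hospitals), replace=False)
        hosp[repl] = empty_hospitals
    med["teaching"] = pd.Series(hosp).map(
        hospitals.set_index("hospital_id")["type"].eq("urban_teaching").astype(int)
    ).to_numpy()
    stratum = pd.Series(hosp).map(hospitals.set_index("hospital_id")["stratum_id"]).to_numpy()

    # --- diagnosis and primary code -------------------------------------
    dx_names = list(config.diagnosis_mix)
    dx_probs = np.array([config.diagnosis_mix[d] for d in dx_names], dtype=float)
    dx_probs = dx_probs / dx_probs.sum()
    diagnosis = rng.choice(dx_names, size=n, p=dx_probs)
    primary = np.empty(n, dtype=object)
    severity = np.zeros(n)
    for d in dx_names:
        codes, offsets, base_p = _DX_CODES[d]
        mask = diagnosis == d
        k = mask.sum()
        if k == 0:
            continue
        if len(codes) == 1:
            primary[mask] = codes[0]
            continue
        # tilt the code draw toward higher-mortality codes for black rows
        off = np.asarray(offsets)
        rank = off / off.max() if off.max() > 0 else off
        logw = np.log(np.asarray(base_p))[None, :] + (
            shift["high_risk_dx"] * black[mask]
        )[:, None] * rank[None, :]
        w = np.exp(logw)
        w /= w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1)
        u = rng.random(k)
        idx = (u[:, None] > cum).sum(axis=1)
        primary[mask] = np.asarray(codes, dtype=object)[idx]
        severity[mask] = off[idx]

    # --- treatment -------------------------------------------------------
    def med_sum(target: str, table: dict) -> np.ndarray:
        eta = np.zeros(n)
        for key, coef in table.items():
            src, _, tgt = key.partition(":")
            if tgt == target and src in med:
                eta += coef * med[src]
        return eta

    base_surg = np.array([
        _DIAGNOSES[d][1] if _DIAGNOSES[d][1] is not None else -99.0
        for d in diagnosis
    ])
    eta_surg = (base_surg - 0.01 * (age - 55.0)
                + med_sum("any_surgery", config.mediator_to_treatment)
                + config.direct_race_effects.get("any_surgery", 0.0) * black)
    any_surgery = (rng.random(n) < _sigmoid(eta_surg)).astype(int)

    base_delay = np.array([
        _DIAGNOSES[d][2] if _DIAGNOSES[d][2] is not None else 0.0
        for d in diagnosis
    ])
    eta_delay = (base_delay
                 + med_sum("surgery_delay", config.mediator_to_treatment)
                 + config.direct_race_effects.get("surgery_delay", 0.0) * black)
    p_day = np.clip(_sigmoid(eta_delay), 1e-3, 1 - 1e-6)
    wait = np.minimum(rng.geometric(p_day) - 1, config.max_surgery_wait)
    wait = np.where(any_surgery == 1, wait, -1)

    # invasiveness category among operated stays
    category = np.full(n, "", dtype=object)
    tilt = med_sum("most_invasive", config.mediator_to_treatment)
    for d in dx_names:
        if d == "other":
            continue
        mask = (diagnosis == d) & (any_surgery == 1)
        k = int(mask.sum())
        if k == 0:
            continue
        p = np.array(_DIAGNOSES[d][5], dtype=float)
        probs = np.tile(p, (k, 1))
        odds_most = (p[2] / (1 - p[2])) * np.exp(tilt[mask])
        probs[:, 2] = odds_most / (1 + odds_most)
        probs[:, :2] *= ((1 - probs[:, 2]) / probs[:, :2].sum(axis=1))[:, None]
        cum = np.cumsum(probs, axis=1)
        u = rng.random(k)
        idx = (u[:, None] > cum).sum(axis=1)
        category[mask] = np.array(["least", "intermediate", "most"], dtype=object)[idx]

    # --- outcomes --------------------------------------------------------
    # the LOS age profile is constant within the five analysis age bands,
    # so band-level adjustment and standardization are exactly aligned with
    # the generating process (mortality keeps a logit-linear age effect)
    band_idx = np.digitize(age, [40, 55, 70, 90])
    los_age_offset = np.array([-0.10, -0.03, 0.03, 0.10, 0.15])[band_idx]
    base_los = np.array([_DIAGNOSES[d][3] for d in diagnosis])
    eta_los = (base_los + los_age_offset
               + med_sum("los", config.to_outcome)
               + config.to_outcome.get("time_to_surgery:los", 0.0)
               * np.where(wait >= 0, wait, 0)
               + config.to_outcome.get("any_surgery:los", 0.0) * any_surgery
               + config.direct_race_effects.get("los", 0.0) * black)
    postop = _draw_negbin(rng, np.exp(eta_los), config.los_dispersion)
    los = np.where(any_surgery == 1, wait + postop, postop).astype(int)

    base_mort = np.array([_DIAGNOSES[d][4] for d in diagnosis])
    eta_died = (base_mort + severity + 0.045 * (age - 55.0)
                + med_sum("died", config.to_outcome)
                + config.to_outcome.get("any_surgery:died", 0.0) * any_surgery
                + config.direct_race_effects.get("died", 0.0) * black)
    died = (rng.random(n) < _sigmoid(eta_died)).astype(int)

    # --- coded fields ----------------------------------------------------
    dx_strings = np.empty(n, dtype=object)
    has_gallstone = rng.random(n) < 0.97
    for i in range(n):
        codes = [primary[i]]
        if diagnosis[i] == "gallstone_pancreatitis" and has_gallstone[i]:
            codes.append(_GALLSTONE_SECONDARY[i % len(_GALLSTONE_SECONDARY)])
        dx_strings[i] = " ".join(codes)

    preadm = rng.random(n) < config.preadmission_surgery_prob
    dayless = rng.random(n) < config.missing_procday_prob
    unusual = rng.random(n) < 0.05
    temporize = rng.random(n) < 0.18
    proc_strings = np.empty(n, dtype=object)
    for i in range(n):
        d = diagnosis[i]
        toks = []
        if any_surgery[i] == 1 and d in _SURGERY_CODES:
            cat_codes = _SURGERY_CODES[d][category[i]]
            code = cat_codes[i % len(cat_codes)]
            if preadm[i]:
                toks.append(f"{code}:-1")
            elif dayless[i]:
                toks.append(f"{code}:")
            else:
                toks.append(f"{code}:{int(wait[i])}")
            if unusual[i]:
                toks.append(f"{_UNUSUAL_CODE[d]}:{int(max(wait[i], 0))}")
        elif d in _TEMPORIZING_CODES and temporize[i]:
            code = _TEMPORIZING_CODES[d][i % len(_TEMPORIZING_CODES[d])]
            toks.append(f"{code}:{int(min(1, los[i]))}")
        proc_strings[i] = " ".join(toks)

    # race_raw / hispanic with occasional missingness
    miss = rng.random(n) < config.missing_race_prob
    hisp = (race == "latinx").astype(int)
    race_raw = np.where(race == "latinx",
                        rng.choice(["white", "native_other"], size=n, p=[0.6, 0.4]),
                        race)
    race_raw = np.where(miss, "", race_raw).astype(object)

    # socioeconomic fields
    zipq = np.where(
        med["lowest_income"] == 1, 1, rng.integers(2, 5, size=n)
    ).astype(object)
    zipq[rng.random(n) < 0.02] = "unavailable"
    payer = np.empty(n, dtype=object)
    medicare = (age >= 65) & (rng.random(n) < 0.85)
    payer[:] = "private"
    other_pay = rng.random(n)
    payer[other_pay < 0.12] = "other"
    payer[other_pay > 0.985] = "no_charge"
    payer[med["selfpay"] == 1] = "self_pay"
    payer[med["medicaid"] == 1] = "medicaid"
    payer[medicare] = "medicare"
    ama = (rng.random(n) < _sigmoid(_logit(0.004) + 0.7 * black)).astype(int)

    mu_w = np.log(config.weight_mean) - config.weight_sigma**2 / 2
    discwt = rng.lognormal(mu_w, config.weight_sigma, size=n)
    trendwt = discwt * (1.0 + 0.01 * (year - years.min()))

    df = pd.DataFrame({
        "record_id": np.arange(1, n + 1),
        "year": year.astype(int),
        "age": age.astype(int),
        "race_raw": race_raw,
        "hispanic_flag": hisp,
        "diagnosis_codes": dx_strings,
        "procedure_codes": proc_strings,
        "los_days": los,
        "died": died,
        "payer": payer,
        "zip_income_quartile": zipq.astype(str),
        "weekend_admission": med["weekend"],
        "elective_admission": med["elective"],
        "ama_flag": ama,
        "cm_chf": med["cm_chf"],
        "cm_diabetes": med["cm_diabetes"],
        "cm_renal": med["cm_renal"],
        "hospital_id": hosp,
        "stratum_id": stratum,
        "discwt": discwt,
        "trendwt": trendwt,
    })[DISCHARGE_COLUMNS]
    truth = TruthParams(
        race_to_mediator=dict(config.race_to_mediator),
        mediator_to_treatment=dict(config.mediator_to_treatment),
        to_outcome=dict(config.to_outcome),
        direct_race_effects=dict(config.direct_race_effects),
        seed=config.seed,
    )
    return df, truth


def generate_dataset(config: GeneratorConfig):
    """Convenience wrapper: hospitals plus discharges plus truth."""
    hospitals = generate_hospitals(config)
    discharges, truth = generate_discharges(config, hospitals)
    return discharges, hospitals, truth


def true_total_effects(
    config: GeneratorConfig,
    outcomes: tuple = ("any_surgery", "time_to_surgery", "died", "los"),
    n: int = 400_000,
    seed: int | None = None,
    diagnosis: str | None = None,
) -> dict:
    """Brute-force marginal (total) black-vs-white effects on the link scale.

    Simulates a large population from ``config`` and fits, per outcome, an
    unweighted age- and year-adjusted GLM of the outcome on a black
    indicator among black/white rows — the estimand the mediation stage's
    "total effect" targets, with the same base adjustment (age-band dummies,
    continuous age and calendar year).  Logit for binary outcomes; negative binomial
    (alpha from the configured dispersion) for day counts.
    """
    import statsmodels.api as sm

    big = dataclasses.replace(
        config,
        n_discharges=max(n, config.n_hospitals),
        seed=config.seed if seed is None else seed,
        missing_race_prob=0.0,
        preadmission_surgery_prob=0.0,
        missing_procday_prob=0.0,
    )
    df, hospitals, _ = generate_dataset(big)
    from .cohort import load_codemaps, build_cohort

    maps = load_codemaps()
    if diagnosis is None:
        parts = [build_cohort(df, maps[d]) for d in maps]
        cohort = pd.concat(parts, ignore_index=True)
    else:
        cohort = build_cohort(df, maps[diagnosis])
    sub = cohort.loc[cohort["race_ethnicity"].isin(["black", "white"])].copy()
    out = {}
    for name in outcomes:
        d = sub
        if name == "time_to_surgery":
            d = sub.loc[sub["any_surgery"] == 1]
        y = d[name if name != "los" else "los_days"].to_numpy(dtype=float)
        bands = pd.get_dummies(d["age_band"].astype(str), drop_first=True)
        X = np.column_stack([
            np.ones(len(d)),
            (d["race_ethnicity"] == "black").to_numpy(dtype=float),
            bands.to_numpy(dtype=float),
            d["age"].to_numpy(dtype=float) - 55.0,
            d["year"].to_numpy(dtype=float) - np.mean(d["year"]),
        ])
        if name in ("any_surgery", "died"):
            family = sm.families.Binomial()
        else:
            family = sm.families.NegativeBinomial(alpha=max(config.los_dispersion, 1e-8))
        fit = sm.GLM(y, X, family=family).fit()
        out[name] = float(fit.params[1])
    return out


def write_dataset(
    discharges: pd.DataFrame,
    hospitals: pd.DataFrame,
    truth: TruthParams,
    outdir: str | Path,
) -> dict:
    """Write discharges.csv, hospitals.csv and truth.yaml into ``outdir``."""
    outdir = Path(outdir)
    if not outdir.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {outdir}")
    paths = {
        "discharges": outdir / "discharges.csv",
        "hospitals": outdir / "hospitals.csv",
        "truth": outdir / "truth.yaml",
    }
    discharges.to_csv(paths["discharges"], index=False, float_format="%.17g")
    hospitals.to_csv(paths["hospitals"], index=False)
    truth.to_yaml(paths["truth"])
    return paths


def read_dataset(indir: str | Path):
    """Read a dataset written by :func:`write_dataset` (lossless round trip)."""
    indir = Path(indir)
    dpath = indir / "discharges.csv"
    if not dpath.exists():
        raise FileNotFoundError(f"no discharges.csv under {indir}")
    discharges = pd.read_csv(
        dpath,
        dtype={"race_raw": str, "diagnosis_codes": str, "procedure_codes": str,
               "payer": str, "zip_income_quartile": str, "hospital_id": str,
               "stratum_id": str},
        keep_default_na=True,
    )
    for col in ("race_raw", "diagnosis_codes", "procedure_codes"):
        discharges[col] = discharges[col].fillna("")
    hospitals = pd.read_csv(indir / "hospitals.csv", dtype=str)
    truth = TruthParams.from_yaml(indir / "truth.yaml")
    return discharges, hospitals, truth
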