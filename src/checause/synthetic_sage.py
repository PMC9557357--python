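"""Synthetic multistage household survey with known ground truth.

Emulates the structure of the WHO-style aging/adult-health surveys this
pipeline targets: stratified multistage cluster sampling with oversampling
of households containing adults aged 50+, household expenditure and food
consumption, asset-based wealth quintiles, per-respondent inpatient and
outpatient visit counts, and visit records in which the cause is observed
only for the three most recent visits per care level and the out-of-pocket
(OOP) cost only for the single most recent.

The generator draws every visit's true cause and true cost, then a
censoring step removes exactly the cells a real survey would not capture.
The uncensored tables and the generating coefficients are retained as a
truth sidecar so that estimation stages can be tested for parameter
recovery; estimation code never touches the sidecar.

Data-generating model
---------------------
* Visit counts: negative binomial per respondent and care level
  (overdispersed utilization; Poisson is the large-dispersion limit).
* Cause of visit: each respondent has a dominant cause drawn from a
  multinomial-logit model over the seven groups (age, education, urban
  residence and sex shift the mix); individual visits follow the dominant
  cause with probability ``1 - cause_noise``.
* OOP cost: two-part law — zero with probability ``1 - p_positive``, else
  log-normal with a log-scale mean linear in cause, care level, age, urban,
  education, sex and wealth quintile.  The NCD positive-cost mean equals
  the CD mean times ``ncd_cost_ratio``.
* Weights: inverse of stage-wise selection probabilities (PSU draw times a
  household draw that oversamples 50+ households), normalized to a nominal
  adult population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from checause.errors import ConfigError, SchemaError
from checause.survey_io import CARE_LEVELS, CAUSE_ORDER

_N_CAUSES = len(CAUSE_ORDER)

DEFAULT_CAUSE_MIX: dict[str, float] = {
    "NCD": 0.35,
    "CD": 0.30,
    "INJURY": 0.06,
    "PAIN": 0.12,
    "SURGERY": 0.04,
    "OTHER": 0.08,
    "UNIDENTIFIED": 0.05,
}

# codes per group for emitting raw reason codes (mirrors the default codebook)
_GROUP_CODES: dict[str, tuple[str, ...]] = {
    "NCD": (
        "heart_disease",
        "diabetes",
        "cancer",
        "chronic_respiratory",
        "stroke",
        "depression_anxiety",
    ),
    "CD": (
        "malaria_fever",
        "tuberculosis",
        "diarrhoeal_disease",
        "acute_respiratory_infection",
        "childbirth_maternal",
        "child_illness_vaccination",
    ),
    "INJURY": ("road_traffic_injury", "other_injury"),
    "PAIN": ("back_or_joint_pain",),
    "SURGERY": ("planned_surgery",),
    "OTHER": ("other_reason",),
    "UNIDENTIFIED": ("dont_know",),
}

# multinomial-logit covariate effects on the dominant-cause mix, per group,
# scaled by SimulationConfig.cause_signal
_CAUSE_BETAS = {
    # group: (age_z, education_c, urban, female)
    "NCD": (0.9, 0.2, 0.3, 0.0),
    "CD": (-0.6, -0.2, -0.3, 0.3),
    "INJURY": (-0.3, 0.0, 0.0, -0.4),
    "PAIN": (0.4, 0.0, 0.0, 0.1),
    "SURGERY": (0.1, 0.1, 0.1, 0.0),
    "OTHER": (0.0, 0.0, 0.0, 0.0),
    "UNIDENTIFIED": (0.0, -0.3, -0.2, 0.0),
}

DEFAULT_PRIVATE_PROB: dict[str, float] = {
    "NCD": 0.45,
    "CD": 0.30,
    "INJURY": 0.35,
    "PAIN": 0.40,
    "SURGERY": 0.50,
    "OTHER": 0.35,
    "UNIDENTIFIED": 0.30,
}

# cost covariate effects on the log-scale mean of positive OOP
DEFAULT_COST_COVARIATE_EFFECTS: dict[str, float] = {
    "age_z": 0.10,
    "urban": 0.10,
    "education_c": 0.05,
    "female": 0.05,
    "wealth_c": 0.05,
}


@dataclass(frozen=True)
class CostLaw:
    """Two-part positive-cost law for one (cause group, care level) cell."""

    p_positive: float
    log_mean: float
    log_sd: float


def default_cost_params(ncd_cost_ratio: float) -> dict[tuple[str, str], CostLaw]:
    """Cost laws on the 2017 international-dollar scale.

    The CD baseline puts the median outpatient visit near $13 and the
    median inpatient stay near $100; the NCD log-mean offset is
    ``log(ncd_cost_ratio)`` so the planted NCD-vs-CD contrast is exact.
    """
    base = {"outpatient": (0.85, 2.6, 1.0), "inpatient": (0.92, 4.6, 1.1)}
    offsets = {
        "NCD": math.log(ncd_cost_ratio),
        "CD": 0.0,
        "INJURY": 0.2,
        "PAIN": -0.1,
        "SURGERY": 0.8,
        "OTHER": 0.0,
        "UNIDENTIFIED": 0.0,
    }
    return {
        (g, lvl): CostLaw(p, mu + offsets[g], sd)
        for g in CAUSE_ORDER
        for lvl, (p, mu, sd) in base.items()
    }


@dataclass(frozen=True)
class ExpenditureParams:
    """Annual household expenditure (log-normal) and food-share (beta) law."""

    log_mean: float = math.log(4000.0)
    log_sd: float = 0.7
    urban_log_shift: float = 0.15
    size_log_coef: float = 0.10
    food_share_alpha: float = 9.0
    food_share_beta: float = 11.0


@dataclass(frozen=True)
class SimulationConfig:
    n_households: int = 5000
    countries: tuple[str, ...] = ("country_1",)
    seed: int = 0
    share_50plus_households: float = 0.55
    n_strata: int = 10
    psus_per_stratum: int = 4
    visit_rate_outpatient: float = 1.6
    visit_rate_inpatient: float = 0.10
    visit_dispersion: float = 1.0  # negative-binomial size; larger -> Poisson
    visit_cap: int | None = None
    cause_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAUSE_MIX)
    )
    cause_signal: float = 1.0  # scales covariate effects on the cause mix
    cause_noise: float = 0.25  # P(a visit departs from the dominant cause)
    # per dominant cause, multiplies both visit rates (utilization mechanism)
    visit_rate_multipliers: Mapping[str, float] = field(default_factory=dict)
    ncd_cost_ratio: float = 1.6
    cost_params: Mapping[tuple[str, str], CostLaw] | None = None
    cost_covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COST_COVARIATE_EFFECTS)
    )
    expenditure_params: ExpenditureParams = field(default_factory=ExpenditureParams)
    private_sector_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRIVATE_PROB)
    )
    oversample_50plus: float = 2.0
    population_total: float = 1_000_000.0
    ppp_factor: float = 1.0  # nominal currency units per 2017 international $

    def resolved_cost_params(self) -> dict[tuple[str, str], CostLaw]:
        if self.cost_params is not None:
            return dict(self.cost_params)
        return default_cost_params(self.ncd_cost_ratio)

    def validate(self) -> None:
        if self.n_households < 0:
            raise ConfigError("n_households", "must be >= 0")
        if not self.countries:
            raise ConfigError("countries", "must be non-empty")
        if not 0.0 <= self.share_50plus_households <= 1.0:
            raise ConfigError("share_50plus_households", "must be in [0, 1]")
        if self.n_strata < 1:
            raise ConfigError("n_strata", "must be >= 1")
        if self.psus_per_stratum < 1:
            raise ConfigError("psus_per_stratum", "must be >= 1")
        for name in ("visit_rate_outpatient", "visit_rate_inpatient"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        if self.visit_dispersion <= 0:
            raise ConfigError("visit_dispersion", "must be > 0")
        mix = self.cause_mix
        if set(mix) != set(CAUSE_ORDER):
            raise ConfigError("cause_mix", f"must have keys {CAUSE_ORDER}")
        if any(v < 0 for v in mix.values()):
            raise ConfigError("cause_mix", "probabilities must be >= 0")
        if abs(sum(mix.values()) - 1.0) > 1e-12:
            raise ConfigError("cause_mix", "must sum to 1 within 1e-12")
        if not 0.0 <= self.cause_noise <= 1.0:
            raise ConfigError("cause_noise", "must be in [0, 1]")
        if self.ncd_cost_ratio <= 0:
            raise ConfigError("ncd_cost_ratio", "must be > 0")
        for key, law in self.resolved_cost_params().items():
            if not 0.0 <= law.p_positive <= 1.0:
                raise ConfigError("cost_params", f"{key}: p_positive not in [0, 1]")
            if law.log_sd <= 0:
                raise ConfigError("cost_params", f"{key}: log_sd must be > 0")
        for g, p in self.private_sector_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError("private_sector_prob", f"{g}: not in [0, 1]")
        if self.oversample_50plus <= 0:
            raise ConfigError("oversample_50plus", "must be > 0")
        if self.ppp_factor <= 0:
            raise ConfigError("ppp_factor", "must be > 0")
        for g, m in self.visit_rate_multipliers.items():
            if g not in CAUSE_ORDER:
                raise ConfigError("visit_rate_multipliers", f"unknown group {g!r}")
            if m < 0:
                raise ConfigError("visit_rate_multipliers", f"{g}: must be >= 0")


@dataclass
class TrueParameters:
    """Ground truth retained for testing only; never consumed by estimators.

    ``visits`` holds every generated visit with its true cause and cost
    (censoring is reversible through it); the coefficient dicts record the
    generating model so recovery tests can compare against truth.
    """

    visits: pd.DataFrame | None
    cause_coefficients: dict
    cost_coefficients: dict
    config: SimulationConfig


@dataclass
class SimulatedSurvey:
    """One generated dataset: censored observables plus the truth sidecar."""

    households: pd.DataFrame
    respondents: pd.DataFrame
    visits_observed: pd.DataFrame
    truth: TrueParameters

    @property
    def visits_true(self) -> pd.DataFrame:
        return self.truth.visits


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw via inverse CDF (vectorized)."""
    u = rng.random(probs.shape[0])
    cum = probs.cumsum(axis=1)
    return (u[:, None] > cum).sum(axis=1).clip(0, probs.shape[1] - 1)


def generate_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TrueParameters]:
    """Generate households and respondents under the multistage design.

    18–49 households contribute exactly one adult respondent aged 18–49;
    50+ households contribute every member aged 50 or older.  Weights are
    inverse selection probabilities with 50+ oversampling, normalized so
    household weights sum to ``population_total``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_households
    countries = list(config.countries)

    if n == 0:
        households = pd.DataFrame(
            columns=[
                "household_id", "country", "stratum", "psu", "weight", "hh_type",
                "size", "expenditure", "food_expenditure", "asset_index", "wealth_q",
            ]
        )
        respondents = pd.DataFrame(
            columns=[
                "respondent_id", "household_id", "country", "stratum", "psu",
                "weight", "age", "female", "urban", "education", "wealth_q",
            ]
        )
        truth = TrueParameters(None, dict(_CAUSE_BETAS), {}, config)
        return households, respondents, truth

    country = np.array(countries)[rng.integers(0, len(countries), n)]
    # strata/PSUs are per country; ids are globally unique integers
    country_idx = pd.Categorical(country, categories=countries).codes
    stratum_local = rng.integers(0, config.n_strata, n)
    stratum = country_idx * config.n_strata + stratum_local
    psu_local = rng.integers(0, config.psus_per_stratum, n)
    psu = stratum * config.psus_per_stratum + psu_local

    n_psu_total = len(countries) * config.n_strata * config.psus_per_stratum
    psu_select_prob = rng.uniform(0.3, 0.9, n_psu_total)
    psu_urban = (rng.random(n_psu_total) < 0.5).astype(int)

    is_50plus = rng.random(n) < config.share_50plus_households
    hh_type = np.where(is_50plus, "50plus", "18-49")

    # household composition
    n_older = np.where(is_50plus, 1 + (rng.random(n) < 0.6).astype(int), 0)
    n_younger = np.where(is_50plus, rng.poisson(1.0, n), 1 + rng.poisson(1.5, n))
    size = np.maximum(n_older + n_younger, 1)

    # selection probabilities -> weights
    p_hh = np.where(
        is_50plus, np.minimum(0.05 * config.oversample_50plus, 1.0), 0.05
    )
    w_raw = 1.0 / (psu_select_prob[psu] * p_hh)
    weight = w_raw * config.population_total / w_raw.sum()

    urban = psu_urban[psu]
    ep = config.expenditure_params
    z_exp = rng.normal(0.0, 1.0, n)
    log_exp = (
        ep.log_mean
        + ep.log_sd * z_exp
        + ep.urban_log_shift * urban
        + ep.size_log_coef * np.log(size)
    )
    expenditure = np.exp(log_exp)
    food_share = rng.beta(ep.food_share_alpha, ep.food_share_beta, n)
    food_expenditure = food_share * expenditure

    asset_index = 0.8 * z_exp + 0.4 * urban + 0.6 * rng.normal(0.0, 1.0, n)
    wealth_q = weighted_quintiles(asset_index, weight)

    households = pd.DataFrame(
        {
            "household_id": np.arange(n, dtype=np.int64),
            "country": country,
            "stratum": stratum.astype(np.int64),
            "psu": psu.astype(np.int64),
            "weight": weight,
            "hh_type": hh_type,
            "size": size.astype(np.int64),
            "expenditure": expenditure,
            "food_expenditure": food_expenditure,
            "asset_index": asset_index,
            "wealth_q": wealth_q.astype(np.int64),
        }
    )

    # respondents: 1 per 18-49 household, n_older per 50+ household
    n_resp = np.where(is_50plus, n_older, 1)
    hh_rep = np.repeat(np.arange(n), n_resp)
    m = len(hh_rep)
    older = np.repeat(is_50plus, n_resp)
    age = np.where(
        older,
        50 + np.floor(rng.exponential(9.0, m)).astype(int).clip(0, 45),
        rng.integers(18, 50, m),
    )
    female = (rng.random(m) < 0.52).astype(int)
    resp_urban = psu_urban[psu[hh_rep]]
    edu_base = rng.integers(0, 4, m)
    education = np.clip(
        edu_base + resp_urban - (age >= 65).astype(int), 0, 3
    )

    respondents = pd.DataFrame(
        {
            "respondent_id": np.arange(m, dtype=np.int64),
            "household_id": hh_rep.astype(np.int64),
            "country": country[hh_rep],
            "stratum": stratum[hh_rep].astype(np.int64),
            "psu": psu[hh_rep].astype(np.int64),
            "weight": weight[hh_rep],
            "age": age.astype(np.int64),
            "female": female,
            "urban": resp_urban.astype(np.int64),
            "education": education.astype(np.int64),
            "wealth_q": wealth_q[hh_rep].astype(np.int64),
        }
    )

    truth = TrueParameters(
        visits=None,
        cause_coefficients={
            "betas": dict(_CAUSE_BETAS),
            "signal": config.cause_signal,
            "noise": config.cause_noise,
            "base_mix": dict(config.cause_mix),
        },
        cost_coefficients={
            "laws": {f"{g}|{lvl}": law.__dict__ for (g, lvl), law in
                     config.resolved_cost_params().items()},
            "covariate_effects": dict(config.cost_covariate_effects),
            "ncd_cost_ratio": config.ncd_cost_ratio,
        },
        config=config,
    )
    return households, respondents, truth


def weighted_quintiles(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Assign 1..5 by weighted quintile of ``values`` (1 = poorest)."""
    order = np.argsort(values, kind="stable")
    cw = np.cumsum(weights[order])
    frac = cw / cw[-1]
    # cumulative share strictly above k/5 puts a household in quintile k+1
    q_sorted = np.minimum(np.ceil(frac * 5).astype(int), 5).clip(1, 5)
    out = np.empty_like(q_sorted)
    out[order] = q_sorted
    return out


def _cause_probs(config: SimulationConfig, respondents: pd.DataFrame) -> np.ndarray:
    base = np.log(
        np.array([max(config.cause_mix[g], 1e-300) for g in CAUSE_ORDER])
    )
    z_age = (respondents["age"].to_numpy() - 45.0) / 15.0
    edu_c = respondents["education"].to_numpy() - 1.5
    urban = respondents["urban"].to_numpy()
    female = respondents["female"].to_numpy()
    scores = np.empty((len(respondents), _N_CAUSES))
    for j, g in enumerate(CAUSE_ORDER):
        b_age, b_edu, b_urb, b_fem = _CAUSE_BETAS[g]
        scores[:, j] = base[j] + config.cause_signal * (
            b_age * z_age + b_edu * edu_c + b_urb * urban + b_fem * female
        )
    # groups with zero base probability must stay at zero
    zero = np.array([config.cause_mix[g] == 0 for g in CAUSE_ORDER])
    scores[:, zero] = -np.inf
    return _softmax(scores)


def generate_visits(
    respondents: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Draw full visit histories (uncensored) for every respondent.

    Every visit carries its true cause group, a raw reason code consistent
    with that group, a facility sector, a recency rank within respondent and
    care level, and a true OOP cost from the two-part law.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    m = len(respondents)
    cols = [
        "visit_id", "respondent_id", "household_id", "country", "care_level",
        "rank", "cause_group", "reason_code", "private_facility", "oop_cost",
    ]
    if m == 0:
        return pd.DataFrame(columns=cols)

    probs = _cause_probs(config, respondents)
    dominant = _draw_categorical(rng, probs)
    mult = np.array(
        [config.visit_rate_multipliers.get(g, 1.0) for g in CAUSE_ORDER]
    )[dominant]

    counts = {}
    for lvl, rate in (
        ("outpatient", config.visit_rate_outpatient),
        ("inpatient", config.visit_rate_inpatient),
    ):
        mean = rate * mult
        if rate == 0:
            counts[lvl] = np.zeros(m, dtype=int)
            continue
        k = config.visit_dispersion
        p = k / (k + np.maximum(mean, 1e-12))
        c = rng.negative_binomial(k, p)
        c[mean == 0] = 0
        if config.visit_cap is not None:
            c = np.minimum(c, config.visit_cap)
        counts[lvl] = c

    frames = []
    eff = config.cost_covariate_effects
    laws = config.resolved_cost_params()
    z_age = (respondents["age"].to_numpy() - 45.0) / 15.0
    edu_c = respondents["education"].to_numpy() - 1.5
    urban = respondents["urban"].to_numpy()
    female = respondents["female"].to_numpy()
    wealth_c = respondents["wealth_q"].to_numpy() - 3.0
    cov_shift = (
        eff.get("age_z", 0.0) * z_age
        + eff.get("urban", 0.0) * urban
        + eff.get("education_c", 0.0) * edu_c
        + eff.get("female", 0.0) * female
        + eff.get("wealth_c", 0.0) * wealth_c
    )

    for lvl in CARE_LEVELS:
        c = counts[lvl]
        total = int(c.sum())
        if total == 0:
            continue
        ridx = np.repeat(np.arange(m), c)
        rank = np.concatenate([np.arange(1, k + 1) for k in c if k > 0])

        # visit cause: dominant with prob 1 - noise, else fresh draw
        vis_dom = dominant[ridx]
        fresh = _draw_categorical(rng, probs[ridx])
        use_fresh = rng.random(total) < config.cause_noise
        cause_idx = np.where(use_fresh, fresh, vis_dom)
        cause = np.array(CAUSE_ORDER)[cause_idx]

        # raw reason code uniform within group
        code_choice = rng.random(total)
        codes = np.empty(total, dtype=object)
        for g in CAUSE_ORDER:
            sel = cause == g
            opts = _GROUP_CODES[g]
            codes[sel] = np.array(opts, dtype=object)[
                (code_choice[sel] * len(opts)).astype(int)
            ]

        p_priv = np.array([config.private_sector_prob[g] for g in CAUSE_ORDER])
        private = (rng.random(total) < p_priv[cause_idx]).astype(float)

        p_pos = np.array([laws[(g, lvl)].p_positive for g in CAUSE_ORDER])
        mu = np.array([laws[(g, lvl)].log_mean for g in CAUSE_ORDER])
        sd = np.array([laws[(g, lvl)].log_sd for g in CAUSE_ORDER])
        positive = rng.random(total) < p_pos[cause_idx]
        log_cost = (
            mu[cause_idx] + cov_shift[ridx] + sd[cause_idx] * rng.normal(0, 1, total)
        )
        oop = np.where(positive, np.exp(log_cost), 0.0) * config.ppp_factor

        frames.append(
            pd.DataFrame(
                {
                    "respondent_id": respondents["respondent_id"].to_numpy()[ridx],
                    "household_id": respondents["household_id"].to_numpy()[ridx],
                    "country": respondents["country"].to_numpy()[ridx],
                    "care_level": lvl,
                    "rank": rank.astype(np.int64),
                    "cause_group": cause,
                    "reason_code": codes,
                    "private_facility": private,
                    "oop_cost": oop,
                }
            )
        )

    if not frames:
        return pd.DataFrame(columns=cols)
    visits = pd.concat(frames, ignore_index=True)
    visits = visits.sort_values(
        ["respondent_id", "care_level", "rank"], kind="stable"
    ).reset_index(drop=True)
    visits.insert(0, "visit_id", np.arange(len(visits), dtype=np.int64))
    return visits


def censor_to_sage(visits: pd.DataFrame) -> pd.DataFrame:
    """Apply the survey's observation pattern to a full visit table.

    Cause (and reason code, facility sector) are retained only for recency
    ranks 1–3 per care level; OOP cost only for rank 1.  Counts survive
    because every visit row survives — only cells are blanked.
    """
    if len(visits) == 0:
        return visits.copy()
    if "rank" not in visits.columns:
        raise SchemaError("visits table lacks a 'rank' column")
    obs = visits.copy()
    deep = obs["rank"] > 3
    obs.loc[deep, ["cause_group", "reason_code"]] = None
    obs.loc[deep, "private_facility"] = np.nan
    obs.loc[obs["rank"] > 1, "oop_cost"] = np.nan
    return obs


def attach_visit_counts(
    respondents: pd.DataFrame, visits: pd.DataFrame
) -> pd.DataFrame:
    """Add per-respondent annual visit counts (as a survey would report)."""
    out = respondents.copy()
    for lvl in CARE_LEVELS:
        if len(visits):
            cnt = (
                visits[visits["care_level"] == lvl]
                .groupby("respondent_id")
                .size()
            )
        else:
            cnt = pd.Series(dtype=np.int64)
        out[f"n_visits_{lvl}"] = (
            out["respondent_id"].map(cnt).fillna(0).astype(np.int64)
        )
    return out


def simulate(config: SimulationConfig) -> SimulatedSurvey:
    """Full generation cycle: population → visits → censoring.

    Returns the censored observable tables together with the truth sidecar.
    Deterministic: the same config (including seed) yields byte-identical
    tables.
    """
    households, respondents, truth = generate_population(config)
    visits = generate_visits(respondents, config)
    respondents = attach_visit_counts(respondents, visits)
    truth.visits = visits
    observed = censor_to_sage(visits)
    return SimulatedSurvey(households, respondents, observed, truth)


def write_truth_sidecar(truth: TrueParameters, out_dir) -> None:
    """Persist the truth sidecar (visits parquet + coefficient JSON)."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if truth.visits is not None:
        truth.visits.to_parquet(out / "truth_visits.parquet", index=False)
    payload = {
        "cause_coefficients": truth.cause_coefficients,
        "cost_coefficients": truth.cost_coefficients,
        "seed": truth.config.seed,
    }
    (out / "truth_params.json").write_text(json.dumps(payload, indent=2, default=str))


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
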