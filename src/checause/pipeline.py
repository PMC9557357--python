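"""End-to-end orchestration: impute causes → model costs → estimate CHE →
drivers, with a single config, reproducible seeds and a run manifest.

The core entry point is :func:`analyze`, which operates on in-memory
tables; :func:`run_pipeline` wraps it with file I/O for the CLI.
:func:`simulate_and_recover` runs repeated generate → censor → estimate
cycles against the synthetic generator's ground truth and reports bias and
sign-recovery rates — the package's built-in validation harness.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from checause import __version__
from checause.cause_imputation import (
    ImputationSettings,
    impute_causes,
    save_model_report,
)
from checause.che_estimation import (
    bootstrap_ui,
    build_che_cases,
    capacity_to_pay,
    che_by_wealth_quintile,
    che_share_by_disease,
    flag_che,
    food_poverty_line,
    household_oop,
    ncd_share_vs_dalys,
)
from checause.cost_model import (
    CurrencyConversion,
    annual_oop_by_disease,
    apply_cost_models,
    convert_currency,
    fit_cost_models,
    visit_frame,
)
from checause.drivers import (
    regress_che_shape,
    regress_visit_outcome,
    visits_to_che_table,
)
from checause.errors import ConfigError
from checause.survey_io import (
    DISEASE_CATEGORIES,
    ReasonCodebook,
    SurveyDesign,
    map_reasons,
    read_survey,
)
from checause.synthetic_sage import SimulationConfig, simulate, with_seed

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineSettings:
    """Analysis parameters (the survey-methodology constants are defaults)."""

    threshold: float = 0.40  # CHE threshold fraction of capacity-to-pay
    attribution_cutoff: float = 0.75
    equivalence_beta: float = 1.0  # household-size exponent; 0.56 = Xu scale
    percentile_band: tuple[float, float] = (0.45, 0.55)
    bootstrap_B: int = 1000
    seed: int = 0
    cost_family: str = "gamma"
    cost_covariates: tuple[str, ...] = (
        "cause", "age", "female", "urban", "education", "wealth_q",
    )
    imputation: ImputationSettings = field(default_factory=ImputationSettings)
    ppp_factors: dict = field(default_factory=dict)  # country -> factor
    run_bootstrap: bool = True
    weighted_regressions: bool = False

    def validate(self) -> None:
        for name in ("threshold", "attribution_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(name, "must be in (0, 1)")
        if self.bootstrap_B < 2:
            raise ConfigError("bootstrap_B", "must be >= 2")
        if self.cost_family not in ("gamma", "lognormal"):
            raise ConfigError("cost_family", "must be 'gamma' or 'lognormal'")


@dataclass
class PipelineResult:
    """Bundle of all pipeline outputs plus the run manifest."""

    visits_complete: pd.DataFrame
    annual_oop: pd.DataFrame
    cases: pd.DataFrame
    shares: pd.DataFrame
    shares_by_quintile: pd.DataFrame
    visits_to_che: pd.DataFrame
    cause_models: dict
    cost_models: dict
    regressions: dict
    bootstrap: dict
    manifest: dict


def _index_respondent_covariates(
    cases: pd.DataFrame, annual_oop: pd.DataFrame, respondents: pd.DataFrame
) -> pd.DataFrame:
    """Attach the covariates of each household's highest-spending respondent."""
    merged = annual_oop.merge(
        respondents[["respondent_id", "household_id", "age", "female",
                     "urban", "education"]],
        on="respondent_id", validate="1:1",
    )
    idx = merged.loc[
        merged.groupby("household_id")["total"].idxmax(),
        ["household_id", "age", "female", "urban", "education"],
    ]
    return cases.merge(idx, on="household_id", how="left", validate="1:1")


def analyze(
    households: pd.DataFrame,
    respondents: pd.DataFrame,
    visits_observed: pd.DataFrame,
    codebook: ReasonCodebook | None = None,
    settings: PipelineSettings = PipelineSettings(),
) -> PipelineResult:
    """Run the full analysis on validated survey tables.

    Stages: map raw reasons to cause groups; impute unobserved causes per
    country and care level; fit two-part cost models on observed-cost
    visits and predict the rest; convert to 2017 international dollars;
    build per-respondent annual OOP by disease; compute capacity-to-pay
    and flag/attribute CHE; summarize shares (with strata-bootstrap
    uncertainty); compute visits-to-CHE and run the drivers regressions.
    """
    settings.validate()
    t0 = time.time()
    manifest: dict = {
        "package_version": __version__,
        "seed": settings.seed,
        "n_households": len(households),
        "n_respondents": len(respondents),
        "n_visits": len(visits_observed),
        "warnings": [],
    }

    visits = visits_observed.copy()
    if codebook is not None and "reason_code" in visits.columns:
        mapped = map_reasons(visits["reason_code"], codebook)
        visits["cause_group"] = mapped
        manifest["codebook_version"] = codebook.version

    # stage 1: cause imputation
    visits, cause_models = impute_causes(
        visits, respondents, settings.imputation
    )
    manifest["cause_model_accuracy"] = {
        f"{c}|{l}": m.accuracy_overall for (c, l), m in cause_models.items()
    }

    # stage 2: cost models on observed-cost (rank-1) visits
    frame = visit_frame(visits, respondents).merge(
        households[["household_id", "stratum", "psu", "weight"]],
        on="household_id", how="left", validate="m:1",
    )
    cost_models = fit_cost_models(
        frame, covariates=list(settings.cost_covariates),
        family=settings.cost_family,
    )
    frame = apply_cost_models(frame, cost_models)

    # stage 3: currency conversion (household expenditure uses the same factor)
    households = households.copy()
    for country, factor in settings.ppp_factors.items():
        conv = CurrencyConversion(country, "nominal", factor)
        sel = frame["country"] == country
        frame.loc[sel, "final_cost"] = convert_currency(
            frame.loc[sel, "final_cost"], conv
        )
        hsel = households["country"] == country
        for col in ("expenditure", "food_expenditure"):
            households.loc[hsel, col] = convert_currency(
                households.loc[hsel, col], conv
            )

    # stage 4: annual OOP by disease, household totals, CHE
    annual = annual_oop_by_disease(respondents, frame)
    hh_oop = household_oop(annual, respondents)

    design = SurveyDesign.from_households(households)
    cases_all, shares_all, quintiles_all, boot = [], [], [], {}
    for country, hh_c in households.groupby("country", observed=True):
        line = food_poverty_line(hh_c, design=None,
                                 equivalence_beta=settings.equivalence_beta)
        ctp = capacity_to_pay(hh_c, line, settings.equivalence_beta)
        cases = build_che_cases(
            hh_c, hh_oop, ctp,
            threshold=settings.threshold,
            cutoff=settings.attribution_cutoff,
        )
        manifest["warnings"].append(
            {"country": country, "ctp_floored": ctp.n_floored,
             "nonpositive_expenditure_excluded": ctp.n_excluded,
             "subsistence_line": line}
        )
        shares = che_share_by_disease(cases)
        shares.insert(0, "country", country)
        quint = che_by_wealth_quintile(cases)
        quint.insert(0, "country", country)
        cases_all.append(cases)
        shares_all.append(shares)
        quintiles_all.append(quint)

        if settings.run_bootstrap:
            def estimator(df):
                w_che = df.loc[df["che"], "weight"].sum()
                out = {"che_rate": 100.0 * w_che / df["weight"].sum()}
                for cat in DISEASE_CATEGORIES + ("UNALLOCABLE",):
                    w_cat = df.loc[df["category"] == cat, "weight"].sum()
                    out[f"{cat}_share_of_cases"] = (
                        100.0 * w_cat / w_che if w_che > 0 else np.nan
                    )
                return out

            boot[country] = bootstrap_ui(
                estimator, cases, B=settings.bootstrap_B, seed=settings.seed
            )

    cases = pd.concat(cases_all, ignore_index=True)
    shares = pd.concat(shares_all, ignore_index=True)
    quintiles = pd.concat(quintiles_all, ignore_index=True)

    # stage 5: drivers
    vtc = visits_to_che_table(cases, frame, settings.threshold)
    reg_weights = "weight" if settings.weighted_regressions else None
    regressions: dict = {}
    case_cov = _index_respondent_covariates(
        cases[cases["che"]].merge(vtc, on="household_id", validate="1:1"),
        annual, respondents,
    )
    recent = frame[frame["rank"] == 1].copy()
    for country in households["country"].unique():
        for lvl in ("outpatient", "inpatient"):
            sub = recent[(recent["country"] == country)
                         & (recent["care_level"] == lvl)]
            for outcome in ("oop_cost", "private_facility"):
                key = (country, lvl, outcome)
                try:
                    regressions[key] = regress_visit_outcome(
                        sub, outcome, country=country, weights=reg_weights
                    )
                except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                    manifest["warnings"].append(
                        {"regression": str(key), "error": str(exc)}
                    )
        sub = case_cov[case_cov["country"] == country]
        for outcome in ("one_visit", "five_plus"):
            key = (country, "che_shape", outcome)
            try:
                regressions[key] = regress_che_shape(
                    sub, outcome, country=country, weights=reg_weights
                )
            except Exception as exc:  # noqa: BLE001
                manifest["warnings"].append(
                    {"regression": str(key), "error": str(exc)}
                )

    manifest["runtime_s"] = round(time.time() - t0, 3)
    return PipelineResult(
        visits_complete=frame,
        annual_oop=annual,
        cases=cases,
        shares=shares,
        shares_by_quintile=quintiles,
        visits_to_che=vtc,
        cause_models=cause_models,
        cost_models=cost_models,
        regressions=regressions,
        bootstrap=boot,
        manifest=manifest,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """File-based configuration for CLI runs."""

    input_dir: str
    output_dir: str
    codebook_path: str | None = None
    daly_table_path: str | None = None
    settings: PipelineSettings = field(default_factory=PipelineSettings)

    def validate(self) -> None:
        self.settings.validate()
        if not Path(self.input_dir).exists():
            raise ConfigError("input_dir", f"path {self.input_dir} does not exist")
        if self.codebook_path is not None and not Path(self.codebook_path).exists():
            raise ConfigError(
                "codebook_path", f"path {self.codebook_path} does not exist"
            )
        if self.daly_table_path is not None and not Path(
            self.daly_table_path
        ).exists():
            raise ConfigError(
                "daly_table_path", f"path {self.daly_table_path} does not exist"
            )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load inputs, run :func:`analyze`, persist tidy outputs + manifest."""
    config.validate()
    households, respondents, visits, _design = read_survey(config.input_dir)
    codebook = (
        ReasonCodebook.from_csv(config.codebook_path)
        if config.codebook_path
        else ReasonCodebook.default()
    )
    result = analyze(households, respondents, visits, codebook, config.settings)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.shares.to_csv(out / "che_shares.csv", index=False)
    result.shares_by_quintile.to_csv(out / "che_by_quintile.csv", index=False)
    result.cases.to_csv(out / "che_cases.csv", index=False)
    result.visits_to_che.to_csv(out / "visits_to_che.csv", index=False)
    save_model_report(result.cause_models, out / "cause_model_accuracy.csv")

    reg_rows = []
    for (country, lvl, outcome), res in result.regressions.items():
        t = res.tidy.copy()
        t.insert(0, "outcome", outcome)
        t.insert(0, "care_level", lvl)
        t.insert(0, "country", country)
        t["n"] = res.n
        reg_rows.append(t)
    if reg_rows:
        pd.concat(reg_rows, ignore_index=True).to_csv(
            out / "regressions.csv", index=False
        )

    boot_rows = []
    for country, ests in result.bootstrap.items():
        for key, est in ests.items():
            boot_rows.append(
                {"country": country, "metric": key, "estimate": est.point,
                 "lower": est.lower, "upper": est.upper, "B": est.B,
                 "seed": config.settings.seed}
            )
    if boot_rows:
        pd.DataFrame(boot_rows).to_csv(out / "bootstrap_intervals.csv",
                                       index=False)

    if config.daly_table_path:
        daly = pd.read_csv(config.daly_table_path)
        ncd = result.shares[result.shares["category"] == "NCD"][
            ["country", "share_of_cases"]
        ].rename(columns={"share_of_cases": "ncd_che_share"})
        ncd_share_vs_dalys(ncd, daly).to_csv(
            out / "ncd_che_vs_dalys.csv", index=False
        )

    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str)
    )
    return result


def truth_che_summary(
    survey, settings: PipelineSettings = PipelineSettings()
) -> dict:
    """Ground-truth CHE summary from the truth sidecar (tests/validation only).

    Recomputes CHE flags and category shares using every visit's *true*
    cause and cost — the quantity the estimation pipeline is trying to
    recover.  Never used inside the estimation path.
    """
    truth_visits = survey.visits_true.copy()
    truth_visits["final_cause"] = truth_visits["cause_group"]
    truth_visits["final_cost"] = truth_visits["oop_cost"]
    annual = annual_oop_by_disease(survey.respondents, truth_visits)
    hh_oop = household_oop(annual, survey.respondents)
    out = {}
    for country, hh_c in survey.households.groupby("country", observed=True):
        line = food_poverty_line(hh_c, None, settings.equivalence_beta)
        ctp = capacity_to_pay(hh_c, line, settings.equivalence_beta)
        cases = build_che_cases(hh_c, hh_oop, ctp, settings.threshold,
                                settings.attribution_cutoff)
        out[country] = {
            "cases": cases,
            "shares": che_share_by_disease(cases),
            "che_rate": 100.0
            * cases.loc[cases["che"], "weight"].sum()
            / cases["weight"].sum(),
        }
    return out


def simulate_and_recover(
    sim_config: SimulationConfig,
    settings: PipelineSettings = PipelineSettings(),
    n_reps: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated generate → censor → estimate cycles against ground truth.

    Per replicate, reports the estimated-minus-true CHE category shares,
    the estimated vs planted NCD/CD cost ratio, and the NCD contrasts from
    the CHE-shape regressions.
    """
    if n_reps < 1:
        raise ConfigError("n_reps", "must be >= 1")
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]
    for rep, rep_seed in enumerate(child_seeds):
        survey = simulate(with_seed(sim_config, rep_seed))
        result = analyze(
            survey.households, survey.respondents, survey.visits_observed,
            codebook=None, settings=settings,
        )
        truth = truth_che_summary(survey, settings)
        for country in truth:
            t_shares = truth[country]["shares"].set_index("category")[
                "share_of_cases"
            ]
            e_shares = result.shares[result.shares["country"] == country]
            e_shares = e_shares.set_index("category")["share_of_cases"]
            row = {"rep": rep, "country": country, "seed": rep_seed}
            for cat in DISEASE_CATEGORIES:
                row[f"bias_{cat}"] = e_shares.get(cat, np.nan) - t_shares.get(
                    cat, np.nan
                )
            m = result.cost_models.get((country, "outpatient"))
            if m is not None and m.part2 is not None:
                params = pd.Series(
                    np.asarray(m.part2.params), index=m.columns
                )
                row["log_cost_ratio_est"] = params.get("cause_NCD", np.nan)
            for outcome in ("one_visit", "five_plus"):
                res = result.regressions.get((country, "che_shape", outcome))
                try:
                    row[f"{outcome}_ncd_coef"] = (
                        res.coef("category_NCD") if res is not None else np.nan
                    )
                except KeyError:
                    row[f"{outcome}_ncd_coef"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
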