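"""Two-part out-of-pocket (OOP) cost model and annual OOP aggregation.

OOP spending per visit is zero-inflated and heavy-tailed, so it is
modelled in two parts: a logistic model for P(OOP > 0) and a log-link GLM
for the positive amounts (gamma family by default, log-normal with
smearing retransformation as an alternative).  Predicted cost is the
expected value p × E[cost | cost > 0] — a deliberate smoothing choice:
imputed visits contribute their mean spending rather than a stochastic
draw.

Only the single most recent visit per care level carries an observed cost;
the model is fitted on those visits (with their observed causes) and used
to predict costs for all other visits, whose causes may themselves be
imputed.  Observed values always override predictions.  Models are fitted
separately per country and care level, with the cause group entering as a
covariate (reference category CD), so the fitted NCD coefficient is the
log NCD-vs-CD cost ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import GroupKFold

from checause.errors import CheCauseError, ConfigError, PipelineOrderError
from checause.survey_io import CAUSE_ORDER

log = logging.getLogger(__name__)

#: reference category for the cause dummies (so cause_NCD = log cost ratio)
CAUSE_REFERENCE = "CD"

DEFAULT_COVARIATES = ["cause", "age", "female", "urban", "education", "wealth_q"]


def visit_frame(visits: pd.DataFrame, respondents: pd.DataFrame) -> pd.DataFrame:
    """Merge respondent covariates onto visits for cost modelling.

    The returned frame carries a ``cause`` column taken from
    ``final_cause`` if present (post-imputation), else from the observed
    ``cause_group``.
    """
    cov = ["respondent_id", "age", "female", "urban", "education", "wealth_q"]
    out = visits.merge(respondents[cov], on="respondent_id", how="left",
                       validate="m:1")
    out["cause"] = out["final_cause"] if "final_cause" in out else out["cause_group"]
    return out


def build_design(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Design matrix: intercept, cause dummies (ref CD), numeric covariates."""
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for cov in covariates:
        if cov == "cause":
            for g in CAUSE_ORDER:
                if g == CAUSE_REFERENCE:
                    continue
                X[f"cause_{g}"] = (df["cause"] == g).astype(float)
        else:
            X[cov] = pd.to_numeric(df[cov]).astype(float)
    return X


@dataclass
class TwoPartModel:
    """Fitted two-part cost model for one (country, care level) cell."""

    covariates: list[str]
    family: str  # 'gamma' or 'lognormal'
    columns: list[str]
    part1: object | None  # statsmodels results, or None if constant
    part2: object | None
    constant_p: float | None = None  # used when part 1 is degenerate
    smearing: float | None = None  # log-normal retransformation factor
    support: dict = field(default_factory=dict)  # per-column training range
    rmse: float = float("nan")
    country: str | None = None
    care_level: str | None = None
    diagnostics: dict = field(default_factory=dict)

    def predict_p(self, X: pd.DataFrame) -> np.ndarray:
        if self.constant_p is not None:
            return np.full(len(X), self.constant_p)
        # logit inverse-link from params directly: works for both plain and
        # ridge-penalized part-1 results
        eta = np.asarray(X[self.columns] @ np.asarray(self.part1.params))
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_conditional_mean(self, X: pd.DataFrame) -> np.ndarray:
        if self.part2 is None:
            return np.zeros(len(X))
        eta = np.asarray(X[self.columns] @ self.part2.params)
        mean = np.exp(eta)
        if self.family == "lognormal":
            mean = mean * self.smearing
        return mean


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Binomial GLM with a penalized fallback under (near) separation."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 30:
            return res, False
    except Exception:  # noqa: BLE001 - any fit failure routes to fallback
        pass
    warnings.warn("possible separation in part 1; using ridge-penalized fit",
                  stacklevel=3)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
        alpha=1e-3, L1_wt=0.0
    )
    return res, True


def fit_two_part(
    visits_observed: pd.DataFrame,
    covariates: list[str] | None = None,
    family: str = "gamma",
    country: str | None = None,
    care_level: str | None = None,
) -> TwoPartModel:
    """Fit the two-part model on visits with an observed cost.

    Part 1 is fitted on all observed-cost rows; part 2 on the positive
    subset.  Degenerate data are handled explicitly: all costs positive
    gives a constant participation probability of 1, all costs zero skips
    part 2 and predicts 0.
    """
    if family not in ("gamma", "lognormal"):
        raise ConfigError("family", "must be 'gamma' or 'lognormal'")
    covariates = list(covariates) if covariates is not None else list(
        DEFAULT_COVARIATES
    )
    df = visits_observed.dropna(subset=["oop_cost"])
    if len(df) == 0:
        raise CheCauseError("no observed-cost visits to fit on")
    if "cause" in covariates and df["cause"].isna().any():
        raise CheCauseError("observed-cost visits must carry a cause")

    y = df["oop_cost"].to_numpy(dtype=float)
    X = build_design(df, covariates)
    # drop empty dummy columns (cause groups absent from this cell)
    keep = [c for c in X.columns if c == "const" or X[c].nunique() > 1]
    Xk = X[keep]
    support = {
        c: (float(Xk[c].min()), float(Xk[c].max())) for c in keep if c != "const"
    }

    pos = y > 0
    model = TwoPartModel(
        covariates=covariates, family=family, columns=keep,
        part1=None, part2=None, support=support,
        country=country, care_level=care_level,
    )
    if pos.all():
        model.constant_p = 1.0
    elif not pos.any():
        model.constant_p = 0.0
        model.diagnostics["all_zero"] = True
        return model
    else:
        res1, penalized = _fit_logit(pos.astype(float), Xk)
        model.part1 = res1
        model.diagnostics["part1_penalized"] = penalized

    yp = y[pos]
    Xp = Xk[pos]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "gamma":
            res2 = sm.GLM(
                yp, Xp, family=sm.families.Gamma(link=sm.families.links.Log())
            ).fit()
        else:
            res2 = sm.OLS(np.log(yp), Xp).fit()
            model.smearing = float(np.mean(np.exp(res2.resid)))
    if not np.all(np.isfinite(res2.params)):
        raise CheCauseError("part-2 coefficients are not finite")
    model.part2 = res2
    return model


def predict_cost(model: TwoPartModel, visits: pd.DataFrame) -> pd.DataFrame:
    """Expected OOP per visit: P̂(positive) × conditional mean.

    Rows whose covariates fall outside the training support (including a
    cause group unseen at training) are still predicted but flagged in the
    ``out_of_support`` column.
    """
    if len(visits) == 0:
        return pd.DataFrame(columns=["expected_cost", "out_of_support"])
    X = build_design(visits, model.covariates)
    flag = np.zeros(len(visits), dtype=bool)
    for c in X.columns:
        if c == "const":
            continue
        if c not in model.columns:
            flag |= X[c].to_numpy() != 0  # dummy dropped at training
        else:
            lo, hi = model.support[c]
            flag |= (X[c].to_numpy() < lo) | (X[c].to_numpy() > hi)
    if flag.any():
        log.warning("%d prediction rows outside training support", int(flag.sum()))
    p = model.predict_p(X)
    cond = model.predict_conditional_mean(X)
    expected = p * cond
    if (expected < 0).any():
        raise CheCauseError("negative expected cost predicted")
    return pd.DataFrame(
        {"expected_cost": expected, "out_of_support": flag}, index=visits.index
    )


def select_covariates(
    candidate_sets: list[list[str]],
    visits_observed: pd.DataFrame,
    k_folds: int = 5,
    family: str = "gamma",
) -> tuple[list[str], pd.DataFrame]:
    """Choose the candidate covariate set minimizing out-of-sample RMSE.

    Grouped k-fold cross-validation by respondent; RMSE is computed on the
    expected-cost scale over all held-out rows including zeros, mirroring
    how predictions are consumed downstream.  Ties (and identical
    candidates) resolve to the earliest listed set.  Returns the winner
    plus the RMSE table.
    """
    if len(candidate_sets) < 1:
        raise CheCauseError("need at least one candidate covariate set")
    df = visits_observed.dropna(subset=["oop_cost"]).reset_index(drop=True)
    groups = df["respondent_id"].to_numpy()
    if len(np.unique(groups)) < k_folds:
        raise CheCauseError("degenerate folds: fewer respondents than folds")
    gkf = GroupKFold(n_splits=k_folds)
    rows = []
    best, best_rmse = None, np.inf
    for i, cand in enumerate(candidate_sets):
        sq_err = []
        for tr, te in gkf.split(df, groups=groups):
            m = fit_two_part(df.iloc[tr], covariates=cand, family=family)
            pred = predict_cost(m, df.iloc[te])["expected_cost"].to_numpy()
            sq_err.append((pred - df.iloc[te]["oop_cost"].to_numpy()) ** 2)
        rmse = float(np.sqrt(np.concatenate(sq_err).mean()))
        rows.append({"candidate": i, "covariates": "+".join(cand), "rmse": rmse})
        if rmse < best_rmse - 1e-12:  # strict improvement; first set wins ties
            best, best_rmse = cand, rmse
    table = pd.DataFrame(rows)
    log.info("covariate selection RMSE table:\n%s", table.to_string(index=False))
    return list(best), table


@dataclass(frozen=True)
class CurrencyConversion:
    """Linear conversion from a source currency-year to 2017 international $."""

    country: str
    source: str  # e.g. 'LCU-2009'
    factor: float  # international $ per source unit

    def __post_init__(self):
        if not self.factor > 0:
            raise ConfigError("factor", "PPP factor must be > 0")


def convert_currency(amounts, conversion: CurrencyConversion):
    """Elementwise conversion to 2017 international dollars."""
    arr = np.asarray(amounts, dtype=float)
    out = arr * conversion.factor
    if isinstance(amounts, pd.Series):
        return pd.Series(out, index=amounts.index, name=amounts.name)
    return out


def fit_cost_models(
    frame: pd.DataFrame,
    covariates: list[str] | None = None,
    family: str = "gamma",
) -> dict[tuple[str, str], TwoPartModel]:
    """Fit one two-part model per (country, care level) on rank-1 visits."""
    models = {}
    observed = frame[frame["oop_cost"].notna()]
    for (country, lvl), sub in observed.groupby(["country", "care_level"],
                                                observed=True):
        models[(country, lvl)] = fit_two_part(
            sub, covariates=covariates, family=family,
            country=country, care_level=lvl,
        )
    return models


def apply_cost_models(
    frame: pd.DataFrame, models: dict[tuple[str, str], TwoPartModel]
) -> pd.DataFrame:
    """Add ``final_cost``: observed OOP where present, else model prediction."""
    out = frame.copy()
    out["final_cost"] = out["oop_cost"]
    out["cost_imputed"] = out["oop_cost"].isna()
    todo = out[out["oop_cost"].isna()]
    for (country, lvl), sub in todo.groupby(["country", "care_level"],
                                            observed=True):
        if (country, lvl) not in models:
            raise PipelineOrderError(f"no cost model for {(country, lvl)}")
        pred = predict_cost(models[(country, lvl)], sub)
        out.loc[sub.index, "final_cost"] = pred["expected_cost"].to_numpy()
    if out["final_cost"].isna().any():
        raise PipelineOrderError(
            "visit lacking both observed and predicted cost"
        )
    return out


def annual_oop_by_disease(
    respondents: pd.DataFrame, visits_complete: pd.DataFrame
) -> pd.DataFrame:
    """Per-respondent annual OOP totals by cause group.

    Every visit must carry a cause (observed or imputed) and a cost
    (observed rank-1 or predicted).  Respondents without visits get an
    all-zero row.  The ``total`` column equals the sum over groups.
    """
    required = {"final_cause", "final_cost"}
    if len(visits_complete) and not required <= set(visits_complete.columns):
        raise PipelineOrderError(
            "annual_oop_by_disease needs final_cause and final_cost; "
            "run imputation and cost prediction first"
        )
    if len(visits_complete) and visits_complete["final_cost"].isna().any():
        raise PipelineOrderError("visit lacking both observed and predicted cost")
    if len(visits_complete):
        pivot = (
            visits_complete.groupby(["respondent_id", "final_cause"],
                                    observed=True)["final_cost"]
            .sum()
            .unstack(fill_value=0.0)
        )
    else:
        pivot = pd.DataFrame()
    pivot = pivot.reindex(columns=list(CAUSE_ORDER), fill_value=0.0)
    pivot = pivot.reindex(respondents["respondent_id"], fill_value=0.0)
    pivot["total"] = pivot[list(CAUSE_ORDER)].sum(axis=1)
    return pivot.reset_index()
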