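"""Drivers of CHE: visits-to-CHE and comparative regressions.

Two mechanisms can push a household over the CHE threshold: a single
expensive encounter (an acute shock, typical of communicable disease or
injury care) or the accumulation of many cheaper visits (typical of
chronic NCD management).  The "visits-to-CHE" statistic captures this: the
household's per-visit OOP costs are ranked from most to least expensive
and k is the minimal number of visits whose cumulative spending crosses
the CHE threshold amount (40% of capacity-to-pay).  Because the costs are
sorted descending, the greedy prefix is provably a minimum-cardinality
crossing subset, so k does not depend on how ties are ordered.

Comparative regressions are OLS with one-way cluster-robust standard
errors by primary sampling unit (PSU): per-visit OOP cost and private
facility attendance on the most recent (non-modelled) visits, and linear
probability models for CHE arising from one visit or from five or more
visits, restricted to CHE cases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from checause.errors import CheCauseError
from checause.survey_io import CAUSE_ORDER

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VisitsToCHE:
    """Minimal number of visits whose cumulative OOP crosses the threshold."""

    household_id: int
    threshold: float
    k: int
    costs_sorted: tuple[float, ...]

    @property
    def one_visit(self) -> bool:
        return self.k == 1

    @property
    def five_plus(self) -> bool:
        return self.k >= 5


def visits_to_che(
    costs, threshold: float, household_id: int = -1
) -> VisitsToCHE:
    """Compute k for one CHE household.

    ``threshold`` is the CHE threshold amount (threshold fraction ×
    capacity-to-pay).  The household's total OOP must strictly exceed it,
    otherwise the household could not have been flagged and the call is a
    contradiction error.
    """
    c = np.sort(np.asarray(costs, dtype=float))[::-1]
    if c.sum() <= threshold:
        raise CheCauseError(
            "total OOP does not exceed the threshold: household cannot be CHE"
        )
    cum = np.cumsum(c)
    k = int(np.argmax(cum > threshold)) + 1
    return VisitsToCHE(
        household_id=household_id,
        threshold=float(threshold),
        k=k,
        costs_sorted=tuple(c),
    )


def visits_to_che_table(
    cases: pd.DataFrame,
    visits_complete: pd.DataFrame,
    threshold: float = 0.40,
) -> pd.DataFrame:
    """Visits-to-CHE for every flagged household.

    Per-visit costs are the household's final (observed or predicted)
    costs; the independence of visit costs within a household is an
    assumption of this construction.
    """
    che = cases[cases["che"]]
    per_hh = visits_complete.groupby("household_id")["final_cost"]
    costs_by_hh = {hid: grp.to_numpy() for hid, grp in per_hh}
    rows = []
    for _, case in che.iterrows():
        hid = case["household_id"]
        v = visits_to_che(
            costs_by_hh.get(hid, np.array([])),
            threshold * case["ctp"],
            household_id=hid,
        )
        rows.append(
            {
                "household_id": hid,
                "k": v.k,
                "one_visit": int(v.one_visit),
                "five_plus": int(v.five_plus),
            }
        )
    return pd.DataFrame(rows, columns=["household_id", "k", "one_visit",
                                       "five_plus"])


@dataclass
class RegressionResult:
    """Tidy OLS output with one-way PSU-clustered standard errors."""

    outcome: str
    tidy: pd.DataFrame = field(repr=False)  # term, estimate, se, p
    n: int
    n_clusters: int
    country: str | None = None
    degenerate: bool = False
    dropped_terms: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        row = self.tidy[self.tidy["term"] == term]
        if len(row) == 0:
            raise KeyError(term)
        return float(row["estimate"].iloc[0])


def _design(df: pd.DataFrame, covariates: list[str],
            cause_col: str = "cause") -> pd.DataFrame:
    """Design matrix: intercept; 'cause'/'category' expand to dummies with
    CD as reference; 'wealth_q' expands to quintile dummies (ref Q1)."""
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for cov in covariates:
        if cov in ("cause", "category"):
            col = df[cause_col] if cov == "cause" else df["category"]
            if cov == "cause":
                levels = [g for g in CAUSE_ORDER if g != "CD"]
            else:
                levels = ["NCD", "INJURY", "UNALLOCABLE"]
            for g in levels:
                name = f"{cov}_{g}"
                X[name] = (col == g).astype(float)
        elif cov == "wealth_q":
            for q in range(2, 6):
                X[f"wealth_q{q}"] = (df["wealth_q"] == q).astype(float)
        else:
            X[cov] = pd.to_numeric(df[cov]).astype(float)
    return X


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedy left-to-right rank check; later collinear columns dropped."""
    keep, dropped, empty = [], [], []
    M = np.empty((len(X), 0))
    for c in X.columns:
        col = X[c].to_numpy()
        if c != "const" and np.all(col == 0):
            empty.append(c)  # absent factor level; drop silently
            continue
        cand = np.column_stack([M, col])
        if np.linalg.matrix_rank(cand) > M.shape[1]:
            keep.append(c)
            M = cand
        else:
            dropped.append(c)
    if dropped:
        warnings.warn(f"dropping collinear terms {dropped}", stacklevel=3)
    return X[keep], dropped + empty


def _cluster_ols(
    df: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    cluster_col: str = "psu",
    cause_col: str = "cause",
    country: str | None = None,
    weights: str | None = None,
) -> RegressionResult:
    """Shared OLS engine with listwise deletion and PSU-clustered SEs."""
    needed = [outcome, cluster_col] + [
        c for c in covariates if c not in ("cause", "category", "wealth_q")
    ]
    if "cause" in covariates:
        needed.append(cause_col)
    if "category" in covariates:
        needed.append("category")
    if "wealth_q" in covariates:
        needed.append("wealth_q")
    if weights:
        needed.append(weights)
    n_before = len(df)
    df = df.dropna(subset=[c for c in dict.fromkeys(needed) if c in df.columns])
    if n_before - len(df):
        log.info("listwise deletion dropped %d rows", n_before - len(df))

    y = pd.to_numeric(df[outcome]).astype(float).to_numpy()
    groups = df[cluster_col].to_numpy()
    n_clusters = len(np.unique(groups))
    if n_clusters < 2:
        raise CheCauseError("need at least 2 clusters for clustered SEs")
    X, dropped = _drop_collinear(_design(df, covariates, cause_col))

    if np.ptp(y) == 0:
        warnings.warn(
            f"outcome '{outcome}' is constant; no inference possible",
            stacklevel=3,
        )
        tidy = pd.DataFrame(
            {"term": X.columns, "estimate": [y[0] if c == "const" else 0.0
                                             for c in X.columns],
             "se": np.nan, "p": np.nan}
        )
        return RegressionResult(outcome, tidy, len(df), n_clusters, country,
                                degenerate=True, dropped_terms=dropped)

    if weights:
        model = sm.WLS(y, X, weights=df[weights].to_numpy())
    else:
        model = sm.OLS(y, X)
    res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    tidy = pd.DataFrame(
        {
            "term": X.columns,
            "estimate": np.asarray(res.params),
            "se": np.asarray(res.bse),
            "p": np.asarray(res.pvalues),
        }
    )
    return RegressionResult(outcome, tidy, len(df), n_clusters, country,
                            dropped_terms=dropped)


def regress_visit_outcome(
    visits_recent: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    country: str | None = None,
    weights: str | None = None,
) -> RegressionResult:
    """OLS for per-visit OOP cost or private-facility attendance.

    Restricted by the caller to most-recent (non-modelled) visits, per
    country and care level.  The ``cause_NCD`` coefficient is the
    NCD-vs-CD contrast.
    """
    if outcome not in ("oop_cost", "private_facility"):
        raise CheCauseError(f"unsupported visit outcome {outcome!r}")
    if covariates is None:
        covariates = ["cause", "age", "urban", "education", "female",
                      "wealth_q"]
    return _cluster_ols(visits_recent, outcome, covariates,
                        cause_col="cause", country=country, weights=weights)


def regress_che_shape(
    che_cases: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    country: str | None = None,
    weights: str | None = None,
) -> RegressionResult:
    """Linear probability model for the shape of CHE (one visit / 5+ visits).

    ``che_cases`` must contain CHE households only, with their attributed
    ``category`` and the visits-to-CHE indicators merged in.
    """
    if outcome not in ("one_visit", "five_plus"):
        raise CheCauseError(f"unsupported CHE-shape outcome {outcome!r}")
    if covariates is None:
        covariates = ["category", "age", "urban", "education", "female",
                      "wealth_q"]
    return _cluster_ols(che_cases, outcome, covariates, country=country,
                        weights=weights)
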