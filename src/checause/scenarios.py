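"""Named validation scenarios for the synthetic generator.

Each scenario fixes a data-generating condition under which a specific
property of the estimation pipeline can be checked against ground truth:

* ``cost_recovery_config`` — dense outpatient utilization with the planted
  NCD-vs-CD positive-cost ratio of 1.6, for two-part-model coefficient
  recovery.
* ``high_signal_config`` — strong covariate signal and high
  within-respondent cause concentration, so the cause classifier reaches
  held-out accuracy above 0.95 and end-to-end CHE shares can be compared
  with the truth sidecar.
* ``mechanism_config`` — NCD care generates many cheap visits while CD
  care generates rare, expensive inpatient stays, planting the
  "culmination vs shock" contrast in the visits-to-CHE outcomes; the
  ``null=True`` variant removes every NCD/CD difference.
* ``calibration_config`` — a moderate survey (100 PSUs in 20 strata) used
  to check empirical coverage of strata-resampled bootstrap intervals for
  the weighted CHE rate.

These are study conditions, not tuning knobs: tests and the acceptance
script consume them as-is.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from checause.che_estimation import household_oop
from checause.cost_model import annual_oop_by_disease
from checause.synthetic_sage import (
    CostLaw,
    ExpenditureParams,
    SimulationConfig,
    default_cost_params,
)

PLANTED_COST_RATIO = 1.6


def cost_recovery_config(n_households: int = 2400, seed: int = 0) -> SimulationConfig:
    """High-volume outpatient care with the planted cost ratio of 1.6.

    Yields roughly 20 000 positive-cost outpatient visits at the default
    size.
    """
    return SimulationConfig(
        n_households=n_households,
        seed=seed,
        visit_rate_outpatient=8.0,
        ncd_cost_ratio=PLANTED_COST_RATIO,
    )


def high_signal_config(n_households: int = 20000, seed: int = 0) -> SimulationConfig:
    """Near-deterministic cause structure: classifier accuracy >= 0.95."""
    return SimulationConfig(
        n_households=n_households,
        seed=seed,
        cause_signal=10.0,
        cause_noise=0.02,
        visit_rate_inpatient=0.2,
    )


def mechanism_config(
    n_households: int = 2500, seed: int = 0, null: bool = False
) -> SimulationConfig:
    """Plant 'NCD CHE from many cheap visits, CD CHE from one expensive
    visit' (or remove all NCD/CD differences when ``null``)."""
    cp = default_cost_params(1.0)
    if null:
        cp[("NCD", "outpatient")] = cp[("CD", "outpatient")] = CostLaw(0.85, 3.2, 1.0)
        cp[("NCD", "inpatient")] = cp[("CD", "inpatient")] = CostLaw(0.90, 5.0, 1.0)
        multipliers = {}
    else:
        cp[("NCD", "outpatient")] = CostLaw(0.90, 3.7, 0.8)
        cp[("NCD", "inpatient")] = CostLaw(0.90, 3.7, 0.8)
        cp[("CD", "outpatient")] = CostLaw(0.80, 2.5, 0.8)
        cp[("CD", "inpatient")] = CostLaw(0.95, 6.2, 1.0)
        multipliers = {"NCD": 5.0, "CD": 0.7}
    mix = {"NCD": 0.45, "CD": 0.45, "INJURY": 0.04, "PAIN": 0.02,
           "SURGERY": 0.01, "OTHER": 0.02, "UNIDENTIFIED": 0.01}
    return SimulationConfig(
        n_households=n_households,
        seed=seed,
        cause_mix=mix,
        cause_noise=0.05,
        visit_rate_outpatient=2.0,
        visit_rate_inpatient=0.15,
        visit_rate_multipliers=multipliers,
        cost_params=cp,
        expenditure_params=ExpenditureParams(log_mean=math.log(1500.0)),
    )


def calibration_config(n_households: int = 2400, seed: int = 0) -> SimulationConfig:
    """Survey design used for bootstrap-coverage checks (20 strata x 5 PSUs)."""
    return SimulationConfig(
        n_households=n_households, seed=seed, n_strata=20, psus_per_stratum=5
    )


def truth_household_table(survey) -> pd.DataFrame:
    """Households with their true total OOP (no estimation models involved)."""
    tv = survey.visits_true.copy()
    tv["final_cause"] = tv["cause_group"]
    tv["final_cost"] = tv["oop_cost"]
    annual = annual_oop_by_disease(survey.respondents, tv)
    hh = household_oop(annual, survey.respondents)
    out = survey.households.merge(
        hh[["household_id", "total"]], on="household_id", how="left"
    )
    out["total"] = out["total"].fillna(0.0)
    return out.rename(columns={"total": "oop_total"})


def weighted_che_rate(
    df: pd.DataFrame, threshold: float = 0.40, beta: float = 1.0
) -> float:
    """Weighted CHE rate (%) with the subsistence line recomputed from the
    given rows — the estimator whose bootstrap calibration is checked.

    Vectorized numpy implementation of the standard chain: per-equivalent
    food ranking, 45th–55th weighted percentile band, capacity-to-pay with
    the food-below-subsistence convention, strict 40% threshold.
    """
    w = df["weight"].to_numpy()
    food = df["food_expenditure"].to_numpy()
    size = df["size"].to_numpy().astype(float)
    exp_ = df["expenditure"].to_numpy()
    oop = df["oop_total"].to_numpy()

    per_eq = food / size**beta
    order = np.argsort(per_eq, kind="stable")
    v, ws = per_eq[order], w[order]
    cum = np.cumsum(ws) / ws.sum()
    lower = np.concatenate([[0.0], cum[:-1]])
    band = (cum > 0.45) & (lower < 0.55)
    line = np.average(v[band], weights=ws[band])

    subsistence = line * size**beta
    ctp = np.where(food < subsistence, exp_ - food, exp_ - subsistence)
    ctp = np.where(ctp <= 0, 1e-6, ctp)
    flagged = oop > threshold * ctp
    return float(100.0 * w[flagged].sum() / w.sum())
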