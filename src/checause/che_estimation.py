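"""Catastrophic health expenditure (CHE): capacity-to-pay, flagging,
disease attribution, survey-weighted shares and bootstrap uncertainty.

A household incurs CHE when its annual out-of-pocket (OOP) health spending
exceeds 40% of its capacity-to-pay.  Capacity-to-pay is annual household
expenditure minus subsistence spending, where the subsistence (food
poverty) line is the weighted mean of per-equivalent-adult food spending
among households between the 45th and 55th weighted percentiles of that
quantity.  Each CHE case is attributed to NCD, CD or injury when that
category exceeds 75% of the household's *disease-specific* OOP spending
(pain/surgery/other/unidentified spending is excluded from the
denominator); otherwise it is unallocable.

Uncertainty intervals come from a non-parametric bootstrap that respects
the complex survey design: primary sampling units are resampled with
replacement within strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from checause.errors import CheCauseError
from checause.survey_io import DISEASE_CATEGORIES, SurveyDesign

log = logging.getLogger(__name__)

ATTRIBUTION_CATEGORIES = DISEASE_CATEGORIES + ("UNALLOCABLE",)

#: floor for capacity-to-pay when expenditure does not exceed subsistence
CTP_EPSILON = 1e-6


def food_poverty_line(
    households: pd.DataFrame,
    design: SurveyDesign | None = None,
    equivalence_beta: float = 1.0,
) -> float:
    """Subsistence line per equivalent adult.

    Households are ranked by food spending per equivalized member
    (``size ** beta``) using survey weights; the line is the weighted mean
    of that quantity over households whose cumulative-weight interval
    overlaps the open (45%, 55%) band.
    """
    if len(households) == 0:
        raise CheCauseError("food_poverty_line: empty household table")
    for col in ("food_expenditure", "size"):
        if households[col].isna().any():
            raise CheCauseError(f"food_poverty_line: missing {col}")
    w = (
        design.weights_for(households["household_id"]).to_numpy()
        if design is not None
        else households["weight"].to_numpy()
    )
    per_eq = (
        households["food_expenditure"].to_numpy()
        / households["size"].to_numpy() ** equivalence_beta
    )
    order = np.argsort(per_eq, kind="stable")
    v = per_eq[order]
    ws = w[order]
    cum = np.cumsum(ws) / ws.sum()
    lower = np.concatenate([[0.0], cum[:-1]])
    in_band = (cum > 0.45) & (lower < 0.55)
    if not in_band.any():  # can only happen with pathological weights
        in_band = np.isclose(cum, np.clip(cum, 0.45, 0.55))
    return float(np.average(v[in_band], weights=ws[in_band]))


@dataclass
class CapacityToPay:
    """Per-household capacity-to-pay table plus processing counters."""

    table: pd.DataFrame = field(repr=False)
    n_floored: int = 0
    n_excluded: int = 0


def capacity_to_pay(
    households: pd.DataFrame,
    line: float,
    equivalence_beta: float = 1.0,
) -> CapacityToPay:
    """Capacity-to-pay = expenditure − subsistence, with the WHO convention
    that households spending less on food than the subsistence line use
    their actual food spending instead (preventing negative-capacity
    artifacts).  Nonpositive-expenditure households are flagged invalid and
    excluded from CHE denominators; a nonpositive difference is floored at
    a small epsilon and counted.
    """
    if line < 0:
        raise CheCauseError("subsistence line must be >= 0")
    df = households[
        ["household_id", "expenditure", "food_expenditure", "size"]
    ].copy()
    df["equivalized_size"] = df["size"].astype(float) ** equivalence_beta
    df["subsistence"] = line * df["equivalized_size"]
    below = df["food_expenditure"] < df["subsistence"]
    df["ctp"] = np.where(
        below,
        df["expenditure"] - df["food_expenditure"],
        df["expenditure"] - df["subsistence"],
    )
    df["valid"] = df["expenditure"] > 0
    n_excluded = int((~df["valid"]).sum())
    if n_excluded:
        log.info("excluding %d households with nonpositive expenditure",
                 n_excluded)
    floored = df["valid"] & (df["ctp"] <= 0)
    n_floored = int(floored.sum())
    if n_floored:
        log.warning("%d households with capacity-to-pay floored at epsilon",
                    n_floored)
    df.loc[floored, "ctp"] = CTP_EPSILON
    return CapacityToPay(table=df, n_floored=n_floored, n_excluded=n_excluded)


def household_oop(annual_oop: pd.DataFrame, respondents: pd.DataFrame) -> pd.DataFrame:
    """Sum respondent-level annual OOP (total and per group) to households."""
    merged = annual_oop.merge(
        respondents[["respondent_id", "household_id"]],
        on="respondent_id", how="left", validate="m:1",
    )
    value_cols = [c for c in annual_oop.columns if c != "respondent_id"]
    return merged.groupby("household_id", as_index=False)[value_cols].sum()


def flag_che(
    oop_total: pd.Series | np.ndarray,
    ctp: pd.Series | np.ndarray,
    threshold: float = 0.40,
) -> np.ndarray:
    """CHE indicator: OOP strictly exceeds ``threshold`` × capacity-to-pay."""
    return np.asarray(oop_total) > threshold * np.asarray(ctp)


def attribute_che(
    oop_by_cause: pd.Series | dict,
    cutoff: float = 0.75,
) -> str:
    """Attribute one CHE case to NCD, CD, INJURY or UNALLOCABLE.

    Shares are computed over disease-specific spending only (NCD+CD+INJURY);
    the category is assigned when its share strictly exceeds ``cutoff``.
    Zero disease-specific spending is unallocable.
    """
    s = pd.Series(oop_by_cause, dtype=float)
    disease = s.reindex(list(DISEASE_CATEGORIES), fill_value=0.0)
    denom = disease.sum()
    if denom <= 0:
        return "UNALLOCABLE"
    shares = disease / denom
    top = shares.idxmax()
    if shares[top] > cutoff:
        return str(top)
    return "UNALLOCABLE"


def build_che_cases(
    households: pd.DataFrame,
    hh_oop: pd.DataFrame,
    ctp: CapacityToPay,
    threshold: float = 0.40,
    cutoff: float = 0.75,
) -> pd.DataFrame:
    """Join OOP totals with capacity-to-pay, flag CHE and attribute cases.

    Returns one row per *valid* household with columns ``oop_total``,
    ``ctp``, ``che`` and, for flagged households, ``category``.
    """
    base = households[["household_id", "country", "stratum", "psu", "weight",
                       "wealth_q"]].merge(
        ctp.table[["household_id", "ctp", "valid"]], on="household_id",
        validate="1:1",
    )
    oop_cols = [c for c in hh_oop.columns if c != "household_id"]
    base = base.merge(hh_oop, on="household_id", how="left", validate="1:1")
    base[oop_cols] = base[oop_cols].fillna(0.0)
    if "total" not in base.columns:
        raise CheCauseError("household OOP table lacks a 'total' column")
    base = base[base["valid"]].copy()
    base["che"] = flag_che(base["total"], base["ctp"], threshold)
    base["category"] = pd.NA
    flagged = base.index[base["che"]]
    base.loc[flagged, "category"] = [
        attribute_che(
            {g: base.at[i, g] if g in base.columns else 0.0
             for g in DISEASE_CATEGORIES},
            cutoff,
        )
        for i in flagged
    ]
    return base.rename(columns={"total": "oop_total"})


def che_share_by_disease(cases: pd.DataFrame) -> pd.DataFrame:
    """Weighted CHE shares per attribution category, two normalizations.

    ``share_of_households``: weighted % of all (valid) households flagged
    CHE with that category.  ``share_of_cases``: weighted % of CHE cases,
    which sums to 100 over the four categories.  With zero CHE cases the
    case shares are missing.
    """
    w_all = cases["weight"].sum()
    che = cases[cases["che"]]
    w_che = che["weight"].sum()
    rows = []
    for cat in ATTRIBUTION_CATEGORIES:
        w_cat = che.loc[che["category"] == cat, "weight"].sum()
        rows.append(
            {
                "category": cat,
                "share_of_households": 100.0 * w_cat / w_all,
                "share_of_cases": (100.0 * w_cat / w_che) if w_che > 0 else np.nan,
            }
        )
    if w_che == 0:
        log.info("no CHE cases: share_of_cases undefined")
    return pd.DataFrame(rows)


def che_by_wealth_quintile(cases: pd.DataFrame) -> pd.DataFrame:
    """Per-quintile CHE rates and category composition (weighted)."""
    rows = []
    for q in range(1, 6):
        sub = cases[cases["wealth_q"] == q]
        if len(sub) == 0:
            log.info("wealth quintile %d empty", q)
            for cat in ATTRIBUTION_CATEGORIES:
                rows.append({"wealth_q": q, "category": cat,
                             "share_of_households": np.nan,
                             "share_of_cases": np.nan})
            continue
        shares = che_share_by_disease(sub)
        shares.insert(0, "wealth_q", q)
        rows.extend(shares.to_dict("records"))
    return pd.DataFrame(rows)


@dataclass
class BootstrapEstimate:
    """Point estimate with a percentile interval from strata-resampled
    replicates."""

    point: float
    lower: float
    upper: float
    B: int
    resampling: str = "PSUs within strata"

    def __post_init__(self):
        if self.B < 2:
            raise CheCauseError("bootstrap needs B >= 2")
        if np.isfinite(self.point) and not (
            self.lower <= self.point <= self.upper
        ):
            log.warning(
                "percentile interval [%g, %g] does not bracket point %g",
                self.lower, self.upper, self.point,
            )


def _merge_single_psu_strata(strata: np.ndarray, psus: np.ndarray) -> np.ndarray:
    """Merge strata containing a single PSU into the neighbouring stratum."""
    df = pd.DataFrame({"stratum": strata, "psu": psus})
    n_psus = df.groupby("stratum")["psu"].nunique()
    singles = n_psus.index[n_psus < 2].to_numpy()
    if len(singles) == 0:
        return strata
    out = strata.copy()
    ordered = np.sort(n_psus.index.to_numpy())
    for s in singles:
        pos = np.searchsorted(ordered, s)
        neighbour = ordered[pos - 1] if pos > 0 else ordered[min(pos + 1,
                                                                len(ordered) - 1)]
        if neighbour == s and len(ordered) > 1:
            neighbour = ordered[1] if pos == 0 else ordered[pos - 1]
        out[strata == s] = neighbour
        log.info("merged single-PSU stratum %s into %s", s, neighbour)
    return out


def bootstrap_ui(
    estimator,
    data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    level: float = 95.0,
    rao_wu: bool = True,
) -> BootstrapEstimate | dict[str, BootstrapEstimate]:
    """Design-respecting non-parametric bootstrap.

    Within each stratum, PSUs are resampled with replacement (all member
    rows of a sampled PSU are kept together).  By default the Rao–Wu
    rescaling variant is used: k−1 of the stratum's k PSUs are drawn and
    their survey weights multiplied by k/(k−1), which removes the (k−1)/k
    variance deflation of the naive with-replacement cluster bootstrap.
    Set ``rao_wu=False`` for the naive k-draw variant.

    ``estimator`` maps a data frame (with ``stratum``, ``psu`` and
    ``weight`` columns) to a float or a dict of floats; percentile bounds
    at ``level`` are returned.  Strata with a single PSU are merged into a
    neighbour first.  Fully seeded.
    """
    if B < 2:
        raise CheCauseError("bootstrap needs B >= 2")
    rng = np.random.default_rng(seed)
    strata = _merge_single_psu_strata(
        data["stratum"].to_numpy(), data["psu"].to_numpy()
    )
    data = data.assign(stratum=strata)
    point = estimator(data)
    scalar = np.isscalar(point) or isinstance(point, float)

    # pre-index rows by PSU within stratum for fast replicates
    psu_rows: dict[int, list[np.ndarray]] = {}
    for s in np.unique(strata):
        rows = []
        sub = np.flatnonzero(strata == s)
        for p in np.unique(data["psu"].to_numpy()[sub]):
            rows.append(sub[data["psu"].to_numpy()[sub] == p])
        psu_rows[s] = rows

    has_weight = "weight" in data.columns
    base_weight = data["weight"].to_numpy() if has_weight else None
    reps = []
    for _ in range(B):
        idx_parts = []
        scale_parts = []
        for s, rows in psu_rows.items():
            k = len(rows)
            draws = k - 1 if (rao_wu and k > 1) else k
            scale = k / draws
            chosen = rng.integers(0, k, draws)
            for c in chosen:
                idx_parts.append(rows[c])
                scale_parts.append(np.full(len(rows[c]), scale))
        idx = np.concatenate(idx_parts)
        rep_df = data.iloc[idx]
        if has_weight and rao_wu:
            rep_df = rep_df.assign(
                weight=base_weight[idx] * np.concatenate(scale_parts)
            )
        reps.append(estimator(rep_df))

    alpha = (100.0 - level) / 2.0

    def interval(p, vals):
        vals = np.asarray(vals, dtype=float)
        ok = vals[np.isfinite(vals)]
        if len(ok) == 0:
            return BootstrapEstimate(p, np.nan, np.nan, B)
        lo, hi = np.percentile(ok, [alpha, 100.0 - alpha])
        return BootstrapEstimate(float(p), float(lo), float(hi), B)

    if scalar:
        return interval(point, reps)
    keys = list(point)
    return {k: interval(point[k], [r[k] for r in reps]) for k in keys}


def ncd_share_vs_dalys(
    che_shares: pd.DataFrame, daly_table: pd.DataFrame
) -> pd.DataFrame:
    """Join the estimated NCD share of CHE with the external NCD share of
    adult DALYs per country.  The DALY shares are reference inputs (e.g.
    from a burden-of-disease study); nothing is computed on them beyond the
    join.
    """
    required = {"country", "ncd_daly_share_adults_20plus"}
    if not required <= set(daly_table.columns):
        raise CheCauseError(f"daly_table needs columns {sorted(required)}")
    if daly_table["country"].duplicated().any():
        dup = daly_table.loc[daly_table["country"].duplicated(), "country"]
        raise CheCauseError(f"duplicate countries in daly_table: {list(dup)}")
    if len(che_shares) == 0:
        return pd.DataFrame(
            columns=["country", "ncd_che_share", "ncd_daly_share_adults_20plus"]
        )
    missing = set(che_shares["country"]) - set(daly_table["country"])
    if missing:
        raise CheCauseError(f"countries missing from daly_table: {sorted(missing)}")
    out = che_shares.merge(daly_table, on="country", validate="1:1")
    return out
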