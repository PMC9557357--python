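"""Figures: CHE composition by disease area, by wealth quintile, and
forest plots of the NCD-vs-CD regression contrasts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from checause.che_estimation import ATTRIBUTION_CATEGORIES

_COLORS = {"NCD": "#c0392b", "CD": "#2980b9", "INJURY": "#f39c12",
           "UNALLOCABLE": "#95a5a6"}


def plot_che_composition(shares: pd.DataFrame, metric: str = "share_of_cases",
                         ax=None):
    """Stacked bars of CHE composition per country."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    countries = shares["country"].unique()
    bottom = pd.Series(0.0, index=countries)
    for cat in ATTRIBUTION_CATEGORIES:
        vals = (
            shares[shares["category"] == cat]
            .set_index("country")[metric]
            .reindex(countries)
            .fillna(0.0)
        )
        ax.bar(countries, vals, bottom=bottom[countries], label=cat,
               color=_COLORS[cat])
        bottom = bottom.add(vals, fill_value=0.0)
    ax.set_ylabel("% " + ("of CHE cases" if metric == "share_of_cases"
                          else "of households"))
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_che_by_quintile(quintiles: pd.DataFrame, country: str,
                         metric: str = "share_of_households", ax=None):
    """Stacked bars of CHE by wealth quintile for one country."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    sub = quintiles[quintiles["country"] == country]
    bottom = pd.Series(0.0, index=range(1, 6))
    for cat in ATTRIBUTION_CATEGORIES:
        vals = (
            sub[sub["category"] == cat]
            .set_index("wealth_q")[metric]
            .reindex(range(1, 6))
            .fillna(0.0)
        )
        ax.bar(vals.index, vals, bottom=bottom, label=cat, color=_COLORS[cat])
        bottom += vals
    ax.set_xlabel("wealth quintile (1 = poorest)")
    ax.set_ylabel(metric.replace("_", " "))
    ax.set_title(country)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_contrasts(regressions: dict, term: str = "category_NCD", ax=None):
    """Forest plot of a regression term across countries/outcomes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels, est, lo, hi = [], [], [], []
    for key, res in regressions.items():
        row = res.tidy[res.tidy["term"] == term]
        if len(row) == 0 or res.degenerate:
            continue
        e, s = float(row["estimate"].iloc[0]), float(row["se"].iloc[0])
        labels.append(" / ".join(str(k) for k in key))
        est.append(e)
        lo.append(e - 1.96 * s)
        hi.append(e + 1.96 * s)
    y = range(len(labels))
    ax.hlines(y, lo, hi, color="0.4")
    ax.plot(est, y, "o", color="#c0392b")
    ax.axvline(0.0, color="0.7", ls="--")
    ax.set_yticks(list(y), labels, fontsize=7)
    ax.set_xlabel(term)
    return ax
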