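import numpy as np
import pandas as pd
import pytest

from checause.synthetic_sage import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_survey():
    """A modest simulated survey shared by read-only tests."""
    return simulate(SimulationConfig(n_households=1500, seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


def brute_force_poverty_line(food, size, weight, beta):
    """Independent weighted-percentile-band oracle for the subsistence line.

    Plain python: sort by per-equivalent food spending, walk the cumulative
    weight shares, average the values whose interval overlaps (45%, 55%).
    """
    per = [f / s**beta for f, s in zip(food, size)]
    order = sorted(range(len(per)), key=lambda i: per[i])
    total = sum(weight)
    num = den = 0.0
    cum = 0.0
    for i in order:
        lo = cum / total
        cum += weight[i]
        hi = cum / total
        if hi > 0.45 and lo < 0.55:
            num += per[i] * weight[i]
            den += weight[i]
    return num / den


def brute_force_min_visits(costs, threshold):
    """Minimum-cardinality subset of costs whose sum strictly exceeds the
    threshold, by exhaustive search over subset sizes."""
    from itertools import combinations

    for k in range(1, len(costs) + 1):
        if any(sum(c) > threshold for c in combinations(costs, k)):
            return k
    raise AssertionError("no subset crosses the threshold")


def oracle_attribute(shares: dict, cutoff: float = 0.75) -> str:
    """Independent attribution rule: share of disease-specific spending
    strictly above the cutoff wins, else unallocable."""
    disease = {k: shares.get(k, 0.0) for k in ("NCD", "CD", "INJURY")}
    denom = sum(disease.values())
    if denom <= 0:
        return "UNALLOCABLE"
    for cat, v in disease.items():
        if v / denom > cutoff:
            return cat
    return "UNALLOCABLE"


def truth_frame(survey) -> pd.DataFrame:
    """Truth visits dressed as a completed pipeline frame (tests only)."""
    tv = survey.visits_true.copy()
    tv["final_cause"] = tv["cause_group"]
    tv["final_cost"] = tv["oop_cost"]
    return tv
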