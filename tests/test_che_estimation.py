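import numpy as np
import pandas as pd
import pytest

from checause.che_estimation import (
    BootstrapEstimate,
    attribute_che,
    bootstrap_ui,
    build_che_cases,
    capacity_to_pay,
    che_by_wealth_quintile,
    che_share_by_disease,
    flag_che,
    food_poverty_line,
    ncd_share_vs_dalys,
)
from checause.errors import CheCauseError
from conftest import brute_force_poverty_line, oracle_attribute


def hh_frame(food, size, weight, expenditure=None):
    n = len(food)
    return pd.DataFrame(
        {
            "household_id": np.arange(n),
            "food_expenditure": food,
            "size": size,
            "weight": weight,
            "expenditure": expenditure if expenditure is not None
            else np.asarray(food) * 2.5,
        }
    )


class TestFoodPovertyLine:
    def test_identical_households(self):
        hh = hh_frame([70.0] * 20, [1] * 20, [1.0] * 20)
        assert food_poverty_line(hh) == pytest.approx(70.0)

    def test_uniform_1_to_100_gives_50_5(self):
        hh = hh_frame(list(range(1, 101)), [1] * 100, [1.0] * 100)
        assert food_poverty_line(hh) == pytest.approx(50.5)

    @pytest.mark.parametrize("beta", [1.0, 0.56])
    def test_matches_brute_force_oracle(self, beta, rng):
        for _ in range(10):
            n = int(rng.integers(20, 200))
            food = rng.exponential(100.0, n) + 1
            size = rng.integers(1, 8, n)
            weight = rng.exponential(1.0, n) + 0.1
            hh = hh_frame(food, size, weight)
            got = food_poverty_line(hh, equivalence_beta=beta)
            want = brute_force_poverty_line(food, size, weight, beta)
            assert got == pytest.approx(want, rel=1e-12)

    def test_beta_changes_line(self, rng):
        food = rng.exponential(100.0, 80) + 1
        size = rng.integers(1, 8, 80)
        hh = hh_frame(food, size, np.ones(80))
        assert food_poverty_line(hh, equivalence_beta=1.0) != pytest.approx(
            food_poverty_line(hh, equivalence_beta=0.56)
        )

    def test_empty_errors(self):
        with pytest.raises(CheCauseError, match="empty"):
            food_poverty_line(hh_frame([], [], []))


class TestCapacityToPay:
    def test_arithmetic(self):
        hh = hh_frame([300.0], [4], [1.0], expenditure=[1200.0])
        ctp = capacity_to_pay(hh, line=50.0, equivalence_beta=1.0)
        row = ctp.table.iloc[0]
        assert row["subsistence"] == pytest.approx(200.0)
        assert row["ctp"] == pytest.approx(1000.0)

    def test_food_below_subsistence_uses_actual_food(self):
        hh = hh_frame([150.0], [4], [1.0], expenditure=[1200.0])
        ctp = capacity_to_pay(hh, line=50.0)
        assert ctp.table.iloc[0]["ctp"] == pytest.approx(1050.0)

    def test_expenditure_at_subsistence_floors_to_epsilon(self):
        hh = hh_frame([250.0], [4], [1.0], expenditure=[200.0])
        ctp = capacity_to_pay(hh, line=50.0)
        assert ctp.table.iloc[0]["ctp"] > 0
        assert ctp.n_floored == 1

    def test_nonpositive_expenditure_excluded(self):
        hh = hh_frame([10.0, 20.0], [1, 1], [1.0, 1.0],
                      expenditure=[0.0, 500.0])
        ctp = capacity_to_pay(hh, line=5.0)
        assert ctp.n_excluded == 1
        assert not ctp.table.iloc[0]["valid"]

    def test_ctp_never_exceeds_expenditure(self, rng):
        n = 200
        hh = hh_frame(rng.exponential(100, n), rng.integers(1, 7, n),
                      np.ones(n), expenditure=rng.exponential(500, n) + 1)
        ctp = capacity_to_pay(hh, line=30.0)
        ok = ctp.table[ctp.table["valid"]]
        assert (ok["ctp"] <= ok["expenditure"] + 1e-9).all()


class TestFlagChe:
    def test_above_threshold(self):
        assert flag_che(np.array([450.0]), np.array([1000.0]))[0]

    def test_boundary_is_strict(self):
        assert not flag_che(np.array([400.0]), np.array([1000.0]))[0]

    def test_zero_oop_never_flags(self):
        assert not flag_che(np.array([0.0]), np.array([5.0]))[0]

    def test_agrees_with_rowwise_recomputation(self, rng):
        oop = rng.exponential(200.0, 500)
        ctp = rng.exponential(800.0, 500) + 1
        got = flag_che(oop, ctp, 0.40)
        want = np.array([o > 0.40 * c for o, c in zip(oop, ctp)])
        assert (got == want).all()


class TestAttribution:
    def test_single_category(self):
        assert attribute_che({"NCD": 1.0}) == "NCD"

    def test_dominant_share(self):
        assert attribute_che({"NCD": 0.80, "CD": 0.20}) == "NCD"

    def test_split_is_unallocable(self):
        assert attribute_che({"NCD": 0.60, "CD": 0.40}) == "UNALLOCABLE"

    def test_boundary_exactly_cutoff_is_unallocable(self):
        assert attribute_che({"NCD": 0.75, "CD": 0.25}) == "UNALLOCABLE"

    def test_non_disease_spending_excluded_from_denominator(self):
        # PAIN dominates overall spending but NCD is all disease-specific
        assert attribute_che({"NCD": 10.0, "PAIN": 90.0}) == "NCD"

    def test_zero_disease_spending_unallocable(self):
        assert attribute_che({"PAIN": 50.0, "OTHER": 20.0}) == "UNALLOCABLE"

    def test_matches_oracle_on_grid(self):
        # exhaustive grid over disease-share vectors at step 0.05
        grid = np.arange(0.0, 1.0001, 0.05)
        for a in grid:
            for b in grid:
                if a + b > 1.0 + 1e-12:
                    continue
                shares = {"NCD": a, "CD": b, "INJURY": 1.0 - a - b}
                assert attribute_che(shares) == oracle_attribute(shares)


class TestShares:
    @staticmethod
    def cases_frame(categories, weights, che=None):
        n = len(categories)
        return pd.DataFrame(
            {
                "household_id": np.arange(n),
                "weight": weights,
                "che": [True] * n if che is None else che,
                "category": categories,
                "wealth_q": 1,
            }
        )

    def test_all_ncd_is_100(self):
        cases = self.cases_frame(["NCD", "NCD"], [1.0, 2.0])
        out = che_share_by_disease(cases).set_index("category")
        assert out.loc["NCD", "share_of_cases"] == pytest.approx(100.0)

    def test_equal_weights_50_50(self):
        cases = self.cases_frame(["NCD", "NCD", "CD", "CD"], [1.0] * 4)
        out = che_share_by_disease(cases).set_index("category")
        assert out.loc["NCD", "share_of_cases"] == pytest.approx(50.0)
        assert out.loc["CD", "share_of_cases"] == pytest.approx(50.0)

    def test_weighted_tally_matches_hand_computation(self):
        cases = self.cases_frame(
            ["NCD", "CD", "NCD", pd.NA],
            [3.0, 1.0, 2.0, 4.0],
            che=[True, True, True, False],
        )
        out = che_share_by_disease(cases).set_index("category")
        assert out.loc["NCD", "share_of_cases"] == pytest.approx(100 * 5 / 6)
        assert out.loc["NCD", "share_of_households"] == pytest.approx(
            100 * 5 / 10
        )

    def test_case_shares_sum_to_100(self, rng):
        cats = rng.choice(["NCD", "CD", "INJURY", "UNALLOCABLE"], 200)
        cases = self.cases_frame(cats, rng.exponential(1, 200) + 0.01)
        out = che_share_by_disease(cases)
        assert out["share_of_cases"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_no_cases_gives_missing_case_shares(self):
        cases = self.cases_frame([pd.NA], [1.0], che=[False])
        out = che_share_by_disease(cases)
        assert out["share_of_cases"].isna().all()
        assert (out["share_of_households"] == 0).all()

    def test_quintile_breakdown_flat_when_identical(self):
        rows = []
        for q in range(1, 6):
            for cat, che in [("NCD", True), (pd.NA, False)]:
                rows.append({"household_id": len(rows), "weight": 1.0,
                             "che": che, "category": cat, "wealth_q": q})
        out = che_by_wealth_quintile(pd.DataFrame(rows))
        ncd = out[(out.category == "NCD")]
        assert np.allclose(ncd["share_of_households"], 50.0)

    def test_quintile_gradient_recovered(self, rng):
        # plant a monotone gradient: CHE rate declines with wealth
        rows = []
        for q in range(1, 6):
            n_che = 60 - 10 * q
            for i in range(100):
                rows.append({"household_id": len(rows), "weight": 1.0,
                             "che": i < n_che,
                             "category": "NCD" if i < n_che else pd.NA,
                             "wealth_q": q})
        out = che_by_wealth_quintile(pd.DataFrame(rows))
        ncd = out[out.category == "NCD"].sort_values("wealth_q")
        assert (np.diff(ncd["share_of_households"]) < 0).all()


class TestBootstrap:
    @staticmethod
    def design_frame(rng, n=200, n_strata=5, psus=4):
        return pd.DataFrame(
            {
                "stratum": rng.integers(0, n_strata, n),
                "psu": rng.integers(0, psus, n),
                "y": rng.normal(10.0, 2.0, n),
                "weight": rng.exponential(1.0, n) + 0.1,
            }
        ).assign(psu=lambda d: d.stratum * psus + d.psu)

    def test_degenerate_data_zero_width(self, rng):
        df = self.design_frame(rng).assign(y=5.0)
        est = bootstrap_ui(lambda d: float(d["y"].mean()), df, B=50, seed=1)
        assert est.lower == est.upper == est.point == 5.0

    def test_seed_reproducible(self, rng):
        df = self.design_frame(rng)
        f = lambda d: float(np.average(d["y"], weights=d["weight"]))
        a = bootstrap_ui(f, df, B=100, seed=7)
        b = bootstrap_ui(f, df, B=100, seed=7)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_interval_brackets_point(self, rng):
        df = self.design_frame(rng)
        est = bootstrap_ui(lambda d: float(d["y"].mean()), df, B=200, seed=2)
        assert est.lower <= est.point <= est.upper

    def test_single_psu_stratum_merged(self, rng):
        df = self.design_frame(rng, n_strata=3)
        solo = pd.DataFrame(
            {"stratum": [99], "psu": [999], "y": [10.0], "weight": [1.0]}
        )
        df = pd.concat([df, solo], ignore_index=True)
        est = bootstrap_ui(lambda d: float(d["y"].mean()), df, B=50, seed=3)
        assert np.isfinite(est.lower)

    def test_b_below_two_rejected(self, rng):
        with pytest.raises(CheCauseError, match="B >= 2"):
            bootstrap_ui(lambda d: 0.0, self.design_frame(rng), B=1, seed=0)
        with pytest.raises(CheCauseError):
            BootstrapEstimate(0.0, 0.0, 0.0, B=1)

    def test_dict_estimator_gets_per_key_intervals(self, rng):
        df = self.design_frame(rng)
        est = bootstrap_ui(
            lambda d: {"m": float(d["y"].mean()), "s": float(d["y"].std())},
            df, B=60, seed=4,
        )
        assert set(est) == {"m", "s"}
        assert est["m"].lower <= est["m"].point <= est["m"].upper


class TestBuildCases:
    def test_flags_and_attribution_consistent(self, rng):
        n = 60
        hh = pd.DataFrame(
            {
                "household_id": np.arange(n),
                "country": "c",
                "stratum": rng.integers(0, 4, n),
                "psu": rng.integers(0, 12, n),
                "weight": np.ones(n),
                "wealth_q": rng.integers(1, 6, n),
                "expenditure": rng.exponential(1000, n) + 200,
                "food_expenditure": rng.exponential(300, n) + 50,
                "size": rng.integers(1, 6, n),
            }
        )
        hh["food_expenditure"] = np.minimum(hh.food_expenditure,
                                            0.8 * hh.expenditure)
        oop = pd.DataFrame(
            {
                "household_id": np.arange(n),
                "NCD": rng.exponential(120, n),
                "CD": rng.exponential(60, n),
                "INJURY": 0.0,
                "PAIN": rng.exponential(10, n),
                "SURGERY": 0.0,
                "OTHER": 0.0,
                "UNIDENTIFIED": 0.0,
            }
        )
        oop["total"] = oop.drop(columns="household_id").sum(axis=1)
        line = food_poverty_line(hh)
        ctp = capacity_to_pay(hh, line)
        cases = build_che_cases(hh, oop, ctp)
        merged = cases.merge(ctp.table[["household_id"]], on="household_id")
        # independent row-by-row recomputation
        for _, r in merged.iterrows():
            assert r["che"] == (r["oop_total"] > 0.40 * r["ctp"])
            if r["che"]:
                assert r["category"] == oracle_attribute(
                    {g: r[g] for g in ("NCD", "CD", "INJURY")}
                )


class TestDalyJoin:
    def test_passthrough(self):
        che = pd.DataFrame({"country": ["china"], "ncd_che_share": [38.0]})
        daly = pd.DataFrame(
            {"country": ["china"], "ncd_daly_share_adults_20plus": [0.84]}
        )
        out = ncd_share_vs_dalys(che, daly)
        assert out.iloc[0]["ncd_daly_share_adults_20plus"] == 0.84
        assert out.iloc[0]["ncd_che_share"] == 38.0

    def test_empty_country_list(self):
        daly = pd.DataFrame(
            {"country": ["a"], "ncd_daly_share_adults_20plus": [0.5]}
        )
        out = ncd_share_vs_dalys(
            pd.DataFrame(columns=["country", "ncd_che_share"]), daly
        )
        assert len(out) == 0

    def test_duplicate_country_rejected(self):
        che = pd.DataFrame({"country": ["a"], "ncd_che_share": [10.0]})
        daly = pd.DataFrame(
            {"country": ["a", "a"], "ncd_daly_share_adults_20plus": [0.5, 0.6]}
        )
        with pytest.raises(CheCauseError, match="duplicate"):
            ncd_share_vs_dalys(che, daly)

    def test_missing_country_listed(self):
        che = pd.DataFrame({"country": ["a", "b"], "ncd_che_share": [1.0, 2.0]})
        daly = pd.DataFrame(
            {"country": ["a"], "ncd_daly_share_adults_20plus": [0.5]}
        )
        with pytest.raises(CheCauseError, match="b"):
            ncd_share_vs_dalys(che, daly)
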