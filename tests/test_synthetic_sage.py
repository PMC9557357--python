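import numpy as np
import pandas as pd
import pytest
from scipy import stats

from checause.errors import ConfigError
from checause.survey_io import CAUSE_ORDER
from checause.synthetic_sage import (
    SimulationConfig,
    censor_to_sage,
    generate_population,
    generate_visits,
    simulate,
    with_seed,
)


class TestGeneratePopulation:
    def test_empty_config_gives_empty_tables(self):
        hh, resp, _ = generate_population(SimulationConfig(n_households=0))
        assert len(hh) == 0 and len(resp) == 0

    def test_all_50plus_households(self):
        cfg = SimulationConfig(n_households=300, share_50plus_households=1.0,
                               seed=5)
        hh, resp, _ = generate_population(cfg)
        assert (hh["hh_type"] == "50plus").all()
        assert (resp["age"] >= 50).all()

    def test_18_49_households_have_one_adult_respondent(self):
        cfg = SimulationConfig(n_households=400, share_50plus_households=0.0,
                               seed=5)
        hh, resp, _ = generate_population(cfg)
        assert resp.groupby("household_id").size().eq(1).all()
        assert resp["age"].between(18, 49).all()

    def test_weights_positive_and_oversampling_downweights_50plus(self):
        hh, _, _ = generate_population(SimulationConfig(n_households=4000,
                                                        seed=0))
        assert (hh["weight"] > 0).all()
        mean_w = hh.groupby("hh_type")["weight"].mean()
        assert mean_w["50plus"] < mean_w["18-49"]

    def test_wealth_quintiles_weighted_balance(self):
        hh, _, _ = generate_population(SimulationConfig(n_households=8000,
                                                        seed=1))
        shares = hh.groupby("wealth_q")["weight"].sum() / hh["weight"].sum()
        assert shares.index.tolist() == [1, 2, 3, 4, 5]
        assert np.allclose(shares, 0.2, atol=0.02)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_households", -1),
            ("share_50plus_households", 1.5),
            ("visit_rate_outpatient", -0.1),
            ("ncd_cost_ratio", 0.0),
            ("cause_noise", 2.0),
            ("ppp_factor", -1.0),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(ConfigError, match=field):
            cfg.validate()

    def test_cause_mix_must_sum_to_one(self):
        mix = dict.fromkeys(CAUSE_ORDER, 0.1)
        with pytest.raises(ConfigError, match="cause_mix"):
            SimulationConfig(cause_mix=mix).validate()


class TestGenerateVisits:
    def test_zero_rates_give_zero_visits(self):
        cfg = SimulationConfig(n_households=200, visit_rate_outpatient=0.0,
                               visit_rate_inpatient=0.0, seed=3)
        _, resp, _ = generate_population(cfg)
        assert len(generate_visits(resp, cfg)) == 0

    def test_ranks_are_contiguous_within_respondent_level(self, small_survey):
        v = small_survey.visits_true
        for (_, _), grp in list(v.groupby(["respondent_id", "care_level"]))[:50]:
            assert sorted(grp["rank"]) == list(range(1, len(grp) + 1))

    def test_null_cost_ratio_equalizes_ncd_cd_means(self):
        # cause_signal=0 makes cause independent of covariates, so the
        # marginal NCD/CD contrast isolates the planted cost coefficient
        cfg = SimulationConfig(n_households=12000, ncd_cost_ratio=1.0, seed=7,
                               visit_rate_outpatient=4.0, cause_signal=0.0)
        s = simulate(cfg)
        pos = s.visits_true.query("oop_cost > 0 and care_level == 'outpatient'")
        ncd = np.log(pos.loc[pos.cause_group == "NCD", "oop_cost"])
        cd = np.log(pos.loc[pos.cause_group == "CD", "oop_cost"])
        # log-scale means equal under the null (two-sample z within MC error)
        z = (ncd.mean() - cd.mean()) / np.sqrt(
            ncd.var() / len(ncd) + cd.var() / len(cd)
        )
        assert abs(z) < 4

    def test_planted_cost_ratio_recovered_in_generated_data(self):
        cfg = SimulationConfig(n_households=12000, ncd_cost_ratio=1.6, seed=8,
                               visit_rate_outpatient=4.0, cause_signal=0.0)
        s = simulate(cfg)
        pos = s.visits_true.query("oop_cost > 0 and care_level == 'outpatient'")
        ncd = np.log(pos.loc[pos.cause_group == "NCD", "oop_cost"])
        cd = np.log(pos.loc[pos.cause_group == "CD", "oop_cost"])
        diff = ncd.mean() - cd.mean()
        se = np.sqrt(ncd.var() / len(ncd) + cd.var() / len(cd))
        assert diff == pytest.approx(np.log(1.6), abs=4 * se)

    def test_visit_cap_enforced(self):
        cfg = SimulationConfig(n_households=500, visit_rate_outpatient=6.0,
                               visit_cap=4, seed=9)
        s = simulate(cfg)
        counts = s.visits_true.groupby(["respondent_id", "care_level"]).size()
        assert counts.max() <= 4


class TestDistributionalInvariants:
    def test_cause_frequencies_match_mix_without_covariate_signal(self):
        # marginal cause frequencies equal the configured mix only when the
        # covariate signal is off; chi-square GOF at alpha=0.001
        cfg = SimulationConfig(n_households=25000, cause_signal=0.0, seed=10,
                               visit_rate_outpatient=4.0)
        s = simulate(cfg)
        v = s.visits_true
        assert len(v) > 100_000
        obs = v["cause_group"].value_counts().reindex(CAUSE_ORDER, fill_value=0)
        exp = np.array([cfg.cause_mix[g] for g in CAUSE_ORDER]) * len(v)
        _, p = stats.chisquare(obs, exp)
        assert p > 0.001

    def test_zero_cost_fraction_matches_one_minus_p(self, small_survey):
        cfg = small_survey.truth.config
        laws = cfg.resolved_cost_params()
        v = small_survey.visits_true
        sub = v[(v.cause_group == "NCD") & (v.care_level == "outpatient")]
        frac_zero = (sub.oop_cost == 0).mean()
        p = laws[("NCD", "outpatient")].p_positive
        se = np.sqrt(p * (1 - p) / len(sub))
        assert frac_zero == pytest.approx(1 - p, abs=4 * se + 1e-9)


class TestCensoring:
    def test_censoring_pattern(self, small_survey):
        obs = small_survey.visits_observed
        assert obs.loc[obs["rank"] > 3, "cause_group"].isna().all()
        assert obs.loc[obs["rank"] <= 3, "cause_group"].notna().all()
        assert obs.loc[obs["rank"] > 1, "oop_cost"].isna().all()
        assert obs.loc[obs["rank"] == 1, "oop_cost"].notna().all()

    def test_six_visits_three_causes_one_cost(self):
        v = pd.DataFrame(
            {
                "visit_id": range(6),
                "respondent_id": 0,
                "household_id": 0,
                "country": "c",
                "care_level": "outpatient",
                "rank": range(1, 7),
                "cause_group": ["NCD"] * 6,
                "reason_code": ["diabetes"] * 6,
                "private_facility": 1.0,
                "oop_cost": 10.0,
            }
        )
        obs = censor_to_sage(v)
        assert obs["cause_group"].notna().sum() == 3
        assert obs["oop_cost"].notna().sum() == 1
        assert len(obs) == 6  # total counts retained

    def test_censoring_is_subselection_of_truth(self, small_survey):
        truth = small_survey.visits_true
        obs = small_survey.visits_observed
        retained = obs["cause_group"].notna()
        assert (
            obs.loc[retained, "cause_group"]
            == truth.loc[retained, "cause_group"]
        ).all()
        cost_kept = obs["oop_cost"].notna()
        assert np.allclose(
            obs.loc[cost_kept, "oop_cost"], truth.loc[cost_kept, "oop_cost"]
        )

    def test_empty_table(self):
        cfg = SimulationConfig(n_households=0)
        _, resp, _ = generate_population(cfg)
        empty = generate_visits(resp, cfg)
        assert len(censor_to_sage(empty)) == 0


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = SimulationConfig(n_households=400, seed=7)
        a, b = simulate(cfg), simulate(cfg)
        assert a.households.to_csv() == b.households.to_csv()
        assert a.respondents.to_csv() == b.respondents.to_csv()
        assert a.visits_observed.to_csv() == b.visits_observed.to_csv()

    def test_different_seed_differs(self):
        a = simulate(SimulationConfig(n_households=400, seed=7))
        b = simulate(with_seed(SimulationConfig(n_households=400, seed=7), 8))
        assert not a.households["expenditure"].equals(b.households["expenditure"])
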