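import itertools

import numpy as np
import pandas as pd
import pytest

from metqg.errors import ConfigError
from metqg.selection import (SelectionConfig, multiplicative_index,
                             n_selected, response_to_selection, run_scenarios,
                             select)
from metqg.simulate import paper_like_config, simulate_met


def _cfg(**kw):
    base = dict(traits=("WP", "TS"), directions={"WP": "increase",
                                                 "TS": "decrease"},
                lambdas={"WP": 40.0, "TS": 12.0})
    base.update(kw)
    return SelectionConfig(**base)


class TestMultiplicativeIndex:
    def test_direct_product(self):
        vals = pd.DataFrame({"WP": [60.0], "TS": [8.0]}, index=["g1"])
        mi, ok = multiplicative_index(vals, _cfg())
        assert mi["g1"] == pytest.approx(80.0)  # (60-40) * (12-8)
        assert ok["g1"]

    def test_factor_at_limit_gives_zero(self):
        vals = pd.DataFrame({"WP": [40.0], "TS": [8.0]}, index=["g1"])
        mi, ok = multiplicative_index(vals, _cfg())
        assert mi["g1"] == 0.0
        assert not ok["g1"]

    def test_ranking_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame({"WP": rng.uniform(45, 80, 12),
                             "TS": rng.uniform(5, 11, 12)},
                            index=[f"g{i}" for i in range(12)])
        mi, ok = multiplicative_index(vals, _cfg())
        brute = {g: (vals.loc[g, "WP"] - 40.0) * (12.0 - vals.loc[g, "TS"])
                 for g in vals.index}
        assert ok.all()
        ranked = sorted(brute, key=lambda g: -brute[g])
        assert mi.sort_values(ascending=False).index.tolist() == ranked

    def test_scaling_one_trait_preserves_order(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame({"WP": rng.uniform(45, 80, 10),
                             "TS": rng.uniform(5, 11, 10)},
                            index=[f"g{i}" for i in range(10)])
        mi1, _ = multiplicative_index(vals, _cfg())
        scaled = vals.assign(WP=40.0 + 3.0 * (vals["WP"] - 40.0))
        mi2, _ = multiplicative_index(scaled, _cfg())
        assert (mi1.rank() == mi2.rank()).all()

    def test_missing_lambda_rejected(self):
        vals = pd.DataFrame({"WP": [50.0], "TS": [9.0]}, index=["g1"])
        with pytest.raises(ConfigError):
            multiplicative_index(vals, _cfg(lambdas={"WP": 40.0}))


class TestSelect:
    def test_twenty_percent_of_thirty_is_six(self):
        scores = pd.Series(np.arange(30.0), index=[f"g{i:02d}" for i in range(30)])
        assert n_selected(0.20, 30) == 6
        assert len(select(scores, 0.20)) == 6

    def test_full_intensity_selects_all(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        assert set(select(scores, 1.0)) == {"a", "b"}

    def test_direction_min(self):
        scores = pd.Series([5.0, 1.0, 3.0], index=["a", "b", "c"])
        assert select(scores, 1 / 3, "min") == ["b"]

    def test_tie_break_is_lexicographic_and_deterministic(self):
        scores = pd.Series([1.0, 1.0, 0.0], index=["zz", "aa", "mm"])
        for _ in range(3):
            assert select(scores, 1 / 3, "max") == ["aa"]

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            select(pd.Series(dtype=float), 0.2)


class TestResponse:
    def test_mean_blup_of_selected(self):
        blups = pd.DataFrame({"WP": [2.0, 4.0, -1.0]}, index=["a", "b", "c"])
        out = response_to_selection(blups, ["a", "b"], pd.Series({"WP": 10.0}))
        assert out.loc["WP", "RS"] == pytest.approx(3.0)
        assert out.loc["WP", "RS_pct"] == pytest.approx(30.0)

    def test_selecting_everyone_gives_centered_zero(self):
        rng = np.random.default_rng(2)
        b = rng.normal(size=20)
        blups = pd.DataFrame({"WP": b - b.mean()},
                             index=[f"g{i}" for i in range(20)])
        out = response_to_selection(blups, blups.index, pd.Series({"WP": 5.0}))
        assert out.loc["WP", "RS"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_base_mean_flagged(self):
        blups = pd.DataFrame({"WP": [1.0, 2.0]}, index=["a", "b"])
        out = response_to_selection(blups, ["a"], pd.Series({"WP": 0.0}))
        assert np.isnan(out.loc["WP", "RS_pct"])

    def test_truncation_is_optimal_for_the_selected_trait(self):
        """No equally sized subset beats direct truncation on its own trait."""
        rng = np.random.default_rng(3)
        blups = pd.DataFrame({"WP": rng.normal(size=8)},
                             index=[f"g{i}" for i in range(8)])
        chosen = select(blups["WP"], 0.25)
        best = blups.loc[chosen, "WP"].mean()
        for combo in itertools.combinations(blups.index, 2):
            assert blups.loc[list(combo), "WP"].mean() <= best + 1e-12

    def test_correlated_response_follows_genetic_correlation(self):
        """Selecting on one of two traits with genetic correlation +0.9
        drags the second in the same direction nearly always."""
        rng = np.random.default_rng(4)
        same_sign = 0
        for _ in range(100):
            z = rng.standard_normal((200, 2))
            a = z[:, 0]
            b = 0.9 * z[:, 0] + np.sqrt(1 - 0.81) * z[:, 1]
            blups = pd.DataFrame({"A": a - a.mean(), "B": b - b.mean()},
                                 index=[f"g{i}" for i in range(200)])
            chosen = select(blups["A"], 0.2)
            out = response_to_selection(blups, chosen,
                                        pd.Series({"A": 1.0, "B": 1.0}))
            same_sign += np.sign(out.loc["A", "RS"]) == np.sign(out.loc["B", "RS"])
        assert same_sign >= 95


class TestScenarios:
    @staticmethod
    def _blups_and_means(seed=21):
        d, truth = simulate_met(paper_like_config(seed=seed))
        main = truth.genotype_main.loc[[g for g in d.genotypes
                                        if g not in d.parents]]
        main = main.assign(WP=main["WF"] - main["WS"])
        fs = d.records[d.records["genotype"].isin(d.full_sibs)]
        means = fs[list(main.columns)].mean()
        return main - main.mean(), means

    def test_four_scenarios_standard_layout(self):
        blups, means = self._blups_and_means()
        res = run_scenarios(blups, means)
        assert set(res) == {"against_TS", "against_WS", "for_WP", "msi"}
        for r in res.values():
            assert len(r.selected) == 6
            assert set(r.response.index) == set(blups.columns)
        # selecting against TS must lower TS itself
        assert res["against_TS"].response.loc["TS", "RS"] < 0
        assert res["for_WP"].response.loc["WP", "RS"] > 0

    def test_msi_trades_skin_against_pulp(self):
        """Relative to pure pulp-weight selection, the multiplicative index
        sacrifices some pulp gain to pull skin weight and thickness down,
        while keeping the pulp response positive on average."""
        wp_gains = []
        for seed in (21, 22, 23, 24, 25):
            blups, means = self._blups_and_means(seed)
            res = run_scenarios(blups, means)
            msi = res["msi"].response["RS"]
            wp = res["for_WP"].response["RS"]
            assert msi["WS"] < wp["WS"]
            assert msi["TS"] <= wp["TS"] + 1e-9
            wp_gains.append(msi["WP"])
        assert np.mean(wp_gains) > 0

    def test_all_equal_blups_resolved_by_tie_rule(self):
        blups = pd.DataFrame(0.0, index=[f"g{i:02d}" for i in range(10)],
                             columns=["TS", "WS", "WP"])
        means = pd.Series({"TS": 9.0, "WS": 110.0, "WP": 50.0})
        res = run_scenarios(blups, means)
        assert res["against_TS"].selected == res["against_WS"].selected == \
            ["g00", "g01"]
        # every genotype sits exactly at the limits: none admissible
        assert len(res["msi"].non_admissible) == 10

    def test_missing_scenario_trait_rejected(self):
        blups = pd.DataFrame({"TS": [1.0], "WS": [1.0]}, index=["a"])
        with pytest.raises(ConfigError):
            run_scenarios(blups, pd.Series({"TS": 1.0, "WS": 1.0}))

    def test_independent_trait_selection_is_specific(self):
        """Selecting against a trait uncorrelated with the rest moves that
        trait far more than any other."""
        rng = np.random.default_rng(9)
        n = 60
        blups = pd.DataFrame({
            "TS": rng.normal(size=n), "WS": rng.normal(size=n),
            "WP": rng.normal(size=n)}, index=[f"g{i:02d}" for i in range(n)])
        blups -= blups.mean()
        means = pd.Series({"TS": 9.0, "WS": 110.0, "WP": 50.0})
        res = run_scenarios(blups, means)
        resp = res["against_TS"].response["RS_pct"].abs()
        assert resp["TS"] > resp["WS"] and resp["TS"] > resp["WP"]
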