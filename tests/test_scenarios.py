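"""Scenario engine: coupling, closed-form optimisation, grids."""
import numpy as np
import pandas as pd
import pytest

import saltmod as sm
from saltmod.scenarios import ScenarioError
from saltmod.taxonomy import (BREAD_SUBMAJOR, EGG_SUBMAJOR, MILK_SUBMAJOR,
                              SALT_SUBMAJOR)


def make_baseline(rng=None, ul=2060.0, ear=94.0):
    """Random but well-formed baseline profile."""
    rng = rng or np.random.default_rng(0)
    cats = ["111", "122", "182", "191", "251", "301", "311"]
    na = rng.uniform(50, 900, len(cats))
    iod = rng.uniform(1, 60, len(cats))
    coupled = iod * rng.uniform(0, 1, len(cats))
    contrib = pd.DataFrame({"sodium_mg_day": na, "iodine_ug_day": iod,
                            "coupled_iodine_ug_day": coupled}, index=cats)
    return sm.BaselineProfile(contrib, float(na.sum()), float(iod.sum()),
                              ul, ear)


def scenario_for(cats, r=1.0, name="test"):
    return sm.Scenario(name, (sm.InterventionTarget(
        "category_set", frozenset(cats)),), r)


class TestApplyScenario:
    def test_zero_reduction_is_identity(self):
        base = make_baseline()
        res = sm.apply_scenario(base, scenario_for(["122", "251"], r=0.0))
        assert res.sodium_mg_day == base.sodium_total_mg_day
        assert res.iodine_ug_day == base.iodine_total_ug_day

    def test_result_never_exceeds_baseline(self):
        base = make_baseline()
        for r in (0.1, 0.5, 1.0):
            res = sm.apply_scenario(base, scenario_for(["122"], r=r))
            assert res.sodium_mg_day <= base.sodium_total_mg_day
            assert res.iodine_ug_day <= base.iodine_total_ug_day
            assert res.sodium_mg_day >= 0 and res.iodine_ug_day >= 0

    def test_sodium_affine_in_r(self):
        base = make_baseline()
        f = [sm.apply_scenario(base, scenario_for(["122", "251"], r=r)
                               ).sodium_mg_day for r in (0.0, 0.5, 1.0)]
        assert f[1] == pytest.approx((f[0] + f[2]) / 2, rel=1e-12)

    def test_matches_item_level_brute_force(self):
        """Engine result equals scaling each targeted category's
        contributions directly (independent per-item oracle)."""
        base = make_baseline()
        cats = ["122", "301"]
        r = 0.37
        res = sm.apply_scenario(base, scenario_for(cats, r=r))
        c = base.contributions
        na_expected = base.sodium_total_mg_day - r * sum(
            c.loc[k, "sodium_mg_day"] for k in cats)
        i_expected = base.iodine_total_ug_day - r * sum(
            c.loc[k, "coupled_iodine_ug_day"] for k in cats)
        assert res.sodium_mg_day == pytest.approx(na_expected, rel=1e-12)
        assert res.iodine_ug_day == pytest.approx(i_expected, rel=1e-12)

    def test_uncoupled_iodine_is_untouched(self):
        """Iodine from categories outside the targets is conserved
        exactly: the loss equals the targeted coupled iodine and nothing
        else."""
        base = make_baseline()
        r = 0.8
        res = sm.apply_scenario(base, scenario_for(["251"], r=r))
        loss = base.iodine_total_ug_day - res.iodine_ug_day
        assert loss == pytest.approx(
            r * base.contributions.loc["251", "coupled_iodine_ug_day"],
            rel=1e-12)

    def test_overlapping_targets_rejected(self):
        with pytest.raises(ScenarioError, match="more than one target"):
            sm.Scenario("bad", (
                sm.InterventionTarget("category_set",
                                      frozenset({"122", "251"})),
                sm.InterventionTarget("discretionary_salt",
                                      frozenset({"251"}))))

    def test_unknown_target_category_rejected(self):
        base = make_baseline()
        with pytest.raises(ScenarioError, match="999"):
            sm.apply_scenario(base, scenario_for(["999"]))

    def test_reduction_outside_unit_interval_rejected(self):
        with pytest.raises(ScenarioError):
            scenario_for(["122"], r=1.2)


class TestMinimalReduction:
    def test_already_within_limit_gives_zero(self):
        base = make_baseline(ul=1e9)
        sol = sm.find_minimal_reduction(base, scenario_for(["122"]))
        assert sol == sm.MinimalReduction(0.0, True, 0.0)

    def test_closed_form_arithmetic(self):
        contrib = pd.DataFrame(
            {"sodium_mg_day": [1000.0, 2000.0],
             "iodine_ug_day": [10.0, 10.0],
             "coupled_iodine_ug_day": [5.0, 0.0]}, index=["122", "311"])
        base = sm.BaselineProfile(contrib, 3000.0, 20.0, 2500.0, 94.0)
        sol = sm.find_minimal_reduction(base, scenario_for(["122"]))
        assert sol.reduction == pytest.approx(0.5)

    def test_infeasible_when_nothing_targeted_covers_excess(self):
        contrib = pd.DataFrame(
            {"sodium_mg_day": [100.0, 2900.0],
             "iodine_ug_day": [1.0, 1.0],
             "coupled_iodine_ug_day": [0.0, 0.0]}, index=["122", "311"])
        base = sm.BaselineProfile(contrib, 3000.0, 2.0, 2500.0, 94.0)
        sol = sm.find_minimal_reduction(base, scenario_for(["122"]))
        assert not sol.feasible
        assert sol.residual_mg_day == pytest.approx(400.0)

    @pytest.mark.parametrize("seed", [1])
    def test_closed_form_agrees_with_bisection_on_100_baselines(self,
                                                                seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            base = make_baseline(rng, ul=float(rng.uniform(500, 3500)))
            cats = list(rng.choice(base.contributions.index, size=3,
                                   replace=False))
            sc = scenario_for(cats)
            a = sm.find_minimal_reduction(base, sc)
            b = sm.find_minimal_reduction_bisect(base, sc)
            assert a.feasible == b.feasible
            assert abs(a.reduction - b.reduction) < 1e-9


class TestCanonicalScenarios:
    def test_five_scenarios_with_expected_targets(self):
        sc = sm.canonical_scenarios()
        assert set(sc) == {f"scenario_{i}" for i in range(1, 6)}
        assert sc["scenario_1"].target_categories == {SALT_SUBMAJOR}
        assert sc["scenario_2"].target_categories == {BREAD_SUBMAJOR}
        assert sc["scenario_3"].target_categories == \
            sc["scenario_1"].target_categories \
            | sc["scenario_2"].target_categories
        assert sc["scenario_5"].target_categories == \
            sc["scenario_1"].target_categories \
            | sc["scenario_4"].target_categories

    def test_milk_and_eggs_never_targeted(self):
        for scenario in sm.canonical_scenarios().values():
            assert MILK_SUBMAJOR not in scenario.target_categories
            assert EGG_SUBMAJOR not in scenario.target_categories

    def test_bread_scenario_removes_bread_iodine_share(self, study):
        base = sm.baseline_profile(study["clean"], study["nrv"])
        res = sm.apply_scenario(
            base, sm.canonical_scenarios()["scenario_2"].at(1.0))
        bread_i = base.contributions.loc[BREAD_SUBMAJOR, "iodine_ug_day"]
        assert base.iodine_total_ug_day - res.iodine_ug_day == \
            pytest.approx(bread_i, rel=1e-9)


class TestIncrementalGrid:
    def test_rows_monotone_nonincreasing_in_sodium(self):
        base = make_baseline()
        grid = sm.incremental_grid(base, scenario_for(["122", "251"]),
                                   [0.1, 0.25, 0.5])
        assert len(grid) == 3
        assert grid["sodium_mg_day"].is_monotonic_decreasing

    def test_grid_brackets_the_minimal_reduction(self):
        contrib = pd.DataFrame(
            {"sodium_mg_day": [1000.0, 2000.0],
             "iodine_ug_day": [10.0, 10.0],
             "coupled_iodine_ug_day": [5.0, 0.0]}, index=["122", "311"])
        base = sm.BaselineProfile(contrib, 3000.0, 20.0, 2500.0, 94.0)
        sc = scenario_for(["122"])
        r_star = sm.find_minimal_reduction(base, sc).reduction
        grid = sm.incremental_grid(base, sc, [r_star - 1e-6, r_star])
        assert not grid["meets_ul"].iloc[0]
        assert grid["meets_ul"].iloc[1]

    def test_empty_fraction_list_gives_empty_table(self):
        grid = sm.incremental_grid(make_baseline(),
                                   scenario_for(["122"]), [])
        assert grid.empty
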