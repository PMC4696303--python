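"""Aggregation, densities, source attribution and the outlier screen."""
import numpy as np
import pandas as pd
import pytest

import saltmod as sm
from saltmod.consumption import UndefinedDensityError

from conftest import sales_frame, small_config


class TestAggregate:
    def test_pooled_totals_are_additive(self, tiny_table):
        sales = sales_frame([("S1", "2013-01-07", "A1", 1, 200.0),
                             ("S2", "2013-01-07", "A1", 1, 200.0)])
        linked = sm.link_sales(sales, tiny_table)
        totals = sm.aggregate(linked)
        assert totals.sodium_mg == pytest.approx(1600.0)

    def test_pooled_equals_sum_of_per_store(self, small_linked):
        pooled = sm.aggregate(small_linked)
        per_store = sm.aggregate(small_linked, by="store")
        assert per_store["sodium_mg"].sum() == pytest.approx(
            pooled.sodium_mg, rel=1e-12)
        assert per_store["energy_mj"].sum() == pytest.approx(
            pooled.energy_mj, rel=1e-12)

    def test_empty_group_gives_zero_totals(self, small_linked):
        empty = small_linked.iloc[0:0]
        totals = sm.aggregate(empty)
        assert (totals.energy_mj, totals.sodium_mg, totals.iodine_ug) == \
            (0.0, 0.0, 0.0)

    def test_unknown_grouping_raises(self, small_linked):
        with pytest.raises(ValueError, match="grouping"):
            sm.aggregate(small_linked, by="region")


class TestDensity:
    def test_direct_ratio(self):
        d = sm.density(sm.NutrientTotals(2000.0, 622000.0, 46200.0))
        assert d.sodium_mg_per_mj == pytest.approx(311.0)
        assert d.iodine_ug_per_mj == pytest.approx(23.1)

    def test_zero_energy_raises(self):
        with pytest.raises(UndefinedDensityError):
            sm.density(sm.NutrientTotals(0.0, 100.0, 1.0))

    def test_invariant_to_uniform_weight_scaling(self, tiny_table):
        sales = sales_frame([("S1", "2013-01-07", "A1", 1, 200.0),
                             ("S1", "2013-01-07", "A2", 1, 5.0)])
        d1 = sm.density(sm.aggregate(sm.link_sales(sales, tiny_table)))
        scaled = sales.assign(total_weight_g=sales["total_weight_g"] * 7.5)
        d2 = sm.density(sm.aggregate(sm.link_sales(scaled, tiny_table)))
        assert d2.sodium_mg_per_mj == pytest.approx(d1.sodium_mg_per_mj,
                                                    rel=1e-12)
        assert d2.iodine_ug_per_mj == pytest.approx(d1.iodine_ug_per_mj,
                                                    rel=1e-12)


class TestAttribution:
    def test_single_product_holds_all_shares(self, tiny_table):
        sales = sales_frame([("S1", "2013-01-07", "A1", 1, 200.0)])
        att = sm.attribute_sources(sm.link_sales(sales, tiny_table))
        assert att.loc["182", "share_sodium_pct"] == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_shares_sum_to_100_at_each_level(self, seed):
        cfg = small_config(seed=seed, n_stores=3, n_weeks=10,
                           outliers=())
        sales, _ = sm.generate_sales(cfg)
        linked = sm.link_sales(sales, sm.generate_catalogue(cfg))
        for level in ("major", "sub_major", "minor"):
            att = sm.attribute_sources(linked, level=level)
            assert att["share_sodium_pct"].sum() == pytest.approx(
                100.0, abs=0.01)
            assert att["share_iodine_pct"].sum() == pytest.approx(
                100.0, abs=0.01)

    def test_sub_major_share_equals_sum_of_minor_shares(self,
                                                        small_linked):
        sub = sm.attribute_sources(small_linked, level="sub_major")
        minor = sm.attribute_sources(small_linked, level="minor")
        minor_to_sub = minor.copy()
        minor_to_sub["sub"] = [m[:3] for m in minor.index]
        rolled = minor_to_sub.groupby("sub")["share_sodium_pct"].sum()
        pd.testing.assert_series_equal(
            rolled.sort_index(), sub["share_sodium_pct"].sort_index(),
            check_names=False, rtol=1e-9)

    def test_per100g_is_weight_weighted_mean(self, tiny_table):
        # 100 g at 400 mg/100g plus 300 g at 38000 mg/100g, same category
        sales = sales_frame([("S1", "2013-01-07", "A2", 1, 100.0),
                             ("S1", "2013-01-07", "A3", 1, 300.0)])
        att = sm.attribute_sources(sm.link_sales(sales, tiny_table))
        assert att.loc["251", "iodine_ug_per_100g"] == pytest.approx(
            4400.0 * 100 / 400)

    def test_unknown_level_raises(self, small_linked):
        with pytest.raises(ValueError, match="level"):
            sm.attribute_sources(small_linked, level="megagroup")


def weekly_frame(energies, store="S1"):
    return pd.DataFrame({
        "store_id": store,
        "week_start": [f"2013-W{i:02d}" for i in range(len(energies))],
        "energy_mj": energies,
    })


class TestOutlierScreen:
    def test_constant_series_has_no_flags(self):
        flags = sm.screen_outlier_weeks(weekly_frame([100.0] * 20))
        assert flags.empty

    def test_five_fold_week_is_flagged(self):
        series = [100.0, 101.0, 99.0, 100.5, 99.5, 100.0, 101.0, 99.0,
                  500.0, 100.0, 100.0, 99.5]
        flags = sm.screen_outlier_weeks(weekly_frame(series))
        assert len(flags) == 1
        assert flags["energy_mj"].iloc[0] == 500.0

    def test_zero_mad_falls_back_to_exact_deviants(self):
        series = [100.0] * 15 + [100.5]
        flags = sm.screen_outlier_weeks(weekly_frame(series))
        assert len(flags) == 1
        assert flags["energy_mj"].iloc[0] == 100.5

    def test_too_few_weeks_is_an_error(self):
        with pytest.raises(ValueError, match="minimum"):
            sm.screen_outlier_weeks(weekly_frame([100.0] * 5))

    def test_injected_event_weeks_flagged_exactly(self, small_linked,
                                                  small_cfg):
        flags = sm.screen_outlier_weeks(sm.weekly_energy(small_linked))
        expected = {(o.store_id,
                     small_cfg.week_starts[o.week_index].isoformat())
                    for o in small_cfg.outliers}
        assert set(zip(flags["store_id"], flags["week_start"])) == expected

    def test_exclusion_has_bounded_influence(self, small_linked):
        """Dropping flagged weeks moves the pooled density by less than
        those weeks' share of pooled energy."""
        flags = sm.screen_outlier_weeks(sm.weekly_energy(small_linked))
        pooled = sm.aggregate(small_linked)
        clean = sm.aggregate(sm.exclude_weeks(small_linked, flags))
        share = 1.0 - clean.energy_mj / pooled.energy_mj
        d_all = sm.density(pooled).sodium_mg_per_mj
        d_clean = sm.density(clean).sodium_mg_per_mj
        assert abs(d_clean - d_all) / d_all < share


class TestSaltProfile:
    def test_only_iodised_gives_100(self, tiny_table):
        sales = sales_frame([("S1", "2013-01-07", "A2", 1, 500.0)])
        assert sm.salt_profile(sm.link_sales(sales, tiny_table)) == 100.0

    def test_equal_weights_give_50(self, tiny_table):
        sales = sales_frame([("S1", "2013-01-07", "A2", 1, 500.0),
                             ("S1", "2013-01-07", "A3", 1, 500.0)])
        assert sm.salt_profile(sm.link_sales(sales, tiny_table)) == \
            pytest.approx(50.0)

    def test_no_salt_purchases_raise(self, tiny_table):
        sales = sales_frame([("S1", "2013-01-07", "A1", 1, 100.0)])
        with pytest.raises(ValueError, match="salt"):
            sm.salt_profile(sm.link_sales(sales, tiny_table))
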