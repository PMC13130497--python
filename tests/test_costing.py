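"""Bottom-up costing arithmetic, streams and discounting."""
import numpy as np
import pandas as pd
import pytest

from retailcea import costing
from retailcea.synthetic_data import default_cost_config, generate_wages
from retailcea.types import ConfigurationError, CostItem


@pytest.fixture(scope="module")
def wages():
    return generate_wages()


@pytest.fixture()
def cfg():
    return default_cost_config()


def _flat_wages(base: float) -> pd.DataFrame:
    w = generate_wages()
    w["base_hourly_wage"] = base
    w["on_cost_rate"] = 0.0
    w["leave_loading_rate"] = 0.0
    return w


class TestLoadedWage:
    def test_worked_example(self):
        w = pd.DataFrame({"occupation": ["general_manager"], "base_hourly_wage": [50.0],
                          "on_cost_rate": [0.13], "leave_loading_rate": [0.175]})
        assert costing.loaded_wage("general_manager", w) == pytest.approx(
            50 * 1.13 * (1 + 0.175 * 4 / 52), abs=1e-9)
        assert costing.loaded_wage("general_manager", w) == pytest.approx(57.26, abs=5e-3)

    def test_zero_rates_leave_base_unchanged(self):
        assert costing.loaded_wage("sales_assistant", _flat_wages(31.0)) == pytest.approx(31.0)

    def test_loaded_never_below_base(self, wages):
        for occ in wages["occupation"]:
            base = float(wages.loc[wages["occupation"] == occ, "base_hourly_wage"].iloc[0])
            assert costing.loaded_wage(occ, wages) >= base

    def test_unknown_occupation(self, wages):
        with pytest.raises(KeyError):
            costing.loaded_wage("barista", wages)


class TestTransitionCosts:
    def test_stated_labour_hours(self, wages, cfg):
        items = {i.label: i for i in costing.transition_costs(wages, cfg)}
        assert items["head_office_regulation"].quantity == pytest.approx(4 * 12)
        fam = items["store_familiarisation_manager"].quantity \
            + items["store_familiarisation_clerks"].quantity
        assert fam == pytest.approx(4105 * (3 + 2 * 3))  # 36,945 h
        assert costing.layout_hours_per_store(cfg) == pytest.approx(
            7.6 + 7.6 + 4 * 1.5 * 7.6)  # 60.8 h

    def test_all_transition_items_fall_in_year_zero(self, wages, cfg):
        assert all(i.year == 0 and i.sector == "industry"
                   for i in costing.transition_costs(wages, cfg))

    def test_layout_multiplier_scales_layout_only(self, wages, cfg):
        base = {i.label: i.annual_amount for i in costing.transition_costs(wages, cfg)}
        tripled = {i.label: i.annual_amount
                   for i in costing.transition_costs(wages, cfg, layout_days_multiplier=3.0)}
        for label in base:
            if label.startswith("layout"):
                assert tripled[label] == pytest.approx(3 * base[label])
            else:
                assert tripled[label] == pytest.approx(base[label])


class TestOngoingAssessment:
    def test_worked_example(self, cfg):
        cfg["chains"] = 1
        cfg["new_products_per_chain_per_year"] = 1000
        items = costing.ongoing_product_assessment(_flat_wages(60.0), cfg, horizon_years=5)
        assert items[0].annual_amount == pytest.approx(1000 * 0.79 * 0.125 * 60)  # A$5,925

    def test_zero_new_products(self, cfg, wages):
        cfg["new_products_per_chain_per_year"] = 0
        items = costing.ongoing_product_assessment(wages, cfg, horizon_years=5)
        assert items[0].annual_amount == 0.0

    def test_stream_length_equals_horizon(self, cfg, wages):
        items = costing.ongoing_product_assessment(wages, cfg, horizon_years=7)
        summary = costing.summarise_costs(items, 0.0, 7)
        assert int((summary.streams["industry"] > 0).sum()) == 7


class TestMonitoringAndPenalties:
    def test_year_one_penalty_exact(self, cfg):
        _, pen = costing.monitoring_and_penalties(cfg)
        assert pen[0].annual_amount == pytest.approx(4105 * 0.07 * 0.30 * 5500, abs=1e-6)
        assert pen[0].annual_amount == pytest.approx(474127.50, abs=1e-6)

    def test_penalty_ratio_and_cutoff(self, cfg):
        gov, pen = costing.monitoring_and_penalties(cfg)
        amounts = [p.annual_amount for p in pen]
        assert amounts[0] / amounts[2] == pytest.approx(3.0, abs=1e-12)
        assert amounts[1] / amounts[2] == pytest.approx(2.0, abs=1e-12)
        summary = costing.summarise_costs(gov + pen, 0.0, 10)
        for year in range(4, 11):
            assert summary.streams.loc[year].sum() == 0.0

    def test_zero_noncompliance_keeps_monitoring(self, cfg):
        cfg["monitoring"]["noncompliance"] = [0.0, 0.0, 0.0]
        gov, pen = costing.monitoring_and_penalties(cfg)
        assert all(p.annual_amount == 0 for p in pen)
        assert all(g.annual_amount > 0 for g in gov)

    def test_length_mismatch_rejected(self, cfg):
        cfg["monitoring"]["noncompliance"] = [0.3, 0.2]
        with pytest.raises(ConfigurationError):
            costing.monitoring_and_penalties(cfg)


class TestFixedItems:
    def test_default_magnitudes(self, cfg):
        items = {i.label: i for i in costing.fixed_government_items(cfg, 10)}
        assert items["legislation"].annual_amount == pytest.approx(1.56e6)
        assert items["media_campaign"].annual_amount == pytest.approx(0.96e6)
        assert items["legislation"].year == 0 and items["legislation"].duration == 1
        assert items["complaints_handling"].year == 1

    def test_missing_key_rejected(self, cfg):
        del cfg["fixed"]["media"]
        with pytest.raises(ConfigurationError):
            costing.fixed_government_items(cfg, 10)


class TestCPIAdjustment:
    CPI = {2020: 100.0, 2024: 110.0}

    def test_identity_proportionality_roundtrip(self):
        assert costing.adjust_to_base_year(250.0, 2024, self.CPI) == pytest.approx(250.0)
        up = costing.adjust_to_base_year(100.0, 2020, self.CPI)
        assert up == pytest.approx(110.0)
        back = up * self.CPI[2020] / self.CPI[2024]
        assert back == pytest.approx(100.0)

    def test_missing_year(self):
        with pytest.raises(KeyError):
            costing.adjust_to_base_year(1.0, 1999, self.CPI)


class TestSummaries:
    def test_zero_rate_equals_undiscounted(self, wages, cfg):
        items = costing.assemble_costs(wages, cfg, 20)
        s = costing.summarise_costs(items, 0.0, 20)
        assert s.grand_total_discounted == pytest.approx(s.grand_total_undiscounted)

    def test_sector_totals_sum_to_grand_total(self, wages, cfg):
        items = costing.assemble_costs(wages, cfg, 20)
        s = costing.summarise_costs(items, 0.03, 20)
        assert s.grand_total_discounted == pytest.approx(
            s.discounted["government"] + s.discounted["industry"])

    def test_grand_total_invariant_under_regrouping(self, wages, cfg):
        items = costing.assemble_costs(wages, cfg, 20)
        shuffled = list(reversed(items))
        a = costing.summarise_costs(items, 0.03, 20)
        b = costing.summarise_costs(shuffled, 0.03, 20)
        assert a.grand_total_discounted == pytest.approx(b.grand_total_discounted, rel=1e-12)

    @pytest.mark.parametrize("r_lo, r_hi", [(0.0, 0.03), (0.03, 0.07), (0.07, 0.10)])
    def test_discounting_monotone_in_rate(self, wages, cfg, r_lo, r_hi):
        items = costing.assemble_costs(wages, cfg, 30)
        lo = costing.summarise_costs(items, r_lo, 30).grand_total_discounted
        hi = costing.summarise_costs(items, r_hi, 30).grand_total_discounted
        assert hi <= lo

    def test_default_total_in_tens_of_millions(self, wages, cfg):
        items = costing.assemble_costs(wages, cfg, 98)
        total = costing.summarise_costs(items, 0.03, 98).grand_total_discounted
        assert 1e7 < total < 1e8

    def test_every_item_in_exactly_one_sector(self, wages, cfg):
        items = costing.assemble_costs(wages, cfg, 20)
        assert all(i.sector in ("government", "industry") for i in items)
        labels = [i.label for i in items]
        assert len(labels) == len(set(labels))
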