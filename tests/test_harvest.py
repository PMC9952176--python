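"""Harvest-chain arithmetic, full-precision discipline, temporal summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pamharvest.datasets import ionian_counts, ionian_strata
from pamharvest.harvest import (
    ChangeSummary,
    HarvestEstimate,
    StratumConfig,
    adjust_counts,
    aggregate,
    change_table,
    diel_summary,
    estimate_harvest,
    harvest_table,
    percent_change,
    percent_of_breeding_stock,
    round_half_away,
    seasonal_summary,
    weekday_summary,
)
from pamharvest.synthetic import SeasonSimSpec, seasonal_intensity, simulate_season


class TestRounding:
    @pytest.mark.parametrize("x,nd,expected", [
        (2.5, 0, 3.0),
        (-2.5, 0, -3.0),
        (0.5, 0, 1.0),
        (-45.15, 1, -45.2),
        (6780.69, 0, 6781.0),
        (1.6025641, 3, 1.603),
    ])
    def test_half_away_from_zero(self, x, nd, expected):
        assert round_half_away(x, nd) == expected


class TestAdjustCounts:
    @pytest.mark.parametrize("detected,expected", [
        (14012, 22461),
        (2351, 3769),
        (2115, 3390),
        (20905, 33511),
    ])
    def test_published_adjustments(self, detected, expected):
        assert round_half_away(adjust_counts(detected, 0.624)) == expected

    def test_zero_and_identity(self):
        assert adjust_counts(0, 0.624) == 0.0
        assert adjust_counts(123, 1.0) == 123.0

    def test_invalid_recall_rejected(self):
        for r in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                adjust_counts(10, r)

    @given(st.integers(min_value=0, max_value=10**6),
           st.floats(min_value=0.05, max_value=1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_exact_factor_round_trips(self, detected, recall):
        adjusted = adjust_counts(detected, recall, factor_precision=None)
        assert adjusted * recall == pytest.approx(detected, abs=1e-9 * max(detected, 1))


class TestHarvestChain:
    def test_south_coast_stratum(self):
        cfg = StratumConfig(posta_fraction=0.20)
        est = estimate_harvest(adjust_counts(14012, 0.624), cfg, "south_coast")
        d = est.display()
        assert d["adjusted_gunshots"] == 22461
        assert d["killed_monitored"] == 4492
        assert d["killed_or_injured_monitored"] == 7487
        assert d["killed_extrapolated"] == 22461
        assert d["killed_or_injured_extrapolated"] == 37435

    def test_inland_stratum_full_precision_discriminator(self):
        # rounding the monitored kills before extrapolating gives 6780,
        # one bird short: the chain must stay unrounded until display
        cfg = StratumConfig(posta_fraction=0.10)
        est = estimate_harvest(adjust_counts(2115, 0.624), cfg, "inland")
        assert est.display()["killed_extrapolated"] == 6781
        rounded_first = round_half_away(
            round_half_away(est.killed_monitored) / cfg.posta_fraction)
        assert rounded_first == 6780  # the broken order, guarded against

    def test_identity_configuration(self):
        cfg = StratumConfig(posta_fraction=1.0, shots_per_kill=1.0,
                            shots_per_killed_or_injured=1.0, recall=1.0)
        est = estimate_harvest(adjust_counts(500, 1.0), cfg)
        assert est.killed_extrapolated == 500.0

    def test_extrapolation_is_monitored_over_fraction(self):
        cfg = StratumConfig(posta_fraction=0.25)
        est = estimate_harvest(1000.0, cfg)
        assert est.killed_extrapolated == pytest.approx(
            est.killed_monitored / 0.25, abs=1e-9)

    def test_zero_posta_fraction_rejected(self):
        with pytest.raises(ValueError):
            StratumConfig(posta_fraction=0.0)

    @given(st.integers(min_value=1, max_value=10**5),
           st.floats(min_value=0.05, max_value=1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_homogeneity_in_counts_and_fraction(self, detected, fraction):
        cfg = StratumConfig(posta_fraction=fraction)
        one = estimate_harvest(adjust_counts(detected, 0.624, None), cfg)
        three = estimate_harvest(adjust_counts(3 * detected, 0.624, None), cfg)
        assert three.killed_extrapolated == pytest.approx(
            3 * one.killed_extrapolated, rel=1e-9)
        half = StratumConfig(posta_fraction=fraction / 2)
        doubled = estimate_harvest(adjust_counts(detected, 0.624, None), half)
        assert doubled.killed_extrapolated == pytest.approx(
            2 * one.killed_extrapolated, rel=1e-9)


class TestAggregate:
    def _full_table(self):
        counts = {"zakynthos_south_coast": 14012, "zakynthos_inland": 2115,
                  "antipaxi": 2351, "paxi": 1476, "othoni": 240, "mathraki": 711}
        configs, recall, precision = ionian_strata()
        return harvest_table(counts, configs, recall, precision)

    def test_season_totals(self):
        _, total = self._full_table()
        d = total.display()
        assert d["adjusted_gunshots"] == 33511
        assert d["killed_extrapolated"] == 34257
        assert d["killed_or_injured_extrapolated"] == 57095

    def test_totals_are_sums_of_full_precision_components(self):
        estimates, total = self._full_table()
        assert total.killed_extrapolated == pytest.approx(
            sum(e.killed_extrapolated for e in estimates), abs=1e-9)

    def test_empty_aggregate_is_zero(self):
        total = aggregate([])
        assert total.killed_extrapolated == 0.0
        assert total.adjusted_gunshots == 0.0


class TestPercentChange:
    @pytest.mark.parametrize("a,b,expected", [
        (6651, 3647, -45.2),
        (711, 2, -99.7),
        (19709, 10239, -48.0),
        (100, 100, 0.0),
    ])
    def test_published_changes(self, a, b, expected):
        assert percent_change(a, b) == expected

    def test_zero_baseline_undefined(self):
        with pytest.raises(ValueError):
            percent_change(0, 10)


class TestChangeTable:
    def test_ionian_totals_and_exclusions(self):
        counts = ionian_counts()
        per_site, summary = change_table(counts)
        assert summary.count_a == 19709 and summary.count_b == 10239
        assert summary.percent_change == -48.0
        assert set(summary.excluded_sites) == {"Kalipado", "Lefkimi"}
        keri = per_site[per_site["site"] == "Keri"].iloc[0]
        assert keri["percent_change"] == -45.2

    def test_grand_total_all_years(self):
        assert ionian_counts()["detected_gunshots"].sum() == 54014


def _events_at(times):
    return pd.DataFrame({"timestamp": pd.to_datetime(times)})


class TestSeasonalSummary:
    def test_all_events_inside_window(self):
        ev = _events_at(["2021-04-15 09:00", "2021-04-20 10:00"])
        frac, daily = seasonal_summary(ev, "2021-04-10", "2021-05-05")
        assert frac == 1.0
        assert daily.sum() == 2

    def test_daily_series_conserves_events(self):
        spec = SeasonSimSpec(sites={"a": 20.0}, seed=9)
        truth, _ = simulate_season(spec)
        frac, daily = seasonal_summary(truth, "2021-04-10", "2021-05-05")
        assert daily.sum() == len(truth)

    def test_recovered_fraction_matches_generating_intensity(self):
        # the oracle is the integral of the generating intensity in-window
        spec = SeasonSimSpec(sites={"a": 40.0}, seed=10)
        factor = seasonal_intensity(spec)
        in_win = factor[(factor.index >= "2021-04-10") & (factor.index <= "2021-05-05")]
        expected = in_win.sum() / factor.sum()
        fracs = []
        for seed in range(30):
            truth, _ = simulate_season(SeasonSimSpec(sites={"a": 40.0}, seed=seed))
            frac, _ = seasonal_summary(truth, "2021-04-10", "2021-05-05")
            fracs.append(frac)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - expected) < 3 * max(se, 1e-4)
        assert expected == pytest.approx(0.86, abs=0.005)

    def test_empty_event_set_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            seasonal_summary(_events_at([]), "2021-04-10", "2021-05-05")


class TestDielAndWeekday:
    def test_single_hour_concentration(self):
        ev = _events_at(["2021-04-15 09:10", "2021-04-15 09:50"])
        hist, day_frac = diel_summary(ev)
        assert hist.loc[9] == 2 and hist.sum() == 2
        assert day_frac == 1.0

    def test_uniform_schedule_gives_ten_fifteenths(self):
        rng = np.random.default_rng(11)
        hours = 7 + 15 * rng.random(20000)
        times = [f"2021-04-15 {int(h):02d}:{int((h % 1) * 60):02d}" for h in hours]
        hist, day_frac = diel_summary(_events_at(times))
        assert hist.sum() == 20000
        assert day_frac == pytest.approx(10 / 15, abs=0.01)

    def test_event_outside_schedule_warns(self):
        ev = _events_at(["2021-04-15 03:00"])
        with pytest.warns(UserWarning, match="outside"):
            diel_summary(ev)

    def test_weekday_counts(self):
        ev = _events_at(["2021-04-12 09:00", "2021-04-13 09:00", "2021-04-19 09:00"])
        counts = weekday_summary(ev)  # two Mondays, one Tuesday
        assert counts.loc[1] == 2 and counts.loc[2] == 1 and counts.sum() == 3


class TestBreedingStock:
    def test_reported_percentage(self):
        assert percent_of_breeding_stock(57095, 763250) == 3.7

    def test_per_pair_reading_roughly_doubles(self):
        assert percent_of_breeding_stock(57095, 763250, per_pair=True) == 7.5

    def test_trivial_cases(self):
        assert percent_of_breeding_stock(0, 1000) == 0.0
        assert percent_of_breeding_stock(2, 1) == 100.0

    def test_nonpositive_pairs_rejected(self):
        with pytest.raises(ValueError):
            percent_of_breeding_stock(100, 0)
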