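"""Extension metric, union/gap arithmetic, turnover and sign tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from topophen import extension, phenology, synthetic
from topophen.extension import (community_extension,
                                community_extension_table,
                                complementarity_sign_test, extension_metrics,
                                species_combined_duration, turnover,
                                turnover_extension_regression, turnover_table)

from conftest import noise_free_config


def merge_intervals_measure(intervals):
    """Oracle: total measure of a union of closed intervals."""
    ivs = sorted(intervals)
    total, cur_start, cur_end = 0.0, *ivs[0]
    for s, e in ivs[1:]:
        if s > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    return total + (cur_end - cur_start)


def survey_rows(site, aspect, counts_by_doy, species="sp01", plot="p1",
                year="2017"):
    return [dict(site_id=site, aspect=aspect, plot_id=plot,
                 species_id=species, year=year, doy=d, count=c)
            for d, c in counts_by_doy.items()]


class TestExtensionMetrics:
    @pytest.mark.parametrize("south,north,combined,days", [
        (16.2, 20.2, 25.6, 5.4),     # printed 2017 row of the genotype trial
        (23.7, 14.8, 27.6, 3.9),     # printed 2018 row
    ])
    def test_printed_duration_rows(self, south, north, combined, days):
        res = extension_metrics(south, north, combined)
        assert res.extension_days == pytest.approx(days)
        assert res.longer == max(south, north)

    def test_identity_case_is_zero(self):
        res = extension_metrics(20.0, 20.0, 20.0)
        assert res.extension_days == 0.0
        assert res.extension_pct == 0.0

    def test_direct_formula_percent_for_2018_row(self):
        # (27.6 - 23.7) / 23.7 * 100; the published table prints 16.8%
        # because it averages per-site percents rather than using row means
        res = extension_metrics(23.7, 14.8, 27.6)
        assert res.extension_pct == pytest.approx(16.455, abs=0.01)

    def test_zero_longer_reports_missing_percent(self):
        res = extension_metrics(0.0, 0.0, 0.0)
        assert math.isnan(res.extension_pct)

    def test_combined_shorter_than_longer_is_flagged_not_clamped(self):
        res = extension_metrics(10.0, 20.0, 18.0)
        assert res.extension_days == pytest.approx(-2.0)
        assert res.flagged == "combined_shorter_than_longer"


class TestSpeciesCombinedDuration:
    @pytest.mark.parametrize("iv_n,iv_s,duration,gap", [
        ((100, 110), (105, 118), 18, 0),
        ((100, 105), (110, 115), 10, 5),
        ((100, 112), (100, 112), 12, 0),
    ])
    def test_worked_examples(self, iv_n, iv_s, duration, gap):
        assert species_combined_duration(iv_n, iv_s) == (duration, gap)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            species_combined_duration((110, 100), (100, 120))

    @given(st.tuples(st.integers(60, 170), st.integers(0, 40)),
           st.tuples(st.integers(60, 170), st.integers(0, 40)))
    def test_union_matches_interval_merge_oracle(self, a, b):
        iv_n = (a[0], a[0] + a[1])
        iv_s = (b[0], b[0] + b[1])
        dur, gap = species_combined_duration(iv_n, iv_s)
        assert dur == pytest.approx(merge_intervals_measure([iv_n, iv_s]))
        len_n, len_s = iv_n[1] - iv_n[0], iv_s[1] - iv_s[0]
        assert max(len_n, len_s) - 1e-9 <= dur <= len_n + len_s + 1e-9
        assert gap >= 0
        # extension over the longer interval equals the non-overlap measure
        assert dur - max(len_n, len_s) >= -1e-9


class TestCommunityExtension:
    def test_identical_aspect_curves_give_zero_extension(self):
        counts = {100: 5.0, 107: 10.0, 114: 5.0}
        rows = survey_rows("s1", "N", counts) + survey_rows("s1", "S", counts)
        res = community_extension(pd.DataFrame(rows), "s1", "2017")
        assert res.duration_south == res.duration_north == res.duration_combined
        assert res.extension_days == 0.0

    def test_single_aspect_site_is_flagged_with_zero_extension(self):
        rows = survey_rows("s1", "N", {100: 5.0, 107: 5.0})
        rows += survey_rows("s1", "S", {100: 0.0})
        res = community_extension(pd.DataFrame(rows), "s1", "2017")
        assert res.flagged.startswith("single_aspect")
        assert res.extension_days == 0.0
        assert res.duration_combined == res.duration_north

    def test_noise_free_shift_copy_union_combined_adds_the_shift(self):
        # sensitivity 2 d/°C x offset 3 °C -> south earlier by 6 days
        cfg = noise_free_config(aspect_temp_offset_C=3.0,
                                sensitivity_days_per_C=2.0)
        temp = synthetic.simulate_temperature(cfg)
        surv = synthetic.simulate_surveys(cfg, temp)
        res = community_extension(surv, "site1", "2017",
                                  combined_mode="union")
        shift = cfg.sensitivity_days_per_C * cfg.aspect_temp_offset_C
        assert res.duration_combined == pytest.approx(
            res.duration_north + shift, abs=1.0)
        assert res.extension_days == pytest.approx(shift, abs=1.0)


class TestComplementaritySignTest:
    def _dates(self, n_consistent, n_total):
        rows = []
        for i in range(n_total):
            consistent = i < n_consistent
            rows.append(dict(site_id=f"s{i}", year="2017", aspect="S",
                             start_doy=90.0, end_doy=130.0))
            rows.append(dict(site_id=f"s{i}", year="2017", aspect="N",
                             start_doy=100.0,
                             end_doy=140.0 if consistent else 125.0))
        return pd.DataFrame(rows)

    def test_unanimous_sixteen_pairs(self):
        res = complementarity_sign_test(self._dates(16, 16))
        assert (res.n_consistent, res.n_total) == (16, 16)
        assert res.p_value == pytest.approx(2 * 0.5 ** 16)

    def test_even_split_is_null(self):
        res = complementarity_sign_test(self._dates(8, 16))
        assert res.p_value == pytest.approx(1.0)

    def test_all_ties_reported_without_a_test(self):
        df = self._dates(2, 2)
        df["start_doy"] = 100.0
        res = complementarity_sign_test(df)
        assert res.n_total == 0 and res.n_ties == 2
        assert math.isnan(res.p_value)

    def test_noise_free_shift_makes_every_site_year_consistent(self):
        cfg = noise_free_config()
        temp = synthetic.simulate_temperature(cfg)
        surv = synthetic.simulate_surveys(cfg, temp)
        plots = phenology.plot_level_summaries(surv)
        dates = (plots.groupby(["site_id", "aspect", "year"])
                 [["start_doy", "end_doy"]].mean().reset_index())
        res = complementarity_sign_test(dates)
        assert res.n_consistent == res.n_total > 0


class TestTurnover:
    @pytest.mark.parametrize("north,south,expected", [
        ({"A", "B", "C"}, {"B", "C", "D", "E"}, (1, 2, 3)),
        ({"A", "B"}, {"A", "B"}, (0, 0, 0)),
        ({"A", "B"}, {"C", "D", "E"}, (2, 3, 5)),
    ])
    def test_worked_examples(self, north, south, expected):
        t = turnover("s1", "2017", {"N": north, "S": south})
        assert (t.n_unique_north, t.n_unique_south, t.turnover) == expected
        assert t.richness_north == len(north)
        assert t.richness_south == len(south)

    def test_presence_requires_positive_count(self):
        rows = survey_rows("s1", "N", {100: 5.0}, species="spA")
        rows += survey_rows("s1", "N", {100: 0.0}, species="spB")
        rows += survey_rows("s1", "S", {100: 2.0}, species="spA")
        table = turnover_table(pd.DataFrame(rows))
        assert table.loc[0, "turnover"] == 0   # spB never flowered


class TestExtensionWithoutTurnover:
    def test_zero_turnover_reproduces_full_community_result(self):
        cfg = noise_free_config()
        temp = synthetic.simulate_temperature(cfg)
        surv = synthetic.simulate_surveys(cfg, temp)
        full = community_extension_table(surv)
        shared = community_extension_table(surv, shared_only=True)
        cols = ["duration_south", "duration_north", "duration_combined",
                "extension_days"]
        pd.testing.assert_frame_equal(full[cols], shared[cols])

    def test_unique_tail_species_inflate_full_relative_to_shared(self):
        shared_counts = {100: 5.0, 107: 10.0, 114: 5.0}
        rows = (survey_rows("s1", "N", shared_counts, species="spShared")
                + survey_rows("s1", "S", shared_counts, species="spShared")
                + survey_rows("s1", "S", {79: 8.0, 86: 8.0},
                              species="spEarly")
                + survey_rows("s1", "N", {128: 8.0, 135: 8.0},
                              species="spLate"))
        surv = pd.DataFrame(rows)
        full = community_extension(surv, "s1", "2017")
        shared = community_extension(
            surv[surv["species_id"] == "spShared"], "s1", "2017",
            level="community_shared_only")
        assert shared.extension_days <= full.extension_days

    def test_no_shared_species_is_flagged_missing(self):
        rows = (survey_rows("s1", "N", {100: 5.0}, species="spA")
                + survey_rows("s1", "S", {107: 5.0}, species="spB"))
        table = community_extension_table(pd.DataFrame(rows),
                                          shared_only=True)
        assert table.loc[0, "flagged"] == "no_shared_species"
        assert np.isnan(table.loc[0, "extension_days"])


class TestTurnoverExtensionRegression:
    def test_collinear_points_have_unit_r_squared(self):
        df = pd.DataFrame({"turnover": [1, 2, 3, 4],
                           "extension_days": [2.0, 4.0, 6.0, 8.0]})
        slope, intercept, r2, p = turnover_extension_regression(df)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_turnover_is_degenerate(self):
        df = pd.DataFrame({"turnover": [3, 3, 3, 3],
                           "extension_days": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            turnover_extension_regression(df)

    def test_recovers_simulated_linear_relation(self):
        rng = np.random.default_rng(23)
        n, b, sigma = 60, 0.8, 1.0
        x = rng.integers(0, 10, n)
        y = 1.5 + b * x + rng.normal(0, sigma, n)
        df = pd.DataFrame({"turnover": x, "extension_days": y})
        slope, _, _, p = turnover_extension_regression(df)
        se = sigma / (np.sqrt(n) * x.std())
        assert slope == pytest.approx(b, abs=4 * se)
        assert p < 0.001
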