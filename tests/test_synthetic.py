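"""Synthetic landscape generator: contracts, forced limits, conservation."""

import numpy as np
import pandas as pd
import pytest

from topophen import phenology, synthetic
from topophen.config import SyntheticConfig

from conftest import noise_free_config


def paired_diff(temperature: pd.DataFrame) -> pd.Series:
    wide = temperature.pivot_table(
        index=["site_id", "year", "doy", "hour"], columns="aspect",
        values="soil_temp_C")
    return wide["S"] - wide["N"]


class TestTemperature:
    def test_same_seed_is_byte_identical(self, small_config):
        a = synthetic.simulate_temperature(small_config)
        b = synthetic.simulate_temperature(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_pairs_differ_by_exact_offset(self):
        cfg = noise_free_config()
        diffs = paired_diff(synthetic.simulate_temperature(cfg))
        assert np.allclose(diffs, cfg.aspect_temp_offset_C)

    def test_mean_offset_recovered_within_monte_carlo_error(self):
        cfg = SyntheticConfig(seed=3, n_sites=4)
        diffs = paired_diff(synthetic.simulate_temperature(cfg))
        # paired hourly readings: sd of each difference is sqrt(2)*noise sd
        se = np.sqrt(2) * cfg.temp_noise_sd_C / np.sqrt(len(diffs))
        assert abs(diffs.mean() - 3.06) < 3 * se

    def test_timestamps_strictly_increasing_per_sensor(self, small_landscape):
        temp = small_landscape["temperature"]
        for _, grp in temp.groupby(["site_id", "aspect", "year"]):
            t = grp["doy"] * 24 + grp["hour"]
            assert (t.diff().dropna() > 0).all()

    def test_rejects_empty_season_window(self):
        with pytest.raises(ValueError):
            SyntheticConfig(season_window=(120, 100))


class TestSurveys:
    def test_noise_free_south_flowers_earlier_by_sensitivity_times_offset(self):
        cfg = noise_free_config()
        temp = synthetic.simulate_temperature(cfg)
        surv = synthetic.simulate_surveys(cfg, temp)
        mids = phenology.species_aspect_summaries(surv)
        wide = mids.pivot_table(index=["site_id", "species_id", "year"],
                                columns="aspect", values="mid_doy")
        expected = -cfg.sensitivity_days_per_C * cfg.aspect_temp_offset_C
        gaps = wide["S"] - wide["N"]
        assert abs(gaps.mean() - expected) < 1.0  # daily survey resolution

    def test_aspects_are_time_shifted_copies_without_noise_or_turnover(self):
        # integer shift: sensitivity 2 d/°C × offset 3 °C = 6 days
        cfg = noise_free_config(aspect_temp_offset_C=3.0,
                                sensitivity_days_per_C=2.0)
        temp = synthetic.simulate_temperature(cfg)
        surv = synthetic.simulate_surveys(cfg, temp)
        lo, hi = cfg.season_window
        wide = surv.pivot_table(
            index=["site_id", "plot_id", "species_id", "year"],
            columns=["aspect", "doy"], values="count")
        south, north = wide["S"], wide["N"]
        # compare away from window edges where renormalization differs
        interior = [d for d in range(lo + 20, hi - 20)]
        shifted = north[[d + 6 for d in interior]].to_numpy()
        np.testing.assert_allclose(south[interior].to_numpy(), shifted,
                                   atol=0.05)

    def test_zero_turnover_means_every_species_on_both_aspects(self):
        cfg = SyntheticConfig(seed=7, turnover_fraction=0.0)
        temp = synthetic.simulate_temperature(cfg)
        surv = synthetic.simulate_surveys(cfg, temp)
        per_site = surv.groupby(["site_id", "species_id"])["aspect"].nunique()
        assert (per_site == 2).all()

    def test_default_plot_richness_within_observed_study_range(self):
        cfg = SyntheticConfig(seed=9)
        temp = synthetic.simulate_temperature(cfg)
        surv = synthetic.simulate_surveys(cfg, temp)
        richness = (surv.groupby(["site_id", "aspect", "plot_id", "year"])
                    ["species_id"].nunique())
        assert richness.between(1, 22).all()

    def test_expected_total_count_conserves_abundance_mean(self):
        cfg = noise_free_config()
        temp = synthetic.simulate_temperature(cfg)
        surv = synthetic.simulate_surveys(cfg, temp)
        totals = surv.groupby(["site_id", "aspect", "plot_id", "species_id",
                               "year"])["count"].sum()
        np.testing.assert_allclose(totals, cfg.abundance_mean, rtol=1e-9)

    def test_poisson_totals_match_abundance_mean_within_mc_error(self):
        cfg = SyntheticConfig(seed=13, n_sites=4)
        temp = synthetic.simulate_temperature(cfg)
        surv = synthetic.simulate_surveys(cfg, temp)
        totals = surv.groupby(["site_id", "aspect", "plot_id", "species_id",
                               "year"])["count"].sum()
        se = np.sqrt(cfg.abundance_mean / len(totals))
        assert abs(totals.mean() - cfg.abundance_mean) < 4 * se

    def test_higher_sensitivity_widens_aspect_gap(self):
        gaps = []
        for sens in (1.7, 5.1):
            cfg = SyntheticConfig(seed=21, sensitivity_days_per_C=sens)
            temp = synthetic.simulate_temperature(cfg)
            surv = synthetic.simulate_surveys(cfg, temp)
            mids = phenology.plot_level_summaries(surv, mode="interp")
            wide = mids.pivot_table(index=["site_id", "plot_id", "year"],
                                    columns="aspect", values="mid_doy")
            gaps.append((wide["N"] - wide["S"]).mean())
        assert gaps[1] > gaps[0] > 0

    def test_curve_mass_outside_window_is_reported_not_truncated(self):
        cfg = noise_free_config(peak_mean_doy=20.0)  # far before the season
        temp = synthetic.simulate_temperature(cfg)
        with pytest.raises(ValueError, match="outside the season window"):
            synthetic.simulate_surveys(cfg, temp)

    def test_missing_sensor_coverage_is_an_error(self, small_config):
        temp = synthetic.simulate_temperature(small_config)
        partial = temp[temp["site_id"] != "site2"]
        with pytest.raises(ValueError, match="missing"):
            synthetic.simulate_surveys(small_config, partial)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"turnover_fraction": 1.2},
        {"turnover_fraction": -0.1},
        {"survey_interval_days": 0},
        {"var_plot_noise": -1.0},
        {"n_species_pool": 0},
        {"years": {}},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SyntheticConfig(**kw)

    def test_fixed_genotype_mode_zeroes_genotype_variance(self):
        cfg = SyntheticConfig(fixed_genotype_mode=True, var_genotype=9.0)
        assert cfg.var_genotype == 0.0


class TestDatasetIO:
    def test_write_read_round_trip(self, small_landscape, tmp_path):
        synthetic.write_dataset(small_landscape, tmp_path)
        back = synthetic.read_dataset(tmp_path)
        for name, df in small_landscape.items():
            pd.testing.assert_frame_equal(back[name].reset_index(drop=True),
                                          df.reset_index(drop=True))

    def test_refuses_overwrite_without_flag(self, small_landscape, tmp_path):
        synthetic.write_dataset(small_landscape, tmp_path)
        with pytest.raises(FileExistsError):
            synthetic.write_dataset(small_landscape, tmp_path)
        synthetic.write_dataset(small_landscape, tmp_path, overwrite=True)

    def test_truth_records_default_sensitivity(self, tmp_path):
        tables = {"truth": synthetic.truth_table(SyntheticConfig())}
        synthetic.write_dataset(tables, tmp_path)
        truth = synthetic.read_dataset(tmp_path)["truth"]
        row = truth.set_index("parameter").loc["sensitivity_days_per_C"]
        assert float(row["value"]) == 3.4

    def test_empty_tables_round_trip_as_headers_only(self, tmp_path):
        empty = {
            "surveys": pd.DataFrame(columns=synthetic.SURVEYS_COLUMNS),
            "temperature": pd.DataFrame(columns=synthetic.TEMPERATURE_COLUMNS),
        }
        synthetic.write_dataset(empty, tmp_path)
        back = synthetic.read_dataset(tmp_path)
        assert list(back["surveys"].columns) == synthetic.SURVEYS_COLUMNS
        assert back["surveys"].empty and back["temperature"].empty

    def test_survey_keys_unique(self, small_landscape):
        surv = small_landscape["surveys"]
        key = ["site_id", "aspect", "plot_id", "species_id", "year", "doy"]
        assert not surv.duplicated(subset=key).any()
        assert (surv["count"] >= 0).all()
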