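"""Synthetic study generator: determinism, densities, configured structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from soilhealth import (
    ALL_METALS,
    ConfigurationError,
    SynthConfig,
    TrueBeta,
    assign_zones,
    compute_sir,
    derive_standard_rates,
    generate_soil,
    generate_study,
    generate_zones,
)


class TestConfig:
    def test_invalid_configurations_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(n_zones=1)
        with pytest.raises(ConfigurationError):
            SynthConfig(urban_fraction=1.5)
        with pytest.raises(ConfigurationError):
            SynthConfig(grid_shape=(0, 3))
        with pytest.raises(ConfigurationError):
            SynthConfig(samples_per_km2_rural=0.0)

    def test_non_psd_covariance_rejected(self):
        bad = -np.eye(len(ALL_METALS))
        with pytest.raises(ConfigurationError, match="semi-definite"):
            SynthConfig(metal_log_cov=bad)

    def test_roundtrip_through_dict(self):
        cfg = SynthConfig(seed=3, n_zones=12, urban_fraction=0.25)
        again = SynthConfig.from_dict(cfg.to_dict())
        assert again.n_zones == 12 and again.true_beta == cfg.true_beta


class TestZones:
    def test_default_zone_count(self):
        assert len(generate_zones(SynthConfig())) == 279

    def test_exact_urban_fraction_small_case(self):
        zones = generate_zones(SynthConfig(n_zones=4, urban_fraction=0.5))
        assert int(zones["urban"].sum()) == 2

    def test_urban_zones_form_central_block(self):
        zones = generate_zones(SynthConfig(seed=0))
        centre = zones[["row", "col"]].mean()
        d2 = (zones["row"] - centre["row"]) ** 2 + (zones["col"] - centre["col"]) ** 2
        assert d2[zones["urban"]].max() <= d2[~zones["urban"]].min() + 1e-9


class TestSoil:
    def test_urban_density_is_exactly_configured(self, default_study):
        cfg, zones, soil = default_study.config, default_study.zones, default_study.soil
        cells_per_zone = cfg.grid_shape[0] * cfg.grid_shape[1]
        n_urban_cells = int(zones["urban"].sum()) * cells_per_zone
        assert int(soil["urban"].sum()) == n_urban_cells * cfg.samples_per_km2_urban

    def test_every_sample_inside_its_zone(self, default_study):
        reassigned = assign_zones(
            default_study.soil.drop(columns=["zone_id"]), default_study.zones
        )
        assert np.array_equal(reassigned["zone_id"], default_study.soil["zone_id"])

    def test_independent_metals_under_diagonal_covariance(self):
        cfg = SynthConfig(seed=2, metal_log_corr=0.0)
        soil = generate_soil(cfg, generate_zones(cfg))
        urban = soil[soil["urban"]]
        logs = np.log(urban[list(ALL_METALS)].to_numpy())
        corr = np.corrcoef(logs, rowvar=False)
        off = corr[~np.eye(len(ALL_METALS), dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_control_element_independent_of_metals(self, default_study):
        urban = default_study.soil[default_study.soil["urban"]]
        logk = np.log(urban["K"])
        for m in ALL_METALS:
            r = np.corrcoef(logk, np.log(urban[m]))[0, 1]
            assert abs(r) < 0.1

    def test_urban_elevation_sign_across_seeds(self):
        # configured positive urban shift must surface as a higher urban
        # geometric mean for every metal, replicated over 20 seeds
        for seed in range(20):
            cfg = SynthConfig(seed=seed, n_zones=40)
            soil = generate_soil(cfg, generate_zones(cfg))
            for m in ALL_METALS:
                gm_u = np.exp(np.log(soil.loc[soil["urban"], m]).mean())
                gm_r = np.exp(np.log(soil.loc[~soil["urban"], m]).mean())
                assert gm_u > gm_r

    def test_log_moments_converge_to_configuration(self):
        cfg = SynthConfig(seed=9, n_zones=100, samples_per_km2_urban=25, urban_fraction=1.0)
        soil = generate_soil(cfg, generate_zones(cfg))
        logs = np.log(soil[list(ALL_METALS)].to_numpy())
        mu = np.array([cfg.metal_log_means_urban[m] for m in ALL_METALS])
        sd = np.array([cfg.metal_log_sds[m] for m in ALL_METALS])
        n = len(soil)
        assert np.abs(logs.mean(axis=0) - mu).max() < 4 * sd.max() / np.sqrt(n)
        assert np.abs(logs.std(axis=0) / sd - 1).max() < 0.05


class TestStudy:
    def test_fixed_seed_reproduces_study_exactly(self, small_config):
        a = generate_study(small_config)
        b = generate_study(dataclasses.replace(small_config))
        for name in ("zones", "soil", "air", "population", "cases", "deprivation_domains", "covariates"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_case_counts_nonnegative_integers(self, default_study):
        cases = default_study.cases["cases"]
        assert (cases >= 0).all()
        assert (cases == cases.astype(int)).all()

    def test_domain_ranks_are_permutations(self, small_study):
        from soilhealth.deprivation import ALL_DOMAINS

        dom = small_study.deprivation_domains
        n = len(dom)
        for d in ALL_DOMAINS:
            assert sorted(dom[d]) == list(range(1, n + 1))

    def test_uncorrelated_domains_when_configured(self):
        cfg = SynthConfig(seed=4, n_zones=60, domain_corr=0.0, deprivation_soil_assoc=0.0)
        dom = generate_study(cfg).deprivation_domains
        r = np.corrcoef(dom[["income", "employment", "education", "crime"]].T)
        assert np.abs(r[~np.eye(4, dtype=bool)]).max() < 0.15

    def test_deprivation_soil_association_sign_downstream(self):
        # more deprived (lower decile) where the soil index is higher
        for seed in range(5):
            cov = generate_study(SynthConfig(seed=seed, n_zones=60)).covariates.dropna()
            assert np.corrcoef(cov["soil_index"], cov["decile"])[0, 1] < 0

    def test_air_pollutants_strongly_correlated(self, default_study):
        air = default_study.air
        assert np.corrcoef(air["no2"], air["pm10"])[0, 1] > 0.9

    def test_null_model_gives_unit_mean_sir(self):
        cfg = SynthConfig(seed=21, true_beta=TrueBeta(0.0, 0.0, 0.0, (0.0,) * 10))
        s = generate_study(cfg)
        rates = derive_standard_rates(s.population, s.cases_by_stratum)
        sir = compute_sir(s.population, rates, s.cases)
        assert abs(sir["SIR"].mean() - 1.0) < 0.05

    def test_doubling_baseline_rates_doubles_total_cases(self):
        cfg = SynthConfig(seed=13, n_zones=60)
        total = generate_study(cfg).cases["cases"].sum()
        doubled = dataclasses.replace(
            cfg, baseline_rates={k: 2 * v for k, v in cfg.baseline_rates.items()}
        )
        total2 = generate_study(doubled).cases["cases"].sum()
        assert abs(total2 / total - 2.0) < 0.05

    def test_missing_covariate_rejected(self, small_config):
        from soilhealth import generate_population_and_cases

        zones = generate_zones(small_config)
        bad = pd.DataFrame({"zone_id": zones["zone_id"], "soil_index": 20.0, "decile": 5})
        with pytest.raises(ValueError, match="covariate"):
            generate_population_and_cases(small_config, zones, bad)
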