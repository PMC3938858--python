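"""Synthetic study region generator.

Emulates the statistical structure a small-area soil-health analysis
assumes, so every downstream stage can be exercised without any external
download: a grid of contiguous reporting zones with a central urban
block; point soil samples on a systematic grid (dense in urban cells,
every second rural cell); inter-correlated, positively skewed metal
concentrations elevated in urban soil, with an independent control
element (K); zone-mean air NO2 and PM10 sharing the urban contrast and
strongly correlated with each other; seven correlated deprivation domain
rankings over nested data zones, linked to soil quality; and an age-sex
structured population whose respiratory admission counts follow a known
log-linear (Poisson) model in the zone covariates — so parameter
recovery by the fitted GLM is well-posed by construction.

The generating coefficients are configuration, not estimates taken from
any real dataset; see :class:`TrueBeta`.  Randomness comes from one seed
with a deterministic sub-stream per component, so regenerating one
component never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import aggregate as agg
from . import deprivation as depr
from . import index as idx

# --------------------------------------------------------------------------
# configuration


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


# Log-normal location (median, mg/kg; K in wt%) and log-scale spread for
# urban topsoil.  Magnitudes typical of an urban UK geochemical survey.
_URBAN_MEDIANS = {"As": 9.1, "Cr": 107.0, "Cu": 47.8, "Ni": 45.7, "Pb": 118.3, "Se": 0.9, "Zn": 144.4}
_LOG_SDS = {"As": 0.59, "Cr": 0.50, "Cu": 0.88, "Ni": 0.53, "Pb": 0.84, "Se": 0.46, "Zn": 0.74}

DEFAULT_AGE_BANDS = (("0-14", 0, 14), ("15-44", 15, 44), ("45-64", 45, 64), ("65-74", 65, 74), ("75+", 75, 120))
DEFAULT_AGE_SHARES = (0.17, 0.42, 0.25, 0.09, 0.07)
SEXES = ("F", "M")

# Annual respiratory hospital-admission rates per 100,000, rising steeply
# with age and slightly higher for males.
DEFAULT_BASELINE_RATES = {
    ("0-14", "F"): 1400.0,
    ("0-14", "M"): 1800.0,
    ("15-44", "F"): 450.0,
    ("15-44", "M"): 400.0,
    ("45-64", "F"): 1100.0,
    ("45-64", "M"): 1300.0,
    ("65-74", "F"): 3000.0,
    ("65-74", "M"): 3800.0,
    ("75+", "F"): 7000.0,
    ("75+", "M"): 9000.0,
}


@dataclass(frozen=True)
class AirParams:
    """Zone-mean pollutant model: urban/rural means plus correlated noise."""

    no2_mean_urban: float = 30.0
    no2_mean_rural: float = 12.0
    no2_sd: float = 3.5
    pm10_mean_urban: float = 21.0
    pm10_mean_rural: float = 14.0
    pm10_sd: float = 1.8
    noise_corr: float = 0.97  # within-stratum NO2-PM10 correlation


@dataclass(frozen=True)
class TrueBeta:
    """Generating coefficients of the log-linear admission model.

    Placeholder configuration values (no real study deposits a generating
    model); all on the log scale.  ``decile`` gives one effect per
    deprivation decile with decile 1 (most deprived) as the zero
    reference.
    """

    intercept: float = -0.2
    soil_index: float = 0.01
    no2: float = 0.01
    decile: tuple[float, ...] = tuple(-0.06 * d for d in range(10))

    def as_dict(self) -> dict:
        return {"intercept": self.intercept, "soil_index": self.soil_index, "no2": self.no2, "decile": list(self.decile)}


def _default_log_means_urban() -> dict[str, float]:
    return {m: math.log(v) for m, v in _URBAN_MEDIANS.items()}


@dataclass
class SynthConfig:
    """Everything the generator needs; defaults define the study conditions.

    Geometry: ``n_zones`` rectangular zones, each a ``grid_shape``
    (rows, cols) block of 1 km^2 cells, tiled row-major on a near-square
    lattice; the ``round(urban_fraction * n_zones)`` zones closest to the
    lattice centre form the urban block.  Defaults (279 zones of 3 km^2,
    urban fraction 0.42, 4 samples/km^2 urban, one sample in every second
    rural cell) give ~1,400 urban and ~240 rural samples.
    """

    seed: int = 0
    n_zones: int = 279
    grid_shape: tuple[int, int] = (1, 3)
    urban_fraction: float = 0.42
    samples_per_km2_urban: int = 4
    samples_per_km2_rural: float = 0.5
    cell_size: float = 1000.0  # metres

    metals: tuple[str, ...] = agg.ALL_METALS
    metal_log_means_urban: dict = field(default_factory=_default_log_means_urban)
    metal_log_means_rural: dict | None = None  # default: urban - log(3)
    metal_log_sds: dict = field(default_factory=lambda: dict(_LOG_SDS))
    metal_log_corr: float = 0.5
    metal_log_cov: np.ndarray | None = None  # overrides sds+corr when given
    urban_rural_log_shift: float = math.log(3.0)
    control_log_mean_urban: float = math.log(1.25)
    control_log_mean_rural: float = math.log(1.45)
    control_log_sd: float = 0.38

    air_params: AirParams = field(default_factory=AirParams)

    age_bands: tuple = DEFAULT_AGE_BANDS
    age_shares: tuple = DEFAULT_AGE_SHARES
    baseline_rates: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_RATES))
    zone_population_mean: float = 8800.0
    zone_population_sd: float = 1500.0
    zone_population_min: int = 2000

    datazones_per_zone: int = 5
    domain_corr: float = 0.6
    deprivation_soil_assoc: float = 0.6
    datazone_sd: float = 0.6

    true_beta: TrueBeta = field(default_factory=TrueBeta)

    def __post_init__(self) -> None:
        if self.metal_log_means_rural is None:
            self.metal_log_means_rural = {
                m: mu - self.urban_rural_log_shift for m, mu in self.metal_log_means_urban.items()
            }
        self.validate()

    def validate(self) -> None:
        if self.n_zones < 2:
            raise ConfigurationError("need at least 2 zones")
        r, c = self.grid_shape
        if r < 1 or c < 1:
            raise ConfigurationError("grid_shape entries must be positive")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ConfigurationError("urban_fraction must lie in [0, 1]")
        if self.samples_per_km2_urban < 1 or self.samples_per_km2_rural <= 0:
            raise ConfigurationError("sampling densities must be positive")
        if any(v < 0 for v in self.baseline_rates.values()):
            raise ConfigurationError("baseline rates must be non-negative")
        if not math.isclose(sum(self.age_shares), 1.0, abs_tol=1e-9):
            raise ConfigurationError("age shares must sum to 1")
        cov = self.covariance()
        if not np.allclose(cov, cov.T):
            raise ConfigurationError("metal_log_cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-9:
            raise ConfigurationError("metal_log_cov must be positive semi-definite")

    def covariance(self) -> np.ndarray:
        """Log-scale covariance across the (non-control) metals."""
        if self.metal_log_cov is not None:
            return np.asarray(self.metal_log_cov, dtype=float)
        k = len(self.metals)
        corr = np.full((k, k), self.metal_log_corr)
        np.fill_diagonal(corr, 1.0)
        sd = np.array([self.metal_log_sds[m] for m in self.metals])
        return corr * np.outer(sd, sd)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["metal_log_cov"] is not None:
            d["metal_log_cov"] = np.asarray(d["metal_log_cov"]).tolist()
        d["baseline_rates"] = {f"{b}|{s}": v for (b, s), v in self.baseline_rates.items()}
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SynthConfig":
        d = dict(data)
        if "air_params" in d and isinstance(d["air_params"], Mapping):
            d["air_params"] = AirParams(**d["air_params"])
        if "true_beta" in d and isinstance(d["true_beta"], Mapping):
            tb = dict(d["true_beta"])
            if "decile" in tb:
                tb["decile"] = tuple(tb["decile"])
            d["true_beta"] = TrueBeta(**tb)
        if "baseline_rates" in d and isinstance(d["baseline_rates"], Mapping):
            rates = {}
            for k, v in d["baseline_rates"].items():
                band, sex = k.split("|") if isinstance(k, str) else k
                rates[(band, sex)] = float(v)
            d["baseline_rates"] = rates
        for tup in ("grid_shape", "metals", "age_shares"):
            if tup in d and isinstance(d[tup], list):
                d[tup] = tuple(d[tup])
        if "age_bands" in d and isinstance(d["age_bands"], list):
            d["age_bands"] = tuple(tuple(b) for b in d["age_bands"])
        return cls(**d)


# --------------------------------------------------------------------------
# random streams

_COMPONENTS = {"soil": 1, "air": 2, "population": 3, "cases": 4, "deprivation": 5}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_COMPONENTS[component],)))


# --------------------------------------------------------------------------
# zones


def generate_zones(config: SynthConfig) -> pd.DataFrame:
    """Contiguous rectangular zones on a near-square lattice, urban centre.

    Deterministic given the configuration (no randomness is needed).
    Columns: zone_id, row, col, urban, x0, y0, x1, y1 (metres).
    """
    n = config.n_zones
    ncols = math.ceil(math.sqrt(n))
    rows_idx, cols_idx = np.divmod(np.arange(n), ncols)
    zr, zc = config.grid_shape
    w, h = zc * config.cell_size, zr * config.cell_size
    zones = pd.DataFrame(
        {
            "zone_id": np.arange(n),
            "row": rows_idx,
            "col": cols_idx,
            "x0": cols_idx * w,
            "y0": rows_idx * h,
        }
    )
    zones["x1"] = zones["x0"] + w
    zones["y1"] = zones["y0"] + h
    n_urban = int(round(config.urban_fraction * n))
    d2 = (rows_idx - rows_idx.mean()) ** 2 + (cols_idx - cols_idx.mean()) ** 2
    order = np.lexsort((zones["zone_id"].to_numpy(), d2))
    urban = np.zeros(n, dtype=bool)
    urban[order[:n_urban]] = True
    zones["urban"] = urban
    return zones


# --------------------------------------------------------------------------
# soil


def _matrix_root(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def generate_soil(config: SynthConfig, zones: pd.DataFrame) -> pd.DataFrame:
    """Grid soil samples with multivariate log-normal concentrations.

    Urban cells hold exactly ``samples_per_km2_urban`` samples at uniform
    positions; rural cells hold one sample with probability
    ``samples_per_km2_rural`` (a Poisson count for densities above 1).
    The non-control metals share a log-scale covariance with an urban
    location shift; the control element K is drawn independently with a
    mild rural elevation.
    """
    rng = _rng(config.seed, "soil")
    zr, zc = config.grid_shape
    cell = config.cell_size

    # one row per 1 km^2 cell
    reps = zr * zc
    cz = zones.loc[zones.index.repeat(reps)].reset_index(drop=True)
    offs = np.tile(np.stack(np.divmod(np.arange(reps), zc), axis=1), (len(zones), 1))
    cx0 = cz["x0"].to_numpy() + offs[:, 1] * cell
    cy0 = cz["y0"].to_numpy() + offs[:, 0] * cell
    urban_cell = cz["urban"].to_numpy()

    counts = np.empty(len(cz), dtype=int)
    counts[urban_cell] = int(round(config.samples_per_km2_urban))
    d = config.samples_per_km2_rural
    n_rural = int((~urban_cell).sum())
    if d <= 1.0:
        counts[~urban_cell] = rng.random(n_rural) < d
    else:
        counts[~urban_cell] = rng.poisson(d, size=n_rural)

    total = int(counts.sum())
    cell_of = np.repeat(np.arange(len(cz)), counts)
    x = cx0[cell_of] + rng.random(total) * cell
    y = cy0[cell_of] + rng.random(total) * cell
    zone_id = cz["zone_id"].to_numpy()[cell_of]
    urban = urban_cell[cell_of]

    metals = list(config.metals)
    mu_u = np.array([config.metal_log_means_urban[m] for m in metals])
    mu_r = np.array([config.metal_log_means_rural[m] for m in metals])
    mu = np.where(urban[:, None], mu_u, mu_r)
    root = _matrix_root(config.covariance())
    logc = mu + rng.standard_normal((total, len(metals))) @ root.T

    mu_k = np.where(urban, config.control_log_mean_urban, config.control_log_mean_rural)
    logk = mu_k + config.control_log_sd * rng.standard_normal(total)

    soil = pd.DataFrame(
        {"sample_id": [f"S{i:06d}" for i in range(total)], "x": x, "y": y, "zone_id": zone_id, "urban": urban}
    )
    for j, m in enumerate(metals):
        soil[m] = np.exp(logc[:, j])
    soil[agg.CONTROL_ELEMENT] = np.exp(logk)
    return soil


# --------------------------------------------------------------------------
# air


def generate_air(config: SynthConfig, zones: pd.DataFrame) -> pd.DataFrame:
    """Zone-mean NO2 and PM10 sharing the urban contrast and a common noise."""
    rng = _rng(config.seed, "air")
    p = config.air_params
    urban = zones["urban"].to_numpy()
    n = len(zones)
    g = rng.standard_normal(n)
    e = rng.standard_normal(n)
    c = p.noise_corr
    no2 = np.where(urban, p.no2_mean_urban, p.no2_mean_rural) + p.no2_sd * g
    pm10 = np.where(urban, p.pm10_mean_urban, p.pm10_mean_rural) + p.pm10_sd * (c * g + math.sqrt(1 - c * c) * e)
    return pd.DataFrame({"zone_id": zones["zone_id"], "no2": no2, "pm10": pm10})


# --------------------------------------------------------------------------
# deprivation domains


def generate_deprivation_domains(
    config: SynthConfig, zones: pd.DataFrame, zone_signal: pd.Series
) -> pd.DataFrame:
    """Seven correlated domain rankings over data zones nested in zones.

    A zone-level latent deprivation severity correlates (strength
    ``deprivation_soil_assoc``) with the standardised ``zone_signal``
    (typically the zone soil-metal index); each of the
    ``datazones_per_zone`` member data zones perturbs it, and each domain
    loads on the data-zone latent with shared variance ``domain_corr``.
    Domain ranks are permutations of 1..n_datazones, 1 = most deprived.
    """
    if config.datazones_per_zone * config.n_zones < 10:
        raise ConfigurationError("need at least 10 data zones")
    rng = _rng(config.seed, "deprivation")
    sig = zone_signal.reindex(zones["zone_id"]).to_numpy(dtype=float)
    sig = np.where(np.isnan(sig), np.nanmean(sig), sig)
    s = (sig - sig.mean()) / sig.std() if sig.std() > 0 else np.zeros_like(sig)

    rho = config.deprivation_soil_assoc
    latent_zone = rho * s + math.sqrt(max(0.0, 1 - rho * rho)) * rng.standard_normal(len(zones))
    k = config.datazones_per_zone
    n_dz = k * len(zones)
    tau = config.datazone_sd
    latent_dz = np.repeat(latent_zone, k) + tau * rng.standard_normal(n_dz)
    latent_dz /= math.sqrt(1 + tau * tau)

    lam = config.domain_corr
    out = pd.DataFrame(
        {
            "datazone_id": [f"DZ{i:05d}" for i in range(n_dz)],
            "zone_id": np.repeat(zones["zone_id"].to_numpy(), k),
        }
    )
    for dom in depr.ALL_DOMAINS:
        score = math.sqrt(lam) * latent_dz + math.sqrt(1 - lam) * rng.standard_normal(n_dz)
        out[dom] = rankdata(-score, method="ordinal").astype(int)  # 1 = most deprived
    return out


# --------------------------------------------------------------------------
# population and cases


def generate_population_and_cases(
    config: SynthConfig, zones: pd.DataFrame, covariates: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Age-sex populations and Poisson admissions under the known model.

    The expected count in zone z, stratum s is
    ``pop_zs * rate_s / 1e5 * exp(eta_z)`` with
    ``eta_z = b0 + b_index * soil_index_z + d_{decile_z} + b_no2 * no2_z``.
    Returns (population, zone case totals, study stratum case totals,
    zone-by-stratum counts).
    """
    for col in ("soil_index", "decile", "no2"):
        if col not in covariates.columns:
            raise ValueError(f"missing covariate column {col!r}")
    cov = covariates.set_index("zone_id").reindex(zones["zone_id"])
    if cov[["soil_index", "decile", "no2"]].isna().any().any():
        raise ValueError("covariates missing for some zones")

    rng_pop = _rng(config.seed, "population")
    rng_cases = _rng(config.seed, "cases")
    n = len(zones)
    totals = np.maximum(
        np.round(rng_pop.normal(config.zone_population_mean, config.zone_population_sd, size=n)),
        config.zone_population_min,
    ).astype(int)
    shares = np.outer(config.age_shares, [0.5, 0.5]).ravel()
    strata = [(band, sex) for band, _, _ in config.age_bands for sex in SEXES]
    pops = np.vstack([rng_pop.multinomial(t, shares) for t in totals])  # zones x strata

    beta = config.true_beta
    eta = (
        beta.intercept
        + beta.soil_index * cov["soil_index"].to_numpy(dtype=float)
        + np.asarray(beta.decile)[cov["decile"].to_numpy(dtype=int) - 1]
        + beta.no2 * cov["no2"].to_numpy(dtype=float)
    )
    rates = np.array([config.baseline_rates[s] for s in strata])
    mu = pops * (rates / 1e5)[None, :] * np.exp(eta)[:, None]
    counts = rng_cases.poisson(mu)

    zone_ids = zones["zone_id"].to_numpy()
    population = pd.DataFrame(
        {
            "zone_id": np.repeat(zone_ids, len(strata)),
            "age_band": np.tile([b for b, _ in strata], n),
            "sex": np.tile([s for _, s in strata], n),
            "pop": pops.ravel(),
        }
    )
    cases_zone_stratum = population.drop(columns="pop").assign(cases=counts.ravel())
    cases = pd.DataFrame({"zone_id": zone_ids, "cases": counts.sum(axis=1)})
    cases_by_stratum = (
        cases_zone_stratum.groupby(["age_band", "sex"], as_index=False, sort=False)["cases"].sum()
    )
    return population, cases, cases_by_stratum, cases_zone_stratum


# --------------------------------------------------------------------------
# orchestration


@dataclass
class SyntheticStudy:
    """A complete generated study region plus the generating truth."""

    config: SynthConfig
    zones: pd.DataFrame
    soil: pd.DataFrame
    air: pd.DataFrame
    deprivation_domains: pd.DataFrame
    population: pd.DataFrame
    cases: pd.DataFrame
    cases_by_stratum: pd.DataFrame
    cases_zone_stratum: pd.DataFrame
    covariates: pd.DataFrame  # analysis covariates (missing where undefined)
    truth: dict


def generate_study(config: SynthConfig) -> SyntheticStudy:
    """Generate every table of a study under one seed.

    The zone covariates that drive case generation are computed with the
    same aggregation/index/deprivation machinery the analysis uses, so a
    downstream fit estimates exactly the generating coefficients.  Zones
    that drew no soil sample (possible in sparse rural sampling) take the
    study-mean index in the generating predictor; their analysis
    covariate stays missing.
    """
    zones = generate_zones(config)
    soil = generate_soil(config, zones)
    air = generate_air(config, zones)

    scorers = idx.fit_scorers(soil)
    sample_index = idx.score_samples(soil, scorers)
    soil_index = idx.zone_mean_index(sample_index)

    domains = generate_deprivation_domains(config, zones, soil_index)
    dz = depr.datazone_deprivation(domains[["datazone_id", "zone_id", *depr.DOMAINS]])
    zone_decile = depr.zone_median_decile(dz)

    covariates = pd.DataFrame({"zone_id": zones["zone_id"]})
    covariates["soil_index"] = soil_index.reindex(zones["zone_id"]).to_numpy()
    covariates["decile"] = zone_decile.reindex(zones["zone_id"]).to_numpy()
    covariates = covariates.merge(air, on="zone_id")

    gen_cov = covariates.copy()
    gen_cov["soil_index"] = gen_cov["soil_index"].fillna(soil_index.mean())
    population, cases, cases_by_stratum, cases_zone_stratum = generate_population_and_cases(
        config, zones, gen_cov
    )

    truth = {
        "seed": config.seed,
        "true_beta": config.true_beta.as_dict(),
        "n_zones": config.n_zones,
        "n_samples": len(soil),
        "zones_without_samples": sorted(set(zones["zone_id"]) - set(soil_index.index)),
    }
    return SyntheticStudy(
        config=config,
        zones=zones,
        soil=soil,
        air=air,
        deprivation_domains=domains,
        population=population,
        cases=cases,
        cases_by_stratum=cases_by_stratum,
        cases_zone_stratum=cases_zone_stratum,
        covariates=covariates,
        truth=truth,
    )
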