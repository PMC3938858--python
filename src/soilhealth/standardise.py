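"""Indirect age-sex standardisation of zone admission counts.

Disease counts differ across zones partly because their populations
differ in age and sex.  Indirect standardisation removes this: stratum-
specific rates from a standard population (here, the whole study region
by default) are applied to each zone's population to give the count
expected under the standard schedule, and the standardised incidence
ratio SIR = observed / expected summarises the remainder.  SIR = 1 means
parity between observed and expected counts.

With internally derived standard rates the identity
``sum_z E_z = sum_z O_z`` holds exactly, a useful end-to-end check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STRATUM_KEYS = ["age_band", "sex"]

#: Zones with fewer expected cases than this are flagged unstable (kept,
#: never dropped): their SIRs carry large Poisson noise.
DEFAULT_E_FLOOR = 0.5


def derive_standard_rates(population: pd.DataFrame, cases_by_stratum: pd.DataFrame) -> pd.DataFrame:
    """Stratum-specific admission rates per 100,000 from study totals.

    ``population`` has one row per (zone, age_band, sex) with ``pop``;
    ``cases_by_stratum`` has study-wide ``cases`` per (age_band, sex).
    """
    pop = population.groupby(STRATUM_KEYS, as_index=False)["pop"].sum()
    rates = pop.merge(cases_by_stratum[STRATUM_KEYS + ["cases"]], on=STRATUM_KEYS, how="outer")
    if rates["pop"].isna().any() or rates["cases"].isna().any():
        raise ValueError("population and case strata do not match")
    if ((rates["pop"] == 0) & (rates["cases"] > 0)).any():
        raise ValueError("stratum with cases but zero population")
    if (rates["cases"] < 0).any():
        raise ValueError("negative case counts")
    with np.errstate(invalid="ignore"):
        rates["rate_per_100k"] = np.where(
            rates["pop"] > 0, 1e5 * rates["cases"] / rates["pop"], 0.0
        )
    return rates[STRATUM_KEYS + ["pop", "cases", "rate_per_100k"]]


def expected_counts(population: pd.DataFrame, rates: pd.DataFrame) -> pd.Series:
    """Per-zone expected counts: sum over strata of pop x standard rate."""
    merged = population.merge(rates[STRATUM_KEYS + ["rate_per_100k"]], on=STRATUM_KEYS, how="left")
    if merged["rate_per_100k"].isna().any():
        raise ValueError("population contains strata absent from the standard rates")
    merged["expected"] = merged["pop"] * merged["rate_per_100k"] / 1e5
    e = merged.groupby("zone_id")["expected"].sum()
    e.name = "E"
    return e


def compute_sir(
    population: pd.DataFrame,
    rates: pd.DataFrame,
    observed: pd.DataFrame,
    e_floor: float = DEFAULT_E_FLOOR,
) -> pd.DataFrame:
    """Observed, expected and SIR per zone.

    ``observed`` has columns ``zone_id, cases``.  Zones with E = 0 get an
    undefined (NaN) SIR; zones with 0 < E < ``e_floor`` are flagged
    ``unstable`` but retained.
    """
    if (observed["cases"] < 0).any():
        raise ValueError("negative observed counts")
    e = expected_counts(population, rates)
    out = observed.rename(columns={"cases": "O"}).merge(e.reset_index(), on="zone_id", how="left")
    if out["E"].isna().any():
        raise ValueError("observed counts for zones without population data")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["SIR"] = np.where(out["E"] > 0, out["O"] / out["E"], np.nan)
    out["unstable"] = out["E"] < e_floor
    return out[["zone_id", "O", "E", "SIR", "unstable"]]
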