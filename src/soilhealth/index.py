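"""Composite soil-metal index.

A single relative land-quality score per sample, built in three steps:

1. for each metal of regulatory concern (As, Cr, Ni, Pb, Se), class the
   study-wide distribution of log concentrations into deciles and score
   each sample 1–10 (higher concentration, higher score);
2. sum the five per-metal scores into a per-sample total in [5, 50];
3. average the totals within each zone.

The index is rank-based, so it is invariant to any strictly monotone
transform applied study-wide; the log transform is retained because the
rest of the geostatistical processing works on the log scale.  It is a
relative summary of metal loading, not a health-risk threshold.

Decile convention: the nine cut points are the order statistics at
positions ``floor(k*n/10)`` (k = 1..9) of the sorted fitted sample, and a
value belongs to the lowest class whose cut point it does not exceed.
This makes a fitted sample's score exactly ``ceil(10*r/n)`` where ``r``
is its minimum rank, with tied values sharing the lower class, for every
sample size n — classes hold ``floor(n/10)`` or ``ceil(n/10)`` members.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Elements of potential concern under UK contaminated-land (CLEA) guidance
#: that enter the composite index.
CLEA_METALS = ("As", "Cr", "Ni", "Pb", "Se")


@dataclass(frozen=True)
class DecileScorer:
    """Decile classer for one metal: nine log-scale cut points -> scores 1-10."""

    metal: str
    cuts: tuple[float, ...]  # non-decreasing, log mg/kg
    n_fit: int

    def __post_init__(self) -> None:
        if len(self.cuts) != 9 or np.any(np.diff(self.cuts) < 0):
            raise ValueError("scorer needs nine non-decreasing cut points")

    def score(self, values) -> np.ndarray:
        """Score concentrations 1-10; monotone non-decreasing in value."""
        v = np.asarray(values, dtype=float)
        if np.any(v <= 0):
            raise ValueError("concentrations must be positive")
        return np.searchsorted(np.asarray(self.cuts), np.log(v), side="left") + 1


def fit_decile_scorer(values, metal: str = "") -> DecileScorer:
    """Fit decile cut points on the pooled study-wide distribution of a metal."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 10:
        raise ValueError("need at least 10 observations to fit deciles")
    if np.any(v <= 0):
        raise ValueError("concentrations must be positive")
    if np.unique(v).size < 2:
        raise ValueError("degenerate distribution: all values identical")
    logs = np.sort(np.log(v))
    n = logs.size
    pos = np.floor(np.arange(1, 10) * n / 10).astype(int) - 1
    return DecileScorer(metal=metal, cuts=tuple(logs[pos]), n_fit=n)


def fit_scorers(samples: pd.DataFrame, metals: tuple[str, ...] = CLEA_METALS) -> dict[str, DecileScorer]:
    """Fit one scorer per metal on all samples pooled (urban + rural)."""
    return {m: fit_decile_scorer(samples[m].to_numpy(), m) for m in metals}


def score_samples(
    samples: pd.DataFrame,
    scorers: Mapping[str, DecileScorer],
    metals: tuple[str, ...] = CLEA_METALS,
) -> pd.DataFrame:
    """Per-sample decile scores and their sum (the total soil-metal index).

    Returns one row per sample with ``score_<metal>`` columns and
    ``total``; ``zone_id`` is carried through when present.  Samples
    missing any required concentration are flagged ``complete=False``
    with a missing total and are excluded from zone means downstream.
    """
    out = pd.DataFrame({"sample_id": samples["sample_id"].to_numpy()})
    if "zone_id" in samples.columns:
        out["zone_id"] = samples["zone_id"].to_numpy()
    complete = np.ones(len(samples), dtype=bool)
    for m in metals:
        complete &= samples[m].notna().to_numpy()
    total = np.zeros(len(samples), dtype=float)
    for m in metals:
        vals = samples[m].to_numpy(dtype=float)
        sc = np.full(len(samples), np.nan)
        sc[complete] = scorers[m].score(vals[complete])
        out[f"score_{m}"] = sc
        total += sc
    out["total"] = total
    out["complete"] = complete
    return out


def zone_mean_index(sample_index: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of complete per-sample totals within each zone.

    Bounded in [5, 50]; zones with no scored samples are absent (missing).
    """
    if "zone_id" not in sample_index.columns:
        raise ValueError("sample index table must carry zone_id")
    ok = sample_index[sample_index["complete"]]
    from .aggregate import UNASSIGNED

    ok = ok[ok["zone_id"] != UNASSIGNED]
    s = ok.groupby("zone_id")["total"].mean()
    s.name = "soil_index"
    return s


def export_scorers(scorers: Mapping[str, DecileScorer], path: str | Path) -> None:
    """Write fitted cut points to JSON for audit."""
    payload = {
        m: {"cuts_log": list(s.cuts), "cuts_mg_kg": [float(np.exp(c)) for c in s.cuts], "n_fit": s.n_fit}
        for m, s in scorers.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))
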