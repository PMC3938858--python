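"""Health-free multiple-deprivation index.

Official multiple-deprivation indices (SIMD-style) combine domain
rankings — income, employment, health, education, housing, access to
services, crime — into one composite rank per small census area ("data
zone").  Because this pipeline studies associations *with* health, the
health domain is excluded and the composite is rebuilt from the six
remaining domains with the published weighting scheme renormalised.

Construction follows the SIMD methodology: each domain's ranks are put
on [0, 1] (1 = most deprived), passed through an exponential transform
that concentrates weight in the deprived tail, combined as a weighted
sum, and re-ranked.  Composite ranks are then grouped into deciles
(decile 1 = most deprived) and each reporting zone receives the median
decile of its member data zones.

Direction convention throughout: smaller rank / decile = more deprived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: Domains entering the health-free composite.
DOMAINS = ("income", "employment", "education", "housing", "access", "crime")
#: All seven published domains (health present in source data, excluded here).
ALL_DOMAINS = ("income", "employment", "health", "education", "housing", "access", "crime")

#: Published SIMD-2009 domain weights with health removed (renormalised at
#: use time).  Config entries, not values printed by any single study.
DEFAULT_WEIGHTS = {
    "income": 0.28,
    "employment": 0.28,
    "education": 0.14,
    "housing": 0.02,
    "access": 0.09,
    "crime": 0.05,
}

# Exponential rank-transform constants (SIMD/IMD methodology): scores in
# [0, 100] with ~10% of the range covering the least-deprived half.
EXP_SCALE = 23.0
EXP_SPAN = 100.0


@dataclass(frozen=True)
class DomainWeights:
    """Non-negative weights over the six health-free domains; normalised to 1."""

    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        if "health" in self.weights:
            raise ValueError("health domain must not be weighted in the health-free index")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if sum(self.weights.values()) <= 0:
            raise ValueError("weights sum to zero")

    def normalised(self) -> dict:
        s = sum(self.weights.values())
        return {k: w / s for k, w in self.weights.items()}


def _check_permutation(ranks: np.ndarray, n: int, name: str) -> None:
    if not np.array_equal(np.sort(ranks), np.arange(1, n + 1)):
        raise ValueError(f"domain {name!r} is not a complete ranking 1..{n}")


def exponential_transform(ranks: np.ndarray, n: int) -> np.ndarray:
    """Map ranks (1 = most deprived) to tail-weighted scores in [0, 100]."""
    r01 = (n - np.asarray(ranks, dtype=float)) / (n - 1)  # 1 = most deprived
    return -EXP_SCALE * np.log1p(-r01 * (1.0 - np.exp(-EXP_SPAN / EXP_SCALE)))


def combine_domains(
    domain_ranks: pd.DataFrame,
    weights: DomainWeights | None = None,
    transform: str = "exponential",
) -> pd.DataFrame:
    """Weighted combination of domain rankings into a composite ranking.

    ``domain_ranks`` carries one complete ranking (1 = most deprived) per
    weighted domain.  Returns a copy with ``composite_score`` and
    ``composite_rank`` (a permutation of 1..n, 1 = most deprived; ties
    broken by row order).  ``transform`` is ``"exponential"`` (default,
    the published methodology) or ``"linear"``.
    """
    weights = weights or DomainWeights()
    w = weights.normalised()
    missing = set(w) - set(domain_ranks.columns)
    if missing:
        raise ValueError(f"missing domain columns: {sorted(missing)}")
    n = len(domain_ranks)
    if n < 2:
        raise ValueError("need at least two data zones")
    if transform not in ("exponential", "linear"):
        raise ValueError(f"unknown transform {transform!r}")

    score = np.zeros(n)
    for dom, wt in w.items():
        ranks = domain_ranks[dom].to_numpy()
        _check_permutation(ranks, n, dom)
        if transform == "exponential":
            score += wt * exponential_transform(ranks, n)
        else:
            score += wt * (n - ranks.astype(float)) / (n - 1)
    out = domain_ranks.copy()
    out["composite_score"] = score
    out["composite_rank"] = rankdata(-score, method="ordinal").astype(int)
    return out


def to_deciles(composite_ranks) -> np.ndarray:
    """Group ranks into ten classes: decile d holds ranks in ((d-1)n/10, dn/10].

    Class sizes differ by at most one for any n >= 10.
    """
    r = np.asarray(composite_ranks, dtype=int)
    n = r.size
    if n < 10:
        raise ValueError("need at least 10 data zones for deciles")
    _check_permutation(r, n, "composite")
    return np.ceil(10 * r / n).astype(int)


def zone_median_decile(records: pd.DataFrame) -> pd.Series:
    """Median member-data-zone decile per zone.

    Even member counts give a half-integer median; it is floored toward
    the more-deprived class (the conservative direction for an
    inequality analysis).  Zones with no data zones are absent.
    """
    med = records.groupby("zone_id")["decile"].median()
    med = np.floor(med).astype(int)
    med.name = "decile"
    return med


def datazone_deprivation(
    domain_ranks: pd.DataFrame,
    weights: DomainWeights | None = None,
    transform: str = "exponential",
) -> pd.DataFrame:
    """Full data-zone pipeline: combine domains, re-rank, classify deciles."""
    out = combine_domains(domain_ranks, weights, transform)
    out["decile"] = to_deciles(out["composite_rank"].to_numpy())
    return out
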