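"""Association models: correlation screening and log-link GLMs of SIRs.

Two stages mirror standard small-area ecological practice:

1. Pearson correlation matrices over zone-level variables, flagged
   against the n-dependent 5% critical value
   ``t_{a/2, n-2} / sqrt(t^2 + n - 2)``;
2. generalised linear models of the standardised incidence ratios with a
   log link.  The default family is Poisson on the observed counts with
   ``log E`` as offset — the principled likelihood for count-derived
   SIRs, equivalent to modelling SIR on the log scale — with a
   Gaussian-log-link fit on the SIR itself as a documented alternative.

Soil metals are strongly inter-correlated, so exactly one soil covariate
(the composite index or a single metal's zone geometric mean) enters a
model at a time; requesting more is refused.  Likewise NO2 and PM10 are
near-collinear and never entered together.  Deprivation enters as a
categorical decile factor with decile 1 (most deprived) as reference.
Model choice uses AIC = 2k - 2*loglik; the minimum-AIC fit wins, ties
going to the smaller model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

AIR_LABELS = {"no2": "Air NO2", "pm10": "Air PM10"}
DECILE_LEVELS = tuple(range(2, 11))  # decile 1 absorbed in the intercept


class MulticollinearityError(ValueError):
    """Raised when near-collinear covariates are requested together."""


def pearson_r(x, y) -> float:
    """Product-moment correlation; requires n >= 3 and non-zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def critical_r(n: int, alpha: float = 0.05, two_sided: bool = True) -> float:
    """Smallest |r| significant at level ``alpha`` for sample size ``n``.

    Exact closed form from the t test of a zero correlation:
    ``t_{a/2, n-2} / sqrt(t^2 + n - 2)``; strictly decreasing in n.
    (Printed textbook tables built on coarse df grids or the Fisher-scale
    normal approximation can differ in the third decimal.)
    """
    if n < 3:
        raise ValueError("need n >= 3")
    q = 1 - alpha / 2 if two_sided else 1 - alpha
    t = stats.t.ppf(q, n - 2)
    return float(t / np.sqrt(t * t + n - 2))


@dataclass(frozen=True)
class CorrelationResult:
    var_a: str
    var_b: str
    r: float
    n: int
    critical_r: float

    @property
    def significant(self) -> bool:
        return abs(self.r) > self.critical_r


def correlation_matrix(
    data: pd.DataFrame, variables: Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Lower-triangular pairwise Pearson correlations with significance flags.

    Listwise deletion: only rows complete on all ``variables`` are used
    (the common n is reported per pair).  Deprivation deciles keep their
    native direction (1 = most deprived), so its correlations are
    typically negative against adversity measures.
    """
    d = data[list(variables)].dropna()
    n = len(d)
    if n < 3:
        raise ValueError("fewer than 3 complete cases")
    rc = critical_r(n, alpha)
    rows = []
    for a, b in combinations(variables, 2):
        res = CorrelationResult(a, b, pearson_r(d[a], d[b]), n, rc)
        rows.append(
            {"var_a": a, "var_b": b, "r": res.r, "n": n, "critical_r": rc, "significant": res.significant}
        )
    return pd.DataFrame(rows)


@dataclass
class GLMFit:
    """A fitted log-link GLM: tidy coefficient table plus fit metadata."""

    response: str
    family: str
    table: pd.DataFrame  # term, estimate, se, p_value
    aic: float
    n: int
    converged: bool
    dropped_levels: tuple[int, ...] = ()
    result: object = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.table)

    def conf_int(self, term: str, alpha: float = 0.05):
        """Wald interval for one term."""
        row = self.table.set_index("term").loc[term]
        z = stats.norm.ppf(1 - alpha / 2)
        return float(row["estimate"] - z * row["se"]), float(row["estimate"] + z * row["se"])


def _single(name, value, kind):
    if value is None or isinstance(value, str):
        return value
    if isinstance(value, Iterable):
        vals = list(value)
        if len(vals) > 1:
            raise MulticollinearityError(
                f"{kind} covariates are strongly inter-correlated; enter one at a time, got {vals}"
            )
        return vals[0] if vals else None
    raise TypeError(f"{name} must be a column name or None")


def fit_sir_glm(
    data: pd.DataFrame,
    soil_covariate: str | None = "soil_index",
    air: str | None = "no2",
    family: str = "poisson_offset",
    decile_col: str | None = "decile",
    extra_covariates: Sequence[str] = (),
) -> GLMFit:
    """Log-link GLM of zone SIRs on soil, deprivation and air covariates.

    ``data`` needs ``O`` and ``E`` (and hence SIR = O/E) plus the covariate
    columns.  ``soil_covariate`` is the composite index or one metal's
    zone geometric mean — never several (refused on multicollinearity
    grounds); ``air`` is ``"no2"`` or ``"pm10"``, never both.  Deprivation
    deciles enter as indicator terms for deciles 2–10 (decile 1
    reference); levels absent from the data are dropped and recorded.
    Rows with any missing field are excluded listwise.
    """
    soil_covariate = _single("soil_covariate", soil_covariate, "soil")
    air = _single("air", air, "air pollution")
    if family not in ("poisson_offset", "gaussian_log"):
        raise ValueError(f"unknown family {family!r}")

    cols = ["O", "E"] + [c for c in (soil_covariate, air, decile_col) if c] + list(extra_covariates)
    d = data.dropna(subset=[c for c in cols if c in data.columns]).copy()
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    if (d["E"] <= 0).any():
        raise ValueError("all zones in a GLM need E > 0")

    X = pd.DataFrame(index=d.index)
    X["Intercept"] = 1.0
    if soil_covariate:
        X[_soil_label(soil_covariate)] = d[soil_covariate].astype(float)
    dropped: tuple[int, ...] = ()
    if decile_col:
        lv = d[decile_col].astype(int)
        present = [l for l in DECILE_LEVELS if (lv == l).any()]
        dropped = tuple(l for l in DECILE_LEVELS if l not in present)
        for l in present:
            X[f"Decile {l}"] = (lv == l).astype(float)
    if air:
        X[AIR_LABELS.get(air, air)] = d[air].astype(float)
    for c in extra_covariates:
        X[c] = d[c].astype(float)

    if family == "poisson_offset":
        model = sm.GLM(d["O"].astype(float), X, family=sm.families.Poisson(), offset=np.log(d["E"].astype(float)))
        response = "observed counts (offset log E)"
    else:
        sir = d["O"].astype(float) / d["E"].astype(float)
        model = sm.GLM(sir, X, family=sm.families.Gaussian(sm.families.links.Log()))
        response = "SIR"
    res = model.fit(maxiter=200)
    table = pd.DataFrame(
        {"term": X.columns, "estimate": res.params.to_numpy(), "se": res.bse.to_numpy(), "p_value": res.pvalues.to_numpy()}
    )
    return GLMFit(
        response=response,
        family=family,
        table=table,
        aic=float(res.aic),
        n=len(d),
        converged=bool(res.converged),
        dropped_levels=dropped,
        result=res,
    )


def _soil_label(cov: str) -> str:
    if cov == "soil_index":
        return "Soil metal index"
    if cov.startswith("gm_"):
        return f"Soil {cov[3:]} geometric mean"
    return cov


def select_model(fits: Sequence[GLMFit]) -> GLMFit:
    """Minimum-AIC fit among converged candidates; ties -> fewer parameters."""
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no converged candidate models")
    best_aic = min(f.aic for f in ok)
    tied = [f for f in ok if f.aic <= best_aic + 1e-9]
    return min(tied, key=lambda f: f.n_params)
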