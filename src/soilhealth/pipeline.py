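"""End-to-end analysis: files in, correlation tables and GLM fits out.

``run_analysis`` reproduces the full analytic chain on any study
directory (synthetic or real data in the documented layout): assign soil
points to zones, take zone geometric means, build the composite
soil-metal index, standardise admissions into SIRs, reconstruct the
health-free deprivation deciles, then screen pairwise correlations and
fit the log-link GLM of SIRs on one soil covariate, the decile factor
and one air pollutant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import aggregate as agg
from . import deprivation as depr
from . import index as idx
from . import models
from . import standardise as std
from .io import read_study_dir

#: Variables of the environment-health-deprivation correlation screen.
SCREEN_VARIABLES = ("SIR", "soil_index", "decile", "no2", "pm10")


@dataclass
class AnalysisResult:
    zone_table: pd.DataFrame
    zone_summary: pd.DataFrame
    sample_index: pd.DataFrame
    sir: pd.DataFrame
    metal_correlations: pd.DataFrame
    correlations: pd.DataFrame
    glm: models.GLMFit
    soil_covariate: str
    scorers: dict


def build_zone_table(data: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, dict]:
    """Merge every per-zone quantity into one analysis frame."""
    soil = agg.assign_zones(data["soil"], data["zones"])
    summary = agg.summarise_zones(soil)
    scorers = idx.fit_scorers(soil)
    sample_index = idx.score_samples(soil, scorers)
    soil_index = idx.zone_mean_index(sample_index)

    dz = depr.datazone_deprivation(data["deprivation"][["datazone_id", "zone_id", *depr.DOMAINS]])
    zone_decile = depr.zone_median_decile(dz)

    if "cases_by_stratum" in data:
        rates = std.derive_standard_rates(data["population"], data["cases_by_stratum"])
    else:
        raise ValueError(
            "cases_by_stratum.csv required to derive internal standard rates "
            "(or supply external rates to standardise.compute_sir directly)"
        )
    sir = std.compute_sir(data["population"], rates, data["cases"])

    table = data["zones"][["zone_id", "urban"]].copy()
    table = table.merge(summary.reset_index(), on="zone_id", how="left")
    table["soil_index"] = soil_index.reindex(table["zone_id"]).to_numpy()
    table["decile"] = zone_decile.reindex(table["zone_id"]).to_numpy()
    table = table.merge(data["air"], on="zone_id", how="left")
    table = table.merge(sir, on="zone_id", how="left")
    aux = {"scorers": scorers, "sample_index": sample_index, "zone_summary": summary, "sir": sir, "soil": soil}
    return table, aux


def run_analysis(
    indir: str | Path,
    outdir: str | Path | None = None,
    soil_covariate: str = "index",
    air: str = "no2",
    family: str = "poisson_offset",
    seed: int | None = None,
) -> AnalysisResult:
    """Analyse a study directory; optionally write the output tables.

    ``soil_covariate`` is ``"index"`` (composite soil-metal index) or an
    element symbol (its zone geometric mean enters instead).
    """
    data = read_study_dir(indir)
    table, aux = build_zone_table(data)

    metal_vars = [f"gm_{el}" for el in agg.ELEMENTS]
    metal_corr = models.correlation_matrix(table, metal_vars)
    screen_corr = models.correlation_matrix(table, list(SCREEN_VARIABLES))

    cov = "soil_index" if soil_covariate == "index" else f"gm_{soil_covariate}"
    if soil_covariate != "index" and soil_covariate not in agg.ELEMENTS:
        raise ValueError(f"unknown soil covariate {soil_covariate!r}")
    fit = models.fit_sir_glm(table, soil_covariate=cov, air=air, family=family)

    result = AnalysisResult(
        zone_table=table,
        zone_summary=aux["zone_summary"],
        sample_index=aux["sample_index"],
        sir=aux["sir"],
        metal_correlations=metal_corr,
        correlations=screen_corr,
        glm=fit,
        soil_covariate=soil_covariate,
        scorers=aux["scorers"],
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir), indir, air, family, seed)
    return result


def _glm_table_with_aic(fit: models.GLMFit) -> pd.DataFrame:
    aic_row = pd.DataFrame(
        [{"term": "AIC", "estimate": fit.aic, "se": float("nan"), "p_value": float("nan")}]
    )
    return pd.concat([fit.table, aic_row], ignore_index=True)


def _config_hash(indir: str | Path) -> str:
    truth = Path(indir) / "truth.json"
    if truth.exists():
        return hashlib.sha256(truth.read_bytes()).hexdigest()[:12]
    return "n/a"


def _fmt_matrix(corr: pd.DataFrame, variables: list[str]) -> str:
    """Markdown lower-triangular matrix with significant entries starred."""
    lut = {(r.var_a, r.var_b): r for r in corr.itertuples(index=False)}
    lines = ["| | " + " | ".join(variables[:-1]) + " |", "|" + "---|" * len(variables)]
    for i, vb in enumerate(variables[1:], start=1):
        cells = []
        for va in variables[:-1]:
            r = lut.get((va, vb))
            if r is None:
                cells.append("")
            else:
                cells.append(f"{r.r:.3f}{'*' if r.significant else ''}")
        lines.append("| " + vb + " | " + " | ".join(cells) + " |")
    return "\n".join(lines)


def _fmt_glm(table: pd.DataFrame) -> str:
    lines = ["| Coefficient | Estimate | SE | p value |", "|---|---|---|---|"]
    for row in table.itertuples(index=False):
        lines.append(f"| {row.term} | {row.estimate:.4f} | {row.se:.4f} | {row.p_value:.4f} |")
    return "\n".join(lines)


def _write_outputs(result: AnalysisResult, out: Path, indir, air: str, family: str, seed) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.zone_table.to_csv(out / "zone_summary.csv", index=False)
    result.sample_index.to_csv(out / "sample_index.csv", index=False)
    result.sir.to_csv(out / "sir.csv", index=False)
    result.metal_correlations.to_csv(out / "correlations_metals.csv", index=False)
    result.correlations.to_csv(out / "correlations.csv", index=False)
    _glm_table_with_aic(result.glm).to_csv(out / f"glm_{result.soil_covariate}.csv", index=False)
    idx.export_scorers(result.scorers, out / "scorers.json")

    n = result.glm.n
    rc = result.correlations["critical_r"].iloc[0]
    lines = [
        "# Small-area soil-health analysis report",
        "",
        f"- input: `{indir}`  (config hash {_config_hash(indir)})",
        f"- seed: {seed if seed is not None else 'n/a'}",
        f"- zones analysed (GLM): n = {n}; correlation screen n = {result.correlations['n'].iloc[0]}",
        f"- 5% critical |r| at that n: {rc:.3f}  (starred entries exceed it)",
        "",
        "## Zone metal geometric-mean correlations",
        "",
        _fmt_matrix(result.metal_correlations, [f"gm_{el}" for el in agg.ELEMENTS]),
        "",
        "## Environment, health and deprivation correlations",
        "",
        _fmt_matrix(result.correlations, list(SCREEN_VARIABLES)),
        "",
        f"## GLM of respiratory SIRs ({family}, soil covariate: {result.soil_covariate}, air: {air})",
        "",
        _fmt_glm(result.glm.table),
        "",
        f"AIC {result.glm.aic:.2f}",
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))
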