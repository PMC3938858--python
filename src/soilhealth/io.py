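"""Plain-text study I/O: CSV tables and GeoJSON zone geometries.

File layout written by ``simulate`` and consumed by ``run``:

- ``soil.csv``        sample_id, x, y, zone_id, As..Zn, K
- ``zones.geojson``   FeatureCollection of zone polygons (zone_id, urban)
- ``air.csv``         zone_id, no2, pm10 (ug/m3)
- ``population.csv``  zone_id, age_band, sex, pop
- ``cases.csv``       zone_id, cases
- ``cases_by_stratum.csv``  age_band, sex, cases (study totals)
- ``deprivation.csv`` datazone_id, zone_id, seven domain ranks
- ``truth.json``      generating parameters (synthetic studies only)

Missing values are encoded as empty fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synth import SyntheticStudy


def zones_to_geojson(zones: pd.DataFrame) -> dict:
    feats = []
    for row in zones.itertuples(index=False):
        ring = [
            [row.x0, row.y0],
            [row.x1, row.y0],
            [row.x1, row.y1],
            [row.x0, row.y1],
            [row.x0, row.y0],
        ]
        feats.append(
            {
                "type": "Feature",
                "properties": {"zone_id": int(row.zone_id), "urban": bool(row.urban)},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def read_zones_geojson(path: str | Path) -> pd.DataFrame:
    """Zone table from GeoJSON; rectangles come back as extent columns.

    Axis-aligned rectangular zones yield ``x0, y0, x1, y1`` (so point
    assignment uses the exact half-open convention); anything else keeps
    a shapely ``geometry`` column.
    """
    import shapely
    from shapely.geometry import shape

    gj = json.loads(Path(path).read_text())
    rows, geoms = [], []
    for f in gj["features"]:
        g = shape(f["geometry"])
        rows.append({"zone_id": int(f["properties"]["zone_id"]), "urban": bool(f["properties"].get("urban", False))})
        geoms.append(g)
    zones = pd.DataFrame(rows)
    if all(g.equals(shapely.box(*g.bounds)) for g in geoms):
        b = pd.DataFrame([g.bounds for g in geoms], columns=["x0", "y0", "x1", "y1"])
        zones = pd.concat([zones, b], axis=1)
    else:
        zones["geometry"] = geoms
    return zones


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.soil.drop(columns=["urban"], errors="ignore").to_csv(out / "soil.csv", index=False)
    (out / "zones.geojson").write_text(json.dumps(zones_to_geojson(study.zones)))
    study.air.to_csv(out / "air.csv", index=False)
    study.population.to_csv(out / "population.csv", index=False)
    study.cases.to_csv(out / "cases.csv", index=False)
    study.cases_by_stratum.to_csv(out / "cases_by_stratum.csv", index=False)
    study.deprivation_domains.to_csv(out / "deprivation.csv", index=False)
    (out / "truth.json").write_text(
        json.dumps({**study.truth, "config": study.config.to_dict()}, indent=2, default=str)
    )
    return out


def read_study_dir(indir: str | Path) -> dict[str, pd.DataFrame]:
    d = Path(indir)
    data = {
        "zones": read_zones_geojson(d / "zones.geojson"),
        "soil": pd.read_csv(d / "soil.csv"),
        "air": pd.read_csv(d / "air.csv"),
        "population": pd.read_csv(d / "population.csv"),
        "cases": pd.read_csv(d / "cases.csv"),
        "deprivation": pd.read_csv(d / "deprivation.csv"),
    }
    cbs = d / "cases_by_stratum.csv"
    if cbs.exists():
        data["cases_by_stratum"] = pd.read_csv(cbs)
    return data
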