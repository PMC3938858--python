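"""Point-to-zone aggregation of soil geochemistry.

Soil surveys deliver point samples; the analysis unit is the reporting
zone (an intermediate-geography area of roughly 4,000 households).  This
module assigns each sample point to the zone containing it and reduces a
zone's samples to per-element geometric means — the appropriate average
for positively skewed concentration data.

Zones may be supplied either as axis-aligned rectangles (columns
``x0, y0, x1, y1``; containment uses the half-open convention
``[x0, x1) x [y0, y1)`` so shared edges belong to exactly one zone) or as
arbitrary polygons in a ``geometry`` column of shapely objects (boundary
points go to the lowest containing ``zone_id``).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Metals/metalloids of potential health concern carried through the pipeline.
ALL_METALS = ("As", "Cr", "Cu", "Ni", "Pb", "Se", "Zn")
#: Generally non-harmful control element (wt%), used as a negative control.
CONTROL_ELEMENT = "K"
ELEMENTS = ALL_METALS + (CONTROL_ELEMENT,)

#: Sentinel zone id for samples falling outside every zone.
UNASSIGNED = -1


class GeometryError(ValueError):
    """Raised when zone geometries overlap or are otherwise invalid."""


def _rect_zones(zones: pd.DataFrame) -> bool:
    return {"x0", "y0", "x1", "y1"}.issubset(zones.columns)


def assign_zones(samples: pd.DataFrame, zones: pd.DataFrame) -> pd.DataFrame:
    """Attach to each sample the id of the zone containing it.

    Returns a copy of ``samples`` with a ``zone_id`` column; samples outside
    every zone receive :data:`UNASSIGNED`.  Overlapping zone interiors raise
    :class:`GeometryError`.
    """
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample table")
    out = samples.copy()
    x = samples["x"].to_numpy(dtype=float)
    y = samples["y"].to_numpy(dtype=float)
    assigned = np.full(len(samples), UNASSIGNED, dtype=np.int64)

    if _rect_zones(zones):
        hit = np.zeros(len(samples), dtype=bool)
        for zid, x0, y0, x1, y1 in zones[["zone_id", "x0", "y0", "x1", "y1"]].itertuples(index=False):
            m = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
            if np.any(m & hit):
                raise GeometryError(f"zone {zid} overlaps a previously assigned zone")
            assigned[m] = zid
            hit |= m
    else:
        import shapely

        geoms = np.asarray(zones["geometry"].to_numpy())
        zone_ids = zones["zone_id"].to_numpy()
        order = np.argsort(zone_ids, kind="stable")
        geoms, zone_ids = geoms[order], zone_ids[order]
        pts = shapely.points(x, y)
        tree = shapely.STRtree(geoms)
        pt_idx, geom_idx = tree.query(pts, predicate="covered_by")
        # interior double-containment means overlapping zones
        pi, gi = tree.query(pts, predicate="within")
        if len(pi) and np.any(np.bincount(pi, minlength=len(pts)) > 1):
            raise GeometryError("zone polygons overlap")
        # boundary points may be covered by several zones: lowest zone_id wins
        for p, g in zip(pt_idx, geom_idx):
            if assigned[p] == UNASSIGNED or zone_ids[g] < assigned[p]:
                assigned[p] = zone_ids[g]

    out["zone_id"] = assigned
    return out


def geometric_mean(values: Iterable[float]) -> float:
    """exp of the mean log — the average used for skewed concentrations.

    Empty input yields ``nan`` (missing); non-positive values are a domain
    error.  Always ≤ the arithmetic mean (AM–GM).
    """
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if v.size == 0:
        return float("nan")
    if np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise ValueError("geometric mean requires strictly positive finite values")
    return float(np.exp(np.mean(np.log(v))))


def summarise_zones(
    samples: pd.DataFrame,
    elements: tuple[str, ...] = ELEMENTS,
    detection_limits: Mapping[str, float] | None = None,
    bdl_policy: str = "halve",
) -> pd.DataFrame:
    """Per-zone geometric means and log-scale moments of each element.

    Parameters
    ----------
    samples
        Assigned sample table (``zone_id`` column present); unassigned
        samples are ignored.
    detection_limits
        Optional per-element detection limit.  Values below the limit are
        substituted at half the limit (``bdl_policy="halve"``, default) or
        dropped (``"exclude"``) before averaging.
    Returns a frame indexed by ``zone_id`` with ``n_samples`` and, per
    element, ``gm_<el>``, ``logmean_<el>`` and ``logsd_<el>``.  Zones with
    no samples simply do not appear (their summaries are missing).
    """
    if "zone_id" not in samples.columns:
        raise ValueError("samples must be assigned to zones first")
    if bdl_policy not in ("halve", "exclude"):
        raise ValueError(f"unknown below-detection policy: {bdl_policy!r}")
    df = samples[samples["zone_id"] != UNASSIGNED].copy()
    for el in elements:
        col = df[el].to_numpy(dtype=float)
        if detection_limits and el in detection_limits:
            dl = float(detection_limits[el])
            below = col < dl
            if bdl_policy == "halve":
                col = np.where(below, dl / 2.0, col)
            else:
                col = np.where(below, np.nan, col)
        if np.any(col[~np.isnan(col)] <= 0):
            raise ValueError(f"non-positive concentration for element {el}")
        df[f"_log_{el}"] = np.log(col)

    g = df.groupby("zone_id")
    out = pd.DataFrame({"n_samples": g.size()})
    for el in elements:
        lg = g[f"_log_{el}"]
        out[f"gm_{el}"] = np.exp(lg.mean())
        out[f"logmean_{el}"] = lg.mean()
        out[f"logsd_{el}"] = lg.std(ddof=1)
    out.index.name = "zone_id"
    return out
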