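"""Prediction grids and phenology surfaces.

An equally spaced point grid ("50 km" is a physical distance, not a degree
step) is laid out in a spherical azimuthal-equidistant plane centred on the
study extent and back-projected to longitude/latitude.  A fitted model is
then evaluated at each grid point and the surface summarised.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SYNCHRONY80_FACTOR, FittedICLS, predict

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


@dataclass
class GridSpec:
    spacing_km: float = 50.0
    extent: tuple = (-10.0, 30.0, 40.0, 65.0)  # lon_min, lon_max, lat_min, lat_max

    def __post_init__(self) -> None:
        if self.spacing_km <= 0:
            raise ValueError("spacing_km must be positive")
        lon0, lon1, lat0, lat1 = self.extent
        if lon1 <= lon0 or lat1 <= lat0:
            raise ValueError("degenerate extent")


def aeqd_forward(lon, lat, lon0, lat0, radius=EARTH_RADIUS_KM):
    """Spherical azimuthal equidistant projection; returns (x_km, y_km)."""
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    dlam = lam - lam0
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
    c = np.arccos(np.clip(cosc, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(c), 1.0)
    x = radius * k * np.cos(phi) * np.sin(dlam)
    y = radius * k * (np.cos(phi0) * np.sin(phi)
                      - np.sin(phi0) * np.cos(phi) * np.cos(dlam))
    return x, y


def aeqd_inverse(x, y, lon0, lat0, radius=EARTH_RADIUS_KM):
    """Inverse of :func:`aeqd_forward`; returns (lon, lat) in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    rho = np.hypot(x, y)
    c = rho / radius
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(
            rho > 1e-12,
            np.arcsin(np.cos(c) * np.sin(phi0) + y * np.sin(c) * np.cos(phi0)
                      / np.where(rho > 1e-12, rho, 1.0)),
            phi0,
        )
        lam = lam0 + np.arctan2(
            x * np.sin(c),
            rho * np.cos(c) * np.cos(phi0) - y * np.sin(c) * np.sin(phi0),
        )
    return np.degrees(lam), np.degrees(phi)


def make_grid(spec: GridSpec, mask=None) -> pd.DataFrame:
    """Equally spaced points over the extent, optionally clipped to a polygon.

    The extent boundary is projected into an azimuthal-equidistant plane
    centred on the extent midpoint; points are laid out on a symmetric
    square lattice at ``spacing_km`` covering the projected bounding box and
    back-projected.  ``mask`` is a shapely geometry (or GeoJSON-like
    mapping) in lon/lat; points outside it are dropped.
    """
    lon0 = 0.5 * (spec.extent[0] + spec.extent[1])
    lat0 = 0.5 * (spec.extent[2] + spec.extent[3])
    # densified boundary of the lon/lat rectangle
    lons = np.linspace(spec.extent[0], spec.extent[1], 41)
    lats = np.linspace(spec.extent[2], spec.extent[3], 41)
    blon = np.concatenate([lons, np.full(41, spec.extent[1]), lons[::-1],
                           np.full(41, spec.extent[0])])
    blat = np.concatenate([np.full(41, spec.extent[2]), lats,
                           np.full(41, spec.extent[3]), lats[::-1]])
    bx, by = aeqd_forward(blon, blat, lon0, lat0)

    def _axis(vmin, vmax):
        span = vmax - vmin
        n = int(np.floor(span / spec.spacing_km + 1e-9)) + 1
        start = 0.5 * (vmin + vmax) - 0.5 * (n - 1) * spec.spacing_km
        return start + spec.spacing_km * np.arange(n)

    xs = _axis(bx.min(), bx.max())
    ys = _axis(by.min(), by.max())
    gx, gy = np.meshgrid(xs, ys)
    lon, lat = aeqd_inverse(gx.ravel(), gy.ravel(), lon0, lat0)
    grid = pd.DataFrame({"lon": lon, "lat": lat,
                         "x_km": gx.ravel(), "y_km": gy.ravel()})
    if mask is not None:
        from shapely.geometry import Point, shape
        from shapely.prepared import prep
        geom = mask if hasattr(mask, "contains") else shape(mask)
        prepared = prep(geom)
        keep = [prepared.contains(Point(lo, la)) for lo, la in zip(grid.lon, grid.lat)]
        grid = grid[keep].reset_index(drop=True)
        if grid.empty:
            raise ValueError("no grid points remain after masking")
    grid.insert(0, "point_id", np.arange(len(grid)))
    return grid


@dataclass
class Surface:
    points: pd.DataFrame        # per-point lon/lat/covariates/mu/sigma/synchrony80
    summary: pd.DataFrame       # min/mean/max/std for mu and synchrony80


def predict_surface(fit: FittedICLS, grid: pd.DataFrame,
                    standardization: pd.DataFrame | None = None) -> Surface:
    """Evaluate a fitted model at every grid point (random effects at zero).

    ``standardization`` (or the constants stored on the fit) converts the
    grid's raw covariates to the z-scored scale of the fitting table.
    """
    consts = standardization if standardization is not None else fit.standardization
    needed = [c for c in list(fit.beta.index) + list(fit.gamma.index)
              if c != "intercept" and not c.startswith("region_")]
    missing = sorted(set(needed) - set(grid.columns))
    if missing:
        raise ValueError(f"grid is missing covariate columns: {missing}")
    work = grid.copy()
    if consts is not None:
        for _, row in consts.iterrows():
            if row["covariate"] in work.columns:
                work[row["covariate"]] = ((work[row["covariate"]] - row["mean"])
                                          / row["sd"])
    mus, sigmas = np.empty(len(work)), np.empty(len(work))
    rows = work.to_dict("records")
    for i, r in enumerate(rows):
        p = predict(fit, r)
        mus[i], sigmas[i] = p.mu, p.sigma
    pts = grid.copy()
    pts["mu"] = mus
    pts["sigma"] = sigmas
    pts["synchrony80"] = pts["sigma"] * SYNCHRONY80_FACTOR
    summ = pd.DataFrame(
        [{"quantity": q, "min": pts[q].min(), "mean": pts[q].mean(),
          "max": pts[q].max(), "std": pts[q].std(ddof=0)}
         for q in ("mu", "synchrony80")]
    )
    return Surface(points=pts, summary=summ)


def elevation_classes(records: pd.DataFrame, min_records: int = 10) -> pd.DataFrame:
    """Three representative elevations per region from the birth locations.

    lowest = 10th percentile, average = mean elevation of the records
    between the 45th and 55th percentiles, highest = 90th percentile
    (linear-interpolation percentiles throughout).  Regions with fewer than
    ``min_records`` locations are skipped with a warning.
    """
    rows = []
    for region, grp in records.groupby("region_id"):
        e = grp["elevation"].to_numpy(float)
        if len(e) < min_records:
            warnings.warn(f"region {region}: only {len(e)} records, skipped")
            continue
        p45, p55 = np.percentile(e, [45, 55])
        mid = e[(e >= p45) & (e <= p55)]
        rows.append({
            "region_id": region,
            "lowest": float(np.percentile(e, 10)),
            "average": float(mid.mean()) if mid.size else float(np.percentile(e, 50)),
            "highest": float(np.percentile(e, 90)),
        })
    return pd.DataFrame(rows)


def surface_to_geojson(surface: Surface) -> str:
    feats = []
    for _, r in surface.points.iterrows():
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [r["lon"], r["lat"]]},
            "properties": {"mu": r["mu"], "sigma": r["sigma"],
                           "synchrony80": r["synchrony80"]},
        })
    return json.dumps({"type": "FeatureCollection", "features": feats})
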