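"""Genetic landscape shape interpolation.

Localities are connected by a Delaunay triangulation; each edge carries
the mean genetic distance between the individuals of its two endpoint
localities and the great-circle distance between them.  Genetic distance
is regressed on geographic distance (recommended when geographic
distances between connected localities vary strongly), and the residuals,
attached to edge midpoints, are interpolated by inverse-distance
weighting onto a regular lat/lon grid (default 0.05 degree cells,
alpha = 1), masked to the convex hull of the localities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .seqio import DistanceMatrix, SampleMetadata

__all__ = [
    "ConnectivityNetwork",
    "LandscapeSurface",
    "haversine_km",
    "build_connectivity",
    "residual_distances",
    "interpolate_surface",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def _gc_midpoint(lat1, lon1, lat2, lon2) -> tuple[float, float]:
    """Great-circle midpoint in decimal degrees."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    l1, l2 = math.radians(lon1), math.radians(lon2)
    bx = math.cos(p2) * math.cos(l2 - l1)
    by = math.cos(p2) * math.sin(l2 - l1)
    lat = math.atan2(
        math.sin(p1) + math.sin(p2), math.sqrt((math.cos(p1) + bx) ** 2 + by**2)
    )
    lon = l1 + math.atan2(by, math.cos(p1) + bx)
    return math.degrees(lat), math.degrees(lon)


@dataclass
class ConnectivityNetwork:
    localities: pd.DataFrame         # locality, lat, lon
    edges: pd.DataFrame              # loc_a, loc_b, genetic, geographic_km, mid_lat, mid_lon

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class LandscapeSurface:
    lat0: float                      # grid origin (min lat)
    lon0: float                      # grid origin (min lon)
    cell: float                      # cell size, degrees
    values: np.ndarray               # (n_lat, n_lon); NaN where masked
    mask: np.ndarray                 # True where outside the interpolation domain

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray]:
        n_lat, n_lon = self.values.shape
        return (
            self.lat0 + self.cell * np.arange(n_lat),
            self.lon0 + self.cell * np.arange(n_lon),
        )

    def to_frame(self) -> pd.DataFrame:
        lats, lons = self.grid_coords()
        rows = []
        for i, la in enumerate(lats):
            for j, lo in enumerate(lons):
                if not self.mask[i, j]:
                    rows.append({"lat": la, "lon": lo, "value": self.values[i, j]})
        return pd.DataFrame(rows)

    def to_ascii_grid(self, path, nodata: float = -9999.0) -> None:
        """ESRI ASCII grid (rows from north to south)."""
        n_lat, n_lon = self.values.shape
        vals = np.where(self.mask, nodata, self.values)
        with open(path, "w") as fh:
            fh.write(f"ncols {n_lon}\nnrows {n_lat}\n")
            fh.write(f"xllcorner {self.lon0}\nyllcorner {self.lat0}\n")
            fh.write(f"cellsize {self.cell}\nNODATA_value {nodata}\n")
            for row in vals[::-1]:
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def build_connectivity(
    meta: SampleMetadata, d: DistanceMatrix, planar: bool = False
) -> ConnectivityNetwork:
    """Delaunay connectivity network over localities with per-edge distances.

    Per-edge genetic distance is the mean pairwise genetic distance between
    individuals of the two endpoint localities; geographic distance is the
    great-circle distance in km (Euclidean degrees with ``planar=True``).
    """
    locs = meta.localities()
    if len(locs) < 3:
        raise ValueError(
            "need >= 3 localities for a triangulation (or connect all pairs manually)"
        )
    pts = locs[["lon", "lat"]].to_numpy(dtype=float)
    try:
        tri = Delaunay(pts)
    except QhullError as err:
        raise ValueError(
            "localities are collinear; a complete-graph fallback over all pairs is "
            "required for such layouts"
        ) from err

    id_index = {sid: i for i, sid in enumerate(d.ids)}
    members = {
        loc: [id_index[s] for s in meta.table.loc[meta.table["locality"] == loc, "id"]]
        for loc in locs["locality"]
    }
    for loc, mem in members.items():
        if not mem:
            raise ValueError(f"locality without individuals: {loc}")

    edge_set = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                edge_set.add(tuple(sorted((simplex[a], simplex[b]))))

    rows = []
    for ia, ib in sorted(edge_set):
        la, lb = locs["locality"].iloc[ia], locs["locality"].iloc[ib]
        lat_a, lon_a = locs["lat"].iloc[ia], locs["lon"].iloc[ia]
        lat_b, lon_b = locs["lat"].iloc[ib], locs["lon"].iloc[ib]
        sub = d.values[np.ix_(members[la], members[lb])]
        gen = float(sub.mean())
        if planar:
            geo = math.hypot(lat_b - lat_a, lon_b - lon_a)
            mid = ((lat_a + lat_b) / 2, (lon_a + lon_b) / 2)
        else:
            geo = haversine_km(lat_a, lon_a, lat_b, lon_b)
            mid = _gc_midpoint(lat_a, lon_a, lat_b, lon_b)
        rows.append(
            {
                "loc_a": la,
                "loc_b": lb,
                "genetic": gen,
                "geographic_km": geo,
                "mid_lat": mid[0],
                "mid_lon": mid[1],
            }
        )
    return ConnectivityNetwork(localities=locs, edges=pd.DataFrame(rows))


def residual_distances(net: ConnectivityNetwork) -> pd.DataFrame:
    """OLS residuals of edge genetic distance on edge geographic distance.

    Returns the edge table with ``fitted`` and ``residual`` columns;
    residuals (observed - fitted) sum to zero by the intercept property.
    """
    if net.n_edges < 3:
        raise ValueError("need >= 3 edges for the regression")
    x = net.edges["geographic_km"].to_numpy(dtype=float)
    y = net.edges["genetic"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in geographic distances")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    out = net.edges.copy()
    out["fitted"] = fitted
    out["residual"] = y - fitted
    return out


def interpolate_surface(
    mid_lats,
    mid_lons,
    values,
    cell: float = 0.05,
    alpha: float = 1.0,
    hull_points: np.ndarray | None = None,
    planar: bool = False,
) -> LandscapeSurface:
    """Inverse-distance-weighted surface of midpoint values on a lat/lon grid.

    Z(g) = sum z_i w_i / sum w_i with w_i = 1 / dist(g, midpoint_i)^alpha;
    a grid node coinciding with a midpoint takes that midpoint's value.
    ``hull_points`` ((lat, lon) rows, e.g. the localities) defines the
    interpolation domain as their convex hull; without it the bounding box
    of the midpoints is used.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    mid_lats = np.asarray(mid_lats, dtype=float)
    mid_lons = np.asarray(mid_lons, dtype=float)
    values = np.asarray(values, dtype=float)
    if mid_lats.size == 0:
        raise ValueError("need >= 1 midpoint")

    if hull_points is not None:
        hp = np.asarray(hull_points, dtype=float)
        lat0, lon0 = hp[:, 0].min(), hp[:, 1].min()
        lat1, lon1 = hp[:, 0].max(), hp[:, 1].max()
    else:
        lat0, lon0 = mid_lats.min(), mid_lons.min()
        lat1, lon1 = mid_lats.max(), mid_lons.max()
    n_lat = max(int(math.ceil((lat1 - lat0) / cell)) + 1, 1)
    n_lon = max(int(math.ceil((lon1 - lon0) / cell)) + 1, 1)
    lats = lat0 + cell * np.arange(n_lat)
    lons = lon0 + cell * np.arange(n_lon)

    hull = None
    if hull_points is not None and len(hull_points) >= 3:
        try:
            hull = Delaunay(np.asarray(hull_points, dtype=float)[:, ::-1])  # (lon, lat)
        except QhullError:
            hull = None

    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    if hull is not None:
        inside = hull.find_simplex(np.column_stack([glon.ravel(), glat.ravel()])) >= 0
        mask = ~inside.reshape(glat.shape)
    else:
        mask = np.zeros(glat.shape, dtype=bool)

    out = np.full(glat.shape, np.nan)
    for i in range(n_lat):
        for j in range(n_lon):
            if mask[i, j]:
                continue
            if planar:
                dist = np.hypot(mid_lats - glat[i, j], mid_lons - glon[i, j])
            else:
                dist = np.array(
                    [
                        haversine_km(glat[i, j], glon[i, j], mla, mlo)
                        for mla, mlo in zip(mid_lats, mid_lons)
                    ]
                )
            exact = dist < 1e-9
            if exact.any():
                out[i, j] = values[exact][0]
                continue
            w = dist ** (-alpha)
            out[i, j] = float(np.sum(values * w) / np.sum(w))
    return LandscapeSurface(lat0=float(lat0), lon0=float(lon0), cell=cell, values=out, mask=mask)
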