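"""Seasonal cyclone climatology: density surface, risk region, exposure.

Every retained six-hourly best-track record contributes one unit-weight point,
so storms enter the density in proportion to their lifespans.  Points are
projected to a Lambert azimuthal equal-area plane (spherical form, centred on
the hurricane main development region by default) before a bivariate Gaussian
kernel density estimate is fitted; fitting in an equal-area plane keeps the
kernel isotropic in km rather than in degrees.

The x%-highest-density region (HDR) is the smallest set of grid cells whose
density integral reaches the requested probability mass; its threshold is the
exact cell-mass quantile on the grid and its outline is traced as polygons
and inverse-projected to lon/lat.  The 50% HDR is the "core cyclone area"
against which journey exposure is measured.

Exposure time inside the region uses the fixed-speed crossing-time rule: the
entry instant is the last outside fix's time plus (distance from that fix to
the region boundary along the segment) / mean flight speed, and symmetrically
for exits from the last inside fix.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
from scipy import optimize, signal
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import unary_union
from skimage import measure

from .formats_io import BirdTrack, StormTrack
from .geodesy import DEFAULT_PARAMS, GeoParams, crossing_time, gc_distance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Projection:
    """Spherical Lambert azimuthal equal-area projection, km."""

    center_lat: float = 25.0
    center_lon: float = -60.0
    earth_radius_km: float = DEFAULT_PARAMS.earth_radius_km

    def forward(self, lon, lat):
        lam = np.deg2rad(np.asarray(lon, dtype=float) - self.center_lon)
        phi = np.deg2rad(np.asarray(lat, dtype=float))
        phi0 = math.radians(self.center_lat)
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        k = np.sqrt(2.0 / denom)
        x = self.earth_radius_km * k * np.cos(phi) * np.sin(lam)
        y = self.earth_radius_km * k * (np.cos(phi0) * np.sin(phi)
                                        - np.sin(phi0) * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / self.earth_radius_km
        y = np.asarray(y, dtype=float) / self.earth_radius_km
        phi0 = math.radians(self.center_lat)
        rho = np.hypot(x, y)
        rho_safe = np.where(rho == 0, 1.0, rho)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        phi = np.where(
            rho == 0, phi0,
            np.arcsin(np.clip(np.cos(c) * math.sin(phi0)
                              + y * np.sin(c) * math.cos(phi0) / rho_safe, -1.0, 1.0)))
        lam = np.where(
            rho == 0, 0.0,
            np.arctan2(x * np.sin(c),
                       rho * math.cos(phi0) * np.cos(c) - y * math.sin(phi0) * np.sin(c)))
        lon = np.rad2deg(lam) + self.center_lon
        lat = np.rad2deg(phi)
        return lon, lat


@dataclass
class DensityGrid:
    """Gridded probability density on the equal-area plane (per km^2)."""

    x_centers: np.ndarray        # (nx,) km
    y_centers: np.ndarray        # (ny,) km
    values: np.ndarray           # (ny, nx) density, integrates to 1
    cell_km: float
    bandwidth: np.ndarray        # 2x2 H matrix, km^2
    projection: Projection
    n_points: int

    @property
    def cell_area(self) -> float:
        return self.cell_km ** 2

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.cell_area)

    def density_at(self, x, y):
        """Nearest-cell density lookup (km coordinates)."""
        ix = np.clip(np.rint((np.asarray(x) - self.x_centers[0]) / self.cell_km).astype(int),
                     0, len(self.x_centers) - 1)
        iy = np.clip(np.rint((np.asarray(y) - self.y_centers[0]) / self.cell_km).astype(int),
                     0, len(self.y_centers) - 1)
        return self.values[iy, ix]

    def to_text(self, path) -> None:
        """Plain-text export: JSON header line + rows of density values."""
        header = {
            "cell_km": self.cell_km,
            "x0": float(self.x_centers[0]), "y0": float(self.y_centers[0]),
            "nx": len(self.x_centers), "ny": len(self.y_centers),
            "center_lat": self.projection.center_lat,
            "center_lon": self.projection.center_lon,
            "bandwidth": self.bandwidth.tolist(),
            "n_points": self.n_points,
        }
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            np.savetxt(fh, self.values, fmt="%.8e")


@dataclass
class RiskRegion:
    """Superlevel set of the density holding a stated probability mass."""

    mass_level: float
    density_threshold: float
    polygons: MultiPolygon          # lon/lat
    projected: MultiPolygon         # km, equal-area plane
    projection: Projection
    achieved_mass: float

    def contains(self, lat: float, lon: float) -> bool:
        x, y = self.projection.forward(lon, lat)
        return bool(self.projected.contains(Point(float(x), float(y))))

    def to_geojson(self, path=None) -> dict:
        feats = [{
            "type": "Feature",
            "properties": {"mass_level": self.mass_level,
                           "density_threshold": self.density_threshold},
            "geometry": json.loads(json.dumps(self.polygons.__geo_interface__)),
        }]
        doc = {"type": "FeatureCollection", "features": feats}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(doc, fh)
        return doc


@dataclass
class ExposureRecord:
    bird_id: str
    year: int
    intervals: list[tuple[datetime, datetime]]
    total_days: float
    mode: str = "nonstop"  # or 'grounded'


# ---------------------------------------------------------------------------

def build_storm_points(storms: Sequence[StormTrack]) -> np.ndarray:
    """(n, 2) lon/lat array, one unit-weight row per retained record."""
    rows = [(p.lon, p.lat) for s in storms for p in s.points]
    if not rows:
        raise ValueError("no storm points: season filter removed everything?")
    return np.asarray(rows, dtype=float)


def _normal_reference_H(xy: np.ndarray) -> np.ndarray:
    # normal-scale rule for d=2: H = n^(-1/3) * Sigma
    n = len(xy)
    return np.cov(xy.T) * n ** (-1.0 / 3.0)


def _scv_H(xy: np.ndarray, rng_cap: int = 2500) -> np.ndarray:
    """Smoothed cross-validation choice of H = h^2 * Sigma.

    Minimises the SCV criterion (Gaussian kernels; pilot bandwidth from the
    normal-scale rule).  O(n^2) in the number of points, so inputs beyond
    ``rng_cap`` points are thinned deterministically (every k-th point).
    """
    if len(xy) > rng_cap:
        step = int(np.ceil(len(xy) / rng_cap))
        xy = xy[::step]
    n = len(xy)
    sigma = np.cov(xy.T)
    sig_inv = np.linalg.inv(sigma)
    det_sig = np.linalg.det(sigma)
    diff = xy[:, None, :] - xy[None, :, :]
    # squared Mahalanobis distances under Sigma
    m2 = np.einsum("ijk,kl,ijl->ij", diff, sig_inv, diff)

    g2 = n ** (-1.0 / 3.0)  # pilot multiplier (normal-scale)

    def phi_sum(a: float) -> float:
        # sum over all pairs of N(0, a*Sigma) density at the differences
        return float(np.exp(-m2 / (2.0 * a)).sum()) / (2.0 * np.pi * a * np.sqrt(det_sig))

    def scv(log_h2: float) -> float:
        h2 = np.exp(log_h2)
        term0 = 1.0 / (n * 4.0 * np.pi * h2 * np.sqrt(det_sig))
        dbl = (phi_sum(2 * h2 + 2 * g2) - 2.0 * phi_sum(h2 + 2 * g2) + phi_sum(2 * g2))
        return term0 + dbl / n ** 2

    res = optimize.minimize_scalar(scv, bounds=(np.log(g2) - 4, np.log(g2) + 4),
                                   method="bounded")
    return float(np.exp(res.x)) * sigma


def fit_kde(points_xy: np.ndarray,
            bandwidth_method: str = "plugin",
            bandwidth: np.ndarray | float | None = None,
            cell_km: float = 25.0,
            pad_sigmas: float = 5.0) -> DensityGrid:
    """Bivariate Gaussian KDE on an equal-area grid.

    points_xy : (n, 2) projected coordinates in km.
    bandwidth_method : 'plugin' (normal-scale rule, default), 'scv'
        (smoothed cross-validation), or 'fixed' (pass ``bandwidth``: a 2x2
        matrix in km^2 or a scalar standard deviation in km).
    The estimate is computed by binning the points and convolving with the
    kernel via FFT; the grid is renormalised so its mass is exactly 1.
    """
    xy = np.asarray(points_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(xy)
    if n < 20:
        raise ValueError("need at least 20 points for a stable KDE")
    cov = np.cov(xy.T)
    if np.linalg.det(cov) <= 0:
        raise ValueError("singular point covariance (collinear points); "
                         "KDE bandwidth selection is degenerate")

    if bandwidth_method == "fixed":
        if bandwidth is None:
            raise ValueError("bandwidth_method='fixed' requires a bandwidth")
        H = (np.eye(2) * float(bandwidth) ** 2 if np.isscalar(bandwidth)
             else np.asarray(bandwidth, dtype=float))
    elif bandwidth_method == "plugin":
        H = _normal_reference_H(xy)
    elif bandwidth_method == "scv":
        H = _scv_H(xy)
    else:
        raise ValueError(f"unknown bandwidth_method {bandwidth_method!r}")
    H = np.asarray(H, dtype=float)
    if H.shape != (2, 2) or np.linalg.det(H) <= 0:
        raise ValueError("bandwidth matrix must be 2x2 positive definite")

    sig_max = float(np.sqrt(np.max(np.linalg.eigvalsh(H))))
    pad = pad_sigmas * sig_max
    x0, x1 = xy[:, 0].min() - pad, xy[:, 0].max() + pad
    y0, y1 = xy[:, 1].min() - pad, xy[:, 1].max() + pad
    nx = int(np.ceil((x1 - x0) / cell_km)) + 1
    ny = int(np.ceil((y1 - y0) / cell_km)) + 1
    x_centers = x0 + cell_km * np.arange(nx)
    y_centers = y0 + cell_km * np.arange(ny)

    ix = np.clip(np.rint((xy[:, 0] - x0) / cell_km).astype(int), 0, nx - 1)
    iy = np.clip(np.rint((xy[:, 1] - y0) / cell_km).astype(int), 0, ny - 1)
    counts = np.zeros((ny, nx))
    np.add.at(counts, (iy, ix), 1.0)

    # kernel sampled on cell offsets out to pad_sigmas
    kr = int(np.ceil(pad / cell_km))
    off = cell_km * np.arange(-kr, kr + 1)
    ox, oy = np.meshgrid(off, off)
    Hinv = np.linalg.inv(H)
    q = Hinv[0, 0] * ox ** 2 + 2 * Hinv[0, 1] * ox * oy + Hinv[1, 1] * oy ** 2
    kernel = np.exp(-0.5 * q) / (2.0 * np.pi * np.sqrt(np.linalg.det(H)))

    dens = signal.fftconvolve(counts, kernel, mode="same") / n
    dens = np.clip(dens, 0.0, None)
    dens /= dens.sum() * cell_km ** 2  # exact unit mass on the grid
    return DensityGrid(x_centers, y_centers, dens, cell_km, H,
                       Projection(), n)


def _rings_to_multipolygon(rings: list[np.ndarray]) -> MultiPolygon:
    """Assemble closed rings into polygons with holes by containment parity."""
    polys = []
    for r in rings:
        if len(r) >= 4:
            p = Polygon(r)
            if p.is_valid and p.area > 0:
                polys.append(p)
            elif not p.is_valid:
                p = p.buffer(0)
                if not p.is_empty:
                    polys.append(p if p.geom_type == "Polygon" else max(
                        p.geoms, key=lambda g: g.area))
    if not polys:
        raise ValueError("no closed contour at this level")
    polys.sort(key=lambda p: p.area, reverse=True)
    shells: list[Polygon] = []
    holes: list[Polygon] = []
    for p in polys:
        depth = sum(1 for q in polys if q is not p and q.area > p.area
                    and q.contains(p.representative_point()))
        (shells if depth % 2 == 0 else holes).append(p)
    geom = unary_union(shells)
    for h in holes:
        geom = geom.difference(h)
    if geom.geom_type == "Polygon":
        geom = MultiPolygon([geom])
    return geom


def hdr_region(grid: DensityGrid, mass: float = 0.5) -> RiskRegion:
    """Highest-density region holding ``mass`` of the probability.

    The threshold is the largest density t such that the integral over cells
    with density >= t reaches ``mass`` (exact cell-mass quantile on the
    grid).  The superlevel set's outline is traced with marching squares and
    returned both in the projected plane and inverse-projected to lon/lat.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    cell_mass = grid.values * grid.cell_area
    order = np.argsort(grid.values, axis=None)[::-1]
    csum = np.cumsum(cell_mass.ravel()[order])
    k = int(np.searchsorted(csum, mass))
    if k >= order.size:
        raise ValueError("requested mass unreachable on this grid; "
                         "refit with a finer or wider grid")
    threshold = float(grid.values.ravel()[order[k]])
    achieved = float(csum[k])

    # pad with zeros so contours touching the frame close
    padded = np.pad(grid.values, 1, mode="constant")
    contours = measure.find_contours(padded, threshold)
    rings_xy = []
    for c in contours:
        iy = c[:, 0] - 1.0
        ix = c[:, 1] - 1.0
        x = grid.x_centers[0] + ix * grid.cell_km
        y = grid.y_centers[0] + iy * grid.cell_km
        rings_xy.append(np.column_stack([x, y]))
    projected = _rings_to_multipolygon(rings_xy)

    rings_ll = []
    for ring in rings_xy:
        lon, lat = grid.projection.inverse(ring[:, 0], ring[:, 1])
        rings_ll.append(np.column_stack([lon, lat]))
    lonlat = _rings_to_multipolygon(rings_ll)
    return RiskRegion(mass, threshold, lonlat, projected, grid.projection, achieved)


def region_from_polygon(poly_ll, mass_level: float = 0.5,
                        projection: Projection | None = None,
                        densify_deg: float = 0.1) -> RiskRegion:
    """Wrap an externally supplied lon/lat polygon as a RiskRegion.

    The boundary is densified before projection so the projected outline
    follows the curved image of the polygon's edges.
    """
    proj = projection or Projection()
    geoms = (poly_ll.geoms if poly_ll.geom_type == "MultiPolygon" else [poly_ll])
    proj_polys = []
    for g in geoms:
        ring = np.asarray(g.exterior.coords)
        dense = [ring[0]]
        for a, b in zip(ring[:-1], ring[1:]):
            steps = max(1, int(np.hypot(*(b - a)) / densify_deg))
            for s in range(1, steps + 1):
                dense.append(a + (b - a) * s / steps)
        dense = np.asarray(dense)
        x, y = proj.forward(dense[:, 0], dense[:, 1])
        proj_polys.append(Polygon(np.column_stack([x, y])))
    lonlat = MultiPolygon(list(geoms))
    return RiskRegion(mass_level, float("nan"), lonlat,
                      MultiPolygon(proj_polys), proj, mass_level)


def exposure_time(track: BirdTrack, region: RiskRegion,
                  params: GeoParams = DEFAULT_PARAMS,
                  mode: str = "nonstop") -> ExposureRecord:
    """Total time a journey spends inside the risk region.

    Fix-level point-in-polygon tests delimit inside runs; each boundary
    crossing is timed with the fixed-speed rule (see module docstring).
    Multiple entries and exits are summed.  A track entirely outside the
    region yields zero days.
    """
    pts = track.points
    if not pts:
        raise ValueError("empty track")
    inside = np.array([region.contains(p.lat, p.lon) for p in pts])
    boundary = region.polygons
    intervals: list[tuple[datetime, datetime]] = []
    entry: datetime | None = None
    for i, p in enumerate(pts):
        if inside[i] and entry is None:
            if i == 0:
                entry = p.timestamp
            else:
                try:
                    entry = crossing_time(pts[i - 1], p, boundary, params)
                except ValueError:
                    entry = p.timestamp  # grazing geometry: fall back to the fix
        elif not inside[i] and entry is not None:
            last_in = pts[i - 1]
            try:
                exit_t = crossing_time(last_in, p, boundary, params)
            except ValueError:
                exit_t = last_in.timestamp
            intervals.append((entry, max(entry, exit_t)))
            entry = None
    if entry is not None:
        intervals.append((entry, pts[-1].timestamp))
    total_days = sum((b - a).total_seconds() for a, b in intervals) / 86400.0
    year = pts[0].timestamp.year
    return ExposureRecord(track.bird_id, year, intervals, total_days, mode)
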