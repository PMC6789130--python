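"""Utilization distributions: projection, bandwidth selection, KDE, contours.

Positions are projected with a Lambert conformal conic (spherical form,
standard parallels 33N/45N, central meridian 5E by default -- the western
Mediterranean / NE Atlantic study region), densities are estimated with a
fixed bivariate Gaussian kernel on a regular km grid (1x1 km default), the
bandwidth matrix comes from a 2-stage unconstrained multivariate plug-in
selector, and percentage contours are the smallest sets of cells (by
descending density) holding the nominal probability mass.

Plug-in selector internals (documented here because only the selector
*family* is standard): the data are pre-sphered with the sample covariance;
6th-order integrated density-derivative functionals are taken from the
normal reference; these feed the asymptotic-MSE pilot bandwidth for
kernel estimation of the 4th-order functionals (odd-order multi-indices
reuse the (2,2) pilot, whose AMSE constant is well-defined); the AMISE
criterion built from the estimated functionals is minimised numerically
over symmetric positive-definite matrices via a log-Cholesky
parametrisation, and the result is back-transformed.  Degenerate scatter
falls back to the bivariate normal-reference matrix n^(-1/3) S with a
warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.signal import fftconvolve

from .geodesy import EARTH_RADIUS_KM

__all__ = [
    "LambertParams",
    "ProjectedPoints",
    "DensityGrid",
    "ContourSet",
    "project",
    "unproject",
    "plugin_bandwidth",
    "normal_reference_bandwidth",
    "kernel_density",
    "contour_levels",
    "write_esri_ascii",
    "contours_to_geojson",
]

DEFAULT_LEVELS = (25, 50, 70, 90)


@dataclass(frozen=True)
class LambertParams:
    """Spherical Lambert conformal conic parameters (degrees)."""

    sp1: float = 33.0
    sp2: float = 45.0
    lon0: float = 5.0
    lat0: float = 39.0


@dataclass
class ProjectedPoints:
    x: np.ndarray  # km
    y: np.ndarray  # km
    params: LambertParams

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def _lcc_constants(p: LambertParams):
    phi1, phi2, lat0 = np.radians([p.sp1, p.sp2, p.lat0])
    if np.isclose(phi1, phi2):
        n = np.sin(phi1)
    else:
        n = np.log(np.cos(phi1) / np.cos(phi2)) / np.log(
            np.tan(np.pi / 4 + phi2 / 2) / np.tan(np.pi / 4 + phi1 / 2)
        )
    f = np.cos(phi1) * np.tan(np.pi / 4 + phi1 / 2) ** n / n
    rho0 = EARTH_RADIUS_KM * f / np.tan(np.pi / 4 + lat0 / 2) ** n
    return n, f, rho0


def project(lon, lat=None, params: LambertParams = LambertParams()) -> ProjectedPoints:
    """Forward Lambert conformal conic: degrees -> km.

    Accepts scalars/arrays, or a fixes DataFrame with lon/lat columns (only
    retained rows are used when a ``retained`` column is present).
    """
    if hasattr(lon, "columns"):  # a fixes DataFrame
        df = lon
        if "retained" in df.columns:
            df = df[df["retained"]]
        lon, lat = df["lon"].to_numpy(float), df["lat"].to_numpy(float)
    lon = np.atleast_1d(np.asarray(lon, float))
    lat = np.atleast_1d(np.asarray(lat, float))
    if lon.size == 0:
        raise ValueError("no points to project")
    if np.any(np.abs(lat) >= 90.0):
        raise ValueError("latitude at projection singularity")
    n, f, rho0 = _lcc_constants(params)
    phi = np.radians(lat)
    rho = EARTH_RADIUS_KM * f / np.tan(np.pi / 4 + phi / 2) ** n
    theta = n * np.radians(lon - params.lon0)
    return ProjectedPoints(rho * np.sin(theta), rho0 - rho * np.cos(theta), params)


def unproject(x, y, params: LambertParams = LambertParams()):
    """Inverse Lambert conformal conic: km -> (lon, lat) degrees."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, f, rho0 = _lcc_constants(params)
    rho = np.sign(n) * np.hypot(x, rho0 - y)
    theta = np.arctan2(x, rho0 - y)
    lon = params.lon0 + np.degrees(theta / n)
    phi = 2.0 * np.arctan((EARTH_RADIUS_KM * f / rho) ** (1.0 / n)) - np.pi / 2
    return lon, np.degrees(phi)


# ---------------------------------------------------------------------------
# bandwidth selection


def _phi_deriv0(m: int, sigma: float = 1.0) -> float:
    """m-th derivative of the N(0, sigma^2) density at 0."""
    if m % 2:
        return 0.0
    k = m // 2
    dfact = 1.0
    for i in range(m - 1, 0, -2):
        dfact *= i
    return (-1) ** k * dfact * sigma ** (-(m + 1)) / np.sqrt(2 * np.pi)


def _psi_normal(r: tuple[int, int]) -> float:
    # integral of f^(r) f for f = N(0, I): equals phi_{2I}^(r)(0)
    return _phi_deriv0(r[0], np.sqrt(2)) * _phi_deriv0(r[1], np.sqrt(2))


def _hermite(m: int, u: np.ndarray) -> np.ndarray:
    """Probabilists' Hermite polynomial He_m(u)."""
    h0 = np.ones_like(u)
    if m == 0:
        return h0
    h1 = u
    for k in range(1, m):
        h0, h1 = h1, u * h1 - k * h0
    return h1


def _psi_hat(xs: np.ndarray, g: float, r: tuple[int, int], chunk: int = 256) -> float:
    """Kernel estimate of the order-r integrated density-derivative
    functional with spherical pilot ``g`` (all pairs, including a == b)."""
    n = len(xs)
    total = 0.0
    norm = g ** (-(r[0] + r[1] + 2)) / (2 * np.pi) * (-1) ** (r[0] + r[1])
    for s in range(0, n, chunk):
        d = (xs[s : s + chunk, None, :] - xs[None, :, :]) / g
        e = np.exp(-0.5 * (d[..., 0] ** 2 + d[..., 1] ** 2))
        total += float(
            np.sum(_hermite(r[0], d[..., 0]) * _hermite(r[1], d[..., 1]) * e)
        )
    return norm * total / n**2


def _sym_sqrt(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, v = np.linalg.eigh(s)
    w = np.maximum(w, 1e-300)
    return (v * np.sqrt(w)) @ v.T, (v / np.sqrt(w)) @ v.T


def normal_reference_bandwidth(points) -> np.ndarray:
    """Bivariate normal-reference bandwidth matrix n^(-1/3) S."""
    x = points.xy if isinstance(points, ProjectedPoints) else np.asarray(points, float)
    return len(x) ** (-1.0 / 3.0) * np.cov(x.T)


_R4 = [(4, 0), (3, 1), (2, 2), (1, 3), (0, 4)]


def plugin_bandwidth(points, *, max_pairs_n: int = 4000) -> np.ndarray:
    """2-stage unconstrained multivariate plug-in bandwidth matrix (km^2).

    ``points`` is a :class:`ProjectedPoints` or an (n, 2) array.  For
    n > ``max_pairs_n`` the pairwise functional estimates use a
    deterministic stride subsample (the double sum is O(n^2)).
    """
    x = points.xy if isinstance(points, ProjectedPoints) else np.asarray(points, float)
    n = len(x)
    if n < 10:
        raise ValueError("plug-in bandwidth needs n >= 10 points")
    s = np.cov(x.T)
    ev = np.linalg.eigvalsh(s)
    if ev[0] <= 0 or ev[0] / ev[1] < 1e-10:
        warnings.warn("degenerate scatter: ridged normal-reference bandwidth",
                      stacklevel=2)
        s = s + np.eye(2) * max(ev[1], 1e-12) * 1e-6
        return n ** (-1.0 / 3.0) * s
    a, a_inv = _sym_sqrt(s)
    xs = x @ a_inv
    xs_pairs = xs[:: max(1, int(np.ceil(n / max_pairs_n)))]

    # stage 1: normal-reference 6th-order functionals -> AMSE pilots for
    # the 4th-order functional estimates
    pilots = {}
    for r in [(4, 0), (2, 2), (0, 4)]:
        num = -2.0 * _phi_deriv0(r[0]) * _phi_deriv0(r[1])
        den = len(xs_pairs) * (
            _psi_normal((r[0] + 2, r[1])) + _psi_normal((r[0], r[1] + 2))
        )
        pilots[r] = (num / den) ** (1.0 / 8.0)
    pilots[(3, 1)] = pilots[(1, 3)] = pilots[(2, 2)]

    psi4 = {r: _psi_hat(xs_pairs, pilots[r], r) for r in _R4}
    psi = np.empty((2, 2, 2, 2))
    for i in range(2):
        for j in range(2):
            for k in range(2):
                for l in range(2):
                    r1 = (i, j, k, l).count(1)
                    psi[i, j, k, l] = psi4[(4 - r1, r1)]

    def amise(params3):
        la, lb, lc = params3
        low = np.array([[np.exp(la), 0.0], [lb, np.exp(lc)]])
        h = low @ low.T
        quart = float(np.einsum("ij,kl,ijkl->", h, h, psi))
        return (4 * np.pi) ** (-1.0) / n / np.sqrt(np.linalg.det(h)) + 0.25 * quart

    h0_diag = 0.5 * np.log(n ** (-1.0 / 3.0))
    res = minimize(amise, [h0_diag, 0.0, h0_diag], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    low = np.array([[np.exp(res.x[0]), 0.0], [res.x[1], np.exp(res.x[2])]])
    h_star = low @ low.T
    quart = float(np.einsum("ij,kl,ijkl->", h_star, h_star, psi))
    if not res.success or quart <= 0 or not np.all(np.isfinite(h_star)):
        warnings.warn("plug-in optimisation failed: normal-reference fallback",
                      stacklevel=2)
        return n ** (-1.0 / 3.0) * s
    return a @ h_star @ a


# ---------------------------------------------------------------------------
# kernel density on a regular grid


@dataclass
class DensityGrid:
    """Cell-centred density raster (values in probability per km^2)."""

    x0: float  # x of the centre of column 0 (km)
    y0: float  # y of the centre of row 0 (km)
    cell_km: float
    values: np.ndarray  # shape (ny, nx), row-major in y
    bandwidth: np.ndarray
    n: int

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.cell_km**2)

    def x_centers(self) -> np.ndarray:
        return self.x0 + np.arange(self.values.shape[1]) * self.cell_km

    def y_centers(self) -> np.ndarray:
        return self.y0 + np.arange(self.values.shape[0]) * self.cell_km


def kernel_density(
    points,
    bandwidth: np.ndarray | None = None,
    cell_km: float = 1.0,
    *,
    weights: np.ndarray | None = None,
    pad_sd: float = 4.0,
    max_cells: float = 2e7,
) -> DensityGrid:
    """Fixed-kernel Gaussian density on a regular grid.

    Points are linearly binned to cell centres and convolved (FFT) with the
    Gaussian kernel of matrix ``bandwidth`` (plug-in estimate when None).
    The grid covers the data bounding box plus ``pad_sd`` marginal kernel
    SDs, so essentially all kernel mass stays on the grid and the density
    integrates to 1 within grid tolerance.
    """
    x = points.xy if isinstance(points, ProjectedPoints) else np.asarray(points, float)
    n = len(x)
    if n == 0:
        raise ValueError("no points")
    h = plugin_bandwidth(points) if bandwidth is None else np.asarray(bandwidth, float)
    sdx, sdy = np.sqrt(h[0, 0]), np.sqrt(h[1, 1])
    x0 = x[:, 0].min() - pad_sd * sdx
    x1 = x[:, 0].max() + pad_sd * sdx
    y0 = x[:, 1].min() - pad_sd * sdy
    y1 = x[:, 1].max() + pad_sd * sdy
    nx = int(np.ceil((x1 - x0) / cell_km)) + 1
    ny = int(np.ceil((y1 - y0) / cell_km)) + 1
    if nx * ny > max_cells:
        raise ValueError(
            f"grid of {nx}x{ny} cells exceeds {max_cells:.0f}; use a coarser cell"
        )
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w = w / w.sum()

    # linear binning to the four surrounding cell centres
    gx = (x[:, 0] - x0) / cell_km
    gy = (x[:, 1] - y0) / cell_km
    ix = np.floor(gx).astype(int)
    iy = np.floor(gy).astype(int)
    fx = gx - ix
    fy = gy - iy
    counts = np.zeros((ny, nx))
    np.add.at(counts, (iy, ix), w * (1 - fx) * (1 - fy))
    np.add.at(counts, (iy, np.minimum(ix + 1, nx - 1)), w * fx * (1 - fy))
    np.add.at(counts, (np.minimum(iy + 1, ny - 1), ix), w * (1 - fx) * fy)
    np.add.at(counts, (np.minimum(iy + 1, ny - 1), np.minimum(ix + 1, nx - 1)), w * fx * fy)

    # kernel patch out to pad_sd + 1 SDs
    rx = int(np.ceil((pad_sd + 1) * sdx / cell_km))
    ry = int(np.ceil((pad_sd + 1) * sdy / cell_km))
    px = np.arange(-rx, rx + 1) * cell_km
    py = np.arange(-ry, ry + 1) * cell_km
    pxg, pyg = np.meshgrid(px, py)
    h_inv = np.linalg.inv(h)
    q = (
        h_inv[0, 0] * pxg**2
        + 2 * h_inv[0, 1] * pxg * pyg
        + h_inv[1, 1] * pyg**2
    )
    kern = np.exp(-0.5 * q) / (2 * np.pi * np.sqrt(np.linalg.det(h)))
    vals = fftconvolve(counts, kern, mode="same")
    vals = np.maximum(vals, 0.0)
    return DensityGrid(x0=float(x0), y0=float(y0), cell_km=float(cell_km),
                       values=vals, bandwidth=h, n=n)


# ---------------------------------------------------------------------------
# contours


@dataclass
class ContourSet:
    levels: tuple
    cell_km: float
    masks: dict  # level -> boolean array
    masses: dict  # level -> probability mass inside the mask
    thresholds: dict  # level -> density threshold
    polygons: dict  # level -> list of (k, 2) arrays of (x, y) km vertices

    def area_km2(self, level) -> float:
        return float(self.masks[level].sum() * self.cell_km**2)


def contour_levels(grid: DensityGrid, levels=DEFAULT_LEVELS) -> ContourSet:
    """Probability contours: the level-p mask is the smallest set of cells
    (by descending density) whose mass reaches p/100."""
    levels = tuple(sorted(levels))
    for p in levels:
        if not (0 < p < 100):
            raise ValueError(f"contour level {p} outside (0, 100)")
    v = grid.values
    cell_area = grid.cell_km**2
    flat = v.ravel()
    order = np.argsort(-flat, kind="stable")
    cum = np.cumsum(flat[order]) * cell_area
    masks, masses, thresholds, polygons = {}, {}, {}, {}
    for p in levels:
        target = p / 100.0
        k = int(np.searchsorted(cum, min(target, cum[-1] - 1e-15)))
        mask = np.zeros(flat.shape, bool)
        mask[order[: k + 1]] = True
        masks[p] = mask.reshape(v.shape)
        masses[p] = float(cum[k])
        thresholds[p] = float(flat[order[k]])
        polygons[p] = _trace_polygons(grid, thresholds[p])
    return ContourSet(levels, grid.cell_km, masks, masses, thresholds, polygons)


def _trace_polygons(grid: DensityGrid, threshold: float) -> list[np.ndarray]:
    from skimage import measure

    polys = []
    for c in measure.find_contours(grid.values, threshold):
        xs = grid.x0 + c[:, 1] * grid.cell_km
        ys = grid.y0 + c[:, 0] * grid.cell_km
        polys.append(np.column_stack([xs, ys]))
    return polys


# ---------------------------------------------------------------------------
# writers (plain-text interchange)


def write_esri_ascii(grid: DensityGrid, path) -> None:
    """ESRI ASCII raster (cell corners; km units of the projection)."""
    ny, nx = grid.values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {grid.x0 - grid.cell_km / 2:.6f}\n")
        fh.write(f"yllcorner {grid.y0 - grid.cell_km / 2:.6f}\n")
        fh.write(f"cellsize {grid.cell_km:.6f}\n")
        fh.write("NODATA_value -9999\n")
        for row in grid.values[::-1]:
            fh.write(" ".join(f"{x:.8g}" for x in row) + "\n")


def contours_to_geojson(
    contours: ContourSet,
    path=None,
    *,
    params: LambertParams | None = None,
) -> dict:
    """GeoJSON FeatureCollection of contour polylines.

    With ``params`` given, vertices are unprojected to lon/lat; otherwise
    they stay in projected km.
    """
    feats = []
    for p in contours.levels:
        for poly in contours.polygons[p]:
            coords = poly
            if params is not None:
                lon, lat = unproject(poly[:, 0], poly[:, 1], params)
                coords = np.column_stack([lon, lat])
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"level_percent": p},
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [[float(a), float(b)] for a, b in coords],
                    },
                }
            )
    gj = {"type": "FeatureCollection", "features": feats}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(gj, fh)
    return gj
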