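"""Brownian Bridge Movement Model (BBMM) home ranges on a regular grid.

The utilization distribution (UD) is the probability distribution of an
animal's use of space.  The BBMM builds it by conditioning a Brownian
motion on each consecutive pair of observed locations: the density
contributed by a pair ``(z1, t1) -> (z2, t2)`` is the time average over the
bridge fraction ``a in [0, 1]`` of circular normals centred on the linear
interpolant with variance

    s2(a) = dt * a * (1 - a) * sigma_m2 + ((1 - a)**2 + a**2) * sigma_loc**2

where ``sigma_m2`` is the Brownian motion variance (m^2/s, fitted from the
data) and ``sigma_loc`` the location error SD.  In passive acoustic
telemetry the "location" of a reception is the receiver position, so
``sigma_loc`` defaults to the 150 m detection range — the location error is
as large as the range at which a tag can be heard.

Home range (HR) and core area (CA) are the minimum-area sets of grid cells
holding 95% / 50% of the UD volume; overlap between fish is measured with
the utilization distribution overlap index (UDOI): the overlap area of the
two HR regions times the integrated product of the two UDs (0 when
disjoint, 1 for identical uniform distributions over a shared range, > 1
for concentrated coincident use).

The model-fitting surface follows the familiar Model/Results pattern:
``BrownianBridgeModel.from_track(track).fit()`` returns a
:class:`BBMMResults` with the fitted motion variance, the UD, contour
areas and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.special import erf
from shapely.geometry import box, mapping
from shapely.ops import unary_union

__all__ = [
    "BridgeParams",
    "UDGrid",
    "ContourRegion",
    "HomeRangeEstimate",
    "GridCoverageError",
    "estimate_motion_variance",
    "bridge_loglik",
    "compute_ud",
    "volume_contour",
    "home_range",
    "udoi",
    "overlap_matrix",
    "mean_ud",
    "thin_positions",
    "BrownianBridgeModel",
    "BBMMResults",
    "write_ascii_grid",
    "polygons_to_geojson",
]


class GridCoverageError(ValueError):
    """Raised when the UD grid loses more probability mass off its edges
    than the tolerance allows; enlarge the grid or its margin."""


@dataclass(frozen=True)
class BridgeParams:
    """BBMM parameters: motion variance (m^2/s), location error SD (m) and
    the largest time gap that is still bridged (s)."""

    sigma_m2: float
    sigma_loc: float = 150.0
    max_lag: float = 8 * 3600.0

    def __post_init__(self):
        if self.sigma_m2 < 0:
            raise ValueError("sigma_m2 must be >= 0")
        if self.sigma_loc <= 0:
            raise ValueError("sigma_loc must be > 0")


@dataclass
class UDGrid:
    """Gridded utilization probability.

    ``p[j, i]`` is the probability mass of the cell with lower-left corner
    ``(x0 + i*cell, y0 + j*cell)``; masses are non-negative and sum to 1.
    """

    x0: float
    y0: float
    cell: float
    p: np.ndarray  # shape (ny, nx)

    @property
    def nx(self) -> int:
        return self.p.shape[1]

    @property
    def ny(self) -> int:
        return self.p.shape[0]

    @property
    def x_edges(self) -> np.ndarray:
        return self.x0 + self.cell * np.arange(self.nx + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return self.y0 + self.cell * np.arange(self.ny + 1)

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell

    def same_grid(self, other: "UDGrid") -> bool:
        return (
            self.p.shape == other.p.shape
            and abs(self.x0 - other.x0) < 1e-6
            and abs(self.y0 - other.y0) < 1e-6
            and abs(self.cell - other.cell) < 1e-9
        )

    @classmethod
    def covering(cls, xy: np.ndarray, cell: float, margin: float) -> "UDGrid":
        """Empty grid covering all positions plus ``margin`` on each side."""
        xy = np.asarray(xy, dtype=float)
        x0 = float(xy[:, 0].min() - margin)
        y0 = float(xy[:, 1].min() - margin)
        nx = int(np.ceil((xy[:, 0].max() + margin - x0) / cell))
        ny = int(np.ceil((xy[:, 1].max() + margin - y0) / cell))
        return cls(x0=x0, y0=y0, cell=cell, p=np.zeros((ny, nx)))


def _cell_mass_1d(edges: np.ndarray, center: float, sd: float) -> np.ndarray:
    """Exact per-cell mass of N(center, sd^2) between consecutive edges."""
    z = (edges - center) / (sd * np.sqrt(2.0))
    c = 0.5 * (1.0 + erf(z))
    return np.diff(c)


def _accumulate_kernel(ud: UDGrid, cx: float, cy: float, sd: float, w: float) -> None:
    """Add ``w`` times a circular Gaussian kernel, integrated exactly over
    cells, within a 6-sigma window."""
    _accumulate_kernels(ud, np.array([[cx, cy]]), np.array([sd]), np.array([w]))


def _accumulate_kernels(
    ud: UDGrid, centers: np.ndarray, sds: np.ndarray, ws: np.ndarray
) -> None:
    """Add a batch of circular Gaussian kernels sharing one grid window
    (exact per-cell masses via per-axis error functions)."""
    xe, ye = ud.x_edges, ud.y_edges
    r = 6.0 * sds.max()
    i0 = max(int(np.searchsorted(xe, centers[:, 0].min() - r)) - 1, 0)
    i1 = min(int(np.searchsorted(xe, centers[:, 0].max() + r)) + 1, ud.nx)
    j0 = max(int(np.searchsorted(ye, centers[:, 1].min() - r)) - 1, 0)
    j1 = min(int(np.searchsorted(ye, centers[:, 1].max() + r)) + 1, ud.ny)
    if i0 >= i1 or j0 >= j1:
        return
    den = sds[:, None] * np.sqrt(2.0)
    cx_cdf = 0.5 * (1.0 + erf((xe[i0 : i1 + 1][None, :] - centers[:, 0:1]) / den))
    cy_cdf = 0.5 * (1.0 + erf((ye[j0 : j1 + 1][None, :] - centers[:, 1:2]) / den))
    px = np.diff(cx_cdf, axis=1) * ws[:, None]
    py = np.diff(cy_cdf, axis=1)
    ud.p[j0:j1, i0:i1] += np.einsum("kj,ki->ji", py, px)


def compute_ud(
    times,
    xy,
    params: BridgeParams,
    grid: UDGrid | None = None,
    cell: float = 25.0,
    n_alpha: int = 10,
    dwell: float = 600.0,
    max_leakage: float = 1e-3,
) -> UDGrid:
    """Brownian-bridge utilization distribution of a position series.

    Each consecutive pair with gap ``dt <= params.max_lag`` contributes its
    time-weighted bridge density, discretized at ``n_alpha`` midpoint steps
    of the bridge fraction; Gaussian kernels are integrated exactly over
    grid cells (per-axis error functions).  Pairs with longer gaps are not
    bridged: their endpoints contribute static location-error kernels
    weighted by ``dwell`` seconds each.  The grid defaults to the positions
    plus a 3-sigma_loc margin at 25 m cells; if more than ``max_leakage``
    of the accumulated mass falls off the grid a :class:`GridCoverageError`
    asks for a larger one.  The result is normalized to total mass 1.
    """
    t = np.asarray(times, dtype=float)
    z = np.asarray(xy, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 positions")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")
    if grid is None:
        # margin must hold the widest bridge kernel, not just the static
        # location-error kernel
        dts = np.diff(t)
        bridged = dts[(dts > 0) & (dts <= params.max_lag)]
        max_var = (bridged.max() / 4.0) * params.sigma_m2 if bridged.size else 0.0
        margin = max(
            3.0 * params.sigma_loc,
            4.0 * np.sqrt(max_var + params.sigma_loc**2),
        )
        grid = UDGrid.covering(z, cell=cell, margin=margin)
    ud = UDGrid(grid.x0, grid.y0, grid.cell, np.zeros_like(grid.p))

    total_w = 0.0
    alphas = (np.arange(n_alpha) + 0.5) / n_alpha
    for k in range(len(t) - 1):
        dt = t[k + 1] - t[k]
        if dt <= 0:
            continue
        x1, y1 = z[k]
        x2, y2 = z[k + 1]
        if dt <= params.max_lag:
            var = dt * alphas * (1 - alphas) * params.sigma_m2 + (
                (1 - alphas) ** 2 + alphas**2
            ) * params.sigma_loc**2
            centers = np.column_stack(
                [(1 - alphas) * x1 + alphas * x2, (1 - alphas) * y1 + alphas * y2]
            )
            ws = np.full(n_alpha, dt / n_alpha)
            _accumulate_kernels(ud, centers, np.sqrt(var), ws)
            total_w += dt
        else:
            for cx, cy in ((x1, y1), (x2, y2)):
                _accumulate_kernel(ud, cx, cy, params.sigma_loc, dwell)
            total_w += 2 * dwell
    if total_w == 0.0:
        # all gaps zero-length: fall back to a static kernel at the site
        _accumulate_kernel(ud, z[0, 0], z[0, 1], params.sigma_loc, 1.0)
        total_w = 1.0

    mass = float(ud.p.sum())
    leakage = 1.0 - mass / total_w
    if leakage > max_leakage:
        raise GridCoverageError(
            f"{leakage:.2%} of UD mass falls outside the grid; "
            "enlarge the grid or its margin"
        )
    ud.p /= mass
    return ud


def bridge_loglik(sigma_m2: float, times, xy, sigma_loc: float) -> float:
    """Leave-one-out Brownian-bridge log likelihood of the odd-indexed
    positions, each under the bridge defined by its two flanking
    even-indexed neighbours (the standard BBMM variance estimator
    objective)."""
    t = np.asarray(times, dtype=float)
    z = np.asarray(xy, dtype=float)
    i = np.arange(1, len(t) - 1, 2)
    T = t[i + 1] - t[i - 1]
    ok = T > 0
    i, T = i[ok], T[ok]
    a = (t[i] - t[i - 1]) / T
    mu = (1 - a)[:, None] * z[i - 1] + a[:, None] * z[i + 1]
    d2 = np.sum((z[i] - mu) ** 2, axis=1)
    v = T * a * (1 - a) * sigma_m2 + ((1 - a) ** 2 + a**2) * sigma_loc**2
    return float(np.sum(-np.log(2 * np.pi * v) - d2 / (2 * v)))


def estimate_motion_variance(
    times,
    xy,
    sigma_loc: float = 150.0,
    bounds: tuple[float, float] = (1e-8, 1e4),
    n_grid: int = 60,
    rtol: float = 1e-4,
) -> float:
    """Fit the Brownian motion variance ``sigma_m2`` (m^2/s).

    Maximizes :func:`bridge_loglik` over a log-spaced grid on ``bounds``
    followed by golden-section refinement (in log space) to relative
    tolerance ``rtol``.  All-identical positions return 0 with a warning.
    """
    t = np.asarray(times, dtype=float)
    z = np.asarray(xy, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 positions with distinct times")
    if np.allclose(z, z[0]):
        warnings.warn("all positions identical; sigma_m2 = 0", stacklevel=2)
        return 0.0

    cand = np.concatenate([[0.0], np.geomspace(bounds[0], bounds[1], n_grid)])
    ll = np.array([bridge_loglik(s, t, z, sigma_loc) for s in cand])
    k = int(np.argmax(ll))
    if k == 0:
        return 0.0
    lo = np.log(cand[max(k - 1, 1)])
    hi = np.log(cand[min(k + 1, len(cand) - 1)])
    if hi <= lo:
        return float(cand[k])

    # golden-section maximization on the log scale
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc = bridge_loglik(np.exp(c), t, z, sigma_loc)
    fd = bridge_loglik(np.exp(d), t, z, sigma_loc)
    while (b - a) > rtol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = bridge_loglik(np.exp(c), t, z, sigma_loc)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = bridge_loglik(np.exp(d), t, z, sigma_loc)
    return float(np.exp((a + b) / 2.0))


@dataclass
class ContourRegion:
    """A volume contour: the minimum-area cell set holding ``level`` of the
    UD mass, its area and its dissolved polygon outline."""

    level: float
    mask: np.ndarray
    area_km2: float
    polygon: object  # shapely (Multi)Polygon


@dataclass
class HomeRangeEstimate:
    hr95: ContourRegion
    ca50: ContourRegion

    @property
    def hr95_km2(self) -> float:
        return self.hr95.area_km2

    @property
    def ca50_km2(self) -> float:
        return self.ca50.area_km2


def _contour_mask(ud: UDGrid, level: float) -> np.ndarray:
    flat = ud.p.ravel()
    # stable sort on descending mass: equal-probability ties resolve in
    # row-major order, deterministically
    order = np.argsort(-flat, kind="stable")
    cum = np.cumsum(flat[order])
    k = int(np.searchsorted(cum, level - 1e-12)) + 1
    k = min(k, flat.size)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(ud.p.shape)


def _mask_polygon(ud: UDGrid, mask: np.ndarray):
    cells = []
    ys, xs = np.nonzero(mask)
    for j, i in zip(ys, xs):
        cells.append(
            box(
                ud.x0 + i * ud.cell,
                ud.y0 + j * ud.cell,
                ud.x0 + (i + 1) * ud.cell,
                ud.y0 + (j + 1) * ud.cell,
            )
        )
    return unary_union(cells) if cells else None


def volume_contour(ud: UDGrid, level: float, with_polygon: bool = True) -> ContourRegion:
    """Minimum-area volume contour: cells are taken in descending
    probability order until their cumulative mass reaches ``level``."""
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    mask = _contour_mask(ud, level)
    area_km2 = float(mask.sum()) * ud.cell_area / 1e6
    poly = _mask_polygon(ud, mask) if with_polygon else None
    return ContourRegion(level=level, mask=mask, area_km2=area_km2, polygon=poly)


def home_range(
    ud: UDGrid, hr_level: float = 0.95, ca_level: float = 0.50, with_polygon: bool = True
) -> HomeRangeEstimate:
    """95% home range and 50% core area of a UD.  The greedy cell ordering
    is shared, so the core area is nested inside the home range by
    construction."""
    return HomeRangeEstimate(
        hr95=volume_contour(ud, hr_level, with_polygon),
        ca50=volume_contour(ud, ca_level, with_polygon),
    )


def udoi(ud_a: UDGrid, ud_b: UDGrid, hr_level: float = 0.95) -> float:
    """Utilization distribution overlap index of two UDs on one grid.

    ``UDOI = A_overlap * sum(p_a * p_b) / cell_area`` where ``A_overlap``
    is the area of intersection of the two ``hr_level`` volume-contour
    regions.  Passing ``hr_level=1.0`` uses the full UD supports, under
    which the idealized anchors hold exactly (disjoint -> 0, identical
    uniform -> 1); at the default 0.95 values scale by the contour
    coverage.  Mismatched grids raise rather than silently resampling.
    """
    if not ud_a.same_grid(ud_b):
        raise ValueError("UDs are on different grids; recompute on a shared grid")
    ma = _contour_mask(ud_a, hr_level)
    mb = _contour_mask(ud_b, hr_level)
    a_overlap = float((ma & mb).sum()) * ud_a.cell_area
    integral = float(np.sum(ud_a.p * ud_b.p)) / ud_a.cell_area
    return a_overlap * integral


def overlap_matrix(uds: dict[str, UDGrid], hr_level: float = 0.95) -> pd.DataFrame:
    """Symmetric fish-by-fish UDOI matrix."""
    ids = list(uds)
    m = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i:]:
            v = udoi(uds[a], uds[b], hr_level)
            m.loc[a, b] = v
            m.loc[b, a] = v
    return m


def mean_ud(uds: list[UDGrid]) -> UDGrid:
    """Arithmetic mean of UDs on a shared grid, renormalized — the
    per-capture-location mean space-use map."""
    if not uds:
        raise ValueError("no UDs")
    first = uds[0]
    for u in uds[1:]:
        if not first.same_grid(u):
            raise ValueError("UDs are on different grids")
    p = np.mean([u.p for u in uds], axis=0)
    p /= p.sum()
    return UDGrid(first.x0, first.y0, first.cell, p)


def thin_positions(
    times: np.ndarray,
    xy: np.ndarray,
    stations: np.ndarray | None = None,
    thin_interval: float = 1800.0,
    min_spacing: float = 30.0,
) -> np.ndarray:
    """Indices of positions kept for UD fitting.

    Receptions of one transmission heard by several receivers arrive
    within seconds of each other; ``min_spacing`` collapses them to the
    first.  Consecutive receptions at the same station are then thinned to
    one per ``thin_interval`` (30 min default) to bound the segment count;
    the bridge density is time-weighted, so thinning at uniform dwell is
    near neutral.
    """
    t = np.asarray(times, dtype=float)
    keep = []
    last_t = -np.inf
    last_station = None
    for i in range(len(t)):
        st = None if stations is None else stations[i]
        if t[i] - last_t < min_spacing:
            continue
        if st is not None and st == last_station and t[i] - last_t < thin_interval:
            continue
        keep.append(i)
        last_t = t[i]
        last_station = st
    return np.asarray(keep, dtype=int)


class BrownianBridgeModel:
    """BBMM fitted to the receiver positions of one fish's detections.

    Parameters
    ----------
    times : array of seconds (or datetimes convertible to them), ascending
    xy : (n, 2) array of projected receiver coordinates, metres
    sigma_loc : location error SD (m); defaults to the 150 m detection range
    max_lag : longest bridged gap (s); longer gaps contribute only static
        endpoint kernels
    cell : grid cell size (m)
    grid : optional pre-built :class:`UDGrid` (required when UDs of several
        fish must share a grid for overlap)
    """

    def __init__(
        self,
        times,
        xy,
        sigma_loc: float = 150.0,
        max_lag: float = 8 * 3600.0,
        cell: float = 25.0,
        grid: UDGrid | None = None,
        n_alpha: int = 10,
        dwell: float = 600.0,
    ):
        t = np.asarray(times, dtype=float)
        z = np.asarray(xy, dtype=float)
        if len(t) != len(z):
            raise ValueError("times and xy lengths differ")
        self.times = t
        self.xy = z
        self.sigma_loc = float(sigma_loc)
        self.max_lag = float(max_lag)
        self.cell = float(cell)
        self.grid = grid
        self.n_alpha = int(n_alpha)
        self.dwell = float(dwell)

    @classmethod
    def from_track(
        cls,
        track,
        thin_interval: float = 1800.0,
        min_spacing: float = 30.0,
        **kwargs,
    ) -> "BrownianBridgeModel":
        """Build the model from a :class:`~reefrange.io.FishTrack`,
        thinning same-station runs (see :func:`thin_positions`)."""
        det = track.detections
        t = (det["time"].astype("int64") / 1e9).to_numpy()
        xy = det[["x", "y"]].to_numpy(dtype=float)
        idx = thin_positions(
            t, xy, det["station_id"].to_numpy(), thin_interval, min_spacing
        )
        m = cls(t[idx], xy[idx], **kwargs)
        m.tag_id = getattr(track, "tag_id", None)
        return m

    def fit(self, sigma_m2: float | None = None) -> "BBMMResults":
        """Estimate ``sigma_m2`` (unless given) and compute the UD."""
        if sigma_m2 is None:
            if len(self.times) >= 3:
                sigma_m2 = estimate_motion_variance(
                    self.times, self.xy, self.sigma_loc
                )
            else:
                warnings.warn("too few positions to fit sigma_m2; using 0")
                sigma_m2 = 0.0
        params = BridgeParams(
            sigma_m2=sigma_m2, sigma_loc=self.sigma_loc, max_lag=self.max_lag
        )
        ud = compute_ud(
            self.times,
            self.xy,
            params,
            grid=self.grid,
            cell=self.cell,
            n_alpha=self.n_alpha,
            dwell=self.dwell,
        )
        return BBMMResults(model=self, params=params, ud=ud)


@dataclass
class BBMMResults:
    """Fitted BBMM: parameters, utilization distribution and contours."""

    model: BrownianBridgeModel
    params: BridgeParams
    ud: UDGrid

    @property
    def sigma_m2(self) -> float:
        return self.params.sigma_m2

    @cached_property
    def home_range_estimate(self) -> HomeRangeEstimate:
        return home_range(self.ud)

    @property
    def hr95_km2(self) -> float:
        return self.home_range_estimate.hr95_km2

    @property
    def ca50_km2(self) -> float:
        return self.home_range_estimate.ca50_km2

    def summary(self) -> str:
        tag = getattr(self.model, "tag_id", None)
        lines = [
            "Brownian Bridge Movement Model",
            "==============================",
        ]
        if tag:
            lines.append(f"fish:              {tag}")
        lines += [
            f"positions:         {len(self.model.times)}",
            f"sigma_m2 (m^2/s):  {self.sigma_m2:.6g}",
            f"sigma_loc (m):     {self.model.sigma_loc:.1f}",
            f"grid cell (m):     {self.ud.cell:.1f}",
            f"HR 95% (km^2):     {self.hr95_km2:.3f}",
            f"CA 50% (km^2):     {self.ca50_km2:.3f}",
        ]
        return "\n".join(lines)


def write_ascii_grid(ud: UDGrid, path) -> None:
    """Export a UD as an ESRI ASCII grid (cell probabilities)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {ud.nx}\n")
        fh.write(f"nrows {ud.ny}\n")
        fh.write(f"xllcorner {ud.x0}\n")
        fh.write(f"yllcorner {ud.y0}\n")
        fh.write(f"cellsize {ud.cell}\n")
        fh.write("NODATA_value -9999\n")
        for row in ud.p[::-1]:
            fh.write(" ".join(f"{v:.8e}" for v in row) + "\n")


def polygons_to_geojson(named_polygons: dict, path, crs: str = "projected-meters"):
    """Write contour polygons as a GeoJSON FeatureCollection (planar
    coordinates; the CRS label is carried as a property tag)."""
    import json

    features = []
    for name, poly in named_polygons.items():
        if poly is None:
            continue
        features.append(
            {
                "type": "Feature",
                "properties": {"name": name, "crs": crs},
                "geometry": mapping(poly),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
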