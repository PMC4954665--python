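"""Extraordinary-movement detection by day typology.

Each analysed day is described by the percentage of active fish observed
in 1-m depth classes and in 200-m distance-to-home-range classes (distance
from the 95% home-range boundary; detections inside the HR are distance
zero and deliberately excluded from the distance features, so those
features respond only to excursions).  Days are compared with Bray-Curtis
dissimilarity, clustered hierarchically (average linkage by default) and
cut at two clusters: the cluster with the higher mean occupancy of deep
(> 20 m) and beyond-HR classes is labelled *extraordinary*, the other
*ordinary*.  A metric MDS / principal coordinates embedding of the same
dissimilarities visualizes the split.  In the source system extraordinary
days track storms (sheltering in deeper water) and the spawning season
(deep offshore excursions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "OccupancyMatrix",
    "DayTypology",
    "distance_to_hr",
    "occupancy_matrix",
    "bray_curtis",
    "classify_days",
    "pcoa",
    "environmental_overlay",
    "extraordinary_percentage",
]


def distance_to_hr(x: float, y: float, hr_polygon) -> float:
    """Metres from a receiver position to the edge of a home range.

    0 when the point lies inside (or on) the 95% HR polygon; otherwise the
    Euclidean distance to the nearest boundary point.
    """
    from shapely.geometry import Point

    p = Point(x, y)
    if hr_polygon.covers(p):
        return 0.0
    return float(hr_polygon.distance(p))


@dataclass
class OccupancyMatrix:
    """Days x classes grid of fish-occupancy percentages.

    ``data`` is indexed by date, columns are depth classes then distance
    classes; ``active`` maps each day to its denominator (fish detected
    anywhere that day).  Days with fewer than the minimum active fish are
    excluded, not zero-filled.
    """

    data: pd.DataFrame
    depth_cols: list[str]
    dist_cols: list[str]
    active: pd.Series


def _depth_label(k: int) -> str:
    return f"depth_{k:02d}_{k + 1:02d}m"


def _dist_label(k: int, width: float) -> str:
    lo = int((k - 1) * width)
    hi = int(k * width)
    return f"dist_{lo:04d}_{hi:04d}m"


def occupancy_matrix(
    tracks,
    hr_polygons: dict,
    depth_bin: float = 1.0,
    dist_bin: float = 200.0,
    min_active_fish: int = 3,
) -> OccupancyMatrix:
    """Daily percentages of fish per depth class and distance-to-HR class.

    A fish counts in a class on a day iff at least one of its detections
    that day falls in the class; the denominator is the number of fish
    detected anywhere that day.  Depth classes are left-closed 1-m bins
    from 0 to the deepest observed detection.  Distance classes are 200-m
    bins starting beyond the HR edge; inside-HR detections form an
    implicit zero class that is *not* a feature.  Fish without an HR
    estimate contribute to depth classes and the denominator but are
    logged and skipped for distance classes.
    """
    records = []  # (day, fish, depth_class or None, dist_class or None)
    no_hr = []
    for tr in tracks:
        if tr.empty:
            continue
        det = tr.detections
        day = det["time"].dt.floor("D").dt.date
        depth_k = np.floor(det["depth"].to_numpy(dtype=float) / depth_bin).astype("float")
        poly = hr_polygons.get(tr.tag_id)
        if poly is None:
            no_hr.append(tr.tag_id)
            dist_k = np.full(len(det), np.nan)
        else:
            d = np.array(
                [distance_to_hr(x, y, poly) for x, y in det[["x", "y"]].to_numpy()]
            )
            dist_k = np.where(d <= 0.0, 0.0, np.ceil(d / dist_bin))
        records.append(
            pd.DataFrame(
                {"day": day, "fish": tr.tag_id, "depth_k": depth_k, "dist_k": dist_k}
            )
        )
    if no_hr:
        warnings.warn(
            f"no HR for {sorted(no_hr)}; excluded from distance classes", stacklevel=2
        )
    if not records:
        raise ValueError("no detections in any track")
    rec = pd.concat(records, ignore_index=True)

    active = rec.groupby("day")["fish"].nunique()
    good_days = active[active >= min_active_fish].index
    rec = rec[rec["day"].isin(good_days)]
    if not len(rec):
        raise ValueError("no day has enough active fish")

    kmax = int(np.nanmax(rec["depth_k"]))
    depth_cols = [_depth_label(k) for k in range(kmax + 1)]
    dmax = int(np.nanmax(rec["dist_k"])) if np.isfinite(rec["dist_k"]).any() else 0
    dist_cols = [_dist_label(k, dist_bin) for k in range(1, dmax + 1)]

    days = sorted(good_days)
    data = pd.DataFrame(0.0, index=days, columns=depth_cols + dist_cols)
    dep = rec.dropna(subset=["depth_k"]).drop_duplicates(["day", "fish", "depth_k"])
    for (day, k), grp in dep.groupby(["day", "depth_k"]):
        data.loc[day, _depth_label(int(k))] = 100.0 * len(grp) / active[day]
    dis = rec.dropna(subset=["dist_k"])
    dis = dis[dis["dist_k"] > 0].drop_duplicates(["day", "fish", "dist_k"])
    for (day, k), grp in dis.groupby(["day", "dist_k"]):
        data.loc[day, _dist_label(int(k), dist_bin)] = 100.0 * len(grp) / active[day]

    return OccupancyMatrix(
        data=data,
        depth_cols=depth_cols,
        dist_cols=dist_cols,
        active=active[active >= min_active_fish],
    )


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between rows:
    ``BC(j, k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik)``.

    Rows must be non-negative; all-zero rows are undefined under BC and
    must be excluded by the caller (occupancy matrices never contain them,
    since an analysed day has at least one occupied depth class).
    """
    x = matrix.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("negative entries are not allowed")
    if np.any(x.sum(axis=1) == 0):
        raise ValueError("all-zero rows must be pre-excluded")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class DayTypology:
    """Two-cluster day classification with its supporting structures."""

    labels: pd.Series  # date -> 'ordinary' | 'extraordinary'
    dissimilarity: pd.DataFrame
    linkage: np.ndarray | None
    coordinates: pd.DataFrame  # PCoA embedding of the days
    deep_occupancy: pd.Series  # per-day % of fish in > threshold depth classes
    far_occupancy: pd.Series  # per-day % of fish beyond the HR edge
    negative_eig_fraction: float = 0.0
    warnings: list = field(default_factory=list)

    @property
    def n_extraordinary(self) -> int:
        return int((self.labels == "extraordinary").sum())

    @property
    def extraordinary_days(self) -> list:
        return list(self.labels[self.labels == "extraordinary"].index)


def classify_days(
    occ: OccupancyMatrix,
    linkage: str = "average",
    deep_threshold_m: float = 20.0,
    depth_bin: float = 1.0,
) -> DayTypology:
    """Hierarchical 2-cluster classification of days.

    Bray-Curtis dissimilarities between daily occupancy vectors are
    clustered agglomeratively (``average``/UPGMA by default; ``complete``
    and ``ward`` accepted) and the tree is cut at two clusters.  The
    cluster whose days carry the higher mean combined occupancy in deep
    (> ``deep_threshold_m``) and beyond-HR classes is labelled
    extraordinary; it is expected to be the minority — a warning fires if
    it exceeds half the days.  All-identical days collapse to a single
    all-ordinary cluster with a warning.
    """
    data = occ.data
    if len(data) < 3:
        raise ValueError("need at least 3 analysed days")
    deep_cols = [
        c for c in occ.depth_cols
        if int(c.split("_")[1]) * depth_bin >= deep_threshold_m
    ]
    deep = data[deep_cols].sum(axis=1) if deep_cols else pd.Series(0.0, index=data.index)
    far = data[occ.dist_cols].sum(axis=1) if occ.dist_cols else pd.Series(0.0, index=data.index)

    warns: list[str] = []
    dis = bray_curtis(data)
    condensed = squareform(dis.to_numpy(), checks=False)
    if np.all(condensed == 0.0):
        warns.append("all days identical; single ordinary cluster")
        warnings.warn(warns[-1], stacklevel=2)
        labels = pd.Series("ordinary", index=data.index)
        coords, negfrac = pcoa(dis, k=2)
        return DayTypology(labels, dis, None, coords, deep, far, negfrac, warns)

    z = hierarchy.linkage(condensed, method=linkage)
    cl = hierarchy.fcluster(z, t=2, criterion="maxclust")
    score = {c: (deep[cl == c].mean() + far[cl == c].mean()) for c in np.unique(cl)}
    if len(score) == 1:
        extra_cluster = None
    else:
        extra_cluster = max(score, key=score.get)
    labels = pd.Series(
        np.where(cl == extra_cluster, "extraordinary", "ordinary"), index=data.index
    )
    frac = (labels == "extraordinary").mean()
    if frac > 0.5:
        warns.append(
            f"extraordinary cluster holds {frac:.0%} of days — expected a minority; "
            "inspect the dendrogram"
        )
        warnings.warn(warns[-1], stacklevel=2)
    coords, negfrac = pcoa(dis, k=2)
    return DayTypology(labels, dis, z, coords, deep, far, negfrac, warns)


def pcoa(dissimilarity: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, float]:
    """Principal coordinates (classical metric MDS) of a dissimilarity.

    Returns ``(coordinates, lost_fraction)`` where coordinates hold the
    top-``k`` axes and ``lost_fraction`` is the share of total eigenvalue
    magnitude in negative eigenvalues (non-Euclidean part of the input),
    which is dropped.  ``k`` larger than the positive-eigenvalue count is
    reduced with a warning.
    """
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    d = dissimilarity.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be square symmetric")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(d, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    lost = float(np.abs(eig[eig < 0]).sum() / np.abs(eig).sum()) if np.abs(eig).sum() else 0.0
    n_pos = int((eig > 1e-12).sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive axes; reducing k from {k}", stacklevel=2)
        k = max(n_pos, 1)
    coords = res.samples.iloc[:, :k].to_numpy()
    out = pd.DataFrame(
        coords,
        index=dissimilarity.index,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return out, lost


def environmental_overlay(
    typology: DayTypology, env_series: pd.DataFrame
) -> pd.DataFrame:
    """Join day labels with the daily environmental series.

    ``env_series`` has columns ``date, sst_c, wave_m``.  Missing days stay
    as gaps (no imputation); an empty series returns the typology table
    unchanged with a warning.  No statistical test is attached: the
    storm/label comparison is visual by design.
    """
    base = pd.DataFrame(
        {
            "date": list(typology.labels.index),
            "label": typology.labels.to_numpy(),
            "deep_occupancy": typology.deep_occupancy.to_numpy(),
            "far_occupancy": typology.far_occupancy.to_numpy(),
        }
    )
    if env_series is None or env_series.empty:
        warnings.warn("empty environmental series; returning labels only", stacklevel=2)
        return base
    env = env_series.copy()
    env["date"] = pd.to_datetime(env["date"]).dt.date
    return base.merge(env, on="date", how="left")


def extraordinary_percentage(n_ordinary: int, n_extraordinary: int) -> float:
    """Share of analysed days labelled extraordinary, in percent."""
    total = n_ordinary + n_extraordinary
    if total == 0:
        raise ValueError("no analysed days")
    return 100.0 * n_extraordinary / total
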