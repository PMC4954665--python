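"""Residence indices, presence/absence matrices, depth statistics and the
mortality-flagging heuristic.

The residence index RI = DD / TP is the fraction of tracking-period days on
which a fish was detected: DD is the number of distinct detection days and
TP the inclusive day span from first to last detection day.  Days that fall
entirely inside a receiver-outage interval (e.g. a receiver lost in a storm
and replaced weeks later) are masked from both counts, so array downtime
does not depress the index.  RI is computed per protection zone; a day
counts toward every zone in which the fish was detected that day, so
zone-wise detection days may sum to more than DD for boundary-crossing
fish.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import FishTrack

__all__ = [
    "ResidencySummary",
    "residence_index",
    "presence_matrix",
    "tracking_summary",
    "depth_interval",
    "flag_mortality",
    "group_compare",
    "is_early_disappearance",
]


@dataclass
class ResidencySummary:
    """Per-fish residency statistics (one Table-style row)."""

    tag_id: str
    dd: int = 0
    tp: int = 0
    ri: float = float("nan")
    ri_by_zone: dict = field(default_factory=dict)
    dd_by_zone: dict = field(default_factory=dict)
    depth_interval_95: tuple[float, float] | None = None
    n_receptions: int = 0
    valid: bool = True
    reason: str = ""


def _day_set(times: pd.Series) -> set:
    return set(times.dt.floor("D").dt.date)


def _mask_days(days: set, outages) -> set:
    """Days of ``days`` fully inside any outage interval."""
    masked = set()
    for start, end in outages:
        s = pd.Timestamp(start).date()
        e = pd.Timestamp(end).date()
        masked |= {d for d in days if s <= d <= e}
    return masked


def residence_index(
    track: FishTrack, outage_intervals: list[tuple] | None = None
) -> ResidencySummary:
    """Compute DD, TP and RI (overall and per zone) for one fish.

    ``outage_intervals`` are ``(start, end)`` date pairs during which the
    relevant part of the array was not recording; those days are excluded
    from both DD and TP.  RI is reported unrounded; reporting layers round
    half-up to 2 decimals.

    An empty track yields an invalid summary (flagged, not silently zero).
    """
    outages = outage_intervals or []
    if track.empty:
        return ResidencySummary(
            tag_id=track.tag_id, valid=False, reason="no detections"
        )
    det = track.detections
    days = _day_set(det["time"])
    first, last = min(days), max(days)
    span = {d.date() for d in pd.date_range(first, last, freq="D")}
    masked = _mask_days(span, outages)
    tp = len(span - masked)
    dd_days = days - masked
    dd = len(dd_days)

    dd_by_zone: dict[str, int] = {}
    if "zone" in det.columns:
        dated = det.assign(day=det["time"].dt.floor("D").dt.date)
        for zone, grp in dated.groupby("zone", sort=True):
            zdays = set(grp["day"]) - masked
            dd_by_zone[str(zone)] = len(zdays)
    ri_by_zone = {z: (n / tp if tp else float("nan")) for z, n in dd_by_zone.items()}

    depths = det["depth"].dropna()
    interval = depth_interval(depths) if len(depths) else None
    return ResidencySummary(
        tag_id=track.tag_id,
        dd=dd,
        tp=tp,
        ri=dd / tp if tp else float("nan"),
        ri_by_zone=ri_by_zone,
        dd_by_zone=dd_by_zone,
        depth_interval_95=interval,
        n_receptions=len(det),
    )


def presence_matrix(tracks: list[FishTrack]) -> pd.DataFrame:
    """Daily presence grid: rows are dates, columns fish, values the zone
    label of that day's detections ('' on absent days, the modal zone when
    a fish crossed zones within a day)."""
    frames = {}
    for tr in tracks:
        if tr.empty:
            continue
        det = tr.detections
        day = det["time"].dt.floor("D").dt.date
        zone = det["zone"] if "zone" in det.columns else pd.Series("", index=det.index)
        modal = (
            pd.DataFrame({"day": day, "zone": zone})
            .groupby("day")["zone"]
            .agg(lambda s: s.mode().iloc[0])
        )
        frames[tr.tag_id] = modal
    if not frames:
        return pd.DataFrame()
    mat = pd.DataFrame(frames)
    full = pd.date_range(mat.index.min(), mat.index.max(), freq="D").date
    return mat.reindex(full).fillna("")


def is_early_disappearance(
    track: FishTrack, release_date, within_days: int = 15
) -> bool:
    """True when the fish was last detected within ``within_days`` of
    release — the configurable early-loss rule for excluding fish that
    vanished at the start of monitoring from cohort aggregates."""
    if track.empty:
        return True
    last = track.detections["time"].max()
    return (last - pd.Timestamp(release_date)) <= pd.Timedelta(days=within_days)


def tracking_summary(
    table: pd.DataFrame, value: str, group: str = "group"
) -> pd.DataFrame:
    """Mean ± sample SD (n−1) of ``value`` per ``group`` over a tidy
    per-fish table.  Callers exclude early-disappearance fish before
    calling (see :func:`is_early_disappearance`).  Groups of size 1 get a
    missing SD."""
    rows = []
    for g, grp in table.groupby(group, sort=True):
        v = grp[value].dropna().to_numpy(dtype=float)
        rows.append(
            {
                group: g,
                "n": len(v),
                "mean": float(np.mean(v)) if len(v) else float("nan"),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def depth_interval(depths, coverage: float = 0.95) -> tuple[float, float]:
    """Central empirical quantile interval holding ``coverage`` of all
    receptions (2.5th–97.5th percentiles for the default 0.95)."""
    d = np.asarray(pd.Series(depths).dropna(), dtype=float)
    if d.size == 0:
        raise ValueError("no depth values available")
    lo = (1.0 - coverage) / 2.0
    q = np.quantile(d, [lo, 1.0 - lo])
    return float(q[0]), float(q[1])


def flag_mortality(
    track: FishTrack, min_days: float = 30.0, max_depth_sd: float = 0.5
) -> tuple[bool, dict]:
    """Heuristic death/tag-loss audit.

    A tag lying on the bottom keeps transmitting from one spot: the track
    ends with a long run of receptions at a single receiver at near
    constant depth.  Flag fires when the terminal single-station run spans
    ``>= min_days`` and its depth SD is ``<= max_depth_sd`` metres.
    Returns ``(flag, evidence)``; evidence carries the run start, station,
    span and depth SD regardless of the outcome.
    """
    if track.empty:
        return False, {"reason": "no detections"}
    det = track.detections
    st = det["station_id"].to_numpy()
    # start index of the terminal run of a single station
    change = np.nonzero(st[1:] != st[:-1])[0]
    start = int(change[-1]) + 1 if change.size else 0
    run = det.iloc[start:]
    span_days = (run["time"].iloc[-1] - run["time"].iloc[0]) / pd.Timedelta(days=1)
    depths = run["depth"].dropna()
    depth_sd = float(np.std(depths, ddof=0)) if len(depths) else float("nan")
    flag = bool(
        span_days >= min_days
        and len(depths)
        and depth_sd <= max_depth_sd
    )
    evidence = {
        "station_id": str(run["station_id"].iloc[0]),
        "run_start": run["time"].iloc[0],
        "run_days": float(span_days),
        "depth_sd": depth_sd,
        "n_receptions": int(len(run)),
    }
    return flag, evidence


def group_compare(
    values, groups, test: str = "kruskal_wallis"
) -> tuple[float, float]:
    """Between-group comparison: Kruskal-Wallis or one-way ANOVA.

    No multiplicity correction is applied.  Degenerate input (all values
    identical) returns ``p = 1`` with a warning instead of a NaN from the
    underlying test.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    samples = [v[g == lab] for lab in pd.unique(g)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if np.all(v == v[0]):
        warnings.warn("all values identical; p set to 1", stacklevel=2)
        return 0.0, 1.0
    if test == "kruskal_wallis":
        res = stats.kruskal(*samples)
    elif test == "anova":
        res = stats.f_oneway(*samples)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
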