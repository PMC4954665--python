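"""Diel (day/night) activity analysis.

Receptions are split into solar phases — day (sunrise to sunset) and night
(sunset to next sunrise) — and summarized per phase by mean depth and by
hourly reception number (receptions in a phase divided by its duration in
hours).  Repeatable day/night movement shows up in the phase-transition
value ``PT_DN = D_t - N_t``: the day-phase metric minus the following
night's.  A fish that moves deeper at nightfall has a significantly
negative median ``PT_DN`` for mean depth; one moving shallower, positive.
Cyclicity is confirmed by the day-to-day series ``PT_DD = D_t - D_{t+1}``
centring on zero.  Medians are tested against zero with the Wilcoxon
signed-rank test.

Sunrise and sunset come from the NOAA solar position equations evaluated
at the study coordinates; at 30-min analysis resolution the few-minute
differences between ephemeris sources are immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import FishTrack

__all__ = [
    "sun_times",
    "solar_phases",
    "phase_metrics",
    "TransitionSeries",
    "transition_series",
    "DielClassification",
    "classify_diel",
    "wilcoxon_signed_rank",
    "chronogram",
]

_D2R = np.pi / 180.0


def sun_times(dates, lat: float, lon: float) -> pd.DataFrame:
    """Sunrise and sunset (UTC) for each date via the NOAA solar equations.

    ``lon`` east-positive degrees.  Raises for polar day/night (the zenith
    equation has no solution) — unreachable at mid latitudes.
    Returns a frame indexed by date with columns ``sunrise, sunset``.
    """
    dates = pd.DatetimeIndex(pd.to_datetime(list(dates)))
    # Julian day at civil noon UTC
    jd = dates.to_julian_date().to_numpy() + 0.5
    jc = (jd - 2451545.0) / 36525.0

    l0 = np.mod(280.46646 + jc * (36000.76983 + jc * 0.0003032), 360.0)
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eq_ctr = (
        np.sin(m * _D2R) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * m * _D2R) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * m * _D2R) * 0.000289
    )
    true_long = l0 + eq_ctr
    app_long = true_long - 0.00569 - 0.00478 * np.sin((125.04 - 1934.136 * jc) * _D2R)
    mean_obliq = 23.0 + (
        26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0
    ) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos((125.04 - 1934.136 * jc) * _D2R)
    decl = np.arcsin(np.sin(obliq * _D2R) * np.sin(app_long * _D2R))

    var_y = np.tan(obliq * _D2R / 2.0) ** 2
    eq_time = 4.0 / _D2R * (
        var_y * np.sin(2 * l0 * _D2R)
        - 2.0 * ecc * np.sin(m * _D2R)
        + 4.0 * ecc * var_y * np.sin(m * _D2R) * np.cos(2 * l0 * _D2R)
        - 0.5 * var_y**2 * np.sin(4 * l0 * _D2R)
        - 1.25 * ecc**2 * np.sin(2 * m * _D2R)
    )

    # hour angle at the -0.833 deg refracted-horizon zenith
    cos_ha = np.cos(90.833 * _D2R) / (np.cos(lat * _D2R) * np.cos(decl)) - np.tan(
        lat * _D2R
    ) * np.tan(decl)
    if np.any(np.abs(cos_ha) > 1.0):
        raise ValueError("polar day or night: no sunrise/sunset at these dates")
    ha = np.arccos(cos_ha) / _D2R  # degrees

    noon_min = 720.0 - 4.0 * lon - eq_time
    sunrise_min = noon_min - 4.0 * ha
    sunset_min = noon_min + 4.0 * ha
    base = dates.tz_localize("UTC") if dates.tz is None else dates
    out = pd.DataFrame(
        {
            "sunrise": base + pd.to_timedelta(sunrise_min, unit="m"),
            "sunset": base + pd.to_timedelta(sunset_min, unit="m"),
        },
        index=dates.date,
    )
    return out


def solar_phases(dates, lat: float, lon: float) -> pd.DataFrame:
    """Tile the given date span into alternating day/night phases.

    The day phase of date *t* runs sunrise_t to sunset_t; the night phase
    assigned to date *t* runs sunset_t to sunrise_{t+1}.  Together they
    tile time with no gaps; the tiling starts one day before the first
    requested date so that pre-dawn receptions on the first day are still
    covered.  Returns columns ``date, kind, start, end``.
    """
    dates = pd.DatetimeIndex(pd.to_datetime(list(dates))).normalize()
    span = pd.date_range(
        dates.min() - pd.Timedelta(days=1),
        dates.max() + pd.Timedelta(days=1),
        freq="D",
    )
    st = sun_times(span, lat, lon)
    rows = []
    for i in range(len(span) - 1):
        d = span[i].date()
        rows.append(
            {"date": d, "kind": "day", "start": st["sunrise"].iloc[i], "end": st["sunset"].iloc[i]}
        )
        rows.append(
            {"date": d, "kind": "night", "start": st["sunset"].iloc[i], "end": st["sunrise"].iloc[i + 1]}
        )
    return pd.DataFrame(rows)


def phase_metrics(track: FishTrack, phases: pd.DataFrame) -> pd.DataFrame:
    """Per-phase mean depth and hourly reception number.

    Phases without receptions keep NaN metrics (they stay visible in the
    series so D-N/D-D pairing can skip them explicitly).
    """
    det = track.detections
    out = phases.copy()
    starts = phases["start"].to_numpy()
    idx = np.searchsorted(starts, det["time"].to_numpy(), side="right") - 1
    dur_h = (phases["end"] - phases["start"]) / pd.Timedelta(hours=1)

    inside = (idx >= 0) & (idx < len(phases))
    # detections before the first phase start fall outside the span
    grp = pd.DataFrame(
        {"phase": idx[inside], "depth": det["depth"].to_numpy()[inside]}
    ).groupby("phase")
    n = grp.size()
    mean_depth = grp["depth"].mean()

    out["n"] = pd.Series(n, index=n.index).reindex(range(len(phases))).fillna(0).astype(int).to_numpy()
    out["mean_depth"] = mean_depth.reindex(range(len(phases))).to_numpy()
    out["hourly_receptions"] = np.where(out["n"] > 0, out["n"] / dur_h, np.nan)
    return out


@dataclass
class TransitionSeries:
    """Phase-transition values of one metric for one fish."""

    variable: str
    pt_dn: np.ndarray  # day_t - night_t (night following day t)
    pt_dd: np.ndarray  # day_t - day_{t+1}


def transition_series(phase_table: pd.DataFrame, variable: str) -> TransitionSeries:
    """Build ``PT_DN`` (day minus following night) and ``PT_DD`` (day minus
    next day) series for ``variable``; pairs with any missing member are
    skipped."""
    if variable not in phase_table.columns:
        raise KeyError(variable)
    days = phase_table[phase_table["kind"] == "day"].set_index("date")[variable]
    nights = phase_table[phase_table["kind"] == "night"].set_index("date")[variable]

    dn = []
    for d, dv in days.items():
        nv = nights.get(d, np.nan)
        if np.isfinite(dv) and np.isfinite(nv):
            dn.append(dv - nv)
    dd = []
    dates = list(days.index)
    for d0, d1 in zip(dates, dates[1:]):
        if (pd.Timestamp(d1) - pd.Timestamp(d0)) != pd.Timedelta(days=1):
            continue  # only consecutive calendar days pair
        v0, v1 = days[d0], days[d1]
        if np.isfinite(v0) and np.isfinite(v1):
            dd.append(v0 - v1)
    return TransitionSeries(
        variable=variable,
        pt_dn=np.asarray(dn, dtype=float),
        pt_dd=np.asarray(dd, dtype=float),
    )


def wilcoxon_signed_rank(
    values: np.ndarray, zero_method: str = "wilcox"
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of median zero.

    Zeros are dropped by default (classic convention; ``pratt``
    available).  The exact null distribution is used for n <= 25 without
    ties; the normal approximation with continuity correction otherwise.
    Returns ``(statistic, p)``.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    nz = v[v != 0] if zero_method == "wilcox" else v
    if len(nz) < 1 or np.all(v == 0):
        return float("nan"), 1.0
    ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(
        v,
        zero_method=zero_method,
        alternative="two-sided",
        correction=True,
        method=method,
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class DielClassification:
    """Per-fish diel pattern call from the depth PT series."""

    tag_id: str
    pattern: str  # deeper_at_night | shallower_at_night | none
    p_dn: float = float("nan")
    p_dd: float = float("nan")
    median_dn: float = float("nan")
    cyclic: bool | None = None  # PT_DD consistent with zero
    n_dn: int = 0
    n_dd: int = 0
    reason: str = ""
    extras: dict = field(default_factory=dict)


def classify_diel(
    series_depth: TransitionSeries,
    alpha_dn: float = 0.01,
    alpha_dd: float = 0.05,
    min_n: int = 6,
    tag_id: str = "",
    zero_method: str = "wilcox",
) -> DielClassification:
    """Call a fish's diel depth pattern from its PT series.

    ``PT_DN`` median significantly below zero (p < ``alpha_dn``) means the
    fish sits deeper at night (day depth < night depth); above zero,
    shallower at night.  ``PT_DD`` is tested as a cyclicity confirmation —
    reported, not gating.  Too few pairs yields ``none`` with a reason.
    """
    dn, dd = series_depth.pt_dn, series_depth.pt_dd
    if len(dn) < min_n:
        return DielClassification(
            tag_id=tag_id, pattern="none", n_dn=len(dn), n_dd=len(dd),
            reason=f"only {len(dn)} PT_DN values (< {min_n})",
        )
    _, p_dn = wilcoxon_signed_rank(dn, zero_method)
    p_dd = float("nan")
    cyclic = None
    if len(dd) >= min_n:
        _, p_dd = wilcoxon_signed_rank(dd, zero_method)
        cyclic = bool(p_dd >= alpha_dd)
    med = float(np.median(dn))
    if p_dn < alpha_dn and med != 0.0:
        pattern = "deeper_at_night" if med < 0 else "shallower_at_night"
    else:
        pattern = "none"
    return DielClassification(
        tag_id=tag_id,
        pattern=pattern,
        p_dn=p_dn,
        p_dd=p_dd,
        median_dn=med,
        cyclic=cyclic,
        n_dn=len(dn),
        n_dd=len(dd),
    )


def chronogram(track: FishTrack, bin_minutes: int = 30) -> pd.DataFrame:
    """Spatial chronogram: per day and 30-min interval, the receiver with
    the most receptions ('' for empty intervals).  Ties break to the
    lexicographically smallest station id, deterministically.

    Returns a frame indexed by date with one column per within-day bin.
    """
    n_bins = int(24 * 60 / bin_minutes)
    det = track.detections
    if det.empty:
        return pd.DataFrame(columns=range(n_bins))
    t = det["time"]
    day = t.dt.floor("D").dt.date
    b = ((t.dt.hour * 60 + t.dt.minute) // bin_minutes).astype(int)
    counts = (
        pd.DataFrame({"day": day, "bin": b, "station": det["station_id"]})
        .groupby(["day", "bin", "station"])
        .size()
        .reset_index(name="n")
        .sort_values(["day", "bin", "n", "station"], ascending=[True, True, False, True],
                     kind="mergesort")
    )
    modal = counts.groupby(["day", "bin"]).first()["station"]
    grid = modal.unstack("bin")
    full_days = pd.date_range(min(day), max(day), freq="D").date
    grid = grid.reindex(index=full_days, columns=range(n_bins)).fillna("")
    return grid
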