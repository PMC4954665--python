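"""Detection-log ingestion: data model, CSV readers, validation and the
spurious-reception filter.

Passive acoustic telemetry produces one record per decoded transmission
("reception"): a timestamp, the receiver that heard it, the transmitter id
and an optional sensor value (here: pressure, converted to depth).  This
module parses the download-software CSV dialect, validates records against
the receiver deployment history, converts sensor values to metres, and
removes isolated receptions that are almost certainly false decodes.

All coordinates are planar projected metres (e.g. the UTM zone of the study
site); timestamps are stored UTC throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Detection",
    "ReceiverStation",
    "TagDeployment",
    "FishTrack",
    "IngestReport",
    "read_stations",
    "read_tag_registry",
    "read_detections",
    "filter_spurious",
    "build_tracks",
]

#: canonical detection-log column names (download-software dialect)
RAW_COLUMNS = {
    "time": "Date and Time (UTC)",
    "station": "Receiver",
    "tag": "Transmitter",
    "sensor": "Sensor Value",
}

#: columns of the tidy detections frame used throughout the package
DETECTION_COLUMNS = ["tag_id", "station_id", "time", "depth"]


class Detection(NamedTuple):
    """One validated reception of an acoustic tag at a moored receiver."""

    tag_id: str
    station_id: str
    time: pd.Timestamp
    depth: float  # metres below surface; NaN if the tag has no pressure sensor


@dataclass
class ReceiverStation:
    """A moored acoustic receiver with its deployment history.

    ``deployments`` is a list of ``(start, end)`` UTC intervals; a receiver
    lost and later replaced has a gap between episodes, and receptions
    logged inside such a gap are rejected on read.
    """

    station_id: str
    x: float
    y: float
    zone: str  # NT (no-take), PR (partial reserve), NR (no reserve)
    deployments: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)
    detection_range: float = 150.0

    def __post_init__(self) -> None:
        if self.detection_range <= 0:
            raise ValueError(f"{self.station_id}: detection_range must be > 0")
        eps = sorted(self.deployments)
        for (_, e0), (s1, _) in zip(eps, eps[1:]):
            if s1 < e0:
                raise ValueError(f"{self.station_id}: overlapping deployment episodes")
        self.deployments = eps

    def deployed_at(self, t: pd.Timestamp) -> bool:
        return any(s <= t <= e for s, e in self.deployments)


@dataclass
class TagDeployment:
    """Registry entry for one tagged fish."""

    tag_id: str
    fish_length: float  # cm
    capture_site: str
    release_site: str
    release_date: pd.Timestamp
    battery_end: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.release_date < self.battery_end:
            raise ValueError(f"{self.tag_id}: release_date must precede battery_end")

    @property
    def translocated(self) -> bool:
        return self.capture_site != self.release_site


@dataclass
class FishTrack:
    """Time-ordered, filtered detections of a single fish.

    ``detections`` is a frame with columns ``tag_id, station_id, time,
    depth`` plus ``x, y, zone`` merged from the station table.  ``status``
    is ``active`` unless a downstream audit reflags it (``dead-flagged``)
    or the fish produced no surviving detections (``disappeared``).
    """

    tag_id: str
    detections: pd.DataFrame
    status: str = "active"

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def empty(self) -> bool:
        return self.detections.empty


@dataclass
class IngestReport:
    """Record-level accounting of one detection-log read."""

    n_rows: int = 0
    n_kept: int = 0
    n_bad_timestamp: int = 0
    n_bad_sensor: int = 0
    n_unknown_station: int = 0
    n_outside_deployment: int = 0
    per_tag: dict = field(default_factory=dict)

    @property
    def n_bad(self) -> int:
        return self.n_bad_timestamp + self.n_bad_sensor + self.n_unknown_station

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def read_stations(path) -> dict[str, ReceiverStation]:
    """Read a station table CSV into a dict keyed by station id.

    Expected columns: ``station_id, x, y, zone, deployed_from, deployed_to``
    (ISO dates, UTC) and optional ``detection_range``.  A station with
    several deployment episodes (loss and replacement) appears on several
    rows; coordinates of the first row win.
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    stations: dict[str, ReceiverStation] = {}
    for _, row in df.iterrows():
        sid = str(row["station_id"])
        episode = (
            pd.Timestamp(row["deployed_from"], tz="UTC"),
            pd.Timestamp(row["deployed_to"], tz="UTC"),
        )
        if sid in stations:
            st = stations[sid]
            st.deployments = sorted(st.deployments + [episode])
        else:
            stations[sid] = ReceiverStation(
                station_id=sid,
                x=float(row["x"]),
                y=float(row["y"]),
                zone=str(row["zone"]),
                deployments=[episode],
                detection_range=float(row.get("detection_range", 150.0))
                if "detection_range" in df.columns
                else 150.0,
            )
    return stations


def read_tag_registry(path) -> dict[str, TagDeployment]:
    """Read the tag registry CSV (one row per tagged fish)."""
    df = pd.read_csv(path, dtype={"tag_id": str})
    out = {}
    for _, row in df.iterrows():
        out[str(row["tag_id"])] = TagDeployment(
            tag_id=str(row["tag_id"]),
            fish_length=float(row["fish_length"]),
            capture_site=str(row["capture_site"]),
            release_site=str(row["release_site"]),
            release_date=pd.Timestamp(row["release_date"], tz="UTC"),
            battery_end=pd.Timestamp(row["battery_end"], tz="UTC"),
        )
    return out


def read_detections(
    path,
    stations: dict[str, ReceiverStation],
    calibration: tuple[float, float] = (1.0, 0.0),
    max_bad_fraction: float = 0.01,
) -> tuple[pd.DataFrame, IngestReport]:
    """Parse a raw detection-log CSV into a tidy, time-sorted frame.

    Sensor values are converted to depth as ``slope * value + intercept``
    (identity by default — logs that already carry metres pass through).
    Records timed outside every deployment episode of their receiver are
    dropped and counted; unparseable records are counted and the read hard
    fails only if they exceed ``max_bad_fraction`` of rows.

    Returns ``(frame, report)`` where the frame has columns
    ``tag_id, station_id, time, depth`` sorted stably by time.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in RAW_COLUMNS.values() if c not in raw.columns]
    if missing:
        raise ValueError(f"detection log missing columns: {missing}")
    rep = IngestReport(n_rows=len(raw))

    time = pd.to_datetime(
        raw[RAW_COLUMNS["time"]], errors="coerce", utc=True, format="ISO8601"
    )
    rep.n_bad_timestamp = int(time.isna().sum())

    sensor = pd.to_numeric(raw[RAW_COLUMNS["sensor"]], errors="coerce")
    # an absent sensor column value is legitimate (no pressure sensor);
    # only non-numeric non-empty strings count as bad
    nonempty = raw[RAW_COLUMNS["sensor"]].notna() & (
        raw[RAW_COLUMNS["sensor"]].str.strip() != ""
    )
    rep.n_bad_sensor = int((sensor.isna() & nonempty).sum())

    station = raw[RAW_COLUMNS["station"]].astype(str)
    known = station.isin(stations.keys())
    rep.n_unknown_station = int((~known).sum())

    if rep.n_rows and rep.n_bad / rep.n_rows > max_bad_fraction:
        raise ValueError(
            f"{rep.n_bad}/{rep.n_rows} bad records exceeds "
            f"max_bad_fraction={max_bad_fraction}"
        )

    ok = time.notna() & known
    slope, intercept = calibration
    df = pd.DataFrame(
        {
            "tag_id": raw[RAW_COLUMNS["tag"]].astype(str),
            "station_id": station,
            "time": time,
            "depth": slope * sensor + intercept,
        }
    )[ok]

    # reject receptions logged while the receiver was not in the water
    in_dep = np.zeros(len(df), dtype=bool)
    for sid, grp in df.groupby("station_id", sort=False):
        st = stations[sid]
        m = np.zeros(len(grp), dtype=bool)
        for s, e in st.deployments:
            m |= (grp["time"] >= s) & (grp["time"] <= e)
        in_dep[df.index.get_indexer(grp.index)] = m
    rep.n_outside_deployment = int((~in_dep).sum())
    df = df[in_dep]

    # stable sort: equal timestamps keep file order on every run
    df = df.sort_values("time", kind="mergesort").reset_index(drop=True)
    rep.n_kept = len(df)
    rep.per_tag = df["tag_id"].value_counts().to_dict()
    return df, rep


def filter_spurious(
    detections: pd.DataFrame, isolation_window: float = 24.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop isolated single receptions, per tag.

    A reception is spurious iff no other reception of the same tag falls
    within ``±isolation_window/2`` hours of it (default: a centred 24 h
    span, i.e. ±12 h).  Receivers decode overlapping transmissions into
    occasional false ids; a true presence yields runs of receptions at the
    ~2 min transmission cadence, so a reception with an empty 24 h
    neighbourhood is deleted.  The removed set is returned for audit.

    The rule is evaluated against the *original* set, which makes the
    filter idempotent: every kept reception has a kept neighbour (the
    neighbour relation is symmetric).
    """
    if detections.empty:
        return detections.copy(), detections.copy()
    half = pd.Timedelta(hours=isolation_window / 2.0)
    keep = np.zeros(len(detections), dtype=bool)
    pos = 0
    order = detections.sort_values("time", kind="mergesort").index
    det = detections.loc[order]
    half_ns = half.value
    for _, grp in det.groupby("tag_id", sort=False):
        t = grp["time"].astype("int64").to_numpy()
        n = len(t)
        k = np.zeros(n, dtype=bool)
        if n > 1:
            gaps = np.diff(t)
            k[:-1] |= gaps <= half_ns
            k[1:] |= gaps <= half_ns
        keep[detections.index.get_indexer(grp.index)] = k
        pos += n
    kept = detections[keep]
    removed = detections[~keep]
    return kept, removed


def build_tracks(
    detections: pd.DataFrame,
    tag_registry: dict[str, TagDeployment],
    stations: dict[str, ReceiverStation],
) -> tuple[list[FishTrack], list[str]]:
    """Assemble one :class:`FishTrack` per registered tag.

    Station coordinates and zone labels are merged onto the detections.
    Tags with zero surviving detections get an empty track with status
    ``disappeared``; detections of tags absent from the registry produce a
    warning list (returned, and also emitted via :mod:`warnings`).
    """
    st_df = pd.DataFrame(
        [(s.station_id, s.x, s.y, s.zone) for s in stations.values()],
        columns=["station_id", "x", "y", "zone"],
    )
    merged = detections.merge(st_df, on="station_id", how="left")
    warnings_list = []
    unknown = set(merged["tag_id"]) - set(tag_registry)
    for tid in sorted(unknown):
        msg = f"detections for tag {tid!r} absent from registry; ignored"
        warnings_list.append(msg)
        warnings.warn(msg, stacklevel=2)

    tracks = []
    for tid in tag_registry:
        sub = merged[merged["tag_id"] == tid].reset_index(drop=True)
        status = "active" if len(sub) else "disappeared"
        tracks.append(FishTrack(tag_id=tid, detections=sub, status=status))
    return tracks, warnings_list


def write_audit(removed: pd.DataFrame, report: IngestReport, out_dir) -> None:
    """Write the removed-detections CSV and the ingestion report JSON."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    removed.to_csv(out / "removed_detections.csv", index=False)
    report.to_json(out / "ingest_report.json")
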