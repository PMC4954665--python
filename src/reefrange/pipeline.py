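"""Study orchestration: configuration, staged execution, reporting, and
aggregates recomputed from the bundled per-fish summary table.

``run_study`` drives the full chain — ingest and filter the detection log,
build per-fish tracks, compute residency statistics and mortality flags,
fit the BBMM home ranges and overlap, classify diel patterns, run the
day-typology detector and join the environmental series — writing tidy CSV
outputs and a JSON report along the way.  Every source of randomness
derives from the single configured seed.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict, fields as dc_fields
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import daytypology, diel, homerange, io, residency

logger = logging.getLogger("reefrange")

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "load_table1",
    "table1_aggregates",
    "round_half_up",
]

STAGES = ["ingest", "residency", "homerange", "diel", "typology"]


def _build(cls, d: dict | None, where: str):
    d = d or {}
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**d)


@dataclass
class FilterConfig:
    isolation_window_h: float = 24.0
    max_bad_fraction: float = 0.01


@dataclass
class ResidencyConfig:
    early_loss_days: int = 15
    mortality_min_days: float = 30.0
    mortality_max_depth_sd: float = 0.5
    outages: list = field(default_factory=list)  # [[start, end], ...]


@dataclass
class BBMMConfig:
    sigma_loc: float = 150.0
    cell: float = 25.0
    max_lag_h: float = 8.0
    thin_min: float = 30.0
    n_alpha: int = 10
    hr_level: float = 0.95
    ca_level: float = 0.50


@dataclass
class DielConfig:
    alpha_dn: float = 0.01
    alpha_dd: float = 0.05
    min_n: int = 6


@dataclass
class TypologyConfig:
    depth_bin: float = 1.0
    dist_bin: float = 200.0
    min_active_fish: int = 3
    linkage: str = "average"
    deep_threshold_m: float = 20.0


@dataclass
class StudyConfig:
    """Validated study configuration; unknown keys are rejected."""

    detections: str = ""
    stations: str = ""
    tags: str = ""
    environment: str | None = None
    out_dir: str = "study_out"
    seed: int = 0
    lat: float = 42.05
    lon: float = 3.22
    figures: bool = False
    filter: FilterConfig = field(default_factory=FilterConfig)
    residency: ResidencyConfig = field(default_factory=ResidencyConfig)
    bbmm: BBMMConfig = field(default_factory=BBMMConfig)
    diel: DielConfig = field(default_factory=DielConfig)
    typology: TypologyConfig = field(default_factory=TypologyConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        sub = {
            "filter": FilterConfig,
            "residency": ResidencyConfig,
            "bbmm": BBMMConfig,
            "diel": DielConfig,
            "typology": TypologyConfig,
        }
        kw = {}
        for name, sub_cls in sub.items():
            kw[name] = _build(sub_cls, d.pop(name, None), name)
        allowed = {f.name for f in dc_fields(cls)} - set(sub)
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d, **kw)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate_paths(self) -> None:
        for name in ("detections", "stations", "tags"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: missing input file {p!r}")


@dataclass
class StudyReport:
    """Everything a study run produced, with aggregates recomputable from
    the per-fish table it contains."""

    fish_table: pd.DataFrame
    aggregates: pd.DataFrame | None = None
    presence: pd.DataFrame | None = None
    overlap: pd.DataFrame | None = None
    diel_table: pd.DataFrame | None = None
    diel_counts: dict = field(default_factory=dict)
    typology: object = None
    env_overlay: pd.DataFrame | None = None
    out_dir: str | None = None
    timings: dict = field(default_factory=dict)


def _stage(name, timings):
    class _T:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            timings[name] = _time.perf_counter() - self.t0
            logger.info("stage %s: %.2fs", name, timings[name])
            return False

    return _T()


def run_study(config: StudyConfig, through: str = "typology") -> StudyReport:
    """Execute the pipeline through the named stage (default: all).

    Writes per-stage CSV outputs under ``config.out_dir`` and returns the
    in-memory :class:`StudyReport`.  A stage failure propagates with the
    stage name in the log.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; expected one of {STAGES}")
    last = STAGES.index(through)
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    rep = StudyReport(fish_table=pd.DataFrame(), out_dir=str(out), timings=timings)

    # ---- ingest -------------------------------------------------------
    with _stage("ingest", timings):
        stations = io.read_stations(config.stations)
        registry = io.read_tag_registry(config.tags)
        det, ingest_rep = io.read_detections(
            config.detections, stations, max_bad_fraction=config.filter.max_bad_fraction
        )
        kept, removed = io.filter_spurious(det, config.filter.isolation_window_h)
        logger.info(
            "ingest: %d records, %d kept after spurious filter (%d removed)",
            ingest_rep.n_rows, len(kept), len(removed),
        )
        io.write_audit(removed, ingest_rep, out)
        tracks, _warn = io.build_tracks(kept, registry, stations)
    if last == 0:
        return rep

    # ---- residency ----------------------------------------------------
    with _stage("residency", timings):
        rcfg = config.residency
        outages = [(a, b) for a, b in rcfg.outages]
        rows = []
        for tr in tracks:
            summ = residency.residence_index(tr, outages)
            reg = registry[tr.tag_id]
            early = residency.is_early_disappearance(
                tr, reg.release_date, rcfg.early_loss_days
            )
            dead, ev = (False, {}) if tr.empty else residency.flag_mortality(
                tr, rcfg.mortality_min_days, rcfg.mortality_max_depth_sd
            )
            if dead:
                tr.status = "dead-flagged"
            zone = reg.capture_site
            own_ri = summ.ri_by_zone.get(zone, summ.ri if summ.valid else np.nan)
            rows.append(
                {
                    "tag_id": tr.tag_id,
                    "zone": zone,
                    "fish_length": reg.fish_length,
                    "n_receptions": summ.n_receptions,
                    "dd": summ.dd,
                    "tp": summ.tp,
                    "ri": round_half_up(summ.ri, 2) if summ.valid else np.nan,
                    "ri_own_zone": round_half_up(own_ri, 2) if summ.valid else np.nan,
                    "depth_lo": summ.depth_interval_95[0] if summ.depth_interval_95 else np.nan,
                    "depth_hi": summ.depth_interval_95[1] if summ.depth_interval_95 else np.nan,
                    "early_disappearance": bool(early),
                    "dead_flagged": bool(dead),
                    "analysed": bool(summ.valid and not early and not dead),
                }
            )
        fish_table = pd.DataFrame(rows)
        rep.fish_table = fish_table
        rep.presence = residency.presence_matrix(tracks)
        ana = fish_table[fish_table["analysed"]]
        rep.aggregates = residency.tracking_summary(
            ana.melt(id_vars="zone", value_vars=["tp", "ri_own_zone"],
                     var_name="metric").rename(columns={"value": "v"})
            .assign(group=lambda d: d["zone"] + ":" + d["metric"]),
            value="v", group="group",
        )
        fish_table.to_csv(out / "fish_summary.csv", index=False)
        rep.presence.to_csv(out / "presence.csv")
    if last == 1:
        _finish(rep, out, config)
        return rep

    # ---- home range ---------------------------------------------------
    with _stage("homerange", timings):
        bcfg = config.bbmm
        st_xy = np.array([[s.x, s.y] for s in stations.values()])
        analysed_ids = set(rep.fish_table[rep.fish_table["analysed"]]["tag_id"])
        models, sigmas = {}, {}
        for tr in tracks:
            if tr.tag_id not in analysed_ids or len(tr) < 3:
                continue
            model = homerange.BrownianBridgeModel.from_track(
                tr,
                thin_interval=bcfg.thin_min * 60.0,
                sigma_loc=bcfg.sigma_loc,
                max_lag=bcfg.max_lag_h * 3600.0,
                cell=bcfg.cell,
                n_alpha=bcfg.n_alpha,
            )
            if len(model.times) < 3:
                continue
            models[tr.tag_id] = model
            sigmas[tr.tag_id] = homerange.estimate_motion_variance(
                model.times, model.xy, bcfg.sigma_loc
            )
        # one shared grid for all fish (overlap needs it), with a margin
        # wide enough for the widest bridge kernel any fitted fish produces
        max_var = 0.0
        for tag, model in models.items():
            dts = np.diff(model.times)
            bridged = dts[(dts > 0) & (dts <= model.max_lag)]
            if bridged.size:
                max_var = max(max_var, (bridged.max() / 4.0) * sigmas[tag])
        max_bridge_sd = np.sqrt(bcfg.sigma_loc**2 + max_var)
        grid = homerange.UDGrid.covering(
            st_xy, cell=bcfg.cell, margin=4.0 * max_bridge_sd + 100.0
        )
        results = {}
        for tag, model in models.items():
            model.grid = grid
            results[tag] = model.fit(sigma_m2=sigmas[tag])
        hr_col, ca_col, sg_col = {}, {}, {}
        polys = {}
        for tag, res in results.items():
            hr_col[tag] = res.hr95_km2
            ca_col[tag] = res.ca50_km2
            sg_col[tag] = res.sigma_m2
            polys[tag] = res.home_range_estimate.hr95.polygon
        ft = rep.fish_table
        ft["hr95_km2"] = ft["tag_id"].map(hr_col)
        ft["ca50_km2"] = ft["tag_id"].map(ca_col)
        ft["sigma_m2"] = ft["tag_id"].map(sg_col)
        rep.overlap = homerange.overlap_matrix(
            {t: r.ud for t, r in results.items()}, bcfg.hr_level
        )
        rep.overlap.to_csv(out / "overlap.csv")
        homerange.polygons_to_geojson(
            {f"{t}_hr95": p for t, p in polys.items()}, out / "hr95.geojson"
        )
        ft.to_csv(out / "fish_summary.csv", index=False)
    if last == 2:
        _finish(rep, out, config)
        return rep

    # ---- diel ---------------------------------------------------------
    with _stage("diel", timings):
        dcfg = config.diel
        diel_rows = []
        by_tag = {tr.tag_id: tr for tr in tracks}
        for tag in sorted(analysed_ids, key=str):
            tr = by_tag[tag]
            if tr.empty:
                continue
            span = pd.date_range(
                tr.detections["time"].min().date(),
                tr.detections["time"].max().date(),
                freq="D",
            )
            phases = diel.solar_phases(span, config.lat, config.lon)
            pm = diel.phase_metrics(tr, phases)
            ts_depth = diel.transition_series(pm, "mean_depth")
            ts_rec = diel.transition_series(pm, "hourly_receptions")
            cls = diel.classify_diel(
                ts_depth, dcfg.alpha_dn, dcfg.alpha_dd, dcfg.min_n, tag_id=tag
            )
            _, p_rec = (np.nan, np.nan) if len(ts_rec.pt_dn) < dcfg.min_n else (
                diel.wilcoxon_signed_rank(ts_rec.pt_dn)
            )
            diel_rows.append(
                {
                    "tag_id": tag,
                    "pattern": cls.pattern,
                    "p_dn": cls.p_dn,
                    "p_dd": cls.p_dd,
                    "median_dn": cls.median_dn,
                    "cyclic": cls.cyclic,
                    "p_dn_receptions": p_rec,
                    "n_dn": cls.n_dn,
                }
            )
        rep.diel_table = pd.DataFrame(diel_rows)
        if len(rep.diel_table):
            pat = rep.diel_table["pattern"]
            rep.diel_counts = {
                "n_classified": int(len(pat)),
                "n_with_pattern": int((pat != "none").sum()),
                "n_deeper_at_night": int((pat == "deeper_at_night").sum()),
                "n_shallower_at_night": int((pat == "shallower_at_night").sum()),
                "pct_with_pattern": float(100.0 * (pat != "none").mean()),
            }
        rep.diel_table.to_csv(out / "diel.csv", index=False)
    if last == 3:
        _finish(rep, out, config)
        return rep

    # ---- day typology -------------------------------------------------
    with _stage("typology", timings):
        tcfg = config.typology
        ana_tracks = [by_tag[t] for t in sorted(analysed_ids, key=str)
                      if not by_tag[t].empty]
        occ = daytypology.occupancy_matrix(
            ana_tracks, polys, tcfg.depth_bin, tcfg.dist_bin, tcfg.min_active_fish
        )
        rep.typology = daytypology.classify_days(
            occ, tcfg.linkage, tcfg.deep_threshold_m, tcfg.depth_bin
        )
        env = None
        if config.environment:
            env = pd.read_csv(config.environment)
        rep.env_overlay = daytypology.environmental_overlay(rep.typology, env)
        occ.data.to_csv(out / "occupancy.csv")
        rep.typology.dissimilarity.to_csv(out / "dissimilarity.csv")
        rep.typology.labels.rename("label").to_csv(out / "day_labels.csv")
        rep.typology.coordinates.to_csv(out / "pcoa.csv")
        rep.env_overlay.to_csv(out / "env_overlay.csv", index=False)

    _finish(rep, out, config)
    return rep


def _finish(rep: StudyReport, out: Path, config: StudyConfig) -> None:
    summary = {
        "n_fish": int(len(rep.fish_table)),
        "n_analysed": int(rep.fish_table["analysed"].sum()) if len(rep.fish_table) else 0,
        "diel_counts": rep.diel_counts,
        "timings_s": {k: round(v, 3) for k, v in rep.timings.items()},
    }
    if rep.typology is not None:
        lab = rep.typology.labels
        summary["typology"] = {
            "n_days": int(len(lab)),
            "n_extraordinary": int((lab == "extraordinary").sum()),
            "extraordinary_days": [d.isoformat() for d in rep.typology.extraordinary_days],
        }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    if config.figures:
        from . import plots

        plots.save_report_figures(rep, out)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the table's reporting convention), unlike
    banker's rounding."""
    import decimal

    if not np.isfinite(x):
        return x
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def load_table1() -> pd.DataFrame:
    """The bundled per-fish monitoring summary (transcribed in-paper
    table): one row per tagged fish with detection-day counts, tracking
    period, per-zone residence indices and BBMM areas."""
    with resources.files("reefrange.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh, comment="#", dtype={"fish_id": str})


_ZONE_OF_SITE = {"TAS": "NT", "POR": "NT", "ARQ": "PR", "FAL": "NR"}


def table1_aggregates(table: pd.DataFrame | None = None) -> dict:
    """Cohort aggregates recomputed from the per-fish table.

    Returns NT-cohort tracking-period mean/SD (analysed fish only),
    own-zone residence-index mean/SD and home-range mean/SD over the
    analysed fish, and the per-fish DD/TP -> RI consistency checks
    (printed RI equals DD/TP rounded half-up to 2 decimals for fish that
    stayed in their capture zone).
    """
    t = table if table is not None else load_table1()
    t = t.copy()
    t["zone"] = t["capture_location"].map(_ZONE_OF_SITE)
    ana = t[t["fate"] == "ok"]

    nt = ana[ana["zone"] == "NT"]["tp"].astype(float)
    own_ri = ana.apply(lambda r: float(r["ri_" + r["zone"].lower()]), axis=1)
    hr = ana["hr95_km2"].astype(float)

    ri_checks = {}
    for _, r in ana.iterrows():
        ri_checks[r["fish_id"]] = {
            "dd": int(r["dd"]),
            "tp": int(r["tp"]),
            "ri_from_dd_tp": round_half_up(r["dd"] / r["tp"], 2),
            "ri_printed_own_zone": float(own_ri.loc[r.name]),
        }
    return {
        "n_analysed": int(len(ana)),
        "nt_tp_mean": float(nt.mean()),
        "nt_tp_sd": float(nt.std(ddof=1)),
        "nt_n": int(len(nt)),
        "ri_mean": float(own_ri.mean()),
        "ri_sd": float(own_ri.std(ddof=1)),
        "hr95_mean_km2": float(hr.mean()),
        "hr95_sd_km2": float(hr.std(ddof=1)),
        "ri_checks": ri_checks,
    }
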