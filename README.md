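# reefrange

Passive acoustic telemetry analysis for territorial reef fish: from raw
receiver detection logs to residence indices, Brownian-bridge home ranges
and overlap, diel activity statistics and an ordinary/extraordinary day
typology — plus a ground-truthed synthetic telemetry generator to exercise
every estimator.

## Who this is for

Movement ecologists running fixed-receiver acoustic arrays (VR2-style) on
sedentary coastal fish. A tagged fish transmits every 80–180 s; each moored
receiver logs the transmissions it can decode (range ≈ 150 m at >90%
probability). From those logs the package computes, per fish and cohort:

- **Residence index** `RI = DD / TP` — distinct detection days over the
  inclusive tracking-period day span, per protection zone, with
  receiver-outage masking, spurious-reception filtering (sole receptions in
  a 24 h window are deleted), and a single-receiver/constant-depth
  mortality audit.
- **Home range** — the Brownian Bridge Movement Model (BBMM) utilization
  distribution `UD` on a planar grid. Each consecutive location pair
  (receiver coordinates) contributes the time-averaged bridge density with
  variance `s²(α) = Δt·α(1−α)·σ²_m + ((1−α)² + α²)·σ²_loc`, where the
  motion variance σ²_m is fitted by the leave-one-out bridge likelihood and
  σ_loc defaults to the 150 m detection range. Home range (HR) and core
  area (CA) are the minimum-area 95% / 50% UD volume contours; pairwise
  space sharing uses the utilization distribution overlap index,
  `UDOI = A_overlap · ∫∫ UD₁·UD₂` (0 disjoint, 1 identical-uniform, >1
  concentrated overlap).
- **Diel patterns** — receptions split at NOAA sunrise/sunset into
  day/night phases; per-phase mean depth and hourly reception number; the
  phase-transition statistics `PT_DN = D_t − N_t` and `PT_DD = D_t − D_{t+1}`
  tested against median zero by Wilcoxon signed-rank (exact for n ≤ 25).
  A significantly negative depth `PT_DN` median means the fish sits deeper
  at night.
- **Day typology** — daily percentages of fish per 1-m depth class and
  200-m distance-to-HR class, Bray-Curtis dissimilarities between days,
  average-linkage clustering cut at two groups, PCoA ordination, and an
  environmental (SST / wave height) overlay. The minority cluster with
  high deep/far occupancy is the *extraordinary* days — storm sheltering
  and deep spawning excursions.

## Worked example

Simulate a small ground-truthed study and push it through the analysis:

```python
from reefrange import BrownianBridgeModel, SimConfig, build_sim_study
from reefrange.io import (read_stations, read_tag_registry, read_detections,
                          filter_spurious, build_tracks)
from reefrange.residency import residence_index

study = build_sim_study(SimConfig(n_days=30, n_fish_nt=3, n_fish_pr=0,
                                  n_fish_nr=0, n_disappeared=0, n_dead=0),
                        seed=42)
study.write("demo")

stations = read_stations("demo/stations.csv")
registry = read_tag_registry("demo/tags.csv")
det, report = read_detections("demo/detections.csv", stations)
kept, removed = filter_spurious(det)
tracks, _ = build_tracks(kept, registry, stations)

tr = tracks[0]
s = residence_index(tr)
print(f"tag {tr.tag_id}: DD={s.dd}, TP={s.tp}, RI={s.ri:.2f}")
res = BrownianBridgeModel.from_track(tr, sigma_loc=150.0).fit()
print(res.summary())
```

prints

```
tag 10: DD=30, TP=30, RI=1.00
Brownian Bridge Movement Model
==============================
fish:              10
positions:         9980
sigma_m2 (m^2/s):  128.331
sigma_loc (m):     150.0
grid cell (m):     25.0
HR 95% (km^2):     0.922
CA 50% (km^2):     0.152
```

The fish was detected on all 30 tracking days (RI = 1.00). Its estimated
95% home range, 0.92 km², is several times the simulator's true 95% range
for this fish (0.27 km²): with a 150 m location error the error-scaled UD
spills well beyond the space the animal actually used, the overestimation
inherent to passive-telemetry home ranges (see `docs/methods.md`).

A full study — ingest, residency, home ranges, diel classification, day
typology, figures — runs from one YAML config:

```sh
reefrange simulate --out demo --seed 42 --days 60
reefrange run --config study.yaml
reefrange check-paper
```

`check-paper` recomputes cohort aggregates from the bundled per-fish
monitoring table (`src/reefrange/data/table1.csv`, a transcription of the
published study summary):

```
analysed fish:        33
NT tracking period:   329 ± 65 d (n=18)
residence index:      0.95 ± 0.06
home range (95%):     0.49 ± 0.26 km²
```

## Layout

| module | contents |
| --- | --- |
| `reefrange.io` | data model, CSV readers, deployment validation, spurious filter |
| `reefrange.residency` | RI, presence matrix, depth interval, mortality flag, group tests |
| `reefrange.homerange` | `BrownianBridgeModel` / `BBMMResults`, UD grid, contours, UDOI |
| `reefrange.diel` | NOAA solar phases, chronograms, PT series, Wilcoxon classification |
| `reefrange.daytypology` | occupancy matrices, Bray-Curtis clustering, PCoA, env overlay |
| `reefrange.synth` | OU movement simulator, logistic detection model, study builder |
| `reefrange.pipeline` | staged orchestration, config, reporting, bundled-table aggregates |
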