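import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from reefrange.io import FishTrack


def make_track(tag_id, times, stations, depths=None, xy=None, zones=None):
    """Assemble a FishTrack from parallel lists (tests' little helper)."""
    times = pd.to_datetime(list(times), utc=True)
    n = len(times)
    df = pd.DataFrame(
        {
            "tag_id": tag_id,
            "station_id": list(stations),
            "time": times,
            "depth": list(depths) if depths is not None else np.full(n, np.nan),
        }
    )
    if xy is not None:
        df["x"] = [p[0] for p in xy]
        df["y"] = [p[1] for p in xy]
    if zones is not None:
        df["zone"] = list(zones)
    df = df.sort_values("time", kind="mergesort").reset_index(drop=True)
    return FishTrack(tag_id=tag_id, detections=df)


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared by integration tests."""
    from reefrange.synth import SimConfig, build_sim_study

    cfg = SimConfig(
        n_days=30,
        n_fish_nt=4,
        n_fish_pr=2,
        n_fish_nr=2,
        n_disappeared=1,
        n_dead=1,
    )
    return build_sim_study(cfg, seed=11)
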