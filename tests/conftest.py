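"""Shared fixtures: the imaging benchmark movies are expensive, so they are
rendered, segmented and tracked once per session and reused by the
segmentation, tracking, pipeline and acceptance tests."""
from __future__ import annotations

import numpy as np
import pytest

from mitoscreen import synthetic_data as sd
from mitoscreen.cell_tracking import track_movie
from mitoscreen.nuclei_imaging import segment_movie

#: canonical imaging benchmark: 25 seed cells at 2-radii spacing, 4-28 h,
#: division rate 0.04/h -> ~100 cells and ~30 divisions by the last frame
BENCHMARK_SPEC = sd.MovieSpec(t_start=4.0, t_end=28.0)
BENCHMARK_N_CELLS = 25
BENCHMARK_RATE = 0.04
BENCHMARK_SEEDS = (0, 1, 2)


def _build_benchmark(seed: int) -> dict:
    log = sd.simulate_well(
        n_cells=BENCHMARK_N_CELLS, baseline_division_rate=BENCHMARK_RATE,
        spec=BENCHMARK_SPEC, seed=seed,
    )
    stacks = sd.render_movie(log, BENCHMARK_SPEC, seed=seed)
    tables = segment_movie(stacks["H2B_red"])
    tracks, events = track_movie(stacks["H2B_red"])
    return {"seed": seed, "log": log, "spec": BENCHMARK_SPEC, "stacks": stacks,
            "tables": tables, "tracks": tracks, "events": events}


@pytest.fixture(scope="session")
def benchmark_movies() -> list[dict]:
    return [_build_benchmark(seed) for seed in BENCHMARK_SEEDS]


def match_splits(bench: dict, time_tol_h: float = 1.01, radius_um: float = 20.0):
    """Greedy matching of detected splits to ground-truth divisions.

    Returns (n_true, n_detected, n_matched).
    """
    truth = sd.division_truth(bench["log"])
    times = bench["spec"].frame_times()
    used: set[int] = set()
    matched = 0
    for e in bench["events"]:
        t_ev = times[e.frame]
        for i, row in truth.iterrows():
            if i in used:
                continue
            if (abs(row["time_h"] - t_ev) <= time_tol_h
                    and np.hypot(row["x_um"] - e.x, row["y_um"] - e.y) <= radius_um):
                used.add(i)
                matched += 1
                break
    return len(truth), len(bench["events"]), matched
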