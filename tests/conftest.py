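"""Shared fixtures: small rendered movies and track↔truth matching."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nfdyn.features import FeatureConfig
from nfdyn.pipeline import analyze_movie, condition_seed
from nfdyn.response_model import default_presets
from nfdyn.segment import SegmentationConfig
from nfdyn.simulate import ImagingConfig, simulate_condition

SMALL_IMAGING = ImagingConfig(
    height=256,
    width=256,
    nucleus_semi_axes=(5.0, 7.0),
    cyto_extent=9.0,
)
SMALL_SEG = SegmentationConfig(min_peak_distance=5)


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture(scope="session")
def small_movie(presets):
    """One noisy 30-cell 256x256 movie of the Sigma preset at 0.5 µg/mL."""
    return simulate_condition(presets["Sigma"], 0.5, False, 30, SMALL_IMAGING, seed=11)


def match_tracks_to_truth(tracks, truth, max_dist: float = 5.0) -> dict[int, int]:
    """Greedy matching of recovered tracks to ground-truth cells.

    Tracks and cells pair up by mean centroid distance over shared frames;
    each cell is used at most once.  Returns {track_id: cell_id}.
    """
    gt = truth.tracks.set_index(["cell_id", "frame"])
    candidates = []
    cell_ids = truth.tracks["cell_id"].unique()
    for track in tracks:
        frames = np.array([r[0] for r in track.rows])
        pos = np.array([[r[2], r[3]] for r in track.rows])
        for cid in cell_ids:
            sub = gt.loc[cid]
            shared = np.isin(frames, sub.index)
            if not shared.any():
                continue
            ref = sub.loc[frames[shared], ["row", "col"]].to_numpy()
            d = float(np.mean(np.linalg.norm(pos[shared] - ref, axis=1)))
            if d <= max_dist:
                candidates.append((d, track.track_id, int(cid)))
    candidates.sort()
    matched: dict[int, int] = {}
    used: set[int] = set()
    for _, tid, cid in candidates:
        if tid in matched or cid in used:
            continue
        matched[tid] = cid
        used.add(cid)
    return matched


@pytest.fixture(scope="session")
def condition_runs(presets):
    """Reduced end-to-end runs of the five anchor conditions.

    Each entry holds the ground truths, recovered tracks and the pooled
    active-cell feature table with a ``cell_id`` column for truth matching.
    About 100 active cells per condition.
    """
    plan = {
        ("Sigma", 0.5): 4,
        ("EB", 0.5): 4,
        ("UP", 0.5): 4,
        ("UP", 5.0): 4,
        ("UP", 0.05): 17,
    }
    runs = {}
    for (name, conc), n_movies in plan.items():
        tables = []
        pairs = []  # (truth, tracks) per movie
        for m in range(n_movies):
            seed = condition_seed(0, name, conc, False, m)
            movie, truth = simulate_condition(
                presets[name], conc, False, 30, SMALL_IMAGING, seed
            )
            _, tracks, traces, table = analyze_movie(movie, SMALL_SEG, FeatureConfig())
            matched = match_tracks_to_truth(tracks, truth)
            table = table.copy()
            table["cell_id"] = table["track_id"].map(matched)
            table["movie"] = m
            tables.append(table)
            pairs.append((truth, tracks))
        runs[(name, conc)] = {
            "table": pd.concat(tables, ignore_index=True),
            "movies": pairs,
        }
    return runs
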