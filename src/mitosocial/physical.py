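"""Per-cell physical summary statistics of mitochondrial trajectories.

Three statistics, all in calibrated units:

* **speed** (µm/frame): per trajectory, the mean distance moved per frame
  over consecutive spots; when the tracker closed a gap of g frames the
  displacement is divided by g (the gap is treated as continuous
  motion).  Cell-level value = mean (and median) over trajectories.
* **inter-mitochondrial distance** (µm): per frame, the distance from
  each mitochondrion to its nearest neighbour; averaged within the
  frame, then over frames — so crowded frames do not dominate.
* **co-localization time** (frames): per unordered trajectory pair, the
  number of frames both are present within a threshold distance
  (default 1.6 µm) of each other.  The headline cell-level value is the
  mean over pairs that ever co-localize; the mean over *all* pairs is
  reported alongside.

Pairs are evaluated only on frames where both tracks have spots —
nothing is interpolated, so no co-localization evidence is fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import DEFAULT_ENCOUNTER_THRESHOLD_UM
from .io import TrajectorySet


@dataclass
class PhysicalSummary:
    """One cell's physical statistics for one observation window."""

    mean_speed_um_per_frame: float
    median_speed_um_per_frame: float
    pooled_median_step_speed: float
    mean_intermito_distance_um: float
    mean_coloc_time_frames: float  # over pairs that ever co-localize
    mean_coloc_time_all_pairs: float
    n_tracks: int
    n_single_spot_tracks: int
    window_frames: int
    intermito_defined: bool
    any_coloc_pair: bool


def track_speeds(ts: TrajectorySet) -> pd.Series:
    """Mean speed (µm/frame) per track.

    Each step between consecutive spots contributes Euclidean
    displacement divided by the frame gap; a track's speed is the mean
    of its steps.  Tracks with a single spot have no steps and are
    excluded (callers can count them via the difference from
    ``ts.n_tracks``).
    """
    s = ts.spots
    dx = s.groupby("track_id")[["x", "y"]].diff()
    dframe = s.groupby("track_id")["frame"].diff()
    step_speed = np.hypot(dx["x"], dx["y"]) / dframe
    per_track = step_speed.groupby(s["track_id"]).mean().dropna()
    per_track.name = "speed_um_per_frame"
    return per_track


def step_speeds(ts: TrajectorySet) -> np.ndarray:
    """All per-step speeds (µm/frame) pooled over tracks."""
    s = ts.spots
    dx = s.groupby("track_id")[["x", "y"]].diff()
    dframe = s.groupby("track_id")["frame"].diff()
    return (np.hypot(dx["x"], dx["y"]) / dframe).dropna().values


def speed_summary(ts: TrajectorySet) -> tuple[float, float, float]:
    """(mean-of-track-means, median-of-track-means, pooled per-step median)."""
    per_track = track_speeds(ts)
    pooled = step_speeds(ts)
    if len(per_track) == 0:
        return float("nan"), float("nan"), float("nan")
    return (
        float(per_track.mean()),
        float(per_track.median()),
        float(np.median(pooled)),
    )


def inter_mito_distance(ts: TrajectorySet) -> float:
    """Mean nearest-neighbour distance (µm), frame-averaged.

    Frames with fewer than two spots carry no spacing information and
    are skipped; NaN is returned (statistic undefined) when every frame
    is skipped.
    """
    frame_means = []
    for _, grp in ts.iter_frames():
        if len(grp) < 2:
            continue
        pts = grp[["x", "y"]].values
        tree = cKDTree(pts)
        # k=2: nearest neighbour other than the point itself
        dist, _ = tree.query(pts, k=2)
        frame_means.append(dist[:, 1].mean())
    if not frame_means:
        return float("nan")
    return float(np.mean(frame_means))


def coloc_time(
    ts: TrajectorySet,
    threshold_um: float = DEFAULT_ENCOUNTER_THRESHOLD_UM,
    window: Optional[tuple[int, int]] = None,
) -> pd.DataFrame:
    """Per-pair co-localization frame counts.

    Returns a table with columns ``track_i``, ``track_j`` (i < j) and
    ``frames``: the number of frames within ``window`` (inclusive; whole
    video by default) in which both tracks are present and at Euclidean
    distance <= ``threshold_um``.  Only pairs with a positive count
    appear; this table doubles as the weighted edge list of the
    encounter network.
    """
    if window is not None:
        ts = ts.restrict_frames(*window)
    counts: dict[tuple[int, int], int] = {}
    for _, grp in ts.iter_frames():
        if len(grp) < 2:
            continue
        pts = grp[["x", "y"]].values
        ids = grp["track_id"].values
        pairs = cKDTree(pts).query_pairs(threshold_um, output_type="ndarray")
        for a, b in pairs:
            i, j = int(ids[a]), int(ids[b])
            key = (i, j) if i < j else (j, i)
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["track_i", "track_j", "frames"]).astype(
            {"track_i": np.int64, "track_j": np.int64, "frames": np.int64}
        )
    table = pd.DataFrame(
        [(i, j, c) for (i, j), c in sorted(counts.items())],
        columns=["track_i", "track_j", "frames"],
    )
    return table


def coloc_time_summary(
    ts: TrajectorySet,
    threshold_um: float = DEFAULT_ENCOUNTER_THRESHOLD_UM,
) -> tuple[float, float, bool]:
    """(mean over positive pairs, mean over all pairs, any-pair flag).

    The all-pairs mean spreads the total co-localized frame count over
    every unordered track pair; the positive-pair mean — the headline
    statistic — conditions on pairs that ever meet.  With no
    co-localizing pair both means are 0 and the flag is False.
    """
    table = coloc_time(ts, threshold_um)
    n = ts.n_tracks
    n_pairs = n * (n - 1) // 2
    if len(table) == 0:
        return 0.0, 0.0, False
    positive_mean = float(table["frames"].mean())
    all_mean = float(table["frames"].sum() / n_pairs) if n_pairs else 0.0
    return positive_mean, all_mean, True


def physical_summary(
    ts: TrajectorySet,
    threshold_um: float = DEFAULT_ENCOUNTER_THRESHOLD_UM,
) -> PhysicalSummary:
    """Compute the full :class:`PhysicalSummary` for one trajectory set."""
    mean_sp, med_sp, pooled_med = speed_summary(ts)
    imd = inter_mito_distance(ts)
    pos_mean, all_mean, any_pair = coloc_time_summary(ts, threshold_um)
    n_tracks = ts.n_tracks
    n_with_steps = len(track_speeds(ts))
    return PhysicalSummary(
        mean_speed_um_per_frame=mean_sp,
        median_speed_um_per_frame=med_sp,
        pooled_median_step_speed=pooled_med,
        mean_intermito_distance_um=imd,
        mean_coloc_time_frames=pos_mean,
        mean_coloc_time_all_pairs=all_mean,
        n_tracks=n_tracks,
        n_single_spot_tracks=n_tracks - n_with_steps,
        window_frames=ts.n_frames,
        intermito_defined=not np.isnan(imd),
        any_coloc_pair=any_pair,
    )
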