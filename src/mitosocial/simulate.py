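"""Seeded synthetic trajectory generator.

Emulates the motion phenomenology the analysis assumes for plant
hypocotyl cells: per cell, a population of organelles in a bounded 2D
domain showing a mixture of static, diffusive (Brownian) and ballistic
(persistent directed) motion, with optional proximity-triggered
clustering to mimic the aggregated phenotypes of fusion/maintenance
mutants, and optional static chloroplasts.

The generator emits trajectories, not images: its output plugs directly
into the same analysis pipeline as tracker exports, and a ground-truth
sidecar records each track's programmed motion class and the
stick/release events, so downstream statistics can be tested against
known structure.

Model
-----
* Motion classes are assigned deterministically by largest-remainder
  apportionment of the configured fractions, so the realised class
  counts match the fractions as closely as integer counts allow.
* Diffusive steps are Gaussian with per-axis variance 2·D·Δt.
* Ballistic movers advance speed·Δt along a heading kept with
  probability ``direction_persistence`` per frame (otherwise redrawn
  uniformly); a step that would leave the domain reflects the heading,
  preserving the step length.
* Diffusive/static positions are folded back into the domain
  (reflecting boundaries) — cells are bounded, not periodic.
* Clustering: when enabled, two organelles of different clusters within
  ``attraction_radius`` stick with ``sticking_prob`` per frame.  A stuck
  cluster moves jointly — one displacement, drawn from the motion class
  of its lowest-id member, is applied to every member — which is the
  simplest mechanism producing the elevated co-localization times seen
  in clustering mutants.  Each member of a multi-member cluster leaves
  it with ``unsticking_prob`` per frame.
* Chloroplasts are static discs of radius 1.5 µm placed uniformly at
  random without overlap (rejection sampling with bounded retries).

All randomness flows from a single integer seed through numpy's PCG64
generator, so identical seeds give identical output across platforms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import CHLOROPLAST_RADIUS_UM
from .io import (
    CHLOROPLAST,
    MITOCHONDRION,
    CellRecord,
    TrajectorySet,
)

STATIC, DIFFUSIVE, BALLISTIC = "static", "diffusive", "ballistic"


class ConfigurationError(ValueError):
    """The simulation configuration is infeasible."""


@dataclass
class ClusteringConfig:
    """Proximity-triggered sticking parameters.

    ``sticking_prob`` and ``unsticking_prob`` are per frame.  Stuck
    clusters share one displacement per frame and additionally cohere:
    each member relaxes toward the cluster centroid by the fraction
    ``cohesion`` per frame while receiving isotropic Gaussian jitter of
    s.d. ``jitter_um`` — so aggregates are compact blobs whose members
    keep rearranging, as clustered mitochondria do, rather than frozen
    constellations.
    """

    enabled: bool = False
    attraction_radius_um: float = 1.5
    sticking_prob: float = 0.0
    unsticking_prob: float = 0.0
    cohesion: float = 0.2
    jitter_um: float = 0.15


@dataclass
class SimulationConfig:
    """Full parameterization of one simulated cell.

    Defaults describe a plausible wild-type-like hypocotyl cell: an
    elongated 15×100 µm quasi-2D domain (epidermal hypocotyl cells are
    several times longer than wide) holding 100 mitochondria followed
    for 120 frames of 233/120 ≈ 1.94 s each (a 233 s window), with
    30% static, 50% diffusive and 20% ballistic (0.6 µm/s, heading kept
    with probability 0.9 per frame) organelles and no clustering.  The
    default diffusion coefficient, D = 0.01 µm²/s, sits in the measured
    range for plant mitochondria and makes a contact at the 1.6 µm
    encounter threshold persist ~1.6²/(8·D) ≈ 32 s (tens of frames),
    the scale wild-type co-localization times are reported on.
    """

    n_mito: int = 100
    n_chloro: int = 0
    domain_um: tuple[float, float] = (15.0, 100.0)
    n_frames: int = 120
    frame_interval_s: float = 233.0 / 120.0
    fractions: tuple[float, float, float] = (0.3, 0.5, 0.2)  # static, diffusive, ballistic
    diffusion_coeff_um2_s: float = 0.01
    ballistic_speed_um_s: float = 0.6
    direction_persistence: float = 0.9
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (3,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"fractions must be 3 non-negative numbers summing to 1, got {self.fractions}"
            )
        if self.n_mito < 0 or self.n_chloro < 0 or self.n_frames < 1:
            raise ConfigurationError("counts must be non-negative, n_frames >= 1")
        w, h = self.domain_um
        if not (w > 0 and h > 0):
            raise ConfigurationError("domain must have positive extent")
        if self.frame_interval_s <= 0:
            raise ConfigurationError("frame_interval_s must be positive")
        if self.diffusion_coeff_um2_s < 0 or self.ballistic_speed_um_s < 0:
            raise ConfigurationError("rates must be non-negative")
        if not 0 <= self.direction_persistence <= 1:
            raise ConfigurationError("direction_persistence must be in [0, 1]")


@dataclass
class SimulatedCell:
    """A simulated cell plus the ground truth that produced it."""

    cell: CellRecord
    motion_class: dict[int, str]
    #: (track_i, track_j, frame) sticking events, i < j.
    stick_events: list[tuple[int, int, int]]
    #: (track, frame) release events.
    release_events: list[tuple[int, int]]
    chloro_positions: np.ndarray  # (n_chloro, 2), µm


def _apportion(fractions: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n items to len(fractions) classes."""
    quotas = fractions * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    if remainder:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _place_chloroplasts(
    rng: np.random.Generator, n: int, domain: tuple[float, float], radius: float
) -> np.ndarray:
    """Uniform non-overlapping disc centres; raises after bounded retries."""
    centres: list[np.ndarray] = []
    max_tries = 1000 * max(n, 1)
    tries = 0
    while len(centres) < n:
        if tries >= max_tries:
            raise ConfigurationError(
                f"could not place {n} non-overlapping chloroplasts "
                f"of radius {radius} µm in a {domain[0]}x{domain[1]} µm domain"
            )
        tries += 1
        c = rng.uniform((0.0, 0.0), domain)
        if all(np.hypot(*(c - p)) >= 2 * radius for p in centres):
            centres.append(c)
    return np.array(centres).reshape(n, 2)


def _reflect_into(x: np.ndarray, size: float) -> np.ndarray:
    """Fold coordinates into [0, size] by reflection at the walls."""
    period = 2.0 * size
    x = np.mod(x, period)
    return np.where(x > size, period - x, x)


def simulate_cell(cfg: SimulationConfig) -> SimulatedCell:
    """Simulate one cell's trajectories from a :class:`SimulationConfig`.

    Returns a :class:`SimulatedCell` whose ``cell`` is a fully valid
    :class:`~mitosocial.io.CellRecord` (cell area = domain area) and
    whose ground-truth fields record motion classes, stick/release
    events and chloroplast centres.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_mito
    w, h = cfg.domain_um
    dt = cfg.frame_interval_s

    counts = _apportion(np.asarray(cfg.fractions, dtype=float), n)
    classes = np.repeat([STATIC, DIFFUSIVE, BALLISTIC], counts)
    rng.shuffle(classes)

    pos = rng.uniform((0.0, 0.0), (w, h), size=(n, 2))
    headings = rng.uniform(0.0, 2.0 * np.pi, size=n)
    sigma = math.sqrt(2.0 * cfg.diffusion_coeff_um2_s * dt)
    step_len = cfg.ballistic_speed_um_s * dt

    # cluster bookkeeping: cluster[i] == representative track id
    cluster = np.arange(n)
    cl = cfg.clustering
    stick_events: list[tuple[int, int, int]] = []
    release_events: list[tuple[int, int]] = []

    frames = np.empty((cfg.n_frames, n, 2))
    frames[0] = pos

    for t in range(1, cfg.n_frames):
        if cl.enabled and n > 1:
            # releases first, then new bonds, both evaluated on current positions
            sizes = np.bincount(cluster, minlength=n)
            in_multi = sizes[cluster] > 1
            leave = in_multi & (rng.random(n) < cl.unsticking_prob)
            for i in np.flatnonzero(leave):
                release_events.append((int(i), t))
                old_rep = cluster[i]
                cluster[i] = i
                remaining = np.flatnonzero(cluster == old_rep)
                if old_rep == i:
                    # i was the representative: re-anchor the remaining members
                    remaining = np.flatnonzero(cluster == i)
                    remaining = remaining[remaining != i]
                    if len(remaining):
                        cluster[remaining] = remaining.min()
                if len(remaining):
                    # release is a fission event: eject the member just
                    # outside the aggregate's capture zone, in a random
                    # direction, so it genuinely resumes independent motion
                    centroid = pos[remaining].mean(axis=0)
                    rmax = float(
                        np.hypot(*(pos[remaining] - centroid).T).max()
                    )
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    pos[i] = centroid + (rmax + cl.attraction_radius_um) * np.array(
                        [math.cos(theta), math.sin(theta)]
                    )
                    pos[i, 0] = _reflect_into(pos[i, 0], w)
                    pos[i, 1] = _reflect_into(pos[i, 1], h)
            # proximity sticking between distinct clusters
            pairs = cKDTree(pos).query_pairs(cl.attraction_radius_um, output_type="ndarray")
            if len(pairs):
                order = rng.permutation(len(pairs))
                stick = rng.random(len(pairs)) < cl.sticking_prob
                for k in order:
                    if not stick[k]:
                        continue
                    i, j = int(pairs[k, 0]), int(pairs[k, 1])
                    ri, rj = cluster[i], cluster[j]
                    if ri == rj:
                        continue
                    rep = min(ri, rj)
                    cluster[(cluster == ri) | (cluster == rj)] = rep
                    stick_events.append((min(i, j), max(i, j), t))

        # one displacement per cluster, from the representative's motion class
        diff_steps = rng.normal(0.0, sigma, size=(n, 2))
        keep = rng.random(n) < cfg.direction_persistence
        new_heading = rng.uniform(0.0, 2.0 * np.pi, size=n)
        headings = np.where(keep, headings, new_heading)

        reps = np.unique(cluster)
        disp = np.zeros((n, 2))
        for r in reps:
            kind = classes[r]
            if kind == STATIC:
                d = np.zeros(2)
            elif kind == DIFFUSIVE:
                d = diff_steps[r]
            else:
                hx, hy = math.cos(headings[r]), math.sin(headings[r])
                # reflect heading off walls so the step length is preserved
                nx, ny = pos[r, 0] + step_len * hx, pos[r, 1] + step_len * hy
                if nx < 0 or nx > w:
                    hx = -hx
                if ny < 0 or ny > h:
                    hy = -hy
                headings[r] = math.atan2(hy, hx)
                d = np.array([step_len * hx, step_len * hy])
            disp[cluster == r] = d

        pos = pos + disp

        if cl.enabled and n > 1:
            # intra-cluster cohesion: members of multi-member clusters relax
            # toward the cluster centroid with small jitter, keeping
            # aggregates compact and internally rearranging
            jitter = rng.normal(0.0, cl.jitter_um, size=(n, 2))
            for r in np.unique(cluster):
                members = np.flatnonzero(cluster == r)
                if len(members) < 2:
                    continue
                centroid = pos[members].mean(axis=0)
                pos[members] = (
                    centroid
                    + (pos[members] - centroid) * (1.0 - cl.cohesion)
                    + jitter[members]
                )

        pos[:, 0] = _reflect_into(pos[:, 0], w)
        pos[:, 1] = _reflect_into(pos[:, 1], h)
        frames[t] = pos

    spots = pd.DataFrame(
        {
            "track_id": np.tile(np.arange(n), cfg.n_frames),
            "frame": np.repeat(np.arange(cfg.n_frames), n),
            "x": frames[:, :, 0].ravel(),
            "y": frames[:, :, 1].ravel(),
        }
    )
    mito = TrajectorySet(
        spots,
        n_frames=cfg.n_frames,
        frame_interval_s=dt,
        organelle_kind=MITOCHONDRION,
        meta={"units": "um", "simulated": True, "seed": cfg.seed},
    )

    chloro = None
    chloro_pos = np.empty((0, 2))
    if cfg.n_chloro > 0:
        chloro_pos = _place_chloroplasts(rng, cfg.n_chloro, (w, h), CHLOROPLAST_RADIUS_UM)
        cspots = pd.DataFrame(
            {
                "track_id": np.tile(np.arange(cfg.n_chloro), cfg.n_frames),
                "frame": np.repeat(np.arange(cfg.n_frames), cfg.n_chloro),
                "x": np.tile(chloro_pos[:, 0], cfg.n_frames),
                "y": np.tile(chloro_pos[:, 1], cfg.n_frames),
            }
        )
        chloro = TrajectorySet(
            cspots,
            n_frames=cfg.n_frames,
            frame_interval_s=dt,
            organelle_kind=CHLOROPLAST,
            meta={"units": "um", "simulated": True, "seed": cfg.seed},
        )

    cell = CellRecord(
        cell_id=f"sim-{cfg.seed}",
        genotype="simulated",
        mito=mito,
        chloro=chloro,
        cell_area_um2=w * h,
        pixel_scale=float("nan"),
    )
    return SimulatedCell(
        cell=cell,
        motion_class={int(i): str(classes[i]) for i in range(n)},
        stick_events=stick_events,
        release_events=release_events,
        chloro_positions=chloro_pos,
    )


def make_cohort(
    base_cfg: SimulationConfig,
    genotype_specs: dict[str, dict],
    n_cells_per_genotype: int,
    seed: int = 0,
) -> list[CellRecord]:
    """Simulate a cohort of cells across genotypes.

    ``genotype_specs`` maps genotype label → field overrides applied to
    ``base_cfg`` (``clustering`` may be given as a dict of
    :class:`ClusteringConfig` fields).  Per-cell seeds are derived
    deterministically from ``seed`` via numpy's ``SeedSequence``, so the
    same seed reproduces the same cohort; genotype labels and unique
    cell ids are attached.
    """
    valid = {f for f in SimulationConfig.__dataclass_fields__ if f != "seed"}
    cells: list[CellRecord] = []
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(genotype_specs) * n_cells_per_genotype
    ) % (2**31)
    k = 0
    for genotype in genotype_specs:
        overrides = dict(genotype_specs[genotype])
        bad = set(overrides) - valid
        if bad:
            raise ConfigurationError(f"unknown SimulationConfig field(s): {sorted(bad)}")
        if isinstance(overrides.get("clustering"), dict):
            overrides["clustering"] = ClusteringConfig(**overrides["clustering"])
        for i in range(n_cells_per_genotype):
            cfg = replace(base_cfg, **overrides, seed=int(child_seeds[k]))
            k += 1
            sim = simulate_cell(cfg)
            cell = sim.cell
            cell.cell_id = f"{genotype}-{i:03d}"
            cell.genotype = genotype
            cells.append(cell)
    return cells


def write_ground_truth(sim: SimulatedCell, path: str | Path) -> None:
    """Write the ground-truth sidecar (motion classes, events, chloroplasts) as JSON."""
    payload = {
        "motion_class": sim.motion_class,
        "stick_events": sim.stick_events,
        "release_events": sim.release_events,
        "chloro_positions": sim.chloro_positions.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
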