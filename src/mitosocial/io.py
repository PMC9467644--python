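"""Reading, writing and validating organelle trajectory tables.

Input is the spot table exported by a particle tracker (TrackMate-style
CSV: one row per detected spot with a track id, frame index and x/y
position).  Two dialects are supported:

* ``simple`` — a single header row followed by data rows.
* ``trackmate7`` — newer exporters emit extra sub-header rows (human
  readable names and units) between the header and the data; these are
  skipped.

Positions are analysed in µm.  Files exported in pixel units are converted
by dividing by ``pixel_scale`` (pixels per µm).  Frames are 0-based; z is
ignored — the cells analysed are quasi-2D.

The canonical on-disk format is a tidy CSV (``cell_id, organelle,
track_id, frame, x_um, y_um``) preceded by ``#``-comment metadata lines,
with a bit-exact round-trip guarantee.

Tracks are treated at trajectory granularity: one tracker track id is one
node identity for the whole video.  Missing frames inside a track (gap
closing upstream) are *not* interpolated — a track simply contributes
nothing in frames where it has no spot, so no encounter evidence is
fabricated.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .config import DEFAULT_MAX_FRAME_GAP

PathLike = Union[str, Path]

MITOCHONDRION = "mitochondrion"
CHLOROPLAST = "chloroplast"


class FormatError(ValueError):
    """The file does not conform to the expected table format."""


class ValidationError(ValueError):
    """The table violates a trajectory-set invariant."""


class EmptyInputError(ValueError):
    """The file contains no usable spot rows."""


@dataclass(frozen=True)
class Spot:
    """One detection: a track label, a frame index and a position in µm."""

    track_id: int
    frame: int
    x: float
    y: float


@dataclass
class TrajectorySet:
    """All spots of one cell's tracked organelles of one kind.

    Parameters
    ----------
    spots
        Tidy table with integer columns ``track_id`` and ``frame`` and
        float columns ``x`` and ``y`` (µm), sorted by (track_id, frame).
    n_frames
        Total number of frames observed (every spot frame < n_frames).
    frame_interval_s
        Seconds between consecutive frames.  The tracker does not record
        this, so it must be supplied as metadata.
    organelle_kind
        ``"mitochondrion"`` or ``"chloroplast"``.
    meta
        Free-form provenance (units flag, dropped-spot count, ...).
    """

    spots: pd.DataFrame
    n_frames: int
    frame_interval_s: float
    organelle_kind: str = MITOCHONDRION
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spots = _normalise_spots(self.spots)
        self.meta.setdefault("units", "um")
        validate(self)

    # --- accessors -----------------------------------------------------

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def track_ids(self) -> np.ndarray:
        return self.spots["track_id"].unique()

    @property
    def n_tracks(self) -> int:
        return self.spots["track_id"].nunique()

    def frame(self, f: int) -> pd.DataFrame:
        """Spots present in frame ``f``."""
        return self.spots[self.spots["frame"] == f]

    def iter_frames(self) -> Iterable[tuple[int, pd.DataFrame]]:
        """Yield (frame, spots-in-frame) for frames with at least one spot."""
        yield from self.spots.groupby("frame", sort=True)

    def track(self, track_id: int) -> pd.DataFrame:
        """Spots of one track, frame-sorted."""
        return self.spots[self.spots["track_id"] == track_id]

    def restrict_frames(self, start: int, stop: int) -> "TrajectorySet":
        """Spots with start <= frame <= stop, keeping the original n_frames."""
        sub = self.spots[(self.spots["frame"] >= start) & (self.spots["frame"] <= stop)]
        return TrajectorySet(
            sub.reset_index(drop=True),
            n_frames=self.n_frames,
            frame_interval_s=self.frame_interval_s,
            organelle_kind=self.organelle_kind,
            meta=dict(self.meta),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrajectorySet):
            return NotImplemented
        return (
            self.n_frames == other.n_frames
            and self.frame_interval_s == other.frame_interval_s
            and self.organelle_kind == other.organelle_kind
            and self.spots.shape == other.spots.shape
            and (self.spots.values == other.spots.values).all()
        )


@dataclass
class CellRecord:
    """One cell: mitochondrial (and optional chloroplast) trajectories + metadata."""

    cell_id: str
    genotype: str
    mito: TrajectorySet
    chloro: Optional[TrajectorySet] = None
    cell_area_um2: float = float("nan")
    pixel_scale: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.cell_area_um2 > 0):
            raise ValidationError(f"cell_area_um2 must be > 0, got {self.cell_area_um2}")
        if not (math.isnan(self.pixel_scale) or self.pixel_scale > 0):
            raise ValidationError(f"pixel_scale must be > 0, got {self.pixel_scale}")
        if self.chloro is not None:
            if self.chloro.n_frames != self.mito.n_frames:
                raise ValidationError(
                    "mito and chloro frame counts differ: "
                    f"{self.mito.n_frames} != {self.chloro.n_frames}"
                )
            if self.chloro.frame_interval_s != self.mito.frame_interval_s:
                raise ValidationError("mito and chloro frame intervals differ")


# ---------------------------------------------------------------------------
# validation helpers


def _normalise_spots(spots: pd.DataFrame) -> pd.DataFrame:
    required = ["track_id", "frame", "x", "y"]
    missing = [c for c in required if c not in spots.columns]
    if missing:
        raise FormatError(f"spot table missing column(s): {', '.join(missing)}")
    out = spots[required].copy()
    out["track_id"] = out["track_id"].astype(np.int64)
    out["frame"] = out["frame"].astype(np.int64)
    out["x"] = out["x"].astype(np.float64)
    out["y"] = out["y"].astype(np.float64)
    out = out.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)
    return out


def validate(ts: TrajectorySet, max_frame_gap: Optional[int] = None) -> None:
    """Check trajectory-set invariants; raise :class:`ValidationError` on failure.

    ``max_frame_gap`` (tracker gap-closing limit, default 2) is only
    enforced when passed explicitly, since simulated or hand-built sets
    always satisfy it and third-party exports may legitimately differ.
    """
    s = ts.spots
    if ts.n_frames < 0:
        raise ValidationError("n_frames must be non-negative")
    if not (ts.frame_interval_s > 0):
        raise ValidationError("frame_interval_s must be positive")
    if len(s) == 0:
        return
    if not np.isfinite(s[["x", "y"]].values).all():
        raise ValidationError("non-finite positions in spot table")
    if (s["frame"] < 0).any():
        raise ValidationError("negative frame indices")
    if int(s["frame"].max()) >= ts.n_frames:
        raise ValidationError(
            f"spot frame {int(s['frame'].max())} >= n_frames={ts.n_frames}"
        )
    dup = s.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = s[dup].iloc[0]
        raise ValidationError(
            f"duplicate spot for track {int(row.track_id)} at frame {int(row.frame)}"
        )
    if max_frame_gap is not None:
        gaps = s.groupby("track_id")["frame"].diff().dropna()
        worst = gaps.max() if len(gaps) else 1
        if worst is not None and worst - 1 > max_frame_gap:
            raise ValidationError(
                f"track frame gap of {int(worst) - 1} exceeds max_frame_gap={max_frame_gap}"
            )


# ---------------------------------------------------------------------------
# TrackMate-style reader

# Recognised header aliases, lower-cased.
_COLUMN_ALIASES = {
    "track_id": {"track_id", "trackid", "track id", "track"},
    "frame": {"frame", "t", "frame_index"},
    "x": {"position_x", "x", "x_um", "pos_x"},
    "y": {"position_y", "y", "y_um", "pos_y"},
}


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    lowered = {c.lower().strip(): c for c in columns}
    resolved = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        hit = next((lowered[a] for a in aliases if a in lowered), None)
        if hit is None:
            raise FormatError(
                f"could not resolve required column '{canonical}' "
                f"among: {', '.join(columns)}"
            )
        resolved[canonical] = hit
    return resolved


def read_trackmate_csv(
    path: PathLike,
    *,
    dialect: str = "auto",
    pixel_scale: Optional[float] = None,
    frame_interval_s: float = 1.0,
    n_frames: Optional[int] = None,
    organelle_kind: str = MITOCHONDRION,
) -> TrajectorySet:
    """Read a TrackMate-style spot export into a :class:`TrajectorySet`.

    Parameters
    ----------
    path
        CSV file with (at least) track id, frame, x and y columns under
        the usual TrackMate header names (``TRACK_ID``, ``FRAME``,
        ``POSITION_X``, ``POSITION_Y``) or common aliases.  Column order
        and extra columns are irrelevant.
    dialect
        ``"simple"`` (one header row), ``"trackmate7"`` (extra sub-header
        rows after the header) or ``"auto"`` — sniff by checking the
        first data row for non-numeric content.
    pixel_scale
        If given, positions in the file are in pixels and are divided by
        this many pixels per µm.  If None, positions are taken as µm.
    frame_interval_s
        Seconds per frame (not stored in tracker exports).
    n_frames
        Total frames observed; defaults to ``max(frame) + 1``.

    Spots whose track id is missing/unassigned (blank, ``None`` or ``-1``,
    as emitted for unlinked detections) are dropped; the count is recorded
    in ``meta["n_dropped_spots"]``.
    """
    if dialect not in {"auto", "simple", "trackmate7"}:
        raise ValueError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    if raw.empty and len(raw.columns) <= 1:
        raise EmptyInputError(f"no data in {path}")
    cols = _resolve_columns(list(raw.columns))

    frame_numeric = pd.to_numeric(raw[cols["frame"]], errors="coerce")
    if dialect == "simple":
        n_subheader = 0
    else:
        # trackmate7 exporters put 1-3 descriptive rows before the data;
        # they are exactly the leading rows with a non-numeric frame field.
        n_subheader = 0
        while n_subheader < len(raw) and not np.isfinite(frame_numeric.iloc[n_subheader]):
            n_subheader += 1
        if dialect == "trackmate7" and n_subheader == 0:
            raise FormatError("trackmate7 dialect expects sub-header rows; none found")
    data = raw.iloc[n_subheader:]
    if data.empty:
        raise EmptyInputError(f"no spot rows in {path}")

    track_raw = data[cols["track_id"]].astype(str).str.strip()
    track_num = pd.to_numeric(track_raw, errors="coerce")
    unassigned = track_num.isna() | (track_num < 0)
    n_dropped = int(unassigned.sum())
    data = data[~unassigned]
    if data.empty:
        raise EmptyInputError(f"all spots in {path} have unassigned track ids")

    try:
        spots = pd.DataFrame(
            {
                "track_id": pd.to_numeric(data[cols["track_id"]]).astype(np.int64),
                "frame": pd.to_numeric(data[cols["frame"]]).astype(np.int64),
                "x": pd.to_numeric(data[cols["x"]]).astype(np.float64),
                "y": pd.to_numeric(data[cols["y"]]).astype(np.float64),
            }
        )
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric spot values in {path}: {exc}") from exc

    if pixel_scale is not None:
        if not pixel_scale > 0:
            raise ValueError("pixel_scale must be positive")
        spots["x"] /= pixel_scale
        spots["y"] /= pixel_scale

    nf = n_frames if n_frames is not None else int(spots["frame"].max()) + 1
    return TrajectorySet(
        spots,
        n_frames=nf,
        frame_interval_s=frame_interval_s,
        organelle_kind=organelle_kind,
        meta={"units": "um", "n_dropped_spots": n_dropped, "source": str(path)},
    )


def convert_to_um(ts: TrajectorySet, pixel_scale: float) -> TrajectorySet:
    """Convert a pixel-unit set to µm; a set already in µm is returned unchanged."""
    if ts.meta.get("units", "um") == "um":
        return ts
    if not pixel_scale > 0:
        raise ValueError("pixel_scale must be positive")
    spots = ts.spots.copy()
    spots["x"] /= pixel_scale
    spots["y"] /= pixel_scale
    meta = dict(ts.meta)
    meta["units"] = "um"
    return TrajectorySet(
        spots, ts.n_frames, ts.frame_interval_s, ts.organelle_kind, meta
    )


# ---------------------------------------------------------------------------
# canonical format

_CANONICAL_COLUMNS = ["cell_id", "organelle", "track_id", "frame", "x_um", "y_um"]


def write_canonical(ts: TrajectorySet, path: PathLike, *, cell_id: str = "cell") -> None:
    """Write the canonical tidy CSV.

    Metadata (organelle kind, frame count, frame interval) goes in leading
    ``#`` comment lines; positions are printed with ``repr`` so that
    re-reading reproduces every float bit-exactly and repeated writes of
    the same set are byte-identical.
    """
    buf = _io.StringIO()
    buf.write("# mitosocial canonical v1\n")
    buf.write(f"# organelle={ts.organelle_kind}\n")
    buf.write(f"# n_frames={ts.n_frames}\n")
    buf.write(f"# frame_interval_s={ts.frame_interval_s!r}\n")
    buf.write(",".join(_CANONICAL_COLUMNS) + "\n")
    for row in ts.spots.itertuples(index=False):
        buf.write(
            f"{cell_id},{ts.organelle_kind},{row.track_id},{row.frame},"
            f"{row.x!r},{row.y!r}\n"
        )
    Path(path).write_text(buf.getvalue())


def read_canonical(path: PathLike) -> TrajectorySet:
    """Read a canonical tidy CSV written by :func:`write_canonical`."""
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
        else:
            body_start = i
            break
    else:
        raise EmptyInputError(f"no table in {path}")
    for key in ("organelle", "n_frames", "frame_interval_s"):
        if key not in meta:
            raise FormatError(f"canonical file {path} missing '# {key}=' metadata")
    body = "\n".join(lines[body_start:])
    table = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    missing = [c for c in _CANONICAL_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"canonical file missing column(s): {', '.join(missing)}")
    spots = table.rename(columns={"x_um": "x", "y_um": "y"})[
        ["track_id", "frame", "x", "y"]
    ]
    return TrajectorySet(
        spots,
        n_frames=int(meta["n_frames"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        organelle_kind=meta["organelle"],
        meta={"units": "um", "source": str(path)},
    )


# ---------------------------------------------------------------------------
# cell assembly


def convex_hull_area(ts: TrajectorySet) -> float:
    """Area (µm²) of the convex hull of all positions over all frames.

    Fallback estimate of cell area when no measured value is available;
    it under-estimates the true cell outline since organelles do not
    visit the full cytoplasm.
    """
    pts = ts.spots[["x", "y"]].drop_duplicates().values
    if len(pts) < 3:
        raise ValidationError("need >= 3 distinct positions for a convex-hull area")
    hull = ConvexHull(pts)
    return float(hull.volume)  # in 2D, .volume is the enclosed area


def assemble_cell(
    mito: TrajectorySet,
    chloro: Optional[TrajectorySet] = None,
    *,
    cell_id: str,
    genotype: str,
    cell_area_um2: Optional[float] = None,
    pixel_scale: float = float("nan"),
) -> CellRecord:
    """Bundle trajectory sets and metadata into a :class:`CellRecord`.

    If ``cell_area_um2`` is not given, the convex hull of all
    mitochondrial positions is used as a documented fallback.
    """
    if cell_area_um2 is None:
        cell_area_um2 = convex_hull_area(mito)
    return CellRecord(
        cell_id=cell_id,
        genotype=genotype,
        mito=mito,
        chloro=chloro,
        cell_area_um2=cell_area_um2,
        pixel_scale=pixel_scale,
    )
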