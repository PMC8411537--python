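"""Per-larva crawling kinematics from tracked trajectories.

Larvae are recorded crawling freely at a fixed frame rate (default 5
frames/s, 0.13 mm/pixel).  A tracker reports, for every larva and frame,
the centroid position and the body bend angle (0 deg = straight body).
This module turns those per-frame records into the kinematic statistics
used throughout the analysis:

* **bend probability** -- fraction of a larva's frames with |bend angle|
  above a threshold (default 20 deg),
* **crawling speed** -- per-larva median centroid speed over the frames
  *not* labelled bending,
* **crawling distance (1 min)** -- mean straight-line centroid
  displacement over non-overlapping one-minute windows,
* **backward crawling** -- whether the larva shows a sustained bout of
  motion anti-parallel to its tail-to-head axis.

Species-level summaries report the median and s.e.m. of the per-larva
values, and the backward-crawling fraction with its binomial standard
error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default frame rate of the recordings (frames / s)
DEFAULT_FPS = 5.0
#: default image scale (mm / pixel)
DEFAULT_PX_SCALE = 0.13
#: bend-angle threshold separating "bending" from "crawling" frames (deg)
DEFAULT_BEND_THRESHOLD_DEG = 20.0
#: minimum number of continuously tracked frames (strictly greater than)
DEFAULT_MIN_FRAMES = 300
#: frames per one-minute displacement window at 5 fps
FRAMES_PER_MINUTE = 300

REQUIRED_COLUMNS = ("larva_id", "frame", "x_px", "y_px", "bend_angle_deg")
HEAD_TAIL_COLUMNS = ("head_x_px", "head_y_px", "tail_x_px", "tail_y_px")


class TrackFormatError(ValueError):
    """Raised when a tracking file does not match the expected dialect."""


class TrackDataError(ValueError):
    """Raised when the track content violates the table invariants."""


class ConfigurationError(ValueError):
    """Raised when required metadata (fps, px_scale) is missing/invalid."""


@dataclass
class TrackTable:
    """Canonical long-format container of tracked larval trajectories.

    ``data`` holds one row per (larva, frame) with columns ``larva_id``,
    ``frame``, ``x_px``, ``y_px``, ``bend_angle_deg`` and, optionally,
    head/tail coordinates.  ``fps`` and ``px_scale`` carry the recording
    metadata needed to convert pixels and frames to mm and seconds.
    """

    data: pd.DataFrame
    fps: float = DEFAULT_FPS
    px_scale: float = DEFAULT_PX_SCALE

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise TrackFormatError(f"missing required columns: {missing}")
        if not (self.fps > 0) or not (self.px_scale > 0):
            raise ConfigurationError(
                f"fps and px_scale must be positive (got fps={self.fps}, "
                f"px_scale={self.px_scale})"
            )
        df = self.data
        if df.duplicated(subset=["larva_id", "frame"]).any():
            dup = df[df.duplicated(subset=["larva_id", "frame"])].iloc[0]
            raise TrackDataError(
                f"duplicated (larva_id, frame) record: "
                f"({dup['larva_id']}, {dup['frame']})"
            )
        for larva, g in df.groupby("larva_id", sort=False):
            frames = g["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                raise TrackDataError(
                    f"frames not strictly increasing for larva {larva!r}"
                )

    @property
    def larva_ids(self) -> list:
        return list(self.data["larva_id"].unique())

    @property
    def has_head_tail(self) -> bool:
        return all(c in self.data.columns for c in HEAD_TAIL_COLUMNS)

    def groupby_larva(self):
        return self.data.groupby("larva_id", sort=False)


@dataclass
class LarvaKinematics:
    """Kinematic statistics of a single larva."""

    larva_id: object
    bend_probability: float
    crawling_speed: float | None  # mm/s; None when no crawling-labelled frame
    crawling_distance_1min: float | None  # mm; None when trace < one window
    backward: bool | None  # None when head/tail coordinates unavailable
    n_frames: int


@dataclass
class SpeciesKinematics:
    """Species-level summary: per-larva values, medians and s.e.m."""

    species: str
    larvae: list[LarvaKinematics]
    median: dict = field(default_factory=dict)
    sem: dict = field(default_factory=dict)
    backward_probability: float | None = None
    backward_se: float | None = None
    n_larvae: int = 0


# ---------------------------------------------------------------------------
# reading / writing track tables
# ---------------------------------------------------------------------------

def read_tracks(
    path,
    dialect: str = "long",
    fps: float = DEFAULT_FPS,
    px_scale: float = DEFAULT_PX_SCALE,
) -> TrackTable:
    """Read a tracking table from CSV.

    ``dialect="long"`` expects one row per (larva, frame) with the
    canonical columns.  ``dialect="fimtrack_wide"`` expects a tracker-style
    wide layout: a ``frame`` column plus one column block per larva, with
    columns named ``<larva_id>:<field>`` (fields ``x_px``, ``y_px``,
    ``bend_angle_deg`` and optionally head/tail coordinates); untracked
    frames are empty cells.  Traces split by a collision carry distinct
    larva ids and are kept as distinct larvae.
    """
    path = Path(path)
    if dialect == "long":
        df = pd.read_csv(path)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise TrackFormatError(
                f"{path.name}: long dialect is missing columns {missing}"
            )
        cols = list(REQUIRED_COLUMNS) + [
            c for c in HEAD_TAIL_COLUMNS if c in df.columns
        ]
        df = df[cols]
    elif dialect == "fimtrack_wide":
        wide = pd.read_csv(path)
        if "frame" not in wide.columns:
            raise TrackFormatError(f"{path.name}: wide dialect needs a 'frame' column")
        blocks: dict[str, dict[str, pd.Series]] = {}
        for col in wide.columns:
            if col == "frame":
                continue
            if ":" not in col:
                raise TrackFormatError(
                    f"{path.name}: wide column {col!r} is not '<larva>:<field>'"
                )
            larva, fld = col.split(":", 1)
            blocks.setdefault(larva, {})[fld] = wide[col]
        rows = []
        for larva, fields in blocks.items():
            missing = [f for f in ("x_px", "y_px", "bend_angle_deg") if f not in fields]
            if missing:
                raise TrackFormatError(
                    f"{path.name}: larva {larva!r} block missing fields {missing}"
                )
            sub = pd.DataFrame({"frame": wide["frame"], **fields})
            sub = sub.dropna(subset=["x_px", "y_px", "bend_angle_deg"])
            sub.insert(0, "larva_id", larva)
            rows.append(sub)
        df = pd.concat(rows, ignore_index=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = df.sort_values(["larva_id", "frame"], kind="stable").reset_index(drop=True)
    df["frame"] = df["frame"].astype(int)
    return TrackTable(df, fps=fps, px_scale=px_scale)


def write_tracks(table: TrackTable, path, dialect: str = "long") -> None:
    """Write a TrackTable as canonical long CSV or tracker-style wide CSV."""
    path = Path(path)
    if dialect == "long":
        table.data.to_csv(path, index=False)
        return
    if dialect != "fimtrack_wide":
        raise ValueError(f"unknown dialect {dialect!r}")
    fields = ["x_px", "y_px", "bend_angle_deg"] + [
        c for c in HEAD_TAIL_COLUMNS if c in table.data.columns
    ]
    frames = np.arange(table.data["frame"].min(), table.data["frame"].max() + 1)
    out = pd.DataFrame({"frame": frames})
    for larva, g in table.groupby_larva():
        g = g.set_index("frame")
        for fld in fields:
            out[f"{larva}:{fld}"] = g[fld].reindex(frames).to_numpy()
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# filtering and smoothing
# ---------------------------------------------------------------------------

def filter_tracks(table: TrackTable, min_frames: int = DEFAULT_MIN_FRAMES) -> TrackTable:
    """Keep larvae continuously tracked for *more than* ``min_frames`` frames.

    For each larva the longest contiguous run of frame numbers is found;
    the larva is retained, truncated to that run, only when the run length
    strictly exceeds ``min_frames``.  The interspecific analysis uses 300
    frames (1 min at 5 fps); the intraspecific analysis uses 150.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    kept = []
    for larva, g in table.groupby_larva():
        frames = g["frame"].to_numpy()
        breaks = np.flatnonzero(np.diff(frames) != 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [len(frames)]))
        lengths = ends - starts
        best = int(np.argmax(lengths))
        if lengths[best] > min_frames:
            kept.append(g.iloc[starts[best]:ends[best]])
    if not kept:
        logger.info("filter_tracks: no larva exceeded %d contiguous frames", min_frames)
        empty = table.data.iloc[0:0]
        return TrackTable(empty, fps=table.fps, px_scale=table.px_scale)
    out = pd.concat(kept, ignore_index=True)
    return TrackTable(out, fps=table.fps, px_scale=table.px_scale)


def smooth_series(values: Sequence[float], window: int = 5) -> np.ndarray:
    """Centered moving average with a uniform window.

    ``window`` must be an odd positive integer.  Near the edges the window
    shrinks symmetrically so the output stays centered and has the same
    length as the input.  A window of 1 is the identity.  If the window
    exceeds the sequence length every position gets the global mean.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    x = np.asarray(values, dtype=float)
    n = x.size
    if window == 1:
        return x.copy()
    if window > n:
        warnings.warn(
            f"smoothing window {window} exceeds series length {n}; "
            "returning the global mean",
            stacklevel=2,
        )
        return np.full(n, x.mean() if n else np.nan)
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


# ---------------------------------------------------------------------------
# per-frame series
# ---------------------------------------------------------------------------

def centroid_speed(
    table: TrackTable, smooth: bool = True, window: int = 5
) -> pd.Series:
    """Per-frame centroid speed (mm/s), indexed like ``table.data``.

    Speed at frame *t* is the Euclidean distance between the (optionally
    smoothed) centroids at *t-1* and *t*, converted with the pixel scale
    and the frame rate.  The first frame of each larva copies the second.
    """
    out = np.empty(len(table.data))
    pos = 0
    for _, g in table.groupby_larva():
        if len(g) < 2:
            raise TrackDataError("centroid speed needs >= 2 frames per larva")
        x = g["x_px"].to_numpy(float)
        y = g["y_px"].to_numpy(float)
        if smooth:
            x = smooth_series(x, window)
            y = smooth_series(y, window)
        step = np.hypot(np.diff(x), np.diff(y)) * table.px_scale * table.fps
        out[pos] = step[0]
        out[pos + 1 : pos + len(g)] = step
        pos += len(g)
    return pd.Series(out, index=table.data.index, name="speed_mm_s")


def label_frames(
    table: TrackTable, threshold_deg: float = DEFAULT_BEND_THRESHOLD_DEG
) -> pd.Series:
    """Label each frame ``"bending"`` or ``"crawling"``.

    A frame is bending iff the body is bent by strictly more than
    ``threshold_deg`` to either side, i.e. |bend angle| > threshold; a
    bend of exactly the threshold counts as crawling.
    """
    if not threshold_deg > 0:
        raise ValueError("threshold_deg must be positive")
    bending = table.data["bend_angle_deg"].abs() > threshold_deg
    return pd.Series(
        np.where(bending, "bending", "crawling"), index=table.data.index, name="label"
    )


# ---------------------------------------------------------------------------
# per-larva statistics
# ---------------------------------------------------------------------------

def _backward_flag(
    g: pd.DataFrame,
    speeds: np.ndarray,
    px_scale: float,
    min_bout_frames: int,
    speed_floor: float,
) -> bool:
    """True iff some run of >= min_bout_frames frames moves anti-parallel
    to the tail->head axis while faster than speed_floor (mm/s)."""
    hx = g["head_x_px"].to_numpy(float)
    hy = g["head_y_px"].to_numpy(float)
    tx = g["tail_x_px"].to_numpy(float)
    ty = g["tail_y_px"].to_numpy(float)
    ax, ay = hx - tx, hy - ty
    norm = np.hypot(ax, ay)
    norm[norm == 0] = 1.0
    ax, ay = ax / norm, ay / norm
    dx = np.diff(g["x_px"].to_numpy(float))
    dy = np.diff(g["y_px"].to_numpy(float))
    # displacement into frame t projected on the body axis at frame t
    proj = dx * ax[1:] + dy * ay[1:]
    moving = speeds[1:] > speed_floor
    backward = (proj < 0) & moving
    run = 0
    for b in backward:
        run = run + 1 if b else 0
        if run >= min_bout_frames:
            return True
    return False


def larva_kinematics(
    table: TrackTable,
    labels: pd.Series | None = None,
    speeds: pd.Series | None = None,
    threshold_deg: float = DEFAULT_BEND_THRESHOLD_DEG,
    smooth: bool = True,
    crawling_speed_scope: str = "crawling",
    window_frames: int = FRAMES_PER_MINUTE,
    backward_min_frames: int = 10,
    backward_speed_floor: float = 0.1,
) -> list[LarvaKinematics]:
    """Compute per-larva kinematic statistics.

    ``crawling_speed_scope`` selects the frames the speed median runs
    over: ``"crawling"`` (frames not labelled bending; the definition used
    for the species comparisons) or ``"whole"`` (every frame of the
    trace).  Backward crawling is evaluated only when head/tail
    coordinates are present; otherwise the flag is ``None``.
    """
    if crawling_speed_scope not in ("crawling", "whole"):
        raise ValueError("crawling_speed_scope must be 'crawling' or 'whole'")
    if labels is None:
        labels = label_frames(table, threshold_deg)
    if speeds is None:
        speeds = centroid_speed(table, smooth=smooth)
    results = []
    for larva, g in table.groupby_larva():
        lab = labels.loc[g.index].to_numpy()
        spd = speeds.loc[g.index].to_numpy()
        n = len(g)
        bend_probability = float(np.mean(lab == "bending"))
        if crawling_speed_scope == "whole":
            crawl_speed = float(np.median(spd))
        else:
            crawl = spd[lab == "crawling"]
            if crawl.size == 0:
                logger.warning(
                    "larva %r has no crawling-labelled frame; speed undefined", larva
                )
                crawl_speed = None
            else:
                crawl_speed = float(np.median(crawl))
        # straight-line displacement per non-overlapping one-minute window
        n_windows = n // window_frames
        if n_windows >= 1:
            x = g["x_px"].to_numpy(float)
            y = g["y_px"].to_numpy(float)
            disp = [
                np.hypot(
                    x[(w + 1) * window_frames - 1] - x[w * window_frames],
                    y[(w + 1) * window_frames - 1] - y[w * window_frames],
                )
                for w in range(n_windows)
            ]
            distance = float(np.mean(disp) * table.px_scale)
        else:
            distance = None
        if table.has_head_tail:
            backward = _backward_flag(
                g, spd, table.px_scale, backward_min_frames, backward_speed_floor
            )
        else:
            backward = None
        results.append(
            LarvaKinematics(
                larva_id=larva,
                bend_probability=bend_probability,
                crawling_speed=crawl_speed,
                crawling_distance_1min=distance,
                backward=backward,
                n_frames=n,
            )
        )
    return results


def species_summary(
    larvae: Iterable[LarvaKinematics], species: str = ""
) -> SpeciesKinematics:
    """Median and s.e.m. of each statistic over larvae, plus the backward
    fraction with its binomial standard error sqrt(p(1-p)/n)."""
    larvae = list(larvae)
    if not larvae:
        raise ValueError("species_summary needs at least one larva")
    out = SpeciesKinematics(species=species, larvae=larvae, n_larvae=len(larvae))
    for stat in ("bend_probability", "crawling_speed", "crawling_distance_1min"):
        vals = np.array(
            [getattr(l, stat) for l in larvae if getattr(l, stat) is not None],
            dtype=float,
        )
        if vals.size == 0:
            out.median[stat] = None
            out.sem[stat] = None
            continue
        out.median[stat] = float(np.median(vals))
        out.sem[stat] = (
            float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        )
    flags = [l.backward for l in larvae if l.backward is not None]
    if flags:
        n = len(flags)
        p = float(np.mean(flags))
        out.backward_probability = p
        out.backward_se = float(np.sqrt(p * (1 - p) / n))
    return out


def kinematic_points(
    table: TrackTable,
    labels: pd.Series | None = None,
    speeds: pd.Series | None = None,
    smooth: bool = True,
) -> np.ndarray:
    """(speed mm/s, |bend angle| deg) pairs over all larvae and frames,
    the raw material of the 2-D probability grids."""
    if speeds is None:
        speeds = centroid_speed(table, smooth=smooth)
    angles = table.data["bend_angle_deg"].abs().to_numpy(float)
    return np.column_stack([speeds.to_numpy(float), angles])


def extract_species_kinematics(
    table: TrackTable,
    species: str = "",
    min_frames: int = DEFAULT_MIN_FRAMES,
    threshold_deg: float = DEFAULT_BEND_THRESHOLD_DEG,
    smooth: bool = True,
    **kwargs,
) -> SpeciesKinematics:
    """Full per-species pipeline: filter, label, compute, summarize."""
    filtered = filter_tracks(table, min_frames=min_frames)
    if filtered.data.empty:
        raise ValueError(
            f"no larva of {species or 'this species'} exceeded "
            f"{min_frames} contiguous frames"
        )
    larvae = larva_kinematics(
        filtered, threshold_deg=threshold_deg, smooth=smooth, **kwargs
    )
    return species_summary(larvae, species=species)
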