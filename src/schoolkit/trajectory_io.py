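"""Reading, writing, validation and unit conversion of fish trajectory data.

The canonical on-disk format is a long-format CSV with one row per fish per
frame and columns ``frame, time_s, fish_id, x, y, heading``, accompanied by a
YAML sidecar describing the arena geometry, the cohort, the frame rate and the
coordinate units (``px`` or ``cm``).  Positions are converted to centimetres
on read using the arena radius; headings are unwrapped into a continuous
angle sequence (radians, counterclockwise from the +x axis, y up).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ArenaGeometry",
    "CohortSpec",
    "FishTrack",
    "TrialGroup",
    "FormatError",
    "InputError",
    "read_trial",
    "read_trial_wide",
    "write_trial",
    "load_config",
    "save_config",
    "to_tank_radii",
    "from_tank_radii",
    "to_body_lengths",
    "rotate_trial",
    "mirror_trial",
]

REQUIRED_COLUMNS = ("frame", "time_s", "fish_id", "x", "y", "heading")

#: largest tolerated fraction of internally missing frames per fish before a
#: trial is rejected; smaller gaps are interpolated.
MAX_GAP_FRACTION = 0.05


class FormatError(ValueError):
    """The file does not conform to the trajectory CSV format."""


class InputError(ValueError):
    """The file is well-formed but describes an unusable trial."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Circular arena: centre and radius (cm), optionally radius in pixels.

    ``radius_cm / radius_px`` is the pixel-to-centimetre conversion factor
    used when ingesting tracker output recorded in pixels.
    """

    radius_cm: float
    center_xy: tuple[float, float] = (0.0, 0.0)
    radius_px: float | None = None
    depth_mm: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.radius_cm) or self.radius_cm <= 0:
            raise ValueError(f"radius_cm must be positive, got {self.radius_cm}")
        if self.radius_px is not None and (
            not np.isfinite(self.radius_px) or self.radius_px <= 0
        ):
            raise ValueError(f"radius_px must be positive, got {self.radius_px}")

    @property
    def px_to_cm(self) -> float:
        if self.radius_px is None:
            raise ValueError("radius_px unknown; cannot convert pixel coordinates")
        return self.radius_cm / self.radius_px

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.center_xy, dtype=float)


@dataclass(frozen=True)
class CohortSpec:
    """Population/age cohort metadata used for normalisation.

    ``mean_swim_speed_cm_s`` is the cohort-average swimming speed used to
    normalise speeding/turning forces; it may be supplied or computed from
    the cohort's trials.
    """

    population: str
    age_dpf: int
    mean_body_length_cm: float
    mean_swim_speed_cm_s: float | None = None

    def __post_init__(self) -> None:
        if self.age_dpf <= 0:
            raise ValueError("age_dpf must be positive")
        if self.mean_body_length_cm <= 0:
            raise ValueError("mean_body_length_cm must be positive")


@dataclass
class FishTrack:
    """One fish's trajectory: per-frame position (cm) and heading (rad).

    Headings are continuous (unwrapped); frames are strictly increasing and,
    after trial alignment, contiguous and shared by all fish of the trial.
    """

    fish_id: str
    frames: np.ndarray
    t: np.ndarray
    xy: np.ndarray
    phi: np.ndarray
    body_length_cm: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.frames)
        if self.xy.shape != (n, 2) or self.t.shape != (n,) or self.phi.shape != (n,):
            raise ValueError("frames, t, xy, phi must have matching lengths")
        if n > 1 and not np.all(np.diff(self.frames) > 0):
            raise FormatError(f"fish {self.fish_id}: frames not strictly increasing")
        if not np.all(np.isfinite(self.phi)):
            raise FormatError(f"fish {self.fish_id}: non-finite heading")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class TrialGroup:
    """A group trial: N fish sharing a frame index, arena and cohort."""

    trial_id: str
    tracks: list[FishTrack]
    arena: ArenaGeometry
    cohort: CohortSpec
    is_mock: bool = False
    fps: float = 30.0

    def __post_init__(self) -> None:
        if len(self.tracks) < 2:
            raise InputError("a trial needs at least two fish")
        f0 = self.tracks[0].frames
        for tr in self.tracks[1:]:
            if len(tr.frames) != len(f0) or not np.array_equal(tr.frames, f0):
                raise InputError("all tracks must share the same frame index")

    @property
    def n_fish(self) -> int:
        return len(self.tracks)

    @property
    def n_frames(self) -> int:
        return self.tracks[0].n_frames

    @property
    def fish_ids(self) -> list[str]:
        return [tr.fish_id for tr in self.tracks]

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def xy(self) -> np.ndarray:
        """Positions stacked as (n_frames, n_fish, 2), cm."""
        return np.stack([tr.xy for tr in self.tracks], axis=1)

    @property
    def phi(self) -> np.ndarray:
        """Unwrapped headings stacked as (n_frames, n_fish), rad."""
        return np.stack([tr.phi for tr in self.tracks], axis=1)


# ---------------------------------------------------------------------------
# unit conversions


def to_tank_radii(xy: np.ndarray, arena: ArenaGeometry) -> np.ndarray:
    """Express positions (cm) in tank-radius units relative to the centre."""
    if arena.radius_cm == 0:
        raise ValueError("arena radius is zero")
    return (np.asarray(xy, dtype=float) - arena.center) / arena.radius_cm


def from_tank_radii(xy_r: np.ndarray, arena: ArenaGeometry) -> np.ndarray:
    """Inverse of :func:`to_tank_radii`."""
    return np.asarray(xy_r, dtype=float) * arena.radius_cm + arena.center


def to_body_lengths(d, cohort: CohortSpec):
    """Convert a distance in cm to cohort body lengths (BL)."""
    if cohort.mean_body_length_cm <= 0:
        raise ValueError("mean body length must be positive")
    return np.asarray(d, dtype=float) / cohort.mean_body_length_cm


def rotate_trial(trial: TrialGroup, angle: float) -> TrialGroup:
    """Rigidly rotate all trajectories by ``angle`` (rad, CCW) about the
    arena centre.  Pairwise metrics and focal-frame quantities are invariant
    under this transform, which makes it a useful oracle."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    center = trial.arena.center
    tracks = [
        FishTrack(
            fish_id=tr.fish_id,
            frames=tr.frames.copy(),
            t=tr.t.copy(),
            xy=(tr.xy - center) @ rot.T + center,
            phi=tr.phi + angle,
            body_length_cm=tr.body_length_cm,
        )
        for tr in trial.tracks
    ]
    return TrialGroup(trial_id=trial.trial_id, tracks=tracks, arena=trial.arena,
                      cohort=trial.cohort, is_mock=trial.is_mock, fps=trial.fps)


def mirror_trial(trial: TrialGroup) -> TrialGroup:
    """Reflect all trajectories about the horizontal axis through the arena
    centre (y -> -y, heading -> -heading): distances and speeding forces are
    preserved while every turning force changes sign."""
    center = trial.arena.center
    tracks = [
        FishTrack(
            fish_id=tr.fish_id,
            frames=tr.frames.copy(),
            t=tr.t.copy(),
            xy=np.column_stack(
                [tr.xy[:, 0], 2.0 * center[1] - tr.xy[:, 1]]),
            phi=-tr.phi,
            body_length_cm=tr.body_length_cm,
        )
        for tr in trial.tracks
    ]
    return TrialGroup(trial_id=trial.trial_id, tracks=tracks, arena=trial.arena,
                      cohort=trial.cohort, is_mock=trial.is_mock, fps=trial.fps)


# ---------------------------------------------------------------------------
# configuration sidecar


def load_config(path) -> dict:
    """Load a YAML sidecar into ``{'arena', 'cohort', 'fps', 'units'}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    arena = ArenaGeometry(
        radius_cm=float(raw["arena"]["radius_cm"]),
        center_xy=tuple(raw["arena"].get("center_xy", (0.0, 0.0))),
        radius_px=raw["arena"].get("radius_px"),
        depth_mm=raw["arena"].get("depth_mm"),
    )
    c = raw["cohort"]
    cohort = CohortSpec(
        population=str(c["population"]),
        age_dpf=int(c["age_dpf"]),
        mean_body_length_cm=float(c["mean_body_length_cm"]),
        mean_swim_speed_cm_s=c.get("mean_swim_speed_cm_s"),
    )
    return {
        "arena": arena,
        "cohort": cohort,
        "fps": float(raw.get("fps", 30.0)),
        "units": str(raw.get("units", "cm")),
    }


def save_config(path, arena: ArenaGeometry, cohort: CohortSpec, fps: float = 30.0,
                units: str = "cm") -> None:
    doc = {
        "arena": {
            "radius_cm": float(arena.radius_cm),
            "center_xy": [float(v) for v in arena.center_xy],
            "radius_px": arena.radius_px,
            "depth_mm": arena.depth_mm,
        },
        "cohort": {
            "population": cohort.population,
            "age_dpf": cohort.age_dpf,
            "mean_body_length_cm": cohort.mean_body_length_cm,
            "mean_swim_speed_cm_s": cohort.mean_swim_speed_cm_s,
        },
        "fps": float(fps),
        "units": units,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# reading


def _interpolate_gaps(frames, t, x, y, heading, fish_id, fps):
    """Fill internal frame gaps (<= MAX_GAP_FRACTION) by linear interpolation.

    Positions are interpolated linearly; headings are interpolated on the
    unwrapped angle sequence, which is the circular (geodesic) interpolation
    for gaps shorter than half a turn.
    """
    full = np.arange(frames[0], frames[-1] + 1, dtype=np.int64)
    if len(full) == len(frames):
        return full, t, x, y, heading
    missing = len(full) - len(frames)
    frac = missing / len(full)
    if frac > MAX_GAP_FRACTION:
        raise InputError(
            f"fish {fish_id}: {frac:.1%} of frames missing (limit "
            f"{MAX_GAP_FRACTION:.0%})"
        )
    warnings.warn(
        f"fish {fish_id}: interpolating {missing} missing frames "
        f"({frac:.2%})",
        stacklevel=3,
    )
    logger.info("fish %s: interpolated %d missing frames", fish_id, missing)
    xi = np.interp(full, frames, x)
    yi = np.interp(full, frames, y)
    hi = np.interp(full, frames, heading)
    ti = np.interp(full, frames, t)
    return full, ti, xi, yi, hi


def _build_tracks(df: pd.DataFrame, arena: ArenaGeometry, units: str, fps: float,
                  body_length_cm: float | None):
    if units not in ("px", "cm"):
        raise FormatError(f"unknown units {units!r} (expected 'px' or 'cm')")
    scale = arena.px_to_cm if units == "px" else 1.0

    tracks = {}
    for fish_id, sub in df.groupby("fish_id", sort=True):
        frames = sub["frame"].to_numpy(dtype=np.int64)
        if len(frames) > 1 and not np.all(np.diff(frames) > 0):
            raise FormatError(f"fish {fish_id}: frames not strictly increasing")
        heading = np.unwrap(sub["heading"].to_numpy(dtype=float))
        frames, t, x, y, heading = _interpolate_gaps(
            frames,
            sub["time_s"].to_numpy(dtype=float),
            sub["x"].to_numpy(dtype=float) * scale,
            sub["y"].to_numpy(dtype=float) * scale,
            heading,
            fish_id,
            fps,
        )
        tracks[str(fish_id)] = (frames, t, x, y, heading)

    # retain the frame range common to all fish (never fabricate frames
    # absent from every fish)
    lo = max(v[0][0] for v in tracks.values())
    hi = min(v[0][-1] for v in tracks.values())
    if hi < lo:
        raise InputError("fish tracks have no frames in common")
    out = []
    for fish_id, (frames, t, x, y, heading) in tracks.items():
        sel = (frames >= lo) & (frames <= hi)
        out.append(
            FishTrack(
                fish_id=fish_id,
                frames=frames[sel],
                t=t[sel],
                xy=np.column_stack([x[sel], y[sel]]),
                phi=heading[sel],
                body_length_cm=body_length_cm,
            )
        )
    return out


def read_trial(path, arena: ArenaGeometry | None = None,
               cohort: CohortSpec | None = None, *, config=None,
               units: str | None = None, fps: float | None = None,
               trial_id: str | None = None) -> TrialGroup:
    """Read a long-format trajectory CSV into a :class:`TrialGroup`.

    Arena/cohort/units/fps may be given explicitly or through a YAML sidecar
    (``config`` path; defaults to ``<path>.yaml`` when present).  Pixel
    coordinates are converted to cm via the arena radius; headings are
    unwrapped; internal gaps up to 5% of a fish's frames are linearly
    interpolated with a warning.
    """
    path = Path(path)
    if config is None:
        candidate = path.with_suffix(path.suffix + ".yaml")
        if candidate.exists():
            config = candidate
    if config is not None:
        cfg = load_config(config)
        arena = arena or cfg["arena"]
        cohort = cohort or cfg["cohort"]
        units = units or cfg["units"]
        fps = fps or cfg["fps"]
    if arena is None or cohort is None:
        raise InputError("arena and cohort must come from arguments or a sidecar")
    units = units or "cm"
    fps = fps or 30.0

    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"missing columns: {sorted(missing)}")
    if df["fish_id"].nunique() < 2:
        raise InputError("fewer than 2 fish in trial")

    tracks = _build_tracks(df, arena, units, fps, cohort.mean_body_length_cm)
    return TrialGroup(
        trial_id=trial_id or path.stem,
        tracks=tracks,
        arena=arena,
        cohort=cohort,
        fps=fps,
    )


def read_trial_wide(path, arena: ArenaGeometry, cohort: CohortSpec, *,
                    units: str = "cm", fps: float = 30.0,
                    trial_id: str | None = None) -> TrialGroup:
    """Secondary reader for wide-format CSVs.

    Expected columns: ``frame, time_s`` plus ``x_<id>, y_<id>, heading_<id>``
    blocks, one per fish.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "frame" not in df.columns or "time_s" not in df.columns:
        raise FormatError("wide format requires 'frame' and 'time_s' columns")
    ids = sorted(
        c[len("x_"):] for c in df.columns if c.startswith("x_")
    )
    if len(ids) < 2:
        raise InputError("fewer than 2 fish in trial")
    long_rows = []
    for fid in ids:
        for col in (f"x_{fid}", f"y_{fid}", f"heading_{fid}"):
            if col not in df.columns:
                raise FormatError(f"missing column {col}")
        long_rows.append(
            pd.DataFrame(
                {
                    "frame": df["frame"],
                    "time_s": df["time_s"],
                    "fish_id": fid,
                    "x": df[f"x_{fid}"],
                    "y": df[f"y_{fid}"],
                    "heading": df[f"heading_{fid}"],
                }
            )
        )
    long_df = pd.concat(long_rows, ignore_index=True)
    tracks = _build_tracks(long_df, arena, units, fps, cohort.mean_body_length_cm)
    return TrialGroup(
        trial_id=trial_id or path.stem,
        tracks=tracks,
        arena=arena,
        cohort=cohort,
        fps=fps,
    )


def write_trial(trial: TrialGroup, path, *, write_config: bool = True) -> Path:
    """Write a trial as the canonical long-format CSV (+ YAML sidecar)."""
    path = Path(path)
    rows = []
    for tr in trial.tracks:
        rows.append(
            pd.DataFrame(
                {
                    "frame": tr.frames,
                    "time_s": tr.t,
                    "fish_id": tr.fish_id,
                    "x": tr.xy[:, 0],
                    "y": tr.xy[:, 1],
                    "heading": tr.phi,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True).sort_values(["frame", "fish_id"])
    df.to_csv(path, index=False, float_format="%.10g")
    if write_config:
        save_config(path.with_suffix(path.suffix + ".yaml"), trial.arena,
                    trial.cohort, fps=trial.fps, units="cm")
    return path
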