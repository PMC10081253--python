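"""Signed, zone-averaged attraction and alignment statistics.

Three per-trial scalars summarise how a fish manoeuvres relative to its
neighbours:

* attractive speeding force -- the speeding force when the neighbour is ahead,
  minus the speeding force when the neighbour is behind.  Positive values
  mean speed changes reduce the distance to the neighbour.
* attractive turning force -- the turning force when the neighbour is on the
  right, minus the turning force when it is on the left.  Positive values
  mean the trajectory curves towards the neighbour.
* aligning angular acceleration -- the angular acceleration with its sign
  flipped when the heading difference (neighbour minus focal, wrapped to
  (-180, 180)) is negative.  Positive values mean a torque towards the
  neighbour's heading.

Observations are binned on the polar grid, bin means are averaged over the
relevant distance zone weighted by bin area (every possible neighbour
location counts equally), and the cohort-level mock mean -- computed
identically over all cross-trial pairs -- is subtracted from each trial's
value.  Speeding is restricted to the attraction zone (0.15-0.4 tank radii,
beyond the short-range repulsion), turning likewise; alignment uses
0.05-0.4 tank radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .focal_maps import (
    MapAccumulator,
    PairObservations,
    PolarGrid,
    _as_chunks,
    iter_pair_observations,
)
from .kinematics import trial_kinematics

__all__ = [
    "ZoneSpec",
    "ATTRACTION_ZONE",
    "REPULSION_ZONE",
    "ALIGNMENT_ZONE",
    "SCHOOLING_ZONE",
    "signed_bin_stats",
    "zone_average",
    "attraction_statistics",
    "attractive_speeding_force",
    "attractive_turning_force",
    "aligning_angular_acceleration",
    "mock_reference",
    "mock_subtract",
    "attraction_summaries",
]

STAT_NAMES = ("speeding", "turning", "aligning")


@dataclass(frozen=True)
class ZoneSpec:
    """An annulus of neighbour distances, in tank radii."""

    r_min: float
    r_max: float
    role: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_min < self.r_max):
            raise ValueError("need 0 <= r_min < r_max")


ATTRACTION_ZONE = ZoneSpec(0.15, 0.4, "attraction")
REPULSION_ZONE = ZoneSpec(0.05, 0.15, "repulsion")
ALIGNMENT_ZONE = ZoneSpec(0.05, 0.4, "alignment")
SCHOOLING_ZONE = ZoneSpec(0.05, 0.4, "schooling")

DEFAULT_ZONES = {
    "speeding": ATTRACTION_ZONE,
    "turning": ATTRACTION_ZONE,
    "aligning": ALIGNMENT_ZONE,
}


def signed_bin_stats(obs, grid: PolarGrid | None = None):
    """Per-bin sums and counts of the three signed quantities.

    Returns ``{name: (sums, counts)}``.  Ahead/behind and left/right are
    realised as sector membership so scalar statistics stay consistent with
    the heatmaps; observations with a heading difference of exactly 0 or
    +-180 degrees are dropped from the aligning statistic (no defined sign).
    """
    acc = MapAccumulator(grid).add(obs)
    return {name: (acc.signed_sums[name], acc.signed_counts[name])
            for name in STAT_NAMES}


def zone_average(values: np.ndarray, grid: PolarGrid, zone: ZoneSpec,
                 weighting: str = "area",
                 counts: np.ndarray | None = None) -> float:
    """Average per-bin values over a zone's rings.

    ``weighting='area'`` treats every possible neighbour location equally;
    ``weighting='occupancy'`` weights by observation counts instead.  Bins
    with undefined values (NaN) are excluded; NaN is returned when the whole
    zone is undefined.
    """
    rings = grid.zone_rings(zone.r_min, zone.r_max)
    if len(rings) == 0:
        raise ValueError("zone contains no complete ring of the grid")
    vals = values[rings]
    if weighting == "area":
        w = grid.bin_area[rings]
    elif weighting == "occupancy":
        if counts is None:
            raise ValueError("occupancy weighting needs counts")
        w = counts[rings].astype(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    ok = np.isfinite(vals) & (w > 0)
    if not np.any(ok):
        return float("nan")
    return float(np.sum(vals[ok] * w[ok]) / np.sum(w[ok]))


def attraction_statistics(obs, grid: PolarGrid | None = None,
                          zones: dict | None = None,
                          weighting: str = "area") -> dict:
    """All three signed statistics from one set of observations.

    Frame-level observations are reduced to bin means, then area-weighted
    over each statistic's zone; returns ``{name: scalar}`` (NaN when a zone
    holds no observation).
    """
    grid = grid or PolarGrid()
    zones = zones or DEFAULT_ZONES
    acc = signed_bin_stats(obs, grid)
    out = {}
    for name in STAT_NAMES:
        sums, counts = acc[name]
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out[name] = zone_average(means, grid, zones[name], weighting=weighting,
                                 counts=counts)
    return out


def _trial_obs(trial, kin=None, smooth: bool = True):
    return iter_pair_observations(
        [trial], [kin] if kin is not None else None, mode="within",
        smooth=smooth)


def attractive_speeding_force(trial, kin=None, grid=None,
                              zone: ZoneSpec = ATTRACTION_ZONE,
                              weighting: str = "area") -> float:
    """Per-trial mean attractive speeding force (cm/s^2)."""
    return attraction_statistics(
        _trial_obs(trial, kin), grid,
        zones={**DEFAULT_ZONES, "speeding": zone}, weighting=weighting,
    )["speeding"]


def attractive_turning_force(trial, kin=None, grid=None,
                             zone: ZoneSpec = ATTRACTION_ZONE,
                             weighting: str = "area") -> float:
    """Per-trial mean attractive turning force (cm/s^2)."""
    return attraction_statistics(
        _trial_obs(trial, kin), grid,
        zones={**DEFAULT_ZONES, "turning": zone}, weighting=weighting,
    )["turning"]


def aligning_angular_acceleration(trial, kin=None, grid=None,
                                  zone: ZoneSpec = ALIGNMENT_ZONE,
                                  weighting: str = "area") -> float:
    """Per-trial mean aligning angular acceleration (rad/s^2)."""
    return attraction_statistics(
        _trial_obs(trial, kin), grid,
        zones={**DEFAULT_ZONES, "aligning": zone}, weighting=weighting,
    )["aligning"]


def mock_reference(trials, kins=None, grid=None, zones=None,
                   weighting: str = "area") -> dict:
    """Cohort-level mock means of the three statistics over cross-trial pairs.

    Averaging over every possible pair of fish from two different trials is
    equivalent to averaging over every pair within every possible mock group,
    because the statistics are pairwise.
    """
    obs = iter_pair_observations(trials, kins, mode="cross")
    return attraction_statistics(obs, grid, zones=zones, weighting=weighting)


def mock_subtract(real_values, mock_value: float):
    """Corrected per-trial values: real minus the cohort-level mock mean."""
    if mock_value is None or not np.isfinite(mock_value):
        raise ValueError("mock reference is undefined")
    return np.asarray(real_values, dtype=float) - mock_value


def attraction_summaries(trials, kins=None, grid=None, zones=None,
                         weighting: str = "area",
                         cohort_speed: float | None = None) -> pd.DataFrame:
    """Per-trial table of raw, normalised, mock and corrected statistics.

    ``cohort_speed`` (cm/s) scales the ``*_norm`` columns; when omitted it is
    the mean over trials of the trial-mean swimming speed.
    """
    from .kinematics import mean_swim_speed

    trials = list(trials)
    if kins is None:
        kins = [trial_kinematics(t) for t in trials]
    zones = zones or DEFAULT_ZONES
    if cohort_speed is None:
        cohort_speed = float(np.mean([mean_swim_speed(t) for t in trials]))
    mock = mock_reference(trials, kins, grid, zones=zones, weighting=weighting)

    rows = []
    for trial, kin in zip(trials, kins):
        stats = attraction_statistics(_trial_obs(trial, kin), grid,
                                      zones=zones, weighting=weighting)
        row = {"trial_id": trial.trial_id,
               "cohort_mean_speed_cm_s": cohort_speed}
        for name in STAT_NAMES:
            row[f"{name}_raw"] = stats[name]
            row[f"{name}_norm"] = stats[name] / cohort_speed
            row[f"{name}_mock"] = mock[name]
            row[f"{name}_corrected"] = stats[name] - mock[name]
            row[f"{name}_corrected_norm"] = (stats[name] - mock[name]) / cohort_speed
        rows.append(row)
    return pd.DataFrame(rows)
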