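"""Pairwise proximity and alignment metrics and their joint distributions.

All metrics operate on aligned trials.  Pair distance is the Euclidean
distance between the centre points of two fish; pair angle is the absolute
heading difference folded into [0, 180] degrees.  The nearest-neighbour
distance (NND) is each fish's minimum pair distance per frame; the
inter-individual distances (IID) are all N-1 distances from a focal fish to
its group mates, a group-coherency measure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kinematics import mean_swim_speed
from .trajectory_io import TrialGroup, to_body_lengths, to_tank_radii

__all__ = [
    "pair_distance",
    "pair_angle",
    "pair_distance_matrix",
    "pair_angle_matrix",
    "nearest_neighbor_distance",
    "interindividual_distance",
    "nn_pair_angle",
    "joint_distance_angle_distribution",
    "speed_metric_correlation",
    "trial_metric_summary",
    "wall_occupancy_excess",
]


def _distance_scale(trial: TrialGroup, unit: str) -> float:
    if unit == "cm":
        return 1.0
    if unit == "bl":
        return 1.0 / trial.cohort.mean_body_length_cm
    if unit == "tank_radii":
        return 1.0 / trial.arena.radius_cm
    raise ValueError(f"unknown distance unit {unit!r}")


def pair_distance_matrix(trial: TrialGroup) -> np.ndarray:
    """Pairwise distances, shape (T, N, N), cm; diagonal NaN."""
    xy = trial.xy
    d = np.linalg.norm(xy[:, :, None, :] - xy[:, None, :, :], axis=-1)
    idx = np.arange(trial.n_fish)
    d[:, idx, idx] = np.nan
    return d


def pair_angle_matrix(trial: TrialGroup) -> np.ndarray:
    """Pairwise folded heading differences, shape (T, N, N), degrees [0, 180]."""
    phi = trial.phi
    dphi = np.abs(phi[:, :, None] - phi[:, None, :]) % (2.0 * np.pi)
    dphi = np.minimum(dphi, 2.0 * np.pi - dphi)
    ang = np.degrees(dphi)
    idx = np.arange(trial.n_fish)
    ang[:, idx, idx] = np.nan
    return ang


def _unordered_pairs(n: int):
    i, j = np.triu_indices(n, k=1)
    return i, j


def pair_distance(trial: TrialGroup, unit: str = "cm") -> pd.DataFrame:
    """Per-frame distance for every unordered pair of fish."""
    d = pair_distance_matrix(trial) * _distance_scale(trial, unit)
    i, j = _unordered_pairs(trial.n_fish)
    frames = trial.tracks[0].frames
    ids = np.asarray(trial.fish_ids)
    return pd.DataFrame(
        {
            "frame": np.repeat(frames, len(i)),
            "focal_id": np.tile(ids[i], trial.n_frames),
            "neighbor_id": np.tile(ids[j], trial.n_frames),
            "pair_distance": d[:, i, j].ravel(),
        }
    )


def pair_angle(trial: TrialGroup) -> pd.DataFrame:
    """Per-frame pair angle (degrees in [0, 180]) for every unordered pair."""
    ang = pair_angle_matrix(trial)
    i, j = _unordered_pairs(trial.n_fish)
    frames = trial.tracks[0].frames
    ids = np.asarray(trial.fish_ids)
    return pd.DataFrame(
        {
            "frame": np.repeat(frames, len(i)),
            "focal_id": np.tile(ids[i], trial.n_frames),
            "neighbor_id": np.tile(ids[j], trial.n_frames),
            "pair_angle": ang[:, i, j].ravel(),
        }
    )


def nearest_neighbor_distance(trial: TrialGroup, unit: str = "cm") -> pd.DataFrame:
    """Each fish's minimum pair distance per frame, with neighbour identity."""
    d = pair_distance_matrix(trial) * _distance_scale(trial, unit)
    nn_idx = np.nanargmin(d, axis=2)
    nnd = np.take_along_axis(d, nn_idx[:, :, None], axis=2)[:, :, 0]
    frames = trial.tracks[0].frames
    ids = np.asarray(trial.fish_ids)
    return pd.DataFrame(
        {
            "frame": np.repeat(frames, trial.n_fish),
            "fish_id": np.tile(ids, trial.n_frames),
            "neighbor_id": ids[nn_idx.ravel()],
            "nnd": nnd.ravel(),
        }
    )


def interindividual_distance(trial: TrialGroup, unit: str = "cm") -> pd.DataFrame:
    """All N-1 distances from each focal fish to its group mates, per frame."""
    d = pair_distance_matrix(trial) * _distance_scale(trial, unit)
    n = trial.n_fish
    focal, nb = np.where(~np.eye(n, dtype=bool))
    frames = trial.tracks[0].frames
    ids = np.asarray(trial.fish_ids)
    return pd.DataFrame(
        {
            "frame": np.repeat(frames, len(focal)),
            "focal_id": np.tile(ids[focal], trial.n_frames),
            "neighbor_id": np.tile(ids[nb], trial.n_frames),
            "iid": d[:, focal, nb].ravel(),
        }
    )


def nn_pair_angle(trial: TrialGroup) -> pd.DataFrame:
    """Pair angle (deg) between each fish and its nearest neighbour."""
    d = pair_distance_matrix(trial)
    ang = pair_angle_matrix(trial)
    nn_idx = np.nanargmin(d, axis=2)
    nn_ang = np.take_along_axis(ang, nn_idx[:, :, None], axis=2)[:, :, 0]
    frames = trial.tracks[0].frames
    ids = np.asarray(trial.fish_ids)
    return pd.DataFrame(
        {
            "frame": np.repeat(frames, trial.n_fish),
            "fish_id": np.tile(ids, trial.n_frames),
            "neighbor_id": ids[nn_idx.ravel()],
            "nn_pair_angle": nn_ang.ravel(),
        }
    )


def joint_distance_angle_distribution(records: pd.DataFrame, d_bins, a_bins,
                                      distance_col: str = "pair_distance",
                                      angle_col: str = "pair_angle"):
    """Joint histogram of pair distance and pair angle, normalised by the
    total number of records (mass sums to 1 when the bins cover the range).

    Returns ``(prob, d_edges, a_edges)``.
    """
    if len(records) == 0:
        raise ValueError("no records to bin")
    h, d_edges, a_edges = np.histogram2d(
        records[distance_col].to_numpy(),
        records[angle_col].to_numpy(),
        bins=[np.asarray(d_bins, dtype=float), np.asarray(a_bins, dtype=float)],
    )
    return h / len(records), d_edges, a_edges


_METRIC_FUNCS = {
    "nnd": lambda tr, unit: nearest_neighbor_distance(tr, unit=unit)["nnd"],
    "iid": lambda tr, unit: interindividual_distance(tr, unit=unit)["iid"],
    "nn_pair_angle": lambda tr, unit: nn_pair_angle(tr)["nn_pair_angle"],
}


def trial_metric_summary(trial: TrialGroup, unit: str = "bl") -> dict:
    """Per-trial medians and means of NND, IID and NN pair angle.

    The trial is the statistical unit: frame-level values are pooled within
    the trial and summarised by their median (the robust summary used when
    distributions are skewed) and mean.
    """
    out = {"trial_id": trial.trial_id, "is_mock": trial.is_mock}
    for name in ("nnd", "iid", "nn_pair_angle"):
        vals = _METRIC_FUNCS[name](trial, unit).to_numpy()
        out[f"{name}_median"] = float(np.nanmedian(vals))
        out[f"{name}_mean"] = float(np.nanmean(vals))
    return out


def speed_metric_correlation(trials, metric: str = "nnd", unit: str = "bl"):
    """Spearman rank correlation between per-trial mean swimming speed and
    the per-trial mean of a proximity/alignment metric.

    Returns ``(rho, p)``; rho is NaN when either variable is constant.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}")
    if len(trials) < 3:
        raise ValueError("need at least 3 trials")
    speeds = np.array([mean_swim_speed(t) for t in trials])
    vals = np.array(
        [float(np.nanmean(_METRIC_FUNCS[metric](t, unit))) for t in trials]
    )
    if np.ptp(speeds) == 0 or np.ptp(vals) == 0:
        return float("nan"), float("nan")
    res = sps.spearmanr(speeds, vals)
    return float(res.statistic), float(res.pvalue)


def wall_occupancy_excess(trial: TrialGroup, rho_threshold: float = 0.8) -> float:
    """Occupancy of the wall-adjacent annulus relative to a uniform fish.

    The statistic is the fraction of fish-frames with radial position beyond
    ``rho_threshold`` tank radii divided by the annulus' area fraction; 1
    means no wall preference, >1 means wall-following (thigmotaxis).
    """
    rho = np.linalg.norm(to_tank_radii(trial.xy, trial.arena), axis=-1)
    area_fraction = 1.0 - rho_threshold**2
    return float(np.mean(rho > rho_threshold) / area_fraction)
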