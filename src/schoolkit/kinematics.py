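"""Trajectory smoothing, finite-difference kinematics and the
speeding/turning decomposition.

Velocities use the forward difference v_i = (r_{i+1} - r_i)/dt, linear and
angular accelerations the central second difference
(x_{i+1} + x_{i-1} - 2 x_i)/dt^2, and the angular velocity the forward
difference of the unwrapped heading.  Frames where a difference is undefined
(first/last) are NaN, never zero-filled, and are excluded from all downstream
binning.

The speeding force is the tangential component of the acceleration (positive
when the fish speeds up); the turning force is the normal component, counted
positive when it points to the fish's right.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .trajectory_io import CohortSpec, FishTrack, TrialGroup

__all__ = [
    "KinematicSeries",
    "smooth_tracks",
    "smooth_trial",
    "differentiate",
    "decompose_acceleration",
    "normalize_forces",
    "trial_kinematics",
    "mean_swim_speed",
    "wrap_angle",
]

SAVGOL_WINDOW = 5
SAVGOL_POLYORDER = 2

#: relative tolerance on frame-time uniformity
DT_RTOL = 1e-3


def wrap_angle(a):
    """Wrap angles to [-pi, pi)."""
    return (np.asarray(a, dtype=float) + np.pi) % (2.0 * np.pi) - np.pi


@dataclass
class KinematicSeries:
    """Per-frame kinematics for one fish (arrays shaped (T,)/(T,2)) or a whole
    trial (arrays shaped (T, N)/(T, N, 2)).

    ``f_speed``/``f_turn`` are in cm/s^2 unless ``normalized`` is set, in
    which case they have been divided by the cohort mean swimming speed
    (units 1/s).
    """

    dt: float
    v: np.ndarray
    a: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    speed: np.ndarray
    f_speed: np.ndarray | None = None
    f_turn: np.ndarray | None = None
    normalized: bool = False

    @property
    def n_frames(self) -> int:
        return self.v.shape[0]


def smooth_tracks(track: FishTrack, window: int = SAVGOL_WINDOW,
                  polyorder: int = SAVGOL_POLYORDER) -> FishTrack:
    """Savitzky-Golay smooth positions and (unwrapped) headings.

    A window of 5 with polynomial order 2 reproduces constant, linear and
    quadratic signals exactly, which keeps the central second differences of
    analytic test trajectories intact.
    """
    if track.n_frames < window:
        raise ValueError(
            f"track has {track.n_frames} frames; smoothing window is {window}"
        )
    xy = savgol_filter(track.xy, window, polyorder, axis=0)
    phi = savgol_filter(np.unwrap(track.phi), window, polyorder)
    return FishTrack(
        fish_id=track.fish_id,
        frames=track.frames.copy(),
        t=track.t.copy(),
        xy=xy,
        phi=phi,
        body_length_cm=track.body_length_cm,
    )


def smooth_trial(trial: TrialGroup, window: int = SAVGOL_WINDOW,
                 polyorder: int = SAVGOL_POLYORDER) -> TrialGroup:
    return TrialGroup(
        trial_id=trial.trial_id,
        tracks=[smooth_tracks(tr, window, polyorder) for tr in trial.tracks],
        arena=trial.arena,
        cohort=trial.cohort,
        is_mock=trial.is_mock,
        fps=trial.fps,
    )


def _check_uniform_dt(t: np.ndarray, dt: float) -> None:
    if len(t) > 1:
        steps = np.diff(t)
        if np.any(np.abs(steps - dt) > DT_RTOL * dt):
            raise ValueError("frame times are not uniformly spaced")


def differentiate(xy: np.ndarray, phi: np.ndarray, dt: float,
                  t: np.ndarray | None = None) -> KinematicSeries:
    """Finite-difference kinematics of positions (T,...,2) and headings (T,...).

    Forward differences for v and omega (undefined at the last frame),
    central second differences for a and alpha (undefined at first and last
    frames); undefined entries are NaN.
    """
    xy = np.asarray(xy, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if t is not None:
        _check_uniform_dt(np.asarray(t, dtype=float), dt)
    T = xy.shape[0]
    if T < 3:
        raise ValueError("need at least 3 frames for central differences")

    v = np.full_like(xy, np.nan)
    v[:-1] = (xy[1:] - xy[:-1]) / dt
    a = np.full_like(xy, np.nan)
    a[1:-1] = (xy[2:] + xy[:-2] - 2.0 * xy[1:-1]) / dt**2
    omega = np.full_like(phi, np.nan)
    omega[:-1] = (phi[1:] - phi[:-1]) / dt
    alpha = np.full_like(phi, np.nan)
    alpha[1:-1] = (phi[2:] + phi[:-2] - 2.0 * phi[1:-1]) / dt**2
    speed = np.linalg.norm(v, axis=-1)
    return KinematicSeries(dt=dt, v=v, a=a, omega=omega, alpha=alpha, speed=speed)


def decompose_acceleration(kin: KinematicSeries, phi: np.ndarray) -> KinematicSeries:
    """Attach the tangential (speeding) and normal (turning) components.

    f_speed = a . (cos phi, sin phi); f_turn = a . (sin phi, -cos phi),
    i.e. the turning force is positive when the acceleration points to the
    fish's right.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape != kin.a.shape[:-1]:
        raise ValueError("phi shape does not match acceleration shape")
    c, s = np.cos(phi), np.sin(phi)
    f_speed = kin.a[..., 0] * c + kin.a[..., 1] * s
    f_turn = kin.a[..., 0] * s - kin.a[..., 1] * c
    return replace(kin, f_speed=f_speed, f_turn=f_turn)


def normalize_forces(kin: KinematicSeries, cohort: CohortSpec) -> KinematicSeries:
    """Return a view with f_speed/f_turn divided by the cohort mean speed."""
    if kin.f_speed is None or kin.f_turn is None:
        raise ValueError("decompose_acceleration must run first")
    s = cohort.mean_swim_speed_cm_s
    if s is None or s <= 0:
        raise ValueError("cohort mean swimming speed must be positive")
    return replace(kin, f_speed=kin.f_speed / s, f_turn=kin.f_turn / s,
                   normalized=True)


def trial_kinematics(trial: TrialGroup, smooth: bool = True) -> KinematicSeries:
    """Smoothed, decomposed kinematics of a whole trial, arrays (T, N, ...)."""
    if smooth:
        trial = smooth_trial(trial)
    kin = differentiate(trial.xy, trial.phi, trial.dt, t=trial.tracks[0].t)
    return decompose_acceleration(kin, trial.phi)


def mean_swim_speed(trial: TrialGroup, smooth: bool = True) -> float:
    """Trial-mean swimming speed (cm/s), pooled over fish and frames."""
    kin = trial_kinematics(trial, smooth=smooth)
    return float(np.nanmean(kin.speed))


def cohort_mean_speed(trials) -> float:
    """Cohort-average swimming speed: pooled mean over all trials' frames."""
    return float(np.mean([mean_swim_speed(t) for t in trials]))
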