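"""Zonal agent-based simulator and analytic fixtures.

The simulator generates groups of fish-like agents in a circular arena with
known interaction rules, so every analysis stage can be validated against a
ground truth.  Each agent carries a position, a continuous heading and a
speed.  Its social response is a classic metric-zone rule: move away from
neighbours inside the repulsion radius, match the mean heading of neighbours
in the alignment annulus, and head towards the centroid of neighbours in the
attraction annulus.  Near the wall an inward term (avoidance) and a
tangential term (wall following, thigmotaxis) are added.  The weighted sum of
these unit vectors is a desired direction D (weights in 1/s); the heading
turns at the rate given by the component of D perpendicular to the current
heading, and the speed relaxes towards the preferred speed plus a forcing
term proportional to the component of D along the heading -- so an attractive
target ahead makes the agent speed up and one behind makes it slow down, and
the analysis pipeline should recover attraction in both the turning and the
speeding channel.

Presets emulate the three phenotypes relevant to schooling ontogeny studies:
``schooling`` (attraction + alignment), ``asocial_wall`` (no social response,
strong wall following, the cave-like phenotype) and ``null_random``
(independent walkers, the mock-equivalent null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .trajectory_io import ArenaGeometry, CohortSpec, FishTrack, TrialGroup

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_trial",
    "simulate_cohort",
    "make_preset",
    "PRESETS",
    "analytic_fixtures",
    "sign_scenes",
    "line_track",
    "circle_track",
    "sinusoid_track",
    "DEFAULT_ARENA",
    "DEFAULT_COHORT",
]

# 33.9 cm arena diameter with fish of ~1/22 of the diameter, the subadult
# geometry of the assay family this simulator emulates
DEFAULT_ARENA = ArenaGeometry(radius_cm=16.95, center_xy=(0.0, 0.0),
                              radius_px=500.0, depth_mm=25.0)
DEFAULT_COHORT = CohortSpec(population="synthetic", age_dpf=70,
                            mean_body_length_cm=33.9 / 22.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated trial.

    Zone radii are in cm and must satisfy r_rep < r_ali <= r_att; gains are
    turning rates (1/s) applied to the respective unit vectors; noise
    intensities are per square-root second.
    """

    n_fish: int = 5
    fps: float = 30.0
    duration_s: float = 120.0
    arena: ArenaGeometry = DEFAULT_ARENA
    preferred_speed: float = 6.0        # cm/s
    speed_relaxation: float = 1.0       # 1/s
    speed_noise_sd: float = 2.0         # cm/s per sqrt(s)
    heading_noise_sd: float = 0.7       # rad per sqrt(s)
    r_rep: float = 1.5                  # cm
    r_ali: float = 5.0                  # cm
    r_att: float = 12.0                 # cm
    w_rep: float = 4.0                  # 1/s
    w_ali: float = 0.0                  # 1/s
    w_att: float = 0.0                  # 1/s
    wall_avoid_range: float = 3.0       # cm
    wall_gain: float = 2.0              # 1/s
    wall_follow_gain: float = 0.0       # 1/s, tangential wall following
    wall_attract_gain: float = 0.0      # 1/s, pull toward the wall annulus
    wall_preferred_distance: float = 2.0  # cm, thigmotaxis target distance
    wall_attract_range: float = 6.0     # cm, distance scale of the pull
    speed_forcing: float = 0.5          # dimensionless; couples the positional
                                        # social terms into speed modulation
    burn_in_s: float = 10.0
    seed: int = 0
    preset: str = "custom"

    def __post_init__(self) -> None:
        if not (0 < self.r_rep < self.r_ali <= self.r_att):
            raise ValueError("need 0 < r_rep < r_ali <= r_att")
        for g in (self.w_rep, self.w_ali, self.w_att, self.wall_gain,
                  self.wall_follow_gain):
            if g < 0:
                raise ValueError("gains must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Expected qualitative outcome of a preset, fixed by construction."""

    preset: str
    attractive_speeding_sign: int   # expected sign of the corrected statistic
    attractive_turning_sign: int
    aligning_sign: int
    schools: bool
    wall_follower: bool


def _unit_rows(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    return np.divide(v, norm, out=np.zeros_like(v), where=norm > 0)


def simulate_trial(config: SimulationConfig, trial_id: str | None = None) -> TrialGroup:
    """Run one trial and return it as a TrialGroup (positions cm, headings rad).

    The first ``burn_in_s`` seconds are discarded so analyses see
    quasi-stationary behaviour.  Fixed seed => bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_fish
    dt = 1.0 / config.fps
    sqdt = math.sqrt(dt)
    n_burn = int(round(config.burn_in_s * config.fps))
    n_keep = int(round(config.duration_s * config.fps))
    R = config.arena.radius_cm
    center = config.arena.center
    margin = 0.3  # cm, keeps agents strictly inside after reflection

    # initial placement: uniform in the inner 70% of the disk, resampling
    # overlapping fish (< 0.5 cm apart)
    while True:
        rho = 0.7 * R * np.sqrt(rng.random(n))
        theta = rng.uniform(0, 2 * np.pi, n)
        pos = center + np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        if np.all(d[np.triu_indices(n, 1)] > 0.5):
            break
    phi = rng.uniform(0, 2 * np.pi, n)
    speed = np.full(n, config.preferred_speed)

    xy_out = np.empty((n_keep, n, 2))
    phi_out = np.empty((n_keep, n))

    for step in range(n_burn + n_keep):
        heading = np.column_stack([np.cos(phi), np.sin(phi)])

        rel = pos[None, :, :] - pos[:, None, :]          # j relative to i
        dist = np.linalg.norm(rel, axis=-1)
        np.fill_diagonal(dist, np.inf)

        D = np.zeros((n, 2))       # all terms steer the heading
        D_pos = np.zeros((n, 2))   # positional terms also force the speed
        if config.w_rep > 0:
            mask = dist < config.r_rep
            away = -_unit_rows(rel) * mask[:, :, None]
            rep = config.w_rep * _unit_rows(away.sum(axis=1))
            D += rep
            D_pos += rep
        if config.w_ali > 0:
            mask = (dist >= config.r_rep) & (dist < config.r_ali)
            mean_h = (heading[None, :, :] * mask[:, :, None]).sum(axis=1)
            D += config.w_ali * _unit_rows(mean_h)
        if config.w_att > 0:
            mask = (dist >= config.r_ali) & (dist < config.r_att)
            cnt = mask.sum(axis=1)
            centroid = ((pos[None, :, :] * mask[:, :, None]).sum(axis=1)
                        / np.maximum(cnt, 1)[:, None])
            toward = np.where(cnt[:, None] > 0, centroid - pos, 0.0)
            att = config.w_att * _unit_rows(toward)
            D += att
            D_pos += att

        # wall terms ramp up linearly inside the avoidance range
        radial = pos - center
        rho = np.linalg.norm(radial, axis=-1)
        r_hat = _unit_rows(radial)
        d_wall = R - rho
        ramp = np.clip(1.0 - d_wall / config.wall_avoid_range, 0.0, 1.0)
        if config.wall_gain > 0:
            D += -r_hat * (config.wall_gain * ramp)[:, None]
        if config.wall_follow_gain > 0:
            tang = np.column_stack([-r_hat[:, 1], r_hat[:, 0]])
            # follow the tangential direction closer to the current heading
            sign = np.sign(np.sum(tang * heading, axis=-1))
            sign[sign == 0] = 1.0
            D += tang * (config.wall_follow_gain * ramp * sign)[:, None]
        if config.wall_attract_gain > 0:
            # thigmotaxis: steer outward toward the preferred wall distance
            pull = np.clip(
                (d_wall - config.wall_preferred_distance)
                / config.wall_attract_range, 0.0, 1.0)
            D += r_hat * (config.wall_attract_gain * pull)[:, None]

        # turn at the rate of D's component perpendicular to the heading
        omega = heading[:, 0] * D[:, 1] - heading[:, 1] * D[:, 0]
        phi = phi + omega * dt + config.heading_noise_sd * sqdt * rng.standard_normal(n)

        # speed relaxes to preferred, forced by the along-heading component of
        # the positional social terms (speed changes serve proximity control)
        forcing = (config.speed_forcing * np.sum(D_pos * heading, axis=-1)
                   * config.preferred_speed)
        speed = (speed
                 + (config.speed_relaxation * (config.preferred_speed - speed)
                    + forcing) * dt
                 + config.speed_noise_sd * sqdt * rng.standard_normal(n))
        speed = np.clip(speed, 0.0, 3.0 * config.preferred_speed)

        heading = np.column_stack([np.cos(phi), np.sin(phi)])
        pos = pos + speed[:, None] * heading * dt

        # specular reflection off the wall, preserving heading continuity
        radial = pos - center
        rho = np.linalg.norm(radial, axis=-1)
        out = rho > R - margin
        if np.any(out):
            r_hat = _unit_rows(radial[out])
            pos[out] = (center + r_hat
                        * (2.0 * (R - margin) - rho[out])[:, None])
            h = heading[out]
            h_ref = h - 2.0 * np.sum(h * r_hat, axis=-1, keepdims=True) * r_hat
            dphi = np.arctan2(h_ref[:, 1], h_ref[:, 0]) - phi[out]
            phi[out] += (dphi + np.pi) % (2 * np.pi) - np.pi

        if step >= n_burn:
            xy_out[step - n_burn] = pos
            phi_out[step - n_burn] = phi

    frames = np.arange(n_keep, dtype=np.int64)
    t = frames / config.fps
    tracks = [
        FishTrack(
            fish_id=str(i),
            frames=frames,
            t=t,
            xy=xy_out[:, i, :],
            phi=phi_out[:, i],
            body_length_cm=DEFAULT_COHORT.mean_body_length_cm,
        )
        for i in range(n)
    ]
    return TrialGroup(
        trial_id=trial_id or f"{config.preset}-seed{config.seed}",
        tracks=tracks,
        arena=config.arena,
        cohort=DEFAULT_COHORT,
        is_mock=False,
        fps=config.fps,
    )


PRESETS: dict[str, dict] = {
    # attraction + alignment: schools and shoals
    "schooling": dict(w_rep=4.0, w_ali=3.0, w_att=1.5, wall_gain=2.0,
                      wall_follow_gain=0.0, heading_noise_sd=0.7),
    # no social response, strong thigmotaxis: the cave-like phenotype.
    # The wall pull plus a realistic heading-noise level keeps fish in the
    # wall annulus while still letting them meander and reverse direction.
    "asocial_wall": dict(w_rep=0.0, w_ali=0.0, w_att=0.0, wall_gain=1.0,
                         wall_follow_gain=2.0, wall_avoid_range=3.0,
                         wall_attract_gain=1.5, wall_preferred_distance=2.0,
                         heading_noise_sd=1.0),
    # independent walkers: the mock-equivalent null.  Wall handling stays the
    # smooth avoidance turn used by every preset (hard reflections would put
    # non-differentiable kinks in the tracks, which the smoothing +
    # finite-difference chain converts into spurious speeding signal).
    "null_random": dict(w_rep=0.0, w_ali=0.0, w_att=0.0, wall_gain=2.0,
                        wall_follow_gain=0.0, heading_noise_sd=1.2),
}

_GROUND_TRUTHS = {
    "schooling": GroundTruth("schooling", 1, 1, 1, True, False),
    "asocial_wall": GroundTruth("asocial_wall", 0, 0, 0, False, True),
    "null_random": GroundTruth("null_random", 0, 0, 0, False, False),
}


def make_preset(name: str, **overrides) -> tuple[SimulationConfig, GroundTruth]:
    """A fully specified config plus its documented ground truth."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = {**PRESETS[name], **overrides}
    return SimulationConfig(preset=name, **params), _GROUND_TRUTHS[name]


def simulate_cohort(preset: str, n_trials: int = 12, seed: int = 0,
                    **overrides) -> list[TrialGroup]:
    """n_trials independent trials of a preset, seeded from one master seed."""
    config, _ = make_preset(preset, **overrides)
    seeds = np.random.SeedSequence(seed).generate_state(n_trials) % (2**31)
    return [
        simulate_trial(replace(config, seed=int(s)),
                       trial_id=f"{preset}-{seed}-{k:02d}")
        for k, s in enumerate(seeds)
    ]


# ---------------------------------------------------------------------------
# analytic fixtures: trajectories with closed-form kinematics


def _track_from_arrays(fish_id, t, xy, phi) -> FishTrack:
    frames = np.arange(len(t), dtype=np.int64)
    return FishTrack(fish_id=fish_id, frames=frames, t=np.asarray(t),
                     xy=np.asarray(xy), phi=np.asarray(phi),
                     body_length_cm=DEFAULT_COHORT.mean_body_length_cm)


def line_track(speed: float = 3.0, heading: float = 0.0,
               duration_s: float = 2.0, fps: float = 30.0,
               origin=(0.0, 0.0)) -> FishTrack:
    """Uniform straight-line motion: v = speed, a = 0, omega = alpha = 0."""
    t = np.arange(int(round(duration_s * fps))) / fps
    d = np.array([np.cos(heading), np.sin(heading)])
    xy = np.asarray(origin) + speed * t[:, None] * d
    return _track_from_arrays("line", t, xy, np.full_like(t, heading))


def circle_track(radius: float = 5.0, speed: float = 3.0,
                 duration_s: float = 10.0, fps: float = 30.0,
                 ccw: bool = True) -> FishTrack:
    """Uniform circular motion: |a| = speed^2/radius, omega = +-speed/radius,
    alpha = 0; heading tangent to the circle."""
    t = np.arange(int(round(duration_s * fps))) / fps
    sgn = 1.0 if ccw else -1.0
    w = sgn * speed / radius
    theta = w * t
    xy = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    phi = theta + sgn * np.pi / 2.0
    return _track_from_arrays("circle", t, xy, phi)


def sinusoid_track(amplitude: float = 1.0, wavelength: float = 6.0,
                   speed_x: float = 3.0, duration_s: float = 4.0,
                   fps: float = 30.0) -> FishTrack:
    """x = speed_x t, y = A sin(2 pi x / lambda); heading along the velocity."""
    t = np.arange(int(round(duration_s * fps))) / fps
    k = 2 * np.pi / wavelength
    x = speed_x * t
    y = amplitude * np.sin(k * x)
    phi = np.unwrap(np.arctan2(amplitude * k * np.cos(k * x) * speed_x,
                               np.full_like(t, speed_x)))
    return _track_from_arrays("sinusoid", t, np.column_stack([x, y]), phi)


def analytic_fixtures() -> dict:
    """Named fixtures with closed-form kinematics for the oracles."""
    return {
        "line": line_track(),
        "circle": circle_track(),
        "sinusoid": sinusoid_track(),
    }


# ---------------------------------------------------------------------------
# hand-built two-fish scenes with prescribed signs

_SCENE_ARENA = ArenaGeometry(radius_cm=10.0)


def _two_fish_trial(name, t, xy_f, phi_f, xy_n, phi_n) -> TrialGroup:
    return TrialGroup(
        trial_id=name,
        tracks=[_track_from_arrays("0", t, xy_f, phi_f),
                _track_from_arrays("1", t, xy_n, phi_n)],
        arena=_SCENE_ARENA,
        cohort=DEFAULT_COHORT,
        fps=30.0,
    )


def sign_scenes(fps: float = 30.0, duration_s: float = 1.0) -> dict:
    """Two-fish choreographies that pin down the definitional signs.

    Each entry maps a scene name to ``(trial, expected)`` where ``expected``
    gives the sign (+1/-1) of the focal fish 0's contribution to each signed
    statistic, or None when the scene does not constrain it.  Positions and
    headings are polynomial (degree <= 2) in time, so Savitzky-Golay
    smoothing and central differences reproduce them exactly.
    """
    t = np.arange(int(round(duration_s * fps))) / fps
    scenes = {}

    # --- speeding scenes: focal heads +y, speed changes at rate accel;
    #     neighbour co-moves 2.5 cm (0.25 tank radii) ahead or behind
    v0 = 3.0
    for accel, accel_name in ((0.8, "speedup"), (-0.8, "slowdown")):
        y_f = -4.0 + v0 * t + 0.5 * accel * t**2
        xy_f = np.column_stack([np.zeros_like(t), y_f])
        phi = np.full_like(t, np.pi / 2.0)
        for offset, pos_name in ((2.5, "ahead"), (-2.5, "behind")):
            xy_n = np.column_stack([np.zeros_like(t), y_f + offset])
            trial = _two_fish_trial(f"{pos_name}-{accel_name}", t, xy_f, phi,
                                    xy_n, phi)
            sign = int(np.sign(accel) * np.sign(offset))
            scenes[f"{pos_name}-{accel_name}"] = (
                trial, {"speeding": sign, "turning": None, "aligning": None})

    # --- turning scenes: focal on a circular arc (normal acceleration only);
    #     neighbour rides 2.5 cm to the focal's left or right
    R0, s = 5.0, 3.0
    for ccw, turn_name in ((True, "turnleft"), (False, "turnright")):
        sgn = 1.0 if ccw else -1.0
        w = sgn * s / R0
        theta = w * t
        xy_f = R0 * np.column_stack([np.cos(theta), np.sin(theta)])
        phi = theta + sgn * np.pi / 2.0
        # f_turn = -s^2/R0 for ccw (leftward), +s^2/R0 for cw (rightward)
        f_turn_sign = -1 if ccw else 1
        for side_x, side_name in ((2.5, "right"), (-2.5, "left")):
            # neighbour fixed at (side_x, 0) in the focal frame
            right = np.column_stack([np.sin(phi), -np.cos(phi)])
            xy_n = xy_f + side_x * right
            trial = _two_fish_trial(f"{side_name}-{turn_name}", t, xy_f, phi,
                                    xy_n, phi)
            sign = int(f_turn_sign * np.sign(side_x))
            scenes[f"{side_name}-{turn_name}"] = (
                trial, {"speeding": None, "turning": sign, "aligning": None})

    # --- aligning scenes: focal heading accelerates at alpha; neighbour
    #     heading offset keeps a fixed sign of the heading difference
    alpha_mag, dphi0 = 0.8, 0.5
    for alpha, a_name in ((alpha_mag, "accel_ccw"), (-alpha_mag, "accel_cw")):
        xy_f = np.column_stack([-2.0 + 3.0 * t, np.zeros_like(t)])
        phi_f = 0.5 * alpha * t**2
        xy_n = xy_f + np.array([0.0, 2.0])  # 0.2 tank radii away
        for dphi, d_name in ((dphi0, "nb_ccw"), (-dphi0, "nb_cw")):
            phi_n = np.full_like(t, dphi)
            trial = _two_fish_trial(f"{d_name}-{a_name}", t, xy_f, phi_f,
                                    xy_n, phi_n)
            sign = int(np.sign(alpha) * np.sign(dphi))
            scenes[f"{d_name}-{a_name}"] = (
                trial, {"speeding": None, "turning": None, "aligning": sign})

    return scenes
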