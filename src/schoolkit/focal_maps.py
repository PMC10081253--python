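"""Focal-frame polar binning: density, speeding-force and turning-force maps.

Every pairwise observation is a (focal fish, neighbour fish, frame) triple.
The neighbour's position is expressed in the focal fish's coordinate system
(origin at the focal fish, +y along its heading, +x to its right) in
tank-radius units, and binned on a polar grid whose radial edges follow the
density-map convention (0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5 tank radii)
with equal angular sectors.

Density maps hold the probability of finding a neighbour in a bin divided by
the bin's area (fish per square tank radius).  Force maps hold the average
focal-fish speeding or turning force given a neighbour in the bin.  Real
minus mock difference maps control for non-social structure such as arena
walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .kinematics import trial_kinematics, wrap_angle
from .mock_groups import cross_trial_pairs
from .trajectory_io import ArenaGeometry, TrialGroup

__all__ = [
    "PolarGrid",
    "FocalMap",
    "MapAccumulator",
    "PairObservations",
    "focal_frame_transform",
    "iter_pair_observations",
    "density_map",
    "force_map",
    "difference_map",
    "map_to_dataframe",
]

DEFAULT_RADIAL_EDGES = (0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class PolarGrid:
    """Polar binning grid in the focal frame (tank-radius units).

    Sectors are equal wedges indexed clockwise from the focal fish's heading,
    so with the default 12 sectors the ahead/behind and left/right half-plane
    splits fall exactly on sector boundaries.
    """

    radial_edges: tuple = DEFAULT_RADIAL_EDGES
    n_sectors: int = 12

    def __post_init__(self) -> None:
        edges = np.asarray(self.radial_edges, dtype=float)
        if edges[0] != 0 or np.any(np.diff(edges) <= 0):
            raise ValueError("radial edges must increase strictly from 0")
        if self.n_sectors < 1:
            raise ValueError("need at least one sector")

    @property
    def n_rings(self) -> int:
        return len(self.radial_edges) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rings, self.n_sectors)

    @cached_property
    def bin_area(self) -> np.ndarray:
        """Bin areas (square tank radii), shape (n_rings, n_sectors)."""
        edges = np.asarray(self.radial_edges)
        ring_area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) / self.n_sectors
        return np.repeat(ring_area[:, None], self.n_sectors, axis=1)

    @cached_property
    def sector_sign_ahead(self) -> np.ndarray:
        """+1 for sectors in the front half-plane (y > 0), -1 behind."""
        centers = (np.arange(self.n_sectors) + 0.5) * 360.0 / self.n_sectors
        return np.where((centers < 90.0) | (centers > 270.0), 1.0, -1.0)

    @cached_property
    def sector_sign_right(self) -> np.ndarray:
        """+1 for sectors in the right half-plane (x > 0), -1 on the left."""
        centers = (np.arange(self.n_sectors) + 0.5) * 360.0 / self.n_sectors
        return np.where(centers < 180.0, 1.0, -1.0)

    def assign(self, x: np.ndarray, y: np.ndarray):
        """Map focal-frame coordinates to (ring, sector); ring = -1 out of range.

        The angular coordinate is the bearing measured clockwise from the
        focal fish's heading (ahead = 0 deg, right = 90 deg).
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        r = np.hypot(x, y)
        edges = np.asarray(self.radial_edges)
        ring = np.searchsorted(edges, r, side="right") - 1
        ring[(r >= edges[-1])] = -1
        bearing = np.degrees(np.arctan2(x, y)) % 360.0
        sector = np.minimum(
            (bearing / (360.0 / self.n_sectors)).astype(np.int64),
            self.n_sectors - 1,
        )
        return ring, sector

    def zone_rings(self, r_min: float, r_max: float) -> np.ndarray:
        """Indices of rings fully contained in [r_min, r_max]."""
        edges = np.asarray(self.radial_edges)
        inner, outer = edges[:-1], edges[1:]
        return np.where((inner >= r_min - 1e-12) & (outer <= r_max + 1e-12))[0]


@dataclass
class FocalMap:
    """A per-bin statistic on a :class:`PolarGrid`.

    ``values`` is NaN where a bin holds no observation (undefined, not zero).
    """

    grid: PolarGrid
    kind: str  # density | speeding | turning | aligning
    values: np.ndarray
    counts: np.ndarray
    provenance: str = "real"  # real | mock | difference

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")


def focal_frame_transform(focal_xy, focal_phi, neighbor_xy,
                          arena: ArenaGeometry):
    """Neighbour coordinates in the focal fish's frame, in tank radii.

    +y points along the focal fish's heading, +x to its right.  Broadcasts
    over leading axes.
    """
    rel = (np.asarray(neighbor_xy, dtype=float)
           - np.asarray(focal_xy, dtype=float)) / arena.radius_cm
    phi = np.asarray(focal_phi, dtype=float)
    c, s = np.cos(phi), np.sin(phi)
    x = rel[..., 0] * s - rel[..., 1] * c
    y = rel[..., 0] * c + rel[..., 1] * s
    return x, y


@dataclass
class PairObservations:
    """Flat arrays of focal-frame pairwise observations (one chunk)."""

    x: np.ndarray        # neighbour x in focal frame, tank radii
    y: np.ndarray        # neighbour y in focal frame, tank radii
    f_speed: np.ndarray  # focal tangential acceleration
    f_turn: np.ndarray   # focal normal acceleration (right positive)
    alpha: np.ndarray    # focal angular acceleration, rad/s^2
    dphi: np.ndarray     # neighbour heading - focal heading, wrapped (rad)
    focal_trial: np.ndarray
    focal_fish: np.ndarray
    neighbor_trial: np.ndarray
    neighbor_fish: np.ndarray

    @property
    def r(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, mask: np.ndarray) -> "PairObservations":
        """Row subset (e.g. restrict to one focal fish)."""
        import dataclasses

        return PairObservations(
            **{f.name: getattr(self, f.name)[mask]
               for f in dataclasses.fields(self)})


def _pair_block(xy_f, phi_f, fsp, ftn, alp, xy_n, phi_n, radius_cm,
                ti_f, ti_n, mask_diag: bool):
    """Observations for all (focal in trial A) x (neighbour in trial B).

    Arrays are (T, Na, ...) and (T, Nb, ...); output is flattened with
    boundary (NaN-kinematics) frames dropped.
    """
    rel = (xy_n[:, None, :, :] - xy_f[:, :, None, :]) / radius_cm  # (T,Na,Nb,2)
    c = np.cos(phi_f)[:, :, None]
    s = np.sin(phi_f)[:, :, None]
    x = rel[..., 0] * s - rel[..., 1] * c
    y = rel[..., 0] * c + rel[..., 1] * s
    dphi = wrap_angle(phi_n[:, None, :] - phi_f[:, :, None])
    T, Na, Nb = x.shape
    fsp_b = np.broadcast_to(fsp[:, :, None], (T, Na, Nb))
    ftn_b = np.broadcast_to(ftn[:, :, None], (T, Na, Nb))
    alp_b = np.broadcast_to(alp[:, :, None], (T, Na, Nb))
    fa = np.broadcast_to(np.arange(Na)[None, :, None], (T, Na, Nb))
    fb = np.broadcast_to(np.arange(Nb)[None, None, :], (T, Na, Nb))

    keep = np.isfinite(fsp_b)
    if mask_diag:
        keep = keep & (fa != fb)
    return PairObservations(
        x=x[keep],
        y=y[keep],
        f_speed=fsp_b[keep],
        f_turn=ftn_b[keep],
        alpha=alp_b[keep],
        dphi=dphi[keep],
        focal_trial=np.full(keep.sum(), ti_f, dtype=np.int32),
        focal_fish=fa[keep].astype(np.int32),
        neighbor_trial=np.full(keep.sum(), ti_n, dtype=np.int32),
        neighbor_fish=fb[keep].astype(np.int32),
    )


def iter_pair_observations(trials, kins=None, mode: str = "within",
                           smooth: bool = True):
    """Yield chunks of focal-frame pairwise observations.

    ``mode='within'`` yields one chunk per trial with every ordered pair of
    distinct fish of that trial (the real-group observations).
    ``mode='cross'`` yields one chunk per ordered pair of distinct trials,
    covering every cross-trial fish pair over the common frame range -- the
    mock reference for maps and attraction statistics.
    """
    trials = list(trials)
    if kins is None:
        kins = [trial_kinematics(t, smooth=smooth) for t in trials]
    if mode == "within":
        for ti, (trial, kin) in enumerate(zip(trials, kins)):
            xy, phi = trial.xy, trial.phi
            yield _pair_block(xy, phi, kin.f_speed, kin.f_turn, kin.alpha,
                              xy, phi, trial.arena.radius_cm, ti, ti, True)
    elif mode == "cross":
        if len(trials) < 2:
            raise ValueError("cross mode needs at least 2 trials")
        for a, (ta, ka) in enumerate(zip(trials, kins)):
            for b, tb in enumerate(trials):
                if a == b:
                    continue
                T = min(ta.n_frames, tb.n_frames)
                yield _pair_block(
                    ta.xy[:T], ta.phi[:T],
                    ka.f_speed[:T], ka.f_turn[:T], ka.alpha[:T],
                    tb.xy[:T], tb.phi[:T],
                    ta.arena.radius_cm, a, b, False,
                )
    else:
        raise ValueError(f"unknown mode {mode!r}")


def _as_chunks(obs):
    if isinstance(obs, PairObservations):
        return [obs]
    return obs


_FORCE_FIELDS = {"speeding": "f_speed", "turning": "f_turn", "aligning": "alpha"}


class MapAccumulator:
    """Single-pass accumulator of everything binned on a polar grid.

    One pass over (possibly huge) pairwise observation streams collects the
    density counts, the per-bin force sums for all three force kinds, and the
    per-bin sums of the three *signed* quantities used by the attraction
    statistics (speeding signed by ahead/behind, turning by right/left,
    angular acceleration by the sign of the heading difference).
    """

    def __init__(self, grid: PolarGrid | None = None):
        self.grid = grid or PolarGrid()
        shape = self.grid.shape
        self.total = 0
        self.counts = np.zeros(shape, dtype=np.int64)
        self.force_sums = {k: np.zeros(shape) for k in _FORCE_FIELDS}
        self.signed_sums = {k: np.zeros(shape) for k in _FORCE_FIELDS}
        self.signed_counts = {k: np.zeros(shape, dtype=np.int64)
                              for k in _FORCE_FIELDS}

    def add(self, obs) -> "MapAccumulator":
        grid = self.grid
        for chunk in _as_chunks(obs):
            ring, sector = grid.assign(chunk.x, chunk.y)
            self.total += len(chunk)
            inside = ring >= 0
            ring, sector = ring[inside], sector[inside]
            flat = ring * grid.n_sectors + sector
            size = self.counts.size
            shape = grid.shape
            cnt = np.bincount(flat, minlength=size).reshape(shape)
            self.counts += cnt
            for kind, field_name in _FORCE_FIELDS.items():
                vals = getattr(chunk, field_name)[inside]
                self.force_sums[kind] += np.bincount(
                    flat, weights=vals, minlength=size).reshape(shape)
            # signed quantities
            f_speed = getattr(chunk, "f_speed")[inside]
            f_turn = getattr(chunk, "f_turn")[inside]
            alpha = getattr(chunk, "alpha")[inside]
            dphi = getattr(chunk, "dphi")[inside]
            self.signed_sums["speeding"] += np.bincount(
                flat, weights=f_speed * grid.sector_sign_ahead[sector],
                minlength=size).reshape(shape)
            self.signed_counts["speeding"] += cnt
            self.signed_sums["turning"] += np.bincount(
                flat, weights=f_turn * grid.sector_sign_right[sector],
                minlength=size).reshape(shape)
            self.signed_counts["turning"] += cnt
            # drop heading differences of exactly 0 or +-180 deg (no sign)
            sgn = np.sign(dphi)
            defined = (sgn != 0) & (np.abs(np.abs(dphi) - np.pi) > 1e-12)
            fa = flat[defined]
            self.signed_sums["aligning"] += np.bincount(
                fa, weights=alpha[defined] * sgn[defined],
                minlength=size).reshape(shape)
            self.signed_counts["aligning"] += np.bincount(
                fa, minlength=size).reshape(shape)
        return self

    # --- emitters -----------------------------------------------------

    def density(self, provenance: str = "real") -> FocalMap:
        if self.total == 0:
            raise ValueError("no observations")
        values = self.counts / self.total / self.grid.bin_area
        return FocalMap(grid=self.grid, kind="density", values=values,
                        counts=self.counts.copy(), provenance=provenance)

    def force(self, kind: str, provenance: str = "real",
              normalize_by: float | None = None) -> FocalMap:
        if kind not in _FORCE_FIELDS:
            raise ValueError(f"unknown force map kind {kind!r}")
        with np.errstate(invalid="ignore"):
            values = np.where(self.counts > 0,
                              self.force_sums[kind] / np.maximum(self.counts, 1),
                              np.nan)
        if normalize_by is not None:
            if normalize_by <= 0:
                raise ValueError("normalisation speed must be positive")
            values = values / normalize_by
        return FocalMap(grid=self.grid, kind=kind, values=values,
                        counts=self.counts.copy(), provenance=provenance)

    def signed_bin_means(self, kind: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-bin means of a signed quantity and the counts behind them."""
        counts = self.signed_counts[kind]
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0,
                             self.signed_sums[kind] / np.maximum(counts, 1),
                             np.nan)
        return means, counts


def density_map(obs, grid: PolarGrid | None = None,
                provenance: str = "real") -> FocalMap:
    """Neighbour density around the focal fish (fish per square tank radius).

    Bin value = (bin count / total observations) / bin area, where the total
    counts every observation including those beyond the outermost ring, so
    that sum(value x area) equals the fraction of observations within range.
    """
    return MapAccumulator(grid).add(obs).density(provenance)


def force_map(obs, grid: PolarGrid | None = None, kind: str = "speeding",
              provenance: str = "real", normalize_by: float | None = None) -> FocalMap:
    """Average focal-fish force given a neighbour in each bin.

    ``kind`` selects the speeding force, the turning force, or the angular
    acceleration.  ``normalize_by`` optionally divides by the cohort mean
    swimming speed.  Bins without observations are NaN.
    """
    return MapAccumulator(grid).add(obs).force(kind, provenance, normalize_by)


def difference_map(real: FocalMap, mock: FocalMap) -> FocalMap:
    """Real minus mock, bin by bin; undefined where either parent is."""
    if real.grid != mock.grid:
        raise ValueError("grid mismatch")
    if real.kind != mock.kind:
        raise ValueError("kind mismatch")
    values = real.values - mock.values
    return FocalMap(
        grid=real.grid,
        kind=real.kind,
        values=values,
        counts=np.minimum(real.counts, mock.counts),
        provenance=f"difference({real.provenance}-{mock.provenance})",
    )


def map_to_dataframe(fmap: FocalMap) -> pd.DataFrame:
    """Tidy (ring, sector, r_inner, r_outer, value, count) table."""
    nr, ns = fmap.grid.shape
    ring, sector = np.meshgrid(np.arange(nr), np.arange(ns), indexing="ij")
    edges = np.asarray(fmap.grid.radial_edges)
    return pd.DataFrame(
        {
            "ring": ring.ravel(),
            "sector": sector.ravel(),
            "r_inner": edges[:-1][ring.ravel()],
            "r_outer": edges[1:][ring.ravel()],
            "value": fmap.values.ravel(),
            "count": fmap.counts.ravel(),
            "kind": fmap.kind,
            "provenance": fmap.provenance,
        }
    )
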