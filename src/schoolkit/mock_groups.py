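"""Mock-group null model.

Mock groups are virtual groups assembled from fish recorded in *different*
trials: for every combination of r trials (r = group size, 5), one randomly
chosen fish per trial.  The number of mock groups is the binomial coefficient
C(n, r).  Because fish in a mock group never swam together, mock groups
carry the non-social structure of the data (arena walls, locomotion,
development) without any social interaction, and serve as the null reference
for every real-vs-mock comparison.

For *pairwise* quantities (forces, angular acceleration, density around a
focal fish), averaging over every possible pair of fish taken from two
different trials is equivalent to averaging over every pair within every
possible mock group; :func:`cross_trial_pairs` provides that cheaper route.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from . import pairwise_metrics as pm
from .trajectory_io import FishTrack, InputError, TrialGroup

__all__ = [
    "MockCohort",
    "enumerate_mock_groups",
    "assemble_mock_group",
    "make_mock_cohort",
    "iteration_stability",
    "cross_trial_pairs",
]


def enumerate_mock_groups(trial_ids, r: int = 5) -> list[tuple]:
    """All C(n, r) unordered combinations of trial ids."""
    trial_ids = list(trial_ids)
    n = len(trial_ids)
    if n < r:
        raise InputError(f"need at least r={r} trials, got {n}")
    combos = list(combinations(trial_ids, r))
    assert len(combos) == comb(n, r)
    return combos


def _truncate(track: FishTrack, n: int) -> FishTrack:
    return FishTrack(
        fish_id=track.fish_id,
        frames=track.frames[:n],
        t=track.t[:n],
        xy=track.xy[:n],
        phi=track.phi[:n],
        body_length_cm=track.body_length_cm,
    )


def assemble_mock_group(combination, trials_by_id: dict, rng) -> TrialGroup:
    """One mock group: a random fish from each trial of the combination,
    truncated to the shortest common frame count.

    ``rng`` is a :class:`numpy.random.Generator` (or a seed).  Frame indices
    are re-based to the common range so the assembled tracks align.
    """
    rng = np.random.default_rng(rng)
    members = [trials_by_id[tid] for tid in combination]
    arena = members[0].arena
    for t in members[1:]:
        if (t.arena.radius_cm != arena.radius_cm
                or t.fps != members[0].fps):
            raise InputError("mock group members must share arena and fps")
    n_frames = min(t.n_frames for t in members)
    tracks = []
    for t in members:
        fish = t.tracks[int(rng.integers(t.n_fish))]
        fish = _truncate(fish, n_frames)
        # re-base the frame index so members align frame-for-frame
        fish.frames = np.arange(n_frames, dtype=np.int64)
        fish.t = np.arange(n_frames) / t.fps
        fish.fish_id = f"{t.trial_id}:{fish.fish_id}"
        tracks.append(fish)
    return TrialGroup(
        trial_id="mock-" + "+".join(str(c) for c in combination),
        tracks=tracks,
        arena=arena,
        cohort=members[0].cohort,
        is_mock=True,
        fps=members[0].fps,
    )


@dataclass
class MockCohort:
    """One iteration of the mock-group formation process."""

    source_trials: list
    groups: list
    seed: int
    iteration: int


def make_mock_cohort(trials, r: int = 5, seed: int = 0,
                     iteration: int = 0) -> MockCohort:
    """Assemble every C(n, r) mock group, reproducibly.

    Child seeds are spawned deterministically from (seed, iteration) so that
    iterations differ but each is bit-reproducible.
    """
    trials = list(trials)
    trials_by_id = {t.trial_id: t for t in trials}
    combos = enumerate_mock_groups(list(trials_by_id), r=r)
    master = np.random.SeedSequence(entropy=seed, spawn_key=(iteration,))
    groups = [
        assemble_mock_group(combo, trials_by_id, np.random.default_rng(child))
        for combo, child in zip(combos, master.spawn(len(combos)))
    ]
    return MockCohort(source_trials=trials, groups=groups, seed=seed,
                      iteration=iteration)


def iteration_stability(trials, k: int = 10, seed: int = 0, r: int = 5,
                        metrics=("nnd", "iid", "nn_pair_angle"),
                        unit: str = "bl"):
    """Compare k iterations of mock-group formation via Kruskal-Wallis.

    For each metric, the per-group medians of each iteration form one sample;
    the omnibus H test asks whether iterations differ.  Returns a DataFrame
    with one row per metric (H statistic and p); downstream analyses use
    iteration 0.
    """
    import pandas as pd

    if k < 2:
        raise ValueError("need at least 2 iterations to compare")
    per_iter = []
    for it in range(k):
        cohort = make_mock_cohort(trials, r=r, seed=seed, iteration=it)
        summaries = [pm.trial_metric_summary(g, unit=unit) for g in cohort.groups]
        per_iter.append(pd.DataFrame(summaries))
    rows = []
    for metric in metrics:
        samples = [df[f"{metric}_median"].to_numpy() for df in per_iter]
        if np.ptp(np.concatenate(samples)) == 0:
            h, p = 0.0, 1.0
        else:
            try:
                h, p = sps.kruskal(*samples)
            except ValueError:  # all values identical across iterations
                h, p = 0.0, 1.0
        rows.append({"metric": metric, "H": float(h), "p": float(p),
                     "k": k, "groups_per_iteration": len(per_iter[0])})
    return pd.DataFrame(rows)


def cross_trial_pairs(trials) -> list[tuple[int, int, int, int]]:
    """Every ordered (focal, neighbour) fish pair with members from distinct
    trials, as index tuples (focal_trial, focal_fish, nb_trial, nb_fish)."""
    trials = list(trials)
    if len(trials) < 2:
        raise InputError("need at least 2 trials for cross-trial pairs")
    out = []
    for a, ta in enumerate(trials):
        for b, tb in enumerate(trials):
            if a == b:
                continue
            for fa in range(ta.n_fish):
                for fb in range(tb.n_fish):
                    out.append((a, fa, b, fb))
    return out
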