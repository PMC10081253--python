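"""End-to-end orchestration: trials -> kinematics -> metrics -> mock null ->
maps -> attraction statistics -> hypothesis tests -> tables and figures.

``run_pipeline`` takes a :class:`PipelineConfig` describing one or more
cohorts (simulator presets or directories of trajectory CSVs), runs every
stage in the order smoothing/kinematics, pairwise metrics, mock groups,
density/force maps, attraction statistics, tests, and writes tidy CSV tables,
optional figures and a JSON manifest recording seeds, files and versions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __name__ as _pkg_name
from .attraction_stats import DEFAULT_ZONES, STAT_NAMES, zone_average
from .focal_maps import (
    FocalMap,
    MapAccumulator,
    PolarGrid,
    difference_map,
    iter_pair_observations,
    map_to_dataframe,
)
from .kinematics import trial_kinematics
from .mock_groups import iteration_stability, make_mock_cohort
from .pairwise_metrics import (
    joint_distance_angle_distribution,
    pair_angle,
    pair_distance,
    trial_metric_summary,
    wall_occupancy_excess,
)
from .simulate import simulate_cohort
from .stats import one_sample_vs_zero, two_sample_compare
from .trajectory_io import read_trial

logger = logging.getLogger(__name__)

__all__ = ["CohortSpecEntry", "PipelineConfig", "run_pipeline",
           "render_figures", "demo_config"]

METRICS = ("nnd", "iid", "nn_pair_angle")


@dataclass
class CohortSpecEntry:
    """One cohort: either a simulator preset or a set of trajectory CSVs."""

    name: str
    preset: str | None = None
    n_trials: int = 12
    duration_s: float = 120.0
    trial_paths: list = field(default_factory=list)


@dataclass
class PipelineConfig:
    cohorts: list
    out_dir: Path
    seed: int = 0
    grid: PolarGrid = field(default_factory=PolarGrid)
    mock_group_size: int = 5
    stability_iterations: int = 0  # 0 skips the iteration-stability check
    figures: bool = True
    unit: str = "bl"


def demo_config(out_dir, seed: int = 0, n_trials: int = 12,
                duration_s: float = 120.0, figures: bool = True) -> PipelineConfig:
    """The three presets at study-like scale (12 trials per cohort)."""
    cohorts = [
        CohortSpecEntry("schooling", preset="schooling", n_trials=n_trials,
                        duration_s=duration_s),
        CohortSpecEntry("asocial_wall", preset="asocial_wall",
                        n_trials=n_trials, duration_s=duration_s),
        CohortSpecEntry("null_random", preset="null_random",
                        n_trials=n_trials, duration_s=duration_s),
    ]
    return PipelineConfig(cohorts=cohorts, out_dir=Path(out_dir), seed=seed,
                          figures=figures)


def _load_cohort_trials(entry: CohortSpecEntry, seed: int):
    if entry.preset is not None:
        return simulate_cohort(entry.preset, n_trials=entry.n_trials,
                               seed=seed, duration_s=entry.duration_s)
    if not entry.trial_paths:
        raise ValueError(f"cohort {entry.name}: no preset and no trial paths")
    return [read_trial(p) for p in entry.trial_paths]


def analyze_cohort(trials, grid: PolarGrid | None = None,
                   mock_group_size: int = 5, seed: int = 0,
                   unit: str = "bl") -> dict:
    """All per-cohort analyses on an in-memory list of trials.

    Returns a dict with per-trial metric summaries (real and mock groups),
    real-vs-mock tests, real/mock/difference maps, the attraction summary
    table and its one-sample tests, and wall-occupancy statistics.
    """
    grid = grid or PolarGrid()
    trials = list(trials)
    kins = [trial_kinematics(t) for t in trials]
    cohort_speed = float(np.mean([float(np.nanmean(k.speed)) for k in kins]))

    # --- pairwise metrics, real and mock groups (iteration 0) ----------
    real_summaries = pd.DataFrame(
        [trial_metric_summary(t, unit=unit) for t in trials])
    mock_cohort = make_mock_cohort(trials, r=mock_group_size, seed=seed,
                                   iteration=0)
    mock_summaries = pd.DataFrame(
        [trial_metric_summary(g, unit=unit) for g in mock_cohort.groups])

    metric_tests = {}
    for metric in METRICS:
        metric_tests[metric] = two_sample_compare(
            real_summaries[f"{metric}_median"],
            mock_summaries[f"{metric}_median"],
            metric=metric,
        )

    # --- joint pair distance / angle distribution ----------------------
    pair_records = pd.concat(
        [pd.merge(pair_distance(t, unit=unit), pair_angle(t),
                  on=["frame", "focal_id", "neighbor_id"])
         for t in trials],
        ignore_index=True,
    )
    d_max = float(np.nanmax(pair_records["pair_distance"]))
    joint, d_edges, a_edges = joint_distance_angle_distribution(
        pair_records, np.linspace(0, d_max, 25), np.linspace(0, 180, 19))

    # --- maps and attraction statistics (single pass per source) -------
    real_acc = MapAccumulator(grid)
    per_trial_stats = []
    for trial, kin in zip(trials, kins):
        acc = MapAccumulator(grid)
        for chunk in iter_pair_observations([trial], [kin], mode="within"):
            acc.add(chunk)
            real_acc.add(chunk)
        row = {"trial_id": trial.trial_id}
        for name in STAT_NAMES:
            means, counts = acc.signed_bin_means(name)
            row[f"{name}_raw"] = zone_average(means, grid, DEFAULT_ZONES[name])
        per_trial_stats.append(row)

    mock_acc = MapAccumulator(grid)
    for chunk in iter_pair_observations(trials, kins, mode="cross"):
        mock_acc.add(chunk)

    maps = {}
    for kind in ("density", "speeding", "turning"):
        if kind == "density":
            real_map = real_acc.density("real")
            mock_map = mock_acc.density("mock")
        else:
            real_map = real_acc.force(kind, "real", normalize_by=cohort_speed)
            mock_map = mock_acc.force(kind, "mock", normalize_by=cohort_speed)
        maps[kind] = {"real": real_map, "mock": mock_map,
                      "difference": difference_map(real_map, mock_map)}

    attraction = pd.DataFrame(per_trial_stats)
    attraction["cohort_mean_speed_cm_s"] = cohort_speed
    attraction_tests = {}
    for name in STAT_NAMES:
        means, counts = mock_acc.signed_bin_means(name)
        mock_value = zone_average(means, grid, DEFAULT_ZONES[name])
        attraction[f"{name}_mock"] = mock_value
        attraction[f"{name}_corrected"] = attraction[f"{name}_raw"] - mock_value
        attraction[f"{name}_norm"] = attraction[f"{name}_raw"] / cohort_speed
        attraction[f"{name}_corrected_norm"] = (
            attraction[f"{name}_corrected"] / cohort_speed)
        attraction_tests[name] = one_sample_vs_zero(
            attraction[f"{name}_corrected"].to_numpy(), metric=name)

    wall_excess = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "wall_occupancy_excess": [wall_occupancy_excess(t) for t in trials],
        }
    )

    return {
        "trials": trials,
        "kins": kins,
        "cohort_mean_speed_cm_s": cohort_speed,
        "real_summaries": real_summaries,
        "mock_summaries": mock_summaries,
        "metric_tests": metric_tests,
        "joint_distribution": (joint, d_edges, a_edges),
        "maps": maps,
        "attraction": attraction,
        "attraction_tests": attraction_tests,
        "wall_excess": wall_excess,
    }


def _stat_result_row(metric: str, res) -> dict:
    return {
        "metric": metric,
        "test": res.test,
        "statistic": res.statistic,
        "p": res.p,
        "n_real": res.n_real,
        "n_mock": res.n_mock,
        "direction": res.direction,
        "summary_real": res.summary_real,
        "summary_mock": res.summary_mock,
        "real_normal": res.routing.real_normal,
        "mock_normal": res.routing.mock_normal,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every cohort; returns (and writes) the manifest."""
    from . import __version__

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "package": _pkg_name,
                "version": __version__, "cohorts": {}, "files": []}

    def _write(df: pd.DataFrame, rel: str) -> None:
        path = out_dir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)
        manifest["files"].append(rel)

    for k, entry in enumerate(config.cohorts):
        t0 = time.perf_counter()
        cohort_seed = int(
            np.random.SeedSequence(entropy=config.seed,
                                   spawn_key=(k,)).generate_state(1)[0]
            % (2**31)
        )
        logger.info("cohort %s: stage simulate/ingest", entry.name)
        trials = _load_cohort_trials(entry, cohort_seed)
        res = analyze_cohort(trials, grid=config.grid,
                             mock_group_size=config.mock_group_size,
                             seed=cohort_seed, unit=config.unit)

        base = f"{entry.name}"
        _write(res["real_summaries"], f"{base}/real_metric_summaries.csv")
        _write(res["mock_summaries"], f"{base}/mock_metric_summaries.csv")
        _write(
            pd.DataFrame([_stat_result_row(m, r)
                          for m, r in res["metric_tests"].items()]),
            f"{base}/real_vs_mock_tests.csv",
        )
        for kind, variants in res["maps"].items():
            for prov, fmap in variants.items():
                _write(map_to_dataframe(fmap), f"{base}/map_{kind}_{prov}.csv")
        _write(res["attraction"], f"{base}/attraction_per_trial.csv")
        _write(
            pd.DataFrame([_stat_result_row(m, r)
                          for m, r in res["attraction_tests"].items()]),
            f"{base}/attraction_tests.csv",
        )
        _write(res["wall_excess"], f"{base}/wall_occupancy.csv")

        if config.stability_iterations >= 2:
            stab = iteration_stability(trials, k=config.stability_iterations,
                                       seed=cohort_seed,
                                       r=config.mock_group_size,
                                       unit=config.unit)
            _write(stab, f"{base}/mock_iteration_stability.csv")

        manifest["cohorts"][entry.name] = {
            "seed": cohort_seed,
            "n_trials": len(trials),
            "n_frames": int(trials[0].n_frames),
            "cohort_mean_speed_cm_s": res["cohort_mean_speed_cm_s"],
            "elapsed_s": round(time.perf_counter() - t0, 2),
        }

        if config.figures:
            fig_files = render_figures(res, out_dir / base, entry.name)
            manifest["files"].extend(f"{base}/{f}" for f in fig_files)

        logger.info("cohort %s done in %.1fs", entry.name,
                    time.perf_counter() - t0)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# figures


def _polar_heatmap(ax, fmap: FocalMap, symmetric: bool):
    import matplotlib.pyplot as plt  # noqa: F401

    grid = fmap.grid
    # matplotlib polar: theta measured ccw from +x; our bearing is cw from +y
    bearing_edges = np.linspace(0, 2 * np.pi, grid.n_sectors + 1)
    theta = np.pi / 2.0 - bearing_edges
    r_edges = np.asarray(grid.radial_edges)
    vals = fmap.values
    scale = np.nanmax(np.abs(vals))
    shown = vals / scale if scale and np.isfinite(scale) and scale > 0 else vals
    cmap = "coolwarm" if symmetric else "viridis"
    vmin, vmax = (-1, 1) if symmetric else (0, None)
    mesh = ax.pcolormesh(theta, r_edges, shown, cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_yticks(r_edges[1:])
    ax.set_yticklabels([f"{r:g}" for r in r_edges[1:]], fontsize=6)
    return mesh


def render_figures(cohort_result: dict, out_dir, cohort_name: str) -> list[str]:
    """Joint distribution heatmap, polar maps and violin plots for one cohort."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []

    # joint pair distance/angle distribution
    joint, d_edges, a_edges = cohort_result["joint_distribution"]
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    mesh = ax.pcolormesh(a_edges, d_edges, joint, cmap="magma")
    ax.set_xlabel("pair angle (deg)")
    ax.set_ylabel("pair distance (BL)")
    ax.set_title(f"{cohort_name}: joint pair distance/angle")
    fig.colorbar(mesh, ax=ax, label="probability")
    fig.tight_layout()
    name = "fig_joint_distribution.png"
    fig.savefig(out_dir / name, dpi=150)
    plt.close(fig)
    files.append(name)

    # polar heatmaps: real / mock / difference for each kind
    for kind, variants in cohort_result["maps"].items():
        fig, axes = plt.subplots(1, 3, figsize=(10, 3.4),
                                 subplot_kw={"projection": "polar"})
        symmetric = kind != "density"
        for ax, prov in zip(axes, ("real", "mock", "difference")):
            mesh = _polar_heatmap(ax, variants[prov],
                                  symmetric or prov == "difference")
            ax.set_title(f"{kind} ({prov})", fontsize=9)
        fig.tight_layout()
        name = f"fig_map_{kind}.png"
        fig.savefig(out_dir / name, dpi=150)
        plt.close(fig)
        files.append(name)

    # violins: real vs mock medians per metric (one point per trial/group)
    real = cohort_result["real_summaries"]
    mock = cohort_result["mock_summaries"]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    for ax, metric in zip(axes, METRICS):
        df = pd.concat(
            [
                pd.DataFrame({"value": real[f"{metric}_median"], "group": "real"}),
                pd.DataFrame({"value": mock[f"{metric}_median"], "group": "mock"}),
            ],
            ignore_index=True,
        )
        sns.violinplot(data=df, x="group", y="value", hue="group", ax=ax,
                       inner=None, cut=0, legend=False,
                       palette={"real": "#e78ac3", "mock": "#b3b3b3"})
        sns.stripplot(data=df, x="group", y="value", ax=ax, color="k", size=2)
        for grp, xpos in (("real", 0), ("mock", 1)):
            vals = df.loc[df["group"] == grp, "value"]
            ax.hlines(vals.mean(), xpos - 0.3, xpos + 0.3, color="k", lw=1.2)
            ax.hlines(vals.median(), xpos - 0.3, xpos + 0.3, color="k",
                      lw=1.0, linestyles="dotted")
        ax.set_title(metric)
        ax.set_xlabel("")
    fig.suptitle(f"{cohort_name}: real vs mock (solid = mean, dotted = median)",
                 fontsize=9)
    fig.tight_layout()
    name = "fig_violins.png"
    fig.savefig(out_dir / name, dpi=150)
    plt.close(fig)
    files.append(name)

    # corrected attraction statistics per trial
    attraction = cohort_result["attraction"]
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.0))
    for ax, name_ in zip(axes, STAT_NAMES):
        vals = attraction[f"{name_}_corrected"]
        sns.violinplot(y=vals, ax=ax, inner=None, cut=0, color="#8da0cb")
        sns.stripplot(y=vals, ax=ax, color="k", size=3)
        ax.axhline(0, color="r", lw=0.8)
        res = cohort_result["attraction_tests"][name_]
        ax.set_title(f"{name_} (p={res.p:.3g})", fontsize=9)
    fig.suptitle(f"{cohort_name}: mock-corrected attraction statistics",
                 fontsize=9)
    fig.tight_layout()
    name = "fig_attraction.png"
    fig.savefig(out_dir / name, dpi=150)
    plt.close(fig)
    files.append(name)

    return files
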