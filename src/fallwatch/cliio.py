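"""File formats, configuration, per-stage seeding and pipeline orchestration.

Stages are coupled through files only: simulate -> extract -> label ->
evaluate -> stats -> report. Every stage is individually runnable, and the
end-to-end run equals the composition of stage runs given identical seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinlabel import LabelingConfig, label_cohort
from .extract import PARAMETER_NAMES, extract_parameters
from .groupstats import StatConfig, compare_all
from .mlbench import (ClassifierSpec, evaluate_all, fit_full, decision_grid,
                      grid_bounds, rank_results)
from .synthcohort import (CameraModel, CohortConfig, GroundTruth,
                          LabeledTrajectory, SubjectProfile, make_cohort,
                          simulate_day)

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.9g"   # fixed precision makes byte-identical reruns possible

# stage indices for deterministic per-stage seed derivation
_STAGES = ("simulate", "extract", "label", "evaluate", "stats")


class FormatError(ValueError):
    """Malformed input file (message carries the offending line/row)."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Expand the single run seed into a documented per-stage seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0])


def subject_seed(stage_seed_value: int, subject_index: int) -> int:
    ss = np.random.SeedSequence([int(stage_seed_value), int(subject_index)])
    return int(ss.generate_state(1)[0])


# ---------------------------------------------------------------------------
# round-trip formats
# ---------------------------------------------------------------------------

TRAJECTORY_COLUMNS = ["time_s", "x_m", "y_m", "z_m", "activity"]


def write_trajectory_csv(traj: LabeledTrajectory, path) -> None:
    df = traj.to_dataframe()
    # empty coordinate fields exactly when out of room
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trajectory_csv(path) -> LabeledTrajectory:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise FormatError(f"{path}: empty file without header") from e
    if list(df.columns) != TRAJECTORY_COLUMNS:
        raise FormatError(f"{path}: header must be {','.join(TRAJECTORY_COLUMNS)}")
    try:
        return LabeledTrajectory.from_dataframe(df)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=True, float_format=FLOAT_FORMAT)


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    missing = [c for c in PARAMETER_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing parameter columns {missing}")
    return df[PARAMETER_NAMES].astype(float)


def write_labels_csv(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index=True)


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing 'label' column")
    bad = set(df["label"]) - {"low", "high", "missing"}
    if bad:
        raise FormatError(f"{path}: unknown label values {sorted(bad)}")
    return df


def write_cohort_json(profiles, path) -> None:
    payload = [dataclasses.asdict(p) for p in profiles]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_cohort_json(path) -> list:
    payload = json.loads(Path(path).read_text())
    return [SubjectProfile(**{**d, "tug_trials": tuple(d["tug_trials"])})
            for d in payload]


def write_truth_json(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_jsonable(), sort_keys=True))


def read_truth_json(path) -> GroundTruth:
    return GroundTruth.from_jsonable(json.loads(Path(path).read_text()))


def write_results_json(results, path) -> None:
    payload = [{
        "features": list(r.feature_names),
        "algorithm": r.algorithm,
        "per_fold_correct": [bool(c) for c in r.per_fold_correct],
        "mean_accuracy": r.mean_accuracy,
        "dropped_subjects": list(r.dropped_subjects),
    } for r in results]
    Path(path).write_text(json.dumps(payload, indent=0, sort_keys=True))


def read_results_json(path) -> list:
    return json.loads(Path(path).read_text())


def write_depth_dir(depth, out_dir) -> None:
    """Depth frames as 16-bit grayscale PNGs (mm) + camera JSON + background."""
    import imageio.v3 as iio
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "background.png",
                np.round(depth.background).astype(np.uint16))
    for k, frame in enumerate(depth.frames):
        iio.imwrite(out / f"frame_{k:06d}.png", np.round(frame).astype(np.uint16))
    cam = dataclasses.asdict(depth.camera)
    (out / "camera.json").write_text(json.dumps(
        {"camera": cam, "timestamps": depth.timestamps.tolist()}, sort_keys=True))


def read_depth_dir(in_dir):
    import imageio.v3 as iio
    from .synthcohort import DepthSequence
    src = Path(in_dir)
    meta = json.loads((src / "camera.json").read_text())
    cam = CameraModel(**{**meta["camera"],
                         "position": tuple(meta["camera"]["position"])})
    bg = iio.imread(src / "background.png").astype(float)
    frame_paths = sorted(src.glob("frame_*.png"))
    frames = np.stack([iio.imread(p).astype(float) for p in frame_paths]) \
        if frame_paths else np.empty((0,) + bg.shape)
    return DepthSequence(frames=frames,
                         timestamps=np.asarray(meta["timestamps"], float),
                         camera=cam, background=bg)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> CohortConfig:
    """YAML -> CohortConfig; unknown keys are a validation error by name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = CohortConfig(**raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(config: CohortConfig, seed: int, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sseed = stage_seed(seed, "simulate")
    profiles = make_cohort(config, sseed)
    write_cohort_json(profiles, out / "cohort.json")
    for i, p in enumerate(profiles):
        traj, truth = simulate_day(p, config, subject_seed(sseed, i))
        write_trajectory_csv(traj, out / f"{p.subject_id}_trajectory.csv")
        write_truth_json(truth, out / f"{p.subject_id}_truth.json")


def run_extract(in_dir, out_path) -> pd.DataFrame:
    src = Path(in_dir)
    rows = {}
    for traj_path in sorted(src.glob("*_trajectory.csv")):
        subject_id = traj_path.name.replace("_trajectory.csv", "")
        traj = read_trajectory_csv(traj_path)
        rows[subject_id] = extract_parameters(traj).as_dict()
    features = pd.DataFrame.from_dict(rows, orient="index")[PARAMETER_NAMES]
    features.index.name = "subject_id"
    write_features_csv(features, out_path)
    return features


def run_label(cohort_path, out_path,
              config: LabelingConfig = LabelingConfig()) -> pd.DataFrame:
    labels = label_cohort(read_cohort_json(cohort_path), config)
    write_labels_csv(labels, out_path)
    return labels


def run_evaluate(features_path, labels_path, out_dir, seed: int,
                 max_combo: int = 2, algorithms=None) -> pd.DataFrame:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features = read_features_csv(features_path)
    labels = read_labels_csv(labels_path)["label"]
    eseed = stage_seed(seed, "evaluate")
    from .mlbench import ALGORITHMS
    results = evaluate_all(features, labels, seed=eseed, max_size=max_combo,
                           algorithms=algorithms or ALGORITHMS)
    write_results_json(results, out / "results.json")
    board = rank_results(results)
    board.to_csv(out / "leaderboard.csv", index=False,
                 float_format=FLOAT_FORMAT)
    # decision grid for the top two-parameter combination
    top2 = board[board.n_features == 2]
    if not top2.empty:
        combo = tuple(top2.iloc[0]["features"].split(", "))
        algo = top2.iloc[0]["algorithms"].split(", ")[0]
        sub = features[list(combo)].dropna()
        predict = fit_full(sub, labels, ClassifierSpec(algo, eseed))
        grid = decision_grid(predict, combo, grid_bounds(sub), resolution=80)
        pd.DataFrame(grid.classes, index=np.round(grid.ys, 6),
                     columns=np.round(grid.xs, 6)).to_csv(out / "decision_grid.csv")
    return board


def run_stats(features_path, labels_path, out_dir, seed: int) -> pd.DataFrame:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features = read_features_csv(features_path)
    labels = read_labels_csv(labels_path)["label"]
    cfg = StatConfig(seed=stage_seed(seed, "stats"))
    table = compare_all(features, labels, cfg)
    table.to_csv(out / "stats.csv", index=False, float_format=FLOAT_FORMAT)
    _plot_relative_differences(table, out / "relative_differences.png")
    return table


def _plot_relative_differences(table: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(7, 5))
    ypos = np.arange(len(table))
    err = np.array([table.relative_difference_pct - table.ci_low_pct,
                    table.ci_high_pct - table.relative_difference_pct])
    ax.errorbar(table.relative_difference_pct, ypos, xerr=err, fmt="o",
                capsize=3)
    names = [p + (" *" if s else "")
             for p, s in zip(table.parameter, table.significant)]
    ax.set_yticks(ypos, names, fontsize=8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("relative difference high vs. low group (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(board: pd.DataFrame, stats_table: pd.DataFrame, path) -> None:
    lines = ["# Fall-risk benchmark report", "",
             "## Best parameter combinations (LOSO mean accuracy)", ""]
    lines.append(board.head(10).to_markdown(index=False))
    lines += ["", "## Group comparison (Holm-adjusted)", ""]
    lines.append(stats_table.to_markdown(index=False))
    Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(config: CohortConfig, seed: int, out_dir,
                 max_combo: int = 2, algorithms=None) -> dict:
    """Run all stages in order; returns the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": int(seed),
        "stage_seeds": {s: stage_seed(seed, s) for s in _STAGES},
        "config": dataclasses.asdict(config),
        "out_dir": str(out),
        "timings_s": {},
    }
    stages = [
        ("simulate", lambda: run_simulate(config, seed, out)),
        ("extract", lambda: run_extract(out, out / "features.csv")),
        ("label", lambda: run_label(out / "cohort.json", out / "labels.csv")),
        ("evaluate", lambda: run_evaluate(out / "features.csv",
                                          out / "labels.csv", out, seed,
                                          max_combo, algorithms)),
        ("stats", lambda: run_stats(out / "features.csv", out / "labels.csv",
                                    out, seed)),
    ]
    products = {}
    for name, fn in stages:
        t0 = _time.perf_counter()
        try:
            products[name] = fn()
        except Exception as e:
            manifest["failed_stage"] = name
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"stage {name!r} failed: {e}") from e
        manifest["timings_s"][name] = round(_time.perf_counter() - t0, 3)
    write_report(products["evaluate"], products["stats"], out / "report.md")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
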