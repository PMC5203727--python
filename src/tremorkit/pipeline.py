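"""End-to-end orchestration: simulate -> preprocess -> features ->
project -> stats -> classify -> report.

A :class:`RunConfig` collects every tunable of the pipeline with the
study's stated constants as defaults (50 Hz sampling, order-4 band-pass
0.5-25 Hz, degree-20 detrend, 10,000 permutations, 10-fold CV, 1000
subject-wise splits). The full run is deterministic given its seeds;
the serialized config and a hash accompany every output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import classify as clf
from . import features as feat
from . import sammon as sm
from . import stats as st
from .preprocessing import preprocess_recording, segment
from .synthetic import (
    DEFAULT_COHORT_SIZES,
    GroupLabel,
    Recording,
    ScheduleConfig,
    TaskLabel,
    default_group_params,
    generate_cohort,
    read_recording,
)

logger = logging.getLogger("tremorkit")

ALL_TASKS = ("T1", "T2", "T3", "T4")
ALL_COMBOS = tuple(feat.combo_name(c) for c in feat.METHOD_COMBOS)


@dataclass
class RunConfig:
    """Every tunable of the pipeline, defaulting to the study constants."""

    # seeds
    master_seed: int = 0
    sammon_seed: int = 1
    permanova_seed: int = 2
    splits_seed: int = 3
    # acquisition / simulation
    sample_rate_hz: float = 50.0
    n_per_group: dict = field(
        default_factory=lambda: {g.value: n for g, n in DEFAULT_COHORT_SIZES.items()}
    )
    effect_size: float = 1.0
    rest_gap_s: float = 30.0
    n_trials: int = 5
    # preprocessing
    filter_order: int = 4
    band_hz: tuple = (0.5, 25.0)
    detrend_order: int = 20
    # features
    apen_m: int = 2
    apen_r_factor: float = 0.2
    normalization: str = "zscore"
    pool_trials: bool = False
    # projection
    sammon_max_iter: int = 500
    sammon_tol: float = 1e-9
    sammon_step_factor: float = 0.35
    # statistics
    n_permutations: int = 10_000
    # classification
    n_splits: int = 1000
    per_group_split: int = 5
    n_folds: int = 10
    edda_constraint: str = "auto"
    # scope
    tasks: tuple = ALL_TASKS
    combos: tuple = ALL_COMBOS

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return replace(
            cfg,
            band_hz=tuple(cfg.band_hz),
            tasks=tuple(cfg.tasks),
            combos=tuple(cfg.combos),
        )


def _parse_combo(name: str) -> tuple[str, ...]:
    combo = tuple(name.split("-"))
    if combo not in feat.METHOD_COMBOS:
        raise ValueError(f"unknown method combination {name!r}")
    return combo


def load_cohort(input_dir) -> list[Recording]:
    """Read every recording text file in a directory."""
    paths = sorted(Path(input_dir).glob("*.txt"))
    if not paths:
        raise ValueError(f"no recording files (*.txt) in {input_dir}")
    return [read_recording(p) for p in paths]


def cohort_feature_table(
    cohort: list[Recording], config: RunConfig
) -> pd.DataFrame:
    """Preprocess and extract features for every recording."""
    tasks = tuple(TaskLabel(t) for t in config.tasks)
    tables = []
    for rec in cohort:
        triplets = preprocess_recording(
            rec,
            band_hz=tuple(config.band_hz),
            filter_order=config.filter_order,
            detrend_order=config.detrend_order,
        )
        windows = segment(rec)
        tables.append(
            feat.extract_features(
                triplets,
                windows,
                normalization=config.normalization,
                apen_m=config.apen_m,
                apen_r_factor=config.apen_r_factor,
                tasks=tasks,
            )
        )
    table = pd.concat(tables, ignore_index=True)
    if config.pool_trials:
        meta_cols = ["subject_id", "group", "task"]
        table = (
            table.groupby(meta_cols, as_index=False, sort=True)
            .mean(numeric_only=True)
            .assign(trial=1)
        )
    return table


@dataclass
class CellResult:
    """All results of one task x method-combination cell."""

    task: str
    combo: str
    projection: sm.Projection2D
    meta: pd.DataFrame
    permanova: st.PermanovaResult
    split_results: list[clf.SplitResult]


def analyse_cell(
    table: pd.DataFrame,
    task: TaskLabel,
    combo: tuple[str, ...],
    config: RunConfig,
    splits: list[clf.Split],
) -> CellResult:
    fm = feat.build_matrix(table, task, combo)
    proj = sm.sammon_map(
        fm.X,
        max_iter=config.sammon_max_iter,
        tol=config.sammon_tol,
        step_factor=config.sammon_step_factor,
        seed=config.sammon_seed,
    )
    # subject-level permutation: a subject's windows are not
    # exchangeable under the group null, so they travel together
    perm = st.permanova_with_pairwise(
        proj.coords,
        fm.meta["group"],
        n_permutations=config.n_permutations,
        seed=config.permanova_seed,
        subject_ids=fm.meta["subject_id"],
    )
    split_results = clf.evaluate_splits(
        proj.coords,
        fm.meta,
        splits,
        constraint=config.edda_constraint,
        n_folds=config.n_folds,
        seed=config.splits_seed,
    )
    return CellResult(
        task=task.value,
        combo=feat.combo_name(combo),
        projection=proj,
        meta=fm.meta,
        permanova=perm,
        split_results=split_results,
    )


def success_tables(
    cells: list[CellResult], classes: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate split results into the two success-rate tables.

    One row per (method combination, task) with the nine mean
    actual(predicted) rates, MeanTP and StdTP, plus per-combination
    Mean and Std rows — the classification-set table from within-
    training CV, the test table from held-out subjects.
    """
    frames = {"train": [], "test": []}
    for which in ("train", "test"):
        for combo in dict.fromkeys(c.combo for c in cells):
            combo_rows = []
            for cell in [c for c in cells if c.combo == combo]:
                row = {"Method": combo, "Task": cell.task}
                row.update(
                    clf.success_table_row(cell.split_results, which, classes)
                )
                combo_rows.append(row)
            block = pd.DataFrame(combo_rows)
            numeric = block.drop(columns=["Method", "Task"])
            for stat, label in ((numeric.mean(), "Mean"), (numeric.std(ddof=1), "Std")):
                summary = {"Method": combo, "Task": label}
                summary.update(stat.to_dict())
                block = pd.concat(
                    [block, pd.DataFrame([summary])], ignore_index=True
                )
            frames[which].append(block)
    train = pd.concat(frames["train"], ignore_index=True)
    test = pd.concat(frames["test"], ignore_index=True)
    return train, test


def stats_table(cells: list[CellResult]) -> pd.DataFrame:
    rows = []
    for cell in cells:
        row = {
            "task": cell.task,
            "combo": cell.combo,
            "pseudo_F": cell.permanova.pseudo_F,
            "p_value": cell.permanova.p_value,
            "sammon_stress": cell.projection.stress,
        }
        for (ga, gb), raw, corrected in cell.permanova.pairwise:
            row[f"p_raw[{ga}|{gb}]"] = raw
            row[f"p_bonf[{ga}|{gb}]"] = corrected
        rows.append(row)
    return pd.DataFrame(rows)


def _scatter_plot(cell: CellResult, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    markers = {"S_DBS": "^", "S_H": "o", "S_PD": "*"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, marker in markers.items():
        mask = cell.meta["group"].to_numpy() == group
        if not mask.any():
            continue
        ax.scatter(
            cell.projection.coords[mask, 0],
            cell.projection.coords[mask, 1],
            marker=marker,
            label=group,
            alpha=0.8,
        )
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.set_title(f"{cell.task} / {cell.combo} (stress {cell.projection.stress:.3g})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def run_pipeline(
    config: RunConfig,
    out_dir,
    cohort: list[Recording] | None = None,
    input_dir=None,
    make_plots: bool = True,
) -> Path:
    """Execute the full analysis and write all outputs.

    ``cohort`` or ``input_dir`` may supply recordings; otherwise a
    cohort is simulated from the config. Outputs: per-cell projection
    TSVs (and scatter plots), the statistics table, the two success
    tables and a run manifest with the config and its hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    if cohort is None:
        if input_dir is not None:
            cohort = load_cohort(input_dir)
        else:
            logger.info("simulating cohort (effect size %.3g)", config.effect_size)
            cohort = generate_cohort(
                n_per_group={
                    GroupLabel(g): n for g, n in config.n_per_group.items()
                },
                group_params=default_group_params(config.effect_size),
                master_seed=config.master_seed,
                schedule=ScheduleConfig(
                    rest_gap_s=config.rest_gap_s, n_trials=config.n_trials
                ),
            )

    logger.info("extracting features from %d recordings", len(cohort))
    try:
        table = cohort_feature_table(cohort, config)
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc

    subjects_by_group: dict[str, list[str]] = {}
    for rec in cohort:
        subjects_by_group.setdefault(rec.subject.group.value, []).append(
            rec.subject.subject_id
        )
    if len(subjects_by_group) < 2:
        raise ValueError(
            "classification requires at least 2 groups; cohort has "
            f"{len(subjects_by_group)}"
        )
    splits = clf.make_splits(
        subjects_by_group,
        n_splits=config.n_splits,
        per_group=config.per_group_split,
        seed=config.splits_seed,
    )

    cells: list[CellResult] = []
    for task_name in config.tasks:
        for combo_str in config.combos:
            task = TaskLabel(task_name)
            combo = _parse_combo(combo_str)
            logger.info("analysing cell task=%s combo=%s", task_name, combo_str)
            try:
                cell = analyse_cell(table, task, combo, config, splits)
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'analysis' failed for task {task_name}, "
                    f"combo {combo_str}: {exc}"
                ) from exc
            cells.append(cell)
            proj_df = pd.concat(
                [
                    cell.meta.reset_index(drop=True),
                    pd.DataFrame(cell.projection.coords, columns=["dim1", "dim2"]),
                ],
                axis=1,
            )
            proj_df.to_csv(
                out / f"projection_{task_name}_{combo_str}_{chash}.tsv",
                sep="\t",
                index=False,
            )
            if make_plots:
                _scatter_plot(cell, out / f"scatter_{task_name}_{combo_str}_{chash}.svg")

    classes = clf.canonical_classes(subjects_by_group)
    stats_df = stats_table(cells)
    stats_df.to_csv(out / f"stats_{chash}.tsv", sep="\t", index=False)
    train_tab, test_tab = success_tables(cells, classes)
    train_tab.to_csv(out / f"table_classification_{chash}.tsv", sep="\t", index=False)
    test_tab.to_csv(out / f"table_test_{chash}.tsv", sep="\t", index=False)

    config.to_yaml(out / f"config_{chash}.yaml")
    manifest = {
        "config_hash": chash,
        "n_recordings": len(cohort),
        "n_cells": len(cells),
        "classes": classes,
        "config": asdict(config),
    }
    with open(out / f"manifest_{chash}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
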