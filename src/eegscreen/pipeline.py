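"""End-to-end orchestration: simulate -> features -> select -> train -> report.

All randomness flows from one root seed through named substreams; selection,
standardization and hyperparameter tuning see training rows only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    MLPConfig,
    StandardizationStats,
    predict_trials,
    train_lda,
    train_mlp,
    train_qda,
    tune_mlp,
)
from .core import ConfigurationError, EpochedRecording, FEATURE_NAMES, GROUPS
from .evaluate import confusion_matrix3, model_report, subject_votes
from .features import feature_table
from .nonlinear import NonlinearParams, select_nonlinear_params
from .selection import fcbf
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("eegscreen")

_TRAINERS = {"LDA": train_lda, "QDA": train_qda}


@dataclass
class MLPSettings:
    tune: bool = True
    grid_u: list[float] = field(default_factory=lambda: list(range(0, 101, 5)))
    grid_nh: list[int] = field(default_factory=lambda: list(range(1, 21)))
    n_restarts: int = 30
    cv: str = "loso"
    n_folds: int = 3
    max_iterations: int = 300
    n_hidden: int = 11        # used when tune=False
    weight_decay: float = 45.0


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_train_per_group: int = 20
    models: tuple[str, ...] = ("LDA", "QDA", "MLP")
    params: NonlinearParams = field(default_factory=NonlinearParams)
    select_params: bool = False       # run the Kruskal-Wallis grid search
    param_grids: dict | None = None
    mlp: MLPSettings = field(default_factory=MLPSettings)
    psd_method: str = "welch"
    seed: int = 0
    out_dir: str | None = None


def split_subjects(cohort: list[EpochedRecording], n_train_per_group: int,
                   seed: int) -> tuple[list[str], list[str]]:
    """Seeded, group-stratified subject-level split into train and test IDs."""
    train, test = [], []
    rng = np.random.default_rng(seed)
    for group in GROUPS:
        ids = sorted(r.subject_id for r in cohort if r.group == group)
        if not 0 < n_train_per_group < len(ids):
            raise ConfigurationError(
                f"cannot take {n_train_per_group} training subjects from "
                f"{len(ids)} in group {group}")
        picked = rng.choice(len(ids), size=n_train_per_group, replace=False)
        chosen = {ids[i] for i in picked}
        train += sorted(chosen)
        test += sorted(set(ids) - chosen)
    return train, test


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig,
                 cohort: list[EpochedRecording] | None = None) -> dict:
    """Execute every stage and return the report dict.

    A pre-built cohort can be passed to skip generation (e.g. real data read
    from disk); otherwise one is generated from config.cohort with a seed
    derived from config.seed.
    """
    root = np.random.SeedSequence(config.seed)
    seed_cohort, seed_split, seed_mlp = (int(s.generate_state(1)[0])
                                         for s in root.spawn(3))

    if cohort is None:
        log.info("generating synthetic cohort")
        cohort = generate_cohort(replace(config.cohort, rng_seed=seed_cohort))

    train_ids, test_ids = split_subjects(cohort, config.n_train_per_group,
                                         seed_split)
    assert not set(train_ids) & set(test_ids)
    by_id = {r.subject_id: r for r in cohort}
    train_recs = [by_id[s] for s in train_ids]
    test_recs = [by_id[s] for s in test_ids]

    params = config.params
    if config.select_params:
        log.info("selecting nonlinear parameters on the training set")
        params = select_nonlinear_params(train_recs, config.param_grids,
                                         base=params)

    log.info("extracting features (%d train / %d test subjects)",
             len(train_ids), len(test_ids))
    train_table = feature_table(train_recs, params, config.psd_method)
    test_table = feature_table(test_recs, params, config.psd_method)

    selection = fcbf(train_table, list(FEATURE_NAMES))
    selected = selection.selected
    log.info("FCBF selected: %s", selected)

    mlp_settings = config.mlp

    report: dict = {
        "selection": selection.to_dict(),
        "nonlinear_params": asdict(params),
        "split": {"train": train_ids, "test": test_ids},
        "models": {},
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "substream_seeds": {"cohort": seed_cohort, "split": seed_split,
                                "mlp": seed_mlp},
            "config_hash": _config_hash(config),
        },
    }

    report["_feature_tables"] = [train_table, test_table]

    stats = StandardizationStats.fit(train_table, selected)
    train_std = stats.apply(train_table)
    test_std = stats.apply(test_table)
    y_train = train_table["group"].to_numpy()
    y_test = test_table["group"].to_numpy()

    for kind in config.models:
        if kind in _TRAINERS:
            model = _TRAINERS[kind](train_std, y_train,
                                    feature_names=selected, stats=stats)
            mlp_config = None
        elif kind == "MLP":
            if mlp_settings.tune:
                mlp_config = tune_mlp(
                    train_std, selected, grid_u=mlp_settings.grid_u,
                    grid_nh=mlp_settings.grid_nh,
                    n_restarts=mlp_settings.n_restarts, cv=mlp_settings.cv,
                    n_folds=mlp_settings.n_folds, rng_seed=seed_mlp,
                    max_iterations=mlp_settings.max_iterations)
            else:
                mlp_config = MLPConfig(
                    n_hidden=mlp_settings.n_hidden,
                    weight_decay=mlp_settings.weight_decay,
                    n_restarts=mlp_settings.n_restarts, rng_seed=seed_mlp,
                    max_iterations=mlp_settings.max_iterations)
            model = train_mlp(train_std, y_train, mlp_config,
                              feature_names=selected, stats=stats)
        else:
            raise ConfigurationError(f"unknown model kind {kind!r}")

        pred, post = predict_trials(model, test_std)
        trials = pd.DataFrame({
            "subject_id": test_table["subject_id"], "group": y_test,
            "predicted": pred})
        trials = pd.concat([trials, post.set_index(trials.index)], axis=1)
        subjects = subject_votes(trials, posterior_cols=tuple(model.classes))

        cm_trial = confusion_matrix3(y_test, pred, level="trial")
        cm_subject = confusion_matrix3(subjects["group"],
                                       subjects["predicted"], level="subject")
        entry = model_report(cm_trial, cm_subject)
        if mlp_config is not None:
            entry["mlp_config"] = asdict(mlp_config)
        report["models"][kind] = entry
        report.setdefault("_artifacts", {})[kind] = {
            "model": model, "trials": trials, "subjects": subjects}

    if config.out_dir:
        _write_artifacts(report, train_table, test_table, config.out_dir)
    return report


def _write_artifacts(report: dict, train_table: pd.DataFrame,
                     test_table: pd.DataFrame, out_dir: str) -> None:
    from .io import write_feature_table, write_json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_feature_table(train_table, out / "features_train.csv")
    write_feature_table(test_table, out / "features_test.csv")
    for kind, art in report.get("_artifacts", {}).items():
        art["trials"].to_csv(out / f"trials_{kind.lower()}.csv", index=False)
        art["subjects"].to_csv(out / f"subjects_{kind.lower()}.csv",
                               index=False)
        write_json(art["model"].to_dict(), out / f"model_{kind.lower()}.json")
    write_json({k: v for k, v in report.items() if not k.startswith("_")},
               out / "report.json")
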