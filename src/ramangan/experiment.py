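"""Config-driven experiment grid runner.

Executes every (augmentation strategy x classifier family) cell of a grid
with leave-one-out evaluation, derives a stable per-cell seed from the master
seed plus the cell descriptor, and emits a tidy results table (one row per
cell x subgroup x metric). Completed cells are checkpointed as JSON keyed by
a config hash, so an interrupted run resumes without recomputation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .augment import AugmentationSpec
from .classifiers import ClassifierSpec
from .dataset import SpectraDataset, read_spectra_csv
from .evaluate import METRIC_NAMES, SUBGROUPS, loo_evaluate
from .gan import GanConfig
from .smote import SmoteParams

logger = logging.getLogger("ramangan")

__all__ = ["ExperimentConfig", "run_experiment", "load_experiment_config"]

#: default grids
N_PRIME_GRID = (128, 256, 512, 1024)
M_GRID = (1, 2, 4, 6, 8)


@dataclass
class ExperimentConfig:
    data: SpectraDataset
    augmentations: tuple[AugmentationSpec, ...]
    classifiers: tuple[ClassifierSpec, ...]
    master_seed: int = 0
    out_dir: Path | None = None
    global_augment: bool = False

    def validate(self) -> None:
        problems = []
        if not self.augmentations:
            problems.append("augmentation grid is empty")
        if not self.classifiers:
            problems.append("classifier grid is empty")
        if self.data.n == 0:
            problems.append("dataset is empty")
        if problems:
            raise ValueError("invalid experiment config: " + "; ".join(problems))


def _cell_descriptor(aug: AugmentationSpec, clf: ClassifierSpec) -> str:
    return json.dumps(
        {
            "strategy": aug.strategy,
            "generator": aug.generator,
            "n_prime": aug.n_prime,
            "m": aug.m,
            "classifier": clf.kind,
            "pooling": clf.pooling,
            "filters": clf.filters,
            "kernel": clf.kernel,
            "epochs": clf.epochs,
        },
        sort_keys=True,
    )


def _cell_seed(master_seed: int, descriptor: str) -> int:
    digest = hashlib.sha256(descriptor.encode()).digest()
    return (master_seed + int.from_bytes(digest[:4], "big")) % (2**31)


def _cell_name(aug: AugmentationSpec, clf: ClassifierSpec) -> str:
    if aug.strategy == "none":
        tag = "none"
    elif aug.strategy == "balanced":
        tag = f"{aug.generator}_balanced_np{aug.n_prime}"
    else:
        tag = f"{aug.generator}_stratified_m{aug.m}"
    return f"{clf.kind}__{tag}"


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run every grid cell; returns the tidy results table.

    Columns: cell, classifier, strategy, generator, n_prime, m, subgroup,
    metric, value, seed, config_hash. Failed cells are logged and skipped so
    the rest of the grid still completes.
    """
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        (out_dir / "cells").mkdir(parents=True, exist_ok=True)

    rows = []
    for aug in config.augmentations:
        for clf in config.classifiers:
            descriptor = _cell_descriptor(aug, clf)
            seed = _cell_seed(config.master_seed, descriptor)
            chash = hashlib.sha256(descriptor.encode()).hexdigest()[:16]
            name = _cell_name(aug, clf)
            cell_path = out_dir / "cells" / f"{name}.json" if out_dir else None

            result = None
            if cell_path and cell_path.exists():
                cached = json.loads(cell_path.read_text())
                if cached.get("config_hash") == chash:
                    logger.info("cell %s: cached, skipping", name)
                    result = cached
            if result is None:
                logger.info("cell %s: evaluating (seed=%d)", name, seed)
                try:
                    report = loo_evaluate(
                        config.data, aug, clf, seed=seed,
                        global_augment=config.global_augment,
                    )
                except Exception:
                    logger.exception("cell %s failed; continuing", name)
                    continue
                result = {
                    "config_hash": chash,
                    "seed": seed,
                    "metrics": report.metrics,
                    "confusion": report.confusion.tolist(),
                }
                if cell_path:
                    cell_path.write_text(json.dumps(result, indent=1))
            for subgroup in SUBGROUPS:
                for metric in METRIC_NAMES:
                    rows.append(
                        {
                            "cell": name,
                            "classifier": clf.kind,
                            "strategy": aug.strategy,
                            "generator": aug.generator,
                            "n_prime": aug.n_prime,
                            "m": aug.m,
                            "subgroup": subgroup,
                            "metric": metric,
                            "value": result["metrics"][subgroup][metric],
                            "seed": result["seed"],
                            "config_hash": result["config_hash"],
                        }
                    )
    table = pd.DataFrame(rows)
    if out_dir:
        table.to_csv(out_dir / "results.csv", index=False)
    return table


def load_experiment_config(path, data: SpectraDataset | None = None) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML/JSON mapping.

    Recognized keys: ``data`` (CSV path, unless a dataset is passed in),
    ``augmentations`` (list of {strategy, generator, n_prime, m, gan: {...},
    smote: {...}}), ``classifiers`` (list of {kind, ...overrides}),
    ``master_seed``, ``out_dir``, ``global_augment``.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if data is None:
        data = read_spectra_csv(raw["data"])
    augs = []
    for entry in raw.get("augmentations", [{"strategy": "none"}]):
        gan_cfg = GanConfig(**entry.pop("gan", {})) if "gan" in entry else None
        smote = SmoteParams(**entry.pop("smote", {})) if "smote" in entry else None
        augs.append(AugmentationSpec(gan_config=gan_cfg, smote_params=smote, **entry))
    clfs = [ClassifierSpec(**entry) for entry in raw.get("classifiers", [{"kind": "CNN"}])]
    return ExperimentConfig(
        data=data,
        augmentations=tuple(augs),
        classifiers=tuple(clfs),
        master_seed=int(raw.get("master_seed", 0)),
        out_dir=Path(raw["out_dir"]) if raw.get("out_dir") else None,
        global_augment=bool(raw.get("global_augment", False)),
    )
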