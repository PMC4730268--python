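"""End-to-end orchestration: featurize, cross-validate, sweep.

The pipeline ties the stages together: FASTA + pair list -> length filter
-> per-protein PR matrix -> compression -> LPQ descriptor (cached per
protein) -> 512-dim pair features -> Rotation Forest cross-validation or
training.  Everything is driven by a :class:`RunConfig` that can be built
programmatically, from CLI flags, or from a YAML file, and every run
writes a config echo and a structured log next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import MetricsReport, cross_validate
from .io_datasets import (
    PairDataset,
    ProteinRecord,
    filter_by_length,
    read_fasta,
    read_pairs,
)
from .lpq import LPQConfig, lpq_descriptor, pair_feature
from .prm import build_prm, compress_prm
from .properties import PropertyTable, hydrophobicity_table, load_property_table
from .rotation_forest import RFConfig, RotationForestModel, train

__all__ = [
    "RunConfig",
    "DescriptorCache",
    "featurize_pairs",
    "protein_descriptors",
    "run_cv",
    "train_model",
    "sweep_parameters",
    "load_run_config",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """One run's worth of paths and stage options."""

    fasta: str | None = None
    pairs: str | None = None
    property_table: str | None = None
    out_dir: str = "lpqppi_out"
    # PR-matrix stage
    max_side: int = 250
    max_len: int = 5000
    min_len: int = 50
    ambiguous_policy: str = "mean"
    compression: str = "bilinear"
    # LPQ stage
    window_size: int = 3
    whitening: bool = False
    # classifier
    n_subsets: int = 8
    n_trees: int = 20
    bootstrap_fraction: float = 0.6
    max_depth: int | None = None
    min_samples_leaf: int = 1
    # evaluation
    cv_folds: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def lpq_config(self) -> LPQConfig:
        return LPQConfig(window_size=self.window_size, whitening=self.whitening)

    def rf_config(self) -> RFConfig:
        return RFConfig(
            n_subsets=self.n_subsets,
            n_trees=self.n_trees,
            bootstrap_fraction=self.bootstrap_fraction,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            seed=self.seed,
        )

    def table(self) -> PropertyTable:
        if self.property_table:
            return load_property_table(
                self.property_table, ambiguous_policy=self.ambiguous_policy
            )
        return hydrophobicity_table(ambiguous_policy=self.ambiguous_policy)

    def feature_config_key(self) -> str:
        payload = json.dumps(
            {
                "max_side": self.max_side,
                "max_len": self.max_len,
                "ambiguous_policy": self.ambiguous_policy,
                "compression": self.compression,
                "window_size": self.window_size,
                "whitening": self.whitening,
                "property_table": self.property_table or "hydrophobicity(default)",
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()


def load_run_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a flat YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of options")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ValueError(f"{path}: unknown options {unknown}")
    return RunConfig(**data)


class DescriptorCache:
    """Per-protein descriptor cache keyed by (id, sequence, feature config)."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, str, str], np.ndarray] = {}
        self.n_computed = 0
        self.n_hits = 0

    def descriptor(
        self, record: ProteinRecord, config: RunConfig, table: PropertyTable
    ) -> np.ndarray:
        seq_hash = hashlib.sha1(record.sequence.encode()).hexdigest()
        key = (record.id, seq_hash, config.feature_config_key())
        cached = self._store.get(key)
        if cached is not None:
            self.n_hits += 1
            return cached
        prm = build_prm(record.sequence, table, max_len=config.max_len)
        prm = compress_prm(prm, max_side=config.max_side, method=config.compression)
        desc = lpq_descriptor(prm.values, config.lpq_config())
        self._store[key] = desc
        self.n_computed += 1
        return desc


def protein_descriptors(
    records,
    config: RunConfig,
    table: PropertyTable | None = None,
    cache: DescriptorCache | None = None,
) -> pd.DataFrame:
    """256-column descriptor table, one row per protein id."""
    table = table or config.table()
    cache = cache or DescriptorCache()
    rows = {rec.id: cache.descriptor(rec, config, table) for rec in records}
    return pd.DataFrame.from_dict(rows, orient="index")


def featurize_pairs(
    records,
    pairs: PairDataset,
    config: RunConfig,
    table: PropertyTable | None = None,
    cache: DescriptorCache | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Concatenated pair features.

    Returns (features [n_pairs x 512], labels [+1/-1], row index frame).
    Row order follows the pair list; each protein's descriptor is
    computed once and reused through the cache.
    """
    table = table or config.table()
    cache = cache or DescriptorCache()
    by_id = {rec.id: rec for rec in records}
    features = np.empty((len(pairs), 512))
    labels = np.empty(len(pairs), dtype=int)
    index_rows = []
    for i, (id_a, id_b, label) in enumerate(pairs):
        for pid in (id_a, id_b):
            if pid not in by_id:
                raise KeyError(
                    f"pair ({id_a}, {id_b}): protein {pid!r} not in the "
                    "sequence collection"
                )
        desc_a = cache.descriptor(by_id[id_a], config, table)
        desc_b = cache.descriptor(by_id[id_b], config, table)
        features[i] = pair_feature(desc_a, desc_b)
        labels[i] = label
        index_rows.append({"id_a": id_a, "id_b": id_b, "label": label})
    return features, labels, pd.DataFrame(index_rows)


def _load_filtered(config: RunConfig):
    if not config.fasta or not config.pairs:
        raise ValueError("run config must point at FASTA and pair-list files")
    records = read_fasta(config.fasta)
    pairs = read_pairs(config.pairs)
    result = filter_by_length(
        records, pairs, min_len=config.min_len, max_len=config.max_len
    )
    if result.removal_log:
        logger.info("length filter removed %d items", len(result.removal_log))
    return result


def _write_run_metadata(config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    echo = asdict(config)
    echo["config_hash"] = config.feature_config_key()
    with open(out_dir / "config_echo.json", "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True)


def run_cv(config: RunConfig) -> MetricsReport:
    """Cross-validate on the configured dataset and write report artifacts.

    Writes ``metrics.tsv`` (per-fold rows plus mean/sd rows),
    ``roc_fold*.tsv`` point files, ``removals.tsv`` and a config echo to
    ``config.out_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    filtered = _load_filtered(config)
    features, labels, _ = featurize_pairs(filtered.records, filtered.pairs, config)
    report = cross_validate(
        features,
        labels,
        config=config.rf_config(),
        k=config.cv_folds,
        seed=config.seed,
    )
    _write_run_metadata(config, out_dir)
    report.to_tsv(out_dir / "metrics.tsv")
    report.write_roc(out_dir)
    filtered.log_frame().to_csv(out_dir / "removals.tsv", sep="\t", index=False)
    logger.info(
        "cv done: accuracy %.4f +/- %.4f, auc %.4f",
        report.mean("accuracy"),
        report.sd("accuracy"),
        report.mean("auc"),
    )
    return report


def train_model(config: RunConfig) -> RotationForestModel:
    """Fit one Rotation Forest on the full configured dataset."""
    filtered = _load_filtered(config)
    features, labels, _ = featurize_pairs(filtered.records, filtered.pairs, config)
    return train(features, labels, config.rf_config())


def sweep_parameters(
    config: RunConfig,
    k_grid,
    l_grid,
    phase1_trees: int = 20,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Two-phase grid search over the ensemble parameters.

    Phase 1 fixes the tree count at ``phase1_trees`` and scans the
    subset-count grid; phase 2 fixes the best subset count and scans the
    tree-count grid.  Ties break toward the smaller parameter value.
    Returns the full trace and the chosen (K, L).
    """
    k_grid = list(k_grid)
    l_grid = list(l_grid)
    if not k_grid or not l_grid:
        raise ValueError("both parameter grids must be nonempty")
    filtered = _load_filtered(config)
    features, labels, _ = featurize_pairs(filtered.records, filtered.pairs, config)

    def evaluate(k: int, l: int):
        run = replace(config, n_subsets=k, n_trees=l)
        report = cross_validate(
            features, labels, config=run.rf_config(), k=config.cv_folds,
            seed=config.seed,
        )
        return report.mean("accuracy")

    rows = []
    for k in k_grid:
        try:
            acc = evaluate(k, phase1_trees)
            rows.append({"phase": 1, "K": k, "L": phase1_trees,
                         "accuracy": acc, "error": ""})
        except Exception as exc:  # record and continue
            rows.append({"phase": 1, "K": k, "L": phase1_trees,
                         "accuracy": np.nan, "error": str(exc)})
    phase1 = [r for r in rows if r["phase"] == 1 and not r["error"]]
    if not phase1:
        raise RuntimeError("every phase-1 cell failed")
    best_k = min(phase1, key=lambda r: (-r["accuracy"], r["K"]))["K"]
    for l in l_grid:
        try:
            acc = evaluate(best_k, l)
            rows.append({"phase": 2, "K": best_k, "L": l,
                         "accuracy": acc, "error": ""})
        except Exception as exc:
            rows.append({"phase": 2, "K": best_k, "L": l,
                         "accuracy": np.nan, "error": str(exc)})
    phase2 = [r for r in rows if r["phase"] == 2 and not r["error"]]
    if not phase2:
        raise RuntimeError("every phase-2 cell failed")
    best_l = min(phase2, key=lambda r: (-r["accuracy"], r["L"]))["L"]
    return pd.DataFrame(rows), (best_k, best_l)
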