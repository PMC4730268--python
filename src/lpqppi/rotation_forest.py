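"""Rotation Forest ensemble.

Each of the L base decision trees is trained on a rotated copy of the
training matrix X (N samples x n features):

1. the n features are split at random into K disjoint subsets of size
   M = ceil(n/K) (the last subset may be smaller; conceptually it is
   padded with zero-features);
2. for every subset, PCA is fitted on a random draw of a fraction
   (default 3/5) of the samples restricted to that subset's columns, and
   all M principal-axis coefficient vectors are kept;
3. the per-subset coefficient blocks are assembled into a sparse
   block-diagonal rotation aligned with the original feature order, and
   the tree is fitted on X R.

Prediction averages the trees' class-probability vectors over the ensemble
(equal weights) and assigns the class with the larger mean probability;
an exact tie goes to +1.  Labels are +1 (interacting) / -1 (not).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "RFConfig",
    "FeaturePartition",
    "RotationSpec",
    "RotationForestModel",
    "partition_features",
    "fit_block",
    "assemble_rotation",
    "train",
    "predict_proba",
    "predict",
    "label_from_proba",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

CLASSES = np.array([-1, 1])


@dataclass(frozen=True)
class RFConfig:
    """Rotation Forest hyper-parameters.

    ``n_subsets`` is the number K of random feature subsets per tree and
    ``n_trees`` the ensemble size L.  ``bootstrap_fraction`` is the share
    of samples drawn (without replacement by default) before each
    per-subset PCA fit.  ``identity_rotation`` disables the rotations
    entirely, reducing the ensemble to plain trees on raw features.
    """

    n_subsets: int = 8
    n_trees: int = 20
    bootstrap_fraction: float = 0.6
    sample_with_replacement: bool = False
    criterion: str = "gini"
    max_depth: int | None = None
    min_samples_leaf: int = 1
    identity_rotation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 < self.bootstrap_fraction <= 1.0):
            raise ValueError("bootstrap_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FeaturePartition:
    """Random split of n features into K subsets of nominal size M.

    ``subsets`` holds the real feature indices of each subset; the last
    subset may contain fewer than ``subset_size`` indices, in which case
    ``n_padded`` zero-feature slots complete it conceptually (they carry
    zero coefficients in the rotation and never touch the data).
    """

    subsets: tuple[np.ndarray, ...]
    n_features: int
    subset_size: int

    @property
    def n_padded(self) -> int:
        return self.subset_size * len(self.subsets) - self.n_features


def partition_features(n: int, k: int, rng: np.random.Generator) -> FeaturePartition:
    """Randomly partition features {0..n-1} into ``k`` subsets.

    M = ceil(n/k); the first k-1 subsets get exactly M features, the last
    gets the remainder.
    """
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= K <= n, got K={k}, n={n}")
    m = math.ceil(n / k)
    order = rng.permutation(n)
    subsets = tuple(order[i * m : (i + 1) * m] for i in range(k))
    return FeaturePartition(subsets=subsets, n_features=n, subset_size=m)


def fit_block(
    x_sub: np.ndarray,
    y: np.ndarray | None,
    fraction: float,
    rng: np.random.Generator,
    with_replacement: bool = False,
) -> np.ndarray:
    """PCA coefficient block for one feature subset.

    Draws ceil(fraction * N) sample rows (rows span both classes; ``y``
    is accepted for interface symmetry but does not influence the draw),
    mean-centers them and returns all principal-axis coefficient vectors
    as the columns of an M x M orthonormal matrix.  Column signs are
    canonicalized so each column's largest-magnitude entry is positive.
    A degenerate draw (all rows identical) falls back to the identity.
    """
    x_sub = np.asarray(x_sub, dtype=float)
    n_samples, m = x_sub.shape
    n_draw = math.ceil(fraction * n_samples)
    rows = rng.choice(n_samples, size=n_draw, replace=with_replacement)
    drawn = x_sub[rows]
    centered = drawn - drawn.mean(axis=0)
    if not np.any(centered):
        logger.warning("rank-0 PCA draw (all rows identical); using identity block")
        return np.eye(m)
    cov = centered.T @ centered / max(n_draw - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    coeffs = eigvecs[:, order]
    return canonicalize_signs(coeffs)


def canonicalize_signs(coeffs: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-|entry| is positive."""
    coeffs = coeffs.copy()
    lead = np.abs(coeffs).argmax(axis=0)
    signs = np.sign(coeffs[lead, np.arange(coeffs.shape[1])])
    signs[signs == 0] = 1.0
    return coeffs * signs


@dataclass(frozen=True)
class RotationSpec:
    """Block-diagonal rotation aligned with the original feature order."""

    partition: FeaturePartition
    blocks: tuple[np.ndarray, ...]

    def matrix(self) -> np.ndarray:
        """Dense n x n rotation R (zero outside the blocks)."""
        n = self.partition.n_features
        r = np.zeros((n, n))
        for idx, block in zip(self.partition.subsets, self.blocks):
            r[np.ix_(idx, idx)] = block
        return r

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Rotated data X R, computed block-wise."""
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x, dtype=float)
        for idx, block in zip(self.partition.subsets, self.blocks):
            out[:, idx] = x[:, idx] @ block
        return out


def assemble_rotation(
    blocks: Sequence[np.ndarray], partition: FeaturePartition
) -> RotationSpec:
    """Bundle per-subset coefficient blocks into a :class:`RotationSpec`."""
    if len(blocks) != len(partition.subsets):
        raise ValueError(
            f"{len(blocks)} blocks for {len(partition.subsets)} subsets"
        )
    for idx, block in zip(partition.subsets, blocks):
        if block.shape != (len(idx), len(idx)):
            raise ValueError(
                f"block shape {block.shape} does not match subset size {len(idx)}"
            )
    return RotationSpec(partition=partition, blocks=tuple(np.asarray(b) for b in blocks))


@dataclass
class RotationForestModel:
    """Fitted ensemble: L (rotation, tree) pairs plus the config echo."""

    rotations: list[RotationSpec]
    trees: list[DecisionTreeClassifier]
    n_features: int
    config: RFConfig
    classes_: np.ndarray = field(default_factory=lambda: CLASSES.copy())

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return predict_proba(self, x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return predict(self, x)


def _tree_rng(seed: int, tree_index: int) -> np.random.Generator:
    # substream per tree: growing L never reshuffles earlier trees
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(tree_index,)))


def train(x: np.ndarray, y: np.ndarray, config: RFConfig) -> RotationForestModel:
    """Fit a Rotation Forest on features ``x`` and +/-1 labels ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.ndim != 2:
        raise ValueError("x must be 2-D (samples x features)")
    n_samples, n_features = x.shape
    if n_samples < 4:
        raise ValueError(f"need at least 4 samples, got {n_samples}")
    if y.shape != (n_samples,):
        raise ValueError("y length must match the number of rows of x")
    labels = set(np.unique(y).tolist())
    if not labels <= {-1, 1}:
        raise ValueError(f"labels must be +1/-1, got {sorted(labels)}")
    if len(labels) < 2:
        raise ValueError("both classes must be present in y")
    if config.n_subsets > n_features:
        raise ValueError(
            f"n_subsets={config.n_subsets} exceeds feature count {n_features}"
        )

    rotations: list[RotationSpec] = []
    trees: list[DecisionTreeClassifier] = []
    for i in range(config.n_trees):
        rng = _tree_rng(config.seed, i)
        partition = partition_features(n_features, config.n_subsets, rng)
        if config.identity_rotation:
            blocks = [np.eye(len(idx)) for idx in partition.subsets]
        else:
            blocks = [
                fit_block(
                    x[:, idx],
                    y,
                    config.bootstrap_fraction,
                    rng,
                    with_replacement=config.sample_with_replacement,
                )
                for idx in partition.subsets
            ]
        spec = assemble_rotation(blocks, partition)
        tree = DecisionTreeClassifier(
            criterion=config.criterion,
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(spec.apply(x), y)
        rotations.append(spec)
        trees.append(tree)
    return RotationForestModel(
        rotations=rotations, trees=trees, n_features=n_features, config=config
    )


def _as_2d(model: RotationForestModel, x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {x.shape[1]}"
        )
    return x, single


def predict_proba(model: RotationForestModel, x: np.ndarray) -> np.ndarray:
    """Mean class-probability vector over the ensemble.

    Columns follow ``model.classes_`` = [-1, +1]; rows sum to 1.
    """
    x, single = _as_2d(model, x)
    acc = np.zeros((x.shape[0], 2))
    for spec, tree in zip(model.rotations, model.trees):
        proba = tree.predict_proba(spec.apply(x))
        # map tree column order onto [-1, +1]
        cols = np.searchsorted(model.classes_, tree.classes_)
        acc[:, cols] += proba
    acc /= model.n_trees
    return acc[0] if single else acc


def label_from_proba(p_positive: float) -> int:
    """Decision rule: +1 when the interacting-class probability >= 0.5."""
    return 1 if p_positive >= 0.5 else -1


def predict(model: RotationForestModel, x: np.ndarray) -> np.ndarray | int:
    """Hard +/-1 labels; exact 0.5/0.5 ties resolve to +1."""
    proba = predict_proba(model, x)
    if proba.ndim == 1:
        return label_from_proba(proba[1])
    return np.where(proba[:, 1] >= 0.5, 1, -1)


def save_model(model: RotationForestModel, path: str | Path) -> None:
    """Serialize a fitted model; round-trips to bit-identical predictions."""
    joblib.dump(model, path)


def load_model(path: str | Path) -> RotationForestModel:
    model = joblib.load(path)
    if not isinstance(model, RotationForestModel):
        raise TypeError(f"{path} does not contain a RotationForestModel")
    return model
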