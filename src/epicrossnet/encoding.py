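"""Sequence one-hot encoding, feature normalization and dataset splits.

Windows are encoded base-by-base in the fixed row order A, C, G, U
(T is treated as U; N encodes as an all-zero row).  Genomic features are
z-scored using statistics fitted on the training split only; binary
columns are passed through untouched.  Datasets are split 8:1:1 into
train/validation/test with class stratification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import ParameterError
from .schema import FeatureSchema

log = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_INDEX_BASE = "ACGU"
WINDOW_LEN = 41


def one_hot_window(window: str) -> np.ndarray:
    """Encode a 41-nt window as a 41x4 binary matrix (A,C,G,U columns)."""
    if len(window) != WINDOW_LEN:
        raise ParameterError(f"window must be {WINDOW_LEN} nt, got {len(window)}")
    mat = np.zeros((WINDOW_LEN, 4))
    for i, base in enumerate(window.upper()):
        if base == "N":
            continue
        try:
            mat[i, _BASE_INDEX[base]] = 1.0
        except KeyError:
            raise ParameterError(f"invalid base {base!r} at position {i}") from None
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_window` (all-zero rows decode to N)."""
    out = []
    for row in np.asarray(mat):
        if row.sum() == 0:
            out.append("N")
        else:
            out.append(_INDEX_BASE[int(np.argmax(row))])
    return "".join(out)


def encode_windows(windows: list[str]) -> np.ndarray:
    return np.stack([one_hot_window(w) for w in windows])


def relative_position(distance_to_5prime: int, total_length: int) -> float:
    """Metagene coordinate: distance to the region 5' end over region length."""
    if total_length <= 0:
        raise ParameterError("total_length must be positive")
    if not 0 <= distance_to_5prime <= total_length:
        raise ParameterError("distance outside [0, total_length]")
    return distance_to_5prime / total_length


@dataclass
class FeatureMatrix:
    """N x 52 genomic feature table tied to a :class:`FeatureSchema`."""

    site_ids: list[str]
    values: np.ndarray
    schema: FeatureSchema
    normalization_stats: Optional[dict] = None  # name -> (mean, sd); train-only

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.schema)):
            raise ParameterError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.schema)} features"
            )
        if np.isnan(self.values).any():
            raise ParameterError("feature matrix contains missing values")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.schema.index_of(name)]

    def subset(self, site_ids: list[str]) -> "FeatureMatrix":
        pos = {s: i for i, s in enumerate(self.site_ids)}
        idx = [pos[s] for s in site_ids]
        return FeatureMatrix(list(site_ids), self.values[idx], self.schema,
                             self.normalization_stats)


def normalize_features(matrix: FeatureMatrix, train_mask: np.ndarray) -> FeatureMatrix:
    """Z-score continuous features using training-split statistics only.

    Binary features are exempt.  Zero-variance features map to 0 with a
    logged warning so downstream models never see a division by zero.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.shape != (len(matrix.site_ids),) or not train_mask.any():
        raise ParameterError("train_mask must select at least one row")
    values = matrix.values.copy()
    stats: dict[str, tuple[float, float]] = {}
    for j, desc in enumerate(matrix.schema):
        if desc.kind == "binary":
            continue
        mu = float(values[train_mask, j].mean())
        sd = float(values[train_mask, j].std())
        if sd == 0.0:
            log.warning("feature %r has zero variance on the training split; "
                        "column mapped to 0", desc.name)
            warnings.warn(f"zero-variance feature {desc.name!r} mapped to 0",
                          stacklevel=2)
            values[:, j] = 0.0
            stats[desc.name] = (mu, 0.0)
        else:
            values[:, j] = (values[:, j] - mu) / sd
            stats[desc.name] = (mu, sd)
    return FeatureMatrix(list(matrix.site_ids), values, matrix.schema, stats)


@dataclass
class EncodedDataset:
    """Model-ready arrays with a stratified train/val/test assignment."""

    one_hot: np.ndarray  # N x 41 x 4
    genomic: np.ndarray  # N x 52
    labels: np.ndarray  # N, {0,1}
    split: np.ndarray  # N, {'train','val','test'}
    seed: int
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.labels)
        if self.one_hot.shape[0] != n or self.genomic.shape[0] != n:
            raise ParameterError("inputs must share the leading dimension")
        if self.split.shape != (n,):
            raise ParameterError("split assignment length mismatch")

    def mask(self, part: str) -> np.ndarray:
        return self.split == part

    def part(self, part: str):
        m = self.mask(part)
        return self.one_hot[m], self.genomic[m], self.labels[m]

    @property
    def X(self) -> np.ndarray:
        """Flattened model input: sequence block (164) then genomic (52)."""
        n = len(self.labels)
        return np.concatenate([self.one_hot.reshape(n, -1), self.genomic], axis=1)

    def model_inputs(self, part: str, mode: str = "integrated") -> tuple:
        m = self.mask(part)
        n = int(m.sum())
        seq = self.one_hot[m].reshape(n, -1)
        if mode == "integrated":
            return np.concatenate([seq, self.genomic[m]], axis=1), self.labels[m]
        if mode == "sequence_only":
            return self.one_hot[m], self.labels[m]
        if mode == "genomic_only":
            return self.genomic[m], self.labels[m]
        raise ParameterError(f"unknown mode {mode!r}")


def stratified_split(
    labels: np.ndarray, seed: int, ratios: tuple[int, int, int] = (8, 1, 1)
) -> np.ndarray:
    """Assign each row to train/val/test, stratified by class."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < 10:
        raise ParameterError("need at least 10 samples for an 8:1:1 split")
    total = sum(ratios)
    fr_val = ratios[1] / total
    fr_test = ratios[2] / total
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=object)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = int(round(len(idx) * fr_val))
        n_test = int(round(len(idx) * fr_test))
        assignment[idx[:n_val]] = "val"
        assignment[idx[n_val:n_val + n_test]] = "test"
        assignment[idx[n_val + n_test:]] = "train"
    return assignment.astype(str)


def assemble_dataset(
    one_hot: np.ndarray,
    genomic: np.ndarray,
    labels: np.ndarray,
    seed: int,
    site_ids: Optional[list[str]] = None,
) -> EncodedDataset:
    """Bundle encodings with a deterministic stratified 8:1:1 split."""
    one_hot = np.asarray(one_hot, dtype=float)
    genomic = np.asarray(genomic, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (len(one_hot) == len(genomic) == len(labels)):
        raise ParameterError("inputs must have equal length")
    split = stratified_split(labels, seed)
    return EncodedDataset(one_hot, genomic, labels, split, seed,
                          site_ids or [f"row_{i}" for i in range(len(labels))])
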