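"""Sequence featurization: k-mer spectra, one-hot tensors, scaling, PCA.

Two representations feed the classifiers.  The k-mer spectrum concatenates,
for k = 1..6, the frequencies of all 4^k A/C/G/T words (5460 features in
total); windows containing N are skipped and each k-block is normalized by
its own valid-window count, so a block sums to 1 (or to 0 for degenerate
sequences).  The one-hot encoding keeps positional information instead: a
5-row matrix per sequence (rows A, C, G, T, N), zero-padded on the right to
the length m of the longest sequence, giving a 5 x m x n tensor for n
sequences.

Scaling (per-feature standardization) and PCA at a target explained
variance of 96% are fit on the training partition only and are carried
with every trained model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .sim import SequenceRecord

__all__ = [
    "KmerConfig",
    "FeatureMatrix",
    "OneHotTensor",
    "PcaModel",
    "kmer_feature_names",
    "kmer_vector",
    "kmer_matrix",
    "one_hot",
    "decode_one_hot",
    "fit_scaler",
    "apply_scaler",
    "fit_pca",
    "apply_pca",
]

logger = logging.getLogger(__name__)

ONE_HOT_ROW_ORDER = "ACGTN"

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_ROW = np.full(256, 4, dtype=np.int8)  # everything unknown maps to the N row
for _i, _b in enumerate(ONE_HOT_ROW_ORDER):
    _ROW[ord(_b)] = _i
    _ROW[ord(_b.lower())] = _i


@dataclass(frozen=True)
class KmerConfig:
    k_min: int = 1
    k_max: int = 6
    normalize: str = "frequency"  # or "count"

    def __post_init__(self) -> None:
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("require 1 <= k_min <= k_max")
        if self.normalize not in ("frequency", "count"):
            raise ValueError("normalize must be 'frequency' or 'count'")

    @property
    def dim(self) -> int:
        return sum(4 ** k for k in range(self.k_min, self.k_max + 1))


# the full 1..6 spectrum spans 4 + 16 + ... + 4096 = 5460 features
assert KmerConfig().dim == 5460


def kmer_feature_names(config: KmerConfig = KmerConfig()) -> list[str]:
    """All k-mers, lexicographic within each k, blocks in ascending k."""
    return ["".join(p)
            for k in range(config.k_min, config.k_max + 1)
            for p in itertools.product("ACGT", repeat=k)]


def kmer_vector(seq: str | SequenceRecord,
                config: KmerConfig = KmerConfig()) -> np.ndarray:
    """k-mer spectrum of one sequence.

    Sliding windows containing N (or any non-ACGT symbol) are skipped; in
    frequency mode each k-block is divided by its valid-window count, with
    0/0 defined as 0.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    codes = _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    out = np.zeros(config.dim)
    off = 0
    for k in range(config.k_min, config.k_max + 1):
        size = 4 ** k
        nwin = len(codes) - k + 1
        if nwin > 0:
            idx = np.zeros(nwin, dtype=np.int64)
            valid = np.ones(nwin, dtype=bool)
            for i in range(k):
                c = codes[i:i + nwin]
                valid &= c >= 0
                idx = idx * 4 + np.where(c < 0, 0, c)
            counts = np.bincount(idx[valid], minlength=size).astype(float)
            nvalid = int(valid.sum())
            if config.normalize == "frequency" and nvalid > 0:
                counts /= nvalid
            out[off:off + size] = counts
        off += size
    return out


@dataclass
class FeatureMatrix:
    """Per-sequence feature vectors with aligned ids and feature names."""

    ids: list[str]
    X: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.ids), len(self.feature_names)):
            raise ValueError("X shape must be (n_ids, n_features)")

    def save(self, path: str | Path) -> None:
        pd.DataFrame(self.X, index=self.ids, columns=self.feature_names) \
            .to_csv(path, index_label="seq_id")

    @classmethod
    def load(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="seq_id")
        return cls(list(df.index), df.to_numpy(dtype=float), list(df.columns))


def kmer_matrix(records: Sequence[SequenceRecord],
                config: KmerConfig = KmerConfig()) -> FeatureMatrix:
    X = np.stack([kmer_vector(r, config) for r in records]) if records \
        else np.zeros((0, config.dim))
    return FeatureMatrix([r.id for r in records], X, kmer_feature_names(config))


@dataclass
class OneHotTensor:
    """5 x m x n one-hot stack: rows (A,C,G,T,N), m = longest sequence,
    n = number of sequences; padding columns are all-zero."""

    X: np.ndarray
    lengths: list[int]
    ids: list[str] = field(default_factory=list)
    row_order: str = ONE_HOT_ROW_ORDER

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def n(self) -> int:
        return self.X.shape[2]


def one_hot(records: Sequence[SequenceRecord]) -> OneHotTensor:
    """Encode sequences as a 5 x m x n tensor (right-padded with zeros).

    Symbols outside {A,C,G,T,N} are mapped to the N row with a warning.
    """
    if not records:
        raise ValueError("need at least one sequence")
    m = max(len(r.seq) for r in records)
    n = len(records)
    X = np.zeros((5, m, n), dtype=np.float32)
    for j, rec in enumerate(records):
        raw = np.frombuffer(rec.seq.encode(), dtype=np.uint8)
        rows = _ROW[raw]
        known = (_CODE[raw] >= 0) | np.isin(raw, (ord("N"), ord("n")))
        if not known.all():
            logger.warning("sequence %s: %d non-ACGTN symbols mapped to N",
                           rec.id, int((~known).sum()))
        X[rows, np.arange(len(raw)), j] = 1.0
    return OneHotTensor(X, [len(r.seq) for r in records], [r.id for r in records])


def decode_one_hot(tensor: OneHotTensor, index: int) -> str:
    """Inverse of ``one_hot`` for one sequence (ignores padding columns)."""
    cols = tensor.X[:, : tensor.lengths[index], index]
    return "".join(tensor.row_order[i] for i in cols.argmax(axis=0))


def fit_scaler(X: np.ndarray) -> StandardScaler:
    """Per-feature standardization fit on the training partition.

    Zero-variance features pass through unchanged (sklearn would still
    center them; the fitted mean is reset to 0 for those columns).
    """
    scaler = StandardScaler().fit(X)
    zero = scaler.var_ == 0
    if zero.any():
        scaler.mean_ = np.where(zero, 0.0, scaler.mean_)
    return scaler


def apply_scaler(scaler: StandardScaler, X: np.ndarray) -> np.ndarray:
    return scaler.transform(X)


@dataclass
class PcaModel:
    """PCA retaining the smallest number of leading components whose
    cumulative explained-variance ratio reaches ``target_variance``."""

    pca: PCA
    target_variance: float

    @property
    def n_components(self) -> int:
        return int(self.pca.n_components_)

    @property
    def mean(self) -> np.ndarray:
        return self.pca.mean_

    @property
    def components(self) -> np.ndarray:
        return self.pca.components_

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    @property
    def retained_variance(self) -> float:
        return float(self.pca.explained_variance_ratio_.sum())


def fit_pca(X: np.ndarray, target_variance: float = 0.96) -> PcaModel:
    """Fit PCA on the training partition at the given variance target."""
    if not 0.0 < target_variance <= 1.0:
        raise ValueError("target_variance must be in (0, 1]")
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    if target_variance == 1.0:
        n_components: int | float = min(X.shape)
    else:
        n_components = target_variance
    model = PCA(n_components=n_components, svd_solver="full").fit(X)
    return PcaModel(model, target_variance)


def apply_pca(model: PcaModel, X: np.ndarray) -> np.ndarray:
    return model.pca.transform(X)
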