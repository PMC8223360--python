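"""k-mer featurization.

A sequence of length L contributes L - k + 1 sliding windows of width k; the
feature vocabulary is every string over {A,C,G,T} of each length k in
[k_min, k_max], grouped by ascending k and lexicographic within k, so the
(1, 6) vocabulary has 4 + 16 + ... + 4096 = 5460 entries. Windows containing
N are skipped. In ``frequency`` mode each k-block is divided by its number of
valid windows, making sequences of very different lengths comparable; raw
``count`` mode is retained as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_MAX_K = 8


@dataclass(frozen=True)
class KmerFeatureSpec:
    """Ordered k-mer vocabulary for k in [k_min, k_max]."""

    k_min: int
    k_max: int
    mode: str = "frequency"

    def __post_init__(self):
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError(f"need 1 <= k_min <= k_max, got ({self.k_min}, {self.k_max})")
        if self.k_max > _MAX_K:
            raise ValueError(f"k_max > {_MAX_K} is impractical (4^k features)")
        if self.mode not in ("count", "frequency"):
            raise ValueError(f"mode must be 'count' or 'frequency', got {self.mode!r}")

    @property
    def names(self) -> list:
        return [
            "".join(tup)
            for k in range(self.k_min, self.k_max + 1)
            for tup in product(_BASES, repeat=k)
        ]

    @property
    def n_features(self) -> int:
        return sum(4**k for k in range(self.k_min, self.k_max + 1))

    def block_slices(self) -> dict:
        """Map each k to the slice of its block within the full vector."""
        out, start = {}, 0
        for k in range(self.k_min, self.k_max + 1):
            out[k] = slice(start, start + 4**k)
            start += 4**k
        return out


def enumerate_kmers(k_min: int, k_max: int, mode: str = "frequency") -> KmerFeatureSpec:
    return KmerFeatureSpec(k_min, k_max, mode)


def _kmer_index(kmer: str) -> int:
    """Rank of a k-mer within its own k-block (lexicographic)."""
    idx = 0
    for ch in kmer:
        idx = idx * 4 + _BASE_INDEX[ch]
    return idx


def kmer_vector(seq: str, spec: KmerFeatureSpec) -> np.ndarray:
    """Featurize one normalized sequence (may contain N) into the full vector."""
    vec = np.zeros(spec.n_features, dtype=float)
    slices = spec.block_slices()
    for k, sl in slices.items():
        n_windows = len(seq) - k + 1
        if n_windows <= 0:
            warnings.warn(f"sequence shorter than k={k}; zero block emitted")
            continue
        block = vec[sl]
        valid = 0
        for i in range(n_windows):
            window = seq[i : i + k]
            if "N" in window:
                continue
            block[_kmer_index(window)] += 1
            valid += 1
        if spec.mode == "frequency":
            if valid > 0:
                block /= valid
            # no valid windows: zero block stands
    return vec


def build_feature_matrix(records, spec: KmerFeatureSpec) -> pd.DataFrame:
    """Featurize records into a (sequences x k-mers) DataFrame, rows in input order."""
    records = list(records)
    if not records:
        raise ValueError("no records to featurize")
    rows = np.vstack([kmer_vector(r.sequence, spec) for r in records])
    return pd.DataFrame(rows, index=[r.id for r in records], columns=spec.names)


def restrict_features(matrix: pd.DataFrame, keep) -> pd.DataFrame:
    """Column subset in ``keep``'s order (apply a selected-feature union)."""
    keep = list(keep)
    unknown = [name for name in keep if name not in matrix.columns]
    if unknown:
        raise KeyError(f"unknown feature names: {unknown[:10]}")
    return matrix.loc[:, keep]


class KmerFeaturizer(TransformerMixin, BaseEstimator):
    """Transform nucleotide sequences into k-mer feature vectors.

    Parameters
    ----------
    k_min, k_max : int
        Range of k-mer sizes; the vocabulary holds all 4**k strings for each k.
    mode : {"frequency", "count"}
        Per-k-block normalized frequencies (default) or raw window counts.
    vocabulary : list of str, optional
        Restrict the output to this ordered subset of the full vocabulary
        (e.g. an elastic-net-selected union).
    """

    def __init__(self, k_min: int = 1, k_max: int = 6, mode: str = "frequency",
                 vocabulary=None):
        self.k_min = k_min
        self.k_max = k_max
        self.mode = mode
        self.vocabulary = vocabulary

    def fit(self, X=None, y=None):
        spec = KmerFeatureSpec(self.k_min, self.k_max, self.mode)
        self.spec_ = spec
        full = spec.names
        if self.vocabulary is not None:
            unknown = [v for v in self.vocabulary if v not in set(full)]
            if unknown:
                raise ValueError(f"vocabulary entries outside the k-mer space: {unknown[:10]}")
            self.feature_names_ = list(self.vocabulary)
            full_index = {name: i for i, name in enumerate(full)}
            self._columns = np.array([full_index[v] for v in self.feature_names_])
        else:
            self.feature_names_ = full
            self._columns = None
        return self

    def transform(self, X) -> np.ndarray:
        """X: iterable of normalized sequence strings or SequenceRecord."""
        if not hasattr(self, "spec_"):
            self.fit()
        seqs = [x.sequence if hasattr(x, "sequence") else str(x) for x in X]
        rows = np.vstack([kmer_vector(s, self.spec_) for s in seqs]) if seqs else \
            np.empty((0, self.spec_.n_features))
        if self._columns is not None:
            rows = rows[:, self._columns]
        return rows

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "feature_names_"):
            self.fit()
        return np.asarray(self.feature_names_, dtype=object)
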