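"""Featurization of barcode datasets.

Two families: per-column numeric encoding of alignments, and alignment-free
k-mer features over the DNA alphabet — exact spectrum counts, gappy counts
(k-mers occurring as subsequences with at most ``g`` total internal gaps),
and mismatch counts (contiguous k-mer instances within Hamming distance
``m``).  Feature order is lexicographic over {A,C,G,T}^k.

Counts are reported as relative frequencies by default (each row divided by
its total count); raw counts are available via ``relative=False``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import encode_sequence
from .errors import ConfigError, DataError
from .io import BarcodeDataset

ALPHABET = "ACGT"

SCHEMES = ("aligned-columns", "spectrum", "gappy", "mismatch")

#: fixed per-column code for aligned encoding
_COLUMN_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}


@dataclass
class FeatureMatrix:
    instance_ids: list[str]
    labels: list[str]
    feature_names: list[str]
    values: np.ndarray
    scheme: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.instance_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.instance_ids, columns=self.feature_names)
        df.insert(0, "species", self.labels)
        return df

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="record_id")

    def write_long(self, path) -> None:
        """Sparse-friendly long format: record_id, feature, value (zeros dropped)."""
        with open(path, "w") as fh:
            fh.write("record_id\tfeature\tvalue\n")
            for i, rid in enumerate(self.instance_ids):
                for j in np.flatnonzero(self.values[i]):
                    fh.write(f"{rid}\t{self.feature_names[j]}\t{self.values[i, j]:g}\n")

    def write_arff(self, path, relation: str = "barcodes") -> None:
        """ARFF writer for interoperability with attribute/label tabular tools."""
        classes = sorted(set(self.labels))
        with open(path, "w") as fh:
            fh.write(f"@RELATION {relation}\n\n")
            for name in self.feature_names:
                fh.write(f"@ATTRIBUTE {name} NUMERIC\n")
            fh.write(f"@ATTRIBUTE class {{{','.join(classes)}}}\n\n@DATA\n")
            for row, label in zip(self.values, self.labels):
                fh.write(",".join(f"{v:g}" for v in row) + f",{label}\n")


def kmer_names(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product(ALPHABET, repeat=k)]


def encode_alignment(ds: BarcodeDataset) -> FeatureMatrix:
    """Map each alignment column to a fixed numeric code (A1 C2 G3 T4, other 0)."""
    if not ds.aligned:
        raise DataError("encode_alignment requires an aligned dataset")
    if not len(ds):
        raise DataError("empty dataset")
    length = len(ds[0].sequence)
    values = np.zeros((len(ds), length), dtype=float)
    for i, rec in enumerate(ds):
        values[i] = [_COLUMN_CODE.get(c, 0) for c in rec.sequence]
    width = len(str(length))
    return FeatureMatrix(
        instance_ids=list(ds.ids),
        labels=list(ds.species_labels),
        feature_names=[f"pos{j + 1:0{width}d}" for j in range(length)],
        values=values,
        scheme="aligned-columns",
        params={},
    )


def _pow4(k: int) -> np.ndarray:
    return 4 ** np.arange(k - 1, -1, -1)


def _spectrum_counts(codes: np.ndarray, k: int) -> np.ndarray:
    counts = np.zeros(4**k)
    if codes.size < k:
        return counts
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = windows[(windows >= 0).all(axis=1)]
    if valid.size:
        vals = (valid * _pow4(k)).sum(axis=1)
        counts += np.bincount(vals, minlength=4**k)
    return counts


def _gappy_counts(codes: np.ndarray, k: int, g: int) -> np.ndarray:
    # Phi_w = number of index tuples i1 < ... < ik with span <= k-1+g
    # spelling w; positions with non-ACGT symbols are unusable.
    counts = np.zeros(4**k)
    L = codes.size
    pow4 = _pow4(k)
    for i in range(L):
        if codes[i] < 0:
            continue
        if k == 1:
            counts[codes[i]] += 1
            continue
        window = [j for j in range(i + 1, min(L, i + k + g)) if codes[j] >= 0]
        for combo in itertools.combinations(window, k - 1):
            val = codes[i] * pow4[0]
            for pos, p4 in zip(combo, pow4[1:]):
                val += codes[pos] * p4
            counts[val] += 1
    return counts


def _mismatch_counts(codes: np.ndarray, k: int, m: int) -> np.ndarray:
    # Phi_w = number of contiguous k-mer instances within Hamming distance <= m of w.
    counts = np.zeros(4**k)
    if codes.size < k:
        return counts
    pow4 = _pow4(k)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = windows[(windows >= 0).all(axis=1)]
    # precompute position/letter substitution patterns once
    subs = []
    for n_sub in range(m + 1):
        for positions in itertools.combinations(range(k), n_sub):
            for letters in itertools.product(range(4), repeat=n_sub):
                subs.append((positions, letters))
    for window in valid:
        base = int((window * pow4).sum())
        for positions, letters in subs:
            val = base
            ok = True
            for pos, letter in zip(positions, letters):
                if letter == window[pos]:  # not a substitution; avoid double count
                    ok = False
                    break
                val += (letter - window[pos]) * pow4[pos]
            if ok:
                counts[val] += 1
    return counts


def _build(ds: BarcodeDataset, k: int, scheme: str, counter, params, relative: bool):
    values = np.zeros((len(ds), 4**k))
    for i, rec in enumerate(ds):
        codes = encode_sequence(rec.degapped())
        row = counter(codes)
        total = row.sum()
        if total == 0:
            warnings.warn(
                f"record {rec.record_id!r}: no countable {k}-mers; all-zero row",
                stacklevel=3,
            )
        elif relative:
            row = row / total
        values[i] = row
    return FeatureMatrix(
        instance_ids=list(ds.ids),
        labels=list(ds.species_labels),
        feature_names=kmer_names(k),
        values=values,
        scheme=scheme,
        params=params,
    )


def spectrum_features(ds: BarcodeDataset, k: int, relative: bool = True) -> FeatureMatrix:
    """Exact contiguous k-mer counts (gaps stripped, non-ACGT windows skipped)."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    return _build(ds, k, "spectrum", lambda c: _spectrum_counts(c, k), {"k": k}, relative)


def gappy_features(
    ds: BarcodeDataset, k: int, g: int = 1, relative: bool = True
) -> FeatureMatrix:
    """k-mers occurring as subsequences with at most g total internal gaps."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    if g < 0:
        raise ConfigError("g must be >= 0")
    return _build(
        ds, k, "gappy", lambda c: _gappy_counts(c, k, g), {"k": k, "g": g}, relative
    )


def mismatch_features(
    ds: BarcodeDataset, k: int, m: int = 1, relative: bool = True
) -> FeatureMatrix:
    """Contiguous k-mer instances counted into every word within Hamming m."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    if not 0 <= m < k:
        raise ConfigError("need 0 <= m < k")
    return _build(
        ds, k, "mismatch", lambda c: _mismatch_counts(c, k, m), {"k": k, "m": m}, relative
    )


def featurize(ds: BarcodeDataset, scheme: str, **params) -> FeatureMatrix:
    """Dispatch by scheme name (CLI entry point)."""
    if scheme in ("aligned", "aligned-columns"):
        return encode_alignment(ds)
    if scheme == "spectrum":
        return spectrum_features(ds, **params)
    if scheme == "gappy":
        return gappy_features(ds, **params)
    if scheme == "mismatch":
        return mismatch_features(ds, **params)
    raise ConfigError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
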