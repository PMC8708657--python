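"""Pairwise genetic distances: simple (p), JC69, and K80 models.

All models use pairwise deletion by default: for each sequence pair, any site
where either sequence carries a gap or a non-ACGT symbol (N, IUPAC ambiguity)
is excluded from the comparison.  ``deletion="complete"`` excludes a column
for every pair if any record in the dataset is non-ACGT there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DataError, NoComparableSitesError, SaturationError
from .io import BarcodeDataset

MODELS = ("simple", "jc69", "k80")

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to int codes A=0 C=1 G=2 T=3, anything else -1."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


class SiteCounts(NamedTuple):
    n: int
    mismatches: int
    transitions: int
    transversions: int


def comparable_sites(a: str, b: str) -> SiteCounts:
    """Per-pair site bookkeeping under pairwise deletion.

    Transitions are A<->G and C<->T; all other mismatches are transversions.
    Raises on unequal lengths; ``n == 0`` is reported, not raised (distance
    functions raise :class:`NoComparableSitesError` where it matters).
    """
    if len(a) != len(b):
        raise DataError(f"unequal sequence lengths {len(a)} vs {len(b)}")
    return _site_counts(encode_sequence(a), encode_sequence(b))


def _site_counts(xa: np.ndarray, xb: np.ndarray) -> SiteCounts:
    mask = (xa >= 0) & (xb >= 0)
    diff = mask & (xa != xb)
    mismatches = int(diff.sum())
    # |code difference| == 2 exactly for A<->G (0,2) and C<->T (1,3)
    transitions = int((diff & (np.abs(xa - xb) == 2)).sum())
    return SiteCounts(int(mask.sum()), mismatches, transitions, mismatches - transitions)


def p_distance(a: str, b: str) -> float:
    """Simple (uncorrected) distance: mismatch fraction over comparable sites."""
    c = comparable_sites(a, b)
    if c.n == 0:
        raise NoComparableSitesError("no comparable sites between sequences")
    return c.mismatches / c.n


def jc69_from_p(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3); requires p < 0.75."""
    if p >= 0.75:
        raise SaturationError(f"JC69 undefined for p = {p} >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc69(a: str, b: str) -> float:
    return jc69_from_p(p_distance(a, b))


def k80_from_pq(P: float, Q: float) -> float:
    """Kimura two-parameter distance from transition (P) and transversion (Q)
    proportions: d = -(1/2) ln(1-2P-Q) - (1/4) ln(1-2Q)."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K80 undefined for P = {P}, Q = {Q}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k80(a: str, b: str) -> float:
    c = comparable_sites(a, b)
    if c.n == 0:
        raise NoComparableSitesError("no comparable sites between sequences")
    return k80_from_pq(c.transitions / c.n, c.transversions / c.n)


def _from_counts(model: str, c: SiteCounts) -> float:
    if c.n == 0:
        raise NoComparableSitesError("no comparable sites between sequences")
    if model == "simple":
        return c.mismatches / c.n
    if model == "jc69":
        return jc69_from_p(c.mismatches / c.n)
    if model == "k80":
        return k80_from_pq(c.transitions / c.n, c.transversions / c.n)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix keyed by record id."""

    labels: list[str]
    values: np.ndarray
    model: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, record_id: str) -> int:
        return self.labels.index(record_id)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index(id_a), self.index(id_b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle pair distances as a flat array (NaNs dropped)."""
        iu = np.triu_indices(len(self.labels), k=1)
        vals = self.values[iu]
        return vals[~np.isnan(vals)]

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.model)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path, phylip_header: bool = False) -> None:
        with open(path, "w") as fh:
            if phylip_header:
                fh.write(f"{len(self.labels)}\n")
            self.to_dataframe().to_csv(fh, sep="\t")


def distance_matrix(
    ds: BarcodeDataset,
    model: str = "simple",
    deletion: str = "pairwise",
    mode: str = "strict",
) -> DistanceMatrix:
    """All-pairs distances for an aligned dataset.

    ``mode="strict"`` raises on any pair whose model value is undefined,
    naming the pair; ``mode="lenient"`` stores NaN there (such entries are
    dropped by :meth:`DistanceMatrix.condensed`).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if len(ds) < 2:
        raise DataError("distance matrix requires at least 2 records")
    if not ds.aligned:
        raise DataError("distance matrix requires an aligned dataset")
    codes = np.vstack([encode_sequence(r.sequence) for r in ds])
    if deletion == "complete":
        keep = (codes >= 0).all(axis=0)
        codes = codes[:, keep]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n = len(ds)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = _from_counts(model, _site_counts(codes[i], codes[j]))
            except (SaturationError, NoComparableSitesError) as exc:
                if mode == "strict":
                    raise type(exc)(
                        f"pair ({ds.ids[i]!r}, {ds.ids[j]!r}): {exc}"
                    ) from exc
                d = math.nan
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(ds.ids), values, model)
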