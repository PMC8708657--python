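"""Synthetic barcode datasets with controlled divergence structure.

Each species descends from a common root sequence: one ancestor per species
is mutated from the root at the interspecific rate, and each member is
mutated from its ancestor at the intraspecific rate.  Options add singleton
species, gap characters (indels kept as gap columns — no realignment), and
missing bases, emulating the structure of real curated barcode sets.
Substitutions are uniform over the three alternatives by default (so p- and
JC-distance expectations are known in closed form); a transition bias can be
set for K80-shaped data (tstv=2.0 gives TS/TV = 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .io import BarcodeDataset, BarcodeRecord

_BASES = np.array(list("ACGT"))
#: transition partner of each base index (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1])
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass(frozen=True)
class SynthConfig:
    n_species: int = 20
    members_per_species: int = 4
    seq_length: int = 600
    intra_divergence: float = 0.005
    inter_divergence: float = 0.08
    singleton_fraction: float = 0.0
    indel_rate: float = 0.0
    missing_rate: float = 0.0
    tstv: float | None = None
    marker: str = "synth"
    seed: int = 1

    def __post_init__(self):
        if self.n_species < 1 or self.members_per_species < 1 or self.seq_length < 1:
            raise ConfigError("n_species, members_per_species, seq_length must be >= 1")
        if not 0 <= self.intra_divergence < self.inter_divergence <= 0.75:
            raise ConfigError(
                "need 0 <= intra_divergence < inter_divergence <= 0.75"
            )
        for name in ("singleton_fraction", "indel_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.tstv is not None and self.tstv <= 0:
            raise ConfigError("tstv must be positive")


def _mutate_codes(codes: np.ndarray, rate: float, rng, tstv: float | None) -> np.ndarray:
    out = codes.copy()
    hits = np.flatnonzero(rng.random(codes.size) < rate)
    if hits.size == 0:
        return out
    if tstv is None:
        # uniform over the three alternatives
        shift = rng.integers(1, 4, size=hits.size)
        out[hits] = (out[hits] + shift) % 4
    else:
        p_ts = tstv / (tstv + 1.0)
        is_ts = rng.random(hits.size) < p_ts
        cur = out[hits]
        new = np.where(
            is_ts,
            _TRANSITION[cur],
            _TRANSVERSIONS[cur, rng.integers(0, 2, size=hits.size)],
        )
        out[hits] = new
    return out


def mutate_sequence(seq: str, rate: float, seed: int, tstv: float | None = None) -> str:
    """Per-site substitution with the given probability (uniform alternatives)."""
    if not 0 <= rate <= 0.75:
        raise ConfigError("rate must be in [0, 0.75]")
    rng = np.random.default_rng(seed)
    codes = np.array(["ACGT".index(c) for c in seq])
    return "".join(_BASES[_mutate_codes(codes, rate, rng, tstv)])


def generate_dataset(cfg: SynthConfig) -> tuple[BarcodeDataset, dict[str, str]]:
    """Generate a dataset plus the true record-to-species map.

    Deterministic under ``cfg.seed`` (byte-identical FASTA on re-run).
    """
    rng = np.random.default_rng(cfg.seed)
    root = rng.integers(0, 4, size=cfg.seq_length)
    n_singletons = int(round(cfg.singleton_fraction * cfg.n_species))
    singleton_species = set(
        rng.choice(cfg.n_species, size=n_singletons, replace=False).tolist()
    )
    records: list[BarcodeRecord] = []
    truth: dict[str, str] = {}
    acc = 0
    for s in range(cfg.n_species):
        species = f"Species_{s + 1:03d}"
        ancestor = _mutate_codes(root, cfg.inter_divergence, rng, cfg.tstv)
        n_members = 1 if s in singleton_species else cfg.members_per_species
        for _ in range(n_members):
            codes = _mutate_codes(ancestor, cfg.intra_divergence, rng, cfg.tstv)
            seq = _BASES[codes]
            if cfg.indel_rate > 0:
                seq = np.where(rng.random(seq.size) < cfg.indel_rate, "-", seq)
            if cfg.missing_rate > 0:
                seq = np.where(
                    (rng.random(seq.size) < cfg.missing_rate) & (seq != "-"), "N", seq
                )
            acc += 1
            record_id = f"SYN{acc:05d}"
            records.append(
                BarcodeRecord(
                    record_id=record_id,
                    species=species,
                    marker=cfg.marker,
                    sequence="".join(seq),
                    aligned=True,
                )
            )
            truth[record_id] = species
    return BarcodeDataset(records, marker=cfg.marker, aligned=True), truth
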