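import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from barcodekit.distances import distance_matrix
from barcodekit.io import BarcodeDataset, BarcodeRecord
from barcodekit.synth import SynthConfig, generate_dataset


def make_dataset(entries, marker="test", aligned=True):
    """entries: list of (record_id, species, sequence)."""
    records = [
        BarcodeRecord(record_id=rid, species=sp, marker=marker, sequence=seq, aligned=aligned)
        for rid, sp, seq in entries
    ]
    return BarcodeDataset(records, marker=marker, aligned=aligned)


@pytest.fixture(scope="session")
def planted():
    """The spec's planted-gap dataset: 20 species x 4 members, L=600,
    intra 0.005, inter 0.08, seed 1 — with its simple-distance matrix."""
    cfg = SynthConfig(
        n_species=20,
        members_per_species=4,
        seq_length=600,
        intra_divergence=0.005,
        inter_divergence=0.08,
        seed=1,
    )
    ds, truth = generate_dataset(cfg)
    dm = distance_matrix(ds, model="simple")
    return ds, dm, truth


@pytest.fixture(scope="session")
def singleton_rich():
    """Planted-gap dataset with 30% singleton species injected."""
    cfg = SynthConfig(
        n_species=20,
        members_per_species=4,
        seq_length=600,
        intra_divergence=0.005,
        inter_divergence=0.08,
        singleton_fraction=0.3,
        seed=1,
    )
    ds, truth = generate_dataset(cfg)
    dm = distance_matrix(ds, model="simple")
    return ds, dm, truth
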