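"""Hand-built toy datasets with frozen expected outputs.

Each fixture is small enough to verify by hand (<= 15 records).  The stored
expectations were enumerated manually at build time; ``verify_fixtures``
recomputes them through the public API and reports any drift.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import abgd, distances, identify
from .io import BarcodeDataset, BarcodeRecord

# Four records, two species, 20 aligned sites.  Hand-counted p-distances:
# a1-a2 = 1/20, a1-b1 = 10/20, a1-b2 = 2/20, a2-b1 = 10/20, a2-b2 = 3/20,
# b1-b2 = 12/20.  Best Match: a1<->a2 Correct; b1 ties a1/a2 (both species A)
# -> Incorrect; b2's nearest is a1 -> Incorrect.
BM_FIXTURE_FASTA = """\
>Species_A|A1
AAAAAAAAAAAAAAAAAAAA
>Species_A|A2
CAAAAAAAAAAAAAAAAAAA
>Species_B|B1
TTTTTTTTTTAAAAAAAAAA
>Species_B|B2
AAAAAAAAAAAAAAAAAATT
"""

BM_FIXTURE_EXPECTED = {
    "per_record": {"A1": "Correct", "A2": "Correct", "B1": "Incorrect", "B2": "Incorrect"},
    "pct_correct": 50.0,
    "pct_incorrect": 50.0,
    "species_correct_pct": 50.0,
    "true_species_pct": 50.0,
}

# Twelve records, three planted clusters of four (one base + three one-off
# mutants each).  Intra-cluster distances are 1/20 or 2/20; inter-cluster
# distances are >= 8/20, so gap detection at prior 0.01 splits exactly into
# the three species and every group is TRUE.
ABGD_FIXTURE_FASTA = """\
>Species_X|X1
AAAAAAAAAAAAAAAAAAAA
>Species_X|X2
AAAAAAAAAATAAAAAAAAA
>Species_X|X3
AAAAAAAAAAATAAAAAAAA
>Species_X|X4
AAAAAAAAAAAATAAAAAAA
>Species_Y|Y1
CCCCCCCCCCAAAAAAAAAA
>Species_Y|Y2
CCCCCCCCCCTAAAAAAAAA
>Species_Y|Y3
CCCCCCCCCCATAAAAAAAA
>Species_Y|Y4
CCCCCCCCCCAATAAAAAAA
>Species_Z|Z1
GGGGGGGGGGCCCCCCCCCC
>Species_Z|Z2
GGGGGGGGGGTCCCCCCCCC
>Species_Z|Z3
GGGGGGGGGGCTCCCCCCCC
>Species_Z|Z4
GGGGGGGGGGCCTCCCCCCC
"""

ABGD_FIXTURE_EXPECTED = {
    "n_groups": 3,
    "tags": ["TRUE", "TRUE", "TRUE"],
    "pct_true_species": 100.0,
}


@dataclass(frozen=True)
class Fixture:
    name: str
    fasta: str
    expected: dict
    description: str


def _parse(payload: str, marker: str) -> BarcodeDataset:
    records = []
    for block in payload.strip().split(">"):
        if not block:
            continue
        header, seq = block.strip().split("\n", 1)
        species, rid = header.split("|")
        records.append(
            BarcodeRecord(
                record_id=rid, species=species, marker=marker,
                sequence=seq.replace("\n", ""), aligned=True,
            )
        )
    return BarcodeDataset(records, marker=marker, aligned=True)


FIXTURES = [
    Fixture(
        name="best-match-toy",
        fasta=BM_FIXTURE_FASTA,
        expected=BM_FIXTURE_EXPECTED,
        description="4 records, 2 species; Best Match outcomes hand-enumerated",
    ),
    Fixture(
        name="gap-partition-toy",
        fasta=ABGD_FIXTURE_FASTA,
        expected=ABGD_FIXTURE_EXPECTED,
        description="12 records, 3 planted clusters; gap partition recovers species",
    ),
]


def _check_best_match(fx: Fixture) -> list[str]:
    ds = _parse(fx.fasta, "toy")
    dm = distances.distance_matrix(ds, model="simple")
    report = identify.identify_all(dm, ds, criterion="BM")
    problems = []
    got = {o.record_id: o.category for o in report.outcomes}
    if got != fx.expected["per_record"]:
        problems.append(f"per-record outcomes {got} != {fx.expected['per_record']}")
    for key in ("pct_correct", "pct_incorrect", "species_correct_pct", "true_species_pct"):
        if abs(getattr(report, key) - fx.expected[key]) > 1e-9:
            problems.append(f"{key}: {getattr(report, key)} != {fx.expected[key]}")
    return problems


def _check_gap_partition(fx: Fixture) -> list[str]:
    ds = _parse(fx.fasta, "toy")
    dm = distances.distance_matrix(ds, model="simple")
    part = abgd.recursive_partition(dm, prior_p=0.01, X=1.5)
    categories, summary = abgd.categorize_groups(part, ds)
    problems = []
    if part.n_groups != fx.expected["n_groups"]:
        problems.append(f"n_groups {part.n_groups} != {fx.expected['n_groups']}")
    tags = sorted(c.tag for c in categories)
    if tags != sorted(fx.expected["tags"]):
        problems.append(f"tags {tags} != {fx.expected['tags']}")
    if abs(summary["pct_true_species"] - fx.expected["pct_true_species"]) > 1e-9:
        problems.append(f"pct_true_species {summary['pct_true_species']}")
    return problems


_CHECKS = {
    "best-match-toy": _check_best_match,
    "gap-partition-toy": _check_gap_partition,
}


def verify_fixtures() -> dict[str, list[str]]:
    """Recompute every fixture's expected output; return problems per fixture.

    An empty problem list means the fixture passed.
    """
    return {fx.name: _CHECKS[fx.name](fx) for fx in FIXTURES}


def load_fixture(name: str) -> BarcodeDataset:
    for fx in FIXTURES:
        if fx.name == name:
            return _parse(fx.fasta, "toy")
    raise KeyError(name)
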