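"""Distance-based species identification: Best Match, Best Close Match, and
All Species Barcodes criteria, with sequence- and species-level rollups.

Best Match (BM) assigns the query the species of its nearest barcode,
regardless of similarity.  Best Close Match (BCM) additionally demands the
nearest barcode lie within a threshold, else the query has no match.  All
Species Barcodes (ASB) is the strictest: every conspecific barcode must
outrank every allospecific one, and all conspecifics must lie within the
threshold.

Ties are resolved with an absolute epsilon of 1e-12 on distances: a tie that
mixes conspecific and allospecific records is Ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix
from .errors import ComputationError, DataError
from .io import BarcodeDataset

EPSILON = 1e-12

CRITERIA = ("BM", "BCM", "ASB")
CATEGORIES = ("Correct", "Incorrect", "Ambiguous", "NoMatch")


@dataclass(frozen=True)
class IdentificationOutcome:
    record_id: str
    criterion: str
    category: str
    best_match_ids: tuple[str, ...]
    best_distance: float


@dataclass
class IdentificationReport:
    """Per-record outcomes plus sequence- and species-level percentages."""

    criterion: str
    threshold: float | None
    outcomes: list[IdentificationOutcome]
    pct_correct: float
    pct_incorrect: float
    pct_ambiguous: float
    pct_nomatch: float
    species_correct_pct: float
    true_species_pct: float

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for o in self.outcomes:
            out[o.category] += 1
        return out


def _species_for(dm: DistanceMatrix, ds: BarcodeDataset) -> np.ndarray:
    by_id = {r.record_id: r.species for r in ds}
    try:
        return np.array([by_id[label] for label in dm.labels], dtype=object)
    except KeyError as exc:
        raise DataError(f"distance matrix label {exc} not in dataset") from exc


def intraspecific_distances(dm: DistanceMatrix, ds: BarcodeDataset) -> np.ndarray:
    """All unordered conspecific pair distances, pooled over species.

    Singleton species contribute nothing; if no species has >= 2 members the
    percentile threshold is undefined and an error is raised.
    """
    species = _species_for(dm, ds)
    same = species[:, None] == species[None, :]
    iu = np.triu_indices(len(dm.labels), k=1)
    vals = dm.values[iu][same[iu]]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ComputationError(
            "no conspecific pairs: intraspecific distance threshold undefined"
        )
    return vals


def percentile_threshold(values, q: float = 95.0) -> float:
    """q-th percentile with linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ComputationError("percentile of empty value list")
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    return float(np.percentile(values, q, method="linear"))


def _neighbourhood(dm: DistanceMatrix, species: np.ndarray, i: int):
    """Distances from record i to all others, with conspecific flags."""
    n = len(dm.labels)
    others = np.arange(n) != i
    d = dm.values[i]
    return np.flatnonzero(others), d, species == species[i]


def best_match(
    dm: DistanceMatrix, ds: BarcodeDataset, record_id: str, _species=None
) -> IdentificationOutcome:
    """Best Match: nearest barcode decides, regardless of similarity."""
    species = _species_for(dm, ds) if _species is None else _species
    i = dm.index(record_id)
    others, d, consp = _neighbourhood(dm, species, i)
    if others.size == 0:
        raise DataError("best_match requires at least 2 records")
    best = np.nanmin(d[others])
    tied = others[d[others] <= best + EPSILON]
    tied_consp = consp[tied]
    if tied_consp.all():
        category = "Correct"
    elif not tied_consp.any():
        category = "Incorrect"
    else:
        category = "Ambiguous"
    return IdentificationOutcome(
        record_id=record_id,
        criterion="BM",
        category=category,
        best_match_ids=tuple(dm.labels[j] for j in tied),
        best_distance=float(best),
    )


def best_close_match(
    dm: DistanceMatrix,
    ds: BarcodeDataset,
    record_id: str,
    threshold: float,
    _species=None,
) -> IdentificationOutcome:
    """Best Close Match: as BM, but NoMatch when the nearest barcode exceeds
    the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = best_match(dm, ds, record_id, _species=_species)
    if out.best_distance > threshold + EPSILON:
        return IdentificationOutcome(
            record_id=record_id,
            criterion="BCM",
            category="NoMatch",
            best_match_ids=(),
            best_distance=out.best_distance,
        )
    return IdentificationOutcome(
        record_id=record_id,
        criterion="BCM",
        category=out.category,
        best_match_ids=out.best_match_ids,
        best_distance=out.best_distance,
    )


def all_species_barcodes(
    dm: DistanceMatrix,
    ds: BarcodeDataset,
    record_id: str,
    threshold: float,
    _species=None,
) -> IdentificationOutcome:
    """All Species Barcodes: Correct only when every conspecific is strictly
    closer than every allospecific record and all conspecifics lie within the
    threshold.

    Precedence (a documented semantic choice): NoMatch when no record at all
    lies within the threshold; Incorrect when the query is a singleton or any
    allospecific is strictly closer than the farthest conspecific; Ambiguous
    when an allospecific ties (within epsilon) the farthest conspecific;
    otherwise Correct if the farthest conspecific is within threshold, else
    NoMatch (the full conspecific set is out of reach).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    species = _species_for(dm, ds) if _species is None else _species
    i = dm.index(record_id)
    others, d, consp = _neighbourhood(dm, species, i)
    if others.size == 0:
        raise DataError("all_species_barcodes requires at least 2 records")

    def _out(category, match_ids, best):
        return IdentificationOutcome(
            record_id=record_id,
            criterion="ASB",
            category=category,
            best_match_ids=tuple(match_ids),
            best_distance=float(best),
        )

    nearest = np.nanmin(d[others])
    if nearest > threshold + EPSILON:
        return _out("NoMatch", (), nearest)
    con = others[consp[others]]
    allo = others[~consp[others]]
    if con.size == 0:
        tied = others[d[others] <= nearest + EPSILON]
        return _out("Incorrect", (dm.labels[j] for j in tied), nearest)
    d_con_max = float(np.nanmax(d[con]))
    con_ids = (dm.labels[j] for j in con)
    if allo.size:
        allo_min = float(np.nanmin(d[allo]))
        if allo_min < d_con_max - EPSILON:
            return _out("Incorrect", con_ids, d_con_max)
        if np.any(np.abs(d[allo] - d_con_max) <= EPSILON):
            return _out("Ambiguous", con_ids, d_con_max)
    if d_con_max <= threshold + EPSILON:
        return _out("Correct", con_ids, d_con_max)
    return _out("NoMatch", (), d_con_max)


def rollup_species(
    outcomes: list[IdentificationOutcome], ds: BarcodeDataset
) -> tuple[float, float]:
    """Species-level percentages: (correct species %, true species %).

    A species is Correct when at least one of its sequences is Correct; it is
    TRUE when at least one sequence is Correct and none is Incorrect or
    Ambiguous (NoMatch does not veto TRUE status).  Percentages are over all
    species in the dataset.
    """
    by_id = {r.record_id: r.species for r in ds}
    cats: dict[str, set[str]] = {}
    for o in outcomes:
        cats.setdefault(by_id[o.record_id], set()).add(o.category)
    all_species = set(ds.species_labels)
    if not all_species:
        return 0.0, 0.0
    n_correct = sum(1 for sp in all_species if "Correct" in cats.get(sp, set()))
    n_true = sum(
        1
        for sp in all_species
        if "Correct" in cats.get(sp, set())
        and not ({"Incorrect", "Ambiguous"} & cats.get(sp, set()))
    )
    total = len(all_species)
    return 100.0 * n_correct / total, 100.0 * n_true / total


def identify_all(
    dm: DistanceMatrix,
    ds: BarcodeDataset,
    criterion: str = "BM",
    threshold: float | None = 0.03,
) -> IdentificationReport:
    """Run one criterion over every record and roll up the report.

    ``threshold`` is required for BCM and ASB; it may be a fixed value (the
    3% convention) or the output of :func:`percentile_threshold` on
    :func:`intraspecific_distances`.
    """
    criterion = criterion.upper()
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    if criterion != "BM" and threshold is None:
        raise ValueError(f"{criterion} requires a threshold")
    species = _species_for(dm, ds)
    outcomes = []
    for record_id in dm.labels:
        if criterion == "BM":
            o = best_match(dm, ds, record_id, _species=species)
        elif criterion == "BCM":
            o = best_close_match(dm, ds, record_id, threshold, _species=species)
        else:
            o = all_species_barcodes(dm, ds, record_id, threshold, _species=species)
        outcomes.append(o)
    n = len(outcomes)
    counts = {c: 0 for c in CATEGORIES}
    for o in outcomes:
        counts[o.category] += 1
    species_correct, true_species = rollup_species(outcomes, ds)
    return IdentificationReport(
        criterion=criterion,
        threshold=None if criterion == "BM" else threshold,
        outcomes=outcomes,
        pct_correct=100.0 * counts["Correct"] / n,
        pct_incorrect=100.0 * counts["Incorrect"] / n,
        pct_ambiguous=100.0 * counts["Ambiguous"] / n,
        pct_nomatch=100.0 * counts["NoMatch"] / n,
        species_correct_pct=species_correct,
        true_species_pct=true_species,
    )
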