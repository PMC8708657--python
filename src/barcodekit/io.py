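"""Reading, writing, curating and summarizing species-labelled barcode FASTA.

A barcode record is one nucleotide sequence carrying a species label and an
accession id in its FASTA header.  The default header dialect is
``Species_name|accession`` with ``|`` as the field separator; other dialects
are expressed through :class:`LabelSpec`.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import DataError, DuplicateIdError, FastaParseError, HeaderError

GAP_CHARS = frozenset("-.")
#: characters that do not count toward barcode length
_NONCOUNTING = GAP_CHARS | {"N"}


@dataclass(frozen=True)
class LabelSpec:
    """How to split a FASTA header into (species, accession).

    ``fields`` names the role of each ``delimiter``-separated token, in
    order; it must contain ``"species"`` and ``"accession"`` exactly once.
    Extra tokens may be named anything (they are ignored).
    """

    delimiter: str = "|"
    fields: tuple[str, ...] = ("species", "accession")

    def __post_init__(self):
        for role in ("species", "accession"):
            if self.fields.count(role) != 1:
                raise ValueError(f"label spec must name {role!r} exactly once")

    def parse(self, header: str) -> tuple[str, str]:
        """Return ``(accession, species)`` parsed from a header line."""
        tokens = header.strip().split(self.delimiter)
        if len(tokens) < len(self.fields):
            raise HeaderError(
                f"header {header!r} does not match label spec "
                f"{self.delimiter.join(self.fields)!r}"
            )
        by_role = dict(zip(self.fields, tokens))
        return by_role["accession"], by_role["species"]

    def format(self, record: "BarcodeRecord") -> str:
        tokens = []
        for role in self.fields:
            if role == "species":
                tokens.append(record.species)
            elif role == "accession":
                tokens.append(record.record_id)
            else:
                tokens.append("")
        return self.delimiter.join(tokens)


@dataclass(frozen=True)
class BarcodeRecord:
    """One barcode sequence with its species label and accession."""

    record_id: str
    species: str
    marker: str
    sequence: str
    aligned: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise DataError(f"record {self.record_id!r}: empty sequence")
        if not self.species:
            raise DataError(f"record {self.record_id!r}: empty species label")

    @property
    def ungapped_length(self) -> int:
        """Sequence length excluding gap characters and N."""
        return sum(1 for c in self.sequence if c not in _NONCOUNTING)

    def degapped(self) -> str:
        """Sequence with gap characters removed (ambiguity codes kept)."""
        return "".join(c for c in self.sequence if c not in GAP_CHARS)


@dataclass
class BarcodeDataset:
    """An ordered collection of barcode records for one marker.

    Invariants enforced on construction: unique record ids; if ``aligned``,
    uniform sequence length.
    """

    records: list[BarcodeRecord]
    marker: str = ""
    aligned: bool = False

    def __post_init__(self):
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise DuplicateIdError(f"duplicate record id {rec.record_id!r}")
            seen.add(rec.record_id)
        if self.aligned and self.records:
            lengths = {len(r.sequence) for r in self.records}
            if len(lengths) > 1:
                raise DataError(
                    f"aligned dataset has unequal sequence lengths {sorted(lengths)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BarcodeRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> BarcodeRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    @property
    def species_labels(self) -> list[str]:
        return [r.species for r in self.records]

    def species_counts(self) -> dict[str, int]:
        return dict(collections.Counter(r.species for r in self.records))

    def subset(self, ids: Iterable[str]) -> "BarcodeDataset":
        keep = set(ids)
        return BarcodeDataset(
            [r for r in self.records if r.record_id in keep],
            marker=self.marker,
            aligned=self.aligned,
        )


def read_fasta(
    path: str | Path,
    marker: str = "",
    label_spec: LabelSpec | None = None,
    aligned: bool | str = "auto",
) -> BarcodeDataset:
    """Read a species-labelled FASTA file into a :class:`BarcodeDataset`.

    Sequences are uppercased and U is mapped to T.  ``aligned="auto"``
    marks the dataset aligned when every sequence has the same length;
    pass True/False to force.
    """
    label_spec = label_spec or LabelSpec()
    path = Path(path)
    _prescan_fasta(path)
    records: list[BarcodeRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, species = label_spec.parse(entry.description)
        seq = str(entry.seq).upper().replace("U", "T")
        records.append(
            BarcodeRecord(record_id=accession, species=species, marker=marker, sequence=seq)
        )
    if aligned == "auto":
        lengths = {len(r.sequence) for r in records}
        aligned = bool(records) and len(lengths) == 1
    if aligned:
        records = [replace(r, aligned=True) for r in records]
    return BarcodeDataset(records, marker=marker, aligned=bool(aligned))


def _prescan_fasta(path: Path) -> None:
    """Cheap validation pass so parse errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"expected FASTA header, got {stripped[:30]!r}", line=lineno
                )
            return  # first meaningful line is a header; SeqIO handles the rest


def write_fasta(
    ds: BarcodeDataset, path: str | Path, label_spec: LabelSpec | None = None
) -> None:
    """Write a dataset back to FASTA (one line per sequence)."""
    label_spec = label_spec or LabelSpec()
    with open(path, "w") as fh:
        for rec in ds:
            fh.write(f">{label_spec.format(rec)}\n{rec.sequence}\n")


def filter_min_length(ds: BarcodeDataset, min_len: int = 400) -> BarcodeDataset:
    """Keep records whose ungapped length is strictly greater than ``min_len``.

    Length counts non-gap, non-N characters ("more than" semantics: a record
    of exactly ``min_len`` bases is dropped).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return BarcodeDataset(
        [r for r in ds if r.ungapped_length > min_len],
        marker=ds.marker,
        aligned=ds.aligned,
    )


def filter_min_conspecifics(ds: BarcodeDataset, min_n: int = 3) -> BarcodeDataset:
    """Remove entirely any species represented by fewer than ``min_n`` records."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    counts = ds.species_counts()
    return BarcodeDataset(
        [r for r in ds if counts[r.species] >= min_n],
        marker=ds.marker,
        aligned=ds.aligned,
    )


def intersect_markers(
    ds1: BarcodeDataset, ds2: BarcodeDataset
) -> tuple[BarcodeDataset, BarcodeDataset]:
    """Restrict both datasets to the species present in each."""
    common = set(ds1.species_labels) & set(ds2.species_labels)
    out1 = BarcodeDataset(
        [r for r in ds1 if r.species in common], marker=ds1.marker, aligned=ds1.aligned
    )
    out2 = BarcodeDataset(
        [r for r in ds2 if r.species in common], marker=ds2.marker, aligned=ds2.aligned
    )
    return out1, out2


def dataset_summary(ds: BarcodeDataset) -> dict:
    """Descriptive counts: sequences, species, singletons, per-species histogram."""
    counts = ds.species_counts()
    histogram = dict(sorted(collections.Counter(counts.values()).items()))
    return {
        "n_sequences": len(ds),
        "n_species": len(counts),
        "n_singleton_species": sum(1 for c in counts.values() if c == 1),
        "records_per_species_histogram": histogram,
    }
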