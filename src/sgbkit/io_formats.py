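"""Sequence and catalog I/O.

FASTA and FASTQ parsing is delegated to Bio.SeqIO; this module adds the
validation the rest of the pipeline relies on: sequences restricted to
A/C/G/T/N (uppercased on read), non-empty sequences, unique ids per file,
Phred+33 qualities, and strictly-typed TSV catalogs of MAG metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import FormatError, SchemaError, ValidationError

VALID_BASES = frozenset("ACGTN")

#: Closed vocabulary of genome provenance labels. ``reference`` marks genomes
#: from public repositories; the others mark MAGs by host and lifestyle.
HOST_CATEGORIES = frozenset(
    {
        "nhp_wild",
        "nhp_captive",
        "human_westernized",
        "human_nonwesternized",
        "reference",
    }
)

CATALOG_COLUMNS = (
    "mag_id",
    "fasta_path",
    "dataset",
    "sample_id",
    "host_species",
    "host_category",
    "country",
    "completeness",
    "contamination",
)

SAMPLE_COLUMNS = ("sample_id", "dataset", "group_label", "n_raw_reads")


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: a genome, contig, or reference sequence."""

    id: str
    sequence: str
    description: str = ""


@dataclass(frozen=True)
class ReadRecord:
    """One FASTQ read with integer Phred quality scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else math.nan


@dataclass(frozen=True)
class MagCatalogEntry:
    """Provenance, lifestyle, and quality metadata for one genome."""

    mag_id: str
    fasta_path: str
    dataset: str
    sample_id: str
    host_species: str
    host_category: str
    country: str
    completeness: float
    contamination: float


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    dataset: str
    group_label: str
    n_raw_reads: int = 0


def _validate_sequence(seq_id: str, sequence: str) -> str:
    if not sequence:
        raise FormatError(f"record {seq_id!r} has an empty sequence")
    sequence = sequence.upper()
    bad = set(sequence) - VALID_BASES
    if bad:
        raise FormatError(
            f"record {seq_id!r} contains characters outside A/C/G/T/N: "
            f"{sorted(bad)}"
        )
    return sequence


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into validated, uppercased records.

    Raises :class:`FormatError` on malformed headers, empty sequences,
    non-ACGTN characters, or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id) :].strip()
            records.append(
                SequenceRecord(
                    id=rec.id,
                    sequence=_validate_sequence(rec.id, str(rec.seq)),
                    description=desc,
                )
            )
    except ValueError as exc:  # Bio.SeqIO signals syntax problems as ValueError
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(path: str | Path, records: Iterable[SequenceRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse a Phred+33 FASTQ file (4-line records)."""
    reads: list[ReadRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = tuple(rec.letter_annotations["phred_quality"])
            reads.append(
                ReadRecord(
                    id=rec.id,
                    sequence=_validate_sequence(rec.id, str(rec.seq)),
                    qualities=quals,
                )
            )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return reads


def write_fastq(path: str | Path, reads: Iterable[ReadRecord]) -> None:
    bio = []
    for read in reads:
        rec = _BioRecord(Seq(read.sequence), id=read.id, description="")
        rec.letter_annotations["phred_quality"] = list(read.qualities)
        bio.append(rec)
    SeqIO.write(bio, str(path), "fastq")


def _check_percent(name: str, value: float, mag_id: str) -> float:
    value = float(value)
    if math.isnan(value) or not 0.0 <= value <= 100.0:
        raise ValidationError(f"MAG {mag_id!r}: {name} {value} outside [0, 100]")
    return value


def read_catalog(path: str | Path) -> list[MagCatalogEntry]:
    """Read a TSV MAG catalog, validating schema, ranges, and uniqueness."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    entries: list[MagCatalogEntry] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        mag_id = row.mag_id
        if mag_id in seen:
            raise ValidationError(f"{path}: duplicate mag_id {mag_id!r}")
        seen.add(mag_id)
        if row.host_category not in HOST_CATEGORIES:
            raise ValidationError(
                f"MAG {mag_id!r}: host_category {row.host_category!r} not in "
                f"{sorted(HOST_CATEGORIES)}"
            )
        entries.append(
            MagCatalogEntry(
                mag_id=mag_id,
                fasta_path=row.fasta_path,
                dataset=row.dataset,
                sample_id=row.sample_id,
                host_species=row.host_species,
                host_category=row.host_category,
                country=row.country,
                completeness=_check_percent("completeness", row.completeness, mag_id),
                contamination=_check_percent("contamination", row.contamination, mag_id),
            )
        )
    return entries


def write_catalog(path: str | Path, entries: Sequence[MagCatalogEntry]) -> None:
    df = pd.DataFrame([e.__dict__ for e in entries], columns=list(CATALOG_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    samples: list[SampleMetadata] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.sample_id in seen:
            raise ValidationError(f"{path}: duplicate sample_id {row.sample_id!r}")
        seen.add(row.sample_id)
        samples.append(
            SampleMetadata(
                sample_id=row.sample_id,
                dataset=row.dataset,
                group_label=row.group_label,
                n_raw_reads=int(row.n_raw_reads),
            )
        )
    return samples


def write_sample_metadata(path: str | Path, samples: Sequence[SampleMetadata]) -> None:
    df = pd.DataFrame([s.__dict__ for s in samples], columns=list(SAMPLE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)
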