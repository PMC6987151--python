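"""Shared sequence and feature data model, with FASTA / feature-table I/O.

Conventions used throughout the package:

* All genomic and feature coordinates are **1-based inclusive**, the
  convention in which restriction-site positions, flank coordinate ranges
  and element maps are printed in molecular-characterization reports.
  BED export converts to 0-based half-open on the way out only.
* DNA records may contain ``A C G T N``; ``N`` never matches any
  recognition site or k-mer downstream.  Other ambiguity codes are
  rejected at parse time so that digest and scan results are
  deterministic.
* Protein records use the 20 standard residues plus ``X``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import AlphabetError, DataError, DuplicateIdError, FastaError

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Alphabet = Literal["dna", "protein"]
Topology = Literal["linear", "circular"]


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over a declared alphabet.

    ``topology`` is meaningful for DNA only (plasmids are circular,
    assembled event sequences and genomic loci linear); protein records
    must leave it as ``None``.
    """

    id: str
    residues: str
    alphabet: Alphabet = "dna"
    topology: Topology | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("sequence record requires a non-empty id")
        if not self.residues:
            raise DataError(f"record {self.id!r}: empty sequence")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: illegal {self.alphabet} residues {sorted(bad)}"
            )
        if self.alphabet == "dna":
            if self.topology is None:
                object.__setattr__(self, "topology", "linear")
        elif self.topology is not None:
            raise DataError(f"record {self.id!r}: topology is defined for DNA only")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


@dataclass(frozen=True)
class FeatureAnnotation:
    """A named element on a parent sequence (1-based inclusive span)."""

    name: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DataError(
                f"feature {self.name!r}: require 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise DataError(f"feature {self.name!r}: strand must be '+' or '-'")

    def validate_against(self, seq: SequenceRecord) -> None:
        if self.end > len(seq):
            raise DataError(
                f"feature {self.name!r} ends at {self.end}, beyond "
                f"{seq.id!r} length {len(seq)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named reference sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(
                f"interval {self.chrom}:{self.start}-{self.end}: start > end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval (``end - start + 1``)."""
    return iv.length


def gap_between(left: GenomicInterval, right: GenomicInterval) -> int:
    """Number of reference bases strictly between two ordered intervals.

    This is how a host deletion at an insertion locus is read off the two
    flank anchor ranges: bases that belong to neither flank.
    """
    if left.chrom != right.chrom:
        raise DataError("gap_between requires intervals on the same reference")
    if right.start <= left.end:
        raise DataError("intervals must be ordered and non-overlapping")
    return right.start - left.end - 1


def revcomp(seq: SequenceRecord) -> SequenceRecord:
    """Reverse complement of a DNA record (involution)."""
    if seq.alphabet != "dna":
        raise AlphabetError(f"revcomp requires a DNA record, got {seq.alphabet}")
    return SequenceRecord(
        id=seq.id,
        residues=revcomp_str(seq.residues),
        alphabet="dna",
        topology=seq.topology,
    )


def revcomp_str(residues: str) -> str:
    """Reverse complement of a raw DNA string (A<->T, C<->G, N->N)."""
    return residues.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, alphabet: Alphabet = "dna") -> list[SequenceRecord]:
    """Read a multi-record FASTA file into validated records.

    Residues are uppercased; record order is preserved.  Raises
    :class:`FastaError` on an empty file, :class:`DuplicateIdError` on a
    repeated id and :class:`AlphabetError` on illegal residues.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"no such FASTA file: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        if bio_rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate record id {bio_rec.id!r}")
        seen.add(bio_rec.id)
        try:
            records.append(
                SequenceRecord(
                    id=bio_rec.id,
                    residues=str(bio_rec.seq).upper(),
                    alphabet=alphabet,
                )
            )
        except DataError as exc:
            raise FastaError(f"{path}: {exc}") from exc
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (inverse of :func:`read_fasta`)."""
    bio_records = [
        _BioSeqRecord(Seq(rec.residues), id=rec.id, description="") for rec in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio_records)


def read_feature_table(path: str | Path) -> list[FeatureAnnotation]:
    """Read a feature table: TSV with columns name, start, end, strand.

    Lines starting with ``#`` are comments; a header line beginning with
    ``name`` is skipped.
    """
    features: list[FeatureAnnotation] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "name":
            continue
        if len(parts) < 4:
            raise DataError(f"{path}:{lineno}: expected 4 tab-separated columns")
        try:
            features.append(
                FeatureAnnotation(parts[0], int(parts[1]), int(parts[2]), parts[3])
            )
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: {exc}") from exc
    return features


def write_feature_table(features: Iterable[FeatureAnnotation], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("name\tstart\tend\tstrand\n")
        for feat in features:
            handle.write(f"{feat.name}\t{feat.start}\t{feat.end}\t{feat.strand}\n")


def features_to_bed(
    features: Iterable[FeatureAnnotation], chrom: str, path: str | Path
) -> None:
    """Export features as BED (0-based half-open; conversion happens here only)."""
    with open(path, "w") as handle:
        for feat in features:
            handle.write(
                f"{chrom}\t{feat.start - 1}\t{feat.end}\t{feat.name}\t0\t{feat.strand}\n"
            )
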