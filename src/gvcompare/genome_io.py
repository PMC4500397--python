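"""Genome sequence I/O and circular-coordinate arithmetic.

Granulovirus genomes are covalently closed circles of ~80-180 kb; every
coordinate in this package is 1-based inclusive on the forward strand, with
position 1 anchored (by convention) at the first nucleotide of the granulin
start codon.  This module holds the sequence container, composition
statistics, and the wrap-aware subsequence extraction the rest of the
pipeline builds on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularGenome",
    "GenomeStats",
    "GenomeIOError",
    "read_genome",
    "write_fasta",
    "gc_content",
    "reverse_complement",
    "circular_subsequence",
    "genome_stats",
]

_ALPHABET = set("ACGTN")


class GenomeIOError(ValueError):
    """Raised for malformed sequence input (empty, multi-record, bad alphabet)."""


@dataclass
class CircularGenome:
    """A closed (or optionally linear) double-stranded DNA genome.

    The sequence is stored upper-case over {A,C,G,T,N}; ``topology`` controls
    whether coordinate arithmetic may wrap through the origin.
    """

    id: str
    seq: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise GenomeIOError(f"genome {self.id!r}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise GenomeIOError(f"genome {self.id!r}: bad topology {self.topology!r}")
        bad = set(self.seq) - _ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.seq, start=1) if c in bad)
            raise GenomeIOError(
                f"genome {self.id!r}: illegal character {self.seq[pos - 1]!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


@dataclass(frozen=True)
class GenomeStats:
    gc_fraction: float
    at_fraction: float
    length: int


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise GenomeIOError(f"illegal character(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N excluded from the denominator.

    Raises on an empty sequence or one with no unambiguous bases.
    """
    seq = seq.upper()
    denom = sum(seq.count(c) for c in "ACGT")
    if denom == 0:
        raise GenomeIOError("gc_content of empty / all-ambiguous sequence is undefined")
    return (seq.count("G") + seq.count("C")) / denom


def genome_stats(genome: CircularGenome) -> GenomeStats:
    gc = gc_content(genome.seq)
    return GenomeStats(gc_fraction=gc, at_fraction=1.0 - gc, length=genome.length)


def read_genome(path: str | Path, format: str = "fasta", topology: str | None = None) -> CircularGenome:
    """Read a single-record FASTA or GenBank file as a :class:`CircularGenome`.

    GenBank LOCUS topology is honored when present; otherwise ``topology``
    (default circular) applies.  Multi-record files are rejected: the unit of
    analysis here is one genome.
    """
    path = Path(path)
    if format not in ("fasta", "genbank"):
        raise GenomeIOError(f"unsupported format {format!r}")
    records = list(SeqIO.parse(str(path), format))
    if len(records) == 0:
        raise GenomeIOError(f"{path}: no sequence records found")
    if len(records) > 1:
        raise GenomeIOError(
            f"{path}: expected exactly one record, found {len(records)} "
            f"(first extras: {records[1].id})"
        )
    rec = records[0]
    topo = topology
    if format == "genbank" and topo is None:
        topo = rec.annotations.get("topology")
    if topo not in ("circular", "linear"):
        topo = "circular"
    return CircularGenome(id=rec.id, seq=str(rec.seq), topology=topo)


def write_fasta(records: Iterable[tuple[str, str]] | CircularGenome, path: str | Path, wrap: int = 70) -> None:
    """Write (id, seq) pairs or a genome as wrapped FASTA."""
    if isinstance(records, CircularGenome):
        records = [(records.id, records.seq)]
    seq_records = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


def circular_subsequence(genome: CircularGenome, start: int, end: int, strand: str = "+") -> str:
    """Extract the 1-based inclusive subsequence [start, end].

    When ``start > end`` on a circular genome the extraction wraps through the
    origin (positions start..L then 1..end).  ``strand == '-'`` returns the
    reverse complement of the forward-strand extraction.
    """
    L = genome.length
    if not (1 <= start <= L and 1 <= end <= L):
        raise GenomeIOError(
            f"coordinates ({start}, {end}) out of range for genome of length {L}"
        )
    if strand not in ("+", "-"):
        raise GenomeIOError(f"bad strand {strand!r}")
    if start <= end:
        sub = genome.seq[start - 1 : end]
    else:
        if not genome.is_circular:
            raise GenomeIOError(
                f"wrap-around extraction ({start} > {end}) requested on linear genome {genome.id!r}"
            )
        sub = genome.seq[start - 1 :] + genome.seq[:end]
    return reverse_complement(sub) if strand == "-" else sub


def rotate_genome(genome: CircularGenome, new_origin: int) -> CircularGenome:
    """Rotate a circular genome so 1-based position ``new_origin`` becomes nt 1."""
    if not genome.is_circular:
        raise GenomeIOError(f"cannot rotate linear genome {genome.id!r}")
    if not (1 <= new_origin <= genome.length):
        raise GenomeIOError(f"rotation origin {new_origin} out of range")
    k = new_origin - 1
    return CircularGenome(id=genome.id, seq=genome.seq[k:] + genome.seq[:k], topology="circular")
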