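"""Circular-genome ORF annotation.

Baculovirus genomes are annotated by a simple, explicit convention: every
methionine-initiated ORF of at least a minimum length (default 150 nt,
stop codon included) on either strand is a candidate, candidates are pruned
to a minimally-overlapping set, and the surviving ORFs are numbered 1..n
around the circle starting at an anchor gene (granulin), whose start codon
defines genome position 1 on the forward strand.

Internally every ORF carries a 0-based forward-strand span start
(``fwd_start``) and a length; the span may wrap through the origin.  The
published coordinate pair (start = A of ATG, end = last base of the stop
codon) is derived from the span and the strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .genome_io import CircularGenome, reverse_complement

__all__ = [
    "AnnotationConfig",
    "OrfRecord",
    "GenomeAnnotation",
    "AnnotationStats",
    "AnnotationError",
    "enumerate_candidate_orfs",
    "resolve_minimal_overlap",
    "anchor_and_number",
    "annotation_stats",
    "annotate",
    "write_gff3",
    "write_protein_fasta",
]

_STOPS = {"TAA", "TAG", "TGA"}


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationConfig:
    """Selection rules for ORF calling.

    min_orf_nt counts the stop codon (150 nt => 49 aa + stop).
    max_overlap_fraction caps the pairwise nucleotide overlap between two
    retained ORFs at that fraction of the shorter one.
    """

    min_orf_nt: int = 150
    max_overlap_fraction: float = 0.5
    allow_wraparound: bool = True
    genetic_code: int = 1
    all_starts: bool = False  # enumerate every internal ATG, not just the first

    def __post_init__(self) -> None:
        if self.min_orf_nt < 3 or self.min_orf_nt % 3 != 0:
            raise AnnotationError("min_orf_nt must be >= 3 and divisible by 3")
        if not (0.0 <= self.max_overlap_fraction <= 1.0):
            raise AnnotationError("max_overlap_fraction must be in [0, 1]")


@dataclass(frozen=True)
class OrfRecord:
    """A positioned, stranded coding feature on a circular genome.

    ``start`` is the 1-based position of the A of the ATG; ``end`` the last
    base of the stop codon.  On the '-' strand start > end numerically (the
    ORF reads counterclockwise).  ``fwd_start`` is the 0-based leftmost
    forward-strand coordinate of the covered span, which together with
    ``length_nt`` defines the (possibly wrapping) interval.
    """

    orf_id: int
    start: int
    end: int
    strand: str
    length_nt: int
    length_aa: int
    protein: str
    fwd_start: int

    def span_pieces(self, genome_len: int) -> list[tuple[int, int]]:
        """The covered span as 0-based half-open linear intervals (1 or 2 pieces)."""
        i, l = self.fwd_start, self.length_nt
        if i + l <= genome_len:
            return [(i, i + l)]
        return [(i, genome_len), (0, i + l - genome_len)]

    @property
    def left(self) -> int:
        """1-based leftmost forward coordinate of the span (sort key)."""
        return self.fwd_start + 1


def _overlap_nt(a: OrfRecord, b: OrfRecord, genome_len: int) -> int:
    total = 0
    for s1, e1 in a.span_pieces(genome_len):
        for s2, e2 in b.span_pieces(genome_len):
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _coords_from_span(fwd_start: int, length_nt: int, strand: str, L: int) -> tuple[int, int]:
    if strand == "+":
        start = fwd_start + 1
        end = (fwd_start + length_nt - 1) % L + 1
    else:
        start = (fwd_start + length_nt - 1) % L + 1
        end = fwd_start + 1
    return start, end


def _make_record(fwd_start: int, length_nt: int, strand: str, genome: CircularGenome,
                 genetic_code: int, orf_id: int = 0) -> OrfRecord:
    L = genome.length
    start, end = _coords_from_span(fwd_start, length_nt, strand, L)
    doubled = genome.seq + genome.seq
    nt = doubled[fwd_start : fwd_start + length_nt]
    if strand == "-":
        nt = reverse_complement(nt)
    protein = str(Seq(nt[:-3]).translate(table=genetic_code))
    return OrfRecord(
        orf_id=orf_id, start=start, end=end, strand=strand,
        length_nt=length_nt, length_aa=length_nt // 3 - 1,
        protein=protein, fwd_start=fwd_start,
    )


def _scan_oriented(seq: str, circular: bool, min_nt: int, all_starts: bool) -> list[tuple[int, int]]:
    """Scan one orientation; return (pos0 mod L, length_nt) in scan coordinates.

    On a circle the sequence is tripled so that for every locus some copy of
    its preceding in-frame stop falls in the first third with the full ORF
    downstream of it in range; results are deduplicated modulo L by the
    caller.  Only segments between *real* stops yield ORFs on a circle (a
    leading segment has unknown upstream context); on a linear molecule the
    leading segment counts, with a virtual stop before the first codon.
    Degenerate ORFs longer than the genome are rejected.
    """
    L = len(seq)
    s = seq * 3 if circular else seq
    n = len(s)
    found: list[tuple[int, int]] = []
    for frame in range(3):
        stops = [p for p in range(frame, n - 2, 3) if s[p : p + 3] in _STOPS]
        bounds = stops if circular else [frame - 3] + stops
        for prev, nxt in zip(bounds, stops[1:] if circular else stops):
            seg_start = prev + 3
            if nxt <= seg_start:
                continue
            atgs = [p for p in range(seg_start, nxt, 3) if s[p : p + 3] == "ATG"]
            if not atgs:
                continue
            starts = atgs if all_starts else atgs[:1]
            for a in starts:
                length = nxt + 3 - a
                if length < min_nt or (circular and length > L):
                    continue
                found.append((a % L, length))
    return found


def enumerate_candidate_orfs(genome: CircularGenome, config: AnnotationConfig | None = None) -> list[OrfRecord]:
    """All maximal ATG-initiated ORFs >= min length, both strands, all frames.

    "Maximal" follows the one-ORF-per-locus convention: the first in-frame
    ATG after the preceding in-frame stop, through the next in-frame stop.
    Set ``config.all_starts`` to enumerate every internal ATG instead.
    """
    config = config or AnnotationConfig()
    L = genome.length
    circular = genome.is_circular and config.allow_wraparound
    if L < config.min_orf_nt:
        return []
    records: dict[tuple[str, int, int], OrfRecord] = {}
    for strand in ("+", "-"):
        oriented = genome.seq if strand == "+" else reverse_complement(genome.seq)
        for p, l in _scan_oriented(oriented, circular, config.min_orf_nt, config.all_starts):
            fwd_start = p if strand == "+" else (L - p - l) % L
            key = (strand, fwd_start % L, l)
            if key not in records:
                records[key] = _make_record(fwd_start % L, l, strand, genome, config.genetic_code)
    out = sorted(records.values(), key=lambda r: (r.fwd_start, r.strand, -r.length_nt))
    return [replace(r, orf_id=i + 1) for i, r in enumerate(out)]


def resolve_minimal_overlap(candidates: Sequence[OrfRecord], config: AnnotationConfig | None = None,
                            genome_len: int | None = None) -> list[OrfRecord]:
    """Greedy longest-first selection under a pairwise overlap cap.

    A candidate is kept iff its overlap with every already-kept ORF is at
    most ``max_overlap_fraction`` of the shorter of the two.  Ties in length
    break by smaller start, then '+' strand.  Output is ordered by leftmost
    span coordinate.
    """
    config = config or AnnotationConfig()
    if not candidates:
        return []
    if genome_len is None:
        genome_len = max(c.fwd_start + c.length_nt for c in candidates)
    order = sorted(candidates, key=lambda r: (-r.length_nt, r.start, 0 if r.strand == "+" else 1))
    kept: list[OrfRecord] = []
    for cand in order:
        ok = True
        for acc in kept:
            cap = config.max_overlap_fraction * min(cand.length_nt, acc.length_nt)
            if _overlap_nt(cand, acc, genome_len) > cap:
                ok = False
                break
        if ok:
            kept.append(cand)
    kept.sort(key=lambda r: (r.fwd_start, 0 if r.strand == "+" else 1))
    return [replace(r, orf_id=i + 1) for i, r in enumerate(kept)]


@dataclass
class GenomeAnnotation:
    """An anchored, numbered ORF set on a circular genome."""

    genome: CircularGenome
    orfs: list[OrfRecord]
    anchor_orf_id: int | None = None
    coding_fraction: float = field(init=False)
    overlaps: list[tuple[int, int, int]] = field(init=False)

    def __post_init__(self) -> None:
        stats = annotation_stats(self, _partial=True)
        self.coding_fraction = stats.coding_fraction
        self.overlaps = stats.adjacent_overlaps

    def orf(self, orf_id: int) -> OrfRecord:
        for r in self.orfs:
            if r.orf_id == orf_id:
                return r
        raise AnnotationError(f"no ORF with id {orf_id}")


@dataclass(frozen=True)
class AnnotationStats:
    n_orfs: int
    n_plus: int
    n_minus: int
    coding_fraction: float
    adjacent_overlaps: list[tuple[int, int, int]]


def anchor_and_number(orfs: Sequence[OrfRecord], genome: CircularGenome, anchor: OrfRecord,
                      genetic_code: int = 1) -> GenomeAnnotation:
    """Rotate (and flip if needed) so the anchor's ATG is nt 1 on '+', renumber 1..n."""
    if anchor not in orfs:
        raise AnnotationError("anchor ORF is not among the selected ORFs")
    L = genome.length
    seq = genome.seq
    flip = anchor.strand == "-"
    if flip:
        seq = reverse_complement(seq)
    # anchor span start after the optional flip; on '-' the ATG sits at the
    # rightmost span position, which the flip moves to the span start
    a_fwd = anchor.fwd_start
    if flip:
        a_fwd = (L - (anchor.fwd_start + anchor.length_nt)) % L
    rotated = CircularGenome(id=genome.id, seq=seq[a_fwd:] + seq[:a_fwd], topology=genome.topology)
    new_orfs = []
    for r in orfs:
        fwd, strand = r.fwd_start, r.strand
        if flip:
            fwd = (L - (fwd + r.length_nt)) % L
            strand = "-" if strand == "+" else "+"
        fwd = (fwd - a_fwd) % L
        new_orfs.append(_make_record(fwd, r.length_nt, strand, rotated, genetic_code, r.orf_id))
    new_orfs.sort(key=lambda r: (r.fwd_start, 0 if r.strand == "+" else 1))
    new_orfs = [replace(r, orf_id=i + 1) for i, r in enumerate(new_orfs)]
    anchor_id = next(r.orf_id for r in new_orfs if r.fwd_start == 0 and r.strand == "+"
                     and r.length_nt == anchor.length_nt)
    return GenomeAnnotation(genome=rotated, orfs=new_orfs, anchor_orf_id=anchor_id)


def annotation_stats(annot: GenomeAnnotation, _partial: bool = False) -> AnnotationStats:
    """Orientation counts, span-union coding fraction, adjacent-overlap list.

    Adjacent overlaps are computed between consecutive ORFs in anchored order,
    including the circular last-first pair.
    """
    L = annot.genome.length
    orfs = annot.orfs
    covered = np.zeros(L, dtype=bool)
    for r in orfs:
        for s, e in r.span_pieces(L):
            covered[s:e] = True
    coding_fraction = float(covered.sum()) / L if orfs else 0.0
    adjacent: list[tuple[int, int, int]] = []
    n = len(orfs)
    for i in range(n):
        a, b = orfs[i], orfs[(i + 1) % n]
        if n == 1 or (n == 2 and i == 1):
            break
        ov = _overlap_nt(a, b, L)
        if ov > 0:
            adjacent.append((a.orf_id, b.orf_id, ov))
    return AnnotationStats(
        n_orfs=n,
        n_plus=sum(1 for r in orfs if r.strand == "+"),
        n_minus=sum(1 for r in orfs if r.strand == "-"),
        coding_fraction=coding_fraction,
        adjacent_overlaps=adjacent,
    )


def annotate(genome: CircularGenome, config: AnnotationConfig | None = None,
             anchor: OrfRecord | None = None,
             rescue: Sequence[OrfRecord] = ()) -> GenomeAnnotation:
    """End-to-end annotation: enumerate, prune overlaps, optionally anchor.

    ``rescue`` forces sub-threshold ORFs (e.g. ones with known homologs) into
    the selected set after pruning.  Without an anchor the genome keeps its
    input coordinate frame and numbering starts from the leftmost ORF.
    """
    config = config or AnnotationConfig()
    cands = enumerate_candidate_orfs(genome, config)
    selected = resolve_minimal_overlap(cands, config, genome.length)
    if rescue:
        have = {(r.strand, r.fwd_start, r.length_nt) for r in selected}
        extra = [r for r in rescue if (r.strand, r.fwd_start, r.length_nt) not in have]
        selected = sorted(selected + list(extra), key=lambda r: (r.fwd_start, 0 if r.strand == "+" else 1))
        selected = [replace(r, orf_id=i + 1) for i, r in enumerate(selected)]
    if anchor is not None:
        match = [r for r in selected if (r.strand, r.fwd_start, r.length_nt)
                 == (anchor.strand, anchor.fwd_start, anchor.length_nt)]
        if not match:
            raise AnnotationError("anchor ORF not present in the selected set")
        return anchor_and_number(selected, genome, match[0], config.genetic_code)
    return GenomeAnnotation(genome=genome, orfs=selected,
                            anchor_orf_id=selected[0].orf_id if selected else None)


def write_gff3(annot: GenomeAnnotation, path: str | Path) -> None:
    """GFF3 CDS features, 1-based inclusive; origin-spanning ORFs emit two lines sharing an ID."""
    L = annot.genome.length
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annot.genome.id} 1 {L}\n")
        for r in annot.orfs:
            pieces = r.span_pieces(L)
            for s, e in pieces:
                attrs = f"ID=orf{r.orf_id};Name=orf{r.orf_id}"
                fh.write("\t".join([
                    annot.genome.id, "gvcompare", "CDS", str(s + 1), str(e),
                    ".", r.strand, "0", attrs,
                ]) + "\n")


def write_protein_fasta(annot: GenomeAnnotation, path: str | Path) -> None:
    from .genome_io import write_fasta

    write_fasta([(f"{annot.genome.id}|orf{r.orf_id}", r.protein) for r in annot.orfs], path)


def write_overlap_table(annot: GenomeAnnotation, path: str | Path) -> None:
    """TSV of adjacent-ORF overlaps (anchored order, circular pair included)."""
    import pandas as pd

    st = annotation_stats(annot)
    pd.DataFrame(st.adjacent_overlaps, columns=["orf_a", "orf_b", "overlap_nt"]).to_csv(
        path, sep="\t", index=False)
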