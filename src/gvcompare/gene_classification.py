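"""Protein homology, ortholog mapping, and gene-class assignment.

Baculovirus comparative genomics groups each predicted protein into nested
conservation classes: the 37 gene families found in every sequenced
baculovirus ("core"), 25 families shared by all lepidopteran baculoviruses,
19 families specific to the genus Betabaculovirus, genes with homologs
elsewhere in the family, and genes unique to the genome at hand.  Class
calls rest on exact affine-gap pairwise alignment (Smith-Waterman /
Needleman-Wunsch under BLOSUM62, gap open 11 / extend 1) rather than a
heuristic database search: at the scale of a viral proteome the exact DP is
fast, deterministic, and directly checkable against an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .orf_annotation import GenomeAnnotation

__all__ = [
    "HomologyHit",
    "ProteinPanel",
    "OrthologTable",
    "GeneClassTable",
    "ClassificationError",
    "align_protein_pair",
    "alignment_score",
    "ortholog_map",
    "classify_genes",
    "read_panel",
    "CLASS_PRIORITY",
]

CLASS_PRIORITY = ("core", "lepidopteran_shared", "beta_specific", "other_homolog")

_PANEL_CLASS = {
    "core37": "core",
    "lepidopteran25": "lepidopteran_shared",
    "beta19": "beta_specific",
    "other": "other_homolog",
}


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    identity_pct: float
    aligned_cols: int
    score: float


@dataclass
class ProteinPanel:
    """A reference gene set: amino-acid sequences grouped by gene family.

    FASTA ids use ``family|member`` syntax; all members with the same family
    prefix count as one family for presence/absence purposes.
    """

    panel_id: str
    members: dict[str, dict[str, str]]  # family -> member name -> sequence

    def __post_init__(self) -> None:
        for fam, mem in self.members.items():
            for name, seq in mem.items():
                if not seq:
                    raise ClassificationError(f"panel {self.panel_id}: empty sequence {fam}|{name}")

    @property
    def families(self) -> list[str]:
        return list(self.members)

    @property
    def gene_class(self) -> str:
        return _PANEL_CLASS.get(self.panel_id, "other_homolog")


def read_panel(path: str | Path, panel_id: str) -> ProteinPanel:
    members: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" in rec.id:
            family, member = rec.id.split("|", 1)
        else:
            family, member = rec.id, rec.id
        members.setdefault(family, {})[member] = str(rec.seq).upper()
    if not members:
        raise ClassificationError(f"{path}: empty panel")
    return ProteinPanel(panel_id=panel_id, members=members)


def _aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_protein_pair(a: str, b: str, mode: str = "global",
                       query_id: str = "query", subject_id: str = "subject") -> HomologyHit:
    """Exact affine-gap pairwise alignment; identity over all aligned columns.

    Gap columns are included in the identity denominator (the conservative
    convention).  ``mode`` selects Needleman-Wunsch ("global") or
    Smith-Waterman ("local").
    """
    if not a or not b:
        raise ClassificationError("cannot align empty protein sequence")
    if mode not in ("global", "local"):
        raise ClassificationError(f"bad alignment mode {mode!r}")
    aln = _aligner(mode).align(a.upper(), b.upper())[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    if cols == 0:
        return HomologyHit(query_id, subject_id, 0.0, 0, float(aln.score))
    return HomologyHit(
        query_id=query_id, subject_id=subject_id,
        identity_pct=100.0 * counts.identities / cols,
        aligned_cols=cols, score=float(aln.score),
    )


def alignment_score(a: str, b: str, mode: str = "local") -> float:
    """Alignment score only (faster than building the full alignment)."""
    if not a or not b:
        raise ClassificationError("cannot align empty protein sequence")
    return float(_aligner(mode).score(a.upper(), b.upper()))


@dataclass
class OrthologTable:
    """One-to-one reciprocal-best-hit pairs between two annotated genomes."""

    genome_a: str
    genome_b: str
    pairs: list[tuple[int, int, float]]  # (orf_id_a, orf_id_b, score)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["orf_a", "orf_b", "score"])

    def transposed(self) -> "OrthologTable":
        return OrthologTable(self.genome_b, self.genome_a,
                             [(b, a, s) for a, b, s in self.pairs])


def ortholog_map(annot_a: GenomeAnnotation, annot_b: GenomeAnnotation,
                 min_score: float = 50.0) -> OrthologTable:
    """Reciprocal-best-hit ortholog pairing by local alignment score.

    (i, j) is a pair iff j is i's single best-scoring hit, i is j's, and the
    score reaches ``min_score``.  Ties for best hit break by smaller ORF id,
    keeping the mapping deterministic and one-to-one.
    """
    name_a, name_b = annot_a.genome.id, annot_b.genome.id
    if not annot_a.orfs or not annot_b.orfs:
        return OrthologTable(name_a, name_b, [])
    aligner = _aligner("local")
    scores: dict[tuple[int, int], float] = {}
    for ra in annot_a.orfs:
        for rb in annot_b.orfs:
            scores[(ra.orf_id, rb.orf_id)] = float(aligner.score(ra.protein, rb.protein))
    best_for_a = {
        ra.orf_id: max(annot_b.orfs, key=lambda rb: (scores[(ra.orf_id, rb.orf_id)], -rb.orf_id)).orf_id
        for ra in annot_a.orfs
    }
    best_for_b = {
        rb.orf_id: max(annot_a.orfs, key=lambda ra: (scores[(ra.orf_id, rb.orf_id)], -ra.orf_id)).orf_id
        for rb in annot_b.orfs
    }
    pairs = []
    for i, j in best_for_a.items():
        if best_for_b[j] == i and scores[(i, j)] >= min_score:
            pairs.append((i, j, scores[(i, j)]))
    pairs.sort()
    return OrthologTable(name_a, name_b, pairs)


@dataclass
class GeneClassTable:
    """Per-ORF class labels plus per-panel family presence/absence."""

    labels: dict[int, str]  # orf_id -> class
    best_hits: dict[int, HomologyHit | None]
    family_presence: dict[str, dict[str, bool]]  # panel_id -> family -> present

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CLASS_PRIORITY + ("unique",)}
        for label in self.labels.values():
            out[label] += 1
        return out

    def n_present(self, panel_id: str) -> int:
        return sum(self.family_presence.get(panel_id, {}).values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for orf_id, label in sorted(self.labels.items()):
            hit = self.best_hits[orf_id]
            rows.append({
                "orf_id": orf_id, "gene_class": label,
                "best_family": hit.subject_id if hit else "",
                "score": hit.score if hit else 0.0,
                "identity_pct": round(hit.identity_pct, 1) if hit else 0.0,
            })
        return pd.DataFrame(rows)


def classify_genes(annot: GenomeAnnotation, panels: Sequence[ProteinPanel],
                   min_score: float = 50.0) -> GeneClassTable:
    """Assign each ORF to the highest-priority panel with a hit >= min_score.

    Priority: core > lepidopteran_shared > beta_specific > other_homolog;
    ORFs with no qualifying hit anywhere are "unique".  Family presence is
    reported per panel regardless of which class an ORF ends up in.
    """
    panel_order = sorted(
        panels,
        key=lambda p: CLASS_PRIORITY.index(p.gene_class) if p.gene_class in CLASS_PRIORITY else 99,
    )
    aligner = _aligner("local")
    labels: dict[int, str] = {}
    best_hits: dict[int, HomologyHit | None] = {}
    presence: dict[str, dict[str, bool]] = {
        p.panel_id: {fam: False for fam in p.families} for p in panels
    }
    for orf in annot.orfs:
        assigned = None
        best_hit = None
        for panel in panel_order:
            panel_best: tuple[float, str, str] | None = None
            for family, members in panel.members.items():
                for member, seq in members.items():
                    score = float(aligner.score(orf.protein, seq))
                    if score >= min_score:
                        presence[panel.panel_id][family] = True
                        if panel_best is None or score > panel_best[0]:
                            panel_best = (score, family, member)
            if panel_best is not None and assigned is None:
                assigned = panel.gene_class
                score, family, member = panel_best
                best_hit = align_protein_pair(
                    orf.protein, panel.members[family][member], mode="local",
                    query_id=f"orf{orf.orf_id}", subject_id=family,
                )
        labels[orf.orf_id] = assigned or "unique"
        best_hits[orf.orf_id] = best_hit
    return GeneClassTable(labels=labels, best_hits=best_hits, family_presence=presence)
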