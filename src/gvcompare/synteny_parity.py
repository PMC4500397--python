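"""Gene parity plots, collinearity scoring, and inversion detection.

A gene parity plot places each ortholog pair at (rank in genome A, rank in
genome B), where rank is the ordinal position of the ORF in its anchored
annotation.  Collinear genomes trace the diagonal; an inverted genome
segment traces an anti-diagonal run.  Because both genomes are circles the
rank origin is aligned at the shared anchor gene (the granulin homolog)
when it is present in both genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .gene_classification import OrthologTable
from .orf_annotation import GenomeAnnotation

__all__ = [
    "ParityData",
    "InversionSegment",
    "ParityError",
    "parity_coordinates",
    "collinearity_score",
    "detect_inversions",
    "plot_parity",
]


class ParityError(ValueError):
    pass


@dataclass
class ParityData:
    pairs: list[tuple[int, int, bool]]  # (rank_a, rank_b, same_strand)
    n_a: int
    n_b: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["rank_a", "rank_b", "same_strand"])


@dataclass(frozen=True)
class InversionSegment:
    a_start_rank: int
    a_end_rank: int
    n_pairs: int
    span_nt: int
    direction: str = "reversed"


def _ranks(annot: GenomeAnnotation) -> dict[int, int]:
    """orf_id -> ordinal rank (1-based) in annotation order."""
    return {r.orf_id: i + 1 for i, r in enumerate(annot.orfs)}


def parity_coordinates(orthologs: OrthologTable, annot_a: GenomeAnnotation,
                       annot_b: GenomeAnnotation) -> ParityData:
    """Ortholog pairs as rank coordinates with aligned circular origins.

    If the pair containing genome A's rank-1 ORF (the anchor) exists, genome
    B's ranks are rotated so that pair sits at (1, 1); otherwise the rotation
    minimizing the summed circular rank displacement is chosen (smallest
    rotation on ties), which keeps the plot deterministic for unanchored
    inputs.
    """
    rank_a = _ranks(annot_a)
    rank_b = _ranks(annot_b)
    strand_a = {r.orf_id: r.strand for r in annot_a.orfs}
    strand_b = {r.orf_id: r.strand for r in annot_b.orfs}
    n_a, n_b = len(annot_a.orfs), len(annot_b.orfs)
    raw: list[tuple[int, int, bool]] = []
    for ida, idb, _score in orthologs.pairs:
        if ida not in rank_a or idb not in rank_b:
            raise ParityError(f"ortholog pair ({ida}, {idb}) references unknown ORF ids")
        raw.append((rank_a[ida], rank_b[idb], strand_a[ida] == strand_b[idb]))
    if not raw:
        return ParityData(pairs=[], n_a=n_a, n_b=n_b)
    anchor_pair = next((p for p in raw if p[0] == 1), None)
    if anchor_pair is not None:
        shift = anchor_pair[1] - 1
    else:
        def cost(k: int) -> int:
            total = 0
            for ra, rb, _ in raw:
                d = abs((rb - 1 - k) % n_b + 1 - ra)
                total += min(d, n_b - d)
            return total
        shift = min(range(n_b), key=lambda k: (cost(k), k))
    pairs = [(ra, (rb - 1 - shift) % n_b + 1, same) for ra, rb, same in raw]
    pairs.sort()
    return ParityData(pairs=pairs, n_a=n_a, n_b=n_b)


def collinearity_score(parity: ParityData) -> float:
    """Fraction of circularly consecutive pairs whose rank_b steps by +1 mod n_b.

    1.0 for perfectly conserved gene order; a random order scores near
    1/(m-1) for m pairs.
    """
    pairs = sorted(parity.pairs)
    m = len(pairs)
    if m < 2:
        raise ParityError("collinearity_score needs at least 2 ortholog pairs")
    hits = 0
    for i in range(m):
        rb, rb_next = pairs[i][1], pairs[(i + 1) % m][1]
        if (rb_next - rb) % parity.n_b == 1:
            hits += 1
    return hits / m


def detect_inversions(parity: ParityData, annot_a: GenomeAnnotation,
                      min_run: int = 3) -> list[InversionSegment]:
    """Maximal runs of >= min_run consecutive pairs with strictly decreasing rank_b.

    Runs are taken over the pair list sorted by rank_a (not over raw rank
    gaps, so unpaired ORFs do not break a run).  Span is measured in genome
    A nucleotides, boundary genes inclusive.
    """
    pairs = sorted(parity.pairs)
    m = len(pairs)
    segments: list[InversionSegment] = []
    orf_by_rank = {i + 1: r for i, r in enumerate(annot_a.orfs)}
    L = annot_a.genome.length
    i = 0
    while i < m - 1:
        j = i
        while j + 1 < m and pairs[j + 1][1] < pairs[j][1]:
            j += 1
        n_run = j - i + 1
        if n_run >= min_run:
            first, last = orf_by_rank[pairs[i][0]], orf_by_rank[pairs[j][0]]
            left = first.fwd_start
            right_end = last.fwd_start + last.length_nt
            span = right_end - left if right_end > left else right_end - left + L
            segments.append(InversionSegment(
                a_start_rank=pairs[i][0], a_end_rank=pairs[j][0],
                n_pairs=n_run, span_nt=span,
            ))
        i = j + 1 if j > i else i + 1
    return segments


def plot_parity(parity: ParityData, path: str, title: str = "gene parity") -> None:
    """Scatter of ortholog ranks (SVG/PNG by file extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    if parity.pairs:
        xs, ys, same = zip(*parity.pairs)
        colors = ["tab:blue" if s else "tab:red" for s in same]
        ax.scatter(xs, ys, s=12, c=colors)
    ax.set_xlabel("ORF rank, genome A")
    ax.set_ylabel("ORF rank, genome B")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
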