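"""Early/late baculovirus promoter motif scanning.

Baculovirus transcription runs in a temporal cascade: early genes are read
by host RNA polymerase II from TATA-class promoters (TATA box plus a
CAGT/CATT initiator 20-40 nt downstream), late and very late genes by the
viral RNA polymerase from a TAAG initiator.  Following the usual annotation
convention, motifs are called within a fixed window (default 150 nt)
upstream of each ORF's start codon on the coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import circular_subsequence
from .orf_annotation import GenomeAnnotation, OrfRecord

__all__ = ["PromoterConfig", "PromoterHit", "scan_promoters", "upstream_window"]


@dataclass(frozen=True)
class PromoterConfig:
    window_nt: int = 150
    late_motif: str = "TAAG"
    early_tata: str = "TATA"
    early_initiators: tuple[str, ...] = ("CAGT", "CATT")
    tata_initiator_gap: tuple[int, int] = (20, 40)
    intergenic_only: bool = False

    def __post_init__(self) -> None:
        if self.window_nt <= 0:
            raise ValueError("window_nt must be positive")
        motifs = (self.late_motif, self.early_tata, *self.early_initiators)
        if any(set(m) - set("ACGT") for m in motifs):
            raise ValueError("promoter motifs must be plain DNA strings")


@dataclass(frozen=True)
class PromoterHit:
    """position counts nt upstream of the ATG: 1 = immediately adjacent.

    For an early hit the position refers to the first base of the TATA box;
    motif_seq is the literal window text (TATA..initiator for early hits).
    """

    orf_id: int
    kind: str  # early | late
    position: int
    motif_seq: str


def upstream_window(annot: GenomeAnnotation, orf: OrfRecord, window_nt: int) -> str:
    """The window_nt bases 5' of the ATG on the coding strand (circular wrap allowed)."""
    L = annot.genome.length
    w = min(window_nt, L - orf.length_nt)  # never run into the ORF itself from behind
    if w <= 0:
        return ""
    if orf.strand == "+":
        end = (orf.start - 2) % L + 1
        start = (orf.start - 1 - w) % L + 1
        return circular_subsequence(annot.genome, start, end, "+")
    start = orf.start % L + 1
    end = (orf.start + w - 1) % L + 1
    return circular_subsequence(annot.genome, start, end, "-")


def scan_promoters(annot: GenomeAnnotation, config: PromoterConfig | None = None) -> list[PromoterHit]:
    """All early/late promoter hits within the upstream window of every ORF.

    The window string reads 5'->3' toward the ATG, so a motif beginning at
    0-based window index ``k`` lies ``window_len - k`` nt upstream of the
    start codon.  Every TAAG occurrence is a late hit; an early hit needs a
    TATA box whose initiator (CAGT or CATT) starts within the configured gap
    downstream of the TATA end.
    """
    cfg = config or PromoterConfig()
    hits: list[PromoterHit] = []
    gap_lo, gap_hi = cfg.tata_initiator_gap
    for orf in annot.orfs:
        window = upstream_window(annot, orf, cfg.window_nt)
        if cfg.intergenic_only:
            window = _mask_coding(annot, orf, window)
        wlen = len(window)
        for k in range(wlen - len(cfg.late_motif) + 1):
            if window[k : k + len(cfg.late_motif)] == cfg.late_motif:
                hits.append(PromoterHit(orf.orf_id, "late", wlen - k,
                                        window[k : k + len(cfg.late_motif)]))
        tlen = len(cfg.early_tata)
        for k in range(wlen - tlen + 1):
            if window[k : k + tlen] != cfg.early_tata:
                continue
            for gap in range(gap_lo, gap_hi + 1):
                ini_start = k + tlen + gap
                for ini in cfg.early_initiators:
                    if window[ini_start : ini_start + len(ini)] == ini:
                        hits.append(PromoterHit(
                            orf.orf_id, "early", wlen - k,
                            window[k : ini_start + len(ini)],
                        ))
    hits.sort(key=lambda h: (h.orf_id, -h.position, h.kind))
    return hits


def _mask_coding(annot: GenomeAnnotation, orf: OrfRecord, window: str) -> str:
    """Replace window positions covered by other ORFs with 'N' (kills motif matches)."""
    L = annot.genome.length
    wlen = len(window)
    import numpy as np

    covered = np.zeros(L, dtype=bool)
    for r in annot.orfs:
        if r.orf_id == orf.orf_id:
            continue
        for s, e in r.span_pieces(L):
            covered[s:e] = True
    out = list(window)
    for k in range(wlen):
        dist = wlen - k  # nt upstream of ATG
        if orf.strand == "+":
            pos0 = (orf.start - 1 - dist) % L
        else:
            pos0 = (orf.start - 1 + dist) % L
        if covered[pos0]:
            out[k] = "N"
    return "".join(out)


def hits_table(hits: list[PromoterHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.orf_id, h.kind, h.position, h.motif_seq) for h in hits],
        columns=["orf_id", "kind", "position", "motif_seq"],
    )
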