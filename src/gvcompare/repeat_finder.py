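"""Repeat-region discovery: direct imperfect repeats, palindromes, hairpins.

Betabaculovirus genomes carry putative replication origins built from
tandem imperfect direct repeats and palindromes embedded in AT-rich
intergenic spacers ("non-hr" origins, as opposed to the palindrome-centred
hr architecture of nucleopolyhedroviruses).  This module scans intergenic
spacers for such architectures:

* tandem arrays of an imperfect repeat unit (seed-and-extend against a
  column consensus, explicit per-copy mismatch bound),
* imperfect inverted repeats (palindromes) with a bounded loop,
* maximum-base-pairing hairpin structures (Nussinov dynamic programming
  over Watson-Crick pairs; no thermodynamic parameters),

and classifies each repeat region as hr-like, non-hr, or neither.

Coordinates returned by the scanners are 1-based inclusive *within the
scanned sequence*; callers working on spacers add the spacer offset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .orf_annotation import GenomeAnnotation

__all__ = [
    "RepeatConfig",
    "RepeatRegion",
    "Spacer",
    "Palindrome",
    "HairpinStructure",
    "RepeatError",
    "intergenic_spacers",
    "find_direct_repeats",
    "find_palindromes",
    "predict_hairpin",
    "classify_region",
]

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "X"}


class RepeatError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatConfig:
    min_unit_nt: int = 15
    max_mismatch_fraction: float = 0.2
    min_copies: int = 2
    min_palindrome_arm: int = 6
    max_loop_nt: int = 10
    at_window_nt: int = 100
    at_threshold: float = 0.6
    truncated_min_fraction: float = 0.4  # partial copy >= this fraction of the unit
    seed_k: int = 8

    def __post_init__(self) -> None:
        if min(self.min_unit_nt, self.min_copies, self.min_palindrome_arm,
               self.at_window_nt, self.seed_k) <= 0 or self.max_loop_nt < 0:
            raise RepeatError("repeat config values must be positive")
        for f in (self.max_mismatch_fraction, self.at_threshold, self.truncated_min_fraction):
            if not (0.0 <= f <= 1.0):
                raise RepeatError("fractions must be in [0, 1]")


@dataclass(frozen=True)
class Palindrome:
    start: int  # 1-based inclusive
    end: int
    arm_len: int
    mismatches: int
    loop_len: int

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class RepeatRegion:
    start: int  # 1-based inclusive, in the scanned sequence
    end: int
    n_full_copies: int
    has_truncated_copy: bool
    unit_consensus: str
    at_fraction: float
    palindromes: list[Palindrome] = field(default_factory=list)
    classification: str = "none"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Spacer:
    start: int  # 1-based inclusive; start > end means the spacer wraps the origin
    end: int
    length: int
    left_orf_id: int | None
    right_orf_id: int | None


def intergenic_spacers(annot: GenomeAnnotation, min_len: int = 1) -> list[Spacer]:
    """Maximal regions not covered by any ORF span; circular wrap handled."""
    L = annot.genome.length
    covered = np.zeros(L, dtype=bool)
    owner = np.full(L, -1, dtype=int)
    for r in annot.orfs:
        for s, e in r.span_pieces(L):
            covered[s:e] = True
            owner[s:e] = r.orf_id
    if not covered.any():
        return [Spacer(1, L, L, None, None)] if L >= min_len else []
    free = ~covered
    # runs of free positions on the circle
    idx = np.flatnonzero(free)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = []
    run_start = idx[0]
    for b in breaks:
        runs.append((run_start, idx[b]))
        run_start = idx[b + 1]
    runs.append((run_start, idx[-1]))
    # merge a run touching position L-1 with one touching 0 (circular wrap)
    if annot.genome.is_circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == L - 1:
        first = runs.pop(0)
        last = runs.pop()
        runs.append((last[0], first[1]))  # wraps: start > end
    spacers = []
    for s, e in runs:
        length = e - s + 1 if e >= s else L - s + e + 1
        if length < min_len:
            continue
        left = owner[(s - 1) % L]
        right = owner[(e + 1) % L]
        spacers.append(Spacer(
            start=int(s) + 1, end=int(e) + 1, length=int(length),
            left_orf_id=int(left) if left >= 0 else None,
            right_orf_id=int(right) if right >= 0 else None,
        ))
    spacers.sort(key=lambda sp: sp.start)
    return spacers


def _consensus(copies: list[str]) -> str:
    out = []
    for col in zip(*copies):
        counts = sorted(((col.count(b), b) for b in set(col)), key=lambda t: (-t[0], t[1]))
        out.append(counts[0][1])
    return "".join(out)


def _mismatch(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _copy_mismatches(copies: list[str]) -> list[int]:
    """Per-copy mismatches against the column consensus (lexicographic ties)."""
    cons = _consensus(copies)
    return [_mismatch(c, cons) for c in copies]


def _copies_ok(copies: list[str], max_frac: float) -> bool:
    p = len(copies[0])
    return all(m <= max_frac * p for m in _copy_mismatches(copies))


def _refine_boundaries(seq: str, start: int, length: int, cons: str,
                       p: int, cfg: RepeatConfig) -> tuple[int, int]:
    """One boundary-refinement pass for a tandem array.

    The maximum-scoring segment of the match profile re-derives both
    boundaries jointly; outward max-prefix walks re-add partial copies a
    mismatch cluster may have shaved off; a whole flanking copy still within
    the per-copy mismatch bound is rescued even if its edge looks poor.
    """
    ks, ke = _max_scoring_segment(seq, start, length, cons)
    new_start = ks - _max_prefix(
        (seq[max(0, ks - p) : ks])[::-1],
        lambda t: cons[(ks - 1 - t - start) % p])
    new_end = ke + _max_prefix(
        seq[ke : ke + p],
        lambda t: cons[(ke + t - start) % p])
    budget = cfg.max_mismatch_fraction * p
    while new_start - p >= 0:
        copy = seq[new_start - p : new_start]
        ref = "".join(cons[(new_start - p + k - start) % p] for k in range(p))
        if _mismatch(copy, ref) > budget:
            break
        new_start -= p
    while new_end + p <= len(seq):
        copy = seq[new_end : new_end + p]
        ref = "".join(cons[(new_end + k - start) % p] for k in range(p))
        if _mismatch(copy, ref) > budget:
            break
        new_end += p
    return new_start, new_end


def _max_prefix(flank: str, cons_at, mismatch_penalty: float = 2.0) -> int:
    """Length of the max-scoring prefix of ``flank`` (+1 match, -penalty)."""
    best_t = 0
    best = 0.0
    score = 0.0
    for t in range(len(flank)):
        score += 1.0 if flank[t] == cons_at(t) else -mismatch_penalty
        if score > best:
            best = score
            best_t = t + 1
    return best_t


def _max_scoring_segment(seq: str, array_start: int, array_len: int, cons: str,
                         mismatch_penalty: float = 2.0, margin_units: float = 1.5
                         ) -> tuple[int, int]:
    """Refined (start, end) of a tandem array as a max-sum match segment.

    The consensus is tiled periodically from ``array_start`` across a window
    extending ``margin_units`` units beyond the grown array on both sides;
    Kadane's algorithm on the +1/-penalty match profile returns the segment
    boundaries (earliest maximal segment on ties).
    """
    p = len(cons)
    n = len(seq)
    margin = int(margin_units * p)
    lo = max(0, array_start - margin)
    hi = min(n, array_start + array_len + margin)
    best = (0.0, lo, lo)  # (score, start, end)
    cur = 0.0
    cur_start = lo
    for i in range(lo, hi):
        s = 1.0 if seq[i] == cons[(i - array_start) % p] else -mismatch_penalty
        if cur <= 0:
            cur = s
            cur_start = i
        else:
            cur += s
        if cur > best[0]:
            best = (cur, cur_start, i + 1)
    return best[1], best[2]


def _grow_array(seq: str, anchor: int, p: int, cfg: RepeatConfig) -> tuple[int, list[str]] | None:
    """Grow a tandem array of unit length p around the copy starting at anchor."""
    n = len(seq)
    if anchor + p > n:
        return None
    copies = [seq[anchor : anchor + p]]
    start = anchor
    while start + len(copies) * p + p <= n:
        cand = copies + [seq[start + len(copies) * p : start + (len(copies) + 1) * p]]
        if _copies_ok(cand, cfg.max_mismatch_fraction):
            copies = cand
        else:
            break
    while start - p >= 0:
        cand = [seq[start - p : start]] + copies
        if _copies_ok(cand, cfg.max_mismatch_fraction):
            copies = cand
            start -= p
        else:
            break
    if len(copies) < cfg.min_copies:
        return None
    return start, copies


def find_direct_repeats(seq: str, config: RepeatConfig | None = None) -> list[RepeatRegion]:
    """Tandem / near-tandem arrays of an imperfect repeat unit.

    Exact seed k-mers occurring twice at distance p (a candidate unit length)
    anchor array growth in both directions; each full copy must stay within
    ``max_mismatch_fraction`` of the running column consensus.  A trailing or
    leading partial copy of at least ``truncated_min_fraction`` of the unit
    extends the region and sets ``has_truncated_copy``.  Overlapping reports
    are collapsed to the largest region (ties: more copies, then leftmost).
    """
    cfg = config or RepeatConfig()
    seq = seq.upper()
    n = len(seq)
    if n < cfg.min_unit_nt:
        return []
    k = min(cfg.seed_k, cfg.min_unit_nt)
    kmer_pos: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer_pos.setdefault(seq[i : i + k], []).append(i)
    candidates: set[tuple[int, int]] = set()  # (anchor, period)
    for positions in kmer_pos.values():
        if len(positions) < 2:
            continue
        for a, b in itertools.combinations(positions, 2):
            p = b - a
            if cfg.min_unit_nt <= p <= n // cfg.min_copies:
                candidates.add((a, p))
    regions: dict[tuple[int, int, int], RepeatRegion] = {}
    for anchor, p in sorted(candidates):
        grown = _grow_array(seq, anchor, p, cfg)
        if grown is None:
            continue
        start, copies = grown
        cons = _consensus(copies)
        # The grown array may sit off-phase relative to the true unit, its
        # terminal copies may have absorbed background, and a 2-copy
        # consensus can be contaminated by it.  Refinement therefore
        # iterates: re-derive both boundaries from the match profile against
        # the periodically tiled consensus, re-slice copies at the refined
        # phase, rebuild the consensus from them, and repeat to a fixpoint.
        length = len(copies) * p
        new_start, new_end = start, start + length
        for _ in range(3):
            prev = (new_start, new_end)
            new_start, new_end = _refine_boundaries(seq, new_start, new_end - new_start,
                                                    cons, p, cfg)
            n_full = (new_end - new_start) // p
            if n_full < 1:
                break
            sliced = [seq[new_start + k * p : new_start + (k + 1) * p] for k in range(n_full)]
            cons = _consensus(sliced)
            if (new_start, new_end) == prev:
                break
        span = new_end - new_start
        n_full = span // p
        rem = span % p
        # flank trimming can shave a few bases off a genuine terminal copy:
        # a >= 75% remainder is counted as a (trimmed) full copy, a middling
        # remainder as a truncated copy, a small one as boundary slop
        if rem >= 0.75 * p:
            n_full += 1
            truncated = False
        else:
            truncated = rem >= min(cfg.truncated_min_fraction, 0.35) * p
        if n_full < cfg.min_copies:
            continue
        key = (new_start, new_end, p)
        if key in regions:
            continue
        region_seq = seq[new_start:new_end]
        at = (region_seq.count("A") + region_seq.count("T")) / max(1, len(region_seq))
        regions[key] = RepeatRegion(
            start=new_start + 1, end=new_end, n_full_copies=n_full,
            has_truncated_copy=truncated, unit_consensus=cons, at_fraction=at,
        )
    # collapse overlaps: most full copies wins (favors the fundamental unit
    # over its harmonics), then span, smaller unit, leftmost
    chosen: list[RepeatRegion] = []
    for reg in sorted(regions.values(),
                      key=lambda r: (-r.n_full_copies, -r.length, len(r.unit_consensus), r.start)):
        if all(reg.end < c.start or reg.start > c.end for c in chosen):
            chosen.append(reg)
    chosen.sort(key=lambda r: r.start)
    return chosen


def find_palindromes(seq: str, config: RepeatConfig | None = None) -> list[Palindrome]:
    """Maximal imperfect inverted repeats with bounded loop and mismatch fraction.

    Arms are extended outward from every (center, loop) placement while the
    arm mismatch fraction stays within bounds; the outermost arm position
    must base-pair (no dangling mismatch).  Overlapping reports collapse to
    the highest-scoring (arm length minus mismatches, then leftmost).
    """
    cfg = config or RepeatConfig()
    seq = seq.upper()
    n = len(seq)
    hits: list[Palindrome] = []
    for loop in range(cfg.max_loop_nt + 1):
        for l_end in range(n):  # left arm occupies [.., l_end-1], 0-based
            r_start = l_end + loop
            if r_start >= n:
                break
            arm = 0
            mism = 0
            best: tuple[int, int] | None = None
            while l_end - arm - 1 >= 0 and r_start + arm < n:
                a = seq[l_end - arm - 1]
                b = seq[r_start + arm]
                paired = _COMP.get(a) == b
                if not paired:
                    mism += 1
                arm += 1
                if paired and arm >= cfg.min_palindrome_arm and mism <= cfg.max_mismatch_fraction * arm:
                    best = (arm, mism)
            if best is not None:
                arm, mism = best
                hits.append(Palindrome(
                    start=l_end - arm + 1, end=r_start + arm,
                    arm_len=arm, mismatches=mism, loop_len=loop,
                ))
    chosen: list[Palindrome] = []
    # tie-breaks are mirror-invariant (distance to the nearest sequence end)
    # so results on the reverse complement are the mirrored coordinates
    order = sorted(hits, key=lambda h: (-(h.arm_len - h.mismatches), -h.arm_len,
                                        h.loop_len, min(h.start - 1, n - h.end), h.start))
    for pal in order:
        if all(pal.end < c.start or pal.start > c.end for c in chosen):
            chosen.append(pal)
    chosen.sort(key=lambda h: h.start)
    return chosen


def write_bed(regions: list[RepeatRegion], path, chrom: str, offset: int = 0) -> None:
    """BED (0-based half-open) export of repeat regions.

    ``offset`` shifts scanned-sequence coordinates to genome coordinates
    (pass the spacer's 0-based genome start).
    """
    with open(path, "w") as fh:
        for reg in regions:
            name = f"{reg.classification}_{reg.n_full_copies}x{len(reg.unit_consensus)}"
            fh.write(f"{chrom}\t{offset + reg.start - 1}\t{offset + reg.end}\t{name}\n")


@dataclass
class HairpinStructure:
    pairs: list[tuple[int, int]]  # 0-based (i, j) base pairs, i < j
    n_pairs: int
    loop_len: int  # smallest hairpin loop in the structure; 0 when unpaired

    def dot_bracket(self, n: int) -> str:
        s = ["."] * n
        for i, j in self.pairs:
            s[i], s[j] = "(", ")"
        return "".join(s)


_MIN_LOOP = 3


def predict_hairpin(seq: str) -> HairpinStructure:
    """Maximum base-pair nested (pseudoknot-free) structure by dynamic programming.

    Watson-Crick pairs only (DNA: no GU wobble), minimum hairpin loop of 3
    unpaired bases.  Among co-optimal structures the traceback prefers
    closing a pair over unpairing, which yields the most contiguous stem and
    is deterministic.
    """
    seq = seq.upper()
    n = len(seq)
    if not (5 <= n <= 2000):
        raise RepeatError(f"hairpin prediction supports 5..2000 nt, got {n}")

    def pairable(i: int, j: int) -> bool:
        return _COMP.get(seq[i]) == seq[j] and j - i > _MIN_LOOP

    E = np.zeros((n, n), dtype=np.int32)
    for d in range(_MIN_LOOP + 1, n):
        for i in range(0, n - d):
            j = i + d
            best = E[i + 1, j]
            if E[i, j - 1] > best:
                best = E[i, j - 1]
            if pairable(i, j):
                v = E[i + 1, j - 1] + 1
                if v > best:
                    best = v
            if d > 1:
                ks = np.arange(i, j)
                v = int(np.max(E[i, ks] + E[ks + 1, j]))
                if v > best:
                    best = v
            E[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or E[i, j] == 0:
            continue
        if pairable(i, j) and E[i, j] == E[i + 1, j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        elif E[i, j] == E[i + 1, j]:
            stack.append((i + 1, j))
        elif E[i, j] == E[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i, j):
                if E[i, k] + E[k + 1, j] == E[i, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    pairs.sort()
    if pairs:
        inner = [j - i - 1 for i, j in pairs
                 if not any(i < p < q < j for p, q in pairs if (p, q) != (i, j))]
        loop = min(inner)
    else:
        loop = 0
    return HairpinStructure(pairs=pairs, n_pairs=len(pairs), loop_len=loop)


def classify_region(region: RepeatRegion, config: RepeatConfig | None = None,
                    seq: str | None = None) -> str:
    """Classify a repeat region as hr_like, non_hr, or none.

    hr architecture (checked first, being the more specific): every repeat
    unit carries a palindrome centred in its middle half.  non-hr: at least
    ``min_copies`` direct repeats, AT fraction over the region at or above
    ``at_threshold``, and at least one palindrome (or a hairpin of >= 4
    pairs) within the region.  ``seq`` is the sequence the region
    coordinates refer to; it enables palindrome/hairpin evaluation when the
    region does not already carry palindrome annotations.
    """
    cfg = config or RepeatConfig()
    unit = region.unit_consensus
    if unit and len(unit) >= 2 * cfg.min_palindrome_arm:
        # hr architecture: every unit carries a palindrome spanning most of
        # the unit.  The doubled consensus makes the test invariant to the
        # (arbitrary) phase at which the array was detected, and the net
        # pairing evidence (arm length minus mismatches) must dominate the
        # unit — short chance palindromes, common in AT-rich sequence, score
        # far below this bound.
        unit_pals = find_palindromes(unit + unit, cfg)
        net = max((p.arm_len - p.mismatches for p in unit_pals), default=0)
        if net >= max(23.0, 0.45 * len(unit)):
            region.classification = "hr_like"
            return "hr_like"
    pals = list(region.palindromes)
    hairpin_ok = False
    if seq is not None:
        sub = seq[region.start - 1 : region.end]
        if not pals:
            pals = find_palindromes(sub, cfg)
        if not pals and 5 <= len(sub) <= 2000:
            hairpin_ok = predict_hairpin(sub).n_pairs >= 4
    region.palindromes = pals
    if (region.n_full_copies >= cfg.min_copies
            and region.at_fraction >= cfg.at_threshold
            and (pals or hairpin_ok)):
        region.classification = "non_hr"
        return "non_hr"
    region.classification = "none"
    return "none"
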