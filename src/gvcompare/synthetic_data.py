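"""Synthetic annotated genomes with known ground truth.

Every pipeline stage in this package is validated against simulated
circular genomes that emulate betabaculovirus organization: densely packed
ATG-initiated ORFs on both strands with occasional small tail-to-tail
overlaps, ~37% G+C background, AT-rich intergenic spacers that can carry
tandem imperfect repeats and palindromes, and TAAG/TATA-class promoter
motifs planted upstream of chosen ORFs.  Genome families descend from a
common ancestor by codon-aware amino-acid substitution and segmental
inversion, so ortholog maps, parity plots, and trees all have a known
truth.

Two constructions keep the truth exact under the annotation rules:

* every planted ATG is guarded by an immediately-upstream in-frame stop
  codon, so the maximal-ORF convention (first ATG after the previous stop)
  recovers planted start coordinates exactly;
* planted overlaps are tail-to-tail between a '+' ORF and the following
  '-' ORF, with the shared bases engineered so both reading frames are
  stop-free and both stop codons live inside the shared region.

After assembly, background ORFs above the selection threshold that were
not planted are disrupted (a stop codon or start-codon edit at positions
no planted feature covers); rare offenders buried entirely inside planted
features are tolerated and recorded in the truth table.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .genome_io import CircularGenome, reverse_complement
from .orf_annotation import AnnotationConfig, OrfRecord, _make_record, enumerate_candidate_orfs

__all__ = [
    "SimConfig",
    "RepeatSpec",
    "TruthTable",
    "TruthPromoter",
    "TruthRepeat",
    "TruthInversion",
    "SimulationError",
    "simulate_annotated_genome",
    "evolve_genome",
    "plant_repeat_region",
    "simulate_family",
    "verify_truth",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = tuple(_TABLE.stop_codons)
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
_AAS = sorted(_AA_TO_CODONS)
# codons whose reverse complement is a stop: forbidden inside engineered overlaps
_RC_STOP_CODONS = tuple(sorted(reverse_complement(s) for s in _STOPS))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatSpec:
    """Plan for one planted tandem-repeat region."""

    unit_len: int = 30
    n_copies: int = 7
    mismatch_rate: float = 0.1
    at_fraction: float = 0.66
    truncated: bool = True
    with_palindrome: bool = False      # append a perfect palindrome after the array
    centered_palindrome: bool = False  # hr-style: unit built around a centred palindrome
    palindrome_arm: int = 12
    palindrome_loop: int = 4

    @property
    def total_len(self) -> int:
        t = self.unit_len * self.n_copies
        if self.truncated:
            t += max(1, self.unit_len // 2)
        if self.with_palindrome:
            t += 2 * self.palindrome_arm + self.palindrome_loop + 4
        return t


@dataclass(frozen=True)
class SimConfig:
    genome_len: int = 40_000
    n_orfs: int = 40
    gc_target: float = 0.378
    orf_len_range: tuple[int, int] = (300, 1200)  # nt incl stop codon
    overlap_prob: float = 0.2
    min_spacer: int = 30
    promoter_plan: tuple[tuple[int, str], ...] = ()  # (1-based orf index, "late"|"early")
    repeat_spec: RepeatSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.gc_target <= 1 and 0 <= self.overlap_prob <= 1):
            raise SimulationError("fractions must be in [0, 1]")
        lo, hi = self.orf_len_range
        if lo < 150 or hi < lo:
            raise SimulationError("orf_len_range must be >= 150 nt and ordered")
        for idx, kind in self.promoter_plan:
            if not (1 <= idx <= self.n_orfs) or kind not in ("late", "early"):
                raise SimulationError(f"bad promoter plan entry ({idx}, {kind})")


@dataclass(frozen=True)
class TruthPromoter:
    orf_index: int   # planted ORF id
    kind: str
    position: int    # nt upstream of the ATG (1 = adjacent), motif/TATA start
    motif: str       # literal planted bases (TATA+initiator for early, gap excluded)
    gap: int = 0     # early only: nt between TATA end and initiator start
    span: int = 4    # full extent on the genome, gap included


@dataclass
class TruthRepeat:
    start: int  # 1-based genome coords
    end: int
    n_copies: int
    truncated: bool
    unit: str
    at_fraction: float
    palindrome: tuple[int, int] | None = None  # planted palindrome coords


@dataclass
class TruthInversion:
    start_index: int  # planted ORF ids bounding the inverted block
    end_index: int
    seg_start: int    # 1-based inclusive genome coords of the inverted segment
    seg_end: int


@dataclass
class TruthTable:
    orfs: list[OrfRecord]  # orf_id == planted index; list in genome order
    promoters: list[TruthPromoter] = field(default_factory=list)
    repeats: list[TruthRepeat] = field(default_factory=list)
    inversions: list[TruthInversion] = field(default_factory=list)
    orthologs: dict[int, int] = field(default_factory=dict)  # planted id -> parent id
    unsuppressed: list[tuple] = field(default_factory=list)
    seed: int = 0

    def orf_by_id(self, planted_id: int) -> OrfRecord:
        for r in self.orfs:
            if r.orf_id == planted_id:
                return r
        raise KeyError(planted_id)


# ------------------------------------------------------------ base sampling

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)]) if n else ""


def _random_codon(rng: np.random.Generator, gc: float, forbid: tuple[str, ...] = ()) -> str:
    while True:
        c = _random_bases(rng, 3, gc)
        if c not in _STOPS and c not in forbid:
            return c


def _random_stop(rng: np.random.Generator) -> str:
    return _STOPS[rng.integers(0, len(_STOPS))]


def _orf_sequence(rng: np.random.Generator, length_nt: int, gc: float,
                  overlap_out: int = 0, fixed_tail: str = "") -> str:
    """One planted coding sequence: ATG + sense codons + stop.

    ``overlap_out`` > 0 engineers the last overlap_out bases so their reverse
    complement is also a valid ORF tail (used when the *next* '-' ORF shares
    this tail); ``fixed_tail`` forces the final bases (used for the '-' ORF
    whose 3' end is already determined by the shared region).
    """
    n_codons = length_nt // 3
    if fixed_tail:
        assert len(fixed_tail) % 3 == 0
        fixed = len(fixed_tail) // 3
        body = [_random_codon(rng, gc) for _ in range(n_codons - 1 - fixed)]
        return "ATG" + "".join(body) + fixed_tail
    if overlap_out:
        k = overlap_out // 3  # codons inside the shared region, incl this ORF's stop
        body = [_random_codon(rng, gc) for _ in range(n_codons - 2 - k + 1)]
        # first shared codon: reverse complement must be a stop (the '-' ORF's stop)
        first_shared = _RC_STOP_CODONS[rng.integers(0, len(_RC_STOP_CODONS))]
        interior = [_random_codon(rng, gc, forbid=_RC_STOP_CODONS) for _ in range(k - 2)]
        return "ATG" + "".join(body) + first_shared + "".join(interior) + _random_stop(rng)
    body = [_random_codon(rng, gc) for _ in range(n_codons - 2)]
    return "ATG" + "".join(body) + _random_stop(rng)


# ------------------------------------------------------- feature protection

def _protected_mask(L: int, truth: TruthTable) -> np.ndarray:
    mask = np.zeros(L, dtype=bool)
    def cover(a: int, n: int) -> None:  # 0-based start, length, wraps
        for k in range(n):
            mask[(a + k) % L] = True
    for r in truth.orfs:
        cover(r.fwd_start, r.length_nt)
        if r.strand == "+":
            cover((r.fwd_start - 3) % L, 3)  # guard stop
        else:
            cover((r.fwd_start + r.length_nt) % L, 3)
    for pr in truth.promoters:
        orf = truth.orf_by_id(pr.orf_index)
        if orf.strand == "+":
            cover((orf.start - 1 - pr.position) % L, pr.span)
        else:
            cover((orf.start - 1 + pr.position - pr.span + 1) % L, pr.span)
    for rep in truth.repeats:
        cover(rep.start - 1, rep.end - rep.start + 1)
        if rep.palindrome:
            cover(rep.palindrome[0] - 1, rep.palindrome[1] - rep.palindrome[0] + 1)
    return mask


def _suppress_spurious(seq: list[str], truth: TruthTable, rng: np.random.Generator,
                       min_orf_nt: int = 150, max_rounds: int = 40) -> list[tuple]:
    """Disrupt unplanted ORFs >= threshold at unprotected positions, to a fixpoint."""
    L = len(seq)
    mask = _protected_mask(L, truth)
    truth_keys = {(r.strand, r.fwd_start, r.length_nt) for r in truth.orfs}
    cfg = AnnotationConfig(min_orf_nt=min_orf_nt)
    stuck: set[tuple] = set()
    for _ in range(max_rounds):
        genome = CircularGenome(id="sim", seq="".join(seq))
        offenders = [r for r in enumerate_candidate_orfs(genome, cfg)
                     if (r.strand, r.fwd_start, r.length_nt) not in truth_keys
                     and (r.strand, r.fwd_start, r.length_nt) not in stuck]
        if not offenders:
            break
        progress = False
        for orf in offenders:
            edited = _disrupt(seq, mask, orf, rng, L)
            if edited:
                progress = True
            else:
                stuck.add((orf.strand, orf.fwd_start, orf.length_nt))
        if not progress:
            break
    return sorted(stuck)


def _codon_fwd_positions(r: OrfRecord, t: int, L: int) -> list[int]:
    """Forward positions (left-to-right genome order) of codon t of an ORF."""
    if r.strand == "+":
        base = r.fwd_start + 3 * t
    else:
        base = r.fwd_start + r.length_nt - 3 * (t + 1)
    return [(base + k) % L for k in range(3)]


def _disrupt(seq: list[str], mask: np.ndarray, orf: OrfRecord,
             rng: np.random.Generator, L: int) -> bool:
    # write an early in-frame stop at the first fully-unprotected codon that
    # leaves the residual ORF below threshold (stop at nt offset t => length t+3)
    n_codons = orf.length_nt // 3
    for t in range(1, min(n_codons - 1, 49)):
        pos = _codon_fwd_positions(orf, t, L)
        if not any(mask[p] for p in pos):
            stop = _random_stop(rng)
            fwd = stop if orf.strand == "+" else reverse_complement(stop)
            for p, b in zip(pos, fwd):
                seq[p] = b
            return True
    # fall back: destroy the start codon (ATG -> ATC on the coding strand)
    pos = _codon_fwd_positions(orf, 0, L)
    if not any(mask[p] for p in pos):
        if orf.strand == "+":
            seq[pos[2]] = "C"  # forward ATG ends at pos[2]
        else:
            seq[pos[0]] = "G"  # forward 'CAT'; C complements the minus-strand G
        return True
    return False


# ------------------------------------------------------------- simulation

def simulate_annotated_genome(config: SimConfig) -> tuple[CircularGenome, TruthTable]:
    """Generate one circular genome plus its planted-feature truth table.

    Deterministic given ``config`` (including its seed).  The first planted
    ORF starts at nt 1 on '+', playing the granulin/anchor role; its guard
    stop occupies the last 3 nt of the genome.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_orfs
    L = config.genome_len
    lo, hi = config.orf_len_range
    lengths = [int(3 * rng.integers(lo // 3, hi // 3 + 1)) for _ in range(n)]
    strands = ["+"] + ["+" if rng.random() < 0.5 else "-" for _ in range(n - 1)]
    overlaps = [0] * n  # overlap of ORF i with ORF i-1
    for i in range(1, n):
        if strands[i - 1] == "+" and strands[i] == "-" and rng.random() < config.overlap_prob:
            overlaps[i] = int(3 * rng.integers(2, 8))  # 6..21 nt
    # block length on the genome: guard (3) + ORF, minus any shared bases
    block = [lengths[0]] + [lengths[i] + 3 for i in range(1, n)]
    eff = [block[i] - overlaps[i] for i in range(n)]
    gap_min = np.full(n, config.min_spacer, dtype=int)
    for idx, kind in config.promoter_plan:
        i = idx - 1
        gap_idx = (i - 1) % n if strands[i] == "+" else i
        gap_min[gap_idx] = max(gap_min[gap_idx], 90)
    rep_gap = None
    if config.repeat_spec is not None:
        rep_gap = n // 2
        gap_min[rep_gap] = max(gap_min[rep_gap], config.repeat_spec.total_len + 40)
    gap_min[n - 1] = max(gap_min[n - 1], config.min_spacer + 3)  # room for orf1's guard
    extra = L - sum(eff) - int(gap_min.sum())
    if extra < 0:
        raise SimulationError(
            f"infeasible packing: need {sum(eff) + int(gap_min.sum())} nt, have {L}")
    alloc = rng.multinomial(extra, np.full(n, 1.0 / n))
    gaps = (gap_min + alloc).tolist()

    # sequential ORF sequence generation (overlap constraints look one ahead)
    orf_seqs: list[str] = []
    for i in range(n):
        out = overlaps[i + 1] if i + 1 < n else 0
        if overlaps[i]:
            shared = orf_seqs[i - 1][-overlaps[i]:]
            orf_seqs.append(_orf_sequence(rng, lengths[i], config.gc_target,
                                          fixed_tail=reverse_complement(shared)))
        else:
            orf_seqs.append(_orf_sequence(rng, lengths[i], config.gc_target, overlap_out=out))

    seq = list(_random_bases(rng, L, config.gc_target))
    cursor = 0
    fwd_starts: list[int] = []
    for i in range(n):
        cursor -= overlaps[i]
        if strands[i] == "+":
            if i > 0:
                _write(seq, cursor, _random_stop(rng), L)
                cursor += 3
            fwd_starts.append(cursor % L)
            _write(seq, cursor, orf_seqs[i], L)
            cursor += lengths[i]
        else:
            fwd_starts.append(cursor % L)
            _write(seq, cursor, reverse_complement(orf_seqs[i]), L)
            cursor += lengths[i]
            _write(seq, cursor, reverse_complement(_random_stop(rng)), L)
            cursor += 3
        cursor += gaps[i]
    if cursor != L:
        raise SimulationError(f"layout error: cursor {cursor} != genome length {L}")
    _write(seq, L - 3, _random_stop(rng), L)  # guard for the anchor ORF at nt 1

    genome = CircularGenome(id=f"sim{config.seed}", seq="".join(seq))
    orfs = [_make_record(fwd_starts[i], lengths[i], strands[i], genome, 1, i + 1)
            for i in range(n)]
    truth = TruthTable(orfs=orfs, orthologs={r.orf_id: r.orf_id for r in orfs},
                       seed=config.seed)

    for idx, kind in config.promoter_plan:
        _plant_promoter(seq, truth, idx, kind, rng, L)
    genome = CircularGenome(id=genome.id, seq="".join(seq))
    if config.repeat_spec is not None:
        gap_start = (truth.orfs[rep_gap].fwd_start
                     + truth.orfs[rep_gap].length_nt
                     + (3 if strands[rep_gap] == "-" else 0)) % L
        genome, truth = plant_repeat_region(
            genome, truth, config.repeat_spec, position=gap_start + 20 + 1, rng=rng)
        seq = list(genome.seq)

    truth.unsuppressed = _suppress_spurious(seq, truth, rng)
    genome = CircularGenome(id=genome.id, seq="".join(seq))
    truth.orfs = [_make_record(r.fwd_start, r.length_nt, r.strand, genome, 1, r.orf_id)
                  for r in truth.orfs]
    return genome, truth


def _write(seq: list[str], at: int, text: str, L: int) -> None:
    for k, ch in enumerate(text):
        seq[(at + k) % L] = ch


def _plant_promoter(seq: list[str], truth: TruthTable, idx: int, kind: str,
                    rng: np.random.Generator, L: int) -> None:
    orf = truth.orf_by_id(idx)
    if kind == "late":
        motif = "TAAG"
        m = int(rng.integers(12, 61))  # motif start, nt upstream of ATG
    else:
        gap = int(rng.integers(20, 41))
        motif = "TATA" + "N" * gap + ("CAGT" if rng.random() < 0.5 else "CATT")
        m = int(rng.integers(len(motif) + 8, 86))  # fits the bumped spacer
    span = len(motif)
    for k, ch in enumerate(motif):
        if ch == "N":
            continue
        if orf.strand == "+":
            pos = (orf.start - 1 - m + k) % L
        else:
            pos = (orf.start - 1 + m - k) % L
            ch = reverse_complement(ch)
        seq[pos] = ch
    truth.promoters.append(TruthPromoter(
        orf_index=idx, kind=kind, position=m,
        motif=motif.replace("N", ""), gap=motif.count("N"), span=span))


def plant_repeat_region(genome: CircularGenome, truth: TruthTable, spec: RepeatSpec,
                        position: int, rng: np.random.Generator | None = None,
                        seed: int = 0) -> tuple[CircularGenome, TruthTable]:
    """Overwrite an intergenic stretch with a tandem imperfect repeat array.

    ``position`` is 1-based; the array (plus optional truncated copy and
    palindrome) must fit without touching any planted ORF.  Returns new
    genome and truth objects; inputs are not modified.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    L = genome.length
    total = spec.total_len
    mask = np.zeros(L, dtype=bool)
    for r in truth.orfs:
        for s, e in r.span_pieces(L):
            mask[s:e] = True
    span_positions = [(position - 1 + k) % L for k in range(total)]
    if any(mask[p] for p in span_positions):
        raise SimulationError(f"repeat region at {position} (+{total} nt) hits a planted ORF")

    for _ in range(300):
        if spec.centered_palindrome:
            arm = max(6, (spec.unit_len - spec.palindrome_loop) // 2 - 2)
            pal_arm = _at_biased(rng, arm, spec.at_fraction)
            pal = pal_arm + _at_biased(rng, spec.palindrome_loop, spec.at_fraction) + reverse_complement(pal_arm)
            pad = spec.unit_len - len(pal)
            unit = _at_biased(rng, pad // 2, spec.at_fraction) + pal + _at_biased(rng, pad - pad // 2, spec.at_fraction)
        else:
            unit = _at_biased(rng, spec.unit_len, spec.at_fraction)
        if _tandem_stopful(unit):
            break
    else:
        raise SimulationError("could not draw a repeat unit with stops in all frames")
    pieces = []
    for _ in range(spec.n_copies):
        pieces.append(_mutate_unit(rng, unit, spec.mismatch_rate))
    if spec.truncated:
        t = max(1, spec.unit_len // 2)
        pieces.append(_mutate_unit(rng, unit[:t], spec.mismatch_rate))
    array = "".join(pieces)
    pal_coords = None
    if spec.with_palindrome:
        arm = _at_biased(rng, spec.palindrome_arm, spec.at_fraction)
        pal = arm + _at_biased(rng, spec.palindrome_loop, spec.at_fraction) + reverse_complement(arm)
        pal_start = position + len(array) + 2  # 2 nt spacer after the array
        pal_coords = (pal_start, pal_start + len(pal) - 1)
        array = array + "TT" + pal

    seq = list(genome.seq)
    _write(seq, position - 1, array, L)
    new_genome = CircularGenome(id=genome.id, seq="".join(seq))
    new_truth = copy.deepcopy(truth)
    region_seq = array[: spec.unit_len * spec.n_copies + (max(1, spec.unit_len // 2) if spec.truncated else 0)]
    at = (region_seq.count("A") + region_seq.count("T")) / len(region_seq)
    new_truth.repeats.append(TruthRepeat(
        start=position,
        end=position + len(region_seq) - 1,
        n_copies=spec.n_copies, truncated=spec.truncated,
        unit=unit, at_fraction=at, palindrome=pal_coords,
    ))
    new_truth.orfs = [_make_record(r.fwd_start, r.length_nt, r.strand, new_genome, 1, r.orf_id)
                      for r in new_truth.orfs]
    return new_genome, new_truth


def _at_biased(rng: np.random.Generator, n: int, at: float) -> str:
    return _random_bases(rng, n, gc=1.0 - at)


def _tandem_stopful(unit: str) -> bool:
    """True iff an endless tandem of ``unit`` has a stop codon in all 6 frames.

    Guarantees a planted repeat array can never host a spurious ORF above
    the selection threshold.
    """
    # one period of the frame walk spans lcm(3, len(unit)) <= 3*len(unit) nt
    for s in (unit * 4, reverse_complement(unit * 4)):
        for f in range(3):
            codons = [s[f + 3 * k : f + 3 * k + 3] for k in range(len(unit))]
            if not any(c in _STOPS for c in codons if len(c) == 3):
                return False
    return True


def _mutate_unit(rng: np.random.Generator, unit: str, rate: float) -> str:
    out = []
    for ch in unit:
        if rng.random() < rate:
            alt = [b for b in "ACGT" if b != ch]
            out.append(alt[rng.integers(0, 3)])
        else:
            out.append(ch)
    return "".join(out)


# --------------------------------------------------------------- evolution

def evolve_genome(parent: tuple[CircularGenome, TruthTable], aa_divergence: float,
                  inversion_blocks: tuple[tuple[int, int], ...] = (),
                  seed: int = 0, child_id: str | None = None) -> tuple[CircularGenome, TruthTable]:
    """Derive a descendant genome: substitutions in coding, block inversions.

    Substitutions are codon-aware: with probability ``aa_divergence`` a
    codon's amino acid is replaced by a different residue (random sense
    codon), so planted proteins never gain stops and expected protein
    identity to the parent is 1 - aa_divergence.  Codons shared between
    overlapping ORFs, start and stop codons are left untouched.

    ``inversion_blocks`` are (start_rank, end_rank) runs of consecutive
    planted ORFs (1-based ranks in the parent's genome order, 2 <= start,
    end < n so the anchor stays fixed); each block is reverse-complemented
    in place, spacer midpoint to spacer midpoint.
    """
    genome, truth = parent
    rng = np.random.default_rng(seed)
    L = genome.length
    seq = list(genome.seq)
    new_truth = copy.deepcopy(truth)
    new_truth.inversions = []
    new_truth.orthologs = {r.orf_id: r.orf_id for r in truth.orfs}
    new_truth.seed = seed

    coverage = np.zeros(L, dtype=np.int16)
    for r in truth.orfs:
        for s, e in r.span_pieces(L):
            coverage[s:e] += 1

    if aa_divergence > 0:
        for r in truth.orfs:
            n_codons = r.length_nt // 3
            for t in range(1, n_codons - 1):  # skip ATG and stop
                if rng.random() >= aa_divergence:
                    continue
                pos = _codon_fwd_positions(r, t, L)  # left-to-right forward order
                if any(coverage[p] > 1 for p in pos):
                    continue  # bases shared with an overlapping ORF stay fixed
                fwd_codon = "".join(seq[p] for p in pos)
                codon = fwd_codon if r.strand == "+" else reverse_complement(fwd_codon)
                aa = _TABLE.forward_table[codon]
                new_aa = _AAS[rng.integers(0, len(_AAS))]
                while new_aa == aa:
                    new_aa = _AAS[rng.integers(0, len(_AAS))]
                choices = _AA_TO_CODONS[new_aa]
                new_codon = choices[rng.integers(0, len(choices))]
                written = new_codon if r.strand == "+" else reverse_complement(new_codon)
                for p, b in zip(pos, written):
                    seq[p] = b

    # segmental inversions (applied after substitutions; order within ranks)
    order = sorted(range(len(new_truth.orfs)), key=lambda i: new_truth.orfs[i].fwd_start)
    blocks = sorted(inversion_blocks)
    for b1, b2 in zip(blocks, blocks[1:]):
        if b1[1] >= b2[0]:
            raise SimulationError(f"overlapping inversion blocks {b1} and {b2}")
    for start_rank, end_rank in blocks:
        nn = len(order)
        if not (2 <= start_rank <= end_rank <= nn - 1):
            raise SimulationError(f"inversion block ({start_rank}, {end_rank}) out of range")
        # widen the block over any planted overlap at its boundaries so the
        # inversion cuts only intergenic sequence
        while start_rank > 2 and (_extent_end(new_truth.orfs[order[start_rank - 2]], L)
                                  > _extent_start(new_truth.orfs[order[start_rank - 1]], L)):
            start_rank -= 1
        while end_rank < nn - 1 and (_extent_end(new_truth.orfs[order[end_rank - 1]], L)
                                     > _extent_start(new_truth.orfs[order[end_rank]], L)):
            end_rank += 1
        first = new_truth.orfs[order[start_rank - 1]]
        last = new_truth.orfs[order[end_rank - 1]]
        prev = new_truth.orfs[order[start_rank - 2]]
        nxt = new_truth.orfs[order[end_rank]]
        left = (_extent_end(prev, L) + _extent_start(first, L)) // 2
        right = (_extent_end(last, L) + _extent_start(nxt, L)) // 2  # exclusive
        if not (0 <= left < right <= L):
            raise SimulationError("inversion segment crosses the origin; move the block")
        if _extent_end(prev, L) > left or _extent_start(nxt, L) < right:
            raise SimulationError("inversion boundary falls inside a planted feature")
        seq[left:right] = list(reverse_complement("".join(seq[left:right])))
        for i, r in enumerate(new_truth.orfs):
            if left <= r.fwd_start < right:
                new_fwd = left + right - (r.fwd_start + r.length_nt)
                new_strand = "-" if r.strand == "+" else "+"
                new_truth.orfs[i] = dataclasses.replace(
                    r, fwd_start=new_fwd, strand=new_strand)
        for rep in new_truth.repeats:
            if left + 1 <= rep.start and rep.end <= right:
                rep.start, rep.end = left + right - rep.end + 1, left + right - rep.start + 1
                if rep.palindrome:
                    ps, pe = rep.palindrome
                    rep.palindrome = (left + right - pe + 1, left + right - ps + 1)
        new_truth.inversions.append(TruthInversion(
            start_index=first.orf_id, end_index=last.orf_id,
            seg_start=left + 1, seg_end=right))
        order = sorted(range(len(new_truth.orfs)), key=lambda i: new_truth.orfs[i].fwd_start)

    new_id = child_id or f"{genome.id}_d{seed}"
    new_genome = CircularGenome(id=new_id, seq="".join(seq))
    new_truth.orfs = [_make_record(r.fwd_start, r.length_nt, r.strand, new_genome, 1, r.orf_id)
                      for r in new_truth.orfs]
    new_truth.orfs.sort(key=lambda r: r.fwd_start)
    seq = list(new_genome.seq)
    new_truth.unsuppressed = _suppress_spurious(seq, new_truth, rng)
    new_genome = CircularGenome(id=new_id, seq="".join(seq))
    new_truth.orfs = [_make_record(r.fwd_start, r.length_nt, r.strand, new_genome, 1, r.orf_id)
                      for r in new_truth.orfs]
    return new_genome, new_truth


def _extent_start(r: OrfRecord, L: int) -> int:
    s = r.fwd_start
    if r.strand == "+":
        s -= 3  # guard
    return s


def _extent_end(r: OrfRecord, L: int) -> int:
    e = r.fwd_start + r.length_nt
    if r.strand == "-":
        e += 3
    return e


# ------------------------------------------------------------- conveniences

FIXTURE_SEED = 1234
FIXTURE_INVERSION = (10, 21)


def fixture_config() -> SimConfig:
    """The fixed configuration behind the documentation/CI genome family."""
    return SimConfig(
        genome_len=30_000, n_orfs=30, gc_target=0.378, overlap_prob=0.2,
        promoter_plan=((2, "late"), (5, "early"), (11, "late"), (17, "early"), (25, "late")),
        repeat_spec=RepeatSpec(unit_len=30, n_copies=7, mismatch_rate=0.08,
                               at_fraction=0.70, truncated=True, with_palindrome=True),
        seed=FIXTURE_SEED,
    )


def fixture_family() -> list[tuple[CircularGenome, "TruthTable"]]:
    """Ancestor + two descendants (20% aa divergence; one 12-gene inversion).

    Deterministic; regenerated on demand rather than shipped as files.
    """
    return simulate_family(fixture_config(), n_children=2, aa_divergence=0.2,
                           inversion_blocks=(FIXTURE_INVERSION,))

def simulate_family(config: SimConfig, n_children: int = 2, aa_divergence: float = 0.2,
                    inversion_blocks: tuple[tuple[int, int], ...] = (),
                    seed: int | None = None) -> list[tuple[CircularGenome, TruthTable]]:
    """An ancestor plus descendants; the first child gets the inversion blocks."""
    base_seed = config.seed if seed is None else seed
    parent = simulate_annotated_genome(config)
    out = [parent]
    for c in range(n_children):
        blocks = inversion_blocks if c == 0 else ()
        out.append(evolve_genome(parent, aa_divergence, blocks,
                                 seed=base_seed + 1000 + c,
                                 child_id=f"{parent[0].id}_c{c + 1}"))
    return out


def verify_truth(genome: CircularGenome, truth: TruthTable) -> None:
    """Assert the truth table is consistent with the emitted sequence."""
    L = genome.length
    for r in truth.orfs:
        rec = _make_record(r.fwd_start, r.length_nt, r.strand, genome, 1, r.orf_id)
        nt = (genome.seq + genome.seq)[r.fwd_start : r.fwd_start + r.length_nt]
        if r.strand == "-":
            nt = reverse_complement(nt)
        if not nt.startswith("ATG") or nt[-3:] not in _STOPS:
            raise SimulationError(f"planted ORF {r.orf_id} lacks ATG...stop")
        if rec.protein != r.protein:
            raise SimulationError(f"planted ORF {r.orf_id} protein mismatch")
    for pr in truth.promoters:
        orf = truth.orf_by_id(pr.orf_index)
        m = pr.position
        # (motif char, nt upstream of the ATG) for every planted base
        placed = [(ch, m - k) for k, ch in enumerate(pr.motif[:4])]
        if pr.kind == "early":
            ini_start = m - 4 - pr.gap
            placed += [(ch, ini_start - k) for k, ch in enumerate(pr.motif[4:])]
        for ch, dist in placed:
            if orf.strand == "+":
                got = genome.seq[(orf.start - 1 - dist) % L]
            else:
                got = reverse_complement(genome.seq[(orf.start - 1 + dist) % L])
            if got != ch:
                raise SimulationError(f"promoter for ORF {pr.orf_index} not on sequence")
    for rep in truth.repeats:
        if rep.end <= rep.start:
            raise SimulationError("degenerate repeat region in truth")
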