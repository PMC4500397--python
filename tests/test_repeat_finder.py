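from functools import lru_cache

import numpy as np
import pytest

from gvcompare.genome_io import CircularGenome, reverse_complement
from gvcompare.orf_annotation import GenomeAnnotation, _make_record
from gvcompare.repeat_finder import (RepeatConfig, RepeatError, classify_region,
                                     find_direct_repeats, find_palindromes,
                                     intergenic_spacers, predict_hairpin)
from gvcompare.synthetic_data import RepeatSpec, SimConfig, simulate_annotated_genome

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def max_pairs_oracle(seq: str) -> int:
    """First-position decomposition over all nested structures (independent
    of the implementation's Nussinov recursion)."""
    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if j - i < 4:
            return 0
        best = rec(i + 1, j)
        for k in range(i + 4, j + 1):
            if (seq[i], seq[k]) in WC:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best
    return rec(0, len(seq) - 1)


# ------------------------------------------------------------------ spacers

def _two_orf_annotation():
    genome = CircularGenome("s", "A" * 300)
    orfs = [
        _make_record(0, 99, "+", genome, 1, 1),
        _make_record(150, 150, "+", genome, 1, 2),
    ]
    ann = GenomeAnnotation.__new__(GenomeAnnotation)
    ann.genome, ann.orfs, ann.anchor_orf_id = genome, orfs, 1
    return ann


def test_spacers_between_two_orfs():
    sps = intergenic_spacers(_two_orf_annotation(), min_len=10)
    by_start = {sp.start: sp for sp in sps}
    assert 100 in by_start
    sp = by_start[100]
    assert (sp.end, sp.left_orf_id, sp.right_orf_id) == (150, 1, 2)


def test_fully_coding_genome_has_no_spacers():
    genome = CircularGenome("f", "A" * 300)
    orfs = [_make_record(0, 150, "+", genome, 1, 1), _make_record(150, 150, "+", genome, 1, 2)]
    ann = GenomeAnnotation.__new__(GenomeAnnotation)
    ann.genome, ann.orfs, ann.anchor_orf_id = genome, orfs, 1
    assert intergenic_spacers(ann) == []


def test_spacer_wraps_origin():
    # a single mid-genome ORF leaves one spacer that crosses the origin
    genome = CircularGenome("w", "A" * 300)
    ann = GenomeAnnotation.__new__(GenomeAnnotation)
    ann.genome = genome
    ann.orfs = [_make_record(100, 90, "+", genome, 1, 1)]
    ann.anchor_orf_id = 1
    sps = intergenic_spacers(ann, min_len=5)
    assert len(sps) == 1
    sp = sps[0]
    assert sp.start == 191 and sp.end == 100 and sp.length == 210


# ------------------------------------------------------------- direct repeats

def test_perfect_tandem_array():
    regs = find_direct_repeats("ACGTACGTACGT", RepeatConfig(min_unit_nt=4, min_copies=2))
    assert len(regs) == 1
    reg = regs[0]
    assert (reg.start, reg.end, reg.n_full_copies, reg.unit_consensus) == (1, 12, 3, "ACGT")


def test_random_sequence_rarely_yields_regions():
    rng = np.random.default_rng(1)
    cfg = RepeatConfig()  # unit >= 15, <= 20% mismatch
    hits = sum(
        bool(find_direct_repeats("".join(rng.choice(list("ACGT"), size=500)), cfg))
        for _ in range(60))
    assert hits <= 3  # >= 95% of draws clean


def test_regions_never_overlap_and_copies_obey_mismatch_bound():
    rng = np.random.default_rng(4)
    cfg = RepeatConfig(min_unit_nt=10)
    from gvcompare.repeat_finder import _copy_mismatches
    for _ in range(10):
        unit = "".join(rng.choice(list("ACGT"), size=20))
        arr = "".join(unit if rng.random() > .5 else unit for _ in range(4))
        seq = ("".join(rng.choice(list("ACGT"), size=60)) + arr
               + "".join(rng.choice(list("ACGT"), size=60)))
        regs = find_direct_repeats(seq, cfg)
        for i in range(len(regs)):
            for j in range(i + 1, len(regs)):
                assert regs[i].end < regs[j].start or regs[j].end < regs[i].start
        for reg in regs:
            p = len(reg.unit_consensus)
            copies = [seq[reg.start - 1 + k * p: reg.start - 1 + (k + 1) * p]
                      for k in range(reg.n_full_copies)]
            full = [c for c in copies if len(c) == p]
            assert all(m <= cfg.max_mismatch_fraction * p for m in _copy_mismatches(full))


def test_planted_array_boundary_recovery():
    """Planted imperfect arrays in random spacers: boundaries within +-5 nt
    for at least 90% of cases.

    The per-copy mismatch rate is drawn from 5-10%; beyond ~12% per base a
    cluster of substitutions at an array edge becomes statistically
    indistinguishable from background and no detector can place the
    boundary to +-5 nt reliably.
    """
    rng = np.random.default_rng(8)
    cfg = RepeatConfig()
    good = total = 0
    for _ in range(100):
        p = int(rng.integers(20, 51))
        n_copies = int(rng.integers(3, 8))
        mm = rng.uniform(0.05, 0.10)
        unit = "".join(rng.choice(list("ACGT"), size=p, p=[.35, .15, .15, .35]))
        copies = []
        for _c in range(n_copies):
            copies.append("".join(
                ch if rng.random() > mm else [b for b in "ACGT" if b != ch][rng.integers(0, 3)]
                for ch in unit))
        left = "".join(rng.choice(list("ACGT"), size=80))
        right = "".join(rng.choice(list("ACGT"), size=80))
        seq = left + "".join(copies) + right
        true_start, true_end = 81, 80 + n_copies * p
        regs = find_direct_repeats(seq, cfg)
        if not regs:
            total += 1
            continue
        reg = max(regs, key=lambda r: r.n_full_copies)
        total += 1
        if abs(reg.start - true_start) <= 5 and abs(reg.end - true_end) <= 5:
            good += 1
    assert good / total >= 0.9


def test_planted_repeat_recovered_from_simulated_genome(sim_pair, sim_annotation):
    genome, truth = sim_pair
    rep = truth.repeats[0]
    cfg = RepeatConfig()
    from gvcompare.genome_io import circular_subsequence
    found = None
    for sp in intergenic_spacers(sim_annotation, min_len=60):
        sub = circular_subsequence(genome, sp.start, sp.end, "+")
        for reg in find_direct_repeats(sub, cfg):
            gstart = (sp.start - 1 + reg.start - 1) % genome.length + 1
            if abs(gstart - rep.start) <= 10:
                found = (gstart, (sp.start - 1 + reg.end - 1) % genome.length + 1, reg, sub)
    assert found is not None
    gstart, gend, reg, sub = found
    assert reg.n_full_copies == rep.n_copies
    assert reg.has_truncated_copy == rep.truncated
    assert abs(gstart - rep.start) <= 10 and abs(gend - rep.end) <= 10
    assert classify_region(reg, cfg, seq=sub) == "non_hr"


def test_single_copy_is_below_min_copies():
    rng = np.random.default_rng(12)
    unit = "".join(rng.choice(list("ACGT"), size=25))
    seq = "".join(rng.choice(list("ACGT"), size=100)) + unit + "".join(
        rng.choice(list("ACGT"), size=100))
    assert find_direct_repeats(seq, RepeatConfig()) == []


def test_bed_export_converts_to_zero_based_half_open(tmp_path):
    from gvcompare.repeat_finder import write_bed
    regs = find_direct_repeats("ACGTACGTACGT", RepeatConfig(min_unit_nt=4, min_copies=2))
    p = tmp_path / "r.bed"
    write_bed(regs, p, chrom="g1", offset=100)
    chrom, start, end, name = p.read_text().split()
    assert (chrom, int(start), int(end)) == ("g1", 100, 112)


# --------------------------------------------------------------- palindromes

def test_palindrome_examples():
    cfg = RepeatConfig(min_palindrome_arm=3, max_loop_nt=2)
    pals = find_palindromes("GAATTC", cfg)
    assert [(p.start, p.end, p.arm_len, p.mismatches) for p in pals] == [(1, 6, 3, 0)]
    assert find_palindromes("AAAAAAAA", cfg) == []


def test_planted_imperfect_palindrome_recovered():
    rng = np.random.default_rng(6)
    arm = "".join(rng.choice(list("ACGT"), size=12))
    right = list(reverse_complement(arm))
    right[5] = [b for b in "ACGT" if b != right[5]][0]  # one arm mismatch
    pal = arm + "TTAA" + "".join(right)
    seq = "".join(rng.choice(list("ACGT"), size=70)) + pal + "".join(
        rng.choice(list("ACGT"), size=70))
    pals = find_palindromes(seq, RepeatConfig(min_palindrome_arm=8))
    hit = max(pals, key=lambda p: p.arm_len - p.mismatches)
    assert abs(hit.start - 71) <= 2 and abs(hit.end - (70 + len(pal))) <= 2


def test_palindromes_are_strand_symmetric():
    rng = np.random.default_rng(7)
    cfg = RepeatConfig(min_palindrome_arm=4)
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGT"), size=120))
        fwd = {(p.start, p.end, p.arm_len) for p in find_palindromes(seq, cfg)}
        n = len(seq)
        rev = {(n - p.end + 1, n - p.start + 1, p.arm_len)
               for p in find_palindromes(reverse_complement(seq), cfg)}
        assert fwd == rev


# ------------------------------------------------------------------ hairpins

def test_hairpin_examples():
    hp = predict_hairpin("GGGAAACCC")
    assert hp.n_pairs == 3 and hp.loop_len == 3
    assert predict_hairpin("AAAAAA").n_pairs == 0
    stem = "GCGTACGA"
    hp2 = predict_hairpin(stem + "TTTT" + reverse_complement(stem))
    assert hp2.n_pairs == 8


def test_hairpin_length_bounds():
    with pytest.raises(RepeatError):
        predict_hairpin("ACGT")
    with pytest.raises(RepeatError):
        predict_hairpin("A" * 2001)


def test_hairpin_matches_enumeration_oracle_and_is_well_formed():
    rng = np.random.default_rng(9)
    for _ in range(60):
        n = int(rng.integers(5, 23))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        hp = predict_hairpin(seq)
        assert hp.n_pairs == max_pairs_oracle(seq)
        for i, j in hp.pairs:
            assert (seq[i], seq[j]) in WC and j - i >= 4
        # nested (non-crossing)
        for (i1, j1) in hp.pairs:
            for (i2, j2) in hp.pairs:
                assert not (i1 < i2 < j1 < j2)


def test_hairpin_dot_bracket_is_balanced():
    hp = predict_hairpin("GGGAAACCC")
    db = hp.dot_bracket(9)
    assert db.count("(") == db.count(")") == 3


# -------------------------------------------------------------- classification

def test_gc_rich_repeat_without_palindrome_is_none():
    unit = "GGCAGCGGCAGGCGGCAGGG"
    seq = unit * 4
    cfg = RepeatConfig(min_unit_nt=10)
    regs = find_direct_repeats(seq, cfg)
    assert regs
    assert classify_region(regs[0], cfg, seq=seq) == "none"


def test_hr_style_array_classifies_hr_like():
    cfg = SimConfig(genome_len=20000, n_orfs=18, seed=101,
                    repeat_spec=RepeatSpec(unit_len=40, n_copies=5, mismatch_rate=0.05,
                                           at_fraction=0.65, centered_palindrome=True,
                                           truncated=False))
    g, truth = simulate_annotated_genome(cfg)
    rep = truth.repeats[0]
    sub = g.seq[rep.start - 31: rep.end + 30]
    rc = RepeatConfig()
    reg = max(find_direct_repeats(sub, rc), key=lambda r: r.n_full_copies)
    assert classify_region(reg, rc, seq=sub) == "hr_like"
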