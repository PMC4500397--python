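import numpy as np
import pytest

from gvcompare.genome_io import CircularGenome, reverse_complement
from gvcompare.orf_annotation import (AnnotationConfig, AnnotationError, GenomeAnnotation,
                                      anchor_and_number, annotate, annotation_stats,
                                      enumerate_candidate_orfs, resolve_minimal_overlap,
                                      _make_record)

STOPS = {"TAA", "TAG", "TGA"}


def sixframe_oracle(seq: str, min_nt: int) -> set[tuple[str, int, int]]:
    """Literal per-position scan: every maximal ATG..stop span on the circle.

    Independent of the implementation: walks codons base-by-base in both
    directions from every ATG, with no doubling or frame bookkeeping.
    """
    L = len(seq)
    out = set()
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)

        def codon(p):
            return "".join(s[(p + k) % L] for k in range(3))

        for p in range(L):
            if codon(p) != "ATG":
                continue
            q, first_atg = p, None
            for _ in range(L):
                q = (q - 3) % L
                c = codon(q)
                if c in STOPS:
                    first_atg = True
                    break
                if c == "ATG":
                    first_atg = False
                    break
            if not first_atg:
                continue
            length = None
            for step in range(1, L // 3 + 2):
                if codon(p + 3 * step) in STOPS:
                    length = 3 * step + 3
                    break
            if length is None or length > L or length < min_nt:
                continue
            fwd = p if strand == "+" else (L - p - length) % L
            out.add((strand, fwd, length))
    return out


def orf_keys(orfs):
    return {(r.strand, r.fwd_start, r.length_nt) for r in orfs}


def test_config_validation():
    with pytest.raises(AnnotationError):
        AnnotationConfig(min_orf_nt=100)  # not divisible by 3
    with pytest.raises(AnnotationError):
        AnnotationConfig(max_overlap_fraction=1.5)


def test_enumeration_matches_sixframe_oracle_on_random_circles():
    rng = np.random.default_rng(17)
    cfg = AnnotationConfig(min_orf_nt=60)
    for _ in range(30):
        L = int(rng.integers(80, 500))
        seq = "".join(rng.choice(list("ACGT"), size=L, p=[.31, .19, .19, .31]))
        g = CircularGenome("r", seq)
        assert orf_keys(enumerate_candidate_orfs(g, cfg)) == sixframe_oracle(seq, 60)


def test_planted_orf_and_wraparound_detection():
    # 400 nt circle of plain background; one ORF planted crossing the origin
    rng = np.random.default_rng(3)
    orf = "ATG" + "".join(["GCA"] * 50) + "TAA"  # 156 nt, alanine body
    seq = list("C" * 400)
    start0 = 389  # 0-based; wraps through the origin
    for k, ch in enumerate("TAA" + orf):  # guard stop then the ORF
        seq[(start0 - 3 + k) % 400] = ch
    g = CircularGenome("wrap", "".join(seq))
    found = enumerate_candidate_orfs(g, AnnotationConfig(min_orf_nt=150))
    assert ("+", start0, 156) in orf_keys(found)
    rec = [r for r in found if r.fwd_start == start0][0]
    assert rec.start == 390 and rec.protein == "M" + "A" * 50


def test_no_atg_means_no_orfs():
    g = CircularGenome("polyA", "A" * 300)
    assert enumerate_candidate_orfs(g, AnnotationConfig()) == []


def test_genome_shorter_than_min_orf_gives_empty():
    g = CircularGenome("tiny", "ATGAAATAA")
    assert enumerate_candidate_orfs(g, AnnotationConfig(min_orf_nt=150)) == []


def _rec(genome, fwd, ln, strand):
    return _make_record(fwd, ln, strand, genome, 1)


def test_minimal_overlap_drops_the_shorter_of_a_conflicting_pair(sim_pair):
    genome, _ = sim_pair
    a = _rec(genome, 0, 300, "+")
    b = _rec(genome, 30, 300, "+")  # 270/300 = 90% overlap with a
    kept = resolve_minimal_overlap([a, b], AnnotationConfig(), genome.length)
    assert len(kept) == 1 and kept[0].fwd_start == 0  # tie on length -> smaller start


def test_minimal_overlap_keeps_disjoint_candidates(sim_pair):
    genome, _ = sim_pair
    cands = [_rec(genome, 0, 300, "+"), _rec(genome, 400, 300, "-"), _rec(genome, 800, 300, "+")]
    kept = resolve_minimal_overlap(cands, AnnotationConfig(), genome.length)
    assert orf_keys(kept) == orf_keys(cands)


def test_selected_set_never_violates_overlap_cap(sim_annotation):
    cfg = AnnotationConfig()
    L = sim_annotation.genome.length
    orfs = sim_annotation.orfs
    from gvcompare.orf_annotation import _overlap_nt
    for i in range(len(orfs)):
        for j in range(i + 1, len(orfs)):
            ov = _overlap_nt(orfs[i], orfs[j], L)
            assert ov <= cfg.max_overlap_fraction * min(orfs[i].length_nt, orfs[j].length_nt)


def test_anchoring_preserves_proteins_and_sets_anchor_to_position_1(sim_pair):
    genome, truth = sim_pair
    ann = annotate(genome)
    before = sorted(r.protein for r in ann.orfs)
    for anchor in (ann.orfs[5], ann.orfs[12]):
        re_ann = anchor_and_number(ann.orfs, genome, anchor)
        anchor_rec = re_ann.orf(re_ann.anchor_orf_id)
        assert anchor_rec.start == 1 and anchor_rec.strand == "+"
        assert sorted(r.protein for r in re_ann.orfs) == before


def test_anchoring_on_minus_strand_flips_genome(sim_pair):
    genome, _ = sim_pair
    ann = annotate(genome)
    minus = next(r for r in ann.orfs if r.strand == "-")
    re_ann = anchor_and_number(ann.orfs, genome, minus)
    rec = re_ann.orf(re_ann.anchor_orf_id)
    assert rec.start == 1 and rec.strand == "+"
    assert rec.protein == minus.protein


def test_anchor_must_be_selected(sim_pair):
    genome, _ = sim_pair
    ann = annotate(genome)
    stranger = _rec(genome, 9, 300, "+")
    with pytest.raises(AnnotationError):
        anchor_and_number(ann.orfs, genome, stranger)


def test_adjacent_overlap_listing(sim_pair):
    genome, _ = sim_pair
    a = _rec(genome, 0, 102, "+")    # spans 1..102
    b = _rec(genome, 80, 120, "+")   # spans 81..200: 22 nt shared
    ann = GenomeAnnotation(genome=genome, orfs=sorted([a, b], key=lambda r: r.fwd_start))
    st = annotation_stats(ann)
    assert [(x, y, ov) for x, y, ov in st.adjacent_overlaps if ov == 22]


def test_stats_match_planted_truth(sim_pair, sim_annotation):
    genome, truth = sim_pair
    st = annotation_stats(sim_annotation)
    assert st.n_orfs == len(truth.orfs)
    assert st.n_plus == sum(1 for r in truth.orfs if r.strand == "+")
    assert st.n_minus == sum(1 for r in truth.orfs if r.strand == "-")
    # per-base bitmap oracle for the span-union coding fraction
    covered = set()
    for r in truth.orfs:
        for k in range(r.length_nt):
            covered.add((r.fwd_start + k) % genome.length)
    assert st.coding_fraction == pytest.approx(len(covered) / genome.length)
    planted_overlap = sum(
        1 for i in range(len(truth.orfs))
        if set(range(truth.orfs[i].fwd_start, truth.orfs[i].fwd_start + truth.orfs[i].length_nt))
        & set(range(truth.orfs[(i + 1) % len(truth.orfs)].fwd_start,
                    truth.orfs[(i + 1) % len(truth.orfs)].fwd_start
                    + truth.orfs[(i + 1) % len(truth.orfs)].length_nt))
    )
    assert len(st.adjacent_overlaps) == planted_overlap


def test_annotation_recovers_exactly_the_planted_set(sim_pair, sim_annotation):
    _, truth = sim_pair
    assert orf_keys(sim_annotation.orfs) == orf_keys(truth.orfs)


def test_rescue_forces_subthreshold_orf(sim_pair):
    genome, _ = sim_pair
    short_cands = enumerate_candidate_orfs(genome, AnnotationConfig(min_orf_nt=90))
    selected = annotate(genome).orfs
    extra = [r for r in short_cands if r.length_nt < 150
             and (r.strand, r.fwd_start, r.length_nt) not in orf_keys(selected)]
    if not extra:
        pytest.skip("no sub-threshold ORF present in this genome")
    ann = annotate(genome, rescue=extra[:1])
    assert orf_keys(ann.orfs) >= orf_keys(selected) | orf_keys(extra[:1])


def test_gff3_round_trip_coordinates(tmp_path, sim_annotation):
    from gvcompare.orf_annotation import write_gff3
    p = tmp_path / "ann.gff3"
    write_gff3(sim_annotation, p)
    lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) >= len(sim_annotation.orfs)
    for l in lines:
        f = l.split("\t")
        assert f[2] == "CDS" and f[6] in "+-"
        assert 1 <= int(f[3]) <= int(f[4]) <= sim_annotation.genome.length


def test_overlap_table_round_trip(tmp_path, sim_annotation):
    import pandas as pd
    from gvcompare.orf_annotation import write_overlap_table
    p = tmp_path / "overlaps.tsv"
    write_overlap_table(sim_annotation, p)
    df = pd.read_csv(p, sep="\t")
    st = annotation_stats(sim_annotation)
    assert len(df) == len(st.adjacent_overlaps)
    if len(df):
        assert (df["overlap_nt"] > 0).all()
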