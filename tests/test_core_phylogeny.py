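import itertools
import math

import numpy as np
import pytest

from gvcompare.core_phylogeny import (DistanceMatrix, PhylogenyError, Supermatrix,
                                      bootstrap_support, build_supermatrix,
                                      center_star_align, nj_tree, protein_distance)

AA = list("ACDEFGHIKLMNPQRSTVWY")


# --------------------------------------------------- random additive trees

def random_topology(rng, taxa):
    """Random unrooted binary tree as nested tuples, by sequential attachment."""
    tree = tuple(taxa[:3])
    for t in taxa[3:]:
        tree = _insert(tree, t, rng)
    return tree


def _insert(tree, leaf, rng):
    if not isinstance(tree, tuple):
        return (tree, leaf) if rng.random() < 0.5 else (leaf, tree)
    k = int(rng.integers(0, len(tree) + 1))
    if k == len(tree):
        if len(tree) == 3:  # root trifurcation: drop into a random child instead
            k = int(rng.integers(0, 3))
        else:
            return (tree, leaf)
    return tuple(_insert(c, leaf, rng) if i == k else c for i, c in enumerate(tree))


def tree_paths(tree, rng, lengths=None):
    """Assign random positive branch lengths; return leaf-pair path distances
    and the set of non-trivial splits."""
    if lengths is None:
        lengths = {}
    leaf_sets = {}
    dists = {}

    def walk(sub):
        if not isinstance(sub, tuple):
            leaf_sets[id(sub)] = frozenset([sub])
            return {sub: 0.0}
        below = {}
        for c in sub:
            sub_d = walk(c)
            bl = lengths.setdefault(id(c), float(rng.uniform(0.05, 1.0)))
            sub_d = {k: v + bl for k, v in sub_d.items()}
            for k1, v1 in below.items():
                for k2, v2 in sub_d.items():
                    dists[frozenset((k1, k2))] = v1 + v2
            below.update(sub_d)
        leaf_sets[id(sub)] = frozenset(below)
        return below

    all_leaves = frozenset(walk(tree))
    splits = set()

    def collect(sub):
        if not isinstance(sub, tuple):
            return
        for c in sub:
            side = leaf_sets[id(c)] if isinstance(c, tuple) else frozenset([c])
            if 2 <= len(side) <= len(all_leaves) - 2:
                ref = sorted(all_leaves)[0]
                splits.add(all_leaves - side if ref in side else side)
            collect(c)

    collect(tree)
    return dists, splits


def additive_matrix(taxa, dists):
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dists[frozenset((taxa[i], taxa[j]))]
    return DistanceMatrix(list(taxa), m)


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
def test_nj_recovers_random_additive_trees(n_taxa):
    rng = np.random.default_rng(n_taxa)
    taxa = [f"t{i}" for i in range(n_taxa)]
    for _ in range(8):
        topo = random_topology(rng, taxa)
        dists, true_splits = tree_paths(topo, rng)
        dm = additive_matrix(sorted(taxa), dists)
        tree = nj_tree(dm)
        assert tree.bipartitions() == true_splits
        # path lengths reproduce the additive input exactly
        rec = tree.leaf_distance_matrix()
        assert np.allclose(rec.matrix, additive_matrix(rec.taxa, dists).matrix, atol=1e-9)


def test_nj_three_taxon_closed_form():
    dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
    tree = nj_tree(dm)
    lengths = {c.name: c.length for c in tree.root.children}
    assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)


def test_nj_agrees_with_scikit_bio_on_topology():
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(42)
    taxa = [f"t{i}" for i in range(7)]
    topo = random_topology(rng, taxa)
    dists, true_splits = tree_paths(topo, rng)
    dm = additive_matrix(sorted(taxa), dists)
    ours = nj_tree(dm).bipartitions()
    sk_tree = sk_nj(SkDM(dm.matrix, ids=dm.taxa))
    ref = sorted(taxa)[0]
    all_t = frozenset(taxa)
    theirs = set()
    for node in sk_tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_t - side
        if 2 <= len(side) <= len(all_t) - 2:
            theirs.add(side)
    assert ours == theirs == true_splits


def test_nj_input_validation():
    with pytest.raises(PhylogenyError):
        DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))  # asymmetric
    with pytest.raises(PhylogenyError):
        DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]], float))
    with pytest.raises(PhylogenyError):
        nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


# ----------------------------------------------------------------- distances

def test_poisson_distance_closed_form():
    rows = {"a": "A" * 100, "b": "C" * 10 + "A" * 90}
    sm = Supermatrix(taxa=["a", "b"], rows=rows, boundaries=[("g", 0, 100)])
    d = protein_distance(sm)
    assert d.get("a", "b") == pytest.approx(-math.log(0.9), abs=1e-9)
    assert d.get("a", "a") == 0.0


def test_distance_pairwise_deletion_and_errors():
    rows = {"a": "AAAA--", "b": "--AAAA", "c": "CCCC--"}
    sm = Supermatrix(taxa=["a", "b", "c"], rows=rows, boundaries=[("g", 0, 6)])
    d = protein_distance(sm)
    assert d.get("a", "b") == 0.0  # two comparable columns, both identical
    assert d.get("a", "c") == 10.0  # saturated -> capped
    rows2 = {"a": "AA--", "b": "--AA"}
    with pytest.raises(PhylogenyError, match="no comparable"):
        protein_distance(Supermatrix(taxa=["a", "b"], rows=rows2, boundaries=[("g", 0, 4)]))


# --------------------------------------------------------------- supermatrix

def test_supermatrix_concatenation_and_missing_mask():
    b1 = ("g1", {"a": "MKVLYAQRST", "b": "MKVLYAQRSV"})
    b2 = ("g2", {"a": "WYE" * 5, "c": "WYD" * 5})
    sm = build_supermatrix([b1, b2])
    assert sm.taxa == ["a", "b", "c"]
    assert sm.n_columns == 25
    assert sm.boundaries == [("g1", 0, 10), ("g2", 10, 25)]
    assert sm.rows["b"][10:] == "-" * 15
    assert sm.missing == {"b": ["g2"], "c": ["g1"]}
    assert sm.rows["a"] == b1[1]["a"] + b2[1]["a"]  # manual paste oracle


def test_supermatrix_rejects_ragged_blocks():
    with pytest.raises(PhylogenyError, match="conflicting row lengths"):
        build_supermatrix([("g", {"a": "MK", "b": "MKV"})])


def test_center_star_preserves_residues():
    seqs = {"a": "MKVLYAQ", "b": "MKVLYAQ", "c": "MKVLGAQ"}
    aligned = center_star_align(seqs)
    widths = {len(s) for s in aligned.values()}
    assert len(widths) == 1
    for name, s in aligned.items():
        assert s.replace("-", "") == seqs[name]


# ----------------------------------------------------------------- bootstrap

def _clustered_supermatrix(rng, n_cols=120):
    """Two well-separated 3-taxon clusters with hierarchical signal inside
    each cluster, so every internal edge of the true tree is determined."""
    def mutate(row, n_subs):
        row = row.copy()
        idx = rng.choice(n_cols, size=n_subs, replace=False)
        for k in idx:
            row[k] = rng.choice([a for a in AA if a != row[k]])
        return row

    root = rng.choice(AA, size=n_cols)
    rows = {}
    for i in range(2):
        base = mutate(root, 25)  # clusters well apart but far from saturation
        inner = mutate(base, 15)  # shared branch: synapomorphies for (t0, t1)
        rows[f"c{i}t0"] = "".join(mutate(inner, 2))
        rows[f"c{i}t1"] = "".join(mutate(inner, 3))
        rows[f"c{i}t2"] = "".join(mutate(base, 20))
    return Supermatrix(taxa=sorted(rows), rows=rows, boundaries=[("g", 0, n_cols)])


def test_bootstrap_full_support_for_separated_clusters():
    rng = np.random.default_rng(1)
    sm = _clustered_supermatrix(rng)
    tree = bootstrap_support(sm, n_replicates=100, seed=3)
    supports = [c.support for c in _internal_nodes(tree.root) if c.support is not None]
    assert supports and all(s == 100.0 for s in supports)


def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(2)
    sm = _clustered_supermatrix(rng)
    t1 = bootstrap_support(sm, n_replicates=50, seed=9)
    t2 = bootstrap_support(sm, n_replicates=50, seed=9)
    assert t1.newick() == t2.newick()


def test_bootstrap_supports_invariant_to_taxon_order():
    rng = np.random.default_rng(3)
    sm = _clustered_supermatrix(rng)
    perm = list(reversed(sm.taxa))
    sm2 = Supermatrix(taxa=sorted(perm), rows={t: sm.rows[t] for t in perm},
                      boundaries=list(sm.boundaries))
    s1 = _support_by_split(bootstrap_support(sm, 50, seed=5))
    s2 = _support_by_split(bootstrap_support(sm2, 50, seed=5))
    assert s1 == s2


def test_bootstrap_random_alignment_has_weak_support():
    rng = np.random.default_rng(4)
    supports = []
    for _ in range(8):
        rows = {f"t{i}": "".join(rng.choice(AA, size=80)) for i in range(6)}
        sm = Supermatrix(taxa=sorted(rows), rows=rows, boundaries=[("g", 0, 80)])
        tree = bootstrap_support(sm, n_replicates=60, seed=int(rng.integers(0, 2**31)))
        supports += [c.support for c in _internal_nodes(tree.root) if c.support is not None]
    assert supports and float(np.median(supports)) < 70.0
    assert all(0.0 <= s <= 100.0 for s in supports)


def _internal_nodes(node):
    out = []
    for c in node.children:
        if not c.is_leaf:
            out.append(c)
            out.extend(_internal_nodes(c))
    return out


def _support_by_split(tree):
    all_taxa = frozenset(tree.taxa)
    ref = tree.taxa[0]
    out = {}

    def walk(node):
        for c in node.children:
            if not c.is_leaf and c.support is not None:
                side = frozenset(c.leaves())
                if ref in side:
                    side = all_taxa - side
                out[side] = c.support
            walk(c)

    walk(tree.root)
    return out
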