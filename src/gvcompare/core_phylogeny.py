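"""Concatenated core-protein phylogeny: supermatrix, distances, NJ, bootstrap.

Whole-family baculovirus phylogenies are built from the concatenation of
the gene families present in every sequenced genome (the "core" genes).
This module assembles per-gene protein alignments into a supermatrix,
computes Poisson-corrected pairwise distances d = -ln(1 - p) under
pairwise deletion, infers a neighbor-joining tree (Saitou-Nei Q criterion,
deterministic lowest-index tie-break), and attaches nonparametric bootstrap
support by column resampling.  The distance+NJ pipeline is deterministic
and exactly recovers any additive distance matrix, which makes it testable
against closed-form oracles; it stands in for likelihood methods at the
topology level, and the supermatrix can be exported for external ML tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Supermatrix",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "PhylogenyError",
    "center_star_align",
    "build_supermatrix",
    "protein_distance",
    "nj_tree",
    "bootstrap_support",
]

GAP = "-"


class PhylogenyError(ValueError):
    pass


# ---------------------------------------------------------------- alignment

def center_star_align(seqs: dict[str, str]) -> dict[str, str]:
    """Approximate multiple alignment by the center-star method.

    The center is the sequence maximizing the summed global alignment score
    to all others; every other sequence is aligned to the center and the
    pairwise alignments are merged ("once a gap, always a gap").  Adequate
    for the closely-related, indel-poor protein families this package
    simulates; pre-computed alignments may be supplied instead.
    """
    from .gene_classification import _aligner

    names = sorted(seqs)
    if len(names) == 1:
        return dict(seqs)
    aligner = _aligner("global")
    totals = {
        a: sum(float(aligner.score(seqs[a], seqs[b])) for b in names if b != a)
        for a in names
    }
    center = max(names, key=lambda a: (totals[a], -names.index(a)))
    master = seqs[center]  # center row with accumulated gaps
    rows: dict[str, str] = {}
    for name in names:
        if name == center:
            continue
        aln = aligner.align(seqs[center], seqs[name])[0]
        c_aln, o_aln = str(aln[0]), str(aln[1])
        master, rows, new_row = _merge_into_msa(master, rows, c_aln, o_aln)
        rows[name] = new_row
    out = {center: master}
    out.update(rows)
    return {k: out[k] for k in sorted(out)}


def _merge_into_msa(master: str, rows: dict[str, str], c_aln: str, o_aln: str):
    """Merge a (center, other) pairwise alignment into the running MSA."""
    new_master: list[str] = []
    new_rows: dict[str, list[str]] = {k: [] for k in rows}
    new_other: list[str] = []
    i = j = 0
    while i < len(master) or j < len(c_aln):
        a = master[i] if i < len(master) else None
        b = c_aln[j] if j < len(c_aln) else None
        if a is not None and b is not None and (a != GAP) and (b != GAP):
            new_master.append(a)
            for k in rows:
                new_rows[k].append(rows[k][i])
            new_other.append(o_aln[j])
            i += 1
            j += 1
        elif a == GAP and b == GAP:
            new_master.append(GAP)
            for k in rows:
                new_rows[k].append(rows[k][i])
            new_other.append(o_aln[j])
            i += 1
            j += 1
        elif a == GAP:
            new_master.append(GAP)
            for k in rows:
                new_rows[k].append(rows[k][i])
            new_other.append(GAP)
            i += 1
        else:  # b is GAP (or master exhausted): gap column introduced by the new pair
            new_master.append(GAP if b == GAP else (a or GAP))
            if b == GAP:
                for k in rows:
                    new_rows[k].append(GAP)
                new_other.append(o_aln[j])
                j += 1
            else:
                for k in rows:
                    new_rows[k].append(rows[k][i])
                new_other.append(GAP)
                i += 1
    return "".join(new_master), {k: "".join(v) for k, v in new_rows.items()}, "".join(new_other)


# --------------------------------------------------------------- supermatrix

@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]
    boundaries: list[tuple[str, int, int]]  # (gene, start_col, end_col) 0-based half-open
    missing: dict[str, list[str]] = field(default_factory=dict)  # taxon -> genes gap-filled

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def column_sample(self, columns: np.ndarray) -> "Supermatrix":
        rows = {t: "".join(self.rows[t][c] for c in columns) for t in self.taxa}
        return Supermatrix(taxa=list(self.taxa), rows=rows,
                           boundaries=[("resampled", 0, len(columns))],
                           missing=dict(self.missing))

    def write_phylip(self, path: str | Path) -> None:
        """Relaxed PHYLIP (name, two spaces, row) for external ML tools."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)} {self.n_columns}\n")
            for t in self.taxa:
                fh.write(f"{t}  {self.rows[t]}\n")


def build_supermatrix(per_gene_alignments: Sequence[tuple[str, dict[str, str]]]) -> Supermatrix:
    """Column-wise concatenation of per-gene aligned blocks in the given order.

    A taxon absent from a block is gap-filled across that block and recorded
    in the missing mask.  Rows within a block must share one length.
    """
    if not per_gene_alignments:
        raise PhylogenyError("no alignment blocks given")
    taxa = sorted({t for _, block in per_gene_alignments for t in block})
    rows = {t: [] for t in taxa}
    boundaries = []
    missing: dict[str, list[str]] = {}
    col = 0
    for gene, block in per_gene_alignments:
        widths = {len(s) for s in block.values()}
        if len(widths) != 1:
            raise PhylogenyError(f"block {gene!r}: conflicting row lengths {sorted(widths)}")
        w = widths.pop()
        for t in taxa:
            if t in block:
                rows[t].append(block[t])
            else:
                rows[t].append(GAP * w)
                missing.setdefault(t, []).append(gene)
        boundaries.append((gene, col, col + w))
        col += w
    return Supermatrix(taxa=taxa, rows={t: "".join(v) for t, v in rows.items()},
                       boundaries=boundaries, missing=missing)


# ----------------------------------------------------------------- distances

@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise PhylogenyError("distance matrix shape does not match taxa")
        if not np.allclose(m, m.T, atol=1e-12):
            raise PhylogenyError("distance matrix must be symmetric")
        if (m < 0).any():
            raise PhylogenyError("distance matrix must be nonnegative")
        if not np.allclose(np.diag(m), 0.0):
            raise PhylogenyError("distance matrix diagonal must be zero")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])


def protein_distance(sm: Supermatrix, max_distance: float = 10.0,
                     complete_deletion: bool = False) -> DistanceMatrix:
    """Poisson-corrected pairwise distances d = -ln(1 - p).

    p is the mismatch proportion over mutually non-gap columns (pairwise
    deletion; ``complete_deletion`` restricts to columns gapless in every
    taxon).  Saturated pairs (p -> 1) are capped at ``max_distance``.
    """
    taxa = sm.taxa
    if len(taxa) < 2:
        raise PhylogenyError("need at least 2 taxa")
    arr = np.array([list(sm.rows[t]) for t in taxa])
    nongap = arr != GAP
    if complete_deletion:
        keep = nongap.all(axis=0)
        arr = arr[:, keep]
        nongap = nongap[:, keep]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = nongap[i] & nongap[j]
            n_comp = int(comparable.sum())
            if n_comp == 0:
                raise PhylogenyError(
                    f"taxa {taxa[i]!r} and {taxa[j]!r} share no comparable columns")
            p = float((arr[i, comparable] != arr[j, comparable]).sum()) / n_comp
            if p >= 1.0 - 1e-12:
                dij = max_distance
            else:
                dij = min(-math.log(1.0 - p), max_distance)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(taxa=list(taxa), matrix=d)


# ------------------------------------------------------------------ NJ tree

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to the parent
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6f}"


@dataclass
class PhyloTree:
    """Unrooted tree stored with a trifurcating root; support in [0, 100]."""

    root: TreeNode
    taxa: list[str]

    def newick(self) -> str:
        inner = ",".join(c.newick() for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each normalized to the side without taxa[0]."""
        all_taxa = frozenset(self.taxa)
        ref = self.taxa[0]
        splits: set[frozenset[str]] = set()
        def walk(node: TreeNode) -> None:
            for c in node.children:
                side = frozenset(c.leaves())
                if ref in side:
                    side = all_taxa - side
                if 2 <= len(side) <= len(all_taxa) - 2:
                    splits.add(side)
                walk(c)
        walk(self.root)
        return splits

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        edges: dict[str, list[float]] = {}
        ancestry: dict[str, list[int]] = {}
        counter = [0]
        def walk2(node: TreeNode, anc: list[int], lens: list[float]) -> None:
            counter[0] += 1
            nid = counter[0]
            if node.is_leaf:
                ancestry[node.name] = anc + [nid]
                edges[node.name] = lens + [node.length]
                return
            for c in node.children:
                walk2(c, anc + [nid], lens + [node.length])
        for c in self.root.children:
            walk2(c, [0], [0.0])
        n = len(self.taxa)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = self.taxa[i], self.taxa[j]
                anc_a, len_a = ancestry[a], edges[a]
                anc_b, len_b = ancestry[b], edges[b]
                k = 0
                while k < min(len(anc_a), len(anc_b)) and anc_a[k] == anc_b[k]:
                    k += 1
                dist = sum(len_a[k:]) + sum(len_b[k:])
                m[i, j] = m[j, i] = dist
        return DistanceMatrix(taxa=list(self.taxa), matrix=m)


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor joining (Saitou-Nei), deterministic tie-breaking.

    The Q criterion is minimized at each step; ties break on the lowest
    (i, j) index pair in the current working order.  Negative branch lengths
    are clamped to zero with the deficit moved to the sibling edge, which
    preserves the path length between the joined pair.
    """
    n = len(dist.taxa)
    if n < 3:
        raise PhylogenyError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dist.taxa]
    D = dist.matrix.astype(float).copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
            vi = max(vi, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = vi, vj
        new = TreeNode(children=[child_i, child_j])
        new_d = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                D2[a, b] = D[ka, kb]
            D2[a, -1] = D2[-1, a] = max(0.0, new_d[ka])
        nodes = [nodes[k] for k in keep] + [new]
        D = D2
    # final three nodes join at the trifurcating root
    a, b, c = nodes
    va = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    vb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    vc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length, b.length, c.length = (max(0.0, v) for v in (va, vb, vc))
    root = TreeNode(children=[a, b, c])
    return PhyloTree(root=root, taxa=sorted(dist.taxa))


def bootstrap_support(sm: Supermatrix, n_replicates: int = 1000, seed: int = 0,
                      max_distance: float = 10.0,
                      complete_deletion: bool = False) -> PhyloTree:
    """Point-estimate NJ tree with column-bootstrap support percentages.

    Columns are resampled with replacement per replicate; support for each
    internal edge of the point tree is the percentage of replicate trees
    containing the same bipartition.  Deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise PhylogenyError("n_replicates must be >= 1")
    point = nj_tree(protein_distance(sm, max_distance, complete_deletion))
    counts: dict[frozenset[str], int] = {split: 0 for split in point.bipartitions()}
    rng = np.random.default_rng(seed)
    ncol = sm.n_columns
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_sm = sm.column_sample(cols)
        try:
            rep_tree = nj_tree(protein_distance(rep_sm, max_distance, complete_deletion))
        except PhylogenyError:  # a replicate can lose all comparable columns
            continue
        rep_splits = rep_tree.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    all_taxa = frozenset(point.taxa)
    ref = point.taxa[0]
    def attach(node: TreeNode) -> None:
        for c in node.children:
            if not c.is_leaf:
                side = frozenset(c.leaves())
                if ref in side:
                    side = all_taxa - side
                if 2 <= len(side) <= len(all_taxa) - 2:
                    c.support = 100.0 * counts[side] / n_replicates
            attach(c)
    attach(point.root)
    return point
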