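"""Protein distances, neighbour-joining trees and bootstrap support.

Distances use pairwise gap deletion and one of three models for the
proportion p of differing compared sites:

* p-distance:  d = p
* Poisson:     d = -ln(1 - p)
* gamma:       d = alpha * ((1 - p)^(-1/alpha) - 1)

Trees are built by Saitou-Nei neighbour joining on the Q-criterion; on an
additive matrix the output is the unique additive tree with exact branch
lengths.  Negative branch-length estimates are clamped to zero and flagged.
Bootstrap support is the fraction of column-resampled replicate trees that
contain each bipartition of the tree built from the full alignment.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align as _BioAlign
from Bio.Align import substitution_matrices


@dataclass
class Alignment:
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise ValueError("alignment needs at least 2 taxa")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, rng) -> "Alignment":
        idx = rng.integers(0, self.length, size=self.length)
        return Alignment(self.taxa, ["".join(r[i] for i in idx) for r in self.rows])


# ---------------------------------------------------------------------------
# Multiple alignment (center-star progressive merge)
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / len(ka | kb)


def _protein_aligner():
    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    aligner.end_gap_score = 0
    return aligner


def progressive_align(sequences: dict[str, str]) -> Alignment:
    """Center-star multiple alignment: the sequence minimizing summed k-mer
    distance anchors pairwise alignments merged under 'once a gap, always a
    gap'.  Adequate for the closely related within-family proteins this
    package compares; not a general-purpose aligner."""
    taxa = sorted(sequences)
    if len(taxa) == 1:
        return Alignment(taxa, [sequences[taxa[0]]])
    sums = {t: sum(_kmer_distance(sequences[t], sequences[u]) for u in taxa if u != t)
            for t in taxa}
    center = min(taxa, key=lambda t: (sums[t], t))
    aligner = _protein_aligner()

    master = sequences[center]          # center row with accumulated gaps
    rows: dict[str, str] = {center: master}

    for t in taxa:
        if t == center:
            continue
        aln = aligner.align(sequences[center], sequences[t])[0]
        c_aln, t_aln = str(aln[0]), str(aln[1])
        # merge c_aln's gap pattern with the master's
        merged_master: list[str] = []
        merged_new: list[str] = []
        updates: dict[str, list[str]] = {k: [] for k in rows if k != center}
        i = j = 0
        while i < len(master) or j < len(c_aln):
            mc = master[i] if i < len(master) else None
            cc = c_aln[j] if j < len(c_aln) else None
            if mc is not None and cc is not None and (mc == cc or (mc != "-" and cc != "-")):
                merged_master.append(mc)
                merged_new.append(t_aln[j])
                for k in updates:
                    updates[k].append(rows[k][i])
                i += 1
                j += 1
            elif mc == "-" and cc != "-":
                merged_master.append("-")
                merged_new.append("-")
                for k in updates:
                    updates[k].append(rows[k][i])
                i += 1
            else:   # gap introduced by the new pairwise alignment
                merged_master.append("-")
                merged_new.append(t_aln[j])
                for k in updates:
                    updates[k].append("-")
                j += 1
        master = "".join(merged_master)
        for k in updates:
            rows[k] = "".join(updates[k])
        rows[center] = master
        rows[t] = "".join(merged_new)

    return Alignment(taxa, [rows[t] for t in taxa])


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def pairwise_distance(row_a: str, row_b: str, model: str = "poisson",
                      alpha: float = 1.0) -> tuple[float, float]:
    """(p, d) for two gapped rows under pairwise gap deletion."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    compared = diff = 0
    for a, b in zip(row_a, row_b):
        if a == "-" or b == "-":
            continue
        compared += 1
        diff += a != b
    if compared == 0:
        raise ValueError("no comparable (gap-free) columns")
    p = diff / compared
    if model == "p":
        return p, p
    if p >= 1.0:
        raise ValueError("p = 1: distance undefined under poisson/gamma models")
    if model == "poisson":
        return p, -math.log(1.0 - p)
    if model == "gamma":
        return p, alpha * ((1.0 - p) ** (-1.0 / alpha) - 1.0)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    p: np.ndarray
    model: str
    alpha: float | None = None

    @classmethod
    def from_alignment(cls, aln: Alignment, model: str = "poisson",
                       alpha: float = 1.0) -> "DistanceMatrix":
        n = len(aln.taxa)
        d = np.zeros((n, n))
        p = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pij, dij = pairwise_distance(aln.rows[i], aln.rows[j], model, alpha)
                p[i, j] = p[j, i] = pij
                d[i, j] = d[j, i] = dij
        return cls(list(aln.taxa), d, p, model, alpha if model == "gamma" else None)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    root: TreeNode                        # unrooted: the root is a trifurcation
    taxa: list[str]
    support: dict[frozenset, float] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def bipartitions(self) -> set[frozenset]:
        """Nontrivial bipartitions, each canonicalized to the side containing
        the alphabetically first taxon."""
        ref = min(self.taxa)
        full = set(self.taxa)
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> set[str]:
            if not node.children:
                return {node.name}
            below: set[str] = set()
            for c in node.children:
                below |= walk(c)
            if node is not self.root and 2 <= len(below) <= len(full) - 2:
                side = below if ref in below else full - below
                out.add(frozenset(side))
            return below

        walk(self.root)
        return out

    def leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """Patristic distances between all leaf pairs."""
        paths: dict[str, float] = {}
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode, depth: float, acc: list[tuple[str, float]]):
            if not node.children:
                acc.append((node.name, depth))
                return
            for c in node.children:
                walk(c, depth + c.length, acc)

        def pairs(node: TreeNode):
            if not node.children:
                return [(node.name, 0.0)]
            sub = []
            for c in node.children:
                acc: list[tuple[str, float]] = []
                walk(c, c.length, acc)
                sub.append(acc)
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for la, da in sub[i]:
                        for lb, db in sub[j]:
                            dists[(la, lb)] = dists[(lb, la)] = da + db
            merged = [x for acc in sub for x in acc]
            return merged

        def recurse(node: TreeNode):
            for c in node.children:
                recurse(c)
            pairs(node)

        recurse(self.root)
        taxa = sorted(self.taxa)
        n = len(taxa)
        mat = np.zeros((n, n))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i != j:
                    mat[i, j] = dists[(a, b)]
        return taxa, mat

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.2f}"
            return f"({inner}){label}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining on the Q-criterion.

    Deterministic: ties resolve toward the smallest row/column indices.
    Negative branch-length estimates are clamped to zero and the tree is
    flagged ``negative_branch_clamped``.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    D = np.array(dm.d, dtype=float)
    if not np.allclose(D, D.T) or (D < 0).any():
        raise ValueError("distance matrix must be symmetric and non-negative")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    flags: set[str] = set()
    active = list(range(n))
    D = D.copy()

    def clamp(x: float) -> float:
        if x < 0:
            flags.add("negative_branch_clamped")
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode()
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = clamp(li), clamp(lj)
        parent.children = [ni, nj_]
        # reuse slot i for the merged node
        for k in active:
            if k not in (i, j):
                dk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
                D[i, k] = D[k, i] = max(dk, 0.0)
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    root = TreeNode()
    nodes[i].length = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    nodes[j].length = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    nodes[k].length = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    root.children = [nodes[i], nodes[j], nodes[k]]
    if np.allclose(dm.d, 0):
        flags.add("zero_distance_matrix")
    return PhyloTree(root, list(dm.taxa), flags=flags)


def bootstrap_support(aln: Alignment, model: str = "poisson", replicates: int = 100,
                      seed: int = 0, alpha: float = 1.0) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap support values.

    Columns are resampled with replacement per replicate; support for each
    original bipartition is the fraction of replicate trees containing it.
    Deterministic given the seed.
    """
    if replicates < 1:
        raise ValueError("at least one bootstrap replicate required")
    if aln.length < 2:
        raise ValueError("alignment must have at least 2 columns")
    tree = nj_tree(DistanceMatrix.from_alignment(aln, model, alpha))
    originals = tree.bipartitions()
    counts = {bp: 0 for bp in originals}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        rep = aln.resample_columns(rng)
        rep_tree = nj_tree(DistanceMatrix.from_alignment(rep, model, alpha))
        rep_bps = rep_tree.bipartitions()
        for bp in originals:
            if bp in rep_bps:
                counts[bp] += 1
    tree.support = {bp: counts[bp] / replicates for bp in originals}

    # annotate internal nodes with their bipartition's support
    ref = min(tree.taxa)
    full = set(tree.taxa)

    def annotate(node: TreeNode) -> set[str]:
        if not node.children:
            return {node.name}
        below: set[str] = set()
        for c in node.children:
            below |= annotate(c)
        if node is not tree.root and 2 <= len(below) <= len(full) - 2:
            side = frozenset(below if ref in below else full - below)
            node.support = tree.support.get(side)
        return below

    annotate(tree.root)
    return tree


def check_clades(tree: PhyloTree, groups: dict[str, list[str]]) -> dict[str, bool]:
    """True per clade iff its leaves form a bipartition of the unrooted tree
    (the whole leaf set is monophyletic by convention)."""
    bps = tree.bipartitions()
    full = set(tree.taxa)
    ref = min(tree.taxa)
    out = {}
    for clade, members in groups.items():
        mset = set(members)
        if len(mset) < 2:
            raise ValueError(f"clade {clade!r} has fewer than 2 leaves")
        if not mset.issubset(full):
            raise ValueError(f"clade {clade!r} contains unknown leaves")
        if mset == full:
            out[clade] = True
            continue
        if len(mset) > len(full) - 2:
            # complement has < 2 leaves: the group is a bipartition side iff
            # the single outside leaf hangs off the root... treat via complement
            out[clade] = len(full - mset) == 1
            continue
        side = frozenset(mset if ref in mset else full - mset)
        out[clade] = side in bps
    return out
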