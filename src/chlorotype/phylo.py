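"""Distances, neighbor-joining and bootstrap over whole-organelle alignments.

Distances are computed on a star multiple alignment (every genome aligned
pairwise to one designated reference and merged on reference coordinates),
justified for this application by pairwise identities above 99.9%.  Two
models are offered: the raw proportion of differing sites (p-distance) and a
Tamura-Nei (TN93) distance whose base frequencies and transition/
transversion rate ratios are pooled over all pairs in the active set
(composite pooling), the common choice for sets of near-identical
chloroplast genomes.  Gap and N columns are excluded per pair (pairwise
deletion) unless complete deletion is requested.

Trees are built with the Saitou-Nei neighbor-joining algorithm and assessed
by nonparametric bootstrap over alignment columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome_io import CircularGenome
from .variants import align_genomes

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINE = (0, 2)
_PYRIMIDINE = (1, 3)


# ---------------------------------------------------------------------------
# Star multiple alignment
# ---------------------------------------------------------------------------


def star_alignment(
    genomes: list[CircularGenome], ref_id: str | None = None, k: int = 21
) -> tuple[list[str], list[str]]:
    """Multiple alignment by merging pairwise alignments to one reference.

    Returns (taxa, rows): gapped rows of equal length, in input order.
    Insertions relative to the reference are padded to the per-position
    maximum across genomes.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    if ref_id is None:
        ref_id = genomes[0].id
    ref = next(g for g in genomes if g.id == ref_id)
    n = len(ref)
    others = [g for g in genomes if g.id != ref_id]

    # per genome: for reference position p, the query bases aligned to p and
    # the insertion following p (ins[0] = insertion before position 0)
    aligned: dict[str, tuple[list[str], list[str]]] = {}
    ins_len = [0] * (n + 1)
    for g in others:
        aln = align_genomes(ref, g, k=k)
        base = [""] * n
        ins = [""] * (n + 1)
        i = j = 0
        for op, num in aln.ops:
            if op in "=X":
                for t in range(num):
                    base[i + t] = aln.qry_seq[j + t]
                i += num
                j += num
            elif op == "D":
                for t in range(num):
                    base[i + t] = "-"
                i += num
            else:  # I: insertion after reference position i-1
                ins[i] += aln.qry_seq[j : j + num]
                j += num
        aligned[g.id] = (base, ins)
        for p in range(n + 1):
            ins_len[p] = max(ins_len[p], len(ins[p]))

    rows: list[str] = []
    taxa: list[str] = []
    for g in genomes:
        parts: list[str] = []
        if g.id == ref_id:
            parts.append("-" * ins_len[0])
            for p in range(n):
                parts.append(ref.sequence[p])
                if ins_len[p + 1]:
                    parts.append("-" * ins_len[p + 1])
        else:
            base, ins = aligned[g.id]
            parts.append(ins[0].ljust(ins_len[0], "-"))
            for p in range(n):
                parts.append(base[p])
                if ins_len[p + 1]:
                    parts.append(ins[p + 1].ljust(ins_len[p + 1], "-"))
        taxa.append(g.id)
        rows.append("".join(parts))
    assert len({len(r) for r in rows}) == 1
    return taxa, rows


def alignment_matrix(rows: list[str]) -> np.ndarray:
    """Rows as a uint8 matrix: 0..3 = ACGT, 255 = gap/N/other."""
    out = np.full((len(rows), len(rows[0])), 255, dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for b, c in _CODE.items():
        lut[ord(b)] = c
    for i, row in enumerate(rows):
        out[i] = lut[np.frombuffer(row.encode(), dtype=np.uint8)]
    return out


# ---------------------------------------------------------------------------
# Distance models
# ---------------------------------------------------------------------------


@dataclass
class DistanceModel:
    """Distance model with parameters shared across all pairs.

    For ``tn93_mcl`` the base frequencies and the two transition rate ratios
    (purine k1, pyrimidine k2, each relative to the transversion rate) are
    estimated once from counts pooled over every pair in the active set.
    """

    kind: str = "tn93_mcl"  # or "p_distance"
    freqs: dict[str, float] = field(default_factory=dict)
    k1: float = float("nan")
    k2: float = float("nan")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if np.any(~np.isfinite(d)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("nonzero diagonal")
        self.d = d

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


def _pair_site_counts(mat: np.ndarray, i: int, j: int, cols=None):
    a, b = mat[i], mat[j]
    if cols is not None:
        a, b = a[cols], b[cols]
    ok = (a != 255) & (b != 255)
    a, b = a[ok], b[ok]
    n_sites = a.size
    diff = a != b
    ag = diff & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))
    ct = diff & (((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))
    p1 = int(ag.sum())
    p2 = int(ct.sum())
    q = int(diff.sum()) - p1 - p2
    return n_sites, p1, p2, q


def p_distance(mat: np.ndarray, i: int, j: int, cols=None) -> float:
    n_sites, p1, p2, q = _pair_site_counts(mat, i, j, cols)
    if n_sites == 0:
        raise ValueError("zero compared sites between rows")
    return (p1 + p2 + q) / n_sites


def fit_tn93(mat: np.ndarray) -> DistanceModel:
    """Pool base frequencies and rate ratios over all pairs/rows."""
    counts = np.zeros(4)
    for c in range(4):
        counts[c] = int((mat == c).sum())
    freqs = counts / counts.sum()
    P1 = P2 = Q = S = 0
    npair = mat.shape[0]
    for i in range(npair):
        for j in range(i + 1, npair):
            n_sites, p1, p2, q = _pair_site_counts(mat, i, j)
            P1 += p1
            P2 += p2
            Q += q
            S += n_sites
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    if S and Q:
        k1 = (P1 / S) / (Q / S) * (2 * gR * gY) / (2 * gA * gG) if gA * gG else 1.0
        k2 = (P2 / S) / (Q / S) * (2 * gR * gY) / (2 * gT * gC) if gT * gC else 1.0
    else:
        k1 = k2 = 1.0
    return DistanceModel(
        kind="tn93_mcl",
        freqs={"A": gA, "C": gC, "G": gG, "T": gT},
        k1=k1,
        k2=k2,
    )


def tn93_distance(
    mat: np.ndarray, i: int, j: int, model: DistanceModel, cols=None
) -> float:
    """Tamura-Nei distance using pooled base frequencies."""
    n_sites, p1c, p2c, qc = _pair_site_counts(mat, i, j, cols)
    if n_sites == 0:
        raise ValueError("zero compared sites between rows")
    if p1c + p2c + qc == 0:
        return 0.0
    P1, P2, Q = p1c / n_sites, p2c / n_sites, qc / n_sites
    g = model.freqs
    gA, gC, gG, gT = g["A"], g["C"], g["G"], g["T"]
    gR, gY = gA + gG, gC + gT
    if min(gA, gC, gG, gT) <= 0:
        return p_distance(mat, i, j, cols)
    w1 = 1 - gR * P1 / (2 * gA * gG) - Q / (2 * gR)
    w2 = 1 - gY * P2 / (2 * gT * gC) - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if min(w1, w2, w3) <= 0:
        raise ValueError("substitution saturation: TN93 distance undefined")
    return (
        -(2 * gA * gG / gR) * math.log(w1)
        - (2 * gT * gC / gY) * math.log(w2)
        - 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY) * math.log(w3)
    )


def distance_matrix(
    taxa: list[str],
    rows: list[str],
    model: str = "tn93_mcl",
    complete_deletion: bool = False,
) -> tuple[DistanceMatrix, DistanceModel]:
    """All pairwise distances under the chosen model.

    ``complete_deletion`` drops every column with any gap/N before
    computing; the default compares sites pairwise.
    """
    mat = alignment_matrix(rows)
    if complete_deletion:
        keep = np.flatnonzero((mat != 255).all(axis=0))
        mat = mat[:, keep]
    fitted = fit_tn93(mat) if model == "tn93_mcl" else DistanceModel(kind="p_distance")
    npair = len(taxa)
    d = np.zeros((npair, npair))
    for i in range(npair):
        for j in range(i + 1, npair):
            if model == "tn93_mcl":
                val = tn93_distance(mat, i, j, fitted)
            elif model == "p_distance":
                val = p_distance(mat, i, j)
            else:
                raise ValueError(f"unknown model {model!r}")
            d[i, j] = d[j, i] = val
    return DistanceMatrix(taxa=taxa, d=d), fitted


def pairwise_distance(
    a: CircularGenome, b: CircularGenome, model: str = "tn93_mcl", k: int = 21
) -> float:
    """Distance between two genomes from their pairwise alignment.

    Gap columns are excluded from the compared sites.  For ``tn93_mcl`` the
    frequencies/rates are necessarily pooled over this single pair.
    """
    taxa, rows = star_alignment([a, b], ref_id=a.id, k=k)
    D, _ = distance_matrix(taxa, rows, model=model)
    return float(D.d[0, 1])


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    root: TreeNode  # degree-3 internal node: represents the unrooted tree
    taxa: list[str]

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return node.name
            inner = ",".join(
                f"{fmt(child)}:{length:.6f}" for child, length in node.children
            )
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the frozenset of the smaller side's
        leaves (ties broken lexicographically)."""
        all_taxa = frozenset(self.taxa)
        splits: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if not node.children:
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                side = walk(child)
                if 1 < len(side) < len(all_taxa) - 1:
                    other = all_taxa - side
                    canon = min(side, other, key=lambda s: (len(s), sorted(s)))
                    splits.add(canon)
                below |= side
            return below

        walk(self.root)
        return splits

    def internal_edges(self) -> list[tuple[TreeNode, frozenset]]:
        """(node, canonical split) for each internal edge below the root."""
        all_taxa = frozenset(self.taxa)
        out = []

        def walk(node: TreeNode) -> frozenset:
            if not node.children:
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                side = walk(child)
                if 1 < len(side) < len(all_taxa) - 1:
                    other = all_taxa - side
                    canon = min(side, other, key=lambda s: (len(s), sorted(s)))
                    out.append((child, canon))
                below |= side
            return below

        walk(self.root)
        return out


def neighbor_joining(D: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q criterion is joined at each step; ties go to
    the smallest (i, j) index pair in the current ordering (which follows
    the original taxon order).  With ``clamp_negative`` a negative branch
    length is raised to zero and the deficit moved to its sibling.
    """
    taxa = list(D.taxa)
    if len(taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    d = D.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if clamp_negative:
            if li < 0:
                lj += li
                li = 0.0
            if lj < 0:
                li += lj
                lj = 0.0
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [parent]

    # final trifurcation (3 remaining clusters)
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    if clamp_negative:
        l0, l1, l2 = (max(x, 0.0) for x in (l0, l1, l2))
    root = TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    return PhyloTree(root=root, taxa=taxa)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    tree: PhyloTree  # original tree with per-edge supports filled in
    supports: dict[frozenset, float]  # canonical split -> % of replicates
    degenerate: bool = False


def bootstrap_support(
    taxa: list[str],
    rows: list[str],
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "tn93_mcl",
) -> BootstrapResult:
    """Column-resampling bootstrap of the NJ tree.

    Replicate r draws columns with replacement using seed + r, recomputes
    the distance matrix (pairwise deletion within the replicate) and its NJ
    tree, and each original bipartition's support is the percentage of
    replicates containing it.  Supports are tied to taxon names, not input
    order, so they are invariant to reordering the input rows.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    order = sorted(range(len(taxa)), key=lambda i: taxa[i])
    taxa_s = [taxa[i] for i in order]
    rows_s = [rows[i] for i in order]
    mat = alignment_matrix(rows_s)
    D, fitted = distance_matrix(taxa_s, rows_s, model=model)
    if np.allclose(D.d, 0):
        tree = neighbor_joining(D)
        for node, _ in tree.internal_edges():
            node.support = 100.0
        return BootstrapResult(tree=tree, supports={}, degenerate=True)
    tree = neighbor_joining(D)
    target = {split: 0 for _, split in tree.internal_edges()}

    ncols = mat.shape[1]
    npair = len(taxa_s)
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, ncols, size=ncols)
        sub = mat[:, cols]
        dm = np.zeros((npair, npair))
        ok_any = True
        for i in range(npair):
            for j in range(i + 1, npair):
                try:
                    if model == "tn93_mcl":
                        dm[i, j] = dm[j, i] = tn93_distance(sub, i, j, fitted)
                    else:
                        dm[i, j] = dm[j, i] = p_distance(sub, i, j)
                except ValueError:
                    ok_any = False
        if not ok_any:
            continue
        rep_tree = neighbor_joining(DistanceMatrix(taxa=taxa_s, d=dm))
        rep_splits = rep_tree.bipartitions()
        for split in target:
            if split in rep_splits:
                target[split] += 1
    supports = {split: 100.0 * c / n_reps for split, c in target.items()}
    for node, split in tree.internal_edges():
        node.support = supports[split]
    return BootstrapResult(tree=tree, supports=supports)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_phylip(D: DistanceMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(D.taxa)}\n")
        for i, t in enumerate(D.taxa):
            vals = " ".join(f"{x:.8f}" for x in D.d[i])
            fh.write(f"{t[:10]:<10} {vals}\n")


def write_distance_tsv(D: DistanceMatrix, path: str) -> None:
    import pandas as pd

    pd.DataFrame(D.d, index=D.taxa, columns=D.taxa).to_csv(path, sep="\t")
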