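"""Distance-based phylogeny: Poisson-corrected protein distances, Saitou–Nei
neighbor joining, column-bootstrap support and monophyly queries.

Additive distance matrices are recovered exactly by the NJ implementation;
ties in the Q criterion are broken deterministically by the lexicographic
order of the representative taxon-id pair, and negative branch-length
estimates are clamped to zero (counted on the returned tree as
`n_clamped`).
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode


def poisson_distance(protein_msa: dict[str, str]) -> DistanceMatrix:
    """Poisson-corrected pairwise distances d = -ln(1 - p) over an MSA.

    Columns with a gap (or non-letter) in either member of a pair are
    excluded for that pair (pairwise-complete deletion).
    """
    ids = sorted(protein_msa)
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences")
    lengths = {len(protein_msa[i]) for i in ids}
    if len(lengths) != 1:
        raise ValueError("MSA rows must have equal length")
    arrs = {i: np.frombuffer(protein_msa[i].upper().encode(), dtype=np.uint8) for i in ids}
    gap = ord("-")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            ok = (a != gap) & (b != gap)
            n_cols = int(ok.sum())
            if n_cols == 0:
                raise ValueError(f"no comparable columns for {ids[i]}, {ids[j]}")
            p = float((a[ok] != b[ok]).sum()) / n_cols
            if p >= 1.0:
                raise ValueError(f"saturated pair {ids[i]}, {ids[j]} (p = 1)")
            d[i, j] = d[j, i] = -np.log(1.0 - p) if p > 0 else 0.0
    return DistanceMatrix(d, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei NJ with the Q criterion; deterministic tie-breaking.

    Returns an unrooted tree represented with a trifurcating root. Among
    tied minimal-Q pairs the pair whose sorted representative taxon ids are
    lexicographically smallest is joined first. Negative branch estimates
    are clamped to 0; the count is stored as `tree.n_clamped`.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = dm.data.astype(float).copy()
    nodes = [TreeNode(name=i) for i in dm.ids]
    labels = [str(i) for i in dm.ids]  # representative (min) leaf label per node
    n_clamped = 0

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = [
            (tuple(sorted((labels[i], labels[j]))), i, j)
            for i, j in zip(*np.nonzero(Q <= qmin + 1e-12))
            if i < j
        ]
        _, i, j = min(cand)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            li, n_clamped = 0.0, n_clamped + 1
        if lj < 0:
            lj, n_clamped = 0.0, n_clamped + 1
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = float(li), float(lj)
        new_node = TreeNode(children=[child_i, child_j])
        new_dist = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.pad(D[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        D[-1, :-1] = D[:-1, -1] = new_dist[keep]
        nodes = [nodes[k] for k in keep] + [new_node]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # final trifurcation
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    root = TreeNode()
    for node, length in zip(nodes, (l0, l1, l2)):
        if length < 0:
            length, n_clamped = 0.0, n_clamped + 1
        node.length = float(length)
        root.append(node)
    root.n_clamped = n_clamped
    return root


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized as the side not
    containing the lexicographically smallest leaf."""
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    splits = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = clade if ref not in clade else frozenset(leaves - clade)
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def robinson_foulds(tree_a: TreeNode, tree_b: TreeNode) -> int:
    return len(tree_splits(tree_a) ^ tree_splits(tree_b))


def bootstrap_support(
    protein_msa: dict[str, str], n_reps: int = 100, seed: int = 0
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Column bootstrap: support %% for each internal split of the full tree."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids = sorted(protein_msa)
    length = len(protein_msa[ids[0]])
    full_tree = neighbor_joining(poisson_distance(protein_msa))
    target = tree_splits(full_tree)
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(length, size=length)
        msa = {i: "".join(protein_msa[i][c] for c in cols) for i in ids}
        rep_splits = tree_splits(neighbor_joining(poisson_distance(msa)))
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return full_tree, support


def annotate_supports(tree: TreeNode, support: dict[frozenset[str], float]) -> TreeNode:
    """Write split supports onto internal node names (for Newick output)."""
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = clade if ref not in clade else frozenset(leaves - clade)
        if side in support:
            node.name = f"{support[side]:.0f}"
    return tree


def is_monophyletic(tree: TreeNode, taxa: set[str], outgroup: str) -> bool:
    """True iff some edge, with the tree rooted at `outgroup`, separates
    exactly `taxa` from everything else."""
    leaves = {t.name for t in tree.tips()}
    unknown = (set(taxa) | {outgroup}) - leaves
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if outgroup in taxa:
        raise ValueError("outgroup must not be in taxa")
    taxa = frozenset(taxa)
    if len(taxa) == 1:
        return True
    for node in tree.traverse(include_self=False):
        clade = frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset({node.name})
        if clade == taxa or frozenset(leaves - clade) == taxa:
            return True
    return False
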