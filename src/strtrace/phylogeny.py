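"""Neighbor-joining trees from distance matrices, with Newick I/O and an
individual-level allele-sharing distance.

The NJ implementation is the classic Saitou-Nei Q-criterion agglomeration.
It is deterministic: ties in the Q matrix are broken by the lexicographically
smallest pair of cluster labels (a cluster is labelled by its smallest leaf
name).  Negative branch-length estimates are clamped to zero with the
deficit transferred to the sister branch, preserving the sum of the two
sibling branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .differentiation import DistanceMatrix
from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "TreeNode",
    "Tree",
    "allele_sharing_distance",
    "neighbor_joining",
    "write_newick",
    "read_newick",
    "bootstrap_support",
]


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree stored as a rooted structure (trifurcating root for
    trees built from >= 3 taxa); branch lengths in the input distance units."""

    root: TreeNode

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.name or "")
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (additive distances on the tree)."""
        labels = sorted(self.leaves())
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            """Map leaf -> distance from this node, filling cross terms."""
            if node.is_leaf:
                return {node.name: 0.0}
            below: dict[str, float] = {}
            for child, bl in node.children:
                sub = {leaf: d + bl for leaf, d in walk(child).items()}
                for l1, d1 in sub.items():
                    for l2, d2 in below.items():
                        dist[idx[l1], idx[l2]] = dist[idx[l2], idx[l1]] = d1 + d2
                below.update(sub)
            return below

        walk(self.root)
        return DistanceMatrix(labels, dist, "tree_path_length")

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions (each side as the smaller set by a
        canonical rule: the side not containing the alphabetically first leaf)."""
        all_leaves = set(self.leaves())
        anchor = min(all_leaves)
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below: set[str] = set()
            for child, _ in node.children:
                sub = walk(child)
                if 1 < len(sub) < len(all_leaves) - 1:
                    side = sub if anchor not in sub else all_leaves - sub
                    parts.add(frozenset(side))
                below |= sub
            return below

        walk(self.root)
        return parts


def allele_sharing_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Individual-level distance 1 - shared alleles / (2 x compared loci).

    Per locus two genotypes share 0, 1 or 2 alleles under multiset
    semantics ({a,b} vs {a,a} shares one); loci missing in either
    individual are skipped, and a pair with no comparable loci is an error.
    """
    n = matrix.n_individuals
    if n < 2:
        raise ValueError("need at least two individuals")
    a = np.sort(matrix.alleles, axis=2).astype(np.int64)
    present = a[:, :, 0] != MISSING
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            if not both.any():
                raise ValueError(
                    f"individuals {matrix.ids[i]!r} and {matrix.ids[j]!r} share no typed loci"
                )
            gi, gj = a[i, both], a[j, both]
            # multiset intersection size of two sorted pairs
            eq_direct = (gi == gj).sum(axis=1)
            eq_cross = (gi[:, 0] == gj[:, 1]).astype(int) + (gi[:, 1] == gj[:, 0]).astype(int)
            shared = np.maximum(eq_direct, np.minimum(eq_cross, 2))
            # guard double counting when one side is homozygous
            hom_i = gi[:, 0] == gi[:, 1]
            hom_j = gj[:, 0] == gj[:, 1]
            one_hom = hom_i ^ hom_j
            shared = np.where(one_hom & (shared > 1), 1, shared)
            d = 1.0 - shared.sum() / (2.0 * both.sum())
            dist[i, j] = dist[j, i] = d
    return DistanceMatrix(list(matrix.ids), dist, "allele_sharing")


def neighbor_joining(dist: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Exactly recovers the generating tree (topology and branch lengths) for
    any additive input.  Two labels produce a single edge split evenly.
    """
    labels = list(dist.labels)
    d = np.asarray(dist.values, dtype=float).copy()
    if np.abs(d - d.T).max(initial=0.0) > 1e-9:
        raise ValueError("distance matrix is not symmetric")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two labels")
    if n == 2:
        half = d[0, 1] / 2.0
        return Tree(TreeNode(children=[(TreeNode(labels[0]), half), (TreeNode(labels[1]), half)]))

    nodes: list[TreeNode] = [TreeNode(l) for l in labels]
    tags: list[str] = list(labels)  # cluster label = smallest member leaf name

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - row_sums[i] - row_sums[j]
                pair_tag = tuple(sorted((tags[i], tags[j])))
                cand = (q, pair_tag, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = d[i, j] / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _fix_negative(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_d = 0.5 * (d[:, i] + d[:, j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        tags = [tags[k] for k in keep] + [min(tags[i], tags[j])]

    # final three clusters join at the (trifurcating) root
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    l0 = (d01 + d02 - d12) / 2.0
    l1 = (d01 + d12 - d02) / 2.0
    l2 = (d02 + d12 - d01) / 2.0
    l0, l1, l2 = (max(x, 0.0) for x in (l0, l1, l2))
    order = sorted(range(3), key=lambda k: tags[k])
    lens = [l0, l1, l2]
    root = TreeNode(children=[(nodes[k], lens[k]) for k in order])
    return Tree(root)


def _fix_negative(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to zero, moving the deficit to its sister."""
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


# ---------------------------------------------------------------------------
# Newick I/O


def _quote(label: str) -> str:
    if any(c in label for c in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_newick(node: TreeNode) -> str:
    if node.is_leaf:
        return _quote(node.name or "")
    inner = ",".join(f"{_node_newick(c)}:{bl:.10g}" for c, bl in node.children)
    return f"({inner})"


def to_newick(tree: Tree) -> str:
    return _node_newick(tree.root) + ";"


def write_newick(tree: Tree, path: str | Path) -> None:
    """Write standard Newick with branch lengths; labels quoted when needed."""
    Path(path).write_text(to_newick(tree) + "\n")


def read_newick(source: str | Path) -> Tree:
    """Parse a Newick string or file produced by :func:`write_newick`."""
    text = source if isinstance(source, str) and source.strip().endswith(";") else Path(source).read_text()
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_node() -> tuple[TreeNode, float]:
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = []
            while True:
                children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
            label = parse_label()  # internal labels ignored for identity
            node = TreeNode(name=label or None, children=children)
        else:
            node = TreeNode(name=parse_label())
        bl = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            bl = float(s[start:pos])
        return node, bl

    root, _ = parse_node()
    if root.children and root.name:
        root.name = None  # roots carry no identity label
    return Tree(root)


def bootstrap_support(
    matrix: GenotypeMatrix, n_reps: int = 100, seed: int | None = None
) -> dict[frozenset[str], float]:
    """Bipartition support by resampling loci with replacement.

    Rebuilds the allele-sharing NJ tree on each locus bootstrap and returns
    the fraction of replicates containing each bipartition of the original
    tree.
    """
    rng = np.random.default_rng(seed)
    base = neighbor_joining(allele_sharing_distance(matrix))
    target = base.bipartitions()
    hits = {b: 0 for b in target}
    for _ in range(n_reps):
        cols = rng.integers(0, matrix.n_loci, size=matrix.n_loci)
        boot = GenotypeMatrix(
            matrix.ids,
            matrix.pops,
            [f"L{k}" for k in range(matrix.n_loci)],
            matrix.alleles[:, cols, :],
        )
        parts = neighbor_joining(allele_sharing_distance(boot)).bipartitions()
        for b in target:
            if b in parts:
                hits[b] += 1
    return {b: h / n_reps for b, h in hits.items()}
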