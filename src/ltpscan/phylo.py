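"""Neighbor-joining phylogenetics on p-distances with bootstrap support.

p-distance with pairwise deletion: per pair, the proportion of mismatches
over sites where both sequences carry an unambiguous, non-gap residue.
NJ is Saitou–Nei with the standard Q-criterion and deterministic
tie-breaking; negative branch-length estimates are clamped to zero and
flagged.  Bootstrap resamples alignment columns with replacement and
reports, per internal edge of the reference tree, the percentage of
replicate trees containing the same bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AMBIGUOUS = frozenset("-X?*")


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray            # symmetric, zero diagonal, entries in [0,1]
    compared_sites: np.ndarray    # per-cell number of comparable sites

    def __post_init__(self):
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")


@dataclass
class TreeNode:
    name: str | None = None                 # leaf name, or None for internal
    children: list = field(default_factory=list)   # (TreeNode, branch_length)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree represented with a degree-3 (or star) root node."""

    root: TreeNode
    negative_branches_clamped: int = 0
    seed: int | None = None

    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set[frozenset]:
        """Internal-edge bipartitions, canonicalized as the side NOT holding
        the lexicographically smallest taxon."""
        all_leaves = frozenset(self.root.leaves())
        anchor = min(all_leaves)
        bips: set[frozenset] = set()

        def walk(node: TreeNode):
            for child, _ in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    canonical = side if anchor not in side else all_leaves - side
                    bips.add(canonical)
                walk(child)

        walk(self.root)
        return bips

    def to_newick(self, support_as_int: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return node.name
            inner = ",".join(f"{fmt(c)}:{bl:.6f}" for c, bl in node.children)
            label = ""
            if node.support is not None:
                label = str(int(round(node.support))) if support_as_int else f"{node.support:.2f}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def leaf_path_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        def path_to(node: TreeNode, target: str) -> list[float] | None:
            if node.is_leaf():
                return [] if node.name == target else None
            for child, bl in node.children:
                sub = path_to(child, target)
                if sub is not None:
                    return [bl] + sub
            return None

        def lca_dist(node: TreeNode) -> float | None:
            pa = path_to(node, a)
            pb = path_to(node, b)
            if pa is None or pb is None:
                return None
            for child, bl in node.children:
                d = lca_dist(child)
                if d is not None:
                    return d
            return sum(pa) + sum(pb)

        d = lca_dist(self.root)
        if d is None:
            raise KeyError(f"taxa {a!r}/{b!r} not in tree")
        return d


def p_distance(seqs: list[tuple[str, str]], deletion: str = "pairwise") -> DistanceMatrix:
    """Pairwise p-distances over an equal-length alignment.

    ``pairwise`` deletion drops gap/ambiguous sites per pair; ``complete``
    drops every column containing any gap/ambiguous residue globally.
    """
    ids = tuple(name for name, _ in seqs)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon ids")
    rows = [s.upper() for _, s in seqs]
    n = len(rows)
    if n == 0:
        raise ValueError("empty alignment")
    length = len(rows[0])
    for name, s in zip(ids, rows):
        if len(s) != length:
            raise ValueError(f"sequence {name!r} length {len(s)} != {length}")

    if deletion == "complete":
        keep = [j for j in range(length)
                if all(row[j] not in AMBIGUOUS for row in rows)]
        rows = ["".join(row[j] for j in keep) for row in rows]
        length = len(keep)
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")

    matrix = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = length
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for a, b in zip(rows[i], rows[j]):
                if a in AMBIGUOUS or b in AMBIGUOUS:
                    continue
                comparable += 1
                if a != b:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
            matrix[i, j] = matrix[j, i] = mismatch / comparable
            counts[i, j] = counts[j, i] = comparable
    return DistanceMatrix(ids=ids, matrix=matrix, compared_sites=counts)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    Ties in the Q-criterion are broken by the lexicographically smallest
    (sorted) pair of node keys, where a node's key is the smallest leaf name
    beneath it — making the output deterministic.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: dict[str, TreeNode] = {name: TreeNode(name=name) for name in dm.ids}
    # active node keys -> index into the working distance matrix
    keys = list(dm.ids)
    d = {a: {b: dm.matrix[i, j] for j, b in enumerate(dm.ids)}
         for i, a in enumerate(dm.ids)}
    clamped = 0

    while len(keys) > 3:
        m = len(keys)
        r = {a: sum(d[a][b] for b in keys if b != a) for a in keys}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = keys[i], keys[j]
                q = (m - 2) * d[a][b] - r[a] - r[b]
                pair_key = tuple(sorted((a, b)))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and pair_key < best[1]):
                    best = (q, pair_key, a, b)
        _, _, a, b = best
        la = 0.5 * d[a][b] + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = d[a][b] - la
        if la < 0:
            la, clamped = 0.0, clamped + 1
        if lb < 0:
            lb, clamped = 0.0, clamped + 1
        new_key = min(a, b)
        parent = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        new_d = {}
        for c in keys:
            if c in (a, b):
                continue
            new_d[c] = 0.5 * (d[a][c] + d[b][c] - d[a][b])
        keys = [k for k in keys if k not in (a, b)]
        for c in keys:
            d[c][new_key] = new_d[c]
        d[new_key] = new_d
        nodes.pop(a)
        nodes.pop(b)
        nodes[new_key] = parent
        keys.append(new_key)
        keys.sort()

    a, b, c = keys
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    lengths = []
    for l in (la, lb, lc):
        if l < 0:
            l, clamped = 0.0, clamped + 1
        lengths.append(l)
    root = TreeNode(children=[(nodes[a], lengths[0]), (nodes[b], lengths[1]),
                              (nodes[c], lengths[2])])
    return Tree(root=root, negative_branches_clamped=clamped)


def bootstrap_support(seqs: list[tuple[str, str]], n_replicates: int = 1000,
                      seed: int = 0, deletion: str = "pairwise") -> Tree:
    """Reference NJ tree with per-internal-edge bootstrap support (percent of
    column-resampled replicates containing the bipartition)."""
    tree = neighbor_joining(p_distance(seqs, deletion))
    ref_bips = tree.bipartitions()
    if not ref_bips:
        tree.seed = seed
        return tree
    rng = np.random.default_rng(seed)
    length = len(seqs[0][1])
    ids = [name for name, _ in seqs]
    rows = [s for _, s in seqs]
    hits = {bip: 0 for bip in ref_bips}
    effective = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = [(name, "".join(row[j] for j in cols))
                     for name, row in zip(ids, rows)]
        try:
            rep = neighbor_joining(p_distance(resampled, deletion))
        except ValueError:      # replicate with an incomparable pair
            continue
        effective += 1
        rep_bips = rep.bipartitions()
        for bip in ref_bips:
            if bip in rep_bips:
                hits[bip] += 1

    supports = {bip: 100.0 * k / effective if effective else 0.0
                for bip, k in hits.items()}
    all_leaves = frozenset(tree.root.leaves())
    anchor = min(all_leaves)

    def annotate(node: TreeNode):
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                canonical = side if anchor not in side else all_leaves - side
                child.support = supports[canonical]
            annotate(child)

    annotate(tree.root)
    tree.seed = seed
    return tree


def anchored_ecm_alignment(matches: list[tuple[str, "EcmMatch"]]) -> list[tuple[str, str]]:
    """Align ECM sequences by pinning the 8 cysteines columnwise and padding
    each spacer right with gaps to the set-wide maximum spacer length."""
    if not matches:
        raise ValueError("no ECM matches to align")
    max_s = [max(m.spacers[k] for _, m in matches) for k in range(5)]
    out = []
    for name, m in matches:
        c = m.cys_positions
        seq = m.ecm_seq
        off = c[0]
        segs = [seq[c[i] - off + 1: c[i + 1] - off] for i in range(7)]
        # segments between: c1-c2(s1), c2-c3(s2), c3-c4(CC, empty), c4-c5(s3),
        # c5-c6 (single X), c6-c7(s4), c7-c8(s5)
        aligned = (
            "C" + segs[0].ljust(max_s[0], "-")
            + "C" + segs[1].ljust(max_s[1], "-")
            + "CC" + segs[3].ljust(max_s[2], "-")
            + "C" + segs[4]
            + "C" + segs[5].ljust(max_s[3], "-")
            + "C" + segs[6].ljust(max_s[4], "-")
            + "C"
        )
        out.append((name, aligned))
    return out
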