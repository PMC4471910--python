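"""Distance phylogeny of element copies.

Progressive multiple alignment (pairwise global alignments feed a UPGMA guide
tree, profiles merged with sum-of-pairs scoring), p-distances with pairwise or
complete deletion, canonical Saitou–Nei neighbor joining with deterministic
tie-breaking, column-bootstrap support, and newick I/O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._align import nw_matrix, substitution_matrix, encode

logger = logging.getLogger(__name__)

_GAPLESS = "ACGTN"


@dataclass
class MultipleAlignment:
    """Ordered (label, gapped sequence) rows of equal length."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in alignment")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix not symmetric")
        if (m < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("nonzero diagonal")
        self.matrix = m


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; the root of an unrooted NJ tree has 3 children."""

    name: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------

def _profile_counts(rows: list[str]) -> np.ndarray:
    """(L, 5) residue counts per column over A,C,G,T,N (gaps excluded)."""
    L = len(rows[0])
    counts = np.zeros((L, 5), dtype=np.int64)
    for row in rows:
        for pos, c in enumerate(row):
            if c != "-":
                counts[pos, _GAPLESS.index(c)] += 1
    return counts


def _align_profiles(
    rows_a: list[str], rows_b: list[str], match: int, mismatch: int, gap: int
) -> tuple[list[str], list[str]]:
    w = substitution_matrix(match, mismatch)
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    S = (ca @ w @ cb.T).astype(np.int64)
    gap_pen = gap * len(rows_a) * len(rows_b)
    _, path = nw_matrix(S, gap_pen)
    out_a = ["".join(r[i] if i is not None else "-" for i, _ in path) for r in rows_a]
    out_b = ["".join(r[j] if j is not None else "-" for _, j in path) for r in rows_b]
    return out_a, out_b


def _guide_tree_upgma(dist: np.ndarray) -> list:
    """UPGMA merge order as a nested-list topology over leaf indices.

    Ties in the minimum pair distance break toward the smallest index pair,
    so the guide tree (and hence the alignment) is deterministic.
    """
    n = dist.shape[0]
    active = {i: [i] for i in range(n)}
    nodes: dict[int, object] = {i: i for i in range(n)}
    d = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    nxt = n
    while len(active) > 1:
        pair = min(d, key=lambda p: (d[p], p))
        i, j = pair
        merged = [nodes[i], nodes[j]]
        for k in list(active):
            if k in (i, j):
                continue
            a = d.pop((min(i, k), max(i, k)))
            b = d.pop((min(j, k), max(j, k)))
            d[(min(nxt, k), max(nxt, k))] = (
                (a * sizes[i] + b * sizes[j]) / (sizes[i] + sizes[j])
            )
        d.pop((i, j))
        del active[i], active[j], nodes[i], nodes[j]
        active[nxt] = True
        nodes[nxt] = merged
        sizes[nxt] = sizes.pop(i) + sizes.pop(j)
        nxt += 1
    return nodes[next(iter(active))]


def align_progressive(
    seqs: Sequence[tuple[str, str]],
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> MultipleAlignment:
    """Guide-tree progressive multiple alignment.

    All pairwise global alignments give guide distances (pairwise p-distance
    over aligned columns); a UPGMA guide tree orders profile merges.
    Deterministic for a fixed input order and the documented tie rules.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [lab for lab, _ in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    for lab, s in seqs:
        if not s:
            raise ValueError(f"empty sequence {lab!r}")

    n = len(seqs)
    w = substitution_matrix(match, mismatch)
    guide = np.zeros((n, n))
    enc = [encode(s) for _, s in seqs]
    for i in range(n):
        for j in range(i + 1, n):
            S = w[np.ix_(enc[i], enc[j])].astype(np.int64)
            _, path = nw_matrix(S, gap)
            diffs = comp = 0
            for pi, pj in path:
                if pi is None or pj is None:
                    continue
                a, b = seqs[i][1][pi], seqs[j][1][pj]
                if a == "N" or b == "N":
                    continue
                comp += 1
                diffs += a != b
            guide[i, j] = guide[j, i] = diffs / comp if comp else 1.0

    topology = _guide_tree_upgma(guide)

    def merge(node) -> tuple[list[int], list[str]]:
        if isinstance(node, int):
            return [node], [seqs[node][1]]
        (ia, rows_a), (ib, rows_b) = merge(node[0]), merge(node[1])
        rows_a, rows_b = _align_profiles(rows_a, rows_b, match, mismatch, gap)
        return ia + ib, rows_a + rows_b

    order, rows = merge(topology)
    by_index = dict(zip(order, rows))
    return MultipleAlignment(labels=labels, rows=[by_index[i] for i in range(n)])


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def p_distance(
    alignment: MultipleAlignment, deletion: str = "pairwise"
) -> DistanceMatrix:
    """Proportion of differing sites among comparable sites for every pair.

    A site is comparable for a pair when neither row has a gap or N there
    (pairwise deletion); with complete deletion, columns containing any gap
    or N are removed for all pairs first.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    arr = np.array([list(r) for r in alignment.rows])
    informative = (arr != "-") & (arr != "N")
    if deletion == "complete":
        keep = informative.all(axis=0)
        arr, informative = arr[:, keep], informative[:, keep]
    n = alignment.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = informative[i] & informative[j]
            comp = int(both.sum())
            if comp == 0:
                raise ValueError(
                    f"no comparable sites between {alignment.labels[i]!r} "
                    f"and {alignment.labels[j]!r}"
                )
            diffs = int((arr[i, both] != arr[j, both]).sum())
            d[i, j] = d[j, i] = diffs / comp
    return DistanceMatrix(labels=list(alignment.labels), matrix=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    The Q-criterion is minimized at each step; ties break by the
    lexicographically smallest (representative label) pair.  Negative branch
    lengths are clamped to zero with the deficit logged.  Returns an unrooted
    tree (root of degree 3).
    """
    labels = list(dist.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = {
        frozenset((a, b)): dist.matrix[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    # representative = lexicographically smallest leaf label of the cluster
    active = sorted(labels)

    def clamp(x: float, where: str) -> float:
        if x < 0:
            logger.info("clamped negative NJ branch length %.6g at %s", x, where)
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[frozenset((a, b))] for b in active if b != a) for a in active}
        best_pair, best_q = None, None
        for ii in range(n):
            for jj in range(ii + 1, n):
                a, b = active[ii], active[jj]
                q = (n - 2) * d[frozenset((a, b))] - r[a] - r[b]
                key = (q, a, b)
                if best_q is None or key < best_q:
                    best_q, best_pair = key, (a, b)
        a, b = best_pair
        dab = d[frozenset((a, b))]
        la = clamp(dab / 2 + (r[a] - r[b]) / (2 * (n - 2)), f"({a},{b})")
        lb = clamp(dab - (dab / 2 + (r[a] - r[b]) / (2 * (n - 2))), f"({a},{b})")
        nodes[a].length, nodes[b].length = la, lb
        parent = TreeNode(children=[nodes[a], nodes[b]])
        rep = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            dac = d.pop(frozenset((a, c)))
            dbc = d.pop(frozenset((b, c)))
            d[frozenset((rep, c))] = (dac + dbc - dab) / 2
        d.pop(frozenset((a, b)))
        active = sorted(set(active) - {a, b} | {rep})
        del nodes[a], nodes[b]
        nodes[rep] = parent

    a, b, c = active
    dab, dac, dbc = (
        d[frozenset((a, b))], d[frozenset((a, c))], d[frozenset((b, c))]
    )
    nodes[a].length = clamp((dab + dac - dbc) / 2, "final")
    nodes[b].length = clamp((dab + dbc - dac) / 2, "final")
    nodes[c].length = clamp((dac + dbc - dab) / 2, "final")
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def tree_path_lengths(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    leaves = tree.leaf_names()
    index = {lab: i for i, lab in enumerate(leaves)}
    n = len(leaves)
    m = np.zeros((n, n))

    def walk(node: TreeNode, depths: dict[str, float]):
        below: dict[str, float] = {}
        if node.is_leaf:
            below[node.name] = 0.0
        child_maps = []
        for ch in walk_children(node):
            cm = walk(ch, depths)
            cm = {k: v + (ch.length or 0.0) for k, v in cm.items()}
            child_maps.append(cm)
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                for la, da in child_maps[i].items():
                    for lb, db in child_maps[j].items():
                        m[index[la], index[lb]] = m[index[lb], index[la]] = da + db
        for cm in child_maps:
            below.update(cm)
        return below

    def walk_children(node):
        return node.children

    walk(tree, {})
    return DistanceMatrix(labels=leaves, matrix=m)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions, each normalized to the side excluding the
    alphabetically first leaf."""
    all_leaves = set(tree.leaf_names())
    ref = min(all_leaves)
    out = set()
    for node in tree.iter_nodes():
        if node is tree or node.is_leaf:
            continue
        side = set(node.leaf_names())
        if ref in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(frozenset(side))
    return out


def bootstrap_support(
    alignment: MultipleAlignment,
    n_reps: int = 1000,
    seed: int | None = None,
    deletion: str = "pairwise",
) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    Support of an internal bipartition of the point-estimate tree is the
    percentage of replicates whose NJ tree contains it.  Replicates whose
    resampled alignment leaves some pair with no comparable sites are skipped
    (counted against the denominator of successful replicates).
    """
    if alignment.n_rows < 4:
        raise ValueError("bootstrap needs at least 4 rows")
    point = nj_tree(p_distance(alignment, deletion))
    if n_reps == 0:
        return point
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in _bipartitions(point)}
    n_ok = 0
    ncol = alignment.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(r[c] for c in cols) for r in alignment.rows]
        rep = MultipleAlignment(labels=list(alignment.labels), rows=rows)
        try:
            bps = _bipartitions(nj_tree(p_distance(rep, deletion)))
        except ValueError:
            continue
        n_ok += 1
        for bp in counts:
            if bp in bps:
                counts[bp] += 1
    ref = min(set(alignment.labels))
    all_leaves = set(alignment.labels)
    for node in point.iter_nodes():
        if node is point or node.is_leaf:
            continue
        side = set(node.leaf_names())
        if ref in side:
            side = all_leaves - side
        key = frozenset(side)
        if key in counts and n_ok:
            node.support = 100.0 * counts[key] / n_ok
    return point


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def _needs_quoting(label: str) -> bool:
    return any(c in label for c in " \t()[]':;,") or not label.isascii()


def _format_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _to_newick(node: TreeNode) -> str:
    if node.is_leaf:
        s = _format_label(node.name or "")
    else:
        inner = ",".join(_to_newick(c) for c in node.children)
        label = ""
        if node.support is not None:
            label = format(node.support, "g")
        s = f"({inner}){label}"
    if node.length is not None:
        s += f":{node.length:.10g}"
    return s


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(_to_newick(tree) + ";\n")


def read_newick(path) -> TreeNode:
    import dendropy

    dtree = dendropy.Tree.get(path=str(path), schema="newick")

    def convert(dnode) -> TreeNode:
        children = [convert(c) for c in dnode.child_nodes()]
        if children:
            support = None
            if dnode.label is not None:
                try:
                    support = float(dnode.label)
                except ValueError:
                    pass
            node = TreeNode(
                support=support, children=children,
                length=dnode.edge.length,
            )
        else:
            node = TreeNode(
                name=dnode.taxon.label if dnode.taxon else dnode.label,
                length=dnode.edge.length,
            )
        return node

    root = convert(dtree.seed_node)
    root.length = None
    return root
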