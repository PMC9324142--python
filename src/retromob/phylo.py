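"""Distance-based phylogenetics: K80 distances, neighbor joining,
bootstrap bipartition support and branch-cut partitioning.

The family rule downstream consumes only branch lengths and bootstrap
support, both of which are well defined for a neighbor-joining tree on
K80 distances, so no likelihood machinery is needed here.  Trees are
kept as a tiny node structure; Newick export places support values as
internal node labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._util import BASE_CLASS


@dataclass
class Node:
    name: str | None = None          # leaf label; None for internal nodes
    length: float = 0.0              # branch to parent
    support: float | None = None     # % bootstrap, internal edges only
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._nwk() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6f}"


# --------------------------------------------------------------------------
# K80 distances
# --------------------------------------------------------------------------

def k80_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(valid columns, transitions, transversions) for two code arrays.

    Columns where either sequence is not A/C/G/T (gaps, N) are excluded.
    """
    valid = (a < 4) & (b < 4)
    diff = valid & (a != b)
    ts = int((diff & (BASE_CLASS[a % 4] == BASE_CLASS[b % 4])).sum())
    return int(valid.sum()), ts, int(diff.sum()) - ts


def k80_from_pq(p: float, q: float) -> float | None:
    """Closed-form K80 distance; None when a log argument is <= 0."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        return None
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k80_matrix(codes: np.ndarray) -> np.ndarray:
    """Pairwise K80 distances over aligned rows; NaN marks saturated or
    empty-overlap pairs."""
    n = codes.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            nv, ts, tv = k80_counts(codes[i], codes[j])
            if nv == 0:
                dm[i, j] = dm[j, i] = np.nan
                continue
            k = k80_from_pq(ts / nv, tv / nv)
            dm[i, j] = dm[j, i] = np.nan if k is None else k
    return dm


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------

def neighbor_joining(dm: np.ndarray, labels: list[str]) -> Node:
    """Classic NJ.  Returns an unrooted tree represented with a trifurcating
    root (bifurcating for n <= 3 inputs as appropriate); negative branch
    length estimates are clamped to zero."""
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes = [Node(name=lab) for lab in labels]
    if n == 2:
        d = max(float(dm[0, 1]), 0.0)
        nodes[0].length = nodes[1].length = d / 2
        return Node(children=nodes)
    D = dm.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        qm = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qm, np.inf)
        i, j = np.unravel_index(np.argmin(qm), qm.shape)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        nodes[ai].length = max(float(li), 0.0)
        nodes[aj].length = max(float(lj), 0.0)
        parent = Node(children=[nodes[ai], nodes[aj]])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (D[ai, active] + D[aj, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        for col, val in zip(active, new_row):
            D[-1, col] = D[col, -1] = val
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]
    root = Node()
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        for idx, ln in zip((a, b, c), (la, lb, lc)):
            nodes[idx].length = max(float(ln), 0.0)
            root.children.append(nodes[idx])
    else:  # exactly 2 remain (n == 3 collapsed once)
        a, b = active
        nodes[a].length = max(float(D[a, b]) / 2, 0.0)
        nodes[b].length = max(float(D[a, b]) / 2, 0.0)
        root.children = [nodes[a], nodes[b]]
    return root


# --------------------------------------------------------------------------
# bipartitions and bootstrap support
# --------------------------------------------------------------------------

def bipartitions(tree: Node) -> dict[frozenset, Node]:
    """Map canonical split -> node for every internal edge.

    A split is the leaf set under the edge's child node, canonicalized to
    the side *not* containing the alphabetically first leaf, so the same
    unrooted bipartition always gets the same key.
    """
    all_leaves = frozenset(l.name for l in tree.leaves())
    ref = min(all_leaves)
    out: dict[frozenset, Node] = {}
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(l.name for l in node.leaves())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue  # trivial split
        key = side if ref not in side else all_leaves - side
        out[key] = node
    return out


def attach_support(
    tree: Node,
    replicate_trees: list[Node],
) -> None:
    """Set ``support`` (%) on internal edges from replicate bipartitions."""
    main = bipartitions(tree)
    counts = {key: 0 for key in main}
    for rep in replicate_trees:
        for key in bipartitions(rep):
            if key in counts:
                counts[key] += 1
    b = max(len(replicate_trees), 1)
    for key, node in main.items():
        node.support = 100.0 * counts[key] / b


def cut_tree(
    tree: Node, min_support: float = 70.0, min_branch: float = 0.3
) -> list[set[str]]:
    """Partition leaves into maximal qualifying clades plus one residual.

    An edge qualifies when its length is at least ``min_branch`` and, for
    internal edges, its bootstrap support is strictly above
    ``min_support`` (terminal edges carry no bootstrap uncertainty and
    qualify on length alone).  Descent stops at the first qualifying edge
    on any root-to-leaf path, so each reported clade is maximal; all
    leaves under no qualifying edge form a single residual group.
    """
    components: list[set[str]] = []
    residual: set[str] = set()

    def descend(node: Node):
        for child in node.children:
            qualifies = child.length >= min_branch and (
                child.is_leaf
                or (child.support is not None and child.support > min_support)
            )
            if qualifies:
                components.append({l.name for l in child.leaves()})
            elif child.is_leaf:
                residual.add(child.name)
            else:
                descend(child)

    descend(tree)
    if residual:
        components.append(residual)
    return components
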