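"""Shared phylogenetic primitives: TN93 distances, neighbour joining,
Fitch parsimony branch assignment, split extraction.

Trees are kept in a small node/tree structure of their own; Newick text is
parsed through dendropy for robustness and written canonically (children
sorted by their smallest leaf label) so identical trees serialize to
identical strings.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import _seq

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "Node",
    "Tree",
    "Split",
    "FitchResult",
    "tn93_distance",
    "nj_tree",
    "fitch_assign",
    "tree_splits",
    "midpoint_root",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class Alignment:
    """Equal-length nucleotide rows over ACGTN- (uint8 codes)."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix shape must be (n_taxa, n_columns)")

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no records in {path}")
        return cls.from_strings(seqs)

    @classmethod
    def from_strings(cls, seqs: dict[str, str]) -> "Alignment":
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise ValueError("rows differ in length")
        ids = list(seqs)
        return cls(ids, np.vstack([_seq.encode(seqs[i]) for i in ids]))

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def subset(self, taxa: list[str]) -> "Alignment":
        idx = [self.ids.index(t) for t in taxa]
        return Alignment(list(taxa), self.matrix[idx])


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances; inf marks saturated pairs."""

    ids: list[str]
    matrix: np.ndarray
    model: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def has_infinite(self) -> bool:
        return bool(np.isinf(self.matrix).any())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        """Upper triangle, row-major (the unfolded vector used by CADM)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.matrix[iu]


class Node:
    __slots__ = ("children", "parent", "length", "name")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.name = name

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted representation of an (unrooted) phylogeny."""

    def __init__(self, root: Node):
        self.root = root

    def postorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return sorted(n.name for n in self.leaves())

    def _min_leaf(self, node: Node) -> str:
        if node.is_leaf:
            return node.name
        return min(self._min_leaf(c) for c in node.children)

    def sort(self) -> None:
        """Canonical child order: by smallest contained leaf label."""
        for node in self.postorder():
            node.children.sort(key=self._min_leaf)
            for c in node.children:
                c.parent = node

    def newick(self, lengths: bool = True) -> str:
        self.sort()

        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if lengths and node.parent is not None:
                body += f":{node.length:.10g}"
            return body

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dt = dendropy.Tree.get(data=text, schema="newick")

        def convert(dn) -> Node:
            node = Node(name=dn.taxon.label if dn.taxon else None,
                        length=dn.edge.length or 0.0)
            for ch in dn.child_nodes():
                node.add(convert(ch))
            return node

        return cls(convert(dt.seed_node))

    def copy(self) -> "Tree":
        def dup(node: Node) -> Node:
            new = Node(node.name, node.length)
            for c in node.children:
                new.add(dup(c))
            return new

        return Tree(dup(self.root))


@dataclass(frozen=True)
class Split:
    """Canonical bipartition: `side` is the half not containing the
    lexicographically first taxon."""

    side: frozenset
    weight: float = 0.0

    @staticmethod
    def canonical(side: frozenset, all_taxa: frozenset, weight: float = 0.0) -> "Split":
        first = min(all_taxa)
        if first in side:
            side = all_taxa - side
        return Split(frozenset(side), weight)

    def is_trivial(self, n_taxa: int) -> bool:
        return len(self.side) < 2 or n_taxa - len(self.side) < 2


# ---------------------------------------------------------------------------
# TN93


def _tn93_pair(x: np.ndarray, y: np.ndarray, min_overlap: int) -> float:
    ok = (x <= 3) & (y <= 3)
    n = int(ok.sum())
    if n < min_overlap:
        raise ValueError(f"only {n} comparable columns (need >= {min_overlap})")
    a, b = x[ok], y[ok]
    counts = (np.bincount(a, minlength=4)[:4] + np.bincount(b, minlength=4)[:4]) / (2 * n)
    pA, pC, pG, pT = counts
    gR, gY = pA + pG, pC + pT
    diff = a != b
    transA = ((a == 0) & (y[ok] == 2)) | ((a == 2) & (y[ok] == 0))
    transC = ((a == 1) & (y[ok] == 3)) | ((a == 3) & (y[ok] == 1))
    P1 = float(transA.sum()) / n
    P2 = float(transC.sum()) / n
    Q = float(diff.sum()) / n - P1 - P2
    if n == 0:
        return math.inf

    terms = 0.0
    eps = 0.0
    # purine transitions
    if pA * pG > eps:
        w1 = 1 - gR * P1 / (2 * pA * pG) - Q / (2 * gR)
        if w1 <= 0:
            return math.inf
        terms += -2 * pA * pG / gR * math.log(w1)
    elif P1 > 0:
        return math.inf
    # pyrimidine transitions
    if pC * pT > eps:
        w2 = 1 - gY * P2 / (2 * pC * pT) - Q / (2 * gY)
        if w2 <= 0:
            return math.inf
        terms += -2 * pC * pT / gY * math.log(w2)
    elif P2 > 0:
        return math.inf
    # transversions
    if gR * gY > eps:
        w3 = 1 - Q / (2 * gR * gY)
        if w3 <= 0:
            return math.inf
        k3 = 2 * (gR * gY - pA * pG * gY / gR - pC * pT * gR / gY)
        terms += -k3 * math.log(w3)
    elif Q > 0:
        return math.inf
    return max(terms, 0.0)


def tn93_distance(aln: Alignment, min_overlap: int = 50) -> DistanceMatrix:
    """Tamura-Nei (1993) pairwise distances with pairwise deletion.

    Base frequencies are estimated per pair as the mean of the two rows'
    frequencies over their comparable (both ACGT) columns.  Saturated pairs
    (a log argument <= 0) are flagged infinite.
    """
    n = len(aln.ids)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        try:
            v = _tn93_pair(aln.matrix[i], aln.matrix[j], min_overlap)
        except ValueError as exc:
            raise ValueError(f"pair ({aln.ids[i]}, {aln.ids[j]}): {exc}") from None
        d[i, j] = d[j, i] = v
    return DistanceMatrix(ids=list(aln.ids), matrix=d, model="TN93")


# ---------------------------------------------------------------------------
# neighbour joining


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (representative, representative) leaf-name pair.  Negative branch
    lengths are clamped to zero and the deficit moved to the sister branch,
    preserving path lengths.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if dm.has_infinite:
        iu = np.triu_indices(n, k=1)
        bad = [(dm.ids[i], dm.ids[j]) for i, j in zip(*iu)
               if np.isinf(dm.matrix[i, j])]
        raise ValueError(f"saturated pairs: {bad}")
    d = dm.matrix.astype(float).copy()
    nodes = [Node(name=i) for i in dm.ids]
    reps = list(dm.ids)  # smallest leaf label per cluster, for tie-breaks
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai, aj in itertools.combinations(range(m), 2):
            q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
            names = tuple(sorted((reps[active[ai]], reps[active[aj]])))
            key = (q, names)
            if best is None or key < best[0]:
                best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = dij / 2 + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = Node()
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        parent.add(ni)
        parent.add(nj_)
        # distances from the new cluster to the remaining ones
        d = np.pad(d, ((0, 1), (0, 1)))
        knew = d.shape[0] - 1
        for a in active:
            if a not in (i, j):
                d[knew, a] = d[a, knew] = 0.5 * (d[i, a] + d[j, a] - dij)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [a for a in active if a not in (i, j)] + [knew]
    # final three-way join
    i, j, k = active
    root = Node()
    a = (d[i, j] + d[i, k] - d[j, k]) / 2
    b = (d[i, j] + d[j, k] - d[i, k]) / 2
    c = (d[i, k] + d[j, k] - d[i, j]) / 2
    for idx, length in ((i, a), (j, b), (k, c)):
        nodes[idx].length = max(length, 0.0)
        root.add(nodes[idx])
    tree = Tree(root)
    tree.sort()
    return tree


# ---------------------------------------------------------------------------
# splits


def tree_splits(tree: Tree, include_trivial: bool = False) -> list[Split]:
    """One canonical split per internal edge (weight = branch length)."""
    all_taxa = frozenset(tree.leaf_names())
    n = len(all_taxa)
    below: dict[int, frozenset] = {}
    splits = []
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node.parent is not None:
            sp = Split.canonical(below[id(node)], all_taxa, weight=node.length)
            if include_trivial or not sp.is_trivial(n):
                splits.append(sp)
    # deduplicate (the root edge can repeat a child split in rooted trees)
    seen, out = set(), []
    for sp in splits:
        if sp.side not in seen:
            seen.add(sp.side)
            out.append(sp)
    return out


# ---------------------------------------------------------------------------
# midpoint rooting and Fitch assignment


def _leaf_distances(tree: Tree) -> tuple[dict, dict]:
    """Distances from each node to all leaves below; and to the farthest."""
    down: dict[int, dict[str, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            down[id(node)] = {node.name: 0.0}
        else:
            acc = {}
            for c in node.children:
                for leaf, dist in down[id(c)].items():
                    acc[leaf] = dist + c.length
            down[id(node)] = acc
    return down, {}


def midpoint_root(tree: Tree) -> Tree:
    """Copy of the tree rooted at the midpoint of its longest leaf path."""
    t = tree.copy()
    down, _ = _leaf_distances(t)
    # longest path through each node combining two child subtrees
    best = (-1.0, None, None, None)
    for node in t.postorder():
        if node.is_leaf or len(node.children) < 2:
            continue
        tops = []
        for c in node.children:
            leaf, dist = max(down[id(c)].items(), key=lambda kv: (kv[1], kv[0]))
            tops.append((dist + c.length, leaf, c))
        tops.sort(key=lambda x: (-x[0], x[1]))
        total = tops[0][0] + tops[1][0]
        if total > best[0]:
            best = (total, node, tops[0], tops[1])
    total, node, far1, far2 = best
    half = total / 2
    # walk from the farther side's child toward its deepest leaf until the
    # midpoint edge is found
    dist_needed = far1[0] - half  # distance of midpoint above far1 subtree top
    cur = far1[2]
    acc = far1[0]  # distance from `node` through cur to deepest leaf
    while True:
        # midpoint lies on edge (cur.parent, cur) iff remaining distance to
        # the deepest leaf below cur is < half
        below_depth = max(down[id(cur)].values())
        if below_depth <= half <= below_depth + cur.length + 1e-12:
            break
        leaf, dist = max(down[id(cur)].items(), key=lambda kv: (kv[1], kv[0]))
        nxt = None
        for c in cur.children:
            if down[id(c)].get(leaf) is not None and abs(down[id(c)][leaf] + c.length - dist) < 1e-9:
                nxt = c
                break
        cur = nxt
    return _reroot_at_edge(t, cur)


def _reroot_at_edge(tree: Tree, child: Node) -> Tree:
    """Root the tree on the edge above `child` (length split evenly)."""
    old_parent = child.parent
    if old_parent is None:
        return tree
    # build chain from old_parent up to old root
    chain = []
    node = old_parent
    while node is not None:
        chain.append(node)
        node = node.parent
    new_root = Node()
    half = child.length / 2
    old_parent.children.remove(child)
    child.length = half
    new_root.add(child)
    # flip the chain: each former parent becomes a child of its former child
    prev = new_root
    prev_edge = half
    for k, node in enumerate(chain):
        node_parent = chain[k + 1] if k + 1 < len(chain) else None
        if node_parent is not None:
            node_parent.children.remove(node)
        edge_up = node.length
        node.parent = None
        node.length = prev_edge
        prev.add(node)
        prev = node
        prev_edge = edge_up
    t = Tree(new_root)
    # collapse a degree-2 old root if present
    for node in list(t.postorder()):
        if node.parent is not None and not node.is_leaf and len(node.children) == 1:
            only = node.children[0]
            only.length += node.length
            parent = node.parent
            parent.children[parent.children.index(node)] = only
            only.parent = parent
    t.sort()
    return t


@dataclass
class FitchResult:
    """Per-branch substitution assignments from Fitch parsimony."""

    changes: list[dict]            # {branch, side, column, from, to}
    score: int
    per_branch: dict[str, list[int]] = field(default=None)  # branch -> columns
    per_side: dict[tuple, list[int]] = field(default=None)  # descendant side -> columns

    def __post_init__(self):
        if self.per_branch is None:
            per, per_side = {}, {}
            for ch in self.changes:
                per.setdefault(ch["branch"], []).append(ch["column"])
                per_side.setdefault(ch["side"], []).append(ch["column"])
            self.per_branch = per
            self.per_side = per_side


def branch_key(side_leaves: frozenset, all_taxa: frozenset) -> str:
    first = min(all_taxa)
    side = side_leaves if first not in side_leaves else all_taxa - side_leaves
    return "|".join(sorted(side))


def fitch_assign(tree: Tree, aln: Alignment, root: str = "midpoint") -> FitchResult:
    """Fitch parsimony: assign each variant column's state changes to branches.

    The tree is rooted at the midpoint of its longest leaf path (so that
    ambiguous assignments resolve toward the centre of the tree), states are
    computed bottom-up over all columns at once as bitmasks, and the
    top-down pass picks the parent state when allowed, otherwise the
    smallest compatible state.  Branches are identified by the canonical
    bipartition of leaf names they induce.  N and gaps are treated as
    unconstrained (full state set).
    """
    if sorted(aln.ids) != tree.leaf_names():
        raise ValueError("tree leaves and alignment taxa differ")
    t = midpoint_root(tree) if root == "midpoint" else tree.copy()
    all_taxa = frozenset(t.leaf_names())
    L = aln.n_columns
    row_of = {name: k for k, name in enumerate(aln.ids)}
    masks: dict[int, np.ndarray] = {}
    below: dict[int, frozenset] = {}
    score = np.zeros(L, dtype=np.int64)
    order = list(t.postorder())
    for node in order:
        if node.is_leaf:
            codes = aln.matrix[row_of[node.name]]
            m = np.where(codes <= 3, (1 << codes.astype(np.int64)), 15).astype(np.uint8)
            masks[id(node)] = m
            below[id(node)] = frozenset([node.name])
        else:
            cur = masks[id(node.children[0])].copy()
            for c in node.children[1:]:
                inter = cur & masks[id(c)]
                union_needed = inter == 0
                score += union_needed
                cur = np.where(union_needed, cur | masks[id(c)], inter).astype(np.uint8)
            masks[id(node)] = cur
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
    lowest_bit = np.array([0, 0, 1, 0, 2, 0, 1, 0, 3, 0, 1, 0, 2, 0, 1, 0],
                          dtype=np.uint8)
    states: dict[int, np.ndarray] = {id(t.root): lowest_bit[masks[id(t.root)]]}
    changes = []
    variant = np.nonzero(score > 0)[0]
    for node in t.preorder():
        if node.parent is None:
            continue
        pm = states[id(node.parent)]
        m = masks[id(node)]
        keep = (m >> pm) & 1
        st = np.where(keep == 1, pm, lowest_bit[m])
        states[id(node)] = st.astype(np.uint8)
        diff_cols = np.nonzero(st != pm)[0]
        if diff_cols.size:
            key = branch_key(below[id(node)], all_taxa)
            side = tuple(sorted(below[id(node)]))
            for col in diff_cols:
                changes.append({"branch": key, "side": side, "column": int(col),
                                "from": int(pm[col]), "to": int(st[col])})
    return FitchResult(changes=changes, score=int(score.sum()))
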