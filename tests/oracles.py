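"""Independent brute-force oracles used by the tests.

Everything here is written against the definitions, not against the
package: exhaustive tree enumeration with set-based small parsimony, and a
plain-numpy affine local aligner is deliberately NOT reimplemented (the
biotite aligner serves as the Smith-Waterman reference instead).
"""

from __future__ import annotations

import numpy as np


def _insertions(subtree, leaf):
    """All trees obtained by inserting `leaf` on any edge of `subtree`
    (including the edge above it)."""
    yield (subtree, leaf)
    if isinstance(subtree, tuple):
        for idx, child in enumerate(subtree):
            for new_child in _insertions(child, leaf):
                yield subtree[:idx] + (new_child,) + subtree[idx + 1:]


def all_unrooted_trees(taxa: list):
    """All unrooted binary leaf-labeled trees on `taxa`.

    Each tree is returned as the nested tuple hanging below taxa[0]'s
    pendant edge, i.e. the full tree is (taxa[0], T).  Counts: 3 / 15 / 105
    trees for 4 / 5 / 6 taxa.
    """
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    trees = [(taxa[1], taxa[2])]
    for leaf in taxa[3:]:
        trees = [t2 for t in trees for t2 in _insertions(t, leaf)]
    return [(taxa[0], t) for t in trees]


def fitch_steps(tree, states: dict) -> int:
    """Small-parsimony steps of one character on a (nested-tuple) tree.

    Missing taxa (absent from `states`) are unconstrained.
    """
    count = [0]

    def walk(node):
        if not isinstance(node, tuple):
            s = states.get(node)
            return frozenset([s]) if s is not None else None
        sets = [walk(c) for c in node]
        sets = [s for s in sets if s is not None]
        if not sets:
            return None
        cur = sets[0]
        for s in sets[1:]:
            inter = cur & s
            if inter:
                cur = inter
            else:
                count[0] += 1
                cur = cur | s
        return cur

    walk(tree)
    return count[0]


def min_parsimony_steps(taxa: list, column: dict) -> int:
    """Minimum steps of one character over all unrooted trees."""
    return min(fitch_steps(t, column) for t in all_unrooted_trees(taxa))


def min_joint_extra_steps(taxa: list, col_i: dict, col_j: dict) -> int:
    """Minimum, over all trees, of the total extra steps of two characters
    beyond their individual parsimony lower bounds (k - 1 each)."""
    ki = len(set(col_i.values()))
    kj = len(set(col_j.values()))
    best = None
    for t in all_unrooted_trees(taxa):
        total = fitch_steps(t, col_i) + fitch_steps(t, col_j)
        best = total if best is None else min(best, total)
    return best - (ki - 1) - (kj - 1)


def kendall_w_direct(matrices: list[np.ndarray]) -> float:
    """Kendall W by direct rank arithmetic (no tie handling; for no-tie data)."""
    from scipy.stats import rankdata

    ranks = np.vstack([rankdata(m) for m in matrices])
    p, m = ranks.shape
    R = ranks.sum(axis=0)
    S = ((R - R.mean()) ** 2).sum()
    return float(12 * S / (p * p * (m**3 - m)))
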