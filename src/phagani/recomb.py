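"""Recombination detection within groups.

Two complementary detectors:

* the pairwise homoplasy index (PHI): mean refined incompatibility among
  parsimony-informative site pairs lying within a window of each other,
  against a null that permutes the sites' positions.  Recombination makes
  incompatibility grow with distance, so an observed near-pair mean that is
  low relative to the permutation null is the signal.
* a simplified SNP-density clonal-frame scan over a concatenated core
  alignment: iteratively build an NJ tree on TN93 distances, assign SNPs to
  branches by Fitch parsimony, test dense SNP runs per branch with a
  binomial tail at the branch's background density, mask significant
  tracts for that branch, and repeat.  The clonal frame of a branch is the
  fraction of columns not covered by its recombinant tracts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phylo import Alignment, Tree, fitch_assign, nj_tree, tn93_distance

__all__ = [
    "PhiResult",
    "RecombinantTract",
    "ClonalFrameReport",
    "informative_sites",
    "refined_incompatibility",
    "phi_test",
    "detect_recombinant_tracts",
    "clonal_frame",
]


# ---------------------------------------------------------------------------
# PHI


def informative_sites(aln: Alignment) -> list[tuple[int, np.ndarray]]:
    """Parsimony-informative columns: >= 2 states each in >= 2 taxa.

    N and gaps are missing data, ignored per column.  Returns (column
    index, state vector) pairs; missing entries keep their code (> 3).
    """
    out = []
    m = aln.matrix
    for col in range(m.shape[1]):
        states = m[:, col]
        counts = np.bincount(states[states <= 3], minlength=4)
        if (counts >= 2).sum() >= 2:
            out.append((col, states.copy()))
    return out


def refined_incompatibility(site_i: np.ndarray, site_j: np.ndarray) -> int:
    """Minimum extra mutations needed to fit both sites on one tree.

    Computed as the cyclomatic number E - V + C of the partition
    intersection graph: vertices are observed states of each site, edges
    the distinct observed joint states, over taxa non-missing at both.
    """
    ok = (site_i <= 3) & (site_j <= 3)
    a, b = site_i[ok], site_j[ok]
    if a.size == 0:
        return 0
    pairs = set(zip(a.tolist(), b.tolist()))
    va = {x for x, _ in pairs}
    vb = {y for _, y in pairs}
    V = len(va) + len(vb)
    E = len(pairs)
    # connected components of the bipartite state graph
    parent = {("a", x): ("a", x) for x in va} | {("b", y): ("b", y) for y in vb}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for x, y in pairs:
        ra, rb = find(("a", x)), find(("b", y))
        if ra != rb:
            parent[ra] = rb
    C = len({find(u) for u in parent})
    return E - V + C


@dataclass
class PhiResult:
    n_informative: int
    window: int
    phi: float | None
    p_value: float | None
    n_permutations: int
    seed: int
    testable: bool
    gene_id: str = ""


def phi_test(aln: Alignment, w: int = 100, n_perm: int = 1000,
             seed: int = 0, gene_id: str = "") -> PhiResult:
    """Pairwise homoplasy index with a site-position permutation null.

    phi = mean refined incompatibility over unordered informative-site
    pairs separated by at most ``w`` alignment positions.  The null keeps
    the state vectors but shuffles which positions they sit at; one-tailed
    p = (1 + #{phi_perm <= phi_obs}) / (n_perm + 1), small when nearby
    sites are unusually compatible (the recombination signature).  Fewer
    than two informative sites, or no pair within the window under any
    permutation, yields an untestable result rather than an error.
    """
    sites = informative_sites(aln)
    k = len(sites)
    if k < 2:
        return PhiResult(k, w, None, None, n_perm, seed, False, gene_id)
    positions = np.array([c for c, _ in sites])
    S = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        S[i, j] = S[j, i] = refined_incompatibility(sites[i][1], sites[j][1])
    near = np.abs(positions[:, None] - positions[None, :]) <= w
    np.fill_diagonal(near, False)
    iu = np.triu_indices(k, k=1)
    mask = near[iu]
    if not mask.any():
        return PhiResult(k, w, None, None, n_perm, seed, False, gene_id)
    phi_obs = float(S[iu][mask].mean())
    rng = np.random.default_rng(seed)
    count = 0
    vals = S[iu]
    for _ in range(n_perm):
        perm = rng.permutation(k)
        Sp = S[np.ix_(perm, perm)]
        if Sp[iu][mask].mean() <= phi_obs + 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PhiResult(k, w, phi_obs, p, n_perm, seed, True, gene_id)


# ---------------------------------------------------------------------------
# clonal-frame scan


@dataclass
class RecombinantTract:
    branch: str
    start: int
    end: int           # 0-based half-open columns
    n_snps: int
    p_value: float
    side: tuple = ()   # descendant taxa carrying the imported tract

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class ClonalFrameReport:
    fractions: dict[str, float]
    aln_length: int

    @property
    def range(self) -> tuple[float, float]:
        vals = list(self.fractions.values())
        return (min(vals), max(vals)) if vals else (1.0, 1.0)


def _scan_branch(
    columns: np.ndarray,
    aln_len: int,
    alpha: float,
    min_run: int,
    max_gap: int,
) -> list[tuple[int, int, int, float]]:
    """Test dense SNP runs on one branch; returns (start, end, k, p) tracts.

    Runs are maximal stretches of branch SNPs whose consecutive gaps are at
    most ``max_gap`` columns.  A run of k SNPs spanning l columns is scored
    by the binomial tail P(X >= k - 2) for X ~ Bin(l, background): the two
    boundary SNPs that define the span are discounted because they were
    used to select the window, and the background density is the branch's
    overall SNP density (run included, which makes the test conservative
    for runs spanning a large part of the alignment).  Because the window
    span is itself
    chosen by the scan, the significance threshold uses a scan-statistic
    Bonferroni: alpha divided by the number of possible placements of a
    window of that span (aln_len / span), never fewer than the number of
    runs tested.
    """
    cols = np.sort(columns)
    n = cols.size
    if n == 0:
        return []
    breaks = np.nonzero(np.diff(cols) > max_gap)[0] + 1
    runs = np.split(cols, breaks)
    out = []
    for run in runs:
        k = run.size
        if k < min_run:
            continue
        start, end = int(run[0]), int(run[-1]) + 1
        span = end - start
        if span * 2 > aln_len:
            # a run covering most of the alignment is the branch's own
            # substitution background, not an imported tract
            continue
        bg = n / aln_len
        n_tests = max(len(runs), math.ceil(aln_len / span))
        p = float(stats.binom.sf(k - 2 - 1, span, min(bg, 1.0)))
        if p <= alpha / n_tests:
            out.append((start, end, k, p))
    return out


def detect_recombinant_tracts(
    aln: Alignment,
    max_iter: int = 5,
    alpha: float = 0.05,
    min_run: int = 3,
    max_gap: int = 100,
    min_scan_len: int = 1000,
) -> tuple[list[RecombinantTract], Tree]:
    """Iterative SNP-density tract detection on a concatenated core alignment.

    Each round: NJ tree on TN93 distances of the current (branch-masked)
    alignment, Fitch assignment of variant columns to branches, per-branch
    run test (see _scan_branch).  Columns of accepted tracts are masked to
    missing in the taxa below the branch, and the procedure repeats until
    no new tract or ``max_iter`` rounds.  Returns all accepted tracts and
    the final tree.
    """
    if len(aln.ids) < 4:
        raise ValueError("need >= 4 taxa")
    if aln.n_columns < min_scan_len:
        raise ValueError(f"alignment shorter than min_scan_len={min_scan_len}")
    work = Alignment(list(aln.ids), aln.matrix.copy())
    row_of = {name: i for i, name in enumerate(work.ids)}
    tracts: list[RecombinantTract] = []
    tree = None
    for iteration in range(max_iter):
        try:
            tree = nj_tree(tn93_distance(work))
        except ValueError:
            if iteration == 0:
                raise
            # masking left some pair with too few comparable columns (or a
            # saturated distance); keep the tracts found so far
            break
        fr = fitch_assign(tree, work)
        key_of = {ch["side"]: ch["branch"] for ch in fr.changes}
        new = []
        for side, cols in sorted(fr.per_side.items()):
            branch = key_of[side]
            existing = [t for t in tracts if t.side == side]
            for start, end, k, p in _scan_branch(
                    np.array(cols), work.n_columns, alpha, min_run, max_gap):
                if any(t.overlap(start, end) for t in existing):
                    continue
                new.append(RecombinantTract(branch, start, end, k, p, side))
        if not new:
            break
        for t in new:
            for name in t.side:
                work.matrix[row_of[name], t.start:t.end] = 4  # N
        tracts.extend(new)
    tracts.sort(key=lambda t: (t.branch, t.start))
    return tracts, tree


def clonal_frame(tracts: list[RecombinantTract], aln_length: int,
                 tree: Tree) -> ClonalFrameReport:
    """Per-branch fraction of columns untouched by recombinant tracts."""
    from .phylo import tree_splits, branch_key

    all_taxa = frozenset(tree.leaf_names())
    keys = {branch_key(frozenset([n]), all_taxa) for n in all_taxa}
    keys |= {branch_key(s.side, all_taxa) for s in tree_splits(tree)}
    fractions = {k: 1.0 for k in sorted(keys)}
    per: dict[str, list[RecombinantTract]] = {}
    for t in tracts:
        per.setdefault(t.branch, []).append(t)
    for branch, ts in per.items():
        covered = np.zeros(aln_length, dtype=bool)
        for t in ts:
            covered[t.start:t.end] = True
        fractions[branch] = 1.0 - covered.sum() / aln_length
    return ClonalFrameReport(fractions=fractions, aln_length=aln_length)
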