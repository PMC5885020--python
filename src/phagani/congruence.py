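"""Congruence among per-gene distance matrices and consensus splits.

The CADM statistic is Kendall's coefficient of concordance W computed over
the rank-transformed unfolded upper triangles of p distance matrices on a
shared taxa set, with a permutation null that relabels the taxa of every
matrix independently.  A-posteriori Mantel tests give the pairwise picture
(Spearman correlation of unfolded ranks, one-tailed permutation p).  The
progressive procedure re-runs CADM on nested samples (a group, then its
satellites, then a neighbouring group), recomputing the shared single-copy
gene set at every step.  Consensus splits pool the nontrivial bipartitions
of many gene trees, weighting each by its frequency of occurrence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import Alignment, DistanceMatrix, Split, Tree, tn93_distance, tree_splits

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrixSet",
    "CadmResult",
    "ProgressiveResult",
    "SplitSet",
    "gene_distance_set",
    "cadm",
    "progressive_cadm",
    "consensus_splits",
]


@dataclass
class DistanceMatrixSet:
    """One distance matrix per gene, all over the identical taxa set."""

    taxa: list[str]
    matrices: list[DistanceMatrix]
    gene_ids: list[str]

    def __post_init__(self):
        for dm in self.matrices:
            if dm.ids != self.taxa:
                raise ValueError("matrix taxa ordering differs from set taxa")

    @property
    def p(self) -> int:
        return len(self.matrices)


def gene_distance_set(
    gene_alignments: dict[str, Alignment],
    shared_taxa: list[str],
    min_overlap: int = 50,
) -> DistanceMatrixSet:
    """TN93 matrices restricted to the shared taxa; saturated genes dropped."""
    matrices, gene_ids = [], []
    for gene_id in sorted(gene_alignments):
        aln = gene_alignments[gene_id].subset(shared_taxa)
        try:
            dm = tn93_distance(aln, min_overlap=min_overlap)
        except ValueError as exc:
            logger.warning("gene %s dropped: %s", gene_id, exc)
            continue
        if dm.has_infinite:
            logger.warning("gene %s dropped: saturated pair", gene_id)
            continue
        matrices.append(dm)
        gene_ids.append(gene_id)
    if not matrices:
        raise ValueError("no usable genes")
    return DistanceMatrixSet(list(shared_taxa), matrices, gene_ids)


@dataclass
class CadmResult:
    W: float
    friedman_chi2: float
    p_value: float
    n_perm: int
    seed: int
    n_taxa: int
    n_genes: int
    mantel: pd.DataFrame = field(default=None)  # gene_i, gene_j, r, p
    testable: bool = True

    @property
    def mean_spearman(self) -> float:
        """(pW - 1)/(p - 1): the mean pairwise Spearman implied by W."""
        p = self.n_genes
        return (p * self.W - 1) / (p - 1)


def _condensed_pos(n: int) -> np.ndarray:
    """(n, n) lookup from taxa pair to condensed (upper-triangle) index."""
    pos = np.zeros((n, n), dtype=np.int64)
    iu = np.triu_indices(n, k=1)
    pos[iu] = np.arange(iu[0].size)
    pos += pos.T
    return pos


def _pair_permutation_index(n: int, perm: np.ndarray,
                            pos: np.ndarray | None = None) -> np.ndarray:
    """Index mapping of condensed pairs under a taxa relabeling."""
    if pos is None:
        pos = _condensed_pos(n)
    iu = np.triu_indices(n, k=1)
    return pos[perm[iu[0]], perm[iu[1]]]


def _kendall_w(ranks: np.ndarray, ties: np.ndarray) -> float:
    """W from a (p, m) matrix of within-matrix ranks with tie corrections."""
    p, m = ranks.shape
    col_sums = ranks.sum(axis=0)
    S = float(((col_sums - col_sums.mean()) ** 2).sum())
    denom = p * p * (m**3 - m) - p * ties.sum()
    if denom <= 0:
        return float("nan")
    return 12.0 * S / denom


def _tie_correction(vec: np.ndarray) -> float:
    _, counts = np.unique(vec, return_counts=True)
    return float((counts**3 - counts).sum())


def cadm(dms: DistanceMatrixSet, n_perm: int = 999, seed: int = 0,
         mantel: bool = True, mantel_n_perm: int = 999) -> CadmResult:
    """Global CADM test plus a-posteriori Mantel tests.

    W uses mid-ranks with the standard tie correction; Friedman's
    chi-square is p(m-1)W.  The global p permutes the taxa labels of every
    matrix independently and counts permuted W at least as large; Mantel
    tests permute one matrix of each pair.  Degenerate sets (all distances
    tied in every matrix) are flagged untestable.
    """
    n = len(dms.taxa)
    p = dms.p
    if p < 2 or n < 4:
        raise ValueError("need >= 2 matrices over >= 4 taxa")
    rng = np.random.default_rng(seed)
    unfolded = np.vstack([dm.condensed() for dm in dms.matrices])
    m = unfolded.shape[1]
    ranks = np.vstack([stats.rankdata(row) for row in unfolded])
    ties = np.array([_tie_correction(row) for row in unfolded])
    W_obs = _kendall_w(ranks, ties)
    if np.isnan(W_obs):
        return CadmResult(float("nan"), float("nan"), float("nan"), n_perm, seed,
                          n, p, testable=False)
    pos = _condensed_pos(n)
    count = 0
    for _ in range(n_perm):
        perm_ranks = np.empty_like(ranks)
        for g in range(p):
            idx = _pair_permutation_index(n, rng.permutation(n), pos)
            perm_ranks[g] = ranks[g][idx]
        if _kendall_w(perm_ranks, ties) >= W_obs - 1e-12:
            count += 1
    p_value = (1 + count) / (n_perm + 1)
    mantel_df = None
    if mantel:
        # Spearman = Pearson on mid-ranks; normalize rank rows once, then
        # each permutation relabels the first matrix of every pair at once
        Z = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Z, axis=1)
        norms[norms == 0] = 1.0
        Z = Z / norms[:, None]
        r_obs_mat = Z @ Z.T
        counts = np.zeros((p, p), dtype=np.int64)
        for _ in range(mantel_n_perm):
            idx = _pair_permutation_index(n, rng.permutation(n), pos)
            counts += (Z[:, idx] @ Z.T) >= r_obs_mat - 1e-12
        rows = []
        for gi, gj in itertools.combinations(range(p), 2):
            rows.append({"gene_i": dms.gene_ids[gi], "gene_j": dms.gene_ids[gj],
                         "r": float(r_obs_mat[gi, gj]),
                         "p": (1 + int(counts[gi, gj])) / (mantel_n_perm + 1)})
        mantel_df = pd.DataFrame(rows, columns=["gene_i", "gene_j", "r", "p"])
    return CadmResult(W_obs, p * (m - 1) * W_obs, p_value, n_perm, seed, n, p,
                      mantel=mantel_df)


@dataclass
class ProgressiveResult:
    steps: list[dict]  # label, taxa, n_genes, W, p, mantel_r_median, frac_significant

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{k: v for k, v in s.items() if k != "taxa"}
                             for s in self.steps])


def progressive_cadm(
    base: list[str],
    additions: list[tuple[str, list[str]]],
    gene_alignments_for: "callable",
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> ProgressiveResult:
    """CADM over nested samples: base, then base + each addition prefix.

    ``gene_alignments_for(sample)`` must return the per-gene alignments of
    the genes shared (single-copy, in every genome) by the sample — the
    pangenome module provides this.  Steps whose sample has no usable gene
    are flagged and skipped.
    """
    steps = []
    sample = list(base)
    plan = [("base", [])] + [(label, genomes) for label, genomes in additions]
    for label, genomes in plan:
        sample = sample + [g for g in genomes if g not in sample]
        entry = {"label": label, "taxa": list(sample), "n_taxa": len(sample)}
        try:
            alns = gene_alignments_for(sample)
            if not alns:
                raise ValueError("no shared single-copy genes")
            dms = gene_distance_set(alns, sample)
            res = cadm(dms, n_perm=n_perm, seed=seed)
            entry.update({
                "n_genes": dms.p, "W": res.W, "p": res.p_value,
                "mantel_r_median": float(res.mantel["r"].median()),
                "frac_significant": float((res.mantel["p"] < alpha).mean()),
                "ok": True,
            })
        except ValueError as exc:
            logger.warning("step %s flagged: %s", label, exc)
            entry.update({"ok": False, "reason": str(exc)})
        steps.append(entry)
    return ProgressiveResult(steps=steps)


@dataclass
class SplitSet:
    splits: list[Split]     # weight = occurrence frequency
    taxa: list[str]
    min_freq: float

    def weight_of(self, side: frozenset) -> float:
        canon = Split.canonical(side, frozenset(self.taxa)).side
        for s in self.splits:
            if s.side == canon:
                return s.weight
        return 0.0

    def to_nexus(self) -> str:
        """SplitsTree-compatible NEXUS with TAXA and SPLITS blocks."""
        taxa = sorted(self.taxa)
        index = {t: i + 1 for i, t in enumerate(taxa)}
        lines = [
            "#NEXUS", "",
            "BEGIN Taxa;",
            f"DIMENSIONS ntax={len(taxa)};",
            "TAXLABELS",
        ]
        lines += [f"[{i+1}] '{t}'" for i, t in enumerate(taxa)]
        lines += [";", "END;", "", "BEGIN Splits;",
                  f"DIMENSIONS ntax={len(taxa)} nsplits={len(self.splits)};",
                  "FORMAT labels=no weights=yes confidences=no intervals=no;",
                  "MATRIX"]
        for s in sorted(self.splits, key=lambda s: (-s.weight, sorted(s.side))):
            members = " ".join(str(index[t]) for t in sorted(s.side))
            lines.append(f"[{s.weight:.6g}] {s.weight:.6g} \t {members},")
        lines += [";", "END;"]
        return "\n".join(lines) + "\n"


def consensus_splits(trees: list[Tree], min_freq: float = 0.1) -> SplitSet:
    """Pool nontrivial splits over gene trees; weight = occurrence frequency."""
    if len(trees) < 2:
        raise ValueError("need >= 2 trees")
    taxa = trees[0].leaf_names()
    counts: dict[frozenset, int] = {}
    for t in trees:
        if t.leaf_names() != taxa:
            raise ValueError("trees are over different taxa sets")
        for sp in tree_splits(t):
            counts[sp.side] = counts.get(sp.side, 0) + 1
    splits = [Split(side, c / len(trees)) for side, c in counts.items()
              if c / len(trees) >= min_freq]
    splits.sort(key=lambda s: (-s.weight, sorted(s.side)))
    return SplitSet(splits=splits, taxa=taxa, min_freq=min_freq)
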