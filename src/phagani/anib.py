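"""Fragment-based average nucleotide identity (ANIb) and coverage.

The query genome is cut into fixed-length non-overlapping fragments
(default 500 bp); each fragment is locally aligned against the whole target
genome (either strand) and a hit qualifies when its identity is at least
``min_identity`` % over at least ``min_fraction`` of the fragment.  ANI is
the unweighted mean identity of qualifying hits; coverage is the fraction
of the query contained in qualifying fragments.  Group delineation joins
genomes whose symmetrized ANI reaches the cutoff (default 92 %) with
adequate mutual coverage, and takes connected components; genomes whose
best ANI to a group falls in an intermediate band (default 85-92 %) are
reported as satellites of that group, and high-ANI/low-coverage pairs are
flagged as candidate horizontal-transfer events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import _seq
from .align import LocalHit, Scoring, TargetIndex, best_local_match

__all__ = [
    "AnibParams",
    "Fragment",
    "FragmentHit",
    "AniResult",
    "AniMatrix",
    "GroupPartition",
    "fragment_genome",
    "compute_anib",
    "compute_all",
    "delineate_groups",
    "find_satellites",
    "flag_transfer_candidates",
    "ani_report",
]


@dataclass(frozen=True)
class AnibParams:
    """Tunable knobs of the ANIb computation.

    Hit qualification (identity >= 30 % over >= 70 % of the fragment)
    follows the published blast-fragment ANI definition; the trailing
    fragment is kept when it is at least half the fragment length.
    """

    fragment_length: int = 500
    min_identity: float = 30.0
    min_fraction: float = 0.7
    scoring: Scoring = field(default_factory=Scoring)
    exact_max_len: int = 5000
    seed_k: int = 11
    max_windows: int = 2


@dataclass
class Fragment:
    genome_id: str
    index: int
    start: int
    end: int
    sequence: str


@dataclass
class FragmentHit:
    fragment: Fragment
    hit: LocalHit
    identity: float | None
    aligned_fraction: float
    qualifying: bool


@dataclass
class AniResult:
    """Directional ANI of query vs target."""

    query_id: str
    target_id: str
    ani: float | None        # None when no fragment qualifies
    coverage: float
    n_fragments: int
    n_qualifying: int


def fragment_genome(sequence: str, fragment_length: int = 500,
                    genome_id: str = "") -> list[Fragment]:
    """Tile a genome into consecutive non-overlapping fragments.

    The trailing partial fragment is kept iff its length is at least half
    the fragment length.
    """
    if not sequence:
        raise ValueError("empty sequence")
    frags = []
    n_full = len(sequence) // fragment_length
    for i in range(n_full):
        s = i * fragment_length
        frags.append(Fragment(genome_id, i, s, s + fragment_length,
                              sequence[s:s + fragment_length]))
    tail = len(sequence) - n_full * fragment_length
    if tail * 2 >= fragment_length and tail > 0:
        s = n_full * fragment_length
        frags.append(Fragment(genome_id, n_full, s, len(sequence), sequence[s:]))
    return frags


def compute_anib(
    query: str,
    target: str,
    params: AnibParams | None = None,
    query_id: str = "query",
    target_id: str = "target",
    target_index: TargetIndex | None = None,
    return_hits: bool = False,
):
    """Directional ANIb of one genome pair."""
    params = params or AnibParams()
    if not query or not target:
        raise ValueError("both genomes must be non-empty")
    t_codes = _seq.encode(target)
    if target_index is None and len(t_codes) > params.exact_max_len:
        target_index = TargetIndex(t_codes, k=params.seed_k)
    fragments = fragment_genome(query, params.fragment_length, query_id)
    hits: list[FragmentHit] = []
    identities = []
    covered = 0
    for frag in fragments:
        h = best_local_match(
            frag.sequence, t_codes, scoring=params.scoring, index=target_index,
            exact_max_len=params.exact_max_len, k=params.seed_k,
            max_windows=params.max_windows,
        )
        frac = h.aligned_fraction(len(frag.sequence))
        ident = h.identity
        ok = ident is not None and ident >= params.min_identity and frac >= params.min_fraction
        if ok:
            identities.append(ident)
            covered += len(frag.sequence)
        if return_hits:
            hits.append(FragmentHit(frag, h, ident, frac, ok))
    result = AniResult(
        query_id=query_id,
        target_id=target_id,
        ani=float(np.mean(identities)) if identities else None,
        coverage=covered / len(query),
        n_fragments=len(fragments),
        n_qualifying=len(identities),
    )
    return (result, hits) if return_hits else result


@dataclass
class AniMatrix:
    """Directional ANI/coverage for all ordered genome pairs."""

    ids: list[str]
    ani: pd.DataFrame       # directional, query rows x target columns; NaN undefined
    coverage: pd.DataFrame  # directional

    @property
    def sym_ani(self) -> pd.DataFrame:
        """Arithmetic mean of the two directions (diagonal 100)."""
        m = (self.ani + self.ani.T) / 2
        np.fill_diagonal(m.values, 100.0)
        return m

    @property
    def sym_coverage(self) -> pd.DataFrame:
        m = (self.coverage + self.coverage.T) / 2
        np.fill_diagonal(m.values, 1.0)
        return m

    def pair_table(self) -> pd.DataFrame:
        """Long-format table of all ordered pairs with defined ANI."""
        rows = []
        for q in self.ids:
            for t in self.ids:
                if q == t:
                    continue
                a = self.ani.loc[q, t]
                if not math.isnan(a):
                    rows.append({"query": q, "target": t, "ani": a,
                                 "coverage": self.coverage.loc[q, t]})
        return pd.DataFrame(rows, columns=["query", "target", "ani", "coverage"])


def compute_all(genomes: dict[str, str], params: AnibParams | None = None) -> AniMatrix:
    """All-versus-all directional ANIb."""
    params = params or AnibParams()
    ids = list(genomes)
    if len(ids) < 2:
        raise ValueError("need >= 2 genomes")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    ani = pd.DataFrame(np.full((len(ids),) * 2, np.nan), index=ids, columns=ids)
    cov = pd.DataFrame(np.zeros((len(ids),) * 2), index=ids, columns=ids)
    indexes = {}
    for t in ids:
        codes = _seq.encode(genomes[t])
        if len(codes) > params.exact_max_len:
            indexes[t] = TargetIndex(codes, k=params.seed_k)
    for q in ids:
        for t in ids:
            if q == t:
                ani.loc[q, t] = 100.0
                cov.loc[q, t] = 1.0
                continue
            r = compute_anib(genomes[q], genomes[t], params, q, t,
                             target_index=indexes.get(t))
            ani.loc[q, t] = np.nan if r.ani is None else r.ani
            cov.loc[q, t] = r.coverage
    return AniMatrix(ids=ids, ani=ani, coverage=cov)


@dataclass
class GroupPartition:
    """ANI-threshold groups, singletons, satellites and transfer candidates."""

    groups: list[list[str]]
    singletons: list[str]
    satellites: list[dict] = field(default_factory=list)   # genome, group_index, max_ani
    transfer_candidates: list[dict] = field(default_factory=list)
    cutoff: float = 92.0

    def label_of(self) -> dict[str, str]:
        labels = {}
        for k, grp in enumerate(self.groups):
            for g in grp:
                labels[g] = f"group{k}"
        for s in self.singletons:
            labels[s] = f"singleton:{s}"
        return labels

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "groups": self.groups,
            "singletons": self.singletons,
            "satellites": self.satellites,
            "transfer_candidates": self.transfer_candidates,
        }


def delineate_groups(matrix: AniMatrix, cutoff: float = 92.0,
                     min_group_coverage: float = 0.5) -> GroupPartition:
    """Connected components of the >= cutoff ANI graph.

    An edge additionally requires coverage >= ``min_group_coverage`` in both
    directions, so that a short near-identical transferred tract cannot fuse
    otherwise distinct groups.
    """
    sym = matrix.sym_ani
    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    for i, a in enumerate(matrix.ids):
        for b in matrix.ids[i + 1:]:
            s = sym.loc[a, b]
            if (not math.isnan(s) and s >= cutoff
                    and matrix.coverage.loc[a, b] >= min_group_coverage
                    and matrix.coverage.loc[b, a] >= min_group_coverage):
                g.add_edge(a, b)
    groups, singletons = [], []
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            groups.append(sorted(comp))
        else:
            singletons.extend(comp)
    groups.sort(key=lambda c: (-len(c), c[0]))
    return GroupPartition(groups=groups, singletons=sorted(singletons), cutoff=cutoff)


def find_satellites(matrix: AniMatrix, partition: GroupPartition,
                    lo: float = 85.0) -> list[dict]:
    """Genomes whose best ANI to a group sits in [lo, cutoff).

    The relation is per group: one genome can be a satellite of several
    groups.  Results are stored on the partition and returned.
    """
    sym = matrix.sym_ani
    sats = []
    for k, grp in enumerate(partition.groups):
        for s in matrix.ids:
            if s in grp:
                continue
            vals = [sym.loc[s, m] for m in grp if not math.isnan(sym.loc[s, m])]
            if not vals:
                continue
            best = max(vals)
            if lo <= best < partition.cutoff:
                sats.append({"genome": s, "group_index": k, "max_ani": float(best)})
    partition.satellites = sats
    return sats


def flag_transfer_candidates(matrix: AniMatrix, ani_min: float = 92.0,
                             cov_max: float = 0.2,
                             partition: GroupPartition | None = None) -> list[dict]:
    """Ordered pairs with near-identical DNA confined to a small genome
    portion (high ANI, low coverage): candidate horizontal transfers."""
    out = []
    for q in matrix.ids:
        for t in matrix.ids:
            if q == t:
                continue
            a = matrix.ani.loc[q, t]
            c = matrix.coverage.loc[q, t]
            if not math.isnan(a) and a >= ani_min and c <= cov_max:
                out.append({"query": q, "target": t, "ani": float(a),
                            "coverage": float(c)})
    if partition is not None:
        partition.transfer_candidates = out
    return out


def ani_report(matrix: AniMatrix, bin_edges: np.ndarray | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram of defined pairwise ANI values plus the ANI-vs-coverage table."""
    if bin_edges is None:
        bin_edges = np.arange(60.0, 100.5, 1.0)
    pairs = matrix.pair_table()
    counts, edges = np.histogram(pairs["ani"].to_numpy(), bins=bin_edges)
    hist = pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts})
    return hist, pairs
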