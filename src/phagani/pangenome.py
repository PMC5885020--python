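"""Ortholog family clustering under a 50 % AAI / 50 % coverage rule.

Protein pairs are aligned locally (BLOSUM62, affine gaps); two genes are
joined when amino-acid identity over the aligned columns reaches
``aai_min`` % and the alignment covers at least ``cov_min`` of both
proteins.  Families are connected components (single linkage; chaining is a
documented risk, acceptable at the scales handled here).  The core genome
is the set of families present in every genome; the single-copy core is
additionally exactly one member per genome and feeds the alignment-based
stages downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import biotite.sequence as bseq
import biotite.sequence.align as balign

from . import phylo

__all__ = [
    "GeneFamilySet",
    "protein_match",
    "cluster_families",
    "core_genome",
    "presence_absence_dendrogram",
    "group_content_diff",
]

_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()
_PROT_GAP = (-11, -1)  # open, extend (biotite convention: length-1 gap costs -11)


def protein_match(a: str, b: str) -> dict:
    """Best local alignment of two proteins (BLOSUM62, gap open -11 extend -1).

    Returns {'aai': % identical aligned columns, 'coverage_a', 'coverage_b'}.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    sa, sb = bseq.ProteinSequence(a), bseq.ProteinSequence(b)
    alns = balign.align_optimal(sa, sb, _BLOSUM62, gap_penalty=_PROT_GAP,
                                local=True, max_number=1)
    aln = alns[0]
    if aln.score <= 0 or len(aln.trace) == 0:
        return {"aai": 0.0, "coverage_a": 0.0, "coverage_b": 0.0, "score": aln.score}
    trace = aln.trace
    cols = trace.shape[0]
    both = (trace[:, 0] != -1) & (trace[:, 1] != -1)
    codes_a = np.asarray(sa.code)
    codes_b = np.asarray(sb.code)
    matches = int(np.sum(codes_a[trace[both, 0]] == codes_b[trace[both, 1]]))
    ia = trace[trace[:, 0] != -1, 0]
    ib = trace[trace[:, 1] != -1, 1]
    return {
        "aai": 100.0 * matches / cols,
        "coverage_a": (ia.max() - ia.min() + 1) / len(a),
        "coverage_b": (ib.max() - ib.min() + 1) / len(b),
        "score": aln.score,
    }


@dataclass
class GeneFamilySet:
    """Partition of all genes into ortholog families."""

    families: list[list[tuple[str, str]]]          # [(genome_id, gene_id), ...]
    genomes: list[str]
    counts: pd.DataFrame = field(default=None)     # genomes x families

    def __post_init__(self):
        if self.counts is None:
            mat = np.zeros((len(self.genomes), len(self.families)), dtype=int)
            gi = {g: i for i, g in enumerate(self.genomes)}
            for f, fam in enumerate(self.families):
                for genome_id, _ in fam:
                    mat[gi[genome_id], f] += 1
            self.counts = pd.DataFrame(
                mat, index=self.genomes,
                columns=[f"fam{f:04d}" for f in range(len(self.families))])

    @property
    def core(self) -> list[int]:
        return [f for f in range(len(self.families))
                if (self.counts.iloc[:, f] >= 1).all()]

    @property
    def single_copy_core(self) -> list[int]:
        return [f for f in range(len(self.families))
                if (self.counts.iloc[:, f] == 1).all()]

    def presence_absence(self) -> pd.DataFrame:
        return (self.counts >= 1).astype(int)


def _kmer_set(protein: str, k: int = 5) -> set[str]:
    return {protein[i:i + k] for i in range(len(protein) - k + 1)}


def cluster_families(
    genes: pd.DataFrame,
    aai_min: float = 50.0,
    cov_min: float = 0.5,
    prefilter_k: int = 5,
    prefilter_min_shared: int = 2,
    match_cache: dict | None = None,
) -> GeneFamilySet:
    """Cluster genes into families (single linkage over qualifying matches).

    `genes` is a long-format table with columns genome_id, gene_id, protein.
    A cheap shared-k-mer prefilter skips clearly unrelated pairs before the
    exact protein alignment; pairs sharing fewer than ``prefilter_min_shared``
    5-mers cannot realistically reach 50 % identity over half their length.
    Deterministic under genome input order (nodes sorted before clustering).
    """
    required = {"genome_id", "gene_id", "protein"}
    if not required.issubset(genes.columns):
        raise ValueError(f"genes table needs columns {sorted(required)}")
    recs = sorted(genes.itertuples(index=False),
                  key=lambda r: (r.genome_id, r.gene_id))
    genomes = sorted({r.genome_id for r in recs})
    graph = nx.Graph()
    keys = [(r.genome_id, r.gene_id) for r in recs]
    graph.add_nodes_from(keys)
    kmers = [_kmer_set(r.protein, prefilter_k) for r in recs]
    for i, j in itertools.combinations(range(len(recs)), 2):
        if len(kmers[i] & kmers[j]) < prefilter_min_shared:
            continue
        if match_cache is not None:
            ck = (keys[i], keys[j])
            m = match_cache.get(ck)
            if m is None:
                m = protein_match(recs[i].protein, recs[j].protein)
                match_cache[ck] = m
        else:
            m = protein_match(recs[i].protein, recs[j].protein)
        if m["aai"] >= aai_min and min(m["coverage_a"], m["coverage_b"]) >= cov_min:
            graph.add_edge(keys[i], keys[j])
    families = sorted((sorted(c) for c in nx.connected_components(graph)),
                      key=lambda fam: fam[0])
    return GeneFamilySet(families=families, genomes=genomes)


def core_genome(fams: GeneFamilySet) -> tuple[list[int], list[int]]:
    """(core family indices, single-copy-core family indices)."""
    if not fams.genomes:
        raise ValueError("no genomes in family set")
    return fams.core, fams.single_copy_core


def presence_absence_dendrogram(fams: GeneFamilySet) -> "phylo.Tree":
    """NJ dendrogram on simple-matching distances of family presence/absence."""
    pa = fams.presence_absence()
    n = len(fams.genomes)
    if n < 3:
        raise ValueError("need >= 3 genomes for a dendrogram")
    mat = pa.to_numpy()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(mat[i] != mat[j])
    dm = phylo.DistanceMatrix(ids=list(fams.genomes), matrix=d, model="simple-matching")
    return phylo.nj_tree(dm)


def group_content_diff(fams: GeneFamilySet, group_a: list[str],
                       group_b: list[str]) -> list[int]:
    """Families core to every member of A and absent from every member of B."""
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    missing = (set(group_a) | set(group_b)) - set(fams.genomes)
    if missing:
        raise ValueError(f"genomes not in family set: {sorted(missing)}")
    out = []
    for f in range(len(fams.families)):
        col = fams.counts.iloc[:, f]
        if (col.loc[group_a] >= 1).all() and (col.loc[group_b] == 0).all():
            out.append(f)
    return out
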