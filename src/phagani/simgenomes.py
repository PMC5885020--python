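"""Synthetic phage genome evolution with known group structure.

Emulates a sample of lytic dsDNA phage genomes: a few tight groups whose
members are a few percent diverged from each other, optional "satellite"
lineages at intermediate divergence from a group, deep divergence between
groups, shared single-copy genes, intragroup gene conversion, and rare long
intergroup transfer tracts.  Evolution is indel-free so positional homology
is exact and no multiple alignment step is needed downstream.

Substitutions follow an HKY model (configurable transition/transversion
ratio, default 2.0) applied along a star-within-group, groups-off-ancestor
topology; branch lengths get a +/-25 % uniform jitter so gene trees differ
only through recombination.  Recombination is copy-paste of a donor tract
over homologous recipient coordinates, tract lengths geometric with a
configured mean, truncated at genome ends.  Every event is logged and the
realized pairwise divergence is recorded by direct site counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seq

__all__ = [
    "GroupDesign",
    "SimConfig",
    "SimTruth",
    "SimConfigError",
    "generate_ancestor",
    "evolve_sample",
    "simulate",
    "write_sim",
    "read_genomes",
    "read_gene_table",
    "read_truth",
    "simulate_gene_alignment",
    "implant_tract",
    "gene_records",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
MIN_SPACER = 20


class SimConfigError(ValueError):
    """Raised when a simulation configuration is invalid or infeasible."""


@dataclass
class GroupDesign:
    """Design of one genome group (plus optional satellite lineages)."""

    name: str
    n_members: int
    within_divergence: float = 0.05
    stem_divergence: float = 0.13
    satellite_members: int = 0
    satellite_divergence_range: tuple[float, float] = (0.09, 0.15)
    recomb_rate: float = 0.0
    tract_mean_len: int = 1000
    intergroup_transfer_rate: float = 0.0
    intergroup_donor: str | None = None
    n_gene_deletions: int = 0

    def validate(self) -> None:
        if self.n_members < 1:
            raise SimConfigError(f"group {self.name}: n_members must be >= 1")
        for attr in ("within_divergence", "stem_divergence", "recomb_rate",
                     "intergroup_transfer_rate"):
            if getattr(self, attr) < 0:
                raise SimConfigError(f"group {self.name}: {attr} must be >= 0")
        lo, hi = self.satellite_divergence_range
        if self.satellite_members and not (self.within_divergence < lo <= hi):
            raise SimConfigError(
                f"group {self.name}: satellite divergence range must exceed "
                f"within-group divergence"
            )
        if self.tract_mean_len < 1:
            raise SimConfigError(f"group {self.name}: tract_mean_len must be >= 1")


@dataclass
class SimConfig:
    """Full simulation configuration; defaults describe the emulated sample."""

    genome_length: int = 50_000
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (300, 3000)
    gc_content: float = 0.5
    groups: list[GroupDesign] = field(default_factory=list)
    kappa: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length < 1:
            raise SimConfigError("genome_length must be positive")
        lo, hi = self.gene_length_range
        if not (3 <= lo <= hi):
            raise SimConfigError("gene_length_range must satisfy 3 <= lo <= hi")
        if not 0.0 <= self.gc_content <= 1.0:
            raise SimConfigError("gc_content must be in [0, 1]")
        min_len = self.n_genes * ((lo + 2) // 3 * 3 + 6) + (self.n_genes + 1) * MIN_SPACER
        if min_len > self.genome_length:
            raise SimConfigError(
                f"cannot pack {self.n_genes} genes of >= {lo} bp plus spacers "
                f"into {self.genome_length} bp"
            )
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise SimConfigError("group names must be unique")
        for g in self.groups:
            g.validate()
            if g.intergroup_donor is not None and g.intergroup_donor not in names:
                raise SimConfigError(f"unknown intergroup donor {g.intergroup_donor!r}")
        # within < satellite band < between-group divergence
        if len(self.groups) > 1:
            for g in self.groups:
                if not g.satellite_members:
                    continue
                min_between = min(
                    g.stem_divergence + h.stem_divergence
                    for h in self.groups if h is not g
                )
                if g.satellite_divergence_range[1] >= min_between:
                    raise SimConfigError(
                        f"group {g.name}: satellite divergence must stay below "
                        f"between-group divergence ({min_between:.3f})"
                    )


@dataclass
class SimTruth:
    """Ground truth of a simulated sample."""

    labels: dict[str, str]                 # genome_id -> group name or "<group>:satellite"
    divergence: pd.DataFrame               # realized p-distance, symmetric, 0 diagonal
    events: list[dict]                     # recipient, donor, start, end, type
    deleted_genes: dict[str, list[str]]    # group name -> gene ids removed

    def group_of(self, genome_id: str) -> str:
        return self.labels[genome_id].split(":")[0]

    def is_satellite(self, genome_id: str) -> bool:
        return self.labels[genome_id].endswith(":satellite")


# ---------------------------------------------------------------------------
# ancestor construction


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _random_orf(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random ORF of exactly `length` bp (multiple of 3): ATG ... TAA."""
    n_codon = length // 3 - 2
    body = []
    while len(body) < n_codon:
        codon = _seq.decode(_random_seq(rng, 3, gc))
        if codon not in STOP_CODONS:
            body.append(codon)
    return "ATG" + "".join(body) + "TAA"


def generate_ancestor(config: SimConfig) -> tuple[str, pd.DataFrame]:
    """Build the ancestral genome and its gene table.

    Genes are non-overlapping ORFs on either strand, lengths multiples of 3
    drawn from the configured range subject to the remaining-length budget,
    separated by random intergenic spacers of at least 20 bp.  Coordinates
    are 0-based half-open.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    lo3 = (lo + 2) // 3 * 3
    lo3 = max(lo3, 9)
    budget = config.genome_length - (config.n_genes + 1) * MIN_SPACER
    lengths = []
    for i in range(config.n_genes):
        remaining_min = (config.n_genes - 1 - i) * lo3
        cap = min(hi, budget - remaining_min)
        if cap < lo3:
            raise SimConfigError("gene packing infeasible")
        length = int(rng.integers(lo3 // 3, cap // 3 + 1)) * 3
        lengths.append(length)
        budget -= length
    # distribute the leftover over n_genes + 1 spacers
    spacers = np.full(config.n_genes + 1, MIN_SPACER, dtype=int)
    if budget > 0 and config.n_genes >= 0:
        extra = rng.multinomial(budget, np.full(len(spacers), 1 / len(spacers)))
        spacers += extra
    parts, rows = [], []
    pos = 0
    for i, length in enumerate(lengths):
        parts.append(_seq.decode(_random_seq(rng, spacers[i], config.gc_content)))
        pos += spacers[i]
        orf = _random_orf(rng, length, config.gc_content)
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(orf if strand == "+" else _seq.revcomp(orf))
        rows.append({"gene_id": f"g{i:04d}", "start": pos, "end": pos + length,
                     "strand": strand})
        pos += length
    parts.append(_seq.decode(_random_seq(rng, spacers[-1], config.gc_content)))
    genome = "".join(parts)
    assert len(genome) == config.genome_length
    table = pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand"])
    return genome, table


# ---------------------------------------------------------------------------
# evolution


def _hky_transition(freqs: np.ndarray, kappa: float, d: float) -> np.ndarray:
    """HKY transition matrix for branch length d (expected subs/site)."""
    ti_pairs = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = freqs[j] * (kappa if (i, j) in ti_pairs else 1.0)
        Q[i, i] = -Q[i].sum()
    scale = -(freqs * np.diag(Q)).sum()
    return expm(Q * (d / scale))


def _mutate(codes: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    u = rng.random(codes.shape[0])
    for s in range(4):
        idx = np.nonzero(codes == s)[0]
        if idx.size:
            out[idx] = np.searchsorted(np.cumsum(P[s]), u[idx], side="right").astype(np.uint8)
    np.minimum(out, 3, out=out)
    return out


def _geometric_tract(rng: np.random.Generator, mean_len: int) -> int:
    return int(rng.geometric(1.0 / mean_len))


def evolve_sample(
    ancestor: str,
    gene_table: pd.DataFrame,
    designs: list[GroupDesign],
    seed: int,
    kappa: float = 2.0,
    gc_content: float | None = None,
) -> tuple[dict[str, str], dict[str, pd.DataFrame], SimTruth]:
    """Evolve group members (and satellites) from the ancestor.

    Returns (genomes, per-genome gene tables, truth).  Member ids are
    ``<group>_<i>``; satellites ``<group>_sat<i>``.
    """
    for g in designs:
        g.validate()
    names = [g.name for g in designs]
    if len(set(names)) != len(names):
        raise SimConfigError("group names must be unique")
    rng = np.random.default_rng(seed)
    anc = _seq.encode(ancestor)
    L = anc.shape[0]
    counts = np.bincount(anc, minlength=4)[:4]
    freqs = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    gc = gc_content if gc_content is not None else _seq.gc_fraction(ancestor)

    genomes_codes: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    tables: dict[str, pd.DataFrame] = {}
    deleted: dict[str, list[str]] = {}
    members_of: dict[str, list[str]] = {}

    for g in designs:
        g_anc = _mutate(anc, _hky_transition(freqs, kappa, g.stem_divergence), rng)
        g_table = gene_table.copy()
        deleted[g.name] = []
        if g.n_gene_deletions:
            if g.n_gene_deletions > len(g_table):
                raise SimConfigError(f"group {g.name}: more deletions than genes")
            drop = rng.choice(len(g_table), size=g.n_gene_deletions, replace=False)
            for k in sorted(drop):
                row = g_table.iloc[k]
                g_anc[row.start:row.end] = _random_seq(rng, row.end - row.start, gc)
                deleted[g.name].append(row.gene_id)
            g_table = g_table.drop(g_table.index[sorted(drop)]).reset_index(drop=True)
        members_of[g.name] = []
        for i in range(g.n_members):
            gid = f"{g.name}_{i}"
            b = g.within_divergence / 2 * rng.uniform(0.75, 1.25)
            genomes_codes[gid] = _mutate(g_anc, _hky_transition(freqs, kappa, b), rng)
            labels[gid] = g.name
            tables[gid] = g_table.copy()
            members_of[g.name].append(gid)
        for i in range(g.satellite_members):
            gid = f"{g.name}_sat{i}"
            sat_d = rng.uniform(*g.satellite_divergence_range)
            b = max(sat_d - g.within_divergence / 2, 0.0)
            genomes_codes[gid] = _mutate(g_anc, _hky_transition(freqs, kappa, b), rng)
            labels[gid] = f"{g.name}:satellite"
            tables[gid] = g_table.copy()

    events: list[dict] = []
    for g in designs:
        members = members_of[g.name]
        for gid in members:
            if g.recomb_rate > 0 and len(members) > 1:
                for _ in range(rng.poisson(g.recomb_rate)):
                    donor = members[rng.integers(len(members) - 1)]
                    if donor == gid:
                        donor = members[-1]
                    start = int(rng.integers(L))
                    end = min(L, start + _geometric_tract(rng, g.tract_mean_len))
                    genomes_codes[gid][start:end] = genomes_codes[donor][start:end]
                    events.append({"recipient": gid, "donor": donor, "start": start,
                                   "end": end, "type": "intragroup"})
            if g.intergroup_transfer_rate > 0 and len(designs) > 1:
                for _ in range(rng.poisson(g.intergroup_transfer_rate)):
                    if g.intergroup_donor is not None:
                        dg = g.intergroup_donor
                    else:
                        others = [h.name for h in designs if h.name != g.name]
                        dg = others[rng.integers(len(others))]
                    donor = members_of[dg][rng.integers(len(members_of[dg]))]
                    start = int(rng.integers(L))
                    end = min(L, start + _geometric_tract(rng, g.tract_mean_len))
                    genomes_codes[gid][start:end] = genomes_codes[donor][start:end]
                    events.append({"recipient": gid, "donor": donor, "start": start,
                                   "end": end, "type": "intergroup"})

    ids = list(genomes_codes)
    mat = np.zeros((len(ids), len(ids)))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = float(np.mean(genomes_codes[ids[i]] != genomes_codes[ids[j]]))
            mat[i, j] = mat[j, i] = d
    truth = SimTruth(
        labels=labels,
        divergence=pd.DataFrame(mat, index=ids, columns=ids),
        events=events,
        deleted_genes=deleted,
    )
    genomes = {gid: _seq.decode(codes) for gid, codes in genomes_codes.items()}
    return genomes, tables, truth


def simulate(config: SimConfig) -> tuple[dict[str, str], dict[str, pd.DataFrame], SimTruth]:
    """generate_ancestor + evolve_sample under one seed."""
    ancestor, table = generate_ancestor(config)
    return evolve_sample(ancestor, table, config.groups, seed=config.seed + 1,
                         kappa=config.kappa, gc_content=config.gc_content)


# ---------------------------------------------------------------------------
# gene-scale simulation helpers (used by the recombination-test machinery)


def _coalescent_tree(n: int, rng: np.random.Generator):
    """Kingman coalescent topology; returns (children, heights, root) arrays.

    Nodes 0..n-1 are leaves; internal nodes follow.  children[k] = (a, b)
    for internal node k.
    """
    active = list(range(n))
    heights = [0.0] * n
    children = {}
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        children[nxt] = (a, b)
        heights.append(t)
        active = [x for m, x in enumerate(active) if m not in (i, j)] + [nxt]
        nxt += 1
    return children, heights, active[0]


def simulate_gene_alignment(
    n_taxa: int,
    length: int,
    diversity: float,
    seed: int,
    n_recomb: int = 0,
    tract_mean_len: int = 300,
    kappa: float = 2.0,
    gc: float = 0.5,
) -> tuple[list[str], np.ndarray]:
    """Simulate one gene alignment on a random coalescent genealogy.

    The tree is rescaled so the mean pairwise path length equals
    ``diversity`` (expected substitutions/site); HKY substitutions are then
    applied branch by branch.  ``n_recomb`` gene-conversion events are
    applied afterwards between contemporaneous sequences (donor tract
    copy-paste, geometric length), creating mosaic histories.

    Returns (taxa ids, uint8 code matrix of shape (n_taxa, length)).
    """
    rng = np.random.default_rng(seed)
    children, heights, root = _coalescent_tree(n_taxa, rng)
    # mean pairwise path length = 2 * mean coalescence height over pairs
    pair_h = []
    desc: dict[int, set[int]] = {i: {i} for i in range(n_taxa)}
    for k in sorted(children):
        a, b = children[k]
        for x in desc[a]:
            for y in desc[b]:
                pair_h.append(heights[k])
        desc[k] = desc[a] | desc[b]
    scale = diversity / (2 * np.mean(pair_h))
    freqs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    root_seq = rng.choice(4, size=length, p=freqs).astype(np.uint8)
    seqs: dict[int, np.ndarray] = {root: root_seq}
    for k in sorted(children, reverse=True):
        a, b = children[k]
        for child in (a, b):
            d = (heights[k] - heights[child]) * scale
            seqs[child] = _mutate(seqs[k], _hky_transition(freqs, kappa, d), rng)
    aln = np.vstack([seqs[i] for i in range(n_taxa)])
    for _ in range(n_recomb):
        r = int(rng.integers(n_taxa))
        d = int(rng.integers(n_taxa - 1))
        if d == r:
            d = n_taxa - 1
        start = int(rng.integers(length))
        end = min(length, start + _geometric_tract(rng, tract_mean_len))
        aln[r, start:end] = aln[d, start:end]
    ids = [f"t{i:02d}" for i in range(n_taxa)]
    return ids, aln


def mutate_fraction(seq: str, d: float, seed: int) -> str:
    """Substitute exactly round(d * L) distinct sites, each to a different
    base, so the realized p-distance to `seq` is exactly d (up to rounding)."""
    rng = np.random.default_rng(seed)
    codes = _seq.encode(seq)
    n = int(round(d * len(codes)))
    sites = rng.choice(len(codes), size=n, replace=False)
    shift = rng.integers(1, 4, size=n).astype(np.uint8)
    codes[sites] = (codes[sites] + shift) % 4
    return _seq.decode(codes)


def implant_tract(
    aln: np.ndarray,
    taxon: int,
    start: int,
    end: int,
    divergence: float,
    seed: int,
    kappa: float = 2.0,
) -> np.ndarray:
    """Overwrite aln[taxon, start:end] with an extra-diverged copy of itself,
    emulating import of a tract from a distant donor."""
    rng = np.random.default_rng(seed)
    out = aln.copy()
    counts = np.bincount(aln.ravel(), minlength=4)[:4]
    freqs = counts / counts.sum()
    P = _hky_transition(freqs, kappa, divergence)
    out[taxon, start:end] = _mutate(aln[taxon, start:end], P, rng)
    return out


# ---------------------------------------------------------------------------
# I/O


def write_sim(
    genomes: dict[str, str],
    truth: SimTruth,
    outdir: str | Path,
    gene_tables: dict[str, pd.DataFrame] | None = None,
) -> None:
    """Write FASTA per genome + combined, gene table TSV, and truth JSON."""
    if not genomes:
        raise ValueError("no genomes to write")
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    records = []
    for gid, seq in genomes.items():
        rec = SeqRecord(Seq(seq), id=gid, description="")
        SeqIO.write([rec], outdir / "genomes" / f"{gid}.fasta", "fasta")
        records.append(rec)
    SeqIO.write(records, outdir / "genomes.fasta", "fasta")
    if gene_tables is not None:
        rows = []
        for gid, table in gene_tables.items():
            t = table.copy()
            t.insert(0, "genome_id", gid)
            rows.append(t)
        pd.concat(rows, ignore_index=True).to_csv(outdir / "genes.tsv", sep="\t",
                                                  index=False)
    payload = {
        "labels": truth.labels,
        "divergence": {"ids": list(truth.divergence.index),
                       "matrix": truth.divergence.to_numpy().tolist()},
        "events": truth.events,
        "deleted_genes": truth.deleted_genes,
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1))


def read_genomes(path: str | Path) -> dict[str, str]:
    """Read a multi-FASTA file or a directory of FASTA files."""
    path = Path(path)
    files = sorted(path.glob("*.fasta")) + sorted(path.glob("*.fa")) if path.is_dir() else [path]
    genomes: dict[str, str] = {}
    for f in files:
        for rec in SeqIO.parse(str(f), "fasta"):
            if rec.id in genomes:
                raise ValueError(f"duplicate genome id {rec.id!r}")
            genomes[rec.id] = str(rec.seq).upper()
    if not genomes:
        raise ValueError(f"no FASTA records under {path}")
    return genomes


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "gene_id", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    return df


def read_truth(path: str | Path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    ids = payload["divergence"]["ids"]
    return SimTruth(
        labels=payload["labels"],
        divergence=pd.DataFrame(payload["divergence"]["matrix"], index=ids, columns=ids),
        events=payload["events"],
        deleted_genes=payload["deleted_genes"],
    )


def gene_records(
    genomes: dict[str, str],
    gene_tables: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Long-format gene table with nucleotide and protein sequences.

    Minus-strand genes are reverse-complemented before translation.
    """
    rows = []
    for gid, table in gene_tables.items():
        seq = genomes[gid]
        for row in table.itertuples():
            nt = seq[row.start:row.end]
            if row.strand == "-":
                nt = _seq.revcomp(nt)
            rows.append({"genome_id": gid, "gene_id": row.gene_id,
                         "start": row.start, "end": row.end, "strand": row.strand,
                         "nt": nt, "protein": _seq.translate(nt)})
    return pd.DataFrame(rows)
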