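"""End-to-end orchestration: simulate-or-load genomes, ANI and group
delineation, per-group pangenome + recombination statistics, progressive
congruence, consensus splits, and a consolidated report.

All randomness derives from one root seed: stage k of the run uses
``(root_seed * 1009 + k) % 2**31`` so any stage can be re-run in isolation.
Re-running the same configuration and seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import anib, congruence, pangenome, recomb, simgenomes
from .phylo import Alignment, nj_tree, tn93_distance

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run", "compare_to_truth"]


def _stage_seed(root: int, k: int) -> int:
    return (root * 1009 + k) % (2**31)


@dataclass
class PipelineConfig:
    """Validated configuration of a full run."""

    mode: str = "simulate"                     # "simulate" | "fasta"
    sim: simgenomes.SimConfig = None
    fasta_path: str | None = None
    gene_table_path: str | None = None
    outdir: str = "phagani_out"
    seed: int = 0
    # anib
    fragment_length: int = 500
    cutoff: float = 92.0
    satellite_lo: float = 85.0
    min_group_coverage: float = 0.5
    transfer_ani_min: float = 92.0
    transfer_cov_max: float = 0.2
    # pangenome
    aai_min: float = 50.0
    cov_min: float = 0.5
    # recombination / congruence
    min_phi_group_size: int = 4
    phi_window: int = 100
    phi_permutations: int = 200
    phi_alpha: float = 0.05
    cadm_permutations: int = 199
    min_split_freq: float = 0.1
    min_scan_len: int = 1000

    def validate(self) -> None:
        if self.mode not in ("simulate", "fasta"):
            raise ValueError("mode must be 'simulate' or 'fasta'")
        if self.mode == "simulate":
            if self.sim is None:
                raise ValueError("simulate mode needs a sim config")
            self.sim.validate()
        elif not self.fasta_path:
            raise ValueError("fasta mode needs fasta_path")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    genomes: dict
    matrix: anib.AniMatrix
    partition: anib.GroupPartition
    group_reports: pd.DataFrame
    phi_table: pd.DataFrame
    tract_table: pd.DataFrame
    clonal_frames: dict
    progressive: congruence.ProgressiveResult | None
    splits: congruence.SplitSet | None
    truth: simgenomes.SimTruth | None
    outdir: Path


def _group_gene_alignments(genes: pd.DataFrame, sample: list[str],
                           match_cache: dict | None = None) -> dict[str, Alignment]:
    """Per-family alignments of single-copy genes shared by `sample`.

    Clusters the sample's proteins into families and stacks the nucleotide
    sequences of single-copy-core families (equal lengths required; the
    simulator is indel-free, and pre-aligned input is expected otherwise).
    """
    sub = genes[genes.genome_id.isin(sample)]
    fams = pangenome.cluster_families(sub[["genome_id", "gene_id", "protein"]],
                                      match_cache=match_cache)
    out = {}
    by_key = {(r.genome_id, r.gene_id): r.nt for r in sub.itertuples()}
    for f in fams.single_copy_core:
        members = fams.families[f]
        seqs = {genome_id: by_key[(genome_id, gene_id)] for genome_id, gene_id in members}
        if len({len(s) for s in seqs.values()}) != 1:
            logger.warning("family %d skipped: unequal gene lengths (unaligned?)", f)
            continue
        ordered = {g: seqs[g] for g in sample}
        out[f"fam{f:04d}"] = Alignment.from_strings(ordered)
    return out


def _analyze_group(
    label: str,
    members: list[str],
    genes: pd.DataFrame,
    cfg: PipelineConfig,
    seed: int,
    match_cache: dict | None = None,
) -> tuple[dict, pd.DataFrame, pd.DataFrame, recomb.ClonalFrameReport | None]:
    """Table-1-shaped statistics for one group."""
    sub = genes[genes.genome_id.isin(members)]
    fams = pangenome.cluster_families(sub[["genome_id", "gene_id", "protein"]],
                                      aai_min=cfg.aai_min, cov_min=cfg.cov_min,
                                      match_cache=match_cache)
    core, scc = pangenome.core_genome(fams)
    alns = _group_gene_alignments(genes, members, match_cache)
    phi_rows = []
    n_sig = n_testable = 0
    for k, (gene_id, aln) in enumerate(sorted(alns.items())):
        res = recomb.phi_test(aln, w=cfg.phi_window, n_perm=cfg.phi_permutations,
                              seed=_stage_seed(seed, k), gene_id=gene_id)
        phi_rows.append({"group": label, "gene": gene_id,
                         "n_informative": res.n_informative,
                         "phi": res.phi, "p": res.p_value,
                         "testable": res.testable})
        if res.testable:
            n_testable += 1
            if res.p_value < cfg.phi_alpha:
                n_sig += 1
    phi_df = pd.DataFrame(phi_rows, columns=["group", "gene", "n_informative",
                                             "phi", "p", "testable"])
    # clonal frame over the concatenated single-copy core
    tract_rows = []
    frame_report = None
    if alns:
        concat = np.hstack([alns[g].matrix for g in sorted(alns)])
        aln_cat = Alignment(list(next(iter(alns.values())).ids), concat)
        if aln_cat.n_columns >= cfg.min_scan_len and len(members) >= 4:
            tracts, tree = recomb.detect_recombinant_tracts(
                aln_cat, min_scan_len=cfg.min_scan_len)
            frame_report = recomb.clonal_frame(tracts, aln_cat.n_columns, tree)
            for t in tracts:
                tract_rows.append({"group": label, "branch": t.branch,
                                   "start": t.start, "end": t.end,
                                   "snps": t.n_snps, "p": t.p_value})
    tract_df = pd.DataFrame(tract_rows, columns=["group", "branch", "start",
                                                 "end", "snps", "p"])
    # CADM over the group's core genes
    W = p_val = float("nan")
    if len(alns) >= 2 and len(members) >= 4:
        try:
            dms = congruence.gene_distance_set(alns, members)
            if dms.p >= 2:
                res = congruence.cadm(dms, n_perm=cfg.cadm_permutations,
                                      seed=_stage_seed(seed, 500), mantel=False)
                W, p_val = res.W, res.p_value
        except ValueError as exc:
            logger.warning("group %s CADM skipped: %s", label, exc)
    lo, hi = frame_report.range if frame_report else (float("nan"), float("nan"))
    row = {"group": label, "n_phages": len(members),
           "n_families": len(fams.families), "n_core": len(core),
           "n_single_copy_core": len(scc), "phi_testable": n_testable,
           "phi_significant": n_sig, "clonal_frame_min": lo,
           "clonal_frame_max": hi, "cadm_W": W, "cadm_p": p_val}
    return row, phi_df, tract_df, frame_report


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def emit(name: str, text: str) -> None:
        (outdir / name).write_text(text)
        manifest.append(name)

    emit("config.yaml", yaml.safe_dump(config.to_dict(), sort_keys=True))

    stage = "input"
    try:
        truth = None
        gene_tables = None
        if config.mode == "simulate":
            genomes, gene_tables, truth = simgenomes.simulate(config.sim)
            simgenomes.write_sim(genomes, truth, outdir / "sim", gene_tables)
            manifest.append("sim/")
        else:
            genomes = simgenomes.read_genomes(config.fasta_path)
            if len(genomes) < 2:
                raise ValueError("need >= 2 genomes")
            if config.gene_table_path:
                gt = simgenomes.read_gene_table(config.gene_table_path)
                gene_tables = {g: df.drop(columns="genome_id")
                               for g, df in gt.groupby("genome_id")}

        stage = "anib"
        params = anib.AnibParams(fragment_length=config.fragment_length)
        matrix = anib.compute_all(genomes, params)
        hist, pairs = anib.ani_report(matrix)
        emit("ani_pairs.tsv", pairs.to_csv(sep="\t", index=False))
        emit("ani_matrix.tsv", matrix.sym_ani.to_csv(sep="\t"))
        emit("ani_hist.tsv", hist.to_csv(sep="\t", index=False))

        stage = "groups"
        partition = anib.delineate_groups(matrix, cutoff=config.cutoff,
                                          min_group_coverage=config.min_group_coverage)
        anib.find_satellites(matrix, partition, lo=config.satellite_lo)
        anib.flag_transfer_candidates(matrix, ani_min=config.transfer_ani_min,
                                      cov_max=config.transfer_cov_max,
                                      partition=partition)
        emit("partition.json", json.dumps(partition.to_dict(), indent=1))

        stage = "pangenome/recombination"
        genes = simgenomes.gene_records(genomes, gene_tables) if gene_tables else None
        match_cache: dict = {}
        group_rows, phi_parts, tract_parts, frames = [], [], [], {}
        if genes is not None:
            for k, members in enumerate(partition.groups):
                label = f"group{k}"
                if len(members) < config.min_phi_group_size:
                    group_rows.append({"group": label, "n_phages": len(members),
                                       "n_families": float("nan"),
                                       "n_core": float("nan"),
                                       "n_single_copy_core": float("nan"),
                                       "phi_testable": 0, "phi_significant": 0,
                                       "clonal_frame_min": float("nan"),
                                       "clonal_frame_max": float("nan"),
                                       "cadm_W": float("nan"),
                                       "cadm_p": float("nan")})
                    continue
                row, phi_df, tract_df, frame = _analyze_group(
                    label, members, genes, config,
                    _stage_seed(config.seed, k + 1), match_cache)
                group_rows.append(row)
                if not phi_df.empty:
                    phi_parts.append(phi_df)
                if not tract_df.empty:
                    tract_parts.append(tract_df)
                if frame is not None:
                    frames[label] = frame
        group_reports = pd.DataFrame(group_rows)
        phi_cols = ["group", "gene", "n_informative", "phi", "p", "testable"]
        tract_cols = ["group", "branch", "start", "end", "snps", "p"]
        phi_table = (pd.DataFrame(
            [r for df in phi_parts for r in df.to_dict("records")],
            columns=phi_cols) if phi_parts else pd.DataFrame(columns=phi_cols))
        tract_table = (pd.DataFrame(
            [r for df in tract_parts for r in df.to_dict("records")],
            columns=tract_cols) if tract_parts else pd.DataFrame(columns=tract_cols))
        emit("groups_report.tsv", group_reports.to_csv(sep="\t", index=False))
        emit("phi_per_gene.tsv", phi_table.to_csv(sep="\t", index=False))
        emit("tracts.tsv", tract_table.to_csv(sep="\t", index=False))
        frame_rows = [{"group": g, "branch": b, "clonal_frame": f}
                      for g, rep in sorted(frames.items())
                      for b, f in sorted(rep.fractions.items())]
        emit("clonal_frame.tsv",
             pd.DataFrame(frame_rows, columns=["group", "branch", "clonal_frame"])
             .to_csv(sep="\t", index=False))

        stage = "congruence"
        progressive = splits = None
        if genes is not None and partition.groups:
            progressive, splits = _progressive_and_splits(
                config, matrix, partition, genes, match_cache)
            if progressive is not None:
                emit("progressive_cadm.tsv",
                     progressive.to_dataframe().to_csv(sep="\t", index=False))
            if splits is not None:
                emit("splits.nex", splits.to_nexus())

        stage = "truth comparison"
        if truth is not None:
            metrics = compare_to_truth(partition, matrix, truth)
            emit("truth_metrics.json", json.dumps(metrics, indent=1))

        emit("MANIFEST.txt", "\n".join(["status: complete"] + manifest) + "\n")
    except Exception:
        (outdir / "MANIFEST.txt").write_text(
            "\n".join([f"status: INCOMPLETE (failed at stage: {stage})"] + manifest) + "\n")
        logger.error("pipeline failed at stage %s", stage)
        raise

    return PipelineResult(config=config, genomes=genomes, matrix=matrix,
                          partition=partition, group_reports=group_reports,
                          phi_table=phi_table, tract_table=tract_table,
                          clonal_frames=frames, progressive=progressive,
                          splits=splits, truth=truth, outdir=outdir)


def _progressive_and_splits(config, matrix, partition, genes, match_cache=None):
    """Base group -> +its satellites -> +nearest other group, then consensus
    splits of the final sample's gene trees."""
    base_idx = 0
    base = partition.groups[base_idx]
    additions: list[tuple[str, list[str]]] = []
    sats = [s["genome"] for s in partition.satellites
            if s["group_index"] == base_idx]
    if sats:
        additions.append(("+satellites", sorted(sats)))
    if len(partition.groups) > 1:
        sym = matrix.sym_ani
        best = max(range(1, len(partition.groups)),
                   key=lambda k: max(sym.loc[a, b]
                                     for a in base for b in partition.groups[k]))
        additions.append((f"+group{best}", partition.groups[best]))

    def alns_for(sample):
        return _group_gene_alignments(genes, sample, match_cache)

    progressive = congruence.progressive_cadm(
        base, additions, alns_for, n_perm=config.cadm_permutations,
        seed=_stage_seed(config.seed, 900))
    splits = None
    final_sample = progressive.steps[-1]["taxa"]
    alns = alns_for(final_sample)
    trees = []
    for gene_id in sorted(alns):
        try:
            dm = tn93_distance(alns[gene_id])
            if not dm.has_infinite:
                trees.append(nj_tree(dm))
        except ValueError:
            continue
    if len(trees) >= 2:
        splits = congruence.consensus_splits(trees, min_freq=config.min_split_freq)
    return progressive, splits


def compare_to_truth(partition: anib.GroupPartition, matrix: anib.AniMatrix,
                     truth: simgenomes.SimTruth) -> dict:
    """Truth-vs-inferred metrics for a simulated run.

    Groups: adjusted Rand index between the inferred partition (satellite
    genomes count as their own singleton clusters) and the designed one.
    ANI: per-pair absolute error of symmetrized ANI against 100 * (1 - d)
    with d the realized site-count divergence (only pairs with defined ANI).
    """
    ids = matrix.ids
    labels = partition.label_of()
    pred = [labels[g] for g in ids]
    true = [g if truth.is_satellite(g) else truth.group_of(g) for g in ids]
    ari = float(adjusted_rand_score(true, pred))
    errors = []
    sym = matrix.sym_ani
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            s = sym.loc[a, b]
            if not np.isnan(s):
                d = truth.divergence.loc[a, b]
                errors.append(abs(s - 100 * (1 - d)))
    return {
        "ari": ari,
        "n_ani_pairs": len(errors),
        "ani_mean_abs_error": float(np.mean(errors)) if errors else None,
        "ani_max_abs_error": float(np.max(errors)) if errors else None,
        "n_true_groups": len({truth.group_of(g) for g in ids
                              if not truth.is_satellite(g)}),
        "n_inferred_groups": len(partition.groups),
        "n_satellites_inferred": len({s["genome"] for s in partition.satellites}),
    }
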