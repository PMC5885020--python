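# Methods

This note documents the models, estimators and numerical choices behind
phagani, in the spirit of a statistical methods appendix: what each stage
assumes, which knobs matter, and what the synthetic data do and do not
establish about behaviour on real genomes.

## Synthetic genome evolution (`simgenomes`)

The simulator emulates the statistical structure of a sample of lytic
dsDNA phage genomes: a handful of tight genome groups, optional
"satellite" lineages at intermediate divergence from one group, deep
divergence between groups, a shared single-copy gene complement with
occasional group-specific gene losses, gene-conversion recombination
within groups, and rare long transfer tracts between groups.

* **Ancestor.** A random genome at the configured GC content carrying
  non-overlapping ORFs (ATG … TAA, lengths multiples of 3) on both
  strands, separated by ≥ 20 bp spacers.  Gene lengths are drawn from the
  configured range subject to the remaining-length budget, so tight
  configurations bias genes toward the short end; infeasible packings
  raise a configuration error instead of silently truncating.
* **Topology.** Groups hang off the ancestor by their `stem_divergence`;
  members radiate star-like from the group ancestor at
  `within_divergence / 2` per branch with ±25 % uniform jitter.  The star
  shape is deliberate: without recombination, all gene trees in a group
  share one (nearly unresolved) history, so any consistent intragroup
  incongruence that the congruence stage finds is attributable to
  recombination, not to deep clonal structure.  Satellites branch from
  the group ancestor at a divergence drawn from
  `satellite_divergence_range` (default 0.09–0.15 substitutions/site).
* **Substitutions.** HKY with transition/transversion ratio κ = 2.0
  (configurable) and base frequencies taken from the ancestor; each
  branch applies the matrix exponential of the rate matrix scaled to its
  expected substitutions/site.  κ = 2 keeps the two transition classes
  distinct so the TN93 estimator downstream has something non-trivial to
  recover.  Evolution is indel-free by default, which makes positional
  homology exact and removes any need for a multiple-alignment step;
  consequences for realism are listed under Limitations.
* **Recombination.** After substitution, each member lineage receives a
  Poisson number of gene-conversion events (`recomb_rate` expected events
  per lineage): a donor is drawn uniformly from the same group, a tract
  start uniformly on the genome, a geometric tract length with mean
  `tract_mean_len`, truncated at the genome end, and the donor sequence
  is copied over the homologous recipient coordinates.  Intergroup
  transfers work identically with the donor drawn from a named (or
  random) other group.  Events are applied in a fixed deterministic
  order; donors are the current (possibly already recombined) sequences.
  Every event is logged with recipient, donor, half-open coordinates and
  type.
* **Gene loss.** Group-specific deletions replace the gene's span in the
  group ancestor with random sequence at genome GC and drop the gene from
  the group's annotation.  Sequence length is preserved (the simulator is
  indel-free), which approximates loss-with-replacement rather than
  contraction; for gene-content analyses only the annotation matters.
* **Ground truth.** Realized pairwise divergence is recorded by direct
  site counting (p-distance), so tests compare estimators against what
  actually happened, not against the nominal design value (multiple hits
  make the two differ at higher divergence).
* **Gene-scale simulator.** `simulate_gene_alignment` provides a separate
  generator for single-gene alignments on a random Kingman coalescent
  genealogy, rescaled so the mean pairwise path length equals the target
  diversity, with the same HKY machinery and optional post-hoc gene
  conversion among the tips.  The coalescent topology (unlike the star)
  yields parsimony-informative sites without recombination, which is what
  the PHI calibration experiments need.  `implant_tract` over-diverges a
  chosen segment of one taxon to emulate an import from outside the
  sample.  `mutate_fraction` substitutes an exact count of sites for
  identity-recovery checks where the realized p-distance must equal the
  nominal one.

## Fragment ANI (`align`, `anib`)

* **Scores.** blastn-like: match +1, mismatch −2, gap open −5, extend −2,
  with the convention that a gap of length L costs `open + (L−1)·extend`.
  Thresholds for a qualifying hit — identity ≥ 30 % over ≥ 70 % of the
  fragment — follow the published blast-fragment ANI definition; both are
  exposed in `AnibParams`.  The trailing genome fragment is kept iff at
  least half the fragment length (exposed as well).
* **Search.** For targets ≤ 5 kb the full affine Smith–Waterman matrix is
  computed, so the score is exactly optimal (this is also the contract the
  aligner-oracle tests enforce against an independent implementation).
  Larger targets are searched in windows (±64 bp) around clusters of
  exact 11-mer seed diagonals, keeping the top 2 clusters per strand by
  seed count; within each window the DP is exact.  A score-only rolling
  pass ranks the windows; the winning window is re-solved for the
  alignment path.  If a gapless diagonal segment attains the affine
  optimum, it is reported directly (it *is* an optimal local alignment);
  otherwise a full traceback runs.  Among co-optimal alignments the
  reported identity may depend on which optimum is found; scores never do.
* **Directionality.** ANI(q→t) and ANI(t→q) are both computed; clustering
  uses the arithmetic mean (symmetrized) matrix.  The unweighted mean of
  qualifying-hit identities is used (fragments have uniform length, so
  length weighting would change nothing material).
* **Groups.** Edges require symmetrized ANI ≥ 92 % *and* coverage ≥ 0.5
  in both directions; groups are connected components of size ≥ 2.  The
  coverage condition prevents a short, recently transferred tract
  (high ANI, low coverage) from fusing two otherwise distinct groups.
  Chaining is possible by construction and documented behaviour.
  Satellites: a genome whose best symmetrized ANI to a group falls in
  [85, 92) is a satellite *of that group*; the relation is per group.
  Transfer candidates: ordered pairs with ANI ≥ 92 % and coverage ≤ 0.2.

## Pangenome (`pangenome`)

Gene families are connected components of the graph joining protein pairs
with local-alignment amino-acid identity ≥ 50 % covering ≥ 50 % of *both*
proteins (BLOSUM62, gap open −11 extend −1, via biotite).  The
both-proteins reading of the coverage rule is a choice (the rule is often
stated ambiguously); it is exposed as `cov_min` applied to
`min(coverage_a, coverage_b)`.  A shared-5-mer prefilter (≥ 2 shared)
skips pairs that cannot plausibly reach the threshold; at these identity
levels true positives share many 5-mers, so the filter does not affect
results, only runtime.  Single-linkage chaining is a documented risk,
acceptable at the scales handled here.  Core = families present in every
genome; single-copy core = exactly once per genome (these feed all
alignment-based stages).  The presence/absence dendrogram uses
simple-matching distances and the package's own NJ.

## Phylogenetic primitives (`phylo`)

* **TN93.** Pairwise deletion (columns with N or gaps in either sequence
  are dropped for that pair; a complete-deletion alternative would be a
  one-line change in the caller).  Base frequencies per pair are the mean
  of the two sequences' frequencies over comparable columns.  Pairs whose
  log arguments fall to ≤ 0 are flagged infinite (saturated); genes
  containing such pairs are dropped from congruence analyses with a
  logged warning.  Pairs need ≥ 50 comparable columns or the offending
  pair is named in the error.
* **NJ.** Saitou–Nei with the standard Q criterion; ties broken by the
  lexicographically smallest pair of cluster representatives, so the
  output is independent of input order.  Negative branch lengths are
  clamped to 0 with the deficit moved to the sister branch (path lengths
  preserved).  Newick output is canonical (children sorted by smallest
  contained leaf), making tree equality a string comparison.
* **Fitch.** The tree is midpoint-rooted (so ambiguous assignments
  resolve toward the centre), states are propagated bottom-up as bitmasks
  over all columns at once, and the top-down pass keeps the parent state
  when permitted, else the smallest compatible state.  Total assigned
  changes equal the parsimony score (verified against exhaustive
  enumeration on ≤ 6 taxa).  N/gap leaves are unconstrained.

## Recombination detection (`recomb`)

* **PHI.** Informative sites have ≥ 2 states in ≥ 2 taxa each (missing
  ignored per column).  Refined incompatibility of a site pair is the
  cyclomatic number E − V + C of the partition intersection graph over
  taxa complete at both sites — the minimum extra mutations beyond each
  site's parsimony floor on any single tree.  The statistic is the mean
  over unordered informative pairs within w = 100 alignment positions
  (PhiPack's windowing convention).  The null permutes the positions of
  the informative sites while keeping their state vectors; the one-tailed
  p counts permutations with mean ≤ observed, since recombination makes
  incompatibility grow with distance and therefore depresses the
  near-pair mean.  A permutation p (default 200–1000 draws) was preferred
  over the analytic normal approximation: exact at these sizes and
  reproducible given a seed.  Fewer than two informative sites (or no
  pair ever inside the window) yields an explicitly untestable result —
  the test is conservative at low diversity by nature.
* **Clonal-frame scan.** A deliberately simple SNP-density iteration:
  (1) NJ on TN93 distances of the current alignment; (2) Fitch assignment
  of variant columns to branches; (3) per branch, maximal runs of SNPs
  with inter-SNP gaps ≤ 100 columns and ≥ 3 SNPs are candidate tracts.  A
  run of k SNPs spanning ℓ columns is scored by the binomial tail
  P(X ≥ k−2) for X ~ Bin(ℓ, branch SNP density): the two boundary SNPs
  are discounted because they delimit the window, and the density
  includes the run itself, which keeps the test conservative for giant
  runs.  Because ℓ is data-chosen, the significance threshold is a
  scan-statistic Bonferroni — α divided by the number of possible
  placements of a window of that span (≥ the number of runs tested).
  Runs spanning more than half the alignment are the branch's own
  substitution background and are never called.  (4) Accepted tracts are
  masked to missing in the descendant taxa of their branch only, and the
  procedure repeats (≤ 5 rounds).  Clonal frame per branch = 1 − masked
  fraction; the report gives the min–max range over branches, terminal
  and internal alike.
* **Calibration trade-off.** With the default run-gap of 100 columns the
  scan is calibrated at backgrounds of roughly ≤ 1–2 % branch divergence
  (≈ 94 % of clonal 10-taxon 30 kb samples yield zero tracts).  When the
  mean SNP spacing approaches the gap threshold (≳ 4–5 % divergence)
  whole branches collapse into few giant runs and sensitivity drops to
  near zero while occasional false merges appear; detecting tracts inside
  such dense backgrounds would need a density-adaptive gap, which is out
  of scope here and noted as a limitation.

## Congruence (`congruence`)

* **CADM.** Each gene's TN93 matrix is unfolded (upper triangle),
  mid-ranked within the matrix, and Kendall's W computed with the
  standard tie correction: W = 12S / (p²(m³−m) − pΣT).  Friedman's
  χ² = p(m−1)W.  The global null permutes every matrix's taxa labels
  independently (no reference matrix) and counts W at least as large;
  identical matrices give W = 1, rank-reversed pairs give W = 0, and
  r̄ = (pW−1)/(p−1) ties W to the mean pairwise Spearman correlation
  (holds to 1e−9 without ties; asserted in tests).
* **Mantel battery.** Spearman correlation of the unfolded ranks of each
  matrix pair, one-tailed (positive association), with taxa-label
  permutations; the same permutation draw is applied across all pairs in
  a replicate, which is valid under the null and lets the battery be
  computed as one matrix product per draw.  No multiple-testing
  correction is applied to the battery — the reported quantity is the raw
  fraction of p < 0.05, which is itself the figure of interest.
* **Progressive procedure.** Starting from a group, then adding its
  satellites, then the nearest other group, the shared single-copy gene
  set is *recomputed per step* (a family must be single-copy in every
  genome of the current sample), TN93 matrices rebuilt, and CADM re-run.
  Expected pattern on the synthetic designs: W and the significant-Mantel
  fraction increase strictly along the steps, because the added
  divergence injects a common tree signal into every gene.
* **Consensus splits.** Nontrivial bipartitions pooled over per-gene NJ
  trees, weight = occurrence frequency, retained at weight ≥ 0.1 by
  default (exposed; the threshold used by interactive split-network tools
  is not standardized).  Export is a SplitsTree-compatible NEXUS splits
  block; drawing is out of scope.

## Pipeline (`pipeline`)

One root seed drives everything; stage k derives
`(root·1009 + k) mod 2³¹`, so stages can be re-run in isolation and a
full run is byte-reproducible (the config echo differs only by the output
path).  Groups with fewer than 4 members skip PHI/CADM/clonal-frame
(untestable at that size); the per-group report row mirrors the familiar
table shape: phage count, family count, core and single-copy-core counts,
PHI-significant gene count (raw p < 0.05 by default), clonal-frame range,
CADM W and p.  Any stage failure aborts the run with the stage named in
the MANIFEST; partial outputs are kept.

## Problem sizes

The shipped tests and the acceptance script run on deliberately compact
designs chosen to exercise every code path with comfortable statistical
margins: 50 kb pairs for identity recovery; a 15 kb, 18-genome,
three-group + two-satellite sample for delineation; 15-taxon 1.5 kb genes
(200 replicates) for PHI calibration and power; 10-taxon 30 kb cores
(50 replicates) for the clonal-frame null; 8-taxon matrices
(500 replicates) for CADM calibration; 12 kb 9–13-genome samples for the
progressive and determinism runs.

## What passing the synthetic suite does and does not show

The simulator provides exact positional homology, uniform substitution
rates, no indels, no rearrangements, no mosaicism beyond the modelled
conversion events, and annotation that is correct by construction.
Passing therefore establishes correctness of the estimators and
detectors under their own assumptions (and exact agreement with
independent oracles where those exist: Smith–Waterman scores, TN93
closed form, exhaustive parsimony, direct rank arithmetic).  It does not
establish robustness to indel-rich alignments, assembly or annotation
error, repeat-induced spurious seeding, or gene families under
domain-level shuffling — on real data the mafft-style alignment step,
which this package deliberately accepts as input rather than performing,
is where several of those risks live.

## Known limitations

* The clonal-frame scan loses calibration and sensitivity at high branch
  SNP densities (see above); its acceptance surface is tract recovery on
  ~1 % backgrounds.
* Single-linkage families can chain distinct domains shared between
  otherwise unrelated proteins.
* PHI is conservative for low-diversity or small samples (few informative
  sites), and whole-gene conversion between close relatives leaves no
  intragene signal at all — such genes are counted as non-significant,
  not as evidence against recombination.
* The ANI engine reports any one optimal local alignment; identity on
  co-optimal paths may differ in the last decimal.
* Group delineation by connected components inherits the usual
  single-linkage caveat: one borderline pair can bridge two clusters.
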