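# Methods

## Coordinates and overlap

All intervals are 0-based half-open (BED convention); 1-based dialects are
converted at the parser boundary. Overlap requires ≥ 1 shared base: touching
intervals (`[100,200)` / `[200,300)`) neither overlap nor merge. Strand is
carried on genes but ignored by all overlap logic — CTCF anchors, ATAC peaks
and LD blocks are strandless. Anchor padding before overlap tests is
exposed (`anchor_pad`, default 0 bp) because upstream loop callers differ in
how tightly they trim anchors.

## Consensus peaks

Candidate regions are the merged union of all samples' peaks; a candidate's
support is the number of distinct samples with ≥ 1 overlapping base, and it
is kept when `support / n_samples ≥ threshold` (default 0.6) under exact
rational comparison, so 3 of 5 passes despite 0.6 having no exact float
representation. Support is counted per merged region, not per base: this
matches the usual consensus semantics of differential-binding tools and
gives stable region boundaries. When overlaps chain (A–B, B–C, no A–C) the
chain merges first and support is counted once per sample against the whole
merged region; the test suite compares against a per-base oracle on
fixtures where the two definitions coincide. An optional pre-filter keeps
each sample's top-N peaks by score (descending; deterministic coordinate
tie-break) for inputs where the caller emits an unbounded peak list.

## Loop filter and hubs

A loop survives when its read support is ≥ `min_reads` (default 2) and both
anchors overlap a consensus CTCF peak. Surviving anchors are merged into
disjoint nodes; each loop becomes an edge (a self-edge when both anchors
merged together). A hub is the full connected component reachable from a
risk LD block — the graph formalization of "take every region the block
loops to, then every region those loop to, until closure". Components are
computed with networkx; the tests verify equality with a brute-force
transitive closure over the per-base overlap relation on randomized
instances. LD blocks overlapping no node are reported inactive. Blocks
sharing a component merge into one hub with several seed blocks.
Inter-chromosomal loops are accepted (and logged): nothing in the model
forbids a component spanning chromosomes.

Hub membership: a gene joins when its promoter window (TSS ± 2 kb by
default; the field's common promoter heuristic, configurable) overlaps an
anchor region or a seed block; an ATAC consensus region joins when it
overlaps an anchor region or a seed block. Seed-block membership matters:
elements inside the risk block itself must be scoreable even when they sit
between loop anchors.

## Normalization and the per-gene model

log-CPM uses the prior-protected, library-size-corrected form

    log2( (count + c) / (library_size + 2c) * 1e6 ),   c = 0.5 by default,

which is finite at zero and strictly monotone in the count. Library sizes
default to the column sums of the supplied matrix; genome-wide library
sizes can be supplied explicitly when the matrix is a hub-level slice of a
larger table. A gene is expressed when ≥ 5 samples reach CPM ≥ 1;
non-expressed genes are dropped from both response and feature roles. For
each expressed hub gene the design is: response = that gene's log-CPM row;
features = the other member genes' log-CPM rows followed by the member
peaks' log-accessibility rows, over an identical, identically-ordered
matched sample set. ATAC matrix rows are matched to consensus regions by
interval overlap, so ATAC feature ids must encode coordinates
(`chrom:start-end`).

## All-relevant selection with a stability filter

One selection run: every surviving feature is duplicated as a value-permuted
shadow copy (shadow pool padded to ≥ 5 columns when few features remain); a
randomized-tree ensemble is fit on the combined matrix; a feature scores a
hit when its importance exceeds the maximum shadow importance; after each
iteration every undecided feature receives a two-sided binomial test of its
hit count against p = 1/2, Bonferroni-corrected across the currently
undecided features, at level alpha = 0.05. Significantly many hits confirm,
significantly few reject (rejected features leave the matrix, with their
shadows); iteration stops when all features are decided or after
`max_iterations` (default 100), leaving survivors tentative. Zero-variance
features are auto-rejected; a constant response is an error.

The stability filter repeats the run `n_runs` = 50 times with consecutive
seeds (`base_seed + r`, published in logs so any single run can be
re-executed) and retains features confirmed in at least
`ceil(0.95 × n_runs)` = 48 runs. Tentative features count as not
significant by default (`count_tentative` flips this).

The importance engine is an extremely-randomized-trees regressor
implemented in numba (no bootstrap; `max_features = p/3` candidate features
per node, one uniform random threshold each; impurity importance =
node-size-weighted variance reduction, averaged over 100 trees). A
general-purpose estimator pays tens of milliseconds of per-fit overhead,
and a stability study refits the ensemble tens of thousands of times on
20-sample matrices, so the inner loop is jitted; the tests assert agreement
with scikit-learn's ExtraTreesRegressor importances on planted-signal data,
and the sklearn estimator remains available behind
`SelectionParams(estimator="sklearn")`. Out-of-bag permutation importance
(mean OOB squared-error increase per feature, Z-scored over trees, on
bootstrapped trees) is implemented as an alternative measure.

### What the selector can and cannot do at small n

An all-relevant selector reports *in-sample association*. At n = 20, a pure
noise feature can draw a chance sample correlation above 0.5; such a
feature is genuinely associated with the response *in that sample*, and the
shadow comparison — fixed feature versus freshly permuted copies — will
persistently favor it. Repeating the selector 50 times on the same data
removes algorithmic stochasticity but cannot remove fixed chance structure.
Consequently: on small fixed datasets the retained set may include
chance-correlated decoys, and a permuted-response null on a fixed dataset
is *not* guaranteed to come back empty. Discrimination between a planted
effect and an equally-correlated lucky decoy would require multivariate
calibration (e.g. partial-correlation t-statistics with proper degrees of
freedom), which is outside the shadow-feature algorithm's design. The test
suite measures these operating characteristics honestly at benchmark
conditions; users should treat retained features at n ≲ 20 as candidates
for validation, not conclusions.

## Synthetic data

The generator's defaults are the study conditions: 16 matched samples (the
scale of a matched RNA+ATAC patient cohort), 2 hubs of 4 anchors (2 kb
wide, 100 kb apart, chained by consecutive plus closing loops so a single
lost edge cannot split a hub), 6 ATAC peaks and 4 genes per hub, peak
dropout 0.1, loop support 1 + Poisson(4), 4 planted element→gene links with
β = 2 (latent log2 units per accessibility SD), expression noise SD 0.5,
NB dispersion 0.05, and 33/46 of LD blocks active (one active block per
hub covering anchor 0 and the planted peaks; inactive blocks in empty
territory). Accessibility is simulated on the latent log2 scale and
observed as negative-binomial counts (gamma-Poisson, Var = μ + φμ²), so
log-CPM approximately recovers the latent values and planted β is
interpretable in the model's own units. The selection benchmark datasets
define "β = 2 response-SD" as: standard-normal features, unit-SD residual
noise, planted coefficients 2 — each planted feature moves the response by
two residual SDs per feature SD.

What the generator does *not* emulate: genomic sequence content, peak
boundary jitter between samples, correlated dropout, batch effects,
TMM-style composition bias, or hub-to-hub contacts. Passing tests therefore
demonstrate the pipeline's correctness and its behavior under the modeled
noise, not performance on real cohorts.

## Numerical and design choices

- Exact rational comparisons for every "at least X%" rule (consensus 60%,
  retention 95%) to avoid float boundary surprises.
- Loop anchors are stored in canonical sorted order; assignment rows sort by
  (chrom, start, end, target, lead SNP), making all outputs invariant to
  input permutation and byte-identical across repeated seeded runs.
- "Within the LD block" means any-overlap by default (consistent with hub
  seeding); strict containment is a flag.
- Element naming: an element overlapping ≥ 1 gene span takes the leftmost
  gene's id; intergenic elements are `Peak_<k>` with k the 0-based index in
  the coordinate-sorted consensus catalog. Names are labels, never keys.
- Per-gene selection seeds are `base_seed + 1000 × gene_index` over the
  deterministic hub/gene iteration order, recorded in the manifest; a
  manifest suffices to re-run the pipeline bit-identically.
- Benchmark problem sizes (10 recovery datasets, 50 null datasets, 1000
  peaks for the dropout check) keep the full verification suite within a
  few minutes on one CPU while leaving Monte-Carlo error well inside the
  asserted bands.

## Known limitations

- The expressed-gene filter is the method's stated rule; upstream reports
  of expressed-gene totals can differ depending on whether the filter is
  applied per group or across all samples, and this package applies it
  across the supplied matrix.
- Hub discovery treats loops as undirected, unweighted connectivity (read
  support is kept as edge metadata only); no significance re-weighting of
  loops is attempted.
- Selection reports association, not direction or causality; effect sizes
  are deliberately not estimated.
- Consensus support is region-level; heavily chained peak landscapes can
  make region support differ from per-base support (logged when detected
  in tests' fixtures, avoided by construction in the generator).
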