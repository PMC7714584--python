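# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the known limitations of the package.

## Differential expression

The paired design gives per-gene, per-pair log2 differences
d_i = case_i − control_i, i = 1..n. The default test is the plain paired
t-test: log2FC = mean(d), t = mean(d)/(sd(d)/√n) with sd the sample
standard deviation (ddof = 1), and a two-sided p-value from Student's t
with n − 1 degrees of freedom. log2FC is defined as the mean of per-pair
differences — identical to the difference of group means for complete
pairs, but stated because rows with any missing value are dropped (with a
logged count) rather than imputed: paired statistics need complete pairs,
and imputation is out of scope.

`moderation="eb"` enables empirical-Bayes variance moderation with a fixed
prior: s̃² = (d₀·s̄² + (n−1)·s²)/(d₀ + n − 1), where s̄² is the study-wide
mean of the per-gene variances and d₀ (default 4) the prior degrees of
freedom; the t statistic then uses s̃ with d₀ + n − 1 df. This is a
deliberate simplification of full moderated-t machinery (which estimates
d₀ and s₀² from the variance distribution): it captures the stabilising
effect on small-variance genes while remaining fully specified. Results on
real microarray data will differ slightly from a limma analysis.

Degenerate rows in plain mode: sd(d) = 0 with mean 0 is a perfect null
(t = 0, p = 1); sd(d) = 0 with nonzero mean means every pair moved
identically, so p is set to the smallest positive double and a warning
logged. The check is exact zero: values that merely round to equal floats
keep their (astronomically large) finite t.

Multiple testing uses Benjamini–Hochberg step-up
(adj_i = min_{j≥i} m·p_(j)/j, clipped at 1), delegated to
`statsmodels.stats.multitest.multipletests` and verified in the test suite
against an independent sort/cummin oracle. The DEG filter is
|log2FC| ≥ fc_min (inclusive, default 1.0) and adjusted p < alpha (strict,
default 0.05); both conventions match how such thresholds are printed.

## ADME screening

A compound is a bioactive chemical ingredient (BCI) when OB ≥ 30 (percent)
and DL ≥ 0.18, both inclusive. Deduplication is keyed on the molecule ID
alone (names vary in capitalization across sources); the herb field of a
merged record is the sorted, semicolon-joined union of source herbs, and
conflicting OB/DL values across duplicates keep the first encountered with
a logged warning. DL > 1 is suspicious but only warned about, since some
databases emit such values.

## Bipartite pharmacological network

Edges are unweighted and undirected — the source analysis records only the
existence of a compound–target regulation relationship, not an affinity.
Ingredients are keyed by molecule ID and targets by gene symbol; exports
prefix node names (`mol:`, `gene:`, `path:`) so the two namespaces can
never collide in SIF/GraphML files. Target nodes carry the regulation
direction and log2FC from the DEG table; ingredient nodes carry their
source herbs.

## PPI construction and the DC → BC cascade

The interactome expansion rule is: seed genes present in the interactome,
plus their direct interactors, plus **all** interactome edges with both
endpoints in that node set (so interactor–interactor edges inside the
neighborhood are retained). Whether a seed-expansion tool should include
those induced edges is genuinely ambiguous, so `expansion="seeds-only"`
(induced subgraph on the seeds alone) is also exposed.

Degree centrality is the raw incident-edge count. Betweenness is the
unnormalized shortest-path betweenness for undirected unweighted graphs,
endpoints excluded, each unordered pair counted once, computed by Brandes'
dependency accumulation (the ordered-pair accumulation is halved);
`normalized=True` divides by (n−1)(n−2)/2. Disconnected graphs are handled
naturally — BFS never crosses components and unreachable pairs contribute
nothing.

"Top 30%" is read as rank-based with ties kept: k = ceil(fraction·n), the
cut is the k-th largest score, and every node scoring ≥ cut survives, so
tie mass at the cut can push the output above k (with continuous scores it
equals k exactly). The published counts this emulates (130 of 446 nodes =
29.1% after DC, 41 of 130 = 31.5% after BC) show the original tooling did
not land exactly on 30% either; rather than guess its rounding rule, the
rank-with-ties semantics is documented and tested. BC is recomputed on the
induced subnetwork, never inherited from the full graph — a test fixture
where the two rankings disagree pins this down. The DC ranking is global,
not seed-restricted: non-seed interactors can and do dominate the
subnetwork, and crucial genes are defined as the seeds that survive both
cuts.

## Over-representation analysis

For each gene set with at least one overlapping gene, the upper-tail
hypergeometric probability P(X ≥ k) is computed with X ~
Hypergeometric(N, K, n): N the universe size, K the in-universe set size,
n the in-universe query size, k the overlap. The universe defaults to all
genes annotated anywhere in the collection (the common ORA default); an
explicit universe (e.g. all measured genes) can be passed. Sets with zero
overlap are excluded from testing and therefore from the BH family size m
— this matches common ORA practice but does change m, hence it is stated.
BH runs within each category (BP, CC, MF, pathway) separately, matching
the convention of reporting those lists independently; `pool_categories=
True` adjusts across everything at once. No set-size filter is applied by
default; min/max flags exist. Because the gene-ratio denominator convention
varies between tools, both k/n (in-universe) and k/raw-query-size are
emitted as columns.

## Synthetic-data model

The generator produces inputs whose structure mirrors the study conditions
the pipeline was designed around, with one global integer seed driving
every artifact through fixed per-artifact substreams (byte-identical
outputs for identical configs, regardless of generator call order).

* **Expression** (defaults: 2000 genes, 17 pairs, frac_de = 0.05,
  effect = 2.0 log2 units, noise SD = 0.5): round(frac_de·n) genes get a
  case-minus-control shift of exactly ±effect, half up and half down so
  both branches of the sign split are exercised; every measurement adds
  independent N(0, noise_sd²) on a per-gene U(4, 12) baseline. At these
  settings the default DEG filter has sensitivity ≈ 1 and near-zero false
  discovery, which the acceptance script measures rather than assumes.
* **Compounds** (4 herbs × 122 compounds, 30% bioactive, 6 shared IDs):
  pass/fail status is assigned first so exactly round(frac·total) records
  pass; passers draw OB ~ U(30, 100), DL ~ U(0.18, 0.95), failers fail on
  OB, DL or both. Shared molecule IDs are duplicated into a second herb
  with identical scores and pass status — duplicates are preferentially
  bioactive, since cross-herb shared ingredients in real catalogues tend
  to be the well-characterized passing molecules — so screen counts are
  unaffected and the dedup reduction is exact.
* **Target map** (hub fraction 0.9, extra targets ~ Poisson(0.15)): the
  designated hub gene is targeted by round(0.9·n_compounds) compounds,
  emulating the one-hub dominance seen in real compound–target tables;
  `cover_all_genes` tops up uncovered universe genes so intersection
  counts are exact by construction. The demo universe is 20 truly-shifted
  genes plus 220 unshifted ones.
* **Interactome** (900 nodes, 6 edges per new node): a Barabási–Albert
  preferential-attachment graph relabelled to gene symbols. Seed genes are
  placed on early-attached (hub) slots by default, mimicking the dense
  connectivity of well-studied disease genes; with these defaults a
  20-seed expansion lands near the ~450-node scale of the real PPI graph
  this emulates. Preferential attachment is a stand-in for a real
  interactome's generative process, not a claim about it.
* **Gene sets**: 200 decoy sets with sizes U{10..50} cycling through
  BP/CC/MF/pathway, plus caller-planted sets kept verbatim (the demo
  plants one pathway holding exactly the 20 true targets).

What the generator does **not** emulate: probe-level microarray effects,
RMA preprocessing, correlated gene–gene expression, real ADME predictor
error, literature bias in target maps, or interactome confidence scores.
Passing tests on synthetic data therefore demonstrate correctness of the
algorithms and calibration under the stated model, not performance on any
real cohort.

## Problem sizes and determinism

Monte-Carlo characteristics (sensitivity, false-discovery proportion, null
calibration) are measured over 50 replicate studies of 1000 genes × 17
pairs — large enough that the binomial noise on a 5% rate is well under a
point, small enough to run in seconds. Centrality implementations are
verified exactly (tolerance 1e−9, reflecting float accumulation order)
against a naive all-pairs BFS oracle on hundreds of random graphs of ≤ 30
nodes, and the hypergeometric tail against full enumeration for every
parameter combination with N ≤ 12. All randomness flows from explicit
integer seeds; reruns of the pipeline with the same config produce
identical outputs up to timestamps, which the manifest records separately.

## Known limitations

* Probe-to-gene collapsing is out of scope; the pipeline consumes a
  gene-level matrix and real analyses must collapse probes upstream. A
  plain quantile-normalization helper is included, but it is not RMA.
* The empirical-Bayes mode uses a fixed variance prior, not an estimated
  one; on real data it approximates, but does not reproduce, moderated-t
  results.
* The seed-expansion rule of the original PPI tooling is not publicly
  specified; both plausible rules are implemented and the choice is
  recorded in the run manifest.
* Enrichment results depend on annotation-collection versions; only the
  testing machinery, not any annotation snapshot, ships with the package.
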