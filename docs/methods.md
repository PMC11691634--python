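# Methods

## The selection model

The discovery workflow treats marker nomination as deterministic set
filtering, not inference: every stage is a predicate on a gene, and the only
quantities carried forward are pass flags, the specificity fold and the
final expression rank. This mirrors how tissue-of-origin EV marker panels
are actually assembled from public resources (an expression atlas, ontology
annotations, EV compendia, cell-type expression), where the analyst's
choices — fold threshold, propagation mode, catalog logic — matter more than
any sampling variability. Consequently there is no multiple-testing
machinery in the discovery module, and all of those choices are explicit
parameters echoed into the provenance report.

### Specificity rule

A gene is specific to the target tissue when its expression there is at
least `detection_floor` (default 1 expression unit, preventing 0.02-vs-0.005
artifacts at the noise floor) and at least `fold_threshold` times its
maximum expression in every other tissue. The default fold of 4 follows the
"tissue enriched" convention of public protein/RNA atlases. The reported
fold uses an `inf` sentinel when the gene is undetected everywhere else;
TSV output renders it as `inf`. Published candidate counts from such
filters depend on the database snapshot and the atlas's specificity
category, so they are narrative context, not targets this package tries to
reproduce.

### Ontology filter

Only `is_a` subsumption is traversed; naming bare cellular-component terms
is most conservatively read as subsumption, and `part_of` traversal can be
added by the caller if the input carries such edges. Propagation defaults to
true (the true-path rule: annotation to a term implies annotation to its
ancestors) because literal term matching silently drops genes annotated to
more specific descendants; the mode used is recorded in the provenance
report, and both modes are supported. Annotations to terms absent from the
graph are dropped with a logged warning instead of raising — real
association snapshots routinely carry retired terms. Exclusion always wins
over inclusion: a gene under both the membrane and the vesicle branch is
removed, because the point of the vesicle exclusion is to avoid
neurotransmitter-vesicle membrane proteins masquerading as surface markers.

### Catalog logic and ranking

The default catalog mode is `all` (a candidate must appear in every
supplied compendium), the reading that matches taking the joint overlap of
two EV databases; `any` is available. Ranking is by expression in one cell
type, descending, with deterministic lexicographic tie-breaks; genes missing
from the expression table rank last and carry a `missing_expression` flag
rather than disappearing. Identifiers from all inputs are harmonized by
exact string match after uppercase normalization; unmatched ids stay in the
provenance table with missing flags.

## Particle summaries

Diameters outside the size window (default 5–1000 nm, the usual
scatter-tracking instrument limits) are discarded and counted. The mode is
the center of the highest-count histogram bin, bins of fixed width (default
10 nm) anchored at 0, ties resolved to the smallest center. Commercial
tracking software computes modal size with unpublished smoothing; the
histogram mode is transparent and testable, and no numeric agreement with
instrument-reported modes is claimed. Bin percentages are renormalized so
they sum to exactly 100 over retained particles. A marker concentration
exceeding the total yields a warning and an `over_capture` flag rather than
an error, since immunocapture and scatter-mode counting probe different
populations. Relative qPCR expression is `2^(Ct_reference − Ct_target)`, so
larger values mean more transcript; the direction convention is part of the
function contract.

## Cargo statistics

Over-representation uses the upper-tail hypergeometric distribution
(`P(X ≥ k)` with population N, term size K, study size n) with each term set
intersected with the user-supplied population first; the universe is never
an implicit whole genome. Empty terms are skipped and reported.
Benjamini–Hochberg is the only multiplicity adjustment, applied across all
tested terms (and across retained miRNAs in the differential stage).

The differential stage is deliberately a Welch t-test on
`log2(CPM + 0.5)` — the pseudocount follows the common prior-count
convention and is configurable — after filtering features below 1 CPM in
fewer than `min_samples` samples (default: the smaller group size). A
negative-binomial empirical-Bayes fit would track the count-model literature
more closely, but the Welch stage is closed-form, oracle-checkable, and
adequately calibrated at the sample sizes involved; numeric concordance with
NB pipelines is not claimed. Rows where both groups are constant and equal
are mapped to statistic 0, p 1 instead of NaN. PCA is column-centered SVD
with each component's sign fixed by making its largest-magnitude loading
positive, so projections are bit-reproducible.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions under which the pipeline is
validated:

* **Atlas** — background expression is i.i.d. log-normal
  (`exp(N(1, 1))` per gene × tissue), a heavy-tailed stand-in for bulk
  atlas values. Planted markers get a target-tissue value of
  `1.001 · fold · (max_other + 2·5σ) + …`, a margin construction that keeps
  the fold rule satisfied after additive Gaussian noise (clipped at ±5σ)
  and after the 6-significant-digit text round-trip of the TSV writer.
  Background rows that would pass the margin-checked fold rule in the
  target tissue are rejection-resampled, so planted truths are exactly
  recoverable: the specific set equals the planted set by construction,
  which is what makes precision/recall assertions meaningful.
* **Ontology** — a random DAG grown under fixed membrane and vesicle branch
  roots; attaching new terms only to earlier terms guarantees acyclicity,
  which is still asserted on every generation. Planted genes are annotated
  only under the membrane branch.
* **Catalogs** — independent Bernoulli inclusion at the stated coverages,
  planted ids forced in.
* **Particles** — i.i.d. log-normal diameters (default median 140 nm,
  σ_log = 0.45, density mode ≈ 114 nm, mass concentrated in 50–400 nm);
  channel labels are independent Bernoulli draws.
* **miRNA counts** — gamma-Poisson (negative binomial) with a single shared
  dispersion (default 0.1), per-miRNA log-normal baselines with a median of
  100 counts, and means scaled by library size and `2^(lfc · group)`.

Real data differ in ways the generators do not model: correlated expression
across tissues and co-regulated genes, ontology annotation bias and depth
differences, catalog curation bias, instrument-dependent size smearing and
polydispersity, per-miRNA dispersion heterogeneity, compositional effects in
CPM, and contamination of the residual-EV group by marker-positive vesicles.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under stated generative assumptions, not performance on any
particular real dataset.

All randomness flows through one explicit integer seed per generator call;
bundle generation derives independent sub-seeds via numpy seed-sequence
spawning. There is no global random state.

## Problem sizes and numerical choices

The shipped validation uses 100-gene × 8-tissue atlases with 5 planted
markers, 50-term ontologies, 1000-miRNA × 10–20-sample count matrices over
200 (null) and 50 (planted) replicate seeds, and 10⁵ particle draws — sizes
at which every distributional check is stable yet the whole suite runs in
seconds on one CPU. Hypergeometric p-values come from scipy's survival
function; BH from statsmodels' step-up implementation; Welch statistics from
scipy with vectorized row-wise evaluation. Degenerate inputs are contracts,
not surprises: an empty survivor set is a valid discovery result, an empty
size window or a single-tissue atlas is an error, and a zero control count
yields an `inf` fold-change sentinel.

## Known limitations

* The Welch-on-log-CPM differential stage loses power relative to NB
  shrinkage methods at very small n and low counts; its q-values should not
  be compared numerically against edgeR/DESeq2 output.
* The ontology reader handles `[Term]` stanzas with `id`/`name`/`is_a`
  only — sufficient for cellular-component subsets, not full OBO 1.4.
* Catalog membership is exact-string; no ortholog or isoform resolution.
* The histogram mode depends on the bin width; the default 10 nm matches
  typical tracking-report granularity but is a choice, not an estimate.
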