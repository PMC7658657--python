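# Methods

`slscreen` implements an integrative pan-cancer screen for synthetic-lethal
(SL) gene pairs. A synthetic-lethal interaction means that perturbing either
gene alone leaves the cell viable while perturbing both kills it; pairs in
which one gene is recurrently lost (mutated) in tumors and the partner is
recurrently over-expressed are candidate therapeutic targets. The package
chains a cross-source catalog, mutation- and expression-level filter
cascades, survival analysis with a randomization null, drug-response
association, and a dominant-isomiR miRNA–mRNA network, and ships a
synthetic-data generator with planted ground truth so the whole cascade is
testable without controlled-access tumor data.

## Catalog construction

Two provenances feed the candidate catalog:

* **Yeast-derived pairs.** Yeast genetic-interaction scores measure colony
  fitness of double mutants; strongly negative scores indicate synthetic
  lethal/sick interactions. Pairs with score ≤ −0.35 (configurable) are
  retained and transferred to human genes through an ortholog map: a yeast
  pair (a, b) expands to the Cartesian product of the orthologs of a and of
  b. Pairs with an unmapped member are dropped silently but counted —
  large-scale ortholog maps are incomplete by nature. Orthology inference
  itself is upstream; the map is an input.
* **Human pairs** from a curated SL database, labelled `human_predicted` or
  `human_validated`. Any score/confidence columns are carried through
  unused; no stated filter consumes them.

Pairs are unordered: records are canonicalized to lexicographic gene order,
and duplicates merge (sources united, the most negative yeast score kept —
most negative = strongest interaction; no other rule is defensible).
The *original* source order is retained as metadata because the combined
screen's positional analysis distinguishes "first gene" from "second gene".

Interaction degree (number of distinct partners) is binned as
{1, 2–10, 11–50, >50}. Gene-level annotation tests membership in seven
binary characteristic sets supplied as GMT (hallmark, CGC, essential,
oncogene, TSG, actionable, drug target); "core" genes carry at least four
characteristics.

## Differential expression

The per-cancer tumor-vs-normal differential expression produces exactly the
summary the screens consume — `baseMean`, `log2FC`, `pvalue`, `padj`,
`status` — from a deliberately simple estimator:

1. **Median-of-ratios size factors**: factor_j = median over reference
   genes of count_gj / geometric-mean_g, reference genes being those with
   positive counts in all samples (a `pseudo_reference` flag rescues sparse
   matrices by taking each gene's geometric mean over its positive counts
   only — needed for small miRNA panels).
2. **log2FC** = log2((mean normalized tumor + 1)/(mean normalized normal + 1));
   the +1 pseudo-count keeps zero-count genes finite (an all-zero gene gets
   log2FC = 0, status `normal`).
3. **p-value** from a two-sided Welch t-test on log2(normalized + 1);
   zero-variance genes get p = 1.
4. **padj** by Benjamini–Hochberg, within each cancer type separately
   (screens operate per cancer).
5. `status = up` iff log2FC > 1.5 and padj < 0.05; `down` symmetric.

This is not a negative-binomial GLM with dispersion shrinkage. The
trade-off is deliberate: the downstream screens use only the direction call
at |log2FC| > 1.5, padj < 0.05, a regime where shrinkage changes little at
the cohort sizes simulated (n ≥ 20 per condition); the acceptance suite
verifies ±0.2 fold-change accuracy at n = 100/100 and mean false-discovery
proportion ≈ 0.05 under the negative-binomial generator. At very small n or
for genes with tiny baseMean the Welch test is less reliable than a count
model; that limitation is accepted and documented rather than hidden.

## Mutation screen

Mutation frequency = distinct mutated samples / cohort size, with
(sample, gene) deduplication; denominators are explicit cohort sizes, not
the number of samples appearing in the MAF, to avoid silent undercounting.
A pair passes when **both** genes exceed 2% frequency in at least five
common cancer types ("more than 2%" read strictly as > 0.02; "at least
five" as ≥ 5 — all prose thresholds are applied with this strict reading,
uniformly). Patients are grouped per pair as MM (both genes mutated),
MW (exactly one), WW (neither) — an exhaustive, exclusive partition.

Drug response is modeled on a min-max-normalized [0, 1] scale per drug (the
upstream response metric — IC50, AUC, z-score — is abstracted away rather
than guessed). The association statistic is the between-group difference of
mean normalized response; significance requires |effect| > 0.10 **and**
Mann–Whitney p < 0.05 **and** BH-FDR across the drugs of the contrast
< 0.10. Mann–Whitney is used because response distributions are unstated
and groups are often small. All three contrasts (MM vs WW, MM vs MW,
MW vs WW) are supported.

## Expression screen

Per-cancer DE statuses assemble into a gene × cancer dysregulation matrix;
genes dysregulated (status ≠ normal) in more than 10 cancer types (≥ 11)
are retained, and pairs in which both members pass. Direction consistency —
the fraction of a gene's dysregulated cancers sharing the majority sign —
is reported descriptively, never filtered on.

Per-patient abnormality, needed for AA/AN/NN grouping but not defined by
any standard convention, is a z-score rule: on the log2(normalized + 1)
scale, a tumor value is abnormal iff |x − μ_normal| / σ_normal > 1.96, with
μ, σ estimated from ≥ 3 normal samples and σ = 0 genes never abnormal. The
cutoff is a config knob and the rule is flagged in output headers as a
stand-in choice.

The directional z score for an annotated gene set is
(up − down) / count ∈ [−1, 1].

## Combined screen

A pair orientation (mutated gene → partner) qualifies when the mutated gene
exceeds 2% frequency in ≥ 5 cancers and the partner is **up**-regulated in
≥ 11 cancers. Down-regulated partners do not count, and the mutated gene's
own expression is never examined — enforced by construction and asserted in
tests. A pair qualifying in both orientations emits two records, one per
orientation, tracked against the original source order. The high-mutation
subset keeps orientations whose mutated gene exceeds 3% in at least one
cancer.

## Survival analysis and the randomization test

Survival uses the Kaplan–Meier product-limit estimator and a k-sample
log-rank test (chi-square with k − 1 degrees of freedom). The log-rank is
implemented in-house as a vectorized routine with a pre-sorted cohort
(`LogrankEngine`) because the randomization test evaluates it tens of
thousands of times per run; it agrees with lifelines'
`multivariate_logrank_test` to 1e-8 on random instances (asserted in the
test suite). The two-group scheme contrasts the extreme groups (MM vs WW,
AA vs NN); the three-group scheme is the overall 2-df test. Arms smaller
than `min_group` (default 5; chosen to avoid degenerate KM arms) cause the
pair to be skipped and logged.

The randomization test asks whether the number of SL pairs significant at
p < 0.05 exceeds chance: each of B = 1000 iterations draws the same number
of unordered gene pairs uniformly from the analysis universe, excluding the
SL catalog, regroups patients, and recounts. Uniform sampling is the
neutral null; no degree- or expression-matched sampling is attempted (the
construction of the original random sets is not reproducible, and matching
criteria would be a guess). The empirical p is the plain proportion
#{null ≥ observed}/B — reportable as exactly 0.000 — with a +1-corrected
variant behind a flag. The count statistic is the default; a mean
−log10 p statistic is an alternative mode and is what the null
self-consistency check uses, because the count statistic is integer-valued
and its empirical p is too discrete to be uniform. An ordered-trend
three-group variant is deliberately not implemented.

## isomiR collapse and the miRNA–mRNA network

A miRNA locus expresses several isomiRs (sequence/length variants); the
locus representative is the isomiR with the largest total count across the
analyzed cohort, ties broken by lexicographically smallest sequence
(deterministic). Pooled-cohort dominance was chosen over per-sample voting
for stability; all-zero loci fall back to the tie-break and are flagged.
T is normalized to U on input. Collapsing is idempotent.

Collapsed locus vectors go through the same DE engine; miRNAs
down-regulated in ≥ 4 cancer types enter the network. The network is a
typed graph: mRNA nodes (with per-cancer expression status and
characteristic flags), miRNA nodes, `sl` edges between mRNAs and `targets`
edges miRNA → mRNA only — bipartiteness of `targets` edges is asserted
structurally after every build. Target maps are an input file (a database
lookup, not a computation); target edges pointing outside the screened gene
list are excluded and counted. Exports: GraphML and SIF. Only the
miRNA-down / gene-up direction is wired; mixed directions are
unimplemented.

## Synthetic data generator

The generator emulates every input with planted, recorded ground truth:

* **Mutations**: per (gene, cancer) Bernoulli rates; background 0.005,
  signal genes 0.10 in 8 of 20 cancer types (8 > the screen's 5 so that
  binomial sampling noise at 2% × cohort does not erode recall), cohort 100
  samples per cancer. Variant classes are categorical with missense 0.6,
  nonsense/frameshift/splice/other 0.1 each.
* **Counts**: negative binomial with var = μ + 0.1·μ² (gene-level
  dispersion 0.1, the overdispersion regime of bulk RNA-seq); normal means
  log-uniform in [50, 2000]; tumor means scaled by 2^(planted log2FC),
  ±2.5 in 12 cancer types for expression-signal genes. Default 60 tumor /
  30 normal samples.
* **Survival**: exponential event times with hazard
  baseline × HR(group), independent exponential censoring
  (0.43 × baseline ≈ 30% censoring). Exponential is the simplest law with a
  controllable hazard ratio; planted prognostic pairs get HR = 3 for the
  MM/AA group (√3 for the middle group). Hazards compose multiplicatively
  across planted pairs (additive log-hazard), so several pairs can be
  planted in one cohort. In the survival cancer all genes carry a 30%
  mutation rate so random pairs also form testable groups — otherwise the
  randomization null would be degenerate.
* **isomiRs**: per locus, sequences over ACGU, a proportion vector whose
  planted dominant entry (0.7) is strictly largest; per sample the locus
  total is negative binomial and isomiR counts are multinomial. Planted
  down-regulation (log2FC −2 in 4 cancer types) scales tumor locus totals.
  Note that with very few loci, median-of-ratios normalization suffers
  compositional bias when a large fraction is planted down; panels of
  ≳ 20 loci with a null majority behave like real small-RNA data.
* **Drug response**: Normal(μ_drug + shift·1[group = MM], 0.05) truncated
  to [0, 1], planted shift 0.3.

One global seed fans out to fixed per-generator child streams
(`default_rng([seed, stream_code])`), so adding a generator never perturbs
the others and every generator is byte-deterministic in (config, seed).
Planted signal genes are disjoint across categories and from filler-pair
genes, making every screen's expected output set well defined. What the
generator does **not** emulate: mutational signatures, copy-number events,
batch effects, paired tumor/normal designs, library-size variation beyond
NB noise, or correlated expression between genes. Passing tests therefore
demonstrate correctness of the screening logic and calibration of the
statistics under the stated models — not robustness to artefacts of real
cohorts.

## Pipeline, fixture, and problem sizes

`run_pipeline` executes the stages in dependency order, emits a
`StageReport` (records in/out, active thresholds, runtime) per stage, and
stamps every output header with a config hash and seed so threshold drift
is visible in a diff. Every threshold lives in the YAML config with the
screen defaults above; nothing is hard-coded. The packaged fixture is a
150-gene, 12-cancer study (30 null pairs plus 2 mutation-signal, 2
expression-signal, 3 combined, 2 prognostic pairs; B = 200) whose stage
counts and recovered pairs are frozen in a manifest; regeneration is
byte-identical by construction.

The statistical acceptance checks run at: 500 genes × 20 cancers × 20 seeds
(combined-pair recovery), 6000 null replicates (log-rank calibration; the
wider replicate count tightens the rate estimate against the acceptance
band), 200 outer replicates at B = 99 plus 10 seeds at B = 1000
(randomization test), and 500 replicates of a 100-gene FDR simulation.
These sizes were chosen so each property is measured with sampling error
well inside its tolerance.

## Known limitations

* The DE engine's Welch test loses power against count GLMs at very small
  n or low counts; dispersion shrinkage and independent filtering are out
  of scope.
* Per-patient expression abnormality has no field-standard definition; the
  z-score rule is a documented stand-in.
* The randomization null is unmatched uniform sampling; degree-matched
  nulls would be stricter for hub-heavy catalogs.
* `sl` edges are stored once in canonical order inside a directed graph;
  consumers needing symmetric adjacency should treat them as undirected.
* The CLI's `--threads` flag is accepted for interface parity only; all
  stages are single-threaded (and fast at the shipped scales).
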