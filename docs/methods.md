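# Methods

## The question and the experimental design

Relative-abundance profiles from case/control microbiome studies are
compositional (per-sample proportions summing to 1) and sparse (most taxa
absent from most samples). The benchmark asks whether the classification
signal survives degradation of each profile to presence/absence indicators,
and whether differential-feature testing reaches the same biology through
either representation. The design holds everything fixed except the
representation: both arms of every comparison share the same stratified
cross-validation splits and the same per-fold model seeds, so fold-level
score differences reflect the representation alone.

## Profile data model

Profiles are samples × taxa matrices of fractions in [0, 1]. MetaPhlAn-style
merged tables store percent values with pipe-delimited, rank-prefixed
lineages; they are converted to fractions once on reading, and every
threshold elsewhere in the package is expressed in percent at the interface
and converted once on entry. Rank selection keeps only rows whose deepest
populated rank equals the requested rank, and rows carrying a strain
(`t__`) segment are excluded, so coarse-rank rows are never double-counted
with their descendants. If the selected rows do not sum to 1 (unclassified
mass in real exports), the reader warns and leaves the values untouched;
closure can be restored explicitly with `renormalize` (rows divided by
their sums, exact to 1e-12). Rank aggregation sums species up the lineage
and conserves per-sample mass to well below 1e-9.

16S OTU tables are filtered in the order the filters are usually stated:
samples with fewer than 100 total reads are dropped first, then OTUs with
fewer than 10 reads total and/or present in less than 1% of the *surviving*
samples (all three boundaries strict). Counts then become per-sample
relative abundances, OTUs un-annotated at genus are discarded, and genera
are summed — so rows may legitimately sum to less than 1 after the
un-annotated mass is removed. Whether prevalence should be computed before
or after the read filters is genuinely ambiguous; computing it on the
surviving samples is this package's choice and is configurable only through
the threshold arguments. A sample left with zero reads after OTU filtering
is dropped with a warning rather than erroring, since it carries no usable
information.

## Degradation

`binarize(table, t)` sets an entry to 1 iff its abundance is strictly
positive and at least `t` (percent, converted to a fraction internally). At
`t = 0` this is the plain support indicator. The boundary convention —
values *equal* to a positive threshold count as present — follows from
reading the threshold as "values below t are forced to zero". Binarization
always happens after any rank aggregation, never before, because presence
at genus level is not the union of species-level presence calls once a
threshold is involved. Binarizing an already-binary table at `t = 0` is the
identity (idempotence), which the sweep machinery relies on.

## The synthetic cohort generator

The generator replaces thousands of external metagenomes with cohorts whose
ground truth is known. Per taxon: a baseline prevalence drawn from
Beta(2, 3) (mean 0.4 — sparse but not degenerate), and a log-abundance
location drawn from N(0, 1.5). Per sample: presence indicators are drawn
from the class-specific prevalences; present taxa get latent abundances
exp(location + scale·z) with within-sample scale 1.0; the vector is closed
to proportions; and counts are drawn from a multinomial at the sample's
read depth (constant 1e6 by default, matching a typical rarefaction
depth; a log-normal depth law is available). Relative abundances are
counts/depth, so rows sum to 1 exactly and the detection limit emerges
mechanically: a taxon at latent proportion p is observed with probability
1 − (1 − p)^depth. A sample that draws zero present taxa is redrawn up to
100 times and then errors; with realistic prevalences this never triggers.

Two disjoint signal types can be planted:

* **Prevalence shift** — selected taxa get case prevalence = baseline +
  delta (clipped to [0, 1]). The default benchmark condition is 200 vs 200
  samples, 300 taxa, 20 signal taxa, delta 0.4.
* **Abundance shift** — selected taxa are forced fully prevalent in *both*
  classes and differ only in log-abundance location (natural-log fold
  change in cases). Because their presence is constant, presence/absence
  profiles carry zero label information about them by construction; this is
  the lever that lets the benchmark distinguish "presence carries the
  signal" from "only abundance does". In the preset counter-regime the
  signal taxa sit at location −1.2 so that their combined mass share stays
  around 1–3%: the compositional rescaling of all other taxa between
  classes is then well below 2%, and — at depth 1e6, where essentially no
  background taxon sits near the detection boundary — closure leaks
  essentially no presence signal into the rest of the profile.

**Detection-limited preset.** For threshold-sweep experiments, the
prevalence-shift taxa can be pinned to a low location (−3.9), putting their
abundance-when-present around 5e-5 (0.005%) of a sample. At depth 1e6 they
are detected reliably at thresholds 0–0.001%, mostly zeroed at 0.01%, and
entirely zeroed at 0.1%, so classification accuracy should fall along the
sweep exactly where the thresholds cross the biomarkers' abundance.

**Multi-dataset batch structure.** Collections share one taxon universe and
one signal set; each dataset perturbs the latent parameters with a
per-taxon log-normal factor at scale `batch_effect` applied to both classes
(technical/population differences) plus *independent class-specific*
factors at half that scale (cohort-composition differences such as case
definition or severity), both on prevalences (multiplicative, clipped) and
log-abundance locations (additive). The class-specific component is
deliberate: a perturbation shared by both classes preserves the
feature–label relationship in every dataset, and a model trained on nine
pooled datasets then transfers *better* than small within-dataset CV — no
cross-study penalty can appear. Class-specific heterogeneity is what
actually makes models trained elsewhere underperform models trained
in-study, and with scale 2.0 it reproduces that regime clearly (mean LODO
AUC well below mean within-dataset CV AUC) while scale 0 leaves the
datasets iid.

**Rarefaction** subsamples each sample's count vector without replacement
(multivariate hypergeometric) to a target depth and recomputes proportions;
it can only lose detected taxa, never gain them.

One integer seed governs all randomness; multi-dataset collections spawn
independent child streams per dataset, so runs are bit-reproducible.

## Classification

Five families, configured as in standard microbiome meta-analysis practice:
random forest (500 trees, √p split candidates, Gini impurity); Lasso and
Elastic Net regression used as scorers, with regularization strength tuned
by internal stratified 5-fold CV over 50 values log-uniform in
10^[−4, −0.5] (the "50 uniform steps" read on the log scale, since the
endpoints are written as powers of ten) and the ENet mixing parameter over
{0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0}; linear and RBF SVMs with the cost
tuned over a 6-point log grid 1e-2…1e3 by the same internal CV (the
symmetric treatment, since no cost selection is standard). Tuning only ever
sees training-fold data; the chosen hyperparameters are fixed before any
test sample is scored.

Choices this package had to make because none is canonical:

* **Case scores** — class-1 probability for RF, raw regression prediction
  for Lasso/ENet, signed decision value for SVMs. AUC and AUPRC are ranking
  metrics, so any monotone score is valid.
* **Operating point** for precision/recall/F1 — score ≥ 0.5 on
  probability-like scores, positive decision value for SVMs.
* **Feature scaling** — none for RF; per-feature standardization fit on the
  training fold for the penalized and kernel models, which are
  scale-sensitive while abundances span orders of magnitude.
* **Model randomness** — a per-(repetition, fold) seed derived from the
  split seed, so two arms sharing a SplitSet also share model randomness
  fold-by-fold and a self-comparison gives exactly zero differences.

Cross-validation is stratified 10-fold repeated 20 times by default (tests
and presets use fewer repetitions; see "Benchmark sizes"). The SplitSet is
an explicit object built once per dataset and reused by every arm. LODO
builds the union of taxa across datasets (absent taxa imputed as 0/absent),
trains on all datasets but one and scores the held-out one.

`compute_auc` is a rank-based implementation of
P(score_case > score_control) + ½·P(tie), verified in tests against
brute-force pair counting.

## Paired fold-level statistics

For two arms on shared splits, d[j][i] is the fold-i score difference in
repetition j. σⱼ is the SD of the k fold differences (n−1 divisor, recorded
in the run manifest), and the standard error is the repetition-averaged
(1/R)·Σⱼ σⱼ/√k — the two published forms (CI and t) are only mutually
consistent under this reading, so the CI multiplier at k = 10 is the 0.975
t-quantile at 9 df, 2.26. Degenerate spread (SE = 0) is reported as t = 0,
p = 1 when the mean difference is also zero, and as p = 0 with a
degenerate-spread flag otherwise. The statistic treats folds within a
repetition as independent, which makes it anti-conservative under the null;
the test suite bounds its null rejection rate rather than asserting the
nominal level.

## Differential features

Abundance mode: two-sided Mann–Whitney U per taxon — exact by enumeration
when the smaller group has ≤ 8 observations and the pooled values are
tie-free, otherwise the tie-corrected normal approximation with continuity
correction. Presence mode: two-sided Fisher exact test on the 2×2 presence
table after binarizing at the same threshold as the corresponding
classification arm (default 0%). p-values are Benjamini–Hochberg adjusted
across taxa *within one cohort and one mode* (per-dataset significant
counts are the quantity of interest, so the FDR family is per dataset).
A constant-zero taxon gets p = 1, is flagged, and can never be significant.
Direction for q < alpha: the higher-prevalence group in presence mode; the
higher mean-rank group in abundance mode (consistent with the U statistic —
mean abundance would be a different, less robust rule). Concordance between
modes reports the shared fraction (significant in both / significant in
either), the direction-discrepancy fraction over the same union, and the
Spearman correlation of −log10 p over taxa significant in at least one
mode. Per-disease aggregation counts a taxon as hitting a disease when it
is significant in at least one of that disease's datasets.

## Orchestration

`bench run` executes the full factorial (rank × threshold × classifier) on
one config, reusing one SplitSet per dataset across all arms, and writes:
per-arm long-format score TSVs, paired comparisons against the abundance
baseline, differential-feature records for both modes, a concordance
report, a long-format summary table, and a manifest (config, seeds,
package versions, per-stage wall time, artifact list) sufficient to
reproduce the run. The config YAML is validated against a published schema
(`presabs bench schema`). Reruns with the same config and seed are
bit-identical except for the recorded wall times.

## Benchmark sizes and tolerances

The preset study conditions are sized to be decisive yet cheap: the
headline prevalence-shift regime uses 200 vs 200 samples × 300 taxa with
10-fold × 5-repetition CV; the abundance-only counter-regime 300 vs 300 ×
200 taxa (sized so that chance per-taxon prevalence gaps, which scale as
1/√n and which a classifier can exploit within a fixed finite cohort, stay
well below what cross-validation can turn into apparent presence signal);
the detection-limit sweep 100 vs 100 × 150 taxa with 2 repetitions; LODO
ten datasets of 30 vs 30 × 150 taxa. Closure and mass
conservation are asserted to 1e-9; renormalization to 1e-12; Fisher
p-values against enumeration to 1e-7 relative; the exact and asymptotic
MWU branches agree within 0.02 where both apply.

## What the synthetic data does and does not show

The generator reproduces sparsity, compositionality, depth-dependent
detection, prevalence- vs abundance-type signal, and between-study
heterogeneity. It does **not** model phylogenetic correlation among taxa,
longitudinal structure, strain-level variation, or profiler sensitivity:
read depth is the only detection knob, whereas marker-based taxonomic
profilers have detection limits far above the naive 1/depth bound. Passing
benchmarks therefore demonstrate that the *pipeline* measures what it
claims under known ground truth — not that any particular real disease's
signal is presence-driven. Conclusions about real cohorts require running
the same pipeline on real profile tables through the same interfaces.
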