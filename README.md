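# presabs

**Does the *presence* of microbial taxa carry the host-phenotype
classification signal held in their *relative abundances*?**

Machine-learning models for case/control microbiome studies are almost
always trained on relative-abundance profiles — per-sample vectors of taxon
proportions summing to 1. Those profiles are intrinsically sparse, which
raises a question that matters for both biology and diagnostics: if every
abundance is degraded to a 0/1 detection indicator, how much classification
accuracy is lost? `presabs` is a benchmark pipeline for answering that
question rigorously, for microbiome/ML researchers who want to compare
profile representations, detection thresholds, taxonomic ranks and
classifiers under controlled conditions.

## What the pipeline does

1. **Profile IO** — read MetaPhlAn-style merged abundance tables
   (pipe-delimited, rank-prefixed lineages; percent values on disk,
   fractions in memory), aggregate species to genus/family/order, and
   preprocess 16S OTU count tables (sample/read/prevalence filters, genus
   collapse).
2. **Degradation** — binarize profiles at a detection threshold *t*:
   entry → 1 iff abundance > 0 and ≥ *t*; sweep
   *t* ∈ {0, 0.0001, 0.001, 0.01, 0.1}%.
3. **Synthetic cohorts** — sparse compositional case/control cohorts with
   per-taxon Beta prevalence, log-normal abundance-when-present, closure,
   and multinomial read sampling (detection limits emerge mechanically:
   a taxon at proportion *p* is seen with probability 1 − (1 − *p*)^depth).
   Signal can be planted as **prevalence shifts** (presence carries the
   label) or **abundance shifts in fully prevalent taxa** (presence carries
   nothing, by construction), plus multi-dataset batch structure.
4. **Classification** — repeated stratified *k*-fold CV (default 10 × 20)
   with shared splits across arms, and leave-one-dataset-out (LODO)
   transfer; classifiers: random forest (500 trees, √*p* split candidates,
   Gini), Lasso/Elastic Net (strength tuned over 50 log-uniform values in
   10^[−4, −0.5] by internal stratified 5-fold CV), linear and RBF SVM;
   metrics: AUC, AUPRC, precision, recall, F1.
5. **Paired statistics** — fold-level comparison of two arms with

   d̄ ± t₀.₉₇₅,₉ · SE,  SE = (1/R) Σⱼ σⱼ/√k,  t = d̄ / SE  (df = k − 1)

   where σⱼ is the SD of the k fold differences in repetition *j*; with
   k = 10 the CI multiplier is 2.26.
6. **Differential features** — per-taxon Mann–Whitney U on abundances vs
   Fisher exact on presence counts, Benjamini–Hochberg FDR (q < 0.05),
   enrichment directions, and a cross-mode concordance report.

## Worked example

Plant prevalence-shift biomarkers (10 of 100 taxa, prevalence delta 0.5) in
a 50 vs 50 cohort, then ask whether presence/absence profiles classify as
well as abundances:

```python
from presabs import (
    ClassifierSpec, CVConfig, PrevalenceSignal, SyntheticSpec,
    significant_taxa, concordance, simulate_cohort,
)
from presabs.benchmarks import compare_profile_types

spec = SyntheticSpec(
    n_control=50, n_case=50, n_taxa=100,
    prevalence_signal=PrevalenceSignal(indices=tuple(range(10)), delta=0.5),
    seed=42,
)
cohort = simulate_cohort(spec).cohort
cmp = compare_profile_types(
    cohort, ClassifierSpec("rf"), CVConfig(k=10, repetitions=2, seed=0)
)
print(f"abundance AUC  : {cmp.auc_abundance:.3f}")
print(f"presence  AUC  : {cmp.auc_presence:.3f}")
print(f"mean difference: {cmp.result.mean_diff:+.4f}")
print(f"95% CI         : ({cmp.result.ci95[0]:+.4f}, {cmp.result.ci95[1]:+.4f})")
print(f"p (df=9)       : {cmp.result.p_value:.3f}")

rec_ab = significant_taxa(cohort, "abundance")
rec_pa = significant_taxa(cohort, "presence")
report = concordance(rec_ab, rec_pa)
print(f"significant taxa (abundance / presence): "
      f"{report.n_sig_abundance} / {report.n_sig_presence}")
print(f"shared fraction: {report.shared_fraction:.2f}")
```

Output:

```
abundance AUC  : 0.972
presence  AUC  : 0.969
mean difference: -0.0030
95% CI         : (-0.0508, +0.0448)
p (df=9)       : 0.890
significant taxa (abundance / presence): 9 / 10
shared fraction: 0.90
```

Degrading the profiles to 0/1 indicators cost 0.003 AUC — statistically
indistinguishable from nothing (p = 0.89) — and the two differential tests
flagged almost the same taxa: when the biology lives in *which* taxa are
present, detection alone carries the signal. Run the same comparison on a
cohort from `presabs.benchmarks.abundance_shift_spec()` and the presence
arm collapses to chance (AUC ≈ 0.5) while the abundance arm stays above
0.9 — the framework tells the two regimes apart.

## Command line

```bash
presabs simulate   --config spec.yaml --outdir data/
presabs degrade    --input data/profiles.synthetic.tsv --threshold-percent 0.001 --output binary.tsv
presabs cv         --profiles data/profiles.synthetic.tsv --metadata data/metadata.tsv \
                   --classifier rf --k 10 --reps 20 --seed 7 --out scores.tsv
presabs compare    --scores-a presence.tsv --scores-b abundance.tsv --out comparison.json
presabs diffab     --profiles data/profiles.synthetic.tsv --metadata data/metadata.tsv \
                   --mode both --out records.tsv
presabs lodo       --profiles-dir data/ --metadata data/metadata.tsv --out lodo.json
presabs bench run  --config experiment.yaml     # full factorial + manifest
presabs bench report --run-dir presabs_run/     # markdown summary (+ --figures)
```

`presabs bench schema` prints the JSON schema the experiment YAML is
validated against.

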