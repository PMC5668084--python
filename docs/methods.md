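# Methods

## The classifier and why it is shaped this way

The predictor is deliberately simple: a 1-nearest-neighbor rule under
correlation distance, wrapped in feature selection and Monte-Carlo
resampling. Correlation distance (1 − Pearson r over the selected genes)
makes the vote invariant to per-sample affine rescaling, which is the main
nuisance in archival FFPE array profiles; Pearson rather than rank
correlation is the conventional choice for continuous log2 array data.
Welch's unequal-variance t is used for gene ranking because tumor groups
rarely share variances; selection is by |t| magnitude only — the ranking
feeds a classifier inside a resampling loop, so no p-values or
multiple-testing correction apply. k = 1 is the default and k is restricted
to odd values so a majority vote cannot tie; distance ties resolve to the
lowest training index, and |t| ties to the lexicographically smaller gene
ID, making every run bit-reproducible.

Each of the R = 500 repetitions draws 5 of the 153 training samples to hold
out, re-ranks all genes on the remaining 148 only, and stores the top
m = 100 genes with the fitted member. Re-running selection inside every
split is what prevents selection bias (feature selection performed once on
the full cohort leaks the held-out labels). A split whose building set
retains fewer than two samples of either class is redrawn from a dedicated
seeded stream, keeping R fixed and runs reproducible.

Internal scores are strictly out-of-bag: a sample is voted on only by
members that held it out (a 1-NN voting on its own training sample would be
trivially correct), giving each training sample ≈ R·5/153 ≈ 16 votes.
External samples are voted on by all members; no final refit model exists —
the ensemble is the model. The published-style "signature" is the list of
genes ordered by selection frequency across members; it is a reported
artifact of the ensemble, not the feature set of any single member, and its
size is whatever the resampling produces (typically 1.5–3× m), not forced
to a fixed length.

Score conventions: score = mean(±1 votes) ∈ [−1, 1]; score > 0 calls high
risk (a score of exactly 0 falls on the low-risk side); the open interval
(−0.5, 0.5) flags a medium-risk/low-confidence call. Medium-risk samples
are counted in reports but never excluded from hazard-ratio computations —
binary classification of all patients is a deliberate design choice, since
an "intermediate" class is of little use in adjuvant-treatment decisions
and inflates apparent high-vs-low separation.

## Survival evaluation

DFS is time from surgery to recurrence or death, censored at last
follow-up. The evaluation uses:

* **Kaplan–Meier** product-limit curves with Greenwood variance; deaths
  precede censorings at tied times. The 5-year quantity is S(60 months),
  read at the largest event time ≤ 60.
* **Log-rank** (two-group, observed-minus-expected with hypergeometric
  variance).
* **Univariate Cox** for the binary high/low call, maximized by
  Newton–Raphson from β = 0 (convergence |Δβ| < 1e−8, ≤ 50 iterations),
  Breslow tie handling by default with Efron behind a flag (simulated times
  are continuous, so the two coincide in practice). Wald 95% CI
  exp(β ± 1.96·SE); p-value from the likelihood-ratio statistic. A monotone
  likelihood (all events in one group) is reported as an explicit
  infinite-HR flag, never as a number.
* **ROC/AUC** over all score cutoffs (trapezoid AUC, identical to
  Mann–Whitney concordance with ties counted ½) with a DeLong CI;
  sensitivity = P(score > cutoff | recurrent) and
  specificity = P(score ≤ cutoff | non-recurrent) at the default cutoff 0,
  defined against the recurrence class label (the model's training target),
  not the 5-year survival status.

These estimators are implemented in-package because their exact contracts
(tie rules, variance formulas, degenerate-case flags) are part of the
pipeline's definition; independent implementations (lifelines) and
brute-force oracles (grid-search partial likelihood, pairwise concordance,
empirical survival) verify them in the test suite.

## The synthetic cohort generator

The generator emulates the statistical structure of a retrospective,
outcome-selected FFPE microarray cohort; it is the test bed for every
downstream stage. Per patient:

1. a **latent risk class** z ∈ {low, high} (P(high) = `frac_recurrent`,
   default 0.5);
2. **DFS time** from a proportional-hazards Weibull (shape 1 = exponential
   default) whose rate gives the latent-low class a median DFS of
   `baseline_median_dfs_months` (default 240 — most low-risk stage I
   patients never recur within follow-up) and multiplies the hazard by
   `hr_true` (default 4.5) for latent-high patients;
3. **censoring** at min(administrative horizon 120 months, uniform loss to
   follow-up over 24–120 months); event-free patients with follow-up below
   48 months get their censoring time redrawn beyond 48 (retrospective
   enrollment required a minimum follow-up for non-recurrent patients),
   which can reveal an event;
4. the **observed class** is event-before-censoring; with
   `force_exact_ratio` (default on) a larger pool is drawn and subsampled
   to an outcome-balanced cohort (n//2 recurrent), mirroring the study's
   1:1 chart-review selection;
5. **stage** (IA/IB/IIA/IIB/IIIA) sampled conditional on the latent class
   with the published cohort's frequencies (81% stage I overall; high-risk
   patients skew to IB+);
6. **expression**: per-gene baseline ~ N(7, 3²) log2 units, plus a signed
   shift of `effect_size_delta` in a random `frac_de_genes` subset for
   observed-recurrent patients, plus a per-(batch, gene) offset
   ~ N(0, `batch_sd`=0.15), plus N(0, sd_g) noise with sd_g uniform in
   `gene_sd_range` (default 0.3–0.8);
7. each of the 20 batches carries a **replicated reference sample** (one
   shared profile, the batch's offsets, fresh noise) for the cross-batch
   QC, which correlates reference profiles pairwise and passes at a
   configurable threshold (default 0.95; the underlying study states no
   number).

Two classes coexist on purpose. Survival is generated from the *latent*
class, so the Cox stage has a well-defined true hazard ratio to recover
(verified by simulation: the latent-class estimate covers hr_true in ≥90%
of replicates). The expression shift is planted between *observed* outcome
groups, because that is what a retrospective outcome-selected cohort
exhibits and what the t-test/1-NN machinery is built to detect. The two
labels agree for most but not all patients (an event is a stochastic
consequence of risk), which is exactly the label noise such a study lives
with. One consequence worth knowing: under a very strong planted signal
the predicted groups coincide with the observed outcome groups, all events
fall in the predicted-high group, and the evaluation correctly reports the
infinite-HR flag rather than a finite hazard ratio.

**Calibration of defaults.** The study reports no per-gene effect sizes or
variances, so the generator's signal strength is a calibration choice: the
defaults (5% DE genes, shift 0.22 log2 units ≈ 0.4 per-gene SDs) were
chosen once so that the default cohort reproduces the published operating
characteristics of the real data — out-of-bag AUC ≈ 0.8, sensitivity and
specificity ≈ 0.75, training HR ≈ 4.5, with stage-IA HR exceeding the
pooled HR. Reproducing the regime (not the exact numbers, which depend on
the unavailable real cohort) is the design goal.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-level intensity structure and
normalization artifacts, heavy-tailed or non-Gaussian expression noise,
gene–gene correlation (genes are independent given class and batch),
covariate-dependent censoring, and stage as a *cause* of hazard (stage is
correlated with risk only through the latent class). Performance on the
synthetic cohort therefore bounds implementation correctness, not clinical
accuracy.

## Determinism and numerics

Every stage seeds `numpy.random.Generator` explicitly; the pipeline derives
per-stage seeds as `SeedSequence(master, spawn_key=(crc32(stage),))`, so
stages are independently reproducible and identical configurations yield
byte-identical score files. Expression round-trips through text at 6
significant digits. Degenerate inputs have defined behavior rather than
NaNs: zero-variance genes get t = 0 (equal means) or ±∞ (unequal means,
ranked first); constant profiles under correlation distance raise an
explicit error; zero-event survival data and single-risk-group strata are
flagged not-estimable.

## Problem sizes used in the checked runs

The shipped analysis and the statistical test suite run the full study
design (211 patients, 153/58 split, 500 × leave-5-out, m = 100) at 2,000
genes rather than the 40,716 transcripts of the original array; the gene
dimension is a configuration knob and 2,000 preserves every structural
property (selection pressure of top-5% |t|, batch QC geometry) at a size
convenient for routine re-runs. Calibration and recovery tests use 20-seed
batteries at n = 200 and reps = 200, and Cox coverage uses 50 replicates
at n = 400.

## Known limitations

* The Wald/likelihood-ratio machinery of the univariate Cox fit assumes
  proportional hazards between predicted groups; no diagnostic is run.
* The hazard-ratio CI method of the original report is unknown (its
  published intervals are asymmetric around the estimate in a way
  log-scale Wald intervals are not); Wald intervals are implemented.
* Whether the original 500 splits were stratified by class or stage is
  unstated; plain uniform draws are used.
* External scores average the full ensemble's votes; no single final model
  is refit on all training data (no refit is described by the source
  design, and ensemble voting matches its "averaged performance" framing).
* `k` > 1 and class-weighted voting are provided for sensitivity analysis
  but are not the evaluated configuration.
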