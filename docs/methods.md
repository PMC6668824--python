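# Methods

## The analysis

The package implements an individual-differences analysis of memory and
metacognition in a two-group cohort (younger vs older adults). Each
participant contributes 18 measures: for each of two recognition tests
(single items; studied-vs-recombined pairs, the "associate" test) a
recognition score (hit rate minus false-alarm rate) and eight
metacognitive scales — memory self-efficacy (0–100), postdiction (0–100),
postdiction accuracy (postdiction as a proportion minus proportion
correct), perceived strategy success (0–100), and 1–5 ratings of
difficulty, effort, fatigue and stamina.

The multivariate core is deliberately simple and fully inspectable:

1. **Z-scoring.** All 18 variables are standardized columnwise (sample
   SD, n−1 denominator). Every downstream stage operates on z scores;
   raw-scale dispersion is irrelevant after this step.
2. **Classifier.** A feed-forward network 18 → 2 → 1 with the bipolar
   logistic activation 2/(1+e^(−x)) − 1 = tanh(x/2) at every unit is
   trained to emit −1 for younger and +1 for older adults, by full-batch
   gradient descent on the summed squared error ("iterative error
   correction"). Weights and biases start uniform in
   [−0.005, 0.005).
3. **Hidden-unit probing.** The two hidden activations per participant
   are a learned 2-D embedding in which the classification is linear (up
   to the output squashing). k-means with k = 3 (k-means++ seeding,
   Lloyd iterations, best of 50 restarts) groups participants blindly in
   this embedding.
4. **Canonical labels.** Cluster 1 = highest proportion of young;
   cluster 2 = of the remaining two, the one with higher mean z-scored
   associate postdiction accuracy (the "confident, well-calibrated"
   older subgroup); cluster 3 = the rest.
5. **Cluster characterization.** Per-cluster means ± SE of the z-scored
   inputs, and a one-way between-clusters ANOVA per variable with
   Bonferroni correction over the 18 tests (significance at raw
   p < .05/18 ≈ .0028) and partial η² = SS_between/(SS_between+SS_within).
6. **Evaluation.** Leave-one-out cross-validation: for each participant,
   the feature subset is selected, the remaining n−1 rows are re-z-scored,
   a freshly initialized network (fold seed = base seed + CRC32 of the
   held-out id, making predictions invariant to row order) is trained,
   and the held-out row — standardized with the training fold's
   statistics only — is classified. Sensitivity is
   d′ = Φ⁻¹(HR) − Φ⁻¹(FAR) with older adults as the signal class;
   extreme rates use the 1/(2N) correction by default (log-linear
   optional). The item-vs-associate ablation runs this LOOCV on each
   9-column half under identical fold seeds, so the d′ difference is a
   paired comparison.

The univariate companion statistics are a split-plot ANOVA on recognition
scores — Age (2) and Stimulus Type (3) between subjects, Test Type (2)
within, each effect tested against its own error stratum with partial
η² = SS_effect/(SS_effect+SS_error-of-stratum) — two-sample pooled-variance
t tests young vs old per variable with Bonferroni correction, Cohen's d in
the mean-of-SDs convention |m₁−m₂|/((s₁+s₂)/2), and pairwise stimulus-type
contrasts in which each subject contributes the item and the associate
score as two observations (so conditions of 36/36/34 subjects give the
dfs 142/138/138).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `TrainingConfig.init_range` | 0.005 | half-width of the uniform init interval |
| `TrainingConfig.learning_rate` | 0.05 | step size, applied to the **mean** per-participant gradient so its scale is cohort-size independent |
| `TrainingConfig.max_epochs` | 20 000 | full-batch epochs |
| `TrainingConfig.convergence_tol` | 1e-10 | stop when the total squared error changes less than this between epochs |
| `kmeans restarts` | 50 | k-means++ restarts; best (lowest inertia) kept |
| `dprime correction` | 1/(2N) | extreme-proportion handling; LOOCV with ~50 per class can produce perfect rates |
| `SyntheticConfig.residual_sd` | 1.0 | within-cluster noise, in units of each variable's base SD |

Targets ±1 are the activation's asymptotes, so exact convergence to the
targets is impossible; training stops on the error-change criterion.
The learning-rate semantics (mean gradient) mean the classical
sum-of-squares formulation is recovered with rate/n. Simulation studies
inside the test-suite use a larger step (0.5) and a smaller epoch budget
(3 000 for cross-validation folds, 20 000 for the single full-cohort
probe network) — these are problem-size choices for repeated retraining,
not different dynamics; all settings are exposed in `TrainingConfig`.

An output of exactly 0 classifies as "young" (a measure-zero tie, fixed
so the rule is total). An emptied k-means cluster is re-seeded at the
point farthest from its assigned centroid. A singleton cluster leaves
the per-variable ANOVAs undefined; the pipeline then reports an empty
significant-variable set rather than aborting.

## The synthetic cohort generator

`metamem.synthetic` draws cohorts with the latent structure the analysis
is designed to detect, plus ground-truth labels so the whole pipeline can
be scored by parameter recovery. Defaults: 57 young / 49 old; among the
old, latent subgroups of 12 ("confident": above average on postdictions,
strategy success, postdiction accuracies and associate self-efficacy,
below on associate difficulty) and 36 (the mirror image), with 1 older
adult carrying the young-typical profile and 1 younger adult carrying the
confident-older profile — the two crossovers that make the separation
strong but imperfect. The young cluster is average on everything except
item-test fatigue, where the young/older offsets of ±0.45 SD reproduce a
young−old separation of 0.9 SD, the size of the cohort's only significant
univariate age difference (d = 0.82). Offset magnitude is 0.9 z for
cluster-distinguishing variables; both recognition columns carry no
offsets in any cluster (the clusters differ in metacognition, not
performance). Each variable is drawn independently given the cluster as
`base_mean + base_SD · (offset + N(0, residual_sd))` and clipped to its
legal range (clipped draws are counted and reported); base means/SDs
default to the study's printed per-test-type summary statistics averaged
over the two age groups.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data:

* **Within-participant correlation.** Variables are independent given
  the cluster; real metacognitive scales correlate. Identity residual
  covariance is the minimal assumption given that only marginal
  summaries are published.
* **Effect-size coherence.** In this additive independent-noise model no
  single residual scale can reproduce, at the same time, the published
  raw-scale dispersions, the near-perfect hidden-space partition of the
  study's cohort, and its cluster-ANOVA η² band of .88–.96. At the
  default residual of 1.0 SD, recovered-cluster η² for offset variables
  is roughly .1–.5, individuals scatter across cluster boundaries, and a
  minority of cohorts (~a quarter) are drawn in which the network finds a
  representation that does not separate the two older subgroups cleanly.
  Smaller residuals make the classification nearly separable, remove the
  pressure for an XOR-like hidden geometry, and degrade recovery in a
  different way. The default therefore stays at 1.0 (the natural unit),
  and the recovery rates measured in the test suite quantify the
  pipeline's behaviour at that signal-to-noise — they are properties of
  these conditions, not guarantees about any real cohort.
* **Postdiction-accuracy consistency.** Postdiction accuracy is drawn as
  its own variable rather than derived from the drawn postdiction and
  recognition values.
* **Condition effects.** Stimulus condition (words/names/nonwords) is
  assigned uniformly at random and carried as metadata only; the
  generator injects no condition effects, so the split-plot ANOVA's
  Stimulus Type effect is null in synthetic cohorts.

## Numerical choices

* Bipolar logistic computed as `tanh(x/2)`; the identity with
  2/(1+e^(−x)) − 1 is exact.
* Gradient correctness is property-tested against central finite
  differences (relative error < 1e-5 over 50+ random small networks).
* Z-scoring after subsetting equals subsetting after z-scoring
  (columnwise standardization); the pipeline normalizes after
  subsetting, and a test pins the equivalence.
* Unequal split-plot cells use the classical unweighted-means solution
  (unweighted cell means, harmonic-mean effective cell size). On
  balanced data this equals the textbook decomposition exactly and SS of
  effects + errors = total; on unbalanced data the effect SS are not
  additive to the total (a known property of unweighted means).
* Sums of squares below 1e-12 of the total are truncated to zero so a
  constant dataset yields F = 0 rather than 0/0 noise.
* The LOOCV engine trains all n folds as stacked tensors; each fold's
  updates are independent, so this is the sequential per-fold loop
  without the Python overhead.
* All randomness flows through explicit integer seeds; the pipeline fans
  a global seed into per-stage seeds (data, training, clustering,
  cross-validation) via `numpy.random.SeedSequence`, so e.g. changing
  the clustering seed cannot perturb the trained model.

## Known limitations

* The network's hidden representation is not unique: distinct
  initializations can produce equally accurate classifiers whose hidden
  geometries cluster differently. The `run_robustness` helper quantifies
  how often the qualitative three-cluster pattern (one majority-young,
  two majority-old clusters) recurs across retrainings and across the
  2- and 3-hidden-unit architectures.
* d′ from 106 binary held-out outcomes carries sampling noise of roughly
  ±0.25; item-vs-associate differences smaller than that are not
  interpretable from a single cohort even with paired fold seeds.
* k is fixed at 3 by design; no model-selection criterion is implied or
  provided.
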