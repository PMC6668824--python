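# metamem

Neural-network individual-differences analysis of memory and
metacognition in younger and older adults.

## The problem

Cohort studies of cognitive aging often find *no* mean age differences on
recognition memory or on most metacognitive self-reports, yet the older
group may hide qualitatively different subgroups whose opposite profiles
cancel in group averages. `metamem` implements a pipeline that surfaces
such structure: a small artificial neural network is trained to classify
participants as young or old from 18 memory/metacognition measures, and
its two hidden-unit activations — the learned 2-D embedding in which the
classification happens — are clustered to reveal participant subgroups
that univariate statistics miss. It is written for researchers in
cognitive aging and metamemory who want a transparent, fully seeded,
testable version of this analysis, together with the classical statistics
that accompany it.

## The method

For participant *i* with z-scored measures **x**ᵢ ∈ ℝ¹⁸, a network
18 → 2 → 1 with bipolar-logistic units g(x) = 2/(1+e^(−x)) − 1 = tanh(x/2)

    h_j = g(w_j · x + b_j),  j = 1, 2        (hidden activations)
    y   = g(v · h + c)                        (output in (−1, 1))

is trained by full-batch gradient descent on Σᵢ (tᵢ − yᵢ)², with targets
t = −1 (young) and +1 (old), weights initialized uniformly in
[−0.005, 0.005). The fitted (h₁, h₂) per participant are clustered with
k-means (k = 3, k-means++, 50 restarts); clusters are labelled
canonically (1 = predominantly young; 2 = the older subgroup with higher
mean associate postdiction accuracy; 3 = the rest) and characterized by
per-variable one-way ANOVAs with Bonferroni correction (18 tests) and
partial η². Held-out accuracy is measured by leave-one-out
cross-validation summarized as d′ = Φ⁻¹(HR) − Φ⁻¹(FAR) (old = signal
class, 1/(2N) extreme-rate correction), and an ablation compares networks
trained on the 9 item-test vs the 9 associate-test measures under matched
folds. A split-plot mixed ANOVA (Age × Stimulus Type between, Test Type
within), pooled t tests and mean-of-SDs Cohen's d cover the univariate
side. A seeded synthetic-cohort generator with ground-truth latent
clusters makes the whole pipeline testable end to end.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```bash
python examples/full_replication.py
```

```
n = 106 (57 young, 49 old)
resubstitution accuracy : 100.0%
LOOCV d' (all inputs)   : 1.38
LOOCV d' item/associate : 0.72 / 1.14 (difference +0.42)
cluster composition     : {1: {'young': 57, 'old': 0}, 2: {'young': 0, 'old': 14}, 3: {'young': 0, 'old': 35}}
cluster recovery (ARI)  : 0.93
significant variables   : 9
Stimulus Type F         : 0.42 (partial eta^2 = 0.01)

artifacts written to run_output/
robustness: three-cluster pattern in 67% of 3 retraining runs
```

Reading the output: the trained network separates young from old
perfectly on the training cohort, and still classifies *held-out*
participants well above chance (d′ ≈ 1.4, roughly 75% accuracy at a
neutral criterion). The three clusters recover the generator's latent
structure (ARI 0.93; composition close to the planted 57/13/36 split),
the 9 variables flagged by the cluster ANOVAs are exactly the
metacognitive variables the generator offsets — not the recognition
scores — and the associate-task measures carry more age-diagnostic
information than the item-task measures (d′ difference +0.42). The
Stimulus Type effect is null because the generator injects no condition
effects. Hidden-space geometry is not unique across retrainings, so the
robustness line reports how often the qualitative three-cluster pattern
recurs; expect run-to-run variation at this signal-to-noise (see
`docs/methods.md`).

The other example scripts each demonstrate one capability:
`simulate_cohort.py` (data generation), `train_and_probe.py` (training
and hidden-space clustering), `loocv_ablation.py` (cross-validated d′ and
the item/associate comparison), `univariate_stats.py` (split-plot ANOVA,
t tests, effect sizes).

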