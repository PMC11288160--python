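# Methods

## Problem and model

The package classifies single amino acid polymorphisms (missense variants)
as *deleterious* or *neutral* from a table of per-mutation numeric
attributes grouped into six families: `sequence` (alignment-derived
scalars), `sequence_profile` (the 20 per-residue frequencies at the mutated
position), `mutation` (the 20-value substitution encoding), `evolutionary`
(residue conservation), `structural` (solvent accessibility) and
`stability` (folding stability change). Deleterious is the positive class
(label 1) everywhere.

Rather than fitting one classifier, the sampler explores the set of
near-equivalent models. It draws many random *holdouts* (data bags); each
bag takes

1. an independent uniform train/test split at `train_frac` (default 0.75),
2. a random subset of the attribute groups (each group included
   independently with probability 0.5, redrawn if empty), and
3. a random classifier architecture: with probability 1/2 an extreme
   learning machine (ELM), otherwise a random forest (RF).

After training, each bag's test accuracy `Acc_i` (plain fraction correct)
is computed, and the bags satisfying the strict inequality

```
Acc_i > tau * Acc_max,       tau = 0.90
```

form the consensus committee. The committee predicts by an
accuracy-weighted vote of the members' class predictions (weight =
`acc_test`; plain majority available); the consensus score lies in [0, 1]
and the decision threshold is 0.5 with ties going to deleterious — the
conservative direction for a pathogenicity screen. The maximum-accuracy
bag always qualifies, so the committee is never empty.

Blind validation is a stratified k-fold loop (default k = 5): for each
fold, holdouts are generated, fitted and selected using the other k−1 folds
only, and the consensus is scored on the untouched fold. Fold assignment is
stratified by class at the mutation level; proteins may span folds, which
mirrors mutation-level random splitting. (Protein-level grouping to guard
against homology leakage is a known omission; see Limitations.)

### ELM

A single-hidden-layer network `f(x) = Σ_i β_i g(w_i·x + b_i)` with L hidden
nodes. Hidden weights `w_i` and biases `b_i` are i.i.d. uniform on [−1, 1]
and never trained; only β is fit, as the minimum-norm least-squares
solution `β = H⁺ y` of `H β = y` via the Moore–Penrose pseudoinverse
(SVD-based; singular values below `1e−10 · σ_max` truncated — the `rcond`
is fixed so runs are reproducible). Targets are coded −1/+1 and the
decision threshold is 0. Inputs are standardized with the training-bag
mean/sd (constant columns pass through unscaled) so that the sigmoid and
sinusoid activations operate in their responsive range; the constants are
stored in the model. "Number of hidden layers L" is read as the number of
hidden *nodes* of a single layer, consistent with the single sum in the
model equation. The sampled architecture draws L uniformly from [10, 200]
(covering under- and over-parameterized regimes) and the activation
uniformly from {sigmoid, sinusoid, linear}.

### RF

Standard Breiman bagging, delegated to scikit-learn: B = 100 trees, each
grown to purity (minimum leaf 1, no depth cap) on a bootstrap resample of
the training bag, Gini impurity, ⌈√d⌉ random features per split. The
ensemble score is the fraction of trees voting deleterious; a tied vote
(score exactly 0.5) predicts deleterious.

## Posterior analyses

* **Group frequency**: the fraction of selected (vs rejected) holdouts
  whose subset contains each attribute group. Informative groups are
  enriched among the selected bags.
* **Fisher's ratio** per attribute: `FR = (μ₁ − μ₀)² / (σ₁² + σ₀²)` with
  unbiased class variances. Zero within-class variance with unequal means
  is reported as +inf and flagged degenerate rather than dropped.
* **Fold change**: `FC = |μ₁ − μ₀|`, the distance between class centers.
  Despite the name, the default is a difference, matching the
  center-distance definition; a `log2(μ₁/μ₀)` variant is available for
  strictly positive attributes.
* **Metrics**: the confusion matrix is oriented rows = predicted,
  columns = target. MCC uses the standard 2×2 formula (0 when a marginal
  is empty). The ROC sweeps thresholds over the unique scores and the AUC
  is the trapezoid integral, so tied scores contribute diagonal segments —
  numerically identical to the Mann–Whitney U statistic with half-credit
  ties. Accuracy summaries report mean, median, sd (n−1), interquartile
  range (linear-interpolation quartiles), min and max.

## Randomness discipline

One master seed spawns per-holdout child streams by counter
(`numpy.random.SeedSequence.spawn`), so increasing `n_holdouts` never
perturbs earlier holdouts, and every holdout stores the seeds needed to
refit it bit-identically. Each k-fold round derives a fold-specific
sampler seed the same way. scikit-learn forests receive integer seeds
drawn from the holdout stream.

## Synthetic study conditions

The generator emulates the statistical shape of a curated variant training
set at desk scale: n = 1000 samples by default (2000 where a test pins it),
35% deleterious, six groups with effect sizes chosen once to mirror the
qualitative ranking observed in real variant data — mutation and
sequence-profile attributes strongest, evolutionary and structural
moderate, sequence weak, stability null:

| group            | columns | effect d | note                                  |
|------------------|---------|----------|---------------------------------------|
| mutation         | 20      | 1.5      | categorical concentration (see below) |
| sequence_profile | 20      | 0.8      | Gaussian mean shift                   |
| evolutionary     | 1       | 0.5      | Gaussian                              |
| structural       | 1       | 0.4      | Gaussian                              |
| sequence         | 3       | 0.3      | Gaussian                              |
| stability        | 1       | 0.0      | pure noise                            |

Gaussian groups draw `N(d·label, noise_sd)` per column (`noise_sd` = 1), so
d is the standardized between-class mean shift and is recoverable from a
large sample. The mutation group cannot be Gaussian — its columns must be
valid −1/0/+1 mutation vectors — so its 20 columns encode a real wt→mut
substitution whose mutant residue is drawn from a label-dependent
categorical distribution: residues in the first alphabet half get weight
`exp(±d)` depending on the class. Here d is a concentration, not a mean
shift; at the default d = 1.5 the mutation-only Bayes accuracy is ≈ 0.95,
comparable to the 20-column profile group, making both groups "strong" as
intended. A heavy-tailed option (t with 3 df, variance-matched) stresses
the ELM pseudoinverse's noise sensitivity.

What the generator does **not** emulate: real sequence correlation
structure, homologous proteins sharing signal across rows, missing-data
patterns, label noise, and the 38k-scale of curated databases. Passing
tests therefore demonstrate the machinery (selection rule, consensus
benefit, dispersion and enrichment phenomena) on controlled signal, not
clinical-grade accuracy on real variants.

## Numerical and design choices

* Amino-acid order for all 20-vectors: alphabetical single-letter
  (A C D E F G H I K L M N P Q R S T V W Y); fixed and documented because
  any canonical order would do.
* Missing feature cells are imputed with the column median at ingestion
  (strict mode rejects). Standardization inside each ELM fit uses
  train-bag statistics only.
* Profile columns exclude gaps from the frequency denominator; an all-gap
  column yields the uniform 1/20 with a warning. No pseudocounts by
  default (a Dirichlet option exists).
* Mutation positions are 1-based in the query's ungapped sequence;
  `profile_at` maps through the query's gap pattern.
* A training bag with one class is resplit once; if still degenerate the
  holdout is flagged and excluded from selection rather than raising.
* Holdout count defaults to 100, configurable (larger bag counts are
  sometimes useful; the posterior analyses stabilize with more bags).
* Problem sizes in the test suite and the acceptance script (n = 1000–2000,
  20–100 holdouts, 20 replicate seeds) were chosen as the smallest at which
  the ensemble phenomena are statistically stable.

## Limitations

* Mutation-level fold assignment lets homologous mutations of one protein
  appear in both learn and blind folds; protein-level grouping is the
  rigorous alternative and is not yet implemented.
* The ELM accuracy dispersion exceeds the RF dispersion on the default
  conditions, but the gap is narrower than on noisy real data, where the
  pseudoinverse's sensitivity to noise attributes is more pronounced.
* Fisher's ratio and fold change assume roughly unimodal class-conditional
  distributions; multi-modal attributes can score low while still being
  informative to a tree.
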