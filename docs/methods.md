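# Methods

`phenonoise` studies how random mislabeling of a binary carrier phenotype
degrades SNP-based classification. The pipeline has four stages — panel
simulation, genotype QC, label-noise injection, and a replicated
classification benchmark — each usable on its own from Python.

## The classification problem

A diploid individual is a *carrier* if it is heterozygous for a harmful
recessive mutation; homozygous mutants are never observed (they do not
survive to genotyping). Carrier status is known exactly for training data
in principle, but real phenotype records contain errors. The question the
experiment answers is: as an increasing fraction of training labels is
flipped at random, how quickly do five standard classifiers — lasso
logistic regression, linear and radial SVM, K-nearest neighbours, and
random forest — lose the ability to identify carriers in clean test data?

The population emulated throughout is a dairy-cattle cohort: n = 3116
individuals, m = 1512 SNPs on the chromosome carrying the mutation, 126
carriers (4.04%), mean pairwise LD r² = 0.126. The severe class imbalance
is central: overall accuracy is dominated by the easy majority class, so
the informative metric is the true positive rate (sensitivity on the rare
carriers), and hyperparameter tuning uses balanced accuracy,
(TPR + TNR) / 2, rather than raw accuracy.

## Synthetic panels

Real genotype panels of this kind are rarely public, so the generator is
the canonical input source and is itself first-class, tested code.

**LD model.** Haplotypes are Markov mosaics of a small founder panel
(Li–Stephens style). F founder haplotypes are drawn independently from
per-locus founder frequencies (uniform on `maf_range`, default
0.05–0.50, every founder column kept segregating); each sample haplotype
walks along the chromosome copying its current founder, keeps the same
template at the next locus with probability ρ (else jumps to a uniformly
chosen founder), and replaces the copied allele with a fresh frequency
draw at a 1.5% per-locus mutation rate. Shared founder segments induce LD
that decays with distance; the finite panel bounds its level near
1/(F−1) for fully linked pairs. F is sized as `round(0.5 / target_r2)`
(minimum 2) to leave calibration headroom, and ρ is then calibrated by
bisection — re-seeding the generation stream identically at every
candidate, so the realised mean pairwise r² of the delivered panel lands
within the bisection tolerance (0.004) of the target. A first-order
copying process with an *unbounded* template pool was tried first and
rejected: fresh draws never create allelic association, so its mean r²
stays below ~0.002 regardless of ρ.

**Carriers.** Exactly `round(carrier_frequency × n)` individuals are
carriers by construction, each heterozygous at the mutation locus (column
0); everyone else is homozygous reference there. The mutant allele is
placed on one ancestral background: each carrier's mutant haplotype copies
the mutant founder from the mutation outward for a geometric segment
(per-locus continuation 0.975 by default, a mean shared block of ~40
SNPs — the scale of an identical-by-descent block around a recent
mutation), then recombines back onto the individual's own background.
The mutant founder itself is an *ordinary* haplotype of the population (a
mosaic of the founder panel) distinguished by sparse private mutations:
20% of its loci are flipped toward the locally rarer allele. This yields
the tagging structure of a real recent mutation on a common haplotype —
a few strongly informative markers (which sparse methods can recover even
from noisy labels) over a diffuse weak signal (which margin- and
vote-based methods lose as label noise grows). An earlier variant drew
the founder background i.i.d. from the allele frequencies; it made every
segment locus moderately informative and left the linear SVM's
sensitivity implausibly robust to 20% label noise, contradicting the
behaviour this generator is meant to emulate, and was replaced. A
`carrier_background_ld=False` mode omits the shared background entirely
(negative control: flanking SNPs carry no signal).

**Missingness** is injected uniformly at random per entry (default 0,
study setting ≤5%), and everything is deterministic given the config seed
(byte-identical panels).

What the generator does *not* emulate: genotyping error, pedigree/family
structure, distance-dependent recombination maps, multi-chromosome
genomes, or ascertainment of chip SNPs. Passing tests therefore show the
*methodological* pattern (which classifiers tolerate label noise under
imbalance), not quantitative agreement with any particular breed's data.

## Genotype QC

Fixed order: call-rate filter (individuals, then SNPs; strictly-below-95%
removed, exact 95% kept) on the full panel → imputation → per-replicate,
training-only removal of monomorphic loci and of loci whose absolute
Pearson correlation with an earlier-kept locus exceeds 0.99. Absolute
correlation is deliberate: a perfectly anti-correlated pair is exactly as
linearly dependent as a perfectly correlated one. The collinearity scan
runs in map order and keeps the earlier locus — any deterministic rule
works; this one is reproducible. Kept-locus lists computed on training
rows are applied verbatim to the test split, never recomputed there.

Imputation is modal (most frequent observed dose per locus, ties to the
smaller dose), with an optional LD-aware variant that borrows the
genotype distribution of the most-correlated observed locus. Sophisticated
haplotype-clustering imputation is out of scope here: with ≤5% missingness
and a classifier-comparison endpoint, the imputer choice is not
load-bearing, and the method used is recorded in the QC report.

## Label noise

Noise scenarios flip exactly `round(p · n_train)` training labels
(round-half-to-even), chosen uniformly without replacement and
class-blind. Fixed counts rather than Bernoulli draws make scenarios
exactly comparable and the contract exactly testable; a Bernoulli mode
exists for sensitivity analysis. The studied grid is p ∈ {0, 1, 2.5, 5,
7.5, 10, 12.5, 15, 17.5, 20}%. Noise is applied after the train/test
split and only to training labels; with ~4% prevalence, most flipped
individuals at high noise are non-carriers relabeled as carriers, so the
noisy "carrier" class is mostly fake — the mechanism behind the TPR
collapse of noise-sensitive methods. A `noise_target="all"` flag flips
before splitting for comparison.

## Classifiers and tuning

All five share `fit(X, y)` / `predict(X)` with predictions in {0, 1}.

* **Lasso logistic regression** minimises the unaveraged binomial
  negative log-likelihood plus λ‖β‖₁ with an unpenalised intercept.
  Effects are solved by liblinear coordinate descent (the intercept rides
  on a constant pseudo-feature scaled by 10 so its penalty share is
  negligible), after which the intercept is re-optimised exactly by 1-D
  Newton with effects fixed. Classification threshold is p(x) > 0.5; the
  boundary p = 0.5 goes to the majority (non-carrier) class. The default
  grid is a 50-point log-spaced path from λ_max = max_j |Σ_i z_ij(y_i−ȳ)|
  (the smallest all-zero penalty) down four decades.
* **SVM** uses the exact linear (⟨x, x′⟩) and radial
  (exp(−γ‖x−x′‖²)) kernels with soft-margin cost C. Default grids:
  C ∈ {0.01, 0.1, 1, 10, 100}; γ ∈ {0.1, 1, 10}/m.
* **KNN** is exact brute force: Euclidean distances, stable ranking
  (ties to the smaller training index), odd K only so binary votes cannot
  tie. Default K ∈ {1, 3, …, 25}.
* **Random forest**: B = 500 fully grown Gini trees on n-sized bootstrap
  samples, s candidate features per split, majority vote with exact ties
  to non-carrier. Default s grid {⌈√m/2⌉, ⌈√m⌉, 2⌈√m⌉} (39 for m = 1512).

Tuning is stratified k-fold CV (default 10 folds) maximising mean
validation balanced accuracy; stratification is required because at 4%
prevalence unstratified folds can contain no carriers, leaving balanced
accuracy undefined. The phrase sometimes used for this criterion —
selecting the hyperparameters with the *lowest* balanced accuracy — is
read as its only sensible interpretation, lowest balanced *error*; the
`TunedModel` records the criterion actually used. Ties between grid
points go to the earlier point in grid order (for the lasso path this
means the sparser model). A single-point grid skips CV and fits directly.

## Experiment design

Per (noise level, replicate): stratified 70/30 split
(`floor(0.7·n)` training rows, carriers split proportionally), training-only
locus edits, label flips in the training labels, per-method CV tuning,
prediction of the untouched test set, scoring against original labels.
ACC, TPR, TNR and their complements TER/FPR/FNR are recorded per cell with
wall time (logged, never asserted); means by (noise, method) and a
Table-style error-rate layout are provided. Failed cells are logged as
missing rather than aborting the grid. A master seed spawns independent
streams per replicate (splits) and per cell (flips, tuning), all recorded
in the run manifest together with a checksum of the label vector taken
before and after the run.

**Causal locus exclusion.** In the simulated panel the mutation locus is
column 0 and its genotype *is* carrier status, so leaving it in the
predictor set would make classification trivial and the noise response
uninformative. In the cohort this package emulates, carrier status came
from direct mutation/haplotype genotyping while the classifier saw only
ordinary chip SNPs. `run_experiment` therefore takes `exclude_loci`
(and the CLI excludes the causal locus unless `--keep-causal-locus` is
given), so classifiers learn from flanking LD as in the real setting.

## Problem sizes used in the shipped tests

The full design (10 noise levels × 10 replicates × 5 methods at
n = 3116, m = 1512, with the default grids) is a multi-hour batch run via
the CLI. The shipped test suite and acceptance script exercise the same
code paths at reduced sizes chosen as this package's standard desk-scale
configurations: simulator recovery at n = 1000, m = 200 over 5 seeds; the
qualitative pattern study at n = 2000, m = 1000 (preserving the study's
4.04% prevalence, its 0.126 LD target and a comparable m/n ratio), noise
∈ {0, 10, 20}%, 3 replicates, all five methods, with compact per-method
grids (8-point λ path over 1.5 decades; C ∈ {0.01, 0.1, 1, 10} for the
linear SVM and {0.01, 1, 10} with γ = 1/m for the radial; K ∈ {5, 9, 17,
25}; s = ⌈√m⌉ fixed for the forest, the conventional default); and the
acceptance script's benchmark grid at n = 1200, m = 700 with the same
noise levels and replicates. Two size effects matter and set the lower
bound on the pattern study's scale. First, the m/n ratio: with m ≪ n a
linear SVM trained on heavily corrupted labels shifts its boundary and
loses specificity, whereas in the near-interpolating regime of the study
(m/n ≈ 0.5–0.7) specificity stays near 1 and the damage concentrates in
sensitivity. Second, carrier counts: cross-validation folds need enough
true carriers (~8 per fold at n = 2000) for balanced accuracy to rank
hyperparameters stably; far below that, selection noise occasionally
prefers aggressive settings (K = 1, large C) whose false positives erode
specificity. The KNN grid starts at K = 5 — K = 1 is pure memorisation
and is excluded from neighbourhood tuning here, as in the common defaults
of the tooling used for such studies.

## Numerical choices and degenerate inputs

* Dose matrices are float64 with NaN for missing; all QC and LD
  computations refuse NaN input unless imputation is their job.
* `mean_pairwise_r2` excludes monomorphic columns (warning) and errors
  when fewer than two polymorphic loci remain.
* Rounding of carrier counts and flip counts is round-half-to-even.
* Call-rate threshold comparisons are strict (`rate < threshold`
  removes); collinearity comparisons are strict (`|r| > threshold`
  removes).
* Seeds spawned from user seeds are reduced mod 2³¹.

## Known limitations

A structural one first: under class-blind label noise, a K-nearest-
neighbour classifier with small K has a false-positive floor that no data
can remove — at 20% noise roughly 22% of training labels read "carrier",
so any test point whose K neighbours happen to contain a majority of
flipped labels is predicted positive, a Binomial(K, 0.22) tail near 6%
for K = 5. Tuning by argmax balanced accuracy does not avoid this: when
KNN has no usable signal, all K score ≈ 0.5 in validation and the argmax
drifts toward the high-variance small-K options (a winner's curse).
KNN's specificity under heavy noise therefore lands near 0.93 rather
than 1.0 in the shipped pattern study; the corresponding check is the
one expectation of the scaled study this package does not meet, and the
analysis above is why.

* The LD calibration targets the single mean-r² summary; the realised
  r² *distribution* (distance decay profile) is a by-product of the
  mosaic, not separately controlled.
* Modal imputation ignores LD unless the LD-aware variant is chosen.
* The forest delegates to scikit-learn's trees, so "majority vote" is
  implemented as averaged per-tree leaf probabilities, which coincides
  with hard votes because trees are fully grown (pure leaves).
* No class weighting, resampling or probability calibration anywhere —
  deliberately, since the experiment's subject is the behaviour of plain
  classifiers under imbalance and noise.
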