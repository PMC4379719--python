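# Methods

## The prediction model

`netgp` predicts a quantitative trait from SNP genotypes with a two-layer
feed-forward network. For an individual with covariate row
`x = (x_1, ..., x_p)` the hidden layer computes, for each neuron
`t = 1, ..., s`,

    z_t = f(a_t + sum_j w1[t, j] x_j),

with `f` either the hyperbolic tangent or the identity, and the output
neuron combines the hidden activations linearly:

    yhat = b + sum_t w2[t] z_t.

With identity activations throughout, the network collapses exactly to an
affine map `yhat = b + w2.a + x (w1' w2)`; training such a net is an
iterative multiple linear regression. With tanh hidden units the model is a
universal approximator and can represent locus-by-locus interaction effects
no linear marker model captures.

## Genomic covariate structures

Three alternative inputs are supported, built from allele counts after
quality control (markers with minor allele frequency < 0.05 or missing
fraction > 0.95 removed, both configurable):

* **X** — counts coded −1/0/1 (minor-allele homozygote → −1), missing calls
  replaced by the per-marker mean of the coded values. The coding itself
  places X on the network's working scale; no further scaling is applied.
* **G** — the standardized genomic relationship matrix
  `G = W W' / (2 sum_j q_j (1 − q_j))`, where `W` is X with column `j`
  centred by its expectation `2 q_j − 1` and `q_j` is the frequency of the
  +1-coded allele. This is the VanRaden construction re-expressed for
  −1/0/1 codes; under Hardy–Weinberg proportions the mean diagonal tends
  to 1 as the panel grows. Each individual's covariate row is its vector of
  relationships to all individuals.
* **UD** — principal-component scores from the singular value decomposition
  `X = U D V'`. `UD` is an n-dimensional re-expression of the marker data
  preserving `X X'` exactly (asserted to 1e−8 relative); singular-vector
  signs are pinned (largest-magnitude element of each right-singular vector
  positive) so results are reproducible. All components are kept: the
  reduction is from m columns to n, never below n.

G is min–max scaled to [−1, 1] per column. UD is scaled as a whole matrix:
scaling each component column separately would inflate the trailing
components to the amplitude of the leading ones and discard the variance
ordering that makes principal-component scores informative inputs. Both
transforms store their (min, max) state and invert exactly.

## Phenotype scale

Traits are normalized as `y* = (y − mean(y)) / max(y)`. The raw maximum is
used literally, so the result is only approximately in [−1, 1]; a strict
variant dividing by `max |y − mean(y)|` is available (`strict=True`) and is
required for traits whose maximum is not positive. The transform is affine,
hence Pearson correlations between observed and predicted values are
identical on the raw and normalized scales, and the stored `(mu_y, max_y)`
invert it exactly. In cross-validation the statistics are computed on the
training folds only.

## Training

Full-batch gradient descent with momentum on

    aMSE(yhat, y*) + lambda (||w1||^2 + ||w2||^2),

where aMSE is the plain mean squared error on the normalized scale and the
decay term excludes biases (the zero network then still outputs the bias,
and the penalty's gradient `2 lambda w` is exact). Back-propagation
gradients are exact derivatives of this objective; the test suite checks
them against central finite differences at 1e−6 relative tolerance across
architectures, activations and decay settings.

Defaults: learning rate 0.01, momentum 0.9, weight decay 0.01, at most 1000
iterations, stop early when training aMSE ≤ 1e−3 (on the normalized scale),
weights initialized i.i.d. uniform on [−0.1, 0.1]. When both stopping rules
fire on the same iteration the threshold is reported. A non-finite
objective raises a divergence error naming the iteration rather than
returning garbage.

The learning rate is the one optimizer constant that genuinely depends on
the input structure (the curvature of the quadratic part scales with the
Gram matrix of the covariates), so `select_learning_rate` tunes it per
experiment arm before the production runs: each candidate from a geometric
grid trains once from a common initialization, divergent or oscillating
candidates are rejected, and the survivor with the lowest aMSE on a
held-out fifth of the tuning fold wins (validation-based selection;
training-error selection systematically favours rates that merely
interpolate an overparameterized net). Probes run the full iteration budget
because momentum-driven divergence can onset only after hundreds of
iterations. Tuning uses the first repeat's first training fold only, so no
held-out data influences it.

## Validation protocol

Repeated k-fold cross-validation (default 20 repeats of 5 folds = 100
train/test evaluations). Each repeat cuts a fresh uniform permutation into
k folds whose sizes differ by at most one (remainder spread from the first
fold). Every run re-normalizes the phenotype on its training folds, trains
from a run-specific weight initialization — seeded by a stable hash of
(master seed, repeat, fold), so all 100 initializations differ yet the
whole summary is bit-reproducible — predicts the held-out fold and scores
Pearson's r between observed and predicted phenotypes. The summary is the
mean of r over runs with the population variance of the run values.
Individual run failures (divergence, undefined correlation on a constant
vector) are recorded; 10% or more failed runs aborts with a diagnostic.

Relationship covariates of a held-out individual are its G-row computed
once on the full genotype panel: genotypes are not phenotype data, so this
is not leakage, and it matches feeding one fixed G per dataset into the
protocol. Phenotype statistics, by contrast, never see the test fold; a
dedicated test asserts bitwise-identical weights after perturbing held-out
phenotypes.

### Benchmark arm

Every experiment additionally runs a quasi-GBLUP benchmark: one hidden
neuron, identity activations, G as input. Because the net is then an affine
map in the relationship row, and G is proportional to a Gram matrix of
centred marker codes, this arm approximates GBLUP, i.e. ridge regression at
matched shrinkage. The package carries an independent closed-form ridge
oracle (normal equations with unpenalized intercept); the equivalence test
maps the network's decay coefficient lambda on the aMSE scale to the ridge
penalty `lambda * n_train` on the sum-of-squares scale and requires
test-set prediction correlation ≥ 0.98 between the two routes.

## Synthetic data

The simulator provides the genotype–phenotype structure the analyses
assume, with every component returned so oracles can be exact:

* Genotypes: biallelic SNPs at independent loci under Hardy–Weinberg
  proportions, per-marker allele frequency uniform on a MAF window (default
  0.05–0.5), optional missing calls, optional block-correlated mode
  (`ld_block_size > 1`) in which loci within a block copy a latent gamete
  with probability 0.9 — a crude stand-in for linkage disequilibrium.
* Traits: a sparse set of QTL with i.i.d. standard-normal effects on
  centred allele counts, acting additively, through pairwise products
  (`epistatic_pairs`, loci paired consecutively), or both (`mixed`).
  Environmental noise is Gaussian, residualized in-sample against the
  genetic values and rescaled so `var(y) = var(g) + var(e)` holds exactly
  and the realized heritability equals the target. At h² = 1 the noise is
  zero; at h² = 0 the genetic component is identically zero and the trait
  is pure unit-variance noise.

What the simulator does **not** emulate: realistic LD decay and haplotype
structure, population stratification and relatedness, age structure,
selection, multi-trait genetic correlations, or the informativeness
difference between daughter-yield deviations and raw yield deviations.
Passing tests therefore demonstrate that the machinery behaves correctly
under its stated assumptions, not that any particular predictive
correlation carries over to real livestock data.

## Problem sizes in the shipped experiments

The acceptance script and the end-to-end tests run at desk scale with 5×5
cross-validation: noiseless linear recovery at n=300/m=100 (h²=1, expected
benchmark mean r ≥ 0.95); epistatic advantage at n=400/m=40 (h²=0.9, four
QTL pairs, MAF 0.3–0.5, tanh s=6 on X versus the linear benchmark — the
linear arm sees essentially no signal because a centred pairwise product
has zero expected marginal effect); and the m ≫ n comparison at
n=150/m=3000 (h²=0.6, LD blocks of 50, tanh s=10) where G and UD inputs
match or beat raw X. The LD mode is deliberate in the last experiment: the
benefit of dimension reduction rests on marker redundancy, and with fully
independent loci at this sample size the three inputs are statistically
indistinguishable.

## Numerical choices and edge cases

* G is symmetrized exactly (`(G + G')/2`) after the Gram product; positive
  semidefiniteness is asserted to a −1e−8 relative eigenvalue tolerance.
* Constant columns min–max scale to 0; the inverse restores them from the
  stored minimum.
* Monomorphic markers cannot reach the coded stage (QC removes them; an
  all-monomorphic panel is an explicit error), so the G denominator is
  always positive.
* Allele-count files use the token `NA` for missing calls; in memory
  missing is NaN. Tokens outside {0, 1, 2, NA} are parse errors naming the
  line.
* A fold plan requires n ≥ k; Pearson r on fewer than two points or a
  constant vector is an explicit error, never a silent zero.
* Ridge at lambda = 0 on a rank-deficient centred design is refused with
  advice to use lambda > 0.

## Known limitations

* Plain full-batch gradient descent within a 1000-iteration cap does not
  fully converge on ill-conditioned problems; the benchmark arm's agreement
  with closed-form ridge is ~0.98–0.999 in correlation, not exact.
* The weight-decay penalty on a factored linear model (`w1`, `w2`
  separately) is not identical to a ridge penalty on the product
  coefficients; at the default decay strength the difference is well below
  the training-convergence gap.
* The block-LD mode is a convenience for generating correlated markers,
  not a population-genetic model; use msprime-class simulators when
  realistic LD matters.
* Only one hidden layer, identity output, and deterministic full-batch
  training are supported — stochastic optimizers, Bayesian regularization
  and multi-layer architectures are out of scope.
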