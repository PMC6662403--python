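# Methods

## Specialization as inequality

Each species is described by bundles of binary traits (a category is used,
1, or not, 0). Within a bundle of n traits the specialization index is the
Gini coefficient of the trait vector,

    G = Σᵢ Σⱼ |xᵢ − xⱼ| / (2 n² x̄),

computed via the equivalent sorted form Σᵢ (2i − n − 1) x₍ᵢ₎ / (n² x̄).
For binary data the uncorrected maximum is (n−1)/n, reached by a one-hot
row; the default is therefore the bias-corrected variant G·n/(n−1), whose
range is exactly [0, 1] and whose anchors are interpretable: 0 = even use of
every category (generalist), 1 = a single category (specialist). The
uncorrected variant remains available via `corrected=False`.

An all-zero row within a bundle leaves the index undefined (x̄ = 0); it is
treated as a hard validation error rather than silently emitting NaN,
because it almost always indicates a data problem (a species with *no*
recorded diet category, for example). An all-zero *column* is only a
warning: the index is defined, the column is just uninformative.

The **overall index** aggregates a species' bundle indices (mean by
default; max and min are available — max is the natural choice when a
single extreme specialism should dominate the assessment) and min–max
standardizes the aggregate across the species set, so the output always
spans [0, 1] regardless of the aggregate's raw range. Each aggregate is
standardized separately; rankings are unaffected by the standardization.
Which bundles enter the aggregate is an explicit parameter, since strongly
correlated bundles (e.g. two seasonal variants of the same diet traits) are
usually collapsed to one before aggregating.

`classify` labels species specialist/generalist by a user-supplied cutoff
on one bundle's index. There is deliberately no default cutoff: any value
would be arbitrary, and the choice materially changes specialist counts.

Associations among indices use Spearman's rank correlation (specialization
indices are generally non-normal — a Shapiro–Wilk p-value per index is
reported alongside). p-values are two-sided: the t-approximation for
n > 10, exact enumeration of all rank permutations for n ≤ 10.

## Trees

Input trees (Newick or Nexus) are taken as rooted as written; explicitly
unrooted input is rejected rather than silently midpoint-rooted, because
Blomberg's K depends on the root. Tip labels are normalized by trimming
whitespace and converting spaces to underscores, the usual Newick
convention, so trait-table species ids and tip labels match without manual
editing.

The 50% majority-rule consensus of a tree sample keeps exactly the clades
whose frequency across the sample is *strictly greater* than the threshold
(default 0.5; configurable up to 1.0). Strict majority guarantees retained
clades are pairwise nested-or-disjoint, so assembly cannot conflict; a
clade at exactly 50% is excluded. A retained clade's branch length is the
mean of that edge's length over the trees containing the clade (trees
lacking it contribute nothing); tip edges get mean tip-edge lengths. The
mean is computed over sorted values so the consensus is bit-identical under
reordering of the input file. Consensus polytomies are retained as-is —
the covariance matrix is well defined on polytomies and resolving them
with zero-length edges would only make it singular.

The phylogenetic covariance matrix C (Cᵢⱼ = root-to-MRCA depth, Cᵢᵢ =
root-to-tip depth) is computed by a single post-order traversal. Patristic
distances are taken from dendropy's path-length machinery and are checked
against the identity D = diag(C)1' + 1·diag(C)' − 2C in the tests, so the
two matrices come from genuinely independent routes.

## Phylogenetic signal

Blomberg's K is implemented from its definition:

    â    = (1'C⁻¹1)⁻¹ (1'C⁻¹x)             GLS phylogenetic mean
    MSE0 = (x − â)'(x − â) / (n − 1)        (K)
    MSE0* = (x − x̄)'(x − x̄) / (n − 1)       (K*, arithmetic mean)
    MSE  = (x − â)'C⁻¹(x − â) / (n − 1)
    E[MSE0/MSE] = (tr C − n/(1'C⁻¹1)) / (n − 1)
    K    = (MSE0 / MSE) / E[MSE0/MSE]        and K* analogously.

The two variants differ only in how the numerator is centred; on data they
are typically near-identical, and they coincide exactly on a star tree,
where the GLS and arithmetic means agree. With C = I both equal 1 for any
non-constant trait — a useful analytic identity that the tests assert to
1e−10. K is invariant to affine transforms of the trait and to rescaling
all branch lengths by a constant. A constant trait vector has no variance
to partition; K = 0 is returned with a `degenerate` flag. A singular C
(duplicate tips, zero-length terminal branches) is an error; no automatic
jitter is applied, because silently perturbing branch lengths changes the
statistic.

Significance uses the standard permutation scheme: trait values are
shuffled across tips, the GLS mean-squared error is the test statistic
(signal = smaller GLS error than random tip assignment), and the one-tailed
add-one estimator p = (1 + #{MSE_perm ≤ MSE_obs}) / (n_perm + 1) avoids
p = 0. Because the total trait variance is permutation-invariant, this is
exactly the upper-tail test on the permuted K* distribution, and the same
p-value is reported for K and K*; the default is 999 permutations, and the
permuted statistics are evaluated as batched quadratic forms from one
Cholesky factorization. All stochastic routines take explicit seeds and
record them in their outputs.

Moran's I follows the usual cross-product form
I = (n/S₀)·z'Wz / z'z with z = x − x̄. The phylogenetic correlogram splits
the patristic-distance range into equal-width classes (binary weights per
class) and computes I per class; 95% CIs come from bootstrap resampling of
tips, applying the same resampled indices to the trait vector and the
distance matrix and zeroing the weights of zero-distance duplicate pairs.
A class is significantly positive (negative) when its lower (upper) CI
bound clears the permutation-null expectation E[I] = −1/(n − 1). Empty
distance classes are reported as missing with a warning rather than
silently dropped. The number of classes is a tunable (default 10); for
small trees fewer classes are advisable — equal-width bins over the
distances of a ~64-tip pure-birth tree already leave long-distance bins
empty at 8+ classes, and the analyses in the test suite use 4–5 classes at
that size.

## Synthetic data

The generator exists so every statistic is testable with known ground
truth.

* **Trees** are pure-birth (Yule): starting from the root split, the
  waiting time while k lineages exist is Exp(k·λ) (λ = birth rate, default
  1), with one further Exp(n·λ) stretch after the n-th tip appears, giving
  expected root-to-tip depth Σ_{k=2..n} 1/(kλ). Trees are ultrametric and
  binary — a plausible stand-in for a dated supertree sample, not a model
  of any particular posterior.
* **Continuous traits** evolve by Brownian motion (root 0, increments
  Normal(0, σ²·branch length)), so tip values have covariance σ²·C — the
  regime in which K is expected to average 1.
* **Binary trait tables** draw each species' number of used categories in a
  bundle of n traits as m = 1 + Binomial(n − 1, 1 − s), where s ∈ [0, 1] is
  the bundle's specialization target: s = 1 gives one-hot rows (corrected
  Gini exactly 1), s = 0 all-ones rows (Gini 0), with a monotone gradient
  between, and never an all-zero row. The 1s are placed uniformly at
  random.

What the generator does *not* emulate: correlated evolution between
bundles, discrete trait evolution on the tree (trait tables are drawn
independently of the phylogeny unless the user couples them), birth–death
extinction, or posterior tree-sample heterogeneity. Passing tests therefore
demonstrate the statistics' correctness and calibration, not that any
particular empirical dataset will show signal.

## Problem sizes and numerical choices

The statistical checks in the test suite use the sizes at which the
properties are stated: Gini and Moran's I oracle equivalence on ~1,000
random vectors (tolerance 1e−12); K parameter recovery as the mean over
200 Brownian replicates on a 128-tip tree (band [0.9, 1.1]); permutation-
test calibration over 1,000 null replicates at n = 32 with 199 permutations
(type-I error 0.05 ± 0.02) and power over 200 Brownian replicates at
n = 64 (≥ 0.9); correlogram behaviour over 100 replicates at n = 64 with
100 bootstraps. The calibration loops reuse one fixed tree per loop with
fresh trait draws. An independent cross-check of K against the R package
phytools runs on a 16-tip fixture (agreement to 1e−6).

The pipeline (`ecospec run`) prunes tree tips without trait data (with a
logged warning) — trait coverage defines the study set — but a species with
traits and no tip is an error, since its indices could not enter the signal
analysis. All pipeline outputs are a pure function of (inputs, config,
seed), and a manifest with input hashes, versions and the seed is written
alongside them.

## Known limitations

* Binary traits only; percentage/continuous trait support (for which the
  Gini coefficient is arguably better suited) is not implemented.
* No alternative signal statistics (Pagel's λ, Abouheif's Cmean) and no
  Lorenz asymmetry coefficient.
* The correlogram is tabular (binned); no smooth-curve estimate.
* No tree download client; users supply tree files.
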