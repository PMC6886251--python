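# Methods

## Problem setting

A staged disease expression study provides a genes × samples matrix whose
columns carry an ordered stage label Q (here the CAG-repeat count of a
Huntington's-disease mouse model: 20, 80, 92, 111, 140, 175).  Only the
extremes are trustworthy class labels — Q20 animals are normal, the last
stage is unambiguously diseased — while intermediate stages are *weak*:
disease onset varies, so an intermediate sample may or may not express the
disease program.  Separately, a small panel of genes is known to be
disease-related or not.  The package (i) screens differentially expressed
(DE) genes using both strong and weak sample labels and (ii) classifies DE
genes as disease-related by comparing their stage-trajectory changes with
the known panel.

## ℓ2,1-regularized gene ranking

Stage 1 ranks genes with the multi-class objective

    J(W, b) = Σᵢ ‖Wᵀxᵢ + b − yᵢ‖²
            + (λ/2) Σᵢⱼ ‖Wᵀxᵢ − Wᵀxⱼ‖² Sᵢⱼ
            + γ ‖W‖₂,₁

over coefficients W (genes × classes) and intercept b, with yᵢ class
indicator columns and Sᵢⱼ = exp(−‖xᵢ−xⱼ‖²/t²) for same-class sample pairs
(0 across classes).  The second term is λ·tr(Wᵀ X L Xᵀ W) with graph
Laplacian L = D − S, pulling projections of similar same-class samples
together; the ℓ2,1 norm (sum of row norms) zeroes entire gene rows, and
genes are ranked by descending ‖wᵏ‖.

**Solver.** Iteratively reweighted least squares: the penalty is majorized
by γ·tr(WᵀD_wW), D_w = diag(1/(2·max(‖wᵏ‖, ε))), ε = 1e−10, and each sweep
solves the profiled normal equations exactly with the intercept eliminated
by centering (its exact minimizer given W).  Each sweep minimizes a
majorizing surrogate, so the recorded objective trace is nonincreasing (up
to O(γnε) smoothing slack).  When genes outnumber samples the solve runs
in the m-dimensional sample space via the Woodbury identity — an exact
algebraic rewriting, verified against the direct solve in the tests.
Stopping: relative objective decrease < 1e−6 (default) or 30 sweeps; the
first sweep uses D_w = I (a ridge start).

**Parameters.** λ = 1 and t = median pairwise training distance by
default.  γ defaults to the number of training samples m: the fit term is
a sum of m squared residuals, so a constant γ degenerates to vanishing
regularization as m grows, and with n ≫ m the near-interpolating solution
spreads weight onto uninformative genes.  Scaling γ with m keeps the
penalty commensurate with the data term across training-set sizes (the
screening loop grows its training set every round).  All four parameters
are exposed.

## Weakly supervised screening (two-label / single-label schemes)

Each round: (1) rank all genes on the current training samples (binary
normal-vs-disease indicator targets) and union the top M into the DE set;
(2) train a gradient-boosted tree classifier (100 trees, depth 3, seeded)
on the training samples restricted to the current DE genes; (3) classify
the remaining weak-stage candidates and permanently absorb those with
disease probability ≥ 0.5 into the disease class; (4) stop when the update
fraction |new genes| / |DE set| is ≤ θ, when nothing can change any more
(no candidates left and none absorbed), or after max_rounds (10).
Defaults M = 1500, θ = 0.05; the benchmark uses M = 200/500 at its 2000-gene
scale (M scales with the gene universe).  Re-ranking each round covers
*all* genes — the union absorbs duplicates — and the update fraction uses
new-over-current (a symmetric-difference variant is switchable), the
natural reading for a monotone union dynamic.

The two-label scheme screens twice — seeded on the late stage (Q175) and
the mid stage (Q111), both with weak stages Q140/Q92/Q80 — and intersects
the converged sets, keeping genes differential across distinct phases of
progression.  The single-label scheme seeds once on Q175 with all other
disease stages weak; it converges to a larger, less specific set, and the
package reproduces that ordering on synthetic data.

Open points resolved here: the in-loop classifier is retrained on DE genes
only (not all genes), and absorbed weak samples enter the binary disease
class regardless of which stage they came from.

## Difference space and difference kernel

For stage order Q₁ < … < Q_K, a gene's difference profile is
φ(x)ᵢ = m_{Qᵢ} − m_{Qᵢ₊₁} (i = 1…K−1), the adjacent changes of its
stage-group means; the difference kernel is k(a, b) = φ(a)ᵀφ(b).  Group
averaging over 32–48 samples suppresses per-sample noise by √n, and shared
offsets cancel, so two genes are similar iff their expression *moves* the
same way as disease progresses.  The kernel is a plain inner product in a
5-dimensional feature space, hence every Gram matrix is symmetric PSD.
The direction of differencing (earlier − later) only flips the sign of all
coordinates and leaves the kernel unchanged.  One upstream statement of
the kernel reads as a self-inner-product, k(xᵢ,xⱼ) = φ(xᵢ)ᵀφ(xᵢ); a
one-argument form cannot define a two-argument kernel, so the standard
φ(xᵢ)ᵀφ(xⱼ) is implemented.  The pipeline applies φ after per-sample
z-normalization, and performs the gene-view transposition (genes become
data points) exactly once, in the classify stage.

## Transductive SVM

`fit_svm` solves the soft-margin dual over a precomputed Gram matrix
(libsvm via scikit-learn, tolerance 1e−8, per-point box constraints via
sample weights); KKT conditions are asserted in the tests and the dual
optimum is cross-checked against an independent SLSQP solve.  Kernels
enter only as Gram matrices, so difference/linear/rbf are interchangeable
by configuration.  Slightly indefinite kernels are repaired by clipping
negative eigenvalues at zero (with a warning below −1e−8).

`fit_tsvm` is classical label switching: train on the labeled genes, label
the unlabeled so the top pos_fraction by decision value are positive
(pos_fraction defaults to the labeled positive fraction; ties broken by
gene order), then alternate retraining with swaps of +/− unlabeled pairs
whose hinge slacks sum above 2, ramping the unlabeled box constraint C*
geometrically from 1e−5·C to C.  Swaps preserve the positive count, so the
transduced class balance is enforced by construction.  All violating
disjoint pairs are swapped per retrain (the one-pair-per-retrain variant
is equivalent in fixed points but far slower).  Non-convergence after
max_outer retrains returns the best model with a warning flag.

## Evaluation

ROC curves sweep distinct scores (ties grouped); the trapezoidal AUC then
equals the Mann–Whitney U statistic over n⁺n⁻, which the tests assert.
PR curves use step interpolation and the AUPR is the conservative step
integral.  Cross-validation is stratified with a mandatory seed; TSVM
cross-validation treats each test fold as the unlabeled set (the
transductive setting) and scores transduced labels.  Baseline gene
selectors: across-sample variance, and a per-gene chi-square test of the
2×2 table of median-binarized expression against class (applied before
normalization, since the test assumes nonnegative data; the classical
contingency form is used, e.g. a (10,0 / 0,10) table scores 20).

## Synthetic data

The generator emulates the staged design: stage groups of 48, 32, 32, 32,
32, 32 samples; 2000 genes by default; log-scale expression = per-gene
baseline (uniform on 2–14, the dynamic range of real log2 expression)
+ planted stage shifts + Gaussian noise with unit sd scaled by a per-gene
lognormal(0, 0.5) dispersion multiplier (real genes differ strongly in
variability).  Planted DE families (100 genes each by default) shift
linearly with stage from family onsets: *shared* genes from the first
disease stage, *mid* from Q92, *late* from Q140, with per-gene magnitudes
uniform in [0.5, 1.5] × effect_size × noise-sd per stage step.  Half the
planted genes are flagged disease-related; these all shift in the same
direction, so their difference profiles correlate, while non-disease DE
genes take random directions.  The labeled panel (88 positive / 428
negative by default) draws positives from disease genes and negatives from
the rest.  A negative-binomial count mode (exponentiating the log means)
is available behind `mode="nb"`.

**Benchmark conditions.** The screening benchmark uses effect_size = 1.0
per stage step, 2000 genes, M ∈ {200, 500}, θ = 0.05; at this scale a
two-label run converges in 2–4 rounds in a few seconds, and 20 seeded runs
keep the acceptance suite within minutes.  The kernel-comparison benchmark
(`synth.kernel_benchmark_config`) uses effect_size = 0.25: per-sample SNR
≈ 0.25 leaves raw gene profiles dominated by baseline offsets and
dispersion noise, while 32–48-sample group averaging lifts the trajectory
signal well above the difference-space noise floor — the regime the
difference kernel is built for.  At effect 1.0 the cumulative ramps are so
large that any kernel sees them, which is a statement about the simulation,
not about the kernels.

**What the generator does not model**: count sampling depth, gene–gene
correlation beyond the planted trajectory families, batch effects, and
onset heterogeneity across animals within a stage.  Passing tests
therefore demonstrate correctness of the machinery and the claimed
qualitative orderings under the planted model, not performance on real
striatum data.  Note also that non-disease DE genes drifting in the same
direction as the disease program are intrinsically indistinguishable from
disease genes in difference space; they cap attainable precision on the
DE pool and are the realistic hard confusables.

## Numerical and degenerate-input conventions

Population (1/m) standard deviations everywhere; ranking ties broken by
ascending gene index; transduction ties by gene order; zero-variance
sample columns, one-class label sets, empty stages, and M > n_genes are
hard errors; the "unexpressed" filter reads "expression value of 0" as
all-zero across samples (an any-zero switch exists but would be
destructive for sparse data); per-sample normalization is z-scoring with
`none` and `quantile` alternatives; the variance filter keeps
min(n_genes, 10000) genes by default.
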