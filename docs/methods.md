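# Methods

## Model

Each CpG locus *g* contributes two counts per DNA sample: methylated
(Me) and unmethylated (Un) reads.  All 2*n* counts of a locus are
modeled as independent negative-binomial variables sharing one
dispersion,

    y_gi ~ NB(mu_gi, phi_g),    var(y_gi) = mu_gi + phi_g mu_gi^2,
    log mu_gi = sum_j x_ij beta_gj + log N_i,

where `N_i` is the effective library size (library size times
normalization factor) of column *i*.  The observation-level design has
*n* sample-indicator columns followed by *k* condition columns; the
condition block multiplies the sample-level design but is zeroed on the
Un rows.  Consequences that the package relies on and tests:

- Each condition coefficient is the natural-log ratio of expected
  methylated to unmethylated reads — a logit methylation level.  All
  reported values are rescaled to base 2.
- Inference about condition coefficients conditions on per-sample
  totals.  At `phi = 0` a likelihood-ratio contrast test is *exactly*
  the deviance test of a binomial logistic regression of Me on
  condition with size Me + Un (asserted to 1e-6 in the test suite).
- Any two sample-level parametrizations spanning the same column space
  (group means, intercept + treatment) give identical fitted values,
  LR statistics and contrast estimates.
- Because the offset enters only through the sample block, scaling all
  library sizes by one constant — or any per-sample rescaling — leaves
  LR statistics and p-values unchanged.  The only real constraint is
  that the Me and Un columns of one sample share one library size,
  which `equalize_pair_libsizes` enforces (average of the pair by
  default; the `sum` mode differs only by a factor of 2 and yields
  identical p-values).

## Fitting

Per-locus fits use damped Fisher scoring on the log link.  All loci
share one design matrix, so each iteration solves a batched p×p normal
system (`einsum` + batched `solve`); steps that increase the deviance
are halved (up to 40 times), and a ridge of 1e-12 × trace guards the
rare exactly-singular information matrix that arises when a block of
fitted means is driven to zero (e.g. a condition with no unmethylated
reads).  Convergence is declared when the deviance changes by less than
1e-10 (relative); the iteration cap is 100.  Loci that fail to converge
are flagged and keep their last iterate.

Counts of zero are legitimate and common; coefficients for them diverge
to -inf in the raw fit, which is harmless for deviances (they converge)
but useless for reporting.  Reported coefficients therefore come from a
second fit on augmented data: each observation gains
`prior_count * N_i / mean(N)` (default prior 0.125) and effective
library sizes grow by twice the scaled prior.  With equal library sizes
this adds exactly 0.125 to every count.  Raw fits are used for every
deviance and LR statistic; augmented fits only for reported (log2)
coefficients and log-fold-changes.

The likelihood-ratio test of a contrast matrix C constrains
`C' beta = 0` by refitting on `X @ null_space(C')`; since contrasts may
not touch sample columns, the coverage block survives the projection.
LR = deviance(null) − deviance(full), chi-square with df = rank(C);
p-values are upper-tail with no continuity correction; FDR is
Benjamini–Hochberg across loci.

`ave_log_cpm` uses the closed form
`log2(1e6 * (mean count + prior) / (mean lib size + 2 prior))` with
prior 2 — adequate for ranking and plotting, and it reproduces the
reference values on equal library sizes.

## Dispersion estimation

The Cox–Reid adjusted profile log-likelihood

    APL_g(phi) = loglik(y_g; mu_hat_g(phi), phi) - 0.5 log det(X' W X)

is evaluated on a 31-point log-spaced grid spanning [1e-4, 10]
(configurable), with fits warm-started along the grid.  In the
determinant, fitted means are floored at 1e-4 so degenerate blocks
cannot zero the determinant; the floor is constant in phi and does not
move the maximizer.  The common dispersion maximizes the summed APL,
with a quadratic interpolation of the grid maximizer.  No
abundance-dispersion trend is fitted: replicated BS-seq data show no
mean-dispersion relationship.

Tagwise (locus-wise) dispersions maximize the weighted likelihood
`APL_g + prior_n * mean_g(APL_g)` with `prior_n = prior_df /
residual_df`.  When not supplied, prior_df comes from a
method-of-moments estimator evaluated at the common maximum: with
`s_g` and `I_g` the first and negated second derivatives of APL_g with
respect to log phi (finite differences on the grid), homogeneity of
dispersions implies `E[s_g^2] ~= I_g`, while heterogeneity with
variance tau^2 on the log scale inflates it to `I_g + tau^2 I_g^2`.
Hence `tau2 = max(0, (sum s^2 - sum I)/sum I^2)`; `tau2 = 0` maps to
prior_df = inf (all tagwise equal the common value), otherwise
`prior_df = residual_df / (tau2 * mean I)`.  This estimator is the
package's own pinned variant — it is validated by its operating
characteristics (homogeneous simulations give prior_df ≥ 20 in ≥ 90% of
seeded replicates; a low/high dispersion mixture gives finite prior_df
and tagwise values separating the two groups), not by bit-equality with
any external implementation.

## Pipeline conventions

- **Coverage filter**: default keeps loci with Me + Un ≥ 8 in every
  sample (boundary inclusive); promoter-level objects conventionally use
  ≥ 10.  Library sizes are recomputed after any row subset.
- **Nearest-TSS annotation**: the assigned gene minimizes |TSS − pos| on
  the same chromosome; equidistant ties go to the gene earlier in the
  user-supplied table.  The signed distance is transcription-oriented:
  `tss - pos` on plus-strand genes, `pos - tss` on minus-strand genes,
  so positive always means the TSS lies downstream of the CpG.
- **Promoter windows**: "2 kb upstream to 1 kb downstream" therefore
  selects distances in [-1000, +2000] (both ends inclusive).
  Aggregation sums counts per gene over the *unfiltered* locus set
  restricted to windows; gene-total filtering comes afterwards.
- **M-values**: `log2(Me + 2) - log2(Un + 2)`; antisymmetric under
  swapping Me and Un.
- **MDS**: the distance between two samples is the root-mean-square of
  the `top` (default 500) largest |M| differences for that pair —
  selection is pairwise, not a common set; ties at the cutoff break by
  locus order.  Coordinates are classical Torgerson MDS (double
  centering + eigendecomposition); axis signs are arbitrary.
- **TSS profiles**: lowess with tricube weights, 3 robustness
  iterations, span 0.3, after restricting to |distance| below a caller
  chosen window; fewer than 10 points is an error.

## Rotation gene-set tests

Per-locus z statistics are signed square roots of the LR statistics
(signed by logFC), asymptotically N(0, 1) under the null.  For a set
with weights w the directional statistic is `w'z / ||w||` and the mixed
statistic is `mean(z_set^2)`.  The null is generated by random rotations
of the whole z vector: a rotated vector is uniform on the sphere of
radius ||z||, so the set's rotated coordinates are sampled as
`||z|| * d_set / sqrt(||d_set||^2 + Q)` with d standard normal and
`Q ~ chi2(G - m)` carrying the rest of the squared norm.  Using the
observed ||z|| as the scale keeps the test self-contained: a globally
inflated or deflated z scale calibrates itself.  Directional p-values
are two-sided tails (a Direction column carries the sign), computed as
`(1 + #extreme) / (B + 1)` over B rotations (default 9999, seeded);
`n_rotations=0` switches to a documented normal / chi-square
approximation valid for large G.  Negating all weights flips Direction
and leaves the two-sided p unchanged; scaling weights by a positive
constant changes nothing.

The methylation-vs-expression analysis joins per-gene methylation
log-fold-changes to expression log-fold-changes, drops genes without
expression results, and fits least squares through the origin:
slope = Σxy/Σx², with n − 1 residual df for the t test.  The barcode
plot data ranks genes by expression statistic, splits methylation
weights by sign into two bar tracks, and computes each track's
enrichment worm as a boundary-corrected Gaussian-kernel density of the
|weight|-carrying rank positions divided by the uniform expectation
(flat worm at 1 = no enrichment).

## Synthetic data

`simulate_experiment` draws, for locus g in sample i of condition c,

    me ~ NB(c_i * p_gc, phi),    un ~ NB(c_i * (1 - p_gc), phi),

independently with one shared dispersion — exactly the model the
pipeline assumes.  Defaults describe a realistic replicated RRBS
comparison: 2 groups × 3 replicates, mean coverage 30 reads per CpG,
dispersion 0.0275 (the magnitude estimated from replicated mammary
RRBS data), per-locus baseline logits N(0, 1.5²) on the base-2 scale
(most loci between 10% and 90% methylation), 10% of loci shifted by 2
base-2 logit units in the second group (alternating sign unless
`effect_direction` says otherwise), and per-sample log-normal coverage
factors with sigma 0.3 emulating unequal sequencing depth.  Positions
are drawn with uniform gaps along configurable chromosome lengths.

What the generator does *not* emulate: bisulfite conversion failure,
SNP interference, strand effects, spatial correlation of methylation
along CpG islands, and the bimodal genome-wide methylation landscape.
A green end-to-end test therefore establishes correct statistical
behavior under the model's own assumptions — FDR control and power on
real data additionally depend on those unmodeled features.

## Numerical and scope notes

- All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds reproduce experiments byte-for-byte.
- Serialized experiments are directories of plain TSVs (counts, loci,
  samples) — human-readable and diff-friendly.
- Out of scope: read alignment and methylation calling, TMM
  normalization (not required for BS-seq), de-novo DMR discovery,
  quasi-likelihood F tests, and figure styling (functions return
  plot-ready tables, not graphics).
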