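# Methods

## Model

Quasi-UMI normalization treats each cell's gene counts as i.i.d. draws from
a two-parameter compound Poisson family — a Poisson count whose rate λ is
random under a continuous prior:

    P(X = x) = ∫₀^∞ λ^x e^{−λ} / x!  f(λ) dλ

Supported priors and their (shape, scale) parameterizations:

| family   | prior      | shape                  | scale            | tail |
|----------|------------|------------------------|------------------|------|
| `plnorm` | lognormal  | σ (log-sd), σ > 0      | μ (log-mean), ℝ  | ~ lognormal (near power law over decades) |
| `plomax` | Lomax      | α (tail index), α > 0  | θ > 0            | true power law, heaviest |
| `negbin` | gamma      | size (dispersion) > 0  | mean m > 0       | exponential-order, lightest |

With prior mean m and variance v, the marginal mean is m and the marginal
variance m + v. For the Poisson-lognormal, m = exp(μ + σ²/2) and
v = (e^{σ²} − 1)m². For the Poisson-Lomax the moments exist only in
restricted regions: the mean θ/(α − 1) requires α > 1, and the variance
m + (α/(α − 2))m² requires α > 2, the coefficient following from the Lomax
prior variance θ²α/((α − 1)²(α − 2)); both are verified by simulation in
the tests. Tail heaviness (negbin < plnorm < plomax) is an asymptotic
property: at matched mean and variance the ordering of tail mass holds at
deep counts but **not** at moderate quantiles such as the 99.9% point,
where the matched Poisson-Lomax actually has *less* mass than the
Poisson-lognormal. The test suite therefore checks PMF ordering at counts
of 10⁴–10⁵.

## Normalization procedure

For each cell independently:

1. **Zero fraction → scale.** PCR amplification is multiplicative and
   cannot create counts for absent molecules, so the zero fraction of read
   counts equals that of the underlying UMI counts. With the shape fixed,
   the zero probability is strictly decreasing in the scale, and the
   method-of-moments scale estimate solves P(X = 0; shape, scale) = p̂₀ by
   Brent root-finding with geometric bracket expansion (positive scales are
   solved on the log scale); the residual |P(0) − p̂₀| is below 1e−8.
   Cells without zeros are not identified and are passed through with a
   warning unless an explicit scale override is supplied; all-zero cells
   pass through as zeros.
2. **Zero-truncated CDF table.** The log PMF is accumulated over support
   1..K with `logaddexp` and renormalized by 1 − P(0). K is the smallest
   value with truncated CDF ≥ 1 − 1/(2G) (G = number of nonzero genes), so
   the empirical quantile grid is fully resolved, capped at K = 10⁶ (top
   ranks then absorb into the final bin, with a warning).
3. **Rank matching.** Nonzero values are ranked with tied values sharing
   their *mean* rank; quantiles p = rank/G are mapped to the smallest
   support value whose truncated CDF reaches p (binary search; a 1e−9
   tolerance keeps quantiles that land exactly on a tabulated CDF value,
   up to float rounding, in that bin). The top distinct gene has p = 1 and
   lands in the final bin.

**Tie rule.** Mean ranks rather than maximum ranks: with maximum ranks a
tie group's quantile coincides with its own empirical CDF value, so
sampling noise flips entire groups into the neighboring bin about half the
time; mean ranks place each group mid-interval, which maximizes stability
of the value a tie group receives. For cells with all-distinct values the
two conventions agree. Even so, normalization of counts *already* drawn
from the target leaves roughly 90% (not 100%) of the sorted nonzero vector
unchanged at 2000 genes — multinomial fluctuations in tie-group sizes make
bin-boundary flips at moderate counts unavoidable.

`rescale_common_total` optionally rescales every cell to the median of the
original cell totals (for downstream methods that assume equal library
sizes); it is idempotent and exact to 1e−9 relative.

## Numerical evaluation of the PMFs

All likelihood work is in log space with log-sum-exp accumulation.

* **Poisson-lognormal.** After the change of variable λ = exp(μ + σz) the
  mixing integral becomes ∫ φ(z) Pois(x | e^{μ+σz}) dz. A fixed-order rule
  on a global grid fails for large σ²x, where the integrand spike has width
  1/(σ√x) in z; instead the strictly concave log-integrand's mode is found
  by damped Newton iteration (vectorized over counts) and a 201-node
  probabilists' Gauss-Hermite rule is applied after centering at the mode
  and rescaling by the Laplace width 1/√(−g″). Measured relative error
  against a dense brute-force oracle is below 1e−11 for x ≤ 1000 and
  σ ∈ [0.5, 4].
* **Poisson-Lomax.** Per count, the log-integrand in u = log λ (including
  the Jacobian) is again strictly concave; its mode is found by Newton
  iteration, the integration window is expanded until the integrand has
  dropped 60 nats on both sides, and a 1001-node composite Simpson rule is
  applied on that window (≈10³ quadrature points per evaluation; truncation
  error ~e⁻⁶⁰). Measured relative error is below 1e−11 on the same grid.
* **Negative binomial.** Closed form via `scipy.stats.nbinom`.

Sampling draws λ from the prior and then Poisson counts; rates are capped
at 1e12 to stay inside the Poisson sampler's range (relevant only for
Lomax tail indices well below 1).

## Fitting and calibration

Per-cell maximum likelihood uses the histogram of unique count values
weighted by multiplicity (identical to the per-gene sum; zeros included,
since they dominate and carry the scale information) and a Nelder-Mead
simplex over unconstrained transforms (log shape; μ free for `plnorm`, log
scale otherwise). Initialization: shape 2.0 and the MOM scale from the
cell's zero fraction (falling back to the log nonzero mean); at most 500
iterations; non-convergence and cells below 50 genes are flagged, never
raised. BIC is 2 ln(n_genes) − 2 loglik (two free parameters, natural log
throughout). `calibrate_shape` fits every cell, excludes non-converged
cells with a logged count, and returns the median shape MLE — the
recommended custom target shape when matched UMI training data exist;
otherwise the default shape is 2.0. The posterior-predictive check
simulates one vector per converged cell from its fitted parameters using a
per-cell substream (SeedSequence spawn key = cell index, so results are
independent of processing order) and reports ln(max simulated / max
observed), near zero for a well-calibrated tail.

## Synthetic data

The generator emulates the regime the method assumes, with defaults fixed
once: shape 2.0; per-cell scales uniform on (−4.57, −1.76), the MOM scales
at zero fractions 0.95 and 0.70 under shape 2, so zero fractions span the
range seen in real UMI data; amplification multiplies each nonzero entry by
an independent lognormal factor with mean 50 and log-sd 1 and rounds with a
floor of one read (zero-preserving, rank-distorting; single molecules
routinely yield > 100 reads). The optional DE design shifts the scale of a
random 10% of genes by a natural-log fold change of 1.0 in the second group
(half up, half down). Truth labels (scales, groups, DE mask) are always
returned.

Not emulated: per-molecule amplification (noise acts per gene-cell entry),
gene-length and GC bias, sequencing errors, ambient RNA, droplet
artifacts, and cell-to-cell correlation. Passing benchmarks on this
generator therefore show that the method inverts multiplicative,
zero-preserving rank distortion — the mechanism it targets — not that it
corrects those other artifacts.

## Evaluation metrics

* Per-cell accuracy: Euclidean distance between natural-log count vectors
  over genes nonzero in both matrices (zeros omitted; sparsity is preserved
  by the normalization, and disagreeing patterns trigger a warning and
  restriction to the common support).
* Gene statistics: mean and coefficient of variation (sample sd, n − 1)
  across cells.
* DE concordance: per-gene two-sided Fisher exact tests on pseudobulk 2×2
  tables [xₐ, Tₐ − xₐ; x_b, T_b − x_b] (gene's summed count vs the rest of
  the group's library; non-integer inputs rounded half-to-even), Holm
  adjustment (via statsmodels), and three distances between a
  normalization's results and the ground truth's: Manhattan on p-values,
  Kendall as the normalized discordant-pair count of the two rankings
  (ties count as neither concordant nor discordant; computed by mergesort
  inversion counting), and Jaccard between the Holm-significant gene sets
  (0 when both sets are empty).

**Caveat.** The pseudobulk Fisher test is exactly calibrated only when
counts are conditionally Poisson given the margins. Under strong gene-level
overdispersion (e.g. Poisson-lognormal with shape 2) it is anti-conservative
under the null — in one measured configuration 47% of null genes reached
p < 0.05. This is inherent to pseudobulk Fisher testing; the concordance
metrics remain meaningful because every normalization is subjected to the
same test, but absolute significance calls should not be over-interpreted.

## Problem sizes used in the checks

The quantitative test suite runs at desk scale, chosen to make each check
statistically decisive: quadrature accuracy on counts 0..1000 across seven
(family, shape, scale) settings; shape recovery on 100 cells × 2000 genes
per shape in {1, 2, 3} (median absolute error < 0.15); benchmark ordering
on a 3×3 grid of shapes × amplification noise with 25 cells × 2000 genes;
DE concordance over 20 replicates of 50 cells × 800 genes with 10% DE
genes (quasi-UMIs must beat raw reads on all three metrics in ≥ 90% of
replicates).

## Known limitations

* A single global shape per run; datasets whose cells vary in tail
  heaviness (as observed across experimental conditions in real data) are
  normalized with a compromise target, though accuracy degrades slowly
  with shape misspecification.
* Cells without zeros cannot be normalized without an explicit scale.
* Quasi-UMIs are not UMIs: capture/RT efficiency differences between cells
  are intentionally preserved (as with real UMIs) and should be handled by
  downstream count models.
* Poisson-Lomax fitting is numerically less stable than Poisson-lognormal
  (flagged via the `converged` field rather than raised).
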