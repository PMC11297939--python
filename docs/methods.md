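# Methods

## Multivariate ranks by optimal transport

Ordinary ranks have no canonical multivariate analogue; this package uses
the optimal-transport definition. Given observations X¹,…,Xⁿ ∈ ℝᵈ and a
fixed reference set 𝓗ₙᵈ = {h₁,…,hₙ} approximating the uniform distribution
on the unit hypercube, the empirical rank map is the permutation σ̂
maximising Σᵢ⟨Xⁱ, h_σ(i)⟩ (equivalently minimising total squared transport
cost), and R̂(Xⁱ) = h_σ̂(i). The assignment is solved exactly with
`scipy.optimize.linear_sum_assignment` on the negated inner-product cost
matrix; for n ≤ 7 the unit tests verify the optimum against exhaustive
enumeration of all n! permutations.

**Reference grids.** For d = 1 the grid is the exact lattice {i/n}, so the
rank map reduces to sorting (ties broken stably by original index — real
files can contain ties even though continuous models make them
measure-zero). For d > 1 we use the unscrambled Sobol' sequence with the
Joe–Kuo direction numbers as shipped by `scipy.stats.qmc.Sobol`. Scrambling
is off by default because a fixed point set makes every downstream score
bit-reproducible across machines; it can be enabled per call. The raw
sequence starts at the origin, which we drop (and we discard any later
point containing a zero coordinate) so the grid lies strictly in (0, 1]ᵈ.
Halton or (t,m,s)-net alternatives are deliberately not implemented.

**A consequence worth exploiting.** The rank map is always a bijection onto
the grid, so the self distance covariance MrDcov²(X, X) of any ranked
sample is a constant depending only on (n, d, grid kind). `grid_self_dcov2`
caches these constants; screening therefore computes only numerators per
feature, which is what makes p = 10,000 × 2,000-subgroup score tables
tractable.

## Rank distance correlation

For rank vectors R̂ˣ and R̂ʸ the squared rank distance covariance is the
plain V-statistic

    MrS₁ = n⁻² Σᵢⱼ |R̂ˣᵢ−R̂ˣⱼ| |R̂ʸᵢ−R̂ʸⱼ|,
    MrS₂ = (n⁻² Σᵢⱼ |R̂ˣᵢ−R̂ˣⱼ|)(n⁻² Σᵢⱼ |R̂ʸᵢ−R̂ʸⱼ|),
    MrS₃ = n⁻³ Σᵢⱼₗ |R̂ˣᵢ−R̂ˣₗ| |R̂ʸⱼ−R̂ʸₗ|,
    MrDcov² = MrS₁ + MrS₂ − 2·MrS₃,

with Euclidean norms in the respective dimensions and no bias correction
(the U-statistic variant is not provided). The implementation uses the
equivalent double-centered distance-matrix form; the O(n³) literal sums
survive as an independent oracle in the test suite, alongside an external
published distance-correlation implementation. Both matrices are centered
before the elementwise product so that swapping the arguments is exactly
symmetric in floating point.

The correlation is MrDc = MrDcov(X,Y)/√(MrDcov(X,X)·MrDcov(Y,Y)) ∈ [0, 1].
Degenerate denominators cannot occur for ranked data (grid points are
distinct); for the raw-data baseline `dcor`, constant input yields 0/0 and
the convention is to return 0 with a warning. Negative V-statistic values
above −10⁻¹² are clamped to zero; anything lower raises, since it would
indicate a genuine bug rather than roundoff.

Properties that hold exactly and are tested: MrDc(X, X) = 1; invariance
under strictly increasing transforms of 1-d margins; symmetry; bounds
[0, 1]; and distribution-freeness of the null distribution (Kolmogorov–
Smirnov two-sample check between Cauchy and Gaussian margins at n = 200).

## Screening, subgrouping and selection

A q-dimensional response is split into consecutive blocks of
`group_size = 5` columns (the last block may be smaller). Five is the
package default because the benchmark studies show marginal dependence
scores drown once a block carries more than a handful of noise
coordinates: with a single signal coordinate the screen is reliable up to
roughly q = 8 block width and degrades beyond it. Every predictor — an
(n, d) slice of the (n, p, d) platform tensor — is scored against every
block, giving a G × p table flattened row-major: position of (subgroup g,
predictor j) is (g−1)·p + j, 1-based.

**Max-ratio threshold.** Sorted scores ω̂₍₁₎ ≥ … ≥ ω̂₍J₎ are cut at
ŝ₀ = argmaxⱼ ω̂₍ⱼ₎/ω̂₍ⱼ₊₁₎. Two guardrails, both configurable: the search is
restricted to the top half of positions (j ≤ ⌈J/2⌉ — ratios between two
near-zero noise scores explode spuriously), and denominators below 10⁻¹²
end the search. Ties take the smallest j; an all-equal or strictly
geometric score sequence has no separable gap and selects 1 with a warning.

**Two summaries.** Scenario 1 applies one global cut to all G·p scores and
returns the selected (subgroup, predictor) pairs — strong, localised
associations. Scenario 2 cuts within each subgroup separately and
accumulates per-predictor selection counts and maxima across subgroups — a
predictor weakly associated with many response components shows a high
count with an unremarkable maximum (the pleiotropy signature). The final
scenario-2 gene call applies the max-ratio rule to the sorted counts by
default, with a `top_k` override, since no numeric rule is standard.

**Memory contract.** Distance matrices are built per chunk of 256
predictors and discarded; peak memory is O(chunk·n²) regardless of p.
Response-block matrices are computed once and reused across predictors
(`cache_response_ranks=False` recomputes them per chunk, yielding
bit-identical scores).

## Synthetic benchmarks

The generators emulate the stress factors of real multi-omics screening:
heavy tails (multivariate-t, df 1–3), strong serial predictor correlation
(AR(1), ρ = 0.8), nonlinear links, and a response that is almost entirely
noise. Rows are Z/√(W/df) with Z from the AR(1) Gaussian core (built by the
recursion Zⱼ = ρZⱼ₋₁ + √(1−ρ²)εⱼ via an IIR filter — Σ is never
materialised) and W ~ χ²_df. For df = 1 the margins are Cauchy, so "AR(1)
covariance" is to be read as the scale matrix of the Gaussian core; moments
do not exist.

* **study 1** (n = 200, p = 10,000, q = 1):
  y = β₁X₁ + β₂X₆ + β₃X₁₂² + β₄X₂₂ + ε, β ~ U(2,5), ε ~ t₁.
* **study 2**: y = β₁X₁ + β₂log|X₆| + β₃X₁₂² + β₄|X₂₂| + ε. The log is
  applied to |X₆| since the t₁ margin is real-valued.
* **study 3** (three platforms with df 2/1/3, q = 10,000 at full scale):
  response dims 1–12 are β₁X₂,ᵢd₁ + β₂X₄,ᵢd₂ + ε with β ~ U(4,5) and one
  platform id per predictor drawn from {1,2,3}; the rest is t₁ noise
  (12 signal among 9988 noise coordinates, a ratio of ≈ 0.0012). One (id₁, id₂, β₁, β₂) draw is shared
  by the 12 signal dims, matching the single pair in the model equation;
  `per_dim_platforms=True` redraws ids per dimension, the alternative
  reading in which different response components couple to different
  platform combinations.
* **study 4**: only Y₁ carries signal, from predictors {2, 4, 101, 102}
  (the last through a square link), β ~ U(1,2); q varies to trace the
  signal-to-noise decay.

Coefficients and platform ids are redrawn per replicate, and every draw is
recorded in the returned truth metadata, so evaluation never re-derives the
truth from data. All generators are bit-reproducible from (config, seed)
with `numpy.random.default_rng`; replicate seeds are spawned from
`SeedSequence`.

What the generators do **not** emulate: real platform marginals (mixed
discreteness, zero inflation, batch effects), realistic gene–gene
correlation structure beyond AR(1), or missingness. Passing benchmarks
therefore demonstrates robustness to tails/nonlinearity/weak SNR, not
end-to-end performance on any particular cohort.

## Evaluation metrics

S is the minimum model size: scores ranked descending (ties broken by
flattened position), S = the largest rank among the truth positions; a
grow-the-model loop oracle checks the arithmetic in the tests. P_s and P_a
are the per-truth and simultaneous inclusion rates at the cutoffs
s₁ = ⌊n/log n⌋ (37 at n = 200), s₂ = 2s₁, s₃ = 3s₁; P_a ≤ min P_s always.
Percentiles of S use linear interpolation (type 7), which is why reported
quantiles can be fractional.

## Problem sizes used by the shipped benchmarks

Studies 1–2 run at their original scale (n = 200, p = 10,000) with 25
replicates; study 3 is scaled to p = 1000, q = 100 (20 subgroups, truth at
flattened positions {2, 4, 1002, 1004, 2002, 2004}) with 20 replicates;
study 4 uses p = 1000 with q ∈ {2, 80} and 5 replicates per point. With
replicate counts in the tens, success rates carry ±0.15-scale Monte-Carlo
noise and model-size percentiles are stable only to about a factor of two;
the test tolerances reflect that.

## Preprocessing filters

Generic forms of the standard platform-hygiene rules, all order-preserving
and idempotent: prevalence (keep features with value > v in ≥ ⌈f·n⌉
samples, e.g. v=1, f=0.7 for RNA-seq counts; v=10, f=0.8 for miRNA RPM);
pooled-quantile (drop features whose maximum is below the 25% quantile of
all pooled nonzero values — interpolating quantile, our documented choice
where the convention is unstated); exact-duplicate removal (first feature
by input order wins). Multi-platform assembly intersects feature names and
sample ids, aligns rows by id, and stacks slices into the (n, p, d) tensor.

## Known limitations

* The max-ratio search-range guardrail (top half, denominator floor) is a
  documented package choice; the criterion's original source is not
  restated here and may differ in detail.
* No p-values or FDR control exist in this framework; the max-ratio cut is
  a gap heuristic, and under ρ = 0.8 predictor correlation it deliberately
  keeps signal-carrying neighbours of true predictors.
* The V-statistic estimators are biased upward at small n; comparisons
  across very different n should use the same estimator throughout.
* Sobol'-grid ranks depend on the direction numbers; other Sobol'
  implementations will produce slightly different (equally valid) scores.
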