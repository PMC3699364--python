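# Methods

## Problem setting

A heterogeneously differentially expressed gene (hDEG) shows high
expression in a small subset of the experimental samples only. The
non-outlier expressions — all controls plus the unaffected experimental
replicates — form a *tight cluster* whose spread is small relative to the
gap separating it from the outliers. Classical subset statistics (COPA, OS,
ORT, MOST, LSOSS) summarize the upper tail of the experimental group
against a robust location/scale estimate; they lose power when the outlier
subset is very small. DOG instead models only the tight cluster and tests
candidates sequentially, making no assumption about how the outliers
themselves are distributed.

## The DOG procedure

Per gene, with control vector x and experimental vector y, z = x ∪ y:

1. **Candidate split.** Cutoff = max(x) (default) or the r-th percentile ς
   of x (`mode="control_percentile"`, default r = 90) when the controls may
   be contaminated. z⁺ = ascending values strictly above the cutoff;
   z⁻ = the rest. Strict comparison follows the set definition of the
   candidate set; with continuous data the distinction is immaterial.
2. **Tight-cluster model.** z⁻ is modelled as i.i.d. N(μ, σ² = 1/β) with
   conjugate priors μ ~ N(μ₀, 1/β₀) and 1/β ~ InvGamma(a, b). The MAP
   estimate is found by cyclic coordinate updates in the order β → μ → β₀:

       1/β  = (Σ (zⱼ − μ)² + 2b) / (n + 2a + 2)
       μ    = (β Σ zⱼ + β₀ μ₀) / (β n + β₀)
       1/β₀ = ((μ − μ₀)² / 2 + b) / (a + 1)

   starting from μ = μ₀ = med(z⁻). Iteration stops when the largest
   absolute change in (μ, β, β₀) falls below 1e−10 (cap 1000 sweeps; the
   map is a contraction on finite data and converges in a few dozen sweeps;
   a cap overrun raises an error rather than returning silently).
3. **Sequential detection.** The smallest remaining candidate is tested
   with t = (z₁⁺ − μ)√β. If t ≤ t_α the candidate is *absorbed*
   (z⁻ ← z⁻ ∪ z₁⁺, refit, with β₀ carried over to the next fit); otherwise
   detection *terminates* and the whole remaining z⁺ is the outlier set
   (the candidates are ascending, so everything above the first significant
   gap is an outlier). M = |z⁺|; t-values of all detected outliers are
   reported against the final cluster fit, and the per-gene summary
   statistic is their mean (0 when M = 0). Averaging rather than summing
   keeps genes with one extreme outlier competitive with genes having many
   moderate ones.

### Hyperparameters

| parameter | default | meaning |
|---|---|---|
| α | 0.05 | tail probability of the detection test |
| a | 1 | inverse-gamma shape; small values keep the variance prior diffuse |
| b | max per-gene pooled sample variance (ddof = 1) of the analyzed dataset | inverse-gamma scale; "large b, small a" makes absorption permissive so only clear gaps fire |
| β₀⁽¹⁾ | 0.1 | initial prior precision on μ; updated recursively within a gene, reset per gene |
| r | 90 | control percentile for the contaminated-control candidate rule |

b is computed **once per dataset** over all analyzed genes, including any
simulated null panel when one is attached to the analysis; a shared noisy
gene therefore widens every gene's posterior, which is intentional — it
encodes "how variable can a gene in this experiment be".

### The critical threshold t_α

The detection test asks whether the smallest candidate is plausible as a
member of the tight cluster. Since the candidates sit, by construction, at
the top of the gene's empirical distribution, the relevant null reference
is the *maximum* of a cluster-sized Gaussian sample: t_α is the upper-α
quantile of max(Z₁, …, Z_n), i.e. Φ⁻¹((1−α)^{1/n}) with n the current
cluster size (≈ 3.14 for n = 60 at α = 0.05). This calibrates the per-gene
false-detection rate at ≈ α independently of the cluster size; a plain
upper-α normal quantile (1.64) would flag the top of almost every null
gene. The plain normal and Student-t (n − 1 df) thresholds remain available
through `DogHyper(t_dist=...)` for sensitivity analysis.

## Comparator statistics

All five use the pooled median λ and MAD scale σ = 1.4826 × med|z − λ|
(the Gaussian-consistency constant; deviations are taken in absolute
value). All percentiles, here and everywhere else in the package, use
linear interpolation between order statistics (h = (n−1)p + 1, numpy's
default) — one convention applied uniformly since none is mandated.

* **COPA** = (q_r(y) − λ)/σ, default r = 90 (the conventional COPA
  percentile; configurable).
* **OS** = Σ (yⱼ − λ)/σ over yⱼ > q75(z) + IQR(z); 0 when the set is empty.
* **ORT** = the same sum with the control-only threshold q75(x) + IQR(x).
* **MOST**: S_k = Σ over the k largest y of (y − λ)/σ; the statistic is
  max_k (S_k − m_k)/s_k where m_k, s_k are the null mean and SD of S_k.
  These constants are estimated once per (|x|, |y|) by seeded Monte Carlo
  (2000 standard-normal pseudo-datasets) and cached; no closed form is
  available for the order-statistic moments after median/MAD
  standardization. Subset sizes with zero null SD are excluded with a
  warning.
* **LSOSS**: the sorted y is split into top-k and rest with k minimizing
  the total within-group sum of squares (k = 1 … |y|−1); the statistic is
  k(ȳ(k) − x̄)/S with S the pooled SD (df = n₁ + n₂ − 2) of
  {controls ∪ non-outlier experimentals} versus {top-k}. Note the split
  always takes the *top* subset: genes whose outliers lie below the
  controls score near the null level rather than strongly negative.

## Significance

Two empirical null constructions:

* **Simulation panel** — the statistic applied to a large panel of
  by-construction null genes generated alongside the simulated data.
* **Control resampling** (real data) — per gene, new control and
  experimental vectors of the original sizes are drawn with replacement
  from the gene's control values only (controls assumed outlier-free);
  100 rounds per gene by default, pooled across genes without any per-gene
  standardization.

p = #{null values > observed}/n with strict exceedance and no continuity
correction, so p = 0 is representable. Genes with a degenerate scale
(zero MAD or pooled SD) contribute statistic 0 to a null pool with a
warning; per-gene calls raise instead.

## Synthetic data

The generator reproduces the benchmark's generative model: per gene, the
tight cluster is drawn i.i.d. from N(10, 1) — or from the mixture
0.5·N(9,1) + 0.5·N(10,1) in the non-Gaussian variant — with 30 replicates
per group; each planted outlier equals max(tight cluster) + d with
d ~ N(δ, 0.2²) independently per outlier (δ = 2 by default). With i.i.d.
positive gaps added to a common maximum, the smallest draw is the marginal
null-outlier distance. Outliers replace experimental draws (and control
draws in the contaminated-control variant) and are shuffled within their
group; truth metadata records their positions. Scenario 1 plants a single
hDEG per repetition; Scenario 2 plants 50 hDEGs and 50 non-DEGs. Each
repetition carries its own 10,000-gene null panel, shared by all genes of
that repetition, and a master seed spawns independent per-repetition
streams.

What the generator does *not* emulate: gene–gene correlation, heavy-tailed
or skewed technical noise, missing values, and array normalization
artifacts. Passing benchmarks therefore demonstrate correctness of the
algorithms under the stated sampling model, not robustness to everything
real microarray or single-cell data can contain.

## Evaluation

* Confusion counts call a gene positive when p ≤ p_crit.
* MCC with the 0/0 → 0 convention; total accuracy = (TP + TN)/total.
* Cumulative MCC = ∫₀^{p*} ρ_p dp, trapezoid on a uniform grid of 100
  nodes over (0, p*], with the open left endpoint taken as the first
  node's value (the integrand's right limit), so a constant integrand
  integrates exactly.
* ROC: positives are high scores; the partial AUC integrates FPR ∈
  [0, 0.05] with linear interpolation at the right edge and is divided by
  0.05 so a perfect ranking scores 1. Multi-repetition experiments are
  summarized by averaging per-repetition areas (vertical averaging):
  statistic scales are only comparable within a repetition — the variance
  prior b and the realized null panel differ across repetitions — so
  pooling scores would mix calibrations and understate the per-experiment
  ROC.
* The benchmark harness regenerates data per repetition, computes b over
  the evaluation genes plus the panel, scores every requested algorithm,
  calibrates p-values on the panel, and averages metrics over repetitions
  (100 repetitions and a 10,000-gene panel by default — the scale used in
  `scripts/acceptance.py` and the end-to-end tests).

## Numerical and design notes

* Ranking: decreasing statistic, ties broken by gene id for reproducible
  output. M = 0 genes (statistic 0) rank below every detected gene.
* The fast dataset path sorts each gene row once; the tight cluster's
  prefix medians and running sums make each MAP sweep O(1).
* Input matrices are tab-delimited with a header row and gene ids in the
  first column; missing values are rejected with coordinates (every
  downstream formula assumes complete vectors), duplicate ids are
  rejected. Reads use round-trip float parsing so write → read is
  bit-exact.
* Degenerate inputs: constant genes raise a degenerate-scale error in
  per-gene calls; dataset-level nulls record a warning and a 0 statistic.
* Known limitations: DOG's detected count can exceed the planted count by
  ≈ 0.1 on average at δ = 2 because a tight-cluster value occasionally
  fires just before the true outliers and everything above it is then
  declared an outlier; the published benchmark shows the same qualitative
  behaviour only for δ ≤ 1.5. One-sided by design: only high outliers are
  sought (mirror the data to detect low outliers).
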