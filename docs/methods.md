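# Methods

This note documents the models implemented in `foodwebts`, the choices made
where the published protocol leaves the design open, and what the synthetic
data do and do not establish.

## Standardization of assemblage time series

Samples are assigned to spatial units through a deterministic equal-area
square grid built on a sinusoidal projection anchored at (0, 0): marine
samples use 96 km² cells and freshwater samples 99 km² cells, matching the
areas of the hexagonal-grid and subbasin layers these stand in for. Only
unit *identity* matters downstream (a series is a study × unit pair), so
cell shape is immaterial; true hydrological basin delineation is a
non-goal.

Annual coverage is computed on the species-abundance vector pooled over a
series-year's samples, with the abundance-based estimator

Ĉ = 1 − (f₁/n)·[(n−1)f₁ / ((n−1)f₁ + 2f₂)]

(n individuals, f₁ singletons, f₂ doubletons). Series-years with Ĉ < 0.85
are dropped. An alternative reading of "coverage" as the ratio of observed
to Chao1-expected richness is available via `method="richness_ratio"`; the
estimator is the default because it is the standard abundance-based
sample-coverage quantity.

Sampling effort is equalized by sample-based rarefaction: within each
series, every year is subsampled without replacement to the series' minimum
annual sample count, preferring samples from the series' modal climatic
season (warm = April–September in the Northern Hemisphere, inverted in the
Southern); remaining slots and ties are filled uniformly at random.
"Preference" is implemented as a sort on (off-season, random key) — the
modal season is prioritized but never mandatory, so years with only
off-season samples still standardize. The procedure is repeated 100 times
(configurable) and all iterations are retained; it never mutates rows, only
selects samples. Series must span ≥ 2 years, have ≥ 2 sampled years and
≥ 5 species across the sampling period; all three thresholds are
parameters, supporting sensitivity re-runs.

## Trophic levels

A consumer's fractional trophic level is 1 + the weighted mean TL of its
adult-stage diet items; records without usable weights fall back to equal
weights (qualitative data). The classification bins are implemented as
[2, 2.2), [2.2, 2.8), [2.8, 4.0], (4.0, ∞): the printed two-decimal upper
bounds (2.19, 2.79) are read as truncations so the bins tile the line with
no gaps. TL < 2 is flagged out of range and excluded from group
proportions, as are species without diet records — exclusion, not zeroing,
so missingness cannot masquerade as trend. TLs are single-pass item
averages; no web-wide recursive (flow-based) TL is attempted.

## Niche-model calibration and evaluation

Predation windows are affine quantile-regression bounds of prey log10 size
on predator log10 size, fitted at τ = q_low and τ = q_high. Affine bounds
are the minimal structure consistent with allometric predation-window
practice; crossing bounds (possible with sparse tails) are flagged. Window
bounds convert to kernel parameters at predator size m by reading the
window as the central (q_high − q_low) probability band of a normal:
μ(m) = m − midpoint, σ(m) = half-width / z(q_high). θ is unidentifiable
from window calibration and fixed at 1; downstream link realization is
binary (inside the window or not), so θ cancels anyway.

The continuous Boyce index uses 101 moving windows of width 10% of the
background score range (both configurable); P/E per window is the fraction
of holdout presences over the fraction of background scores, and the index
is the Spearman correlation of P/E against the window midpoint, skipping
empty-background windows and returning missing when P/E is degenerate. The
background is built from the holdout marginals: all pairings of (up to 100,
configurable) subsampled holdout predator sizes with subsampled holdout
prey sizes, scored by the fitted kernel. This "size-matched random
pairing" null asks precisely whether the model ranks observed pairings
above random ones drawn from the same size distributions.

Cross-validation draws a fresh 70/30 split per repetition, fits every
candidate window on the training split, scores the holdout, and selects
the candidate with the highest mean Boyce. The desk default is 99
repetitions; `paper_scale` restores 999 (identical estimator, ten times
the runtime). Marine and freshwater records can be calibrated separately
(`realm` tag) or pooled.

## Web construction and metrics

The metaweb contains edge i→j iff species j's size lies inside i's
predation window (boundary inclusive), minus all out-edges of
non-piscivorous species (a size-only model would otherwise let large
herbivores "prey on" smaller fish); species with a missing piscivory flag
are conservatively treated as non-piscivorous. Self-links (cannibalism) are
excluded by default — every reported metric is better behaved without
them — with a toggle. Local webs are induced subgraphs on the species
present in a series-year; isolated nodes are retained and count in S.

Metrics follow their standard definitions (connectance L/S², generality
and vulnerability as mean out-/in-degree over nodes with degree ≥ 1,
trophic similarity as shared prey-plus-predators over the pair's combined
distinct prey-plus-predators). Pairs of completely isolated species have
an undefined similarity (0/0) and are excluded from the mean by default
(`include_empty_pairs` counts them as 0). Modularity is Newman–Girvan Q of
the best partition of the undirected simple projection: exhaustive over
all set partitions for webs of ≤ 8 species (the global optimum — greedy
agglomeration demonstrably misses it on a noticeable fraction of small
graphs), greedy CNM above. Both paths are deterministic under the
canonical sorted node order. Undefined metrics propagate as missing
values, never zeros, to avoid biasing trend slopes.

## Trend estimation

Each metric is regressed on globally mean-centered year with random
intercepts and slopes for study and for unit nested in study. Gaussian
responses use REML (Powell search, lbfgs fallback; if the nested structure
fails, the model falls back to unit-level random slopes and the fit is
flagged). Poisson (log link; richness) and binomial (logit on
group-count/classified-total pairs, expanded to Bernoulli rows) responses
use the variational-Bayes mixed GLM in statsmodels with weak priors; the
year covariate is standardized internally for optimizer stability and the
slope rescaled to per-year units. Fixed-slope recovery of all three
families is validated in the test suite against simulation truths, a plain
GLM cross-check, and (Gaussian) a from-scratch GLS evaluation at the
fitted covariance.

Slopes are pooled across rarefaction iterations as their mean, with 50%
and 95% percentile intervals by default; Rubin's-rules intervals (mean
within-fit variance + (1+1/m) between-fit variance, normal quantiles) are
computed alongside, since the published pooling rule is ambiguous between
the two. Non-converged fits are excluded and logged.

## Synthetic data

The generators emulate the structure of the real compilations: a species
pool with log-normal maximum lengths and a latent TL increasing with size;
interaction records drawn from a known Gaussian kernel (prey size ~
Normal(m_pred − μ, σ), truncated to the pool's size range, labelled with
the nearest-sized pool species); assemblage series in which residents are
replaced, with per-year probability `turnover_rate`, by colonists sampled
∝ exp(−size_selectivity · log10 size) from the remaining pool; and
lognormal-Poisson per-sample counts (overdispersion makes the coverage
filter non-trivial). The default truth kernel uses μ = 0.5, σ = 0.5 log10
length units — piscivores about 3× their prey's length with a broad niche,
within the range reported for fish — which also means that size-compressing
turnover densifies realized webs, the connectance-increase mechanism the
trend stage should detect. Metric panels for trend-stage tests come from
the exact hierarchical random-slope model (identity/log/logit link).

What the synthetic data do *not* emulate: real geography (units sit on an
abstract lattice), taxonomy, ontogenetic diet shifts, abundance-dependent
interaction strengths, or observational size measurement error. Passing
tests therefore demonstrate that the machinery recovers known mechanisms
under the stated generating model, not that the field estimates themselves
are reproduced.

## Problem sizes and numerics

Recovery checks run 25 replicate panels of 20 studies × 5 units × 20 years
per target and 100 cross-validation repetitions for the Boyce adequacy
check — sizes at which Monte-Carlo error is comfortably inside each
target's tolerance while a full run stays in the minutes range on one
core. Quantile regressions use the statsmodels interior-point fit;
coverage of degenerate inputs (empty vectors, constant scores, edgeless
webs, all-identical splits) is by explicit flags or errors as documented
per function. All randomness flows from a single master seed through named
CRC-derived substreams, making every pipeline artifact bit-reproducible
under a fixed config.

## Known limitations

- Quantile-regression windows are affine; strongly nonlinear predation
  windows would be mis-specified.
- The VB approximation is used for non-Gaussian GLMMs; variance components
  are regularized by the prior and are reported for diagnostics, not
  inference (the fixed slope is the contract).
- With very sparse small-predator records the lower window bound can cross
  the upper; the model flags but does not repair this.
- Node- and link-weighted (abundance-based) metrics are deliberately out
  of scope.
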