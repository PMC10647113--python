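# Methods

## The frontier model

The core model is the time-varying random-effects stochastic production
frontier of Battese & Coelli (1992). For province i = 1..n and period
t = 1..T,

    y_it = x_it' β + v_it − u_it
    u_it = b_t u_i,  b_t = exp(−η (t − T))
    v_it ~ iid N(0, σ_v²),  u_i ~ N(μ, σ_u²) truncated below at 0,

with y the log output index and x the log inputs. We use the
reparameterisation σ² = σ_u² + σ_v², γ = σ_u²/σ² ∈ [0,1]. The decay factor
b_t equals 1 in the final period, so u_i is "the final-period inefficiency"
and η > 0 means inefficiency shrinks (efficiency rises) over the sample.

The likelihood integrates u_i out of each unit's joint residual density
analytically. With b the decay vector, A = b'b, ε_i the unit's residual
vector,

    σ*² = σ_u²σ_v² / (σ_v² + A σ_u²)
    μ_i* = (μ σ_v² − b'ε_i σ_u²) / (σ_v² + A σ_u²)

    ℓ_i = −T/2 log 2π − (T−1)/2 log σ_v² − ½ log(σ_v² + A σ_u²)
          − ½ [ ε_i'ε_i/σ_v² + μ²/σ_u² − μ_i*²/σ*² ]
          + log Φ(μ_i*/σ*) − log Φ(μ/σ_u).

u_i | ε_i is N(μ_i*, σ*²) truncated at 0, giving the minimum-MSE
efficiency predictor

    TE_it = exp(−b_t μ_i* + ½ b_t² σ*²) · Φ(μ_i*/σ* − b_t σ*) / Φ(μ_i*/σ*).

Both formulas are verified in the test suite against direct numerical
quadrature of the normal x truncated-normal convolution to ≤1e−6.

Note that TE_it is **not** exactly exponential in b_t: the Φ-ratio
correction makes each unit's implied decay rate deviate slightly from η,
more so for low-efficiency units. Consequently, back-casting a printed
efficiency table through `ln TE_i1 = e^{ηT'} ln TE_iT` reproduces
first-period values only approximately (errors up to ~0.007 on the
embedded reference panel, largest for the least efficient provinces).

### Estimation

* Coordinates: (β, log σ², logit γ, μ, η). The log/logit transforms keep
  the optimiser inside the domain without constrained solvers and behave
  well in the empirically relevant γ → 1 regime. Box bounds (|log σ²|,
  |logit γ| ≤ 30, |μ| ≤ 50, |η| ≤ 2) only guard against overflow.
* Starting values: OLS for β; a COLS-style grid over
  γ ∈ {0.1, 0.3, 0.5, 0.7, 0.9, 0.99} with the intercept shifted by the
  implied mean inefficiency, μ started at 0 and at σ_u. Starts are ranked
  by likelihood; the best are polished with L-BFGS-B then Nelder-Mead.
* Convergence: the fit is declared converged when an optimizer-flagged
  successful start reaches the overall best log-likelihood within 1e−6.
  This guards against the flat ridge in (γ, μ, η) that appears when the
  data carry little inefficiency signal (γ ≈ 0), where a simplex polish
  can exhaust its iteration budget while improving the objective only in
  the 4th decimal. Non-converged fits raise, carrying the best point.
* The likelihood treats γ < 1e−14 as exactly 0 (iid normal residuals) and
  caps γ at 1 − 1e−12 (σ_v = 0 is degenerate).
* Functional forms: Cobb-Douglas (2 slopes) and the 2-input translog
  (5 slopes; quadratic terms enter with the conventional ½ factors).
  Model choice uses LR = −2[ln L(H0) − ln L(H1)]; because the tested
  restrictions may lie on a boundary, both the plain χ²(df) 5% critical
  value and the Kodde-Palm mixed-χ² bound are reported and the caller
  picks the decision rule (default: plain χ²).

## Output aggregation

The standard single-output frontier needs one output, so the three log
service outputs are aggregated by principal components: weights are the
first PC of the **correlation** matrix of the log outputs, rescaled to sum
to 1, applied to the unstandardized logs. This keeps the index on the same
log scale as its components. The PC sign is fixed by forcing the
largest-magnitude loading positive. Covariance-matrix and
standardized-score variants are available as options; published work in
this area rarely states which variant was used, so the default is a
documented choice, not a reproduction.

## Malmquist index

Output-oriented radial DEA distances D = 1/φ* from the envelopment LP
(max φ s.t. Σλe ≤ e₀, Σλp ≥ φp₀, λ ≥ 0, plus Σλ = 1 under VRS), solved
with HiGHS at tolerance ~1e−9. The adjacent-period index is the geometric
mean of the two single-period indices, decomposed as
tfpch = techch × effch and effch = pech × sech (pech from VRS distances).
The identities hold to ≈1e−10 by construction and are asserted, not
assumed. DEA needs positive levels, so log panels are exponentiated before
entering. Cross-period VRS programs can be infeasible; such DMUs are
recorded as NaN with a note (or raised, by option), never silently imputed.
Own-period CRS distances are ≤ 1 with at least one frontier DMU per period.

## Distribution dynamics

* KDE: Gaussian kernel; Silverman bandwidth
  h = 1.06·min(s, IQR/1.34)·n^{−1/5} with the sample (n−1) SD and
  linear-interpolation IQR. Default evaluation grid: 512 points spanning
  the data range ±4h, on which the trapezoid integral of the density is 1
  to well within 1%.
* Markov states: quartile cut points from the pooled set of all unit-year
  values (linear-interpolation percentiles); boundary rule "value ≤ cut →
  lower state". Pooling is the default because the reference panel drifts
  upward slowly relative to its cross-sectional spread; a per-year scheme
  is provided for strongly trending panels, and is also the advised
  fallback when pooled cut points collide on tied values (an error, never
  a silent re-bin). With values printed at 3 decimals, ties straddling a
  quartile boundary are assigned deterministically to the lower state;
  published tables computed from unrounded values can therefore differ by
  a few transitions from what the rounded table yields.
* Transition probabilities are maximum-likelihood estimates n_ij/n_i;
  empty origin rows report NaN, not 0. The spatial variant classifies the
  row-standardised spatial lag Σ_j W_ij te_jt with the same cut points
  (separate lag cuts are an option) and conditions each transition on the
  origin year's lag state; the four blocks partition the unconditional
  tally exactly.

## Spatial statistics

Global Moran's I in its standard double-sum form (expectation −1/(n−1)
under the permutation null), with seeded random-relabelling p-values
(p = (1 + #{|I_perm| ≥ |I_obs|})/(1 + n_perm) two-sided, and a one-sided
version for positive autocorrelation). Local Moran's I_i uses centred
values and conditional permutations (unit i fixed, others permuted among
its neighbour positions); quadrants come from the signs of (z_i, lag_i).
The exact identity Σ_i I_i = S₀ · I (S₀ = ΣΣW_ij) is asserted in tests.

Default weights for the 31-province application: queen contiguity with a
Hainan-Guangdong bridge (the island province would otherwise be an
isolate), row-standardised. Windowed analyses average each unit's values
over year windows before computing I. Published provincial studies often
leave both the weight matrix and the window aggregation unstated; results
are therefore comparable in sign and trend, not digit-for-digit.

## Synthetic data

The generator draws panels from exactly the frontier DGP above: u_i by
inverse-CDF sampling of the truncated normal (stable for any μ/σ ratio),
v_it normal, u_it = b_t u_i, y from the Cobb-Douglas frontier. Defaults
mirror the reference application's scale: n = 31 units, T = 11 periods,
β = (3.0, 0.30, 0.13), σ² = 1.5, γ = 0.95, μ = 2.4, η = 0.014. Log inputs
start from a bivariate normal matched to the observed 2010 cross-section
(means 1.515/1.307, SDs 0.34/0.26, correlation 0.6) and follow
unit-specific linear drifts centred on +0.050/+0.055 per year (SD 0.015)
plus N(0, 0.03²) noise. The drift means match the observed movement of the
cross-sectional input means over 2010-2020; making them unit-specific
mirrors the observed shrinkage of the input cross-sections (provinces
converge) and provides the within-unit variation that identifies the slope
coefficients.

What the generator does **not** emulate: spatially correlated
inefficiency, measurement error in inputs, entry/exit or unbalancedness,
and any feedback from efficiency to input choice. Passing recovery tests
on these panels therefore demonstrates correctness of the estimator under
the model's own assumptions, not robustness to their violation.

A second generator back-propagates final-period efficiencies through the
decay law (u_it = b_t · (−ln TE_iT)) to produce efficiency panels with a
known η for testing the dynamics stages in isolation.

## Problem sizes in the checked examples

Quadrature cross-checks of the likelihood and the efficiency predictor use
n ≤ 3, T ≤ 3 instances; DEA enumeration cross-checks use ≤ 5 DMUs and
≤ 2 inputs/outputs (exhaustive vertex enumeration is exponential);
parameter recovery uses 20 replicates at the full 31 × 11 scale; Moran
permutation-null checks are exhaustive for n ≤ 6 and Monte-Carlo (3
standard errors) at n = 31.

## Known limitations

* The slope coefficients of a 31-unit panel with correlated, trending
  inputs are individually noisy; single-panel point estimates of β should
  be read with that in mind (the variance/decay block γ, η, μ is much
  better determined).
* DEA results depend on whether the aggregated output index or the three
  raw outputs enter; both modes are provided and give different (equally
  valid) technologies.
* The embedded reference efficiency panel is a 3-decimal transcription;
  statistics that are sensitive to ties at quartile boundaries (the Markov
  origin counts) can differ by a few units from values computed on
  unrounded data, as noted above.
* No inefficiency-determinants (Battese-Coelli 1995) model, no
  input-oriented or slack-based DEA, no ergodic/mobility Markov summaries,
  and no map rendering — tabular exports only.
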