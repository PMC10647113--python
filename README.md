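# hsekit

Measurement and temporal-spatial analysis of **healthcare-services
efficiency (HSE)** on provincial panel data.

Health systems convert inputs (health technicians and hospital beds per
1,000 population) into service outputs (outpatient/emergency visits,
discharges, surgical procedures). `hsekit` estimates how efficiently each
province does this and how the resulting efficiency distribution evolves
over time and across space. It is aimed at health-economics and
spatial-epidemiology researchers working with balanced province-by-year
panels (the reference application is mainland China's 31 provinces,
2010-2020).

## What it computes

**1. Stochastic production frontier (Battese-Coelli 1992).** A Cobb-Douglas
(or translog) frontier with a two-part error:

    ln HSO_it = β0 + β1 ln L_it + β2 ln K_it + v_it − u_it
    u_it = exp(−η (t − T)) · u_i,   u_i ~ N(μ, σ_u²) truncated at 0,
    v_it ~ N(0, σ_v²)

estimated by exact maximum likelihood (the unit effect `u_i` is integrated
out analytically). Technical efficiency is predicted as
`TE_it = E[exp(−u_it) | ε_i] ∈ (0, 1]`; `γ = σ_u²/(σ_u²+σ_v²)` measures how
much of the composed error is inefficiency, and `η > 0` means efficiency
improves over time. Likelihood-ratio model tests report both plain χ² and
Kodde-Palm mixed-χ² critical values. The single output `HSO` is a
PCA-weighted aggregate of the three log outputs.

**2. Malmquist TFP decomposition (DEA).** Output-oriented radial distance
functions (linear programs, CRS and VRS) over adjacent years give
`tfpch = techch × effch = techch × pech × sech` per province-pair, with
geometric-mean summaries.

**3. Distribution dynamics.** Gaussian kernel densities with the Silverman
rule-of-thumb bandwidth `h = 1.06·min(s, IQR/1.34)·n^{−1/5}`; a 4-state
quartile Markov transition matrix; and a spatial Markov variant that
conditions each transition on the quartile state of the neighbours'
efficiency (the spatial lag), exposing "club convergence".

**4. Spatial autocorrelation.** Global and local Moran's I with permutation
inference and H-H/H-L/L-L/L-H (LISA) classification, over queen-contiguity
weights for the 31 provinces (with a Hainan-Guangdong bridge) or any
user-supplied adjacency/coordinates.

A synthetic-data module generates panels from exactly the frontier model
above with known ground truth, so every estimator is testable for recovery.
The package ships one reference dataset: the published 31x11 provincial
efficiency panel (3-decimal transcription), which drives the dynamics and
spatial stages directly.

## Worked example

```python
import hsekit as hk

fx = hk.load_efficiency_fixture()          # 31 provinces x 11 years
print(round(fx.data["te"].mean(), 3))       # 0.841

tm = hk.transition_matrix(hk.classify_states(fx))
print(tm.to_frame(decimals=3))
#       N      I     II    III     IV
# I    81  0.926  0.074  0.000  0.000
# II   79  0.000  0.899  0.101  0.000
# III  75  0.000  0.000  0.947  0.053
# IV   75  0.000  0.000  0.000  1.000

w = hk.build_weights(hk.load_china_adjacency(), style="row_standardized")
agg = hk.period_aggregate(fx, [(2019, 2020)]).loc[list(w.ids)]
res = hk.global_moran(agg.iloc[:, 0].to_numpy(), w, n_permutations=999, seed=1)
print(round(res.I, 3), round(res.p_one_sided, 3))   # 0.199 0.038
```

The grand mean 0.841 says the average province produces ~84% of its
frontier output. The transition matrix shows strong persistence (diagonal
0.90-1.00): provinces move between efficiency quartiles only to adjacent
states, and the top quartile never leaves. The positive, significant
Moran's I says efficiency clusters in space — high-efficiency provinces
neighbour high-efficiency provinces.

Fitting the frontier on a synthetic panel with known truth
(β1=0.30, β2=0.13, σ²=1.5, γ=0.95, μ=2.4, η=0.014):

```python
truth = hk.FrontierTruth(seed=3)
panel, u, te_true = hk.generate_panel(truth)
fit = hk.fit_frontier(panel)
print(fit.params_table().round(3))
#      parameter  estimate
#          beta0     3.516
#          beta1     0.041
#          beta2     0.220
#       sigma_sq     2.049
#          gamma     0.964
#             mu     2.383
#            eta     0.014
# log_likelihood  -124.175
```

A single n=31 panel recovers the variance structure (γ, η) well; the two
slope coefficients are individually noisy at this sample size (they are
correlated inputs), which is why recovery is assessed on medians across
replicates in the test suite.

There is also a CLI (`hsekit simulate|fit|malmquist|dynamics|esda|pipeline`)
wrapping the same functions; `hsekit pipeline --config cfg.yaml` runs all
stages and writes CSV tables plus a reproducibility manifest.

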