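# Methods

## The coupled stochastic clock model

Each cell is a three-state delayed negative-feedback oscillator in
concentration units:

    dM/dt   = vs * K1^n / (K1^n + PN^n) − vm * M / (Km + M)
    dPC/dt  = ks * M − vd * PC / (Kd + PC) − k1 * PC + k2 * PN
    dPN/dt  = k1 * PC − k2 * PN

with the coupling entering through the transcription rate of cell *i*,

    vs_i = vs_base + L + alpha * (Mbar_i − M_i),

where `Mbar_i` is the mean mRNA concentration of the cells that directly
influence *i* (cells without in-neighbours run at `vs_base + L`).  `vs_i`
is clamped at zero before it multiplies the birth propensity, because
strong coupling can drive the expression negative.  The stochastic model
replaces concentrations by counts via the system volume Ω: every
concentration `x` becomes `X/Ω` and each cell contributes six reaction
channels (mRNA birth/death, translation, protein degradation, and
nucleocytoplasmic exchange in both directions).  The default integrator is
the exact direct-method SSA; a fixed-step tau-leap (default 0.001 h, with
step halving whenever a leap would drive a count negative) is provided for
networks of ~100 cells.

### Kinetic defaults and why

`vs_base = 0.83`, `Ω = 50` and `alpha = 100` are the study conditions.
The remaining constants start from the classical minimal-PER parameter set
(vm 0.65, Km 0.5, ks 0.38, vd 0.95, K1 1, n 4).  That set was tuned for a
five-state cascade; collapsing the three phosphorylation states into a
single cytoplasmic pool removes enough feedback delay that the three-state
reduction spirals into a stable fixed point (residual amplitude ~1e-10).
Three constants are therefore adjusted to restore a sustained limit cycle:
slower nucleocytoplasmic exchange `k1 = 0.3 /h`, `k2 = 0.65 /h` (restores
the delay) and a tighter protein-degradation Michaelis constant
`Kd = 0.1` (keeps degradation saturated, which the oscillation needs).
The resulting deterministic cycle has a 23.5 h period, mRNA concentration
swinging 0.92–3.70 (counts 46–185 at Ω = 50), and a ~12.6 h rising phase.
At Ω = 50 and alpha = 100 the stochastic network synchronizes (cross-cell
SD of M a few counts), per-minute changes on rising segments have a
slightly positive mean with range about [−4, 4], and pairwise
cross-correlations of the differenced panel are significant at lags of a
few minutes and fade by about five — the regime the method expects.  All
constants are overridable per run.

### Initial conditions

All cells start at the trough of M on the deterministic limit cycle
(found by a 200 h burn-in integration), scaled by Ω and rounded, so
recordings begin synchronized at the start of a rising phase; an optional
per-cell phase jitter (`init_jitter_h`) relaxes this.

## Preprocessing

Rising-interval detection smooths each cell's series with a centered
moving average (default 60 min), finds trough→peak spans of the smoothed
trace (extrema taken with a prominence of 15% of the trace range, so
residual wiggles from counting or measurement noise do not fragment a
phase), intersects the spans across cells, trims 30 min margins and keeps
intervals of at least 3 h.  One-step differences are computed within each
interval only and the segments concatenated in time order; boundary
indices are retained, and by default every regression row whose lag window
would straddle a segment join is dropped (`--paper-concat` keeps them,
treating the concatenation as one unbroken series).  "Hours of
observations" always counts retained differenced samples
(n × interval / 60), not wall-clock recording time.

Measurement noise is i.i.d. Gaussian per sample with SD equal to a chosen
fraction of the largest per-cell sample SD of the series, so fraction 1.0
is a signal-to-noise ratio of one for the most variable cell.

## Inference

The VAR(p) is fit per response by OLS with intercept on p lags of all K
cells (default p = 5, matching the few-minute information-transfer lag
visible in the cross-correlograms; `suggest_model_order` reports the
largest significant CCF lag as a diagnostic).  The pairwise test removes
all p lags of one source and refers

    F = ((RSS_B − RSS_A)/p) / (RSS_A/(n − K·p − 1))

to F(p, n − K·p − 1); both fits always use the identical row set.
p-values below 1e-320 are floored there, and log-scale comparisons use
log10 p with the same floor.  Binary output thresholds p-values at 0.05
with Bonferroni correction over the K(K−1) tests by default; the ROC/AUC
evaluation sweeps the threshold instead and is the primary accuracy
measure.

### Group-LASSO variant

For each response the K·p slope coefficients are partitioned into K groups
(all lags of one source) and estimated by

    argmin ‖y − Xb‖² + λ Σ_k ‖b_Gk‖₂ ,

with predictors standardized, the response centered, and estimates
returned on the original scale.  The penalty is unweighted: all groups
have size p, so group-size weights would only rescale λ.  The solver is
block coordinate descent on the Gram form with *exact* block updates (the
block stationarity condition reduces to a scalar root in the block
eigenbasis, found by a monotone Newton iteration), so the objective is
monotone and KKT conditions hold at convergence (relative objective change
< 1e-8, cap 10000 sweeps; non-convergence is reported on the fit object).

λ is selected per response, by default with 5-fold cross-validation
blocked by rising segment (held-out rows are serially separated from
training rows) over a 20-point log grid spanning [0.01, 1]·λ_max, where
λ_max = max_k ‖2·X_kᵀ(y − ȳ)‖ zeroes every group.  BIC
(n·log(RSS/n) + log(n)·df with df = 1 + p·#active-groups) is available and
cheaper, but it over-shrinks densely connected networks — on the 20-cell
two-group benchmark it zeroes every group and the ranking collapses to
ties — so prediction-optimal CV is the default.

Group inference uses the Wald statistic W = b_Gjᵀ [Cov_OLS(Gj)]⁻¹ b_Gj
with the covariance block of the *unpenalized* OLS estimates of the same
design, reported as F = W/p on (p, n − K·p − 1) degrees of freedom for
comparability with the plain tests.  This approximation is statistically
non-standard — penalized estimators do not have the OLS covariance — and
the resulting p-values should be read as ranking scores, not calibrated
tests; groups zeroed by the penalty score F = 0, p = 1.

## Evaluation

Positives are the true directed edges, negatives all other ordered
non-self pairs, scores are −log10 p (or F).  AUC is the midrank
Mann–Whitney statistic, identical to the trapezoid ROC area without ties
and well-defined with them.  Sweep drivers rerun the full pipeline
(simulate → noise → preprocess → infer → score) per level and seed,
record per-seed AUCs with the derived seeds, and report mean ± SE; any
cell failure is recorded and the sweep continues.  Replicate seeds are
derived from the base seed with `numpy.random.SeedSequence`, so identical
configs reproduce identical results byte-for-byte.

## Problem sizes and known limitations

* Benchmarks run the 3-, 4-, 10- and 20-cell networks with 5–120 h of
  rising-segment observations; a 10-cell, 600-h SSA realization takes
  about a second, and the full benchmark script (ten replicates per
  quantity) finishes in well under a minute on one CPU.  The 100-cell
  scale-free and small-world topologies are provided with the tau-leap
  integrator for larger studies.
* **Sampled-path aliasing.**  With alpha = 100 the cell-to-cell transfer
  time 1/(alpha·G) (G = Hill repression factor, near 1 on rising phases)
  is comparable to the one-minute sampling interval, so the
  discretely-sampled process genuinely contains second-order ("two hops
  in one step") terms: the indirect pair of a chain receives a nonzero
  direct coefficient of relative size ~(alpha·G·Δt)²/2.  True edges still
  dominate the ranking — AUC-based results are unaffected — but the
  orders-of-magnitude gap between true-edge and false-pair p-values
  fluctuates strongly across realizations (means of ~4–5 orders on the
  3-cell chain at 6 h).  Because the event rate and the transfer rate are
  both proportional to the same Ω·G and alpha·G with Ω, alpha and vs_base
  fixed by the study conditions, detection power and indirect leakage
  cannot be tuned independently.
* The simulator emulates intrinsic (counting) noise, instantaneous
  mRNA-mediated coupling and optional additive measurement noise.  It does
  not model VIP/GABA signalling, light schedules beyond a constant offset,
  spatial geometry, cell heterogeneity in kinetic constants, or slow
  baseline drift of real bioluminescence recordings — passing tests show
  the statistics behave correctly under the model's assumptions, not that
  those assumptions hold for any particular experimental recording.
* Granger inference on protein proxies is expected to degrade: translation
  low-pass filters the high-frequency transcription noise that carries the
  causal signal.  The species analyzed is selectable (`species="PC"` etc.)
  so this can be studied directly.
* Degenerate inputs: constant or perfectly collinear series make the OLS
  design rank-deficient and raise immediately; differenced panels shorter
  than K·p + 2 rows are rejected with an "insufficient observations"
  error.
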