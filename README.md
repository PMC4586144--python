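# afgc — Adaptive Frequency Granger Causality

Tools for inferring **directed functional connections** between coupled
circadian oscillators from gene-expression time series, for computational
chronobiologists and methods developers working on network reconstruction
in the suprachiasmatic nucleus (SCN) and similar systems.

Raw circadian traces are oscillatory and non-stationary, so classical
Granger causality cannot be applied to them directly.  AFGC makes the data
Granger-ready by exploiting the rising phase of each cycle: while PER mRNA
is rising, the trace is approximately linear, so its one-step difference
D_i[t] = M_i[t] − M_i[t−1] is stationary, and transcription-mediated
coupling is maximally expressed.  The pipeline is

1. **simulate** (or load) per-cell mRNA counts — the built-in simulator is
   a discrete stochastic three-state clock (mRNA *M*, cytoplasmic protein
   *P_C*, nuclear protein *P_N*) with Hill-repressed transcription,
   coupled through the transcription rate
   `vs_i = vs_base + L + alpha * (mean of in-neighbour M − M_i)` and scaled
   to counts by a system volume Ω (Gillespie SSA, or tau-leaping for large
   networks);
2. **preprocess** — detect the rising intervals common to all cells,
   difference within each interval, concatenate segments across cycles;
3. **infer** — fit a VAR(p) to the differenced panel by OLS (default
   p = 5) and test each ordered pair (j → i) with the nested F statistic

       F = ((RSS_B − RSS_A)/p) / (RSS_A/(n − K·p − 1)),

   where model B omits all p lags of source j; small p-values mean "cell j
   Granger-causes cell i".  For observation-scarce regimes a group-LASSO
   variant penalizes each response regression with one ℓ2 group per source
   cell (`‖Y − Ŷ‖² + λ Σ_k ‖α_Gk‖`) and scores groups by a Wald statistic
   with the OLS covariance approximation;
4. **evaluate** — rank ordered pairs by −log10 p and score against a known
   network with the midrank Mann–Whitney ROC AUC, with sweep drivers for
   observation hours, sampling interval, measurement noise and coupling
   strength.

## Worked example

```python
import numpy as np
import afgc

net = afgc.make_topology("chain3")               # cell 0 -> 1 -> 2
params = afgc.SimulationParams(seed=1)           # omega=50, alpha=100, 1-min sampling
panel = afgc.collect_panel(net, params, hours=6.0)
inferred = afgc.reconstruct_network(panel, p=5)

print("p-values (row = source, column = target):")
with np.printoptions(precision=2):
    print(inferred.p_matrix)
binary = inferred.threshold(0.05, bonferroni=True)
print("edges at Bonferroni 0.05:", sorted(binary.edge_set))
roc = afgc.roc_auc(inferred, net)
print(f"AUC = {100 * roc.auc:.2f}%")
```

prints

```
p-values (row = source, column = target):
[[     nan 1.49e-12 8.21e-03]
 [9.73e-01      nan 3.40e-11]
 [8.10e-01 5.26e-01            nan]]
edges at Bonferroni 0.05: [(0, 1), (0, 2), (1, 2)]
AUC = 100.00%
```

The two true edges (0→1, 1→2) are detected at p ≈ 1e-12 and 3e-11, nine
orders of magnitude below every other pair, and the AUC of the ranking is
perfect.  The *indirect* path 0→2 is by far the strongest false pair
(p ≈ 8e-3, here surviving the Bonferroni cut): at one-minute sampling some
second-order transfer through the intermediate cell is genuinely present in
the sampled process, which is why ranking-based evaluation (ROC/AUC) is the
primary accuracy measure.  See `docs/methods.md` for discussion.

The same pipeline is available from the shell:

```
afgc simulate --config run.yaml --out out/
afgc infer out/trajectory_wide_M.csv --raw --method plain --order 5 --out out/scores.csv
afgc evaluate out/scores.csv out/truth_edges.csv
afgc sweep --config run.yaml --out out/
```

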