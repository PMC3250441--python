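# bicontrol

Analysis toolkit for **bipartite controller–target networks** — the
"many-to-many" wiring by which cells regulate themselves: transcription
factors controlling genes, miRNAs controlling transcripts, kinases
controlling substrates, and, by analogy, kinase inhibitors controlling their
kinase targets. It is aimed at systems biologists and computational
pharmacologists who want to measure these networks' statistics, test them
against random-graph nulls, reason about why their parameters sit where they
do, and design drug libraries that mimic them.

The package has three parts:

1. **Network statistics.** For a directed bipartite graph with `M`
   controllers, `N` targets and `L` links, it computes the comparison-table
   bundle: link density `D = L/(MN)`, mean links per node, the two
   target-set overlap measures (shared targets per controller, directional
   pairwise overlap), giant-component and dual-role fractions. Two exact
   identities tie these together:

   ```
   D = <k_in>/M = <k_out>/N        and        M/N = <k_in>/<k_out>
   ```

   Degree distributions are fitted with a geometric model (`p = 1/<k>`, the
   discrete exponential), compared against the scale-free alternative by R²
   on the linearized scales, and tested against the bipartite random-graph
   (binomial/Poisson) null. Degree-preserving edge-swap randomization gives
   z-scores for `k_out`–`k_in` wiring correlations.

2. **Boolean bipartite model.** Controllers carry binary states; each target
   computes OR / AND / MAJORITY of its inputs in a single step. For the OR
   rule (AND is identical by complement symmetry) the chance that deleting
   one specific link flips a target with `k` inputs is `2^-k`, giving the
   closed-form robustness to `γ` random link deletions

   ```
   R(k) = 1 − k (γ/L) 2^-k
   ```

   and the single-node output entropy `S(k) = −q₀log₂q₀ − q₁log₂q₁` with
   `q₀ = 2^-k`, from which the number of achievable output states is
   estimated as `log₂ Ω ≈ N⟨S⟩`. Both are averaged over
   geometric/Poisson/binomial incoming-degree models via closed-form
   expectations of `E[2^(−ηk)]` and `E[k·2^(−ηk)]`, and validated against
   exhaustive enumeration and Monte-Carlo simulation. Robustness rises
   steeply with `⟨k_in⟩` and saturates above ~5 while the output repertoire
   shrinks — the trade-off that makes the observed `⟨k_in⟩ ≈ 2–10` range
   interesting.

3. **Biomimetic sampling.** A fully profiled inhibitor library is simulated
   as a bipartite configuration model with prescribed geometric marginals
   (inverse-transform sampling + random stub matching); a compound subset
   with natural-network statistics is then extracted either by rejection
   sampling toward a reduced-mean exponential `k_out` distribution, or by an
   exact binary integer program `min Σx s.t. Ax ≥ b` that meets a ranked
   incoming-link profile with the fewest compounds.

## Worked example

```python
import bicontrol as bc

# a "biological-like" synthetic network: geometric out-degrees, mean 20
net = bc.exponential_configuration(150, 1200, mean_kout=20.0, seed=7)
s = bc.summarize(net)
print(f"density={100*s.density:.1f}%  <k_out>={s.mean_k_out:.1f}  <k_in>={s.mean_k_in:.2f}")
print(f"M/N={100*s.mn_ratio:.1f}%  STC={100*s.stc_mean:.1f}%  giant={100*s.giant_fraction:.1f}%")

kout, _ = bc.degree_sequences(net)
print(bc.GeometricDegreeModel(kout).fit().summary())

df = bc.fig3_sweep(10, 10, 0.1, [1, 3, 5, 8], n_trials=400, seed=0)
print(df[["k_in", "R_sim_OR", "R_closed", "log2_omega_closed"]].round(4))
```

prints

```
density=1.6%  <k_out>=19.2  <k_in>=2.40
M/N=12.5%  STC=91.9%  giant=92.0%
Geometric degree-distribution fit
==============================================
nobs (k >= 1)                              150
zero-degree dropped                          0
p (success prob.)                     0.052047
std err (p)                           0.004138
95% CI (p)                    [0.0439, 0.0602]
mu = 1/p (mean links)                  19.2133
 k_in  R_sim_OR  R_closed  log2_omega_closed
    1    0.9446    0.9516             8.7850
    3    0.9878    0.9881             5.6180
    5    0.9965    0.9962             2.6103
    8    0.9995    0.9995             0.4896
```

The summary row reads like the published comparison tables: a sparse
(1.6%) many-to-many network whose controllers nearly all share targets
(STC 92%) and whose fitted mean out-degree (19.2) recovers the generator's
prescription. The sweep shows simulated robustness tracking the closed form
and the robustness/output-state trade-off in `⟨k_in⟩`: by `⟨k_in⟩ = 5`
robustness is already 0.996 while the output repertoire has fallen from
~2⁸·⁸ to ~2²·⁶ states.

A `bicontrol` console script exposes the same operations on TSV edge lists
(`bicontrol stats`, `fit`, `randomize`, `corrz`, `boolean-sim`,
`boolean-analytic`, `simulate-library`, `subsample`, `select-subset`,
`synth`); see `bicontrol --help`.

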