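# Methods

## The network model

A controller–target network is a directed bipartite graph: `M` controller
nodes (transcription factors, miRNAs, kinases, or drugs), `N` target nodes
(genes, transcripts, substrates, or drug targets), `L` unweighted links all
pointing controller → target. Links form a set (simple graph); a molecule
may appear in both layers and its two roles are tracked independently, but
it counts as one node wherever node fractions are reported (component and
dual-role denominators). Edge-list I/O silently collapses duplicate rows
(logged and counted), because interaction databases routinely contain
redundant binding-site records while all statistics here assume a simple
graph.

Link conservation `Σk_out = Σk_in = L` makes two identities exact on every
network, and the test suite asserts them to 1e-12:

    D = L/(MN) = <k_in>/M = <k_out>/N,        M/N = <k_in>/<k_out>.

The second identity is also how the package converts between printed mean
link counts and node ratios (e.g. a panel with `<k_in> = 9.48` and
`<k_out> = 78.8` implies `M/N = 12.0%`).

### Overlap measures

* *Shared targets per controller* (STC): for controller `x`, the fraction of
  `x`'s targets hit by at least one other controller; reported as the mean
  over controllers. Controllers with zero targets are excluded and logged —
  the fraction is undefined for an empty target set, and database-derived
  networks have none by construction.
* *Pairwise overlap* (PO): for the ordered pair `(x_i, x_j)`,
  `|T(x_i) ∩ T(x_j)| / |T(x_i)|`. The matrix is deliberately asymmetric and
  the mean is taken over ordered pairs; a symmetrized average is exposed as
  an option since published tables do not always state the convention.

## Degree-distribution models

Links per node in these networks are mostly exponential-like; the discrete
analogue is the geometric distribution on `k = 1, 2, …` with
`pmf(k) = p(1−p)^(k−1)` and mean `1/p`. Fitting sets `p = 1/mean(k)` over
the zero-excluded sequence — the method of moments, which coincides with
maximum likelihood — with a delta-method standard error
`se(p̂) = p√((1−p)/n)`. Zero-degree nodes are dropped before fitting: the
geometric support starts at 1, and a node with no links is invisible to the
analyses that use the fit.

The null model is the bipartite Erdős–Rényi graph: every controller–target
pair linked independently with probability `D`. Its marginal degrees are
Binomial(`M`,`D`) (targets) and Binomial(`N`,`D`) (controllers); for large
layers the Poisson with `λ = MD` or `ND` is used, and an exact zero-excluded
binomial is kept available because at layer sizes around 10 the Poisson
approximation is visibly off. After dropping `k = 0` the pmf is renormalized
by default (a truncated, unrenormalized variant is exposed as a toggle; the
choice only rescales expectations by `1 − P(0)`).

The exponential-vs-scale-free comparison is the field's simple linearized
regression: relative degree frequencies on the `k ≥ 1` support, empty cells
dropped (log undefined), `log f` regressed on `k` (exponential) and on
`log k` (scale-free), winner by R². This is intentionally not a
Clauset-style maximum-likelihood power-law fit — the comparison mirrors the
straight-line-on-transformed-axes convention, and its exact binning is a
documented package choice rather than a published prescription. The
mean-normalized empirical cdf display avoids binning entirely: every data
point is plotted at `k/<k>`, and for `μ ≫ 1` the normalized geometric cdf
converges to the standard exponential cdf.

Degree-preserving randomization uses double-edge swaps
`(c₁,t₁),(c₂,t₂) → (c₁,t₂),(c₂,t₁)`, rejecting swaps that would duplicate a
link; the default attempt count is `10·L`. Both degree sequences are
conserved exactly, so `M, N, L, D, <k_in>, <k_out>` are all invariant and
only the wiring correlations change. Wiring z-scores bin links by
`(k_out of source, k_in of sink)` — node degrees are swap-invariant, so the
class grid is fixed — and compare observed class counts against the mean and
SD of 30 randomizations (the published default); classes with zero SD
(e.g. unrewirable graphs such as complete bipartite ones) report `z = 0`
with a flag.

## Boolean bipartite signalling model

Controllers hold binary states; each target computes, in a single step with
unweighted links and no feedback,

* **OR** — active iff ≥ 1 linked controller active,
* **AND** — active iff all linked controllers active,
* **MAJORITY** — active iff strictly more than half active (ties inactive,
  the strict reading of "more than half").

A target with no incoming links — possible after deletions — is inactive
under every rule: an unsignalled node carries no state, and this keeps OR
and AND consistent as links vanish.

**Robustness.** Over a uniform random input and a uniform choice of `γ`
distinct deleted links, robustness is the fraction of targets whose output
is unchanged. The fraction is computed over *signal-receiving* targets
(`k_in ≥ 1` in the intact network), matching the analytic treatment, which
excludes the `k_in = 0` class throughout. Under OR, a target with `k`
inputs flips on deletion of one specific link only in the single input
state where that link's controller is the sole active one: probability
`2^-k` over the `2^k` input states. To first order in `γ/L`,

    F_γ(k) = k (γ/L) 2^-k,        R(k) = 1 − F_γ(k),

valid for `γ ≪ L` (the regime of the default mutation fraction `γ/N = 0.1`).
AND equals OR exactly by the complement symmetry `OR(x) = ¬AND(¬x)`;
MAJORITY is simulated only. Printed-formula reconstruction note: the per-k
closed form, the entropy series and the model expectations below are each
validated against independent brute-force enumeration in the test suite
before being relied on.

**Output states.** `Ω` is the number of distinct output vectors over all
`2^M` inputs (enumerated exactly up to `M = 22`, in chunks). The large-
network estimate treats targets as independent: under OR the output of a
`k`-input target is 0 with `q₀ = 2^-k`, so its entropy is
`S(k) = −q₀log₂q₀ − q₁log₂q₁` and `log₂Ω ≈ N⟨S⟩` (returned in log₂ form to
avoid overflow at biological `N`). Expanding `−(1−q₀)log₂(1−q₀)` in powers
of `q₀` expresses `⟨S⟩` through the primitives `E[2^(−ηk)]` and
`E[k·2^(−ηk)]`; the series is truncated at `η = 3` by default (error < 0.03
bits per node at `k = 1`, smaller beyond). Closed forms: for the geometric,
`E[2^(−ηk)] = p·2^(−η)/(1−(1−p)2^(−η))` and
`E[k·2^(−ηk)] = p·2^(−η)/(1−(1−p)2^(−η))²`; for the zero-excluded Poisson,
`E[2^(−ηk)] = e^(−λ)(e^(λ2^(−η))−1)/(1−e^(−λ))` and
`E[k·2^(−ηk)] = λ2^(−η)e^(λ2^(−η))e^(−λ)/(1−e^(−λ))`; binomial expectations
are summed directly. All are cross-checked against numeric summation in
tests.

The estimate's independence assumption is rough on small dense networks:
measured against exhaustive enumeration on 6×6 ER ensembles it is within
~7% of the mean `log₂Ω` at `⟨k_in⟩ = 3` but worse toward the density
extremes (zero-degree targets below, inter-target correlation above); the
regression test pins it at the mid-range density with a 25% band.

**The sweep.** `fig3_sweep` draws a fresh ER network per trial (density
`D = ⟨k_in⟩/M`), a fresh input and a fresh deletion set, and reports
simulated robustness (with Monte-Carlo SE) and mean `Ω` per rule next to
the analytic curves. Two closed-form columns are provided deliberately:
`R_closed` evaluates the degree-model expectation (exact zero-excluded
binomial, since the sweep's `M = 10` is far from the Poisson limit) at the
*expected* `L = N⟨k_in⟩`, while `R_closed_paired` applies the same per-k
formula to each simulated network's realized degree sequence and realized
`L`, removing ensemble-fluctuation mismatch (Jensen-type bias of `γ/L` at
sparse densities) from the formula-vs-simulation comparison. Default sweep
conditions are `M = N = 10`, `γ/N = 0.1`, 1000 trials, `⟨k_in⟩ = 1..8`. The
closed form depends on `N` and `γ` only through `γ/L = (γ/N)/⟨k_in⟩`, so at
fixed mutation fraction it is exactly `N`-independent. Monotonicity
statements (robustness increasing, output states decreasing in `⟨k_in⟩`,
with the marginal robustness gain above ~5 much smaller than below) are
asserted on the analytic curves: at 1000 trials the simulated increments
above `⟨k_in⟩ = 5` (~1e-3) sit below Monte-Carlo noise, and the simulated
mean `Ω` is additionally non-monotone at sparse densities because
zero-degree targets freeze part of the output vector — a finite-size
feature of the `M = N = 10` ensemble, not of the model.

## Simulated libraries and biomimetic subsets

`simulate_library` draws `k_out` per compound and `k_in` per target by
inverse-transform sampling of geometric models (default: 1500 compounds ×
518 targets at `⟨k_out⟩ = 55`, the in-side mean matched by conservation to
`⟨k_in⟩ ≈ 159`), then pairs out-stubs with in-stubs uniformly at random.
Two repairs keep the result a simple bipartite graph with the requested
marginals:

* *Stub reconciliation*: whichever side's stub total is short has random
  nodes' degrees re-drawn, accepting only gap-reducing redraws, until the
  totals agree to within one; the final odd stub is discarded. (A bounded
  iteration cap with a forced single-node fix backs this up; it is logged
  and perturbs one degree.)
* *Collision repair*: duplicate links are resolved by a local pair swap with
  a uniformly chosen unique link that preserves every node's degree;
  after 500 failed attempts the duplicate is dropped and logged (rare and
  only material at extreme densities).

`rejection_subsample` draws compounds uniformly and keeps a compound with
`k_out = k` with probability `f_BM(k)/(c·f_lib(k))`, where `f_BM` is the
geometric pmf at the biomimetic mean `k_out,BM`, `f_lib` the library's
empirical `k_out` pmf and `c = max_k f_BM/f_lib` the rejection constant, so
the kept set's `k_out` law is `f_BM` restricted to the library support. The
acceptance form is a documented reconstruction chosen so that its output
property — an exponential `k_out` at the reduced mean — is the stated
intent; parameter-recovery tests confirm the kept-set fitted mean lands
within 10% of `k_out,BM`.

The profile-driven alternative ranks targets (the ranking criterion —
disease relevance, expression, mutation status — is the caller's concern),
discretizes a non-increasing desired pdf into integer demands `b` by
largest-remainder rounding to a link budget (then sorts non-increasing,
restoring monotonicity that rounding ties can break), and solves
`min Σx  s.t.  Ax ≥ b, x ∈ {0,1}` exactly with scipy's branch-and-bound
MILP. Feasibility is pre-checked (`A·1 ≥ b`) with offending targets listed;
degeneracy is probed by re-solving with a no-good cut at the same
objective, reported as `alternative_exists`.

## Synthetic data: what it does and does not emulate

Generators produce the wiring archetypes the analyses assume — bipartite ER
at a given density, geometric-out-degree configuration networks
("biological-like"), one-to-one and one-to-many layouts — with seeds giving
byte-identical edge lists. Published per-network parameters (node counts,
mean link counts, densities, overlap percentages of ten real networks) are
carried verbatim as reference records and used to parameterize generators
and aggregate checks. The synthetic networks reproduce the *topological
statistics* (densities, degree laws, overlap levels, giant components) but
none of the biological identity: no gene annotation structure, no
binding-affinity weighting, no correlation between a node's roles in
different networks. Tests passing on synthetic networks therefore validate
the estimators and the model mathematics, not claims about any particular
organism's wiring.

## Numerical choices and problem sizes

* Exhaustive `Ω` enumeration is limited to `M ≤ 22` and chunked at 2^14
  inputs; the robustness enumeration oracle is used only at `M, N ≤ 6`.
* Default sweep and test problem sizes (10×10 networks, 1000 trials, 200
  oracle networks, 100-network `Ω`-estimate ensembles, n = 10⁴ fit
  recovery) were chosen as the smallest ensembles at which the targeted
  contrasts clearly exceed sampling noise.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; fixture seeds are fixed constants.
* `mutation_fraction` maps to an integer `γ = round(0.1·N)` in simulation;
  the closed form accepts fractional `γ` (only `γ/L` enters), which is what
  makes exact `N`-independence checks possible.

## Known limitations

* The closed-form robustness is first-order in `γ/L`; no multiple-hit
  correction. It degrades as `γ → L`.
* MAJORITY has no analytic robustness/entropy here; simulation only.
* The `Ω` estimate ignores inter-target correlation and the `2^M` ceiling;
  it is an order-of-magnitude tool away from mid densities.
* Library simulation reconciles stub totals stochastically; prescribed and
  realized marginals agree in distribution (goodness-of-fit tested at
  α = 0.01) but individual degree sequences are not reproduced exactly when
  repairs fire.
* No weighted or signed links, no multi-step dynamics or attractors, no
  feedback from targets to controllers.
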