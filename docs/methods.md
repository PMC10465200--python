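# Methods

## Trophic levels and incoherence

For a simple directed graph with adjacency `A` (`A_ij = 1` iff `i → j`),
levels solve `Λ h = v` with `Λ = diag(k_in + k_out) − A − Aᵀ` and
`v = k_in − k_out`. `Λ` is the Laplacian of the underlying undirected graph,
hence symmetric positive semi-definite with one zero mode (the constant
vector) per weakly connected component. We therefore pin the lowest-index
node of each component to zero, solve the reduced positive-definite system
(dense Cholesky-backed solve below 400 free nodes, sparse LU above), verify
the residual `‖Λh − v‖ ≤ 1e−8 ‖v‖ + 1e−12`, and shift the assembled vector so
the global minimum level is zero. Pinning gives a deterministic, testable
contract; the min-zero shift is pure convention and cannot change `F`, which
is translation invariant per component.

Incoherence is `F = mean over edges of (h_j − h_i − 1)²`. The levels are the
exact minimizer of this quadratic — the test suite checks this both by random
perturbation and against a generic BFGS minimization on small random graphs.
At the minimum the identity `F = η²/(1+η²)` holds with `η = σ/μ` computed
from the edge level differences (population standard deviation, `ddof = 0`);
for balanced graphs `μ = σ = 0` and we report `η = inf`, consistent with
`F = 1`.

Disconnected graphs are solved per component and `F` remains the global edge
average; components without edges are an error (levels are undefined), except
inside the generator, where isolated seed-graph nodes are assigned level 0.

## Network generator

The generator emulates growing networks of fixed size `N`, mean degree
`⟨k⟩` and tunable incoherence. Stage one gives every non-basal node in-degree
exactly one, source uniform over the other nodes; basal nodes (an explicitly
configured count, default 0) never receive in-edges, in either stage. Stage
two freezes the seed-graph levels `h̃` and accepts absent ordered pairs with
probability `exp(−(h̃_j − h̃_i − 1)²/(2 T_gen))` until the total edge count
reaches `round(N⟨k⟩)` (seed edges included in the budget).

Sampling: the default scheme ranks all candidate pairs by
`log w + Gumbel(0,1)` noise and takes the top `m` — Gumbel-top-k is exactly
sequential weighted sampling without replacement, i.e. the same edge
distribution as an accept/reject loop, but it works in log-space and cannot
stall when weights underflow (at `T_gen = 0.01` a level gap of 3 has weight
`e^−200`). A literal rejection sampler is provided as `method="rejection"`
with a proposal cap; a two-sample KS test in the suite confirms the two
schemes produce indistinguishable incoherence distributions.

What the generator does *not* emulate about real networks: heterogeneous
(e.g. scale-free) degree distributions, degree–level correlations beyond
those induced by the growth rule, weighted or bidirectional-by-construction
edges, and multi-component structure. Passing ensemble tests therefore
demonstrates the structural mechanism (hierarchy ↔ incoherence ↔ influence),
not quantitative predictions for any particular real system.

## Dynamics

*Majority vote*: parallel sweeps of `S_i ← sgn(Σ_j A_ji S_j)`. `sgn(0)` and
empty in-neighbourhoods retain the previous state — the minimal-intervention
rule, which preserves absorbing consensus. The map is deterministic, so fixed
points and period-2 cycles are detected and the remaining sweeps
short-circuited (parity-correct); a reference fixed-step loop in the tests
guards the bookkeeping.

*Voter model*: each node copies a uniformly chosen in-neighbour, in parallel
sweeps to mirror the majority-vote choice; an asynchronous single-node-event
mode is available behind a flag but makes no equivalence claim. "1000
updates" is read as 1000 parallel sweeps throughout.

*Kuramoto*: `dθ_i/dt = ω_i + (K/k_in_i) Σ_j A_ji sin(θ_j − θ_i)`, integrated
with adaptive RK45 (`rtol 1e−6`) from identical zero phases; basal nodes get
a zero coupling term. Phases stay unwrapped, so per-node frequencies are
plain phase differences over time differences, averaged across 50 evenly
spaced samples in `[t_end/2, t_end]`. Default coupling in sweeps is
`K = 20⟨k⟩`, far above the locking threshold from a synchronized start.

A note on the high-incoherence limit: in the locked state the collective
frequency equals `π · ω`, where `π` is the stationary distribution of the
random walk that steps to a uniform in-neighbour (this follows from
linearizing the coupling around synchrony). With 20% of nodes at `ω = −1` a
perfectly uniform weighting would give `+0.6`, and the residual hierarchy of
high-temperature networks weights the low-level (perturbed) nodes above
uniform, so the measured mean frequency settles near `+0.4` rather than
approaching `+1`. The package reproduces this to 7 significant digits
against the closed-form stationary-distribution computation.

## Strategy games

Strategies are nodes; an edge source dominates its target (so successful
strategies sit at low trophic level; a flag flips the convention, which the
direction-reversal symmetry makes equivalent). A well-mixed population
(default 1000 players) meets in uniformly random distinct pairs; the loser
adopts the winner's strategy, reciprocal edges are resolved by a fair coin,
unrelated strategies do nothing. Success is time-and-player-averaged
occupancy over the run (default 1e5 encounters; occupancy is accounted
lazily, so the run is O(encounters)). Ranking comparisons use the normalized
area under cumulative occupancy curves, which is scale-free — the encounter
count and per-game normalization affect curve values but not area orderings.

## Spectral structure

Eigenvector localization uses all `N` right eigenvectors of the dense
adjacency: IPR on L2-normalized moduli, normalized Shannon entropy on
L1-normalized moduli with `0 ln 0 = 0`. Complex eigenvectors are handled by
taking elementwise moduli before normalization. For very coherent
(near-nilpotent) adjacencies the dense solver's output is reported as
computed; no regularization is applied. The left/right overlap takes the
principal eigenvectors of `A` and `Aᵀ` (largest modulus, ties toward the
largest real part; ARPACK above 300 nodes with a dense fallback), moduli, L2
normalization, then the dot product; a nilpotent adjacency triggers a
warning since the principal pair is then ill-defined.

The scaled pseudospectral radius is `(ρ_ε − ρ)/ε` with
`ρ_ε = max{|z| : σ_min(zI − A) ≤ ε}` (spectral-norm perturbations, the
standard pseudospectra convention; `ε = 1e−3` by default). The grid search
works on the complex Schur form, so each `σ_min` evaluation is inverse power
iteration with two triangular solves; rays through the largest-modulus
eigenvalues are bisected directly and a 64-angle circular sweep with coarse
scan plus bisection (radius tolerance `1e−9` relative) refines the maximum.
For normal matrices this returns 1 to three decimals; for a 10-node path it
reproduces the `ε^(1/N)` Jordan-block scaling within a few percent. The
`sampled` method (max spectral radius over random norm-`ε` perturbations) is
a logged lower bound used for cross-checking.

## Ensemble protocols and problem sizes

Sweep drivers derive one deterministic sub-seed per (temperature, replicate)
cell from a `SeedSequence`, record it in the output row together with the
realized `F`, and skip (with a logged warning) configurations that fail to
generate. Default problem sizes are desk-scale choices that keep the full
test suite in the minutes range while leaving the qualitative transitions
unambiguous: influence transitions at `N = 100`, `⟨k⟩ = 5`, 10 seeds per
temperature extreme; structure sweeps at `N = 100`, `⟨k⟩ = 20`, 10
temperatures × 10 seeds; strategy games at 100 networks per regime;
generator calibration at `N = 500`, `⟨k⟩ = 20`, 30 seeds. Paper-scale
parameters (`N = 500–1000`, 20–30 networks per temperature, 1000-network
scatter clouds) are plain arguments away.

## Known limitations

* Weighted trophic analysis and the legacy basal-node ("ecological") level
  definition are out of scope; only the `η ↔ F` conversion is provided.
* The pseudospectral grid search assumes the outer boundary is captured by a
  64-ray sweep; pathological pseudospectra with very narrow outward lobes
  between rays could be underestimated (the sampled cross-check bounds this).
* The generator's analytic calibration `F ≈ T_gen/(1+T_gen)` degrades for
  small dense networks at low temperature and saturates below the prediction
  at very high temperature (`η² < T_gen` there); calibration checks use
  `N = 500` accordingly.
* GraphML loaders strip self-loops and collapse multi-edges with a logged
  warning and operate on the full (possibly multi-component) graph.
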