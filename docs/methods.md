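# Methods

## Discrete multiplex: analytic Lyapunov theory

The discrete model couples doubling maps through the supra-Laplacian
L = ε L^B + γα L^A, where L^B = blockdiag(B₁, B₂) collects the intra-layer
Laplacians and L^A = [[D₁, −A], [−Aᵀ, D₂]] is built from the inter-layer
adjacency A with its row/column degree matrices. Because the Jacobian
2I − L is constant, every Lyapunov exponent is λᵢ = log|2 − μᵢ| exactly;
no trajectory statistics are involved, and the mod-1 wrap of the orbit has
no effect on any Lyapunov quantity (the package still iterates orbits for
diagnostics, with tangent growth always computed from 2I − L, never from
finite differences of the orbit).

**Mirror multiplexes.** For two identical layers in which every node links
to its mirror node the eigenvalues pair up as μ₂ᵢ₋₁ = εωᵢ,
μ₂ᵢ = εωᵢ + 2γα. When the mirror carries multiplicity m (l₁₂ = mN₁), the
multiplicity enters this closed form through the global density α = l₁₂/N₁
while L^A keeps the binary connection pattern; the package therefore
builds L^A from the 0/1 pattern and counts multiplicity in l₁₂ and α,
which makes the pairing exact for every m (verified against the dense
symmetric eigensolver to 1e−10). The general constructor takes an
arbitrary duplicate-free inter-edge list and promises no closed form.

**Weak-coupling expansions.** First-order expansions of Σ log|2 − μ| give
H_KS ≈ N₁ log 2 − (ε/2)S for a single layer, H_KS ≈ N log 2 − (ε/2)S′ −
γl₁₂ for the all-positive multiplex (S′ = 2S), and the mixed-sign variant
with u non-positive exponents that keeps log(1 − γα) unexpanded. The
implementation emits a warning (never an error) when ε·ω_max > 0.5 or
γα > 0.5, since validity only requires the couplings to be "small" and the
exact routes remain available. Exponents equal to zero are counted in u
(the non-positive count), making u deterministic. μᵢ = 2 exactly raises a
degenerate-spectrum error with a hint to perturb the couplings.

A documented discrepancy: the source text states that all-positive spectra
require ε > 1/ω_max, while |2 − εω| > 1 gives εω < 1 (small-ε branch),
i.e. ε < 1/ω_max. The package always evaluates the exact condition
|2 − μᵢ| > 1 and does not encode the printed inequality.

## Extensivity classification and invariance constants

Extensivity is asymptotic; a finite-size test needs explicit tolerances.
`fit_hks_scaling` combines an unweighted OLS fit H_KS = σN + ν (slope
standard error from the usual OLS formulas; no weighting is prescribed by
the theory) with a log–log fit whose slope estimates θ + 1 in
H_KS ∝ N^{θ+1}. A family is classified *extensive* iff |θ̂| ≤ 0.1 (config)
and the linear fit has R² ≥ 0.95 (config); otherwise the sign of θ̂ decides
sub- vs super-extensive. Families containing non-positive H_KS values
cannot be log-fitted and are reported sub-extensive with θ̂ = NaN.
Because the intercept ν biases θ̂ downward at small N, the scaling
experiments use size ranges (up to N = 256 for the analytic families)
where the asymptotic exponent is resolved.

The invariance constants C = d̄/ω_max, C₁ = ε·ω_max and C₂ = C₁(C − 1) + 1
govern the collapse of λᵢ vs i/N. C₂ equals the spectral average
(1/N₁)Σᵢ(C₁ωᵢ/ω_max + 1 − C₁) identically — this identity, which holds to
machine precision for any layer, is the module's self-consistency anchor
and is computed independently on both sides. In the ε = 1/N convenience
form of the extensivity condition, the mean intra-degree is modelled as
d̄ = aN + ξ; note that a is a growth rate distinct from the
inter-connection density α = l₁₂/N₁ (two historically overloaded symbols;
the package keeps them as separate fields). For fixed layer spectra the
two exponent branches of that case tend to log 2 (odd branch) and 0 (even
branch) as N → ∞.

## Hindmarsh-Rose multiplex

Each neuron follows the three-variable HR system (membrane potential p,
fast recovery q, slow adaptation n) with the canonical constants a = 1,
b = 3, c = 1, d = 5, s = 4, p₀ = −1.6, r = 0.005, I_ext = 3.25, at which a
single neuron is chaotic with multi-scale spiking/bursting. Electrical
(diffusive) coupling acts through the intra-layer Laplacian on p;
chemical coupling acts between layers as −γ(pᵢ − V_syn)Σⱼ Aᵢⱼ K(pⱼ) with
the sigmoid K(p) = 1/(1 + e^{−λ(p−θ)}), θ_syn = −0.25, λ = 10 and
V_syn = 2 (excitatory). Electrical coupling is intra-layer only and
chemical coupling inter-layer only throughout.

**Integration.** Fixed-step classical RK4, default dt = 0.01. A fixed
step keeps the tangent-frame propagation consistent with the flow; the
slow variable (r = 0.005) demands long horizons, which rules out adaptive
steppers for reproducible tangent dynamics at this scale. A step-halving
test (dt 0.01 → 0.005 over t = 100) bounds the trajectory discrepancy
below 1e−4. Divergence (|p| > 10³) aborts with a diagnostic.

**Lyapunov spectra.** Tangent-space QR: the flow and an orthonormal frame
are integrated jointly (stage Jacobians evaluated at the RK4 stage
states), with QR re-orthonormalisation every renorm_interval = 1.0 time
units and exponents read off the time-averaged log of the R diagonal.
Defaults: t_transient = 1000 discarded, t_total = 20000 averaged — at
these budgets single-neuron exponents are reproducible across seeds to
±0.005 and the neutral (flow-direction) exponent sits within a few 1e−5
of zero. Two internal oracles validate the machinery: (i) on the linear
flow ẏ = (CI − L)y the computed exponents match the closed form C − μᵢ to
≲1e−3; (ii) the exponent sum matches the orbit-averaged Jacobian trace
(tracked in the same run) to well under 2%. A convergence flag monitors
the running λ₁ estimate over the last 20% of the averaging window
(tolerance 0.01, config). Initial states are drawn per neuron from
p ∈ (−1.6, 1.6), q ∈ (−1, 1), n ∈ (2.8, 3.2) — a spread around the
attractor — in the documented stream order (all p, then all q, then all
n) from one seeded generator that also seeds the tangent frame.

The tangent propagation is matrix-free: the Jacobian-times-frame products
are assembled from the coupling matrices blockwise, so a run tracking m
exponents costs O(N²m) per stage instead of O(N²·3N). Network runs track
m = N + 2 leading exponents during evolution screening; the truncation
cuts inside the near-zero band, so the H_KS it misses is negligible,
and final networks are re-evaluated with the full frame. An explicit
dense Jacobian (finite-difference-checked) is exported for verification.

## Greedy evolution and the desk-scale experiment

Evolution starts from a multiplex with one inter-edge, visits every
absent (i, j) pair exactly once in seeded random order, and keeps an edge
iff the estimated H_KS strictly increases — ties are rejections, matching
the strict-increase rule, so accepted steps are strictly monotone. The
couplings and intra-topologies stay fixed; only α grows. The estimator is
a contract: the analytic map estimator makes the whole greedy path exact
and bit-reproducible (the fast oracle for the logic); the HR estimator
evaluates a reduced-budget Benettin run with identical initial conditions
for every candidate, and an optional acceptance margin δ (default 0, the
literal rule) guards against estimator noise if desired. A (γ, ε) sweep
runs one evolution per grid point from the same initial network; argmax
ties break toward smallest γ, then smallest ε.

The desk-scale HR extensivity experiment uses sizes N ∈ {8, 12, 16} (two
equal Watts–Strogatz layers of N/2 nodes, k = 2, p_rewire = 0.2, different
seeds per layer, so S_in = 2N + 2 exactly), fixed couplings
ε = 0.005 ≪ γ = 0.1, screening budget dt = 0.02, t_transient = 200,
t_total = 1500 with m = N + 2 exponents, and a final full-spectrum
re-evaluation at dt = 0.01, t_total = 5000. These problem sizes keep the
whole experiment at a few minutes on one CPU while leaving the
qualitative conclusions (positive σ, linear degree sums) intact; they are
far below the scale needed to reproduce published slope values for
O(100)-neuron sweeps, which is out of scope for the bundled experiments.

## Synthetic data and what passing tests show

All networks are generated programmatically: circulant rings (total
degree k, k/2 neighbours per side, so S = kN₁), Watts–Strogatz rewiring
(edge-count preserving; regenerated with an incremented seed when
disconnected, at most 100 attempts), complete graphs and Erdős–Rényi
graphs (same connectivity policy). The generators emulate the *topology
classes* of the theory — their degree-sum scaling is what the scaling laws
consume — not any empirical connectome: real neuronal networks have
weighted, directed, plastic synapses, heterogeneous neurons and noise,
none of which the model contains. Passing tests therefore demonstrate the
internal consistency of the theory and its numerical machinery, not a
statement about biological tissue.

## Known limitations

- Two layers only; undirected, unweighted intra-layer graphs.
- No inhibitory synapses, delays or noise in the HR model; network sizes
  beyond a few hundred neurons are impractical without further
  parallelism.
- Benettin estimates at screening budgets carry O(1e−3..1e−2) noise per
  exponent; the greedy rule with δ = 0 will occasionally accept or reject
  on noise, as any literal implementation must.
- The extensivity classifier is a finite-size heuristic; near the
  tolerance boundaries its label depends on the chosen size range.
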