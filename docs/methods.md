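# Methods

## Model and assumptions

A macromolecule with `n` ligand-binding sites and `N` conformations is
represented as a finite-state continuous-time Markov process on the product
state space `(conformation, bound subset)` — `N·2^n` vertices. The package
works throughout at thermodynamic equilibrium (detailed balance): only
ratios of forward to reverse rates matter, and these equilibrium labels are
determined by free-energy differences, `ℓ_eq(i→j) = exp(−(Φ_j−Φ_i)/kBT)`.
Equivalently, label products around every cycle equal 1 (the cycle
condition), and steady-state probabilities are proportional to path
products `μ_v` of labels from a reference vertex.

Assumptions inherited from this setting:

* **Grand-canonical ligand**: the free ligand concentration `x` is a fixed
  reservoir parameter appearing linearly in binding-edge labels; binding
  does not deplete it.
* **Conformational selection**: conformations pre-exist binding (product
  structure). Induced fit can be emulated by conformations with very small
  horizontal weight, but no induced-fit-specific machinery is provided.
* **Single ligand species**, non-overlapping sites.
* **Steady state only**: coarse graining preserves equilibrium occupancies,
  not dynamics; transient relaxation is out of scope.

Within a conformation, the independent binding parameters are the `n` bare
association constants `K[c,i,∅]` (units: concentration⁻¹) and the
intrinsic higher-order cooperativities `ω[c,i,S]` (dimensionless) for the
pairs with `i < S` (`i` below every element of `S`) — `2^n − 1` numbers per
conformation. Constants for any other `(i, S)` are *derived* from these by
hypercube path products, never stored, so the cycle condition holds by
construction rather than by trusted input. Horizontally, only the `N − 1`
path products `λ_c` of the empty-binding layer are free; every other
horizontal label follows from detailed balance. The concrete horizontal
edge set is not physically determined at equilibrium; the default
realization is a star from the reference conformation, and the test suite
checks the steady state is identical for star, path and complete
realizations.

## Coarse graining and effective parameters

Partitioning any equilibrium graph into blocks and summing `μ` per block
yields a quotient graph, again at equilibrium, whose block probabilities
equal the summed fine probabilities. Partitioning an allostery graph by its
horizontal layers gives a single effective binding hypercube; its labels,
divided by `x`, define the effective association constants. These are
computed two independent ways — closed-form λ-weighted conformational
averages, and explicit coarse-graining of the built graph — and the tests
require their agreement to 1e-10, with the Laplacian-kernel steady state
(valid away from equilibrium, solved by least squares with the
normalisation row appended) as a third, structurally independent oracle.

Elementary consequences verified as properties: effective HOCs are
independent of `x`; `ωϕ[i,∅] = 1` exactly; a single conformation returns
its intrinsic HOCs; for MWC-like ensembles (independent identical sites)
the effective HOCs are moment ratios of the per-conformation constant and
form a non-decreasing chain `1 ≤ ωϕ_1 ≤ … ≤ ωϕ_{n−1}`, strict unless the
constant is degenerate; and for two conformations with two independent
sites, negative effective cooperativity occurs exactly when the two sites'
constants order oppositely across the conformations.

## Binding functions

The effective partition polynomial `Ψ(x) = Σ a_s x^s` has `a_s` equal to
sums over size-`s` subsets of ordered products of effective constants
(binding the highest site first, so only independent parameters enter).
Saturation uses the exact moment identities of the subset-size distribution
`Pr_S ∝ a_s x^s`: `f = m₁/n` and `x·f′(x) = (m₂ − m₁²)/n`, both evaluated
with log-sum-exp, so no finite differencing is involved anywhere.

Normalization solves `f(u₀.₅) = 1/2` by Brent root finding on
`log10 x ∈ [−12, 12]` (tolerance 1e-13 in the log-domain argument); a curve
whose half-point lies outside that range raises an error. Shape measures
scan the analytic derivative of the normalized curve on a 512-point log
grid over `[1e-3, 1e3]` and refine the bracketed maximum with bounded
scalar minimisation (tolerance 1e-12 in log-x); a maximum at a grid end is
reported with a boundary flag (e.g. the `h = 1` Hill function, whose slope
is maximal as `x → 0`).

The Hill deviation `δ(g, H_h)` is the mean absolute difference over a fixed
grid of 1000 logarithmically spaced points between 0.0005 and 5
(`0.0005·u^j`, `j = 0..999`, `u = 10^(4/999)`), kept fixed so that reported
errors are comparable across runs.

## Higher-order measures

The free-energy landscape `Φ_S` over all `2^n` subsets (dimensionless, kBT
units, no zero-point convention: `Φ_∅` is carried explicitly) is
interconverted with three measures: HOCs (edge quantities), residual free
energies (vertex quantities; computed both by the peel-off recursion and by
the signed Möbius/inclusion–exclusion sum, which must agree), and
mutant-cycle higher-order couplings (ordered perturbation sequences around
an offset). Identities exercised as properties: couplings at empty offset
equal residual free energies; couplings are invariant under permutation of
the perturbation sequence; the HOC expressions for residuals are invariant
to the anchor-site choice. Note the order-counting mismatch between
languages — the `k = 2` coupling corresponds to the order-1 (pairwise)
HOC — is deliberately left exposed rather than reconciled. Perturbation
chemistry (which residue replaces which) is not modelled.

## The flexibility construction

Targets are `β_i > 0` and `α[i,S] > 0` for `i < S` — `2^n − 1` numbers.
The constructed ensemble has one conformation per site subset `T`, bare
constants `κ_i` (for `i ∈ T`) or `ε·κ_i` (otherwise), no intrinsic
cooperativity, horizontal weights `λ_T` given by nested α-products times
`δ^|T|`, and `κ_i = β_i·Σλ / Σ_{T∋i} λ`. Exposed free parameters: `2^n − 1`
horizontal weights plus `n` κ's.

The two controls act *nested*: the residual error scales like
`O(ε/δ) + O(δ)`, so `ε` must shrink faster than `δ`. The worked four-site
examples use `δ = 1e-7` with `ε` between `1e-12` and `1e-16` and achieve
maximum relative errors of 0.00105–0.00386 (recomputed at run time by
`verify`, never hard-coded). Because `λ_T ~ δ^n` and vertical weights pick
up `ε` powers, all path-product and averaging arithmetic is done in the
log domain with log-sum-exp; naive products underflow double precision
well before the worked examples' control values. `verify(..., attribute=True)`
re-runs the construction at `ε/10` and at `δ/10` to show which control
limits the residual (shrinking `δ` alone can worsen the `ε/δ` term, so
this is attribution, not a bound).

Exact (rather than asymptotic) realization, constructions with fewer
conformations, and bounded parameter ranges are open problems and not
attempted.

## Hill-function search

The search space is `N·n` bare constants in `[1e-4, 1e4]` plus `N − 1`
horizontal labels in `[1e-6, 1e6]` (defaults `n = 6`, `N = 4`: 27
parameters), sampled and perturbed logarithmically, clamped at the box.
Step 1 screens random draws for normalized curves with position
`γ ∈ [0.5, 1.2]` and steepness `ρ ∈ [0.5, 1.3]`. Step 2 perturbs each
parameter with probability `p` by a log-uniform factor in `[m, M]`,
accepting improvements always and deteriorations with fixed probability
`β` — a single Bernoulli draw, deliberately *not* Metropolis–Hastings:
acceptance is independent of the size of the error increase. `p` and
`[m, M]` anneal as the best error falls; the default piecewise schedule is
`(p, m, M) = (0.5, 0.1, 10) → (0.2, 0.5, 2) → (0.05, 0.9, 1.1)` at error
thresholds 0.01 and 0.001. These schedule constants are this package's
own documented defaults and are freely overridable in `MCSettings`.

One RNG stream per run, consumed in a fixed order (proposal mask, then
replacement values, then — only on a worsening move — the acceptance draw),
makes runs bit-reproducible from the seed. The inner loop evaluates the
partition polynomial by the factorised independent-sites route
(λ-weighted product polynomials); `evaluate` cross-checks it against the
generic effective-parameter route.

Reaching `δ < 2e-4` for `h = 6` typically needs long runs (the iteration
cap is 5×10⁶ and a run of that length takes hours on one CPU at ~2.5 ms
per iteration); the test suite therefore exercises the loop's deterministic
guarantees — monotone best-so-far error, box respect, bitwise seeded
reproducibility — on runs of a few thousand iterations, which already
reduce the error by two orders of magnitude (0.083 → 8.8e-4 in 3000
iterations for the first screened seed). Whether the screening windows
guarantee eventual success is unknown; screening exhaustion is a reported
outcome, not an error in the procedure.

## Synthetic fixtures

`interface.random_ensemble` draws bare constants, intrinsic HOCs (optional)
and horizontal weights log-uniformly within configurable ranges
(defaults: K in `[1e-2, 1e2]`, λ in `[1e-3, 1e3]`, ω in `[0.1, 10]`),
seeded and byte-reproducible. This emulates the scale-free spread of real
association constants but none of the structure of real proteins —
no site symmetry, no correlation between conformations, no energetic
realism — so passing property tests certify the *mathematical identities*
(coarse-graining conservation, route equalities, moment chains) on generic
parameter values, not agreement with any experimental system.

## Problem sizes and tolerances

Tests run ensembles up to `n = 6` sites and `N = 16` conformations and
random graphs of 8–12 vertices; these sizes make every identity checkable
against the dense Laplacian oracle in well under a second while exercising
all code paths. Default tolerances: cycle-condition residual 1e-9 per
log-unit edge; probability conservation 1e-10–1e-12; dual-route equalities
1e-10 relative. Degenerate inputs: single-vertex graphs are valid (trivial
steady state); `x = 0` returns zero saturation exactly; full binding
subsets have no free site and are excluded from effective-constant
indexing.

## Known limitations

* Equilibrium only; non-equilibrium steady states are reachable solely
  through the Laplacian oracle, and entropy-producing cycles are rejected
  by the equilibrium code paths.
* One ligand species; no overlapping or competing sites.
* The coarse graining preserves occupancy statistics, not kinetics.
* The Hill search is a heuristic: no convergence guarantee, no claim about
  the minimal number of conformations needed for a given Hill coefficient.
* Binding polynomials are evaluated by log-sum-exp over subset sums;
  for `n` much beyond ~12 the `2^n` subset enumeration in the generic
  (non-factorised) routes becomes the bottleneck.
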