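# Methods

This note records the model conventions, parameter meanings, numerical
choices and known limitations behind catkinetics.  It states no empirical
result that the test suite and `scripts/acceptance.py` do not themselves
compute.

## Categorical master equations

A system of binary chemical species occupies one of 2^n joint states; its
distribution `p(τ)` evolves linearly, `dp/dτ = L p`, under a transition
rate matrix with zero column sums and non-negative off-diagonal entries.
Conventions:

* **Stationary distribution.** `p(∞)` is the right singular vector of `L`
  with zero singular value.  Zero is detected scale-invariantly: singular
  values below `1e-10 × σ_max` count as zero.  Exactly one must qualify —
  none signals an invalid rate matrix, more than one a reducible chain
  (multiple communicating classes), and both are reported as distinct
  errors rather than silently resolved.  The singular vector of an
  irreducible chain is single-signed; it is flipped to be non-negative and
  normalized to unit sum.
* **Flow decomposition.** With `Λ = diag(p(∞))⁻¹` and `A = L Λ⁻¹`,
  `Q = (A − Aᵀ)/2` and `Γ = −(A + Aᵀ)/2` give `L = (Q − Γ)Λ`.  Because
  both row and column sums of `A` vanish, all three flow modes conserve
  total probability exactly; solenoidal trajectories leave the simplex by
  developing *negative* entries, which is why solenoidal simulation
  returns unnormalized states and applies no clamping.
* **Free energy.** `F(p) = p·(ln p − ln p(∞)) + z(∞)` with `0 ln 0 ≜ 0`.
  The evidence constant `z(∞)` defaults to 0, so `F` is the KL divergence
  for a closed system; callers studying open systems may supply a
  constant.  Mass of `p` outside the support of `p(∞)` makes `F` infinite
  and raises a dedicated error (never an overflow).
* **Linearized functional.** The gradient `ln p − ln p(∞) + 1` linearizes
  to `Λp` around `Λp = 1`.  The induced quadratic `½ p·Λp` is exactly
  conserved by the solenoidal flow (`x·Qx = 0`) and is used only as a
  diagnostic for mode simulations; the domain of validity of the
  linearization is not characterized, so exact `F` is always what gets
  reported.

## Generative models and mean-field operators

A generative model is a list of binary species (index 0 = present) plus
conditional probability factors whose product is the joint steady state.
The joint index orders species as declared, leftmost varying slowest;
every indicator row-vector in the operator basis uses the same order.

The **Markov blanket** of a species is the union of the members of every
factor it appears in, minus itself — parents, children, co-children and
children's co-parents.

Each species' mean-field operator is `L_i = λ_i a v_i` with `a = [1, −1]ᵀ`
(probability conservation per species) and `v_i` a weighted sum of
Kronecker indicator products restricted to subsets of the blanket plus the
species itself.  `λ_i` defaults to 1 and only sets the time scale.  The β
coefficients are fixed as follows:

* **Reaction structure.**  When the steady-state support splits the
  relevant species into a co-present set A and an anti-present set B (the
  two sides of a reversible reaction), every member gets the *shared* flux
  `J = β r_B − r_A` with its own sign (−J on side A, +J on side B), so the
  summed presence probability is conserved.  β comes in two flavours:
  `correction="exact"` solves `v·p(∞) = 0` against the true joint
  (β = mass(A)/mass(B)); `correction="marginal"` (the default) uses the
  mean-field-corrected power form — the product of side-A steady-state
  present-marginals over the product of side-B marginals, the
  `α^{n_substrates}/(1−α)^{n_products}` rule in the symmetric case — which
  makes the *mean-field* fixed point match the model's marginals.  The
  corrected operator is orthogonal to the product-of-marginals steady
  state rather than the exact joint; each operator stores the reference it
  was built against and validates orthogonality against it.
* **Generic factors.**  Without reaction structure, β solves the two
  orthogonality constraints (exact joint and mean-field product) by SVD
  over the blanket-restricted basis, enumerated by subset size then
  declaration order with the constant term first.  Many solutions exist;
  the smallest-singular-value direction is a reproducible tie-break, with
  sign fixed so the operator is locally restoring in its own coordinate
  and scale fixed by unit maximum coefficient.  No global stability claim
  is made for this generic choice.
* **Isolated species** relax to their own steady marginal
  (`v = q̄ − indicator(present)`), which is exactly the two-state master
  equation.
* **Open systems.**  A non-equilibrium constant (the β₁ term) can be
  injected to model constant production/removal; it is stored separately
  so orthogonality of the reaction part remains checkable.

Mean-field simulation integrates the coupled present-marginals and warns
when trajectories leave the simplex — the symptom of initial conserved
mass inconsistent with the target steady state (reaction systems need the
summed probability of presence of each conserved pool equal to its
steady-state value; the bundled examples satisfy this).

The mean-field free energy of a trajectory is reported as
`Σ_i KL(q_i(τ) ‖ q_i(∞))` — the joint KL between product distributions.
The KL against the *exact* joint is typically infinite (the joint has
restricted support), so the product-form functional is the meaningful
Lyapunov quantity in the mean-field description.

## From probabilities to kinetics

Concentrations are `u_i = N q₁ⁱ / V` with N the maximum molecule count and
V the volume; all examples use the reduced units N = V = λ = 1, so
concentrations are dimensionless multiples of N/V and no unit registry is
needed.

Rate constants for the bundled systems are closed-form functions of the
model parameters:

* Coupled pair `S1 + S2 ⇌ S3 ⇌ S4 + S5`:
  `κ₁ = λN⁻¹V z α₁⁻²α₂⁻¹(α₂−α₁)`, `κ₂ = λz`, `κ₃ = λ(1−z)`,
  `κ₄ = λN⁻¹V(1−z)α₁⁻²α₂(1−α₂)⁻²(α₂−α₁)`; requires `α₂ ≥ α₁`.  The
  implied steady state is `q₁ = q₂ = α₁`, `q₃ = 1 − α₁/α₂`,
  `q₄ = q₅ = α₁(1−α₂)/α₂`, satisfying the conservation
  `q₁ + q₃ + q₄ = 1`.
* Open enzymatic system `S + E ⇌ C ⇌ P + E` with substrate production and
  product removal at rate c: `κ₁ = λN⁻¹V(z − α₁z + c)α₁⁻²α₂⁻¹`,
  `κ₂ = λz`, `κ₃ = λ(1−z)`, `κ₄ = λN⁻¹V((1−z)(1−α₁) − c)α₁⁻²(1−α₂)⁻¹`;
  all non-negative iff `c ≤ (1−z)(1−α₁)`.  The consistent marginals are
  `q_E = α₁`, `q_C = 1−α₁`, `q_S = α₁α₂`, `q_P = α₁(1−α₂)` — with these,
  both reaction pairs carry a net flux of exactly c (verified
  symbolically and by the fixed-point tests).  α₁ is the steady-state
  probability that the enzyme is *free*; large α₁ means the enzyme rarely
  sits in complex and the reaction is easily disconnected by pushing α₁
  to its upper limit.
* **Stoichiometry orientation.**  Ω is species × directed reactions, so
  `du/dτ = Ω r(u) + s`; reversible reactions contribute two directed
  columns.  Catalysts (σ = ρ) are allowed: zero net coefficient, but they
  enter the rate product.
* **Source/sink.**  The throughput c is a constant influx on the
  substrate and efflux on the product.  The efflux ramps off smoothly
  over a 1e-9 concentration scale near zero, so concentrations cannot be
  driven negative while the right-hand side stays smooth for the stiff
  integrator; the induced steady-state residual (< 1e-10 in the bundled
  examples) is far below the 1e-8 steady-state criterion.  Source and
  sink cancel in the pool `u_S + u_C + u_P`, so the open system conserves
  it alongside the enzyme moiety `u_E + u_C`; initial conditions must put
  both pools at their steady-state values (1 and 1 in reduced units) to
  reach the model's marginals.

### Michaelis–Menten reduction

Fast binding equilibrium `κ₁ u_S u_E = κ₂ u_C` gives
`u_C = e₀ u_S/(κ_m + u_S)` with `κ_m = κ₂/κ₁` and `e₀ = u_E + u_C`, so the
slow product-formation rate `κ₃ u_C` saturates at `v_max = κ₃ e₀`.  An
alternative convention `v_max = κ₁κ₃ e₀` circulates in the source
literature for this construction; the form used here is the one a
quasi-equilibrium derivation from this package's own rate constants
yields, and it is validated against numerical simulation of the full
four-species system (the reduced product trajectory tracks the full one to
within 5% under strong separation).  Validity requires z near 1 (binding
and unbinding much faster than catalysis); `mm_reduce` warns — rather than
fails, since the approximation degrades continuously — when `κ₂ < 10 κ₃`.

The reduction-quality study in the tests and acceptance script uses
`α₁ = 0.99, α₂ = 0.5, c = 9.9e-5` (99% of the throughput bound at
z = 0.99) with initial conditions `u_S = 0.9, u_E = 1, u_C = 0,
u_P = 0.1`, and sweeps z over {0.5, 0.7, 0.9, 0.99}.  This regime keeps
enzyme sequestration (~1% of the substrate pool) and the reverse catalytic
flux (~1% of the throughput) both small at z = 0.99, so the comparison
isolates the timescale-separation error: the relative error of the reduced
product trajectory falls monotonically along the z grid and is a few
percent at z = 0.99, while at z = 0.5 — where quasi-equilibrium does not
hold — the reduction is badly wrong, as it should be.

## Implicit beliefs

In the open enzymatic system, `q̃_S = α₂ − q_P` and `q̃_P = α₂ − q_S` are
linear functions of each side's concentration that converge to the other
side's marginal as the non-equilibrium steady state is attained.  The
convergence identity requires `α₁ = α₂` (at steady state
`q_S + q_P = α₁`, and the beliefs target `α₂ − q`); the bundled enzymatic
example therefore uses `α₁ = α₂ = 0.8`.  Beliefs are clipped to [0, 1]
with a warning — the linear relations can exit the unit interval
transiently under mean-field error — and the role swap S ↔ P with
`α₂ → 1 − α₂` mirrors the construction exactly at the symmetric point
`α₂ = ½`.

The per-side free-energy series score the belief against the model's
conditional given the enzyme state.  The averaging is under-determined by
the construction, so the following convention is used: the belief is first
conditioned on the free-enzyme state (divided by `q_E`, which makes it
converge to the conditional `P(species | enzyme present)`), then scored as

    F_side(τ) = q_E(τ) · KL( belief_side(τ) ‖ P(side | E present) ).

The complex-conditioned term vanishes identically — given the complex,
substrate and product are surely absent, which is also what the
conditioned beliefs assert — so only the enzyme term contributes.  Only
the qualitative shapes are treated as testable: both series end below
their starting values at a converged run and reach their minima, and the
product side shows a transient increase (an interior maximum) while the
substrate is still actively changing the enzyme concentration.  The
bundled initial conditions (`u_S = u_P = 0.5`, `u_E = 1`, `u_C = 0`) were
chosen to exhibit exactly this phenomenology.

## Reaction networks, lesions, diaschisis

Networks are declared in the shared YAML/JSON schema and assembled into
directed reaction columns.  Conserved moieties are left null vectors of Ω
restricted to source-free species.  Steady state is *declared* when
`‖du/dτ‖∞ < 1e-8` sustained over one time unit of open-ended integration
(chunked, default horizon 1e4 time units so oscillatory inputs
terminate); non-convergence is a reported state with its residual, never
an exception.

The bundled seven-species network chains
source → S3 ⇌ S2 ⇌ S1, then branches S1 → S4 → S5 → sink and
S1 → S6 → S7 → sink, all Michaelis–Menten (v_max = 1, κ_m = 1; reverse
trunk reactions at v_max = 0.5; influx 0.1).  The topology lives in
`examples/fig6.yaml`, not in code, so an alternative network can be
substituted.  The design rationale: the trunk must be *reversible* for a
downstream lesion to raise upstream concentrations (back-pressure), and
the sinks must be saturating rather than constant so the surviving branch
can absorb the diverted flux.  With these choices a lesion of `S1_to_S4`
(v_max → 0; stoichiometry untouched) abolishes S4 and S5, raises S2 and
S6, and the network attains a different steady state with source influx
still balancing sink efflux.  Diaschisis classification uses a 1e-6
threshold: 'lost' means present before and essentially zero after.

SBML Level 3 Version 2 export is write-only and covers species, reactions
and kinetic laws of assembled networks; it exists for interoperability and
is checked by parsing the XML back and comparing numbers, not bit-exactly.

## Numerical contract

One integrator serves the whole package: LSODA (stiff-capable,
adaptive) at rtol 1e-8 / atol 1e-10.  Exact linear systems are
additionally cross-checked against the matrix exponential in the tests.
CSV output uses 17 significant digits and CSV input re-parses with
correctly-rounded floats, so repeated runs of a bundled example are
byte-identical and round trips are exact.  Problem sizes in the tests and
acceptance script: joint spaces up to 2⁵ states, random rate matrices of
2–10 states (100 instances), networks of ≤ 7 species, and integration
horizons up to 3×10⁴ time units for the slow Michaelis–Menten regime.

## What the bundled examples do and do not show

The examples are exact realizations of the theory's own study conditions —
small networks, mass-action/MM rate laws, reduced units, noiseless
deterministic dynamics.  Passing tests demonstrate internal consistency
(probabilistic ↔ kinetic equivalence, conservation laws, Lyapunov
descent, reduction quality) under those conditions.  They do not
demonstrate that a *real* metabolic network follows these kinetics:
thermodynamic consistency beyond non-negativity, temperature dependence,
crowding, multi-site binding (Hill-type kinetics), non-binary abundance
states and parameter identification from data are all out of scope.  The
mean-field description is an approximation whose marginals only match the
joint model after the β correction, and the generic (non-reaction) β
solver is a reproducible convention, not a uniqueness claim.
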