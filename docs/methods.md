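# Methods

## Model structure and assumptions

The model couples two SI (susceptible–infectious) contagion processes to a
predator–prey interaction. The gang population `N_g = S_g + I_g` grows by
entry at rate `b`, loses members at rate `μ₁`, and experiences crowding
(in-fighting) through the intraspecific terms `S_g·N_g/K` and `I_g·N_g/K`.
Commitment spreads from core members to susceptible youth by standard
incidence `β₁·S_g·I_g/N_g` — the appropriate contact scaling for a large
population with few infectious individuals. The police force is constant
at `P` officers (entry `γ` is constrained equal to exit `μ₂`), so
`S_p = P − I_p` is slaved and the force equation is exactly conservative:
`S_p' + I_p' = μ₂(P − (S_p + I_p)) = 0` on the invariant set. Corruption
spreads to susceptible officers from core gang members (`β₂`) and from
corrupt officers (`β₃`), again by standard incidence in `P`. Captured gang
members enter the justice-system sink `Z`, processed at `μ₃`; nobody
returns from `Z`. Corruption does not flow from police to gangs, and the
"hunting" of corrupt officers by susceptible ones is not part of the
analysed system. Dynamics are deterministic and continuous.

Standard-incidence ratios are defined as 0 at `N_g = 0` (their continuous
limit), making the empty state a genuine fixed point; the same one-sided
limit is used in the Jacobian at gang-free states.

The auxiliary aggregate form `N_g' = (b−μ₁)N_g − N_g²/K` is provided only
as a diagnostic (`ng_logistic_residual`): it omits the predation losses,
and the tests verify that it differs from the sum of the two gang
equations by exactly the total capture flux. All analysis uses the
component equations.

## Functional response

The capture terms derive from a time-budget argument. A police team's
operation time splits as `T = T_search + T_handling − T_cooperation`:
handling each arrest costs `t_h` (core members `λ·t_h`, they resist
arrest longer), and pre-planned cooperation among the `P` officers saves
search time in proportion to `c = b'·t_c` (communication rate times time
saved per encounter; only the product is identifiable, so the package
stores `c` directly). Solving for captures per unit time gives the
per-officer rates `f_i = a·X_i/(U·D)` with the shared denominator
`D = 1 + h(S_g + λI_g) − cP`, `h = a·t_h`. The attack rate `a` is a team
property; dividing by the team size `U` gives the per-officer coefficient
`a' = a/U` that appears in all closed-form conditions. Corrupt officers
hunt at the reduced fraction `r`, so the effective predator abundance is
`P − (1−r)I_p`.

Validation requires `c·P < 1`; since `h ≥ 0`, this makes `D > 0` at every
admissible state. `D ≤ 0` (reachable only with invalid parameters) is a
hard error, not a clamp — the time budget is meaningless there. With
`λ = 1, c = 0` the response reduces to the classic saturating
(Holling type II / interference-free Beddington–De Angelis) form in total
prey, and additionally with `t_h = 0` to mass action; both limits are
tested.

## Equilibria

* `E0` (all zero, `S_p = P`) always exists.
* `E1` (criminal-free, corruption endemic) exists iff `β₃ > μ₂`, with
  `I_p = Ω·P`, `Ω = (β₃−μ₂)/β₃`.
* `E2`/`E3` (core-free, `I_g = 0`): `S_g` solves the quadratic
  `((b−μ₁) − S_g/K)(1 + hS_g − cP) = a'·P_eff` with `P_eff = P` (E2) or
  `P − (1−r)ΩP` (E3). Roots are kept when positive, below the logistic
  cap `(b−μ₁)K` (so `Z ≥ 0`), and with positive denominator.
* `E4` (coexistence): the corrupt-police balance forces
  `I_g = ((μ₂P − β₃(P−I_p))/(β₂(P−I_p)))·I_p`, positive exactly on
  `I_p ∈ (ΩP, P)`; equating the per-capita growth of the two gang
  compartments (both face identical crowding, capture and exit terms)
  forces `b·N_g/S_g = β₁`, i.e. `S_g = b·I_g/(β₁−b)`, so coexistence
  needs `β₁ > b`. Substituting into the core balance leaves one equation
  in `I_p`.

The coexistence equation is solved twice: (A) a sign-change scan over
`I_p ∈ (ΩP + ε, P − ε)`, ε = 1e-9·P, uniform plus geometrically refined
near the lower edge (the branch emerges there as `β₁ ↓ b`), each bracket
bisected to relative tolerance 1e-12; and (B) the real roots of the
quartic in `I_p` obtained by clearing denominators (coefficients built by
exact polynomial arithmetic; the recruitment term collapses to the
constant `b`), polished against the residual. The two root sets must agree
to 1e-6 relative or the solver raises; unmatched roots within numerical
resolution of the window edges — where the coexistence branch exchanges
with a boundary branch and membership is genuinely ambiguous — are
discarded rather than reported. All roots are returned (the quartic admits
up to four); uniqueness is not assumed. Degenerate equalities
(`β₁ = b`, `β₃ = μ₂`) yield empty/inadmissible results, not limiting
branches. Populations are real-valued; rounding to whole persons (half
away from zero) happens only in report formatting.

## Stability

The linearization is 3-dimensional in `(S_g, I_g, I_p)`; `Z` contributes a
decoupled eigenvalue `−μ₃` and is excluded. The analytic Jacobian is the
primary path and must match a central finite-difference oracle to 1e-6 in
the tests. Classification uses the largest eigenvalue real part with a
marginal band of 1e-9; a state at a detected bifurcation is reported
"marginal", never silently rounded. Routh–Hurwitz coefficients
`(a₁, a₂, a₃, a₁a₂−a₃)` are exposed and checked for sign-consistency with
the eigenvalues.

Closed-form threshold inequalities govern the gang directions at the
boundary states: gang invasion of `E0` is blocked iff
`a'P/(1−cP) > b−μ₁`, of `E1` iff `a'P(1−Ω(1−r))/(1−cP) > b−μ₁`; the
core-free states are stable against core growth iff `β₁ < b` together
with the saturation condition `h·a'·P_eff/(1+hS_g−cP)² < 1/K`. The
corruption direction carries its own threshold, independent of these: at
any corruption-free state the `I_p` equation linearizes to eigenvalue
`β₃ − μ₂` (the derivative of `β₃(P−I_p)I_p/P − μ₂I_p` at `I_p = 0`), so
`E0` and `E2` are additionally unstable whenever `β₃ > μ₂` — corruption
invades and the endemic branches `E1`/`E3` replace them as candidates.
The package keeps the gang-direction inequalities as the named conditions
(they are what the bifurcation analysis rests on) and reports the
corruption threshold as a separate check; the sampled-parameter tests
verify that conditions plus corruption threshold exactly predict the
numeric classification.

Hopf bifurcations are excluded at all boundary equilibria: in the
`(I_g, I_p)` sub-block the trace term
`μ₁ + μ₂ + a'(P−(1−r)I_p)/(1−cP) + 2β₃I_p/P` (no-criminal states) or
`b − β₁ + μ₂ + 2β₃I_p/P` (core-free states, in their stability regime
`β₁ < b`) is strictly positive, so a purely imaginary pair is impossible.
Every detected regime change is therefore transcritical — a single real
eigenvalue crossing — which the tests confirm at the refined critical
points.

At the default parameters the coexistence state is stable with
eigenvalues ≈ (−0.010, −0.041, −0.097); the qualitative sign pattern (all
negative), not any particular eigenvalue list, is the contract the tests
enforce.

## Bifurcation analysis

Closed forms follow from solving the `E1`/`E3` stability conditions as
equalities: `β₁* = b`, `μ₁* = b − a'P(1−Ω(1−r))/(1−cP)`,
`P* = (b−μ₁)/(a'(1−Ω(1−r)) + c(b−μ₁))`,
`a* = U(b−μ₁)(1−cP)/(P(1−Ω(1−r)))`, and for the entry rate the window
`(μ₁ + a'P(1−Ω(1−r))/(1−cP), β₁)`.

Scans recompute all equilibria and eigenvalues on a grid and label each
row by the unique stable admissible equilibrium — linear stability, not
long-time simulation, because it is fast and unambiguous away from
criticality (a simulation-based cross-check exists in the simulation
module). Rows with zero or several stable equilibria are flagged
"indeterminate" rather than forced. Detected label changes are refined by
Brent root finding on the stability margin of a bridging branch (one
admissible on both sides whose largest real part changes sign), to
absolute tolerance better than 1e-8; a bracket with no sign-changing
bridge is an error, not a guess. `b`-scans hold `β₁` fixed while `b`
crosses it; the `b = β₁` point itself is degenerate and classified
marginal.

## Simulation

`solve_ivp`/LSODA with defaults rtol 1e-8, atol 1e-10. Terminal events
guard against the capture denominator reaching zero (reported with the
failure time) and blow-up. Adaptive steps may dip round-off-deep below an
absorbing boundary near extinction; the right-hand side is evaluated with
such sub-tolerance negatives clipped to zero while genuinely negative
states still fail loudly. The perturbation experiment displaces every
component by `+δ` (a signs argument allows directed shocks; the
susceptible police are slaved to keep `S_p + I_p = P`) and declares return
when every component is within `1e-3·(1+|x|)` of the equilibrium. Regime
determination from trajectories defaults to `t_end = 5000` because slow
modes near transcritical points make shorter horizons inconclusive; an
unsettled trajectory yields "undetermined", never a guess.

## Parameters

Defaults (per unit time unless noted): `b = 0.2`, `μ₁ = 0.12`,
`μ₂ = γ = 0.0476`, `μ₃ = 0.2`, `β₁ = 0.21`, `β₂ = 0.105`, `β₃ = 0.0525`,
`a = 0.001`, `U = 10` (officers per team), `r = 0.75`, `λ = 1.5`,
`t_h = 0.01`, `c = 0.001`, `K = 50000` (persons), `P = 300` (officers).
These place the system in the endemic-corruption, stable-coexistence
regime (`β₃ > μ₂`, `β₁ > b`). `P = 300` is the force size consistent with
the reference coexistence populations (`S_p + I_p = 123 + 177`); it is
configurable like every other field. The parameter `K` is used exactly as
it appears in the equations; the interpretation `K·(b−μ₁)` as the maximum
sustainable gang population is documentation only (`k_cap` in the derived
parameters).

The sampling box used by the property tests spans roughly a factor of a
few around each default while respecting `c·P < 1`, `0 ≤ r ≤ 1`, `U ≥ 1`;
draws violating an invariant are rejected. Sampling is a test fixture
generator, not a statistical statement about plausible societies: passing
property tests demonstrate internal consistency (solver agreement,
closed-form/eigenvalue agreement, conservation) across the box, not
fidelity to any real police force or gang.

## Known limitations

* No data fitting: parameters are inputs, not estimates.
* The justice system is a pure sink; recidivism would change the gang
  entry balance.
* No stochastic, discrete-population, or spatial effects; with the small
  corrupt-police margins near thresholds, demographic noise would matter
  in reality.
* Global basins of attraction are not computed; regime labels are local
  stability statements plus simulation spot-checks.
* Center-manifold/normal-form analysis at the degenerate points is out of
  scope; such points are reported marginal.
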