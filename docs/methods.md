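# Methods

## Model

An infinite, well-mixed population plays the one-shot donation game under
public assessment. Each time unit a random donor meets a random recipient;
the donor's action is prescribed by the shared action rule `P(X, Y)` and the
donor's next reputation by the shared assignment rule `R(X, Y, A)`, both
deterministic. Because assessment is public, everyone agrees on every
reputation at all times, including mistaken ones.

Two error channels:

* **implementation error** `mu_e` — a donor who intends to cooperate
  defects; defection is never executed as cooperation;
* **assignment error** `mu_a` — the population records a wrong reputation,
  with the total misassignment mass split equally over the k−1 wrong labels
  (`mu_a/2` per label for k = 3, the standard binary convention for k = 2).
  This equal split is the unique symmetric extension across k.

The per-encounter kernel for a donor at (X, Y) is

    K(X,Y → Z) = (1 − 3/2 mu_a) [ (1 − mu_e) δ_{R(X,Y),Z} + mu_e δ_{R(X,Y,D),Z} ] + mu_a/2

(with the obvious k-generalisation), where `R(X,Y) = R(X, Y, P(X,Y))` is the
on-path assignment. When defection is prescribed, the row is independent of
`mu_e`. The reputation shares evolve by

    dh_Z/dt = Σ_{X,Y} h_X h_Y K(X,Y → Z) − h_Z,

which preserves Σ h = 1 exactly.

The cooperation level `p_c = Σ h*_X h*_Y [P(X,Y) = C]` is the *prescribed*
rate; the implementation error discounts payoffs instead:
`pi_res = p_c (1 − mu_e)(b − c)`. A rare mutant differs in its action rule
only (reputations are assigned by the population's shared rule, so
assignment-rule deviations are invisible in a vanishing-fraction mutant).
Its conditional reputation distribution `H*` is the stationary distribution
of the linear chain `M(X → Z) = Σ_Y h*_Y K̂(X, Y → Z)`, where K̂ uses the
resident assignment applied to the mutant's chosen action; its payoff is
`pi_mut = p_c(res→mut)(1 − mu_e) b − p_c(mut→res)(1 − mu_e) c`.

### CESS criterion and parameters

A norm is a cooperative ESS when `p_c >= p_c_th` and
`pi_res > pi_mut` strictly for all `2^(k²) − 1` alternative action rules.
Defaults (the standard study setting): `mu_e = mu_a = 1e-3`,
`p_c_th = 0.99` (chosen between mu and sqrt(mu), so that norms whose
defection level decays slower than O(mu) are rejected), cost normalised to
`c = 1`, and the b/c grid {1.1, 1.5, 2, 3, …, 10}; the **core set** is the
intersection of the CESS sets over this grid. Strictness is enforced as
`pi_res − pi_mut > 1e-9 · max(1, |pi_res|)`; exact ties count as invadable.
The per-norm `p_d = O(mu)` behaviour can be confirmed post hoc through
`scaling_exponent(norm, "p_d")` (slope ≈ 1 for every packaged example).

## Numerical choices

* **Stationary states.** RK4 from the uniform initial condition (the
  representative attractor when several coexist), `dt = 0.1`, shares
  renormalised every step, stopping when `max |dh/dt| < 1e-10` (far below
  the four-decimal reporting precision), at most 1e6 steps. Two
  accelerations that change speed, not the limit: the step is raised
  fivefold once the residual falls below 1e-2 (stationary points are exact
  fixed points of an RK4 step of any stable size, and the flow's Jacobian
  is bounded by ~3 in modulus, keeping `5·dt` inside the stability region),
  and once the residual falls below 1e-5 a Newton iteration on the
  simplex-reduced flow is attempted. The Newton root is accepted only when
  the iteration converges inside the simplex, the root is dynamically
  stable (reduced-Jacobian eigenvalues with non-positive real part) and
  lies within 0.5 of the current trajectory point; otherwise integration
  continues. This matters twice: for "frozen" C3 norms whose slow
  relaxation rate is O(mu) the pure integrator would need O(1/mu) steps,
  and near any slow mode a flow residual of 1e-10 still leaves a solution
  error of order `1e-10 / rate`, which the polish removes. Non-convergence
  (a possible cycle) raises an explicit error carrying the last state; it
  never resolves silently.
* **Mutant chains** are solved by direct linear solve (batched over all
  action rules) with normalisation; reducible chains — possible only at
  `mu_a = 0` — fall back to iterating the chain from uniform.
* **Scaling fits** regress `log10(quantity)` on `log10(mu)` over
  `mu ∈ {1e-3, 1e-4, 1e-5, 1e-6}` with `mu_e = mu_a = mu`; points where the
  quantity vanishes exactly are excluded and flagged. The mu → 0 limits of
  finite quantities are Richardson-extrapolated linearly in mu from the two
  smallest grid points (finite limits are approached with O(mu)
  corrections).
* **Relabelling convention.** G is the label with the largest stationary
  share, B the label produced by `R(G, G, D)`, N the remainder. Candidates
  within 1e-6 of the maximal share are admitted for near-ties (the C3
  families sit at `h_G* − h_N* = O(mu)`) and ranked by (valid convention,
  strictly larger share, smaller canonical encoding) — a deterministic
  tie-break the protocol needs at finite precision. A norm where defection
  at (G, G) keeps the majority label is reported as not relabelable.
* **Classification bands.** The C-type uses slope bands with edges 0.25 and
  0.75, the midpoints between the theoretical exponents 0, 1/2 and 1;
  slopes outside [−0.1, 1.25] are flagged rather than forced. The P/R
  patterns are matched on the prescribed action and the **on-path**
  assignment only. The off-path character printed with some patterns is
  not used: the C1-P1-R1 example itself carries `BG:CG:N` (off-path N, not
  B) and still has one-step recovery, so strict five-character matching
  would contradict the class the norm demonstrably belongs to. Norms
  matching no pattern are flagged unclassifiable, never forced — the
  twelve-subclass exhaustiveness is a testable claim, not an assumption.
* **Canonical representatives.** Encodings are donor-major, then recipient,
  then action (B < N < G, C < D), most significant first; the canonical
  orbit representative is the lexicographic minimum of the joint
  (assignment, action) encoding over all k! relabellings. Scans enumerate
  joint-canonical norms, so scan records can never contain orbit
  duplicates. Burnside counting is exposed for assignment rules, action
  rules and joint norms; note `64,573,605 × 512` (assignment-only
  reduction) slightly over-counts joint orbits whenever a permutation
  fixes an assignment but not the attached action rule — both accountings
  are reported.
* **Transition graphs.** Edge `XY:AZ` carries weight `h*_X h*_Y P(A)`;
  implementation-error edges are dashed. The display threshold `mu^1.5`
  separates the O(mu) flows that carry the mechanism from the O(mu²) noise
  floor. Pure misassignment edges (Z ≠ R(X, Y, A)) are suppressed by
  default — they attach uniformly to every context and obscure the
  mechanism — and are emitted (dotted) when the threshold is zero.

## Scope of validation at desk scale

The full third-order sweep is a cluster job (chunked, resumable,
merge-verified: partial chunk sets fail loudly). The package is validated
at desk scale by: the exhaustive binary sweep (the eight known norms, and
only they, survive), the exhaustive second-order ternary sweep (33 core
norms: 18 C1-P1-R1, 9 C1-P2-R1, 6 C3-P1-R1, with the spade/club
merge-equivalences to Simple Standing / Stern Judging), the twelve packaged
example norms (stationary shares and cooperation levels to four decimals,
subclasses, scaling exponents, and the closed-form limits 1/5, 1/2 and
(3 − √5)/2 of the three C3 dynamical families), prune soundness
(exhaustive over the binary space, sampled over the ternary space),
relabelling invariance of verdicts, chunk-invariance of scan results, and
agreement of the RK4+Newton stationary solver with an independent damped
Picard fixed-point oracle on random norms. What this does not show: conduct
of the model outside the public-assessment, infinite-population,
two-error-channel setting (private or noisy assessment, finite populations,
polymorphic resident mixtures and stochastic reputation dynamics are out of
scope), nor the exact subclass percentages of the full core set, which
require the complete sweep.

## Known limitations

* Only `k ∈ {2, 3}` is in the tested envelope (the formulas generalise and
  larger k is accepted, but cost grows as `k^(2k²)`).
* Mixed (probabilistic) rules and higher-than-third-order norms are out of
  scope.
* Multistability is handled by convention (uniform start), matching the
  reporting convention of the reference setting;
  `picard_fixed_points` exposes a multi-start diagnostic for norms
  suspected of carrying several attractors.
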