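# Methods

## Model

`aedesgm` simulates the urban population dynamics of *Aedes aegypti* under
releases of genetically modified (GM, RIDL-type) males.  Five density
fields on a 2-D domain (mosquitoes/m²) evolve by a reaction–diffusion
system:

    ∂t E = α β F M − e E
    ∂t A = e E (1 − A/k) − (η_a + μ_a) A
    ∂t F = ∇·(D_m ∇F) − μ_f F + r η_a A
    ∂t M = ∇·(D_m ∇M) − μ_m M + (1 − r) η_a A
    ∂t G = ∇·(D_g ∇G) − μ_g G + l(x, y, t)

with E eggs, A aquatic stages (larvae + pupae), F reproductive females,
M wild males and G released GM males, and α = M/(M+G) (α = 1 when
M = G = 0) the wild share of matings.  Offspring of GM fathers die before
emergence, so GM males enter only through the release term l and through
α.  Only the aquatic stage is density-limited (skip oviposition justifies
no egg-stage capacity); eggs are effectively immortal on the simulated
time scale; the immobile phases E, A do not diffuse.  The domain of
definition (all fields ≥ 0, A ≤ k) is invariant under the flow, and the
discretization enforces it.

Heterogeneity enters through the carrying-capacity field k alone: cells of
a raster city map are either *house blocks* (k_house) or *streets*
(k_street), with k_house = 5 k_street (80% of breeding sites are in
houses).

### Parameters

| symbol | meaning | default | units |
|--------|---------|---------|-------|
| β    | eggs per female–male encounter | 34 | m²/day |
| e    | egg hatching rate | 0.24 | 1/day |
| η_a  | aquatic → adult emergence rate | 0.5596 | 1/day |
| μ_a  | aquatic mortality | 0.025 | 1/day |
| μ_f, μ_m | female / wild-male mortality | 0.1177 | 1/day |
| μ_g  | GM-male mortality | 0.62 | 1/day |
| r    | female emergence fraction | 0.5 | — |
| D_m  | wild-adult diffusion | 111 | m²/day |
| D_g  | GM-male diffusion | 331.4062 | m²/day |

All defaults are literature values.  Diffusion coefficients come from the
spreading-radius relation R(t) = √(4Dt)·erfinv(0.9): with the mean adult
lifetime dispersal of 65 m over a 7-day characteristic time,
D_m = 65²/(4·7·erfinv(0.9)²) ≈ 111.5 m²/day.  Note that erfinv(0.9) is
the 90% quantile of the *one-axis* displacement of a diffusing cloud (the
radial 2-D quantile would be √(ln 10) ≈ 1.517); the one-axis convention
is what reproduces 65 m from D = 111, and the package's Monte-Carlo
cross-check measures exactly that projection.  The GM default 331.4062
is the conventional literature value; feeding the GM dispersal data
(67.3 m, 2.17 days) through the same relation would give ≈385.7 m²/day —
both are exposed, the conventional value wins as default.  Similarly the
adult mortality default is the conventional 0.1177/day rather than
−ln(0.9) ≈ 0.105 implied by "10% die per day".

## Single-cell reduction and equilibria

Integrating the system over one isolated grid cell χ (no-flux faces,
area a) gives a five-dimensional ODE for the cell totals, with two
reduced coefficients: K = k·a and the *encounter dilution* β/a.  The
area factor matters: β multiplies a product of two densities, so the
per-cell encounter rate is β F M / a.  All equilibrium functions take an
explicit `area` argument (default 1, the unit-area cell where the
classical formulas hold verbatim); the domain pipeline passes the actual
cell area of 25 m².  Consistency of this choice is confirmed empirically:
calibrating to the standard 10000-female equilibrium returns
K_house = 3.6815 / K_street = 0.7363, matching the conventional fitted
values (3.6876 / 0.7375) to 0.2%, and the domain aquatic equilibrium
4206.6 matches the documented 4206; the unit-area reading misses both by
3% and misplaces the critical release rate by a factor ≈27.

Stationary aquatic totals solve

    A³ − K A² + b K A + b c K = 0,
    b = (μ_a + η_a) μ_f μ_m a / ((1−r) r β η_a²),
    c = μ_m L / ((1−r) η_a μ_g),

with L the constant daily GM release into the cell.  At L = 0 the cubic
factors through A = 0 into A² − KA + bK, giving the wild equilibria
A* = K(1 ± √(1 − 1/Q0))/2 with basic offspring number Q0 = K/(4b);
a non-trivial equilibrium exists iff Q0 ≥ 1.  The companion phases are
E = (μ_a+η_a)A/(e(1−A/K)), F = rη_aA/μ_f, M = (1−r)η_aA/μ_m, G = L/μ_g
(the general-r forms are used throughout).  For L > 0 the roots are
evaluated by Cardano's formula through the discriminant
φ = (P/3)³ + (Q/2)² of the depressed cubic (P = bK − K²/3,
Q = −2K³/27 + bK²/3 + bcK); φ < 0 gives two admissible positive roots —
the larger an attractor, the smaller a saddle — and φ > 0 none, i.e.
extinction.  Roots are cross-checked against a companion-matrix solver to
1e-9 in tests.  The critical per-cell rate L_c(K) solves φ = 0 in closed
form and requires K > 3b (Q0 > 3/4); the domain-level critical rate
applies L_c to the block-count-weighted mean capacity
(n_h K_h + n_s K_s)/(n_h + n_s).

Stability is classified numerically: central-difference Jacobian
(step 1e-6 × component scale) and eigenvalue real parts against
−1e-9 × (largest rate).  Forward integrations seeded near each point
confirm the labels in the test suite.

### Calibration

Field data constrain the female equilibrium (10000 adults over the
40000 m² reference domain, 0.25/m²).  `calibrate_carrying_capacities`
solves n_h F*(5K_s) + w n_s F*(K_s) = F_target for K_s by bracketing,
with street weight w = 1 by default (a plain block-count sum; an
alternative convention discounts the street term by 0.2 and is exposed
as an option).  Feasibility requires the street class to persist
(K_s > 4b); smaller targets raise with the feasible range in the message.

## Spatial discretization

Finite volumes on the raster cells; five-point diffusion stencil with
arithmetic-mean face coefficients and zero-flux boundaries (the same
isolation assumption as the ODE reduction; it conserves mass exactly
without reactions, which tests assert to 1e-10).  Time stepping is
Crank–Nicolson with dt = 1 day by default; each step solves the coupled
nonlinear system for all five fields by a damped Newton iteration with
the analytic sparse Jacobian (block 5×5 reaction part + diffusion),
tolerance 1e-10 on the scaled residual, at most 50 iterations, LU
factorization of the sparse system (dense solve below 65 cells).

Two robustness mechanisms, both package design choices:

* **Rannacher startup at release discontinuities.**  A pulse release
  deposits a near-delta GM spike; at the default resolution the Fourier
  number D_g·dt/dx² ≈ 13 and the time-centered scheme is not
  positivity-preserving on such data (oscillating negative lobes around
  the footprint).  Steps in which the release field switches on or off
  are therefore taken as two backward-Euler half-steps, the standard
  damping treatment for non-smooth data under Crank–Nicolson; it keeps
  the global second-order accuracy and restores positivity.  Daily
  (period-1) schedules have a constant release field and run pure
  Crank–Nicolson after the first step.
* **Domain-checked adaptive sub-stepping.**  The discrete nonlinear
  system can possess spurious roots far outside the invariant domain;
  on large pulse jumps Newton can land on one (or stall).  Every
  sub-step's solution is checked against the invariant domain
  (fields ≥ −1e-9 × scale, A ≤ k(1 + 1e-9)); failure or violation
  bisects the sub-step, up to six levels.  For small enough steps Newton
  provably stays in the physical basin.

After each accepted step, round-off is clamped (negative values above
−1e-9 × scale to zero, A to at most k); larger violations raise.  An
instantaneous release of N mosquitoes is applied as the rate
N/(area·dt) during the step containing the event, so released totals are
exact for every dt and period.

The reduction and the solver close the loop: on a 1×1 map the
Crank–Nicolson trajectory at dt = 0.01 matches a tightly-tolerated stiff
ODE integration of the cell reduction to 1e-6 relative over 100 days
(the dt is chosen to bring the O(dt²) discretization error below that
comparison tolerance).

## Synthetic city map

The original study map (a 200 m × 200 m urban neighborhood rasterized to
40×40 cells of 5 m) is available only as a figure, so the
package ships a synthetic stand-in emulating its composition: a
Manhattan-style street grid (bands every 6 cells, width 1, zero phase)
trimmed by flipping the 17 leftmost bottom-row house cells to street,
giving exactly 1072 house / 528 street cells (26800 / 13200 m²).  The
generator `synthesize_city_map` produces the same family of layouts with
a seed-controlled street phase (restricted to phases of maximal street
coverage so composition is seed-independent).  The localized-release
footprint is a committed mask of 38 contiguous central cells (950 m²,
emulating the ~944 m² central release area); release rates are scaled so
the released *total* is exact, the small footprint-area mismatch affects
only the local density (≈116/m²/day at the 11× level).

What the synthetic map does not capture: the real street topology
(irregular block sizes and shapes, diagonal roads), within-class capacity
variation, and any environment dependence of diffusion or mortality.
Map-dependent simulation results therefore reproduce the documented
numbers only approximately; the analytic and single-cell results are
map-free and reproduce them tightly.

## Release experiments

All experiments start at the per-cell wild equilibrium and release
multiples of the domain female equilibrium (the conventional launch size
is 11×, i.e. 110000 GM males/day here):

* **Heterogeneity** — the same localized 11× release run on the
  heterogeneous map and on a homogenized map (every cell at the
  block-count-weighted mean capacity, starting from its own equilibrium).
  On the committed map the maximum difference over 100 days is ≈12–13%
  of the initial population (females 12.5, aquatic 13.5), somewhat above
  the ≈8% documented on the original raster — this metric is sensitive
  to the street layout, which the stand-in map only emulates.
* **Localization** — localized vs homogeneous release of the same total
  daily amount on the heterogeneous map.  Differences are measured on
  the adult-female totals (the phase whose maximum falls on day 60, as
  documented; the aquatic phase peaks ~10 days earlier): maximum ≈41%
  of the initial population at day 60, ≈23% remaining difference at day
  100 (documented: ≈44% and ≈29%).
* **Release-rate sweep** — 300-day simulations under daily homogeneous
  release, compared with the expected equilibrium curve (sum of the
  per-cell attractor roots).  The curve tracks the simulations to a few
  percent in the mid range and both collapse above the critical rate,
  but the isolated-cell curve is structurally approximate at the range
  ends: at small L street cells are re-seeded by immigrating females
  (simulation ≈7% above the curve), and near the threshold the coupled
  system collapses already at ≈0.85 L_crit because the mobile phases
  mix across cell classes while E and A do not.  The domain critical
  rate L_crit ≈ 18.4/cell/day (≈29500/day domain-wide) is thus a good
  but not exact predictor of the spatial collapse threshold — and the
  11× release (110000/day) is comfortably supercritical.
* **Frequency scan** — release periods 1–30 days at a fixed 30-day
  total (the 11× daily equivalent).  The "population still collapses"
  criterion is operationalized as the aquatic total at day 100 falling
  below 50% of its initial value (configurable; the underlying change is
  abrupt: 19% remaining at period 1–4 versus >85% at period ≥9).  On the
  committed map the critical period is 6 days (documented: ≈7, matching
  the egg-to-adult development cycle).

## Numerical choices and degenerate inputs

* Capacity densities are primary; per-cell totals are always K = k·dx·dy.
* k = 0 cells are disallowed (streets carry a small positive capacity),
  keeping the logistic factor well-defined.
* α at M = G = 0 takes its definition value 1; the branch only arises at
  extinction where the F·M factor vanishes anyway.
* The capacity inversion K = A²/(A−b) requires A > b; A → 2b gives the
  smallest admissible capacity 4b (the Q0 = 1 point) and smaller aquatic
  populations have no admissible capacity (explicit error).
* Tie-breaks in the frequency threshold (largest collapsing period) are
  irrelevant in practice since the scanned response is monotone through
  the transition.

## Known limitations

Constant optimal-environment parameters (no temperature, rainfall or food
dependence); no advection; capacity-only heterogeneity; disease
transmission out of scope.  Conclusions transfer to real landscapes only
to the extent the synthetic raster emulates them — the map-dependent
percentages above shift by several points across admissible layouts,
while the analytic machinery (equilibria, critical rates) is exact for
any given map.
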