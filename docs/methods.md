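# Methods

## Model class

A network is a list of species (internal or external), a stoichiometry
matrix N over the internal species (exact rational entries), a growth
rate μ, and one rate law per reaction in the separable form
v_j = e_j·f_j(x), with f_j a closed-form expression in species
concentrations and kinetic parameters.  Metabolite dilution by growth is
neglected (ẋ_I = N v); enzyme dilution is not (ė_j = E_j − μ e_j), since
enzyme turnover happens on the growth timescale.  Rate laws are parsed
into sympy expressions once per network; ordinary parameters are
substituted numerically at parse time, while parameters declared
*adjustable* (scheduled by the environment or estimated by the
controller, e.g. a Michaelis constant) remain symbolic.  All derivatives
used anywhere in the package are symbolic; a finite-difference fallback
is unnecessary for the rate-law class supported (rational expressions of
the concentrations).

The packaged rate laws are reversible saturable kinetics: a bilinear
forward-minus-backward numerator over a product of linear saturation
factors.  This family keeps the enzyme-cost objective strictly convex on
its feasible domain and makes both flow orientations attainable.

## Elementary flux modes

EFMs are computed by exhaustive support enumeration with exact rational
nullspaces: a reaction subset is an EFM support iff its restricted
stoichiometry has a one-dimensional nullspace generated by a
nowhere-zero vector and no proper subset does.  This is exponential in
the reaction count and entirely adequate for the ≤ 12-reaction networks
targeted here; `enumerate_efms` refuses m > 24.  Support minimality is
judged sign-agnostically; irreversibility constraints then filter
orientations, and fully reversible modes are reported once with a
canonical sign (first support coefficient positive) because the
controller handles flow reversal dynamically rather than by duplicating
orientations.  The flux degree of freedom is fixed by normalising the
designated output reaction to 1.

## Enzyme-cost optimum

O(x_I) = Σ_j V_j/f_j is minimised in log-concentration coordinates
(the positive orthant becomes unconstrained) by BFGS followed by Newton
polishing with the exact Hessian; convergence requires the gradient
infinity-norm in concentration coordinates to fall below 1e-9.  Before
any step a feasibility probe checks sign f_j = sign V_j at the starting
point; `feasible_start` finds such a point deterministically when none
is supplied.  Uniqueness of the minimum is not assumed: the test-suite
verifies positive-definite Hessians and multi-start agreement (1e-6) on
every fixture and on seeded random chains, standing in numerically for
the strict-convexity theory.

## The controller

The predicted optimum ξ(x_S) solves the square system {ξ_S = x_S,
∂O/∂ξ_i = 0 ∀ i internal} for the non-sensor internals plus the
unknowns (externals and/or adjustable parameters).  The solver is a
damped Newton iteration on the symbolic gradient with its symbolic
Jacobian, demanding a residual infinity-norm below 1e-9 relaxed only by
the floating-point noise floor |J|·|u|·eps — a relaxation that matters
solely near thermodynamic equilibrium, where the equations blow up like
1/f³ while their root stays smooth.

The optimality equations admit *mixed-sign* roots (some reactions with,
some against the mode direction) that are not optima of any orientation;
these are rejected.  Cold starts therefore select the branch explicitly:
guess the unknowns (a deterministic grid scaled by the sensor magnitude,
then wide random draws from a fixed seed), solve the sensor-pinned inner
minimisation over the free internals — a strictly convex sub-problem
that cannot land on a spurious branch — and only then run the full
Newton solve, accepting sign-consistent roots only.  The forward
orientation is tried before the reversed one.

Warm-started continuation defines the solution branch by history, as in
the underlying differential-algebraic formulation; `continue_prediction`
subdivides large sensor moves (≤ ~5% per substep, bisecting on failure)
because the predicted optimum is generally multivalued in the sensors
and coarse stepping can hop branches.

Synthesis rates are evaluated in the product form
E_j = μ V_j Π_{l≠j} f_l / Σ_l V_l Π_{k≠l} f_k (over the support), which
is algebraically identical to the ratio of enzyme demands but finite
when a single rate crosses zero, positive for either flow orientation,
and sums to μ exactly.

### Crossing thermodynamic equilibrium

During flux reversal the predicted optimum passes through the state
where every supported rate vanishes.  The equations are singular there;
the package crosses the tube |f_j| < 0.1 in three layers: (i) the
noise-floor convergence relaxation above; (ii) an explicit traversal
step that locates the nearby all-rates-zero state by Gauss–Newton on
f(ξ) = 0 and reflects the stranded iterate through it in log
coordinates, restarting Newton on the far side; (iii) if no oriented
root exists yet, the simulator briefly holds the last synthesis rates
(they are bounded, positive and sum to μ) while the metabolic state
carries the sensors across, resuming the algebraic solve as soon as it
succeeds — after at most 2000 consecutive held evaluations the original
error is raised.  Outside the equilibrium tube no such forgiveness
applies: a singular Jacobian raises an IFT-violation error carrying the
condition number (hard ceiling 1e12, warning at 1e8 — engineering
choices; the theory only requires nonsingularity), and Newton failure
raises a distinct solver error.

## Simulator

The coupled system integrates (x_I, e) with scipy's LSODA (rtol 1e-8,
atol 1e-10 by default); the algebraic controller is solved inside the
right-hand side with a warm start carried between evaluations, rather
than as a monolithic DAE — this keeps the controller a pure function
testable in isolation.  Externals and scheduled parameters are piecewise
constant; the integrator restarts at each boundary with state
continuity and no smoothing.  Metabolite and enzyme coordinates are
clipped at zero for rate evaluation; undershoot below −1e-12 logs a
warning and below −1e-6 is an error.  Stored predictions, fluxes and
the distance-to-optimum series are recomputed along the stored grid
with the same branch-tracking continuation.

Steady-state detection recomputes exact derivatives (not finite
differences) over a terminal window and flags a segment steady when all
fall below the tolerance; the flagged state is then compared against
the directly minimised optimum at the segment's true environment — the
package's numerical rendering of "a steady state of the controlled
pathway is necessarily optimal".

## Fixtures and the generator

* `example1` — the four-step C/N pathway with fully specified printed
  kinetics; one scheduled external (the carbon source), sensor x2.  The
  nitrogen-pool parameter `Ntot = 10` and the scheduled carbon values
  are fixture choices, tagged as such in the fixture's provenance block
  (printed numbers are transcribed verbatim and locked by checksum in
  the tests).
* `branched_network` — two inputs, two outputs, a condensation step and
  allosteric cross-inhibition between the product branches; four
  sensors track four independently changing externals.  All kinetic
  values are fixture-chosen; tests assert properties (oracle
  equivalence, counting rule), never particular numbers.
* `linear_chain(n, seed)` — reversible chains with parameters drawn
  reproducibly from the seed: kf ∈ [0.8, 1.5], kr/kf ∈ [0.65, 0.9],
  saturation coefficients ∈ [0.1, 0.4].  The near-equilibrium ratio
  kr/kf is deliberate: it keeps reversed flow attainable, which the
  flux-reversal scenario requires.  One sensor sits adjacent to each
  external end, tracking both boundary concentrations.
* `km_sensing_fixture(valid)` — a six-species chain whose third
  reaction's Michaelis constant K3 is a tracked unknown.  The valid
  variant senses the substrate/product pair flanking that reaction
  (x3, x4); the invalid variant swaps x3 for x2 and passes every static
  requirement yet drives the optimality system into a singular point
  after the first environmental change — failure is surfaced as a
  truncated trajectory with the IFT diagnostic, never silently.

Initial states of the chain and branched fixtures are the optimum of a
*previous* environment: a pathway meets a new condition while adapted to
an old one, and — more practically — an arbitrary uniform state can pin
the sensors outside the range attainable by any optimum, where the
control law is undefined.

### Problem sizes and time horizons

At total enzyme 1 the pathway flux equals 1/O ≈ 0.05–0.1 for these
fixtures, so the metabolic relaxation time is tens of time units; the
quantitative steady-state and recovery checks therefore integrate
constant segments of 150–1800 time units (fractions of a second each),
while the packaged demonstration schedules keep shorter segments that
show the characteristic approach dynamics.  The test-suite and the
acceptance script together run in well under two minutes on one CPU.

### What the synthetic fixtures do and do not show

The fixtures exercise the control loop, not biology: rate laws are
low-order saturable kinetics with made-up constants, environments
change as clean steps, gene expression is deterministic and delay-free,
and there is no transcription-factor mechanism — the package emits the
input–output relation a circuit must realise, not the circuit.  Passing
tests demonstrate the mathematical construction (optimality of steady
states, identifiability of unknowns through sensors, failure modes), and
say nothing about parameter values in any real pathway.

## Known limitations

* Convergence to the optimum is not guaranteed in general — the control
  is built from steady-state properties and is invariant under time
  reversal; the simulator reports non-convergence (truncation,
  non-steady flags) rather than asserting it cannot happen.
* Sensor selection is user input with diagnostics; no automatic search.
* EFM enumeration is exhaustive and limited to small networks; no
  double-description method.
* No SBML import; the YAML model format is the only interchange format.
* Multiple EFMs through the same output are not optimised over jointly;
  the user selects the mode.
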