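# Methods

## Model class

Everything in `twinreg` is a deterministic mass-action chemical reaction
network (CRN). A network is a list of species, a list of reactions with
integer stoichiometry, and a table of strictly positive rate constants; the
rate of a reaction is its constant times the product of reactant
concentrations raised to their coefficients. The induced ODE system is
`dx/dt = S·v(x)` with `S` the stoichiometry matrix and `v` the rate vector.
Units are fixed to nanomolar and minutes (zeroth order: nM min⁻¹, first
order: min⁻¹, second order: nM⁻¹ min⁻¹); no unit-conversion layer exists
because every parameter in the built-in scenarios is already given in these
units. Hill or Michaelis–Menten kinetics, stochastic (CME/SSA) semantics and
SBML input are deliberately out of scope.

## The plant

The process under control is a pair of mutually activating birth–death
species:

    ∅ →(b1) Y1,  ∅ →(b2) Y2,  Y1 →(d1) ∅,  Y2 →(d2) ∅,
    Y1 →(α2) Y1+Y2,  Y2 →(α1) Y1+Y2

so that Ẏ1 = b1 − d1·Y1 + α1·Y2 and Ẏ2 = b2 − d2·Y2 + α2·Y1. Whenever
d1·d2 > α1·α2 this linear system has the unique, globally exponentially
stable steady state

    Y1* = (α1·b2 + b1·d2)/(d1·d2 − α1·α2),
    Y2* = (α2·b1 + b2·d1)/(d1·d2 − α1·α2).

`plant_steady_state` implements this closed form and refuses parameters
outside the validity region. The coupling means a disturbance entering
through either output shifts both — the problem the regulators solve.

## Regulator families and their guarantees

All controllers are built on molecular sequestration: two controller species
annihilate each other (possibly through an intermediate complex), and a
linear combination of controller concentrations — the *memory variable* —
has a time derivative equal to a control error. If the closed loop settles,
the error must average to zero, which pins the regulated quantity exactly
(robust perfect adaptation). The families and their memory variables:

| family | controller species | memory variable(s) | guarantee at steady state |
|---|---|---|---|
| R | Z1, Z2 | Z1−Z2 | Y1*/Y2* = k2/k1 |
| R_PRODUCT | Z1, Z2 | Z1−Z2 | Y1*·Y2* = k1/k2 |
| LC | Z1, Z2 | Z1−Z2 | k1·Y1* − k2·Y2* = θ2 − θ1 |
| D1 | Z1–Z4 | Z3−Z1, Z4−Z2 | Y1* = θ1/k1, Y2* = θ2/k2 |
| D2 | Z1–Z4 | Z3−Z1, Z4−Z2 | Y1* = θ1/k1, Y2* = θ2/k2 |
| D3 | Z1, Z2, Z3, C | Z3−Z1, Z3+C−Z2 | Y1* = θ1/k1, Y2* = θ1/k2 |

D1 and D2 obey identical controller ODEs but actuate differently (D1
inhibits the outputs catalytically, D2 produces them from Z3/Z4), so their
transients differ while their steady states agree. D2_MISPAIRED is D2 with
the annihilation pairs swapped to Z1–Z4 / Z2–Z3; its nominal equilibrium
(θ2/k1, θ1/k2) exists for many parameter sets but is never locally stable
(see the pairing scan below). The optional reaction Y1+Z1→Z1 (rate k4) adds
control action on Y1 for the R/LC families without altering the controller
ODEs — only the plant's Y1 equation changes.

Regulator fragments are written against abstract targets Y1/Y2 and bound to
a plant's two designated outputs at composition time (`close_loop`).
Binding is to designated outputs only; indirect actuation on non-output
species is not supported. Controller parameter names are prefixed `ctrl.`
only when they collide with a plant parameter; the built-in scenarios never
collide.

### Feasibility caveat

The guarantees presuppose a positive equilibrium. Inhibition-only actuation
can only *lower* an output, so set-points above what the open loop can reach
have no positive equilibrium and the sequestration integrator winds up (Z
grows without bound). This is visible in the product variant: on the
standard plant with b1 = 2 the demonstration point k1=0.5, k2=1, k3=1, η=10
(target Y1*·Y2* = 0.5) is stability-certified, while a target of 2 is
infeasible pre-disturbance. The robustness sweeps treat such rows as
excluded, mirroring the standing stability assumption.

## Simulation

`simulate.run` integrates with SciPy's LSODA (stiff-capable; the η = 10
nM⁻¹min⁻¹ annihilation terms make the loops moderately stiff) at rtol 1e-8,
atol 1e-10, with the analytic Jacobian supplied. Timed disturbances restart
the integration at the exact event time with the stepped parameter — no
interpolation through the discontinuity. The caller's network is never
mutated; the post-event parameter table is returned with the result.

Initial conditions default to 0 nM for every species. The source scenarios
never state initial conditions; zero-initialised circuits are the
conventional reading for synthetic networks, and the steady-state claims are
initial-condition independent inside the basin of attraction.

Steady state is declared over the trailing 5 % of the horizon when the
relative drift of every species is below 1e-6 *and* ‖rhs‖∞ < 1e-8 nM min⁻¹
at the window mean. The default horizon is 500 min (the scenarios settle
well before the 50 min disturbance; measured final residuals are ≤ 1e-10).
The slow mode of the product variant needs ~2000 min. Non-convergence is a
flag, not an exception; the objective checker refuses non-converged input.
Trajectory entries below −1e-9 nM would be clipped to zero and logged; in
practice the integrator never produces any.

## Stability analysis

`find_equilibrium` polishes a seed with a Newton-type solve (Powell hybrid,
analytic Jacobian) on the raw polynomial right-hand side, judged by the
residual ‖rhs‖∞ ≤ 1e-10 rather than the solver's progress flag (which false-
negatives when seeded exactly on the root). Roots with negative components
are refused. The default seed is a convergence-run endpoint; dual-rail
(D2-type) loops instead use their closed-form equilibrium, which also covers
the unstable mispaired case where a trajectory endpoint is useless.

Eigenvalues of the analytic Jacobian are the authoritative local test, with
a ±1e-9 margin: anything inside it is reported *marginal*, never coerced.
The Routh–Hurwitz criterion is computed as an independent cross-check on the
characteristic polynomial (built from the eigenvalues, not by determinant
expansion, to stay well-conditioned at dimension ≤ 6). Exact zeros in the
first Routh column are reported as marginal with no epsilon perturbation.
A contradiction between two clearly-signed verdicts raises — it would
indicate numerical pathology, not a borderline case.

### Pairing scan

"No realistic parameter set stabilises the mispaired loop" is
operationalised as: all eight controller constants on a log grid over
[0.01, 100] in their natural units, 4 points per decade per axis. A full
factorial (16⁸ points) is out of the question, so 10⁴ points are selected by
an unscrambled Halton sequence snapped to the axis values — deterministic,
seed-free, space-filling. Each point uses the closed-form equilibrium of the
dual-rail structure (Y1* = θ2/k1, Y2* = θ1/k2 for the mispairing; Z3*, Z4*
from the actuation balance; Z1*, Z2* from the annihilation balance); points
where Z3* or Z4* would be non-positive are recorded as `no_equilibrium`.
The scan covers ~600 genuine equilibria, none stable, and runs in about a
second. The bounds and density are arguments, not constants.

### Positive-real balance

For R/LC loops with both inhibitions, `pr_balance_check` returns
k2·k4·Z1* − k1·k3·Z2* at equilibrium. Zero flags the configuration whose
controller block is positive real (a sufficient-stability ingredient when
the plant block is weakly strictly positive real); a nonzero residual draws
no conclusion. The formal passivity machinery itself is out of scope.

## Robustness studies

`rpa_experiment` applies constant multiplicative perturbations per
parameter. Plant-parameter rows test rejection (the objective must not
move); controller-parameter rows test tracking (the set-point moves with
the parameter and the loop follows). Rows whose perturbed loop loses
stability or a positive equilibrium are excluded from judgement, not
failed — the guarantees are conditional on convergence. Default sweep:
all six plant parameters × multipliers {0.5, 1, 1.5}.

`degradation_study` adds first-order decay X→∅ at one shared rate δ
(min⁻¹) to every controller species, emulating host-growth dilution. The
integral action is then leaky and the objective acquires an error that
grows monotonically with δ over the small-δ range swept (0–0.05 min⁻¹).
The leading error term is δ·(memory offset)/(sensing gain) — e.g.
δ·(Z1*−Z3*)/k1 for the D1 output Y1 — and Z1* is pinned by actuation
demand, so scaling η alone hits an error floor (verified numerically:
η×100 leaves the residual essentially unchanged). The implemented
mitigation (`tuned=True`) therefore scales η *and* the set-point-preserving
sensing pairs (θ, k1, k2) by the tuning factor (default 100), which shrinks
the residual roughly in proportion while leaving the target untouched.

## What the tests do and do not show

The suite and the acceptance script run the exact printed parameter sets of
the seven figure scenarios (plant b1=2, b2=1, d1=d2=1, α1=0.1, α2=0.4; the
b1: 2→4 step at t = 50 min) plus property sweeps around them. Agreement is
to integration precision because the claims are exact steady-state
identities of the deterministic model. None of this probes stochastic
(low-copy) behaviour, global basins of attraction, resource competition, or
non-mass-action effects in real implementations — the deterministic ODE
model is a good approximation only at sufficiently high molecule counts.
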