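# Methods

## Model

`pepwave` simulates the central carbon metabolism of glucose-grown
*E. coli* — glycolysis, the pentose phosphate pathway and two gluconeogenic
reactions — as a system of 18 mass balances over 32 enzyme-catalysed
reactions:

    dC/dt = S · (e(t) ∘ r(C; P)) + b − μ C

* `C` (mM): 17 intracellular metabolite pools plus the extracellular
  glucose pool of the chemostat the source model was identified in.
* `r(C; P)` (mM/s): the kinetic rate laws of the established dynamic model
  of this pathway (PTS uptake with g6p inhibition and PEP/pyruvate
  coupling, allosteric PFK and PK (Monod–Wyman–Changeux), reversible
  two-substrate laws for GAPDH/PGK, Hill kinetics for PDH and DAHPS,
  Michaelis–Menten drains for the biosynthetic exits, plus
  phosphoenolpyruvate synthase (PPS) and fructose-1,6-bisphosphatase (FBP)
  as Michaelis–Menten steps with product/AMP inhibition).  Co-metabolites
  (ATP, ADP, AMP, NAD(H), NADP(H)) are held at constant measured
  concentrations; over multi-hour horizons their original short-term
  transients are irrelevant and constants keep the system autonomous.
* `e(t)`: dimensionless enzyme levels, one per reaction, all 1.0 at the
  reference state.  An enzyme level multiplies its rate law linearly —
  the modelling assumption is that expression changes rescale V_max
  without changing the enzyme's kinetics.
* `b`: the chemostat feed (dilution rate × feed concentration) entering
  the extracellular glucose pool; `μ C` drains every pool into biomass at
  the specific growth rate μ = 2.78×10⁻⁵ s⁻¹.

Units are mM and seconds internally (rates mM/s); the CLI accepts horizons
in hours.

### Top-down calibration

Three quantities are not taken from in vitro data but fixed so that the
nominal concentration vector is an exact steady state
(`calibrate_network`):

1. **r_max of PTS** — with the extracellular balance reduced to one pool,
   the import scale is set so the g6p node balances (uptake = PGI + G6PDH
   + PGM + dilution).
2. **r_max of PPS and FBP** — the gluconeogenic enzymes run a small futile
   cycle against PK and PFK.  Their nominal flux is 5% of the opposing
   glycolytic flux (futile cycling in glucose-grown cells is minor), and
   r_max of PK and PFK are scaled by 1.05 so the pep/pyr and f6p/fdp nodes
   still balance.  The fraction is a load-time parameter.
3. **The PTS coefficient on extracellular glucose** — the biomass-to-
   reactor volume conversion, set so feed exactly covers uptake plus
   washout at the nominal point.

After calibration the steady state is refined by Newton iteration and
stored in the parameter file; `‖dC/dt‖∞` at the stored state is ~10⁻¹⁴
mM/s, so the steady-state acceptance gate (10⁻⁶ mM/s) holds by
construction and any regression signals a transcription error.

The supplied steady state retains the glucose balance deliberately: with
extracellular glucose frozen as a constant instead, step tests on PTS, PDH
and SYN2 create or destroy *total carbon influx* and spuriously move PEP
by 2–15%; the chemostat balance pins uptake to the feed and removes these
artefacts.

## Enzyme-level programs

Forced enzymes follow biased cosine waves `e(t) = h + A·cos(ωt + φ)` with
h = 1 (or the square-wave analogue, or a constant).  Levels are clamped to
the admissible band [e_min, e_max] = [1/20, 20] **after** evaluating the
waveform: a symmetric cosine around 1 cannot reach 20-fold overexpression
while staying above 1/20, so the band is enforced by rectification.  This
makes large-amplitude waves flat-topped (approaching square waves), which
is also the behaviour a saturating promoter would produce.  A strict
amplitude-bound mode (`clamp=False`, requiring A ≤ min(e_max−h, h−e_min))
is available for users who prefer unclipped sinusoids.

Producers assumed to be supplied from a plasmid on top of the genomic copy
(GAPDH, PFK by default) have their floor raised to 1.0.  The light-circuit
program couples all members to one periodic input: induced members share
(ω, φ), repressed members run in anti-phase (`inverted`).

## Simulation

LSODA (stiff-capable, adaptive) integrates the forced system; output is
reported on a uniform grid decoupled from solver steps (default 1 s,
coarser in optimization).  The maximum step is capped at a tenth of the
fastest active forcing period so the solver cannot step over whole
oscillations.  Production-quality runs use rtol 10⁻⁸ / atol 10⁻¹⁰ mM;
optimization search runs use 10⁻⁵ / 10⁻⁸, which reproduces the objective
to ~3×10⁻⁶ relative at a third of the cost, and every reported optimum is
re-verified at the tight tolerances.

"Total PEP" is the time integral of the PEP concentration over the
horizon (composite trapezoid on the reporting grid).  All gains are ratios
of this integral between a forced and the unforced run; the ratio is
identical whether one integrates or time-averages.

Negative-concentration policy: rate laws clip solver trial values at zero
element-wise (the dilution term then pushes the pool back up), accepted
output is required to stay above −10⁻⁶ mM, and user-supplied states below
−10⁻⁹ mM are rejected as domain errors.

## Sensitivity screen

Each enzyme is fixed at 1.5× nominal, the system is relaxed to its new
steady state (‖dC/dt‖∞ < 10⁻⁸ mM/s, capped at 100 simulated hours, with a
Newton polish once the relaxation is close), and the ratio of new to
nominal steady-state PEP is recorded.  Enzymes moving PEP by more than 2%
in either direction are flagged.  On the shipped network the flagged set
has nine members — PFK and GAPDH raising PEP, PK, PEPC, RPPK, SER, SYN1,
DAHPS and G6PDH lowering it — and the next-nearest enzyme (G1PAT) sits at
−1.9%, so the set is robust to small threshold perturbations.

## Dynamic optimization

Decision variables: per-enzyme (A, ω, φ) for independent clusters; shared
(ω, φ) plus per-member amplitudes for the coupled circuit; constant levels
for the time-invariant control case.  Bounds: A ∈ [0, 19] (so the raw peak
h + A reaches at most 20), periods between 15 min and the 8 h horizon
(sub-15-min transcription–translation cycling is not implementable in
vivo, and the network low-pass filters faster forcing anyway), φ ∈ [0, 2π).
Static levels vary in [0, 20], essential enzymes (RPPK, GAPDH, PGK, ENO,
PTS) in [0.25, 20].

The objective is total PEP with metabolite path constraints enforced by an
exact penalty:

    J = ∫ C_pep dt − w · ( ∫ viol dt + 0.01 · T · max viol ),   w = 10⁴

where `viol` sums the out-of-band excursions of the constrained
metabolites.  The integral term alone makes the penalty exact (it prices
sustained violation at w× its possible objective gain, and any w > 1
suffices); the worst-point term only guards spikes the reporting grid
barely sees and is deliberately small — at the optimum PEP grazes its
ceiling, and a heavier spike term turns that active constraint into a
cliff that collapses the simplex search prematurely.  Feasibility is
declared below 10⁻⁶ mM worst-case violation.  PEP is constrained to the
experimentally reported 1–10 mM range; pyruvate, rib5p, e4p and g6p get a
10-fold band centred geometrically on their steady states, mirroring the
10-fold PEP treatment (the load-bearing constraint in practice is the PEP
ceiling).

Search: the clamped waveforms make J only piecewise smooth, so the
optimizer is gradient-free multi-start — the unforced baseline (so a
feasible baseline bounds the reported gain at 1.0), hint-based starts
(PEP-positive enzymes swinging high in phase, PEP-negative ones low in
anti-phase, at periods of T, T/2, T/4 and several producer/consumer
amplitude scales), and seeded Latin-hypercube points with log-uniform
frequencies.  All starts are scored once and the budget is spent polishing
the three most promising.  Small problems use joint Nelder–Mead (with an
initial simplex scaled to 5% of each coordinate's value, falling back to
5% of its bound range at zero — the scipy default's absolute perturbation
freezes zero-amplitude starts).  Clusters of ≥3 enzymes are refined in
stages, because joint Nelder–Mead alone stalls at the baseline in the
27-dimensional nine-enzyme problem: first a shared-wave *group* stage
(the PEP-positive and PEP-negative enzymes each share (A, ln ω, φ),
collapsing the cluster to five variables; the influential enzymes move as
synchronized groups, so this finds the right basin quickly, and it is
restarted from a few frequency initializations — one and two cycles per
horizon — to which it is otherwise sensitive), then block-coordinate
descent over per-enzyme (A, ω, φ) triples (up to four sweeps, ~40
evaluations per block), then a short joint polish.  The three best
candidates plus the baseline are re-simulated at tight tolerances and the
best feasible one is reported; a run that finds no feasible point returns
`converged=False` rather than silently reporting an infeasible optimum.
Everything is deterministic given the seed list.

Default problem sizes (reduced-budget policy): 2000 evaluations / 10
starts for the nine-enzyme cluster, 600 / 6 for the circuit, 240 / 3 per
single enzyme — chosen so the full headline reproduction (screen,
knockout, nine single-enzyme runs, nine-enzyme and circuit optimizations)
completes in a few minutes on one core.

## Scenarios and analysis

Knockouts pin a level at 0 for 8 h (refused for essential genes),
overexpression at 100×; both report total-PEP gains vs baseline and are
simulations, not optimizations — path constraints are reported as warnings
only.  The pair screen optimizes all unordered pairs from a candidate set
at reduced budget and ranks by gain (ties alphabetical).  Correlation
analysis computes pairwise Pearson r between any mix of enzyme-level and
metabolite series on the reporting grid; exactly constant series yield a
NaN "undefined" sentinel instead of a spurious 0.

## Toy fixture

`make_toy_network` builds a seeded linear chain of irreversible
Michaelis–Menten steps with constant influx, dilution on every pool and an
optional linear branch drain.  Each node balance is a quadratic with one
positive root, so the steady state is known in closed form and ships with
the network — an independent oracle for the steady-state solver, the RHS
and the optimizer's bookkeeping.  The toy deliberately lacks everything
that makes the real network interesting (allostery, reversibility,
carbon-supply limitation), so toy-passing says the *machinery* is right,
not that the biology is.

## What the synthetic conditions do and do not show

The network, its parameters and the study conditions (8 h horizon, 20×
level ceiling, 1–10 mM PEP band, 1.5× step tests, 2% threshold) are the
source model's, so reproduced quantities (the nine-enzyme cluster, the
~1.67× PEPC-knockout gain, optimization gains around 1.2×/1.9×/2.2×)
check the transcription and the optimization machinery against an
independent implementation — they are not new biological evidence.  Known
limitations: co-metabolites do not feed back (a real 20× PFK swing would
move ATP), enzyme levels switch instantaneously (no synthesis/degradation
lag, so optimal waveforms are an upper envelope on what a real circuit
could track), the light circuit is modelled only through its induced
waveforms, and gradient-free multi-start certifies no global optimality —
reported gains are lower bounds on the model's true optimum.
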