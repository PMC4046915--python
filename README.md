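# pepwave

Optimally tuned periodic oscillation of enzyme levels as a metabolic
engineering strategy, implemented on a kinetic model of *E. coli* central
carbon metabolism.

Metabolic engineers usually raise production of a target metabolite with
knockouts or constitutive overexpression.  An alternative is to make the
levels of a few selected enzymes *oscillate* — realizable with synthetic
gene circuits (e.g. a light-inducible two-component system) — and to tune
the oscillations so that, over a working horizon, the cell accumulates
more of the target than it would at steady state.  `pepwave` implements
this programme end-to-end for phosphoenolpyruvate (PEP), the limiting
precursor of aromatic amino acid production:

1. an 18-metabolite, 32-reaction kinetic model of glycolysis, the pentose
   phosphate pathway and gluconeogenesis (PPS, FBP), with a dimensionless
   enzyme level `e_j(t)` multiplying each rate law and a dilution term for
   growth:  `dC/dt = S·(e(t)∘r(C)) + b − μC`;
2. a step-test sensitivity screen (every enzyme to 1.5×; enzymes that move
   steady-state PEP by >2% are flagged) that identifies the nine-member
   PEP-influencing cluster;
3. dynamic optimization of enzyme waveforms
   `e_j(t) = clamp(1 + A_j·cos(ω_j t + φ_j))`, maximizing total PEP
   `∫₀ᵀ C_pep dt` over 8 h subject to metabolite path constraints
   (PEP ∈ [1, 10] mM), enzyme bounds [1/20, 20], by penalized
   single-shooting with seeded multi-start;
4. knockout / 100× overexpression scenarios, two-enzyme combination
   screening, a coupled three-enzyme light-circuit mode (GAPDH + PFK
   induced, RPPK repressed in anti-phase), and Pearson correlation maps of
   the resulting trajectories.

The kinetic parameters, rate laws and operating point are transcribed from
the established chemostat model of this pathway; three maximal rates are
recalibrated top-down so the shipped nominal state is an exact steady
state (see `docs/methods.md`).

## Worked example

```python
from pepwave import load_builtin, steady_state_residual
from pepwave.sensitivity import screen
from pepwave.scenarios import knockout
from pepwave.optimize import OptimizationProblem, optimize_dynamic

net = load_builtin()
print(f"steady-state residual: {steady_state_residual(net):.2e} mM/s")

rep = screen(net)
print(f"influential enzymes ({len(rep.flagged)}):")
for enz in rep.flagged:
    print(f"  {enz:6s} PEP ratio {rep.ratios[enz]:.3f}")

print(f"PEPC knockout gain: {knockout(net, 'PEPC'):.3f}")

problem = OptimizationProblem(cluster=["GAPDH"], seeds=(0, 1, 2),
                              budget=240,
                              direction_hints={"GAPDH": 1.0})
res = optimize_dynamic(problem, net)
best = res.program.profile_for("GAPDH")
print(f"optimized GAPDH oscillation: gain {res.gain:.3f} "
      f"(A={best.A:.1f}, period {best.period/3600:.1f} h, "
      f"phi={best.phi:.2f} rad)")
```

prints

```
steady-state residual: 1.73e-14 mM/s
influential enzymes (9):
  PK     PEP ratio 0.797
  G6PDH  PEP ratio 0.805
  PEPC   PEP ratio 0.806
  GAPDH  PEP ratio 1.149
  SER    PEP ratio 0.911
  RPPK   PEP ratio 0.924
  SYN1   PEP ratio 0.927
  DAHPS  PEP ratio 0.934
  PFK    PEP ratio 1.037
PEPC knockout gain: 1.677
optimized GAPDH oscillation: gain 1.230 (A=6.0, period 6.5 h, phi=0.00 rad)
```

Reading this: the shipped parameter file is at steady state to machine
precision; raising each enzyme 50% and relaxing to the new steady state
flags nine enzymes (PFK and GAPDH push PEP up, the other seven—all routes
draining PEP or diverting carbon—push it down); deleting the PEP-consuming
carboxylase raises total PEP 1.68-fold over 8 h; and an optimally tuned
oscillation of GAPDH alone (amplitude 6, period 6.5 h, peak at t = 0)
yields 23% more PEP than the unoptimized system while PEP stays inside its
1–10 mM physiological band.

The same pipeline is scriptable from the shell:

```
pepwave sensitivity --out sens.csv
pepwave optimize --config scenario.yaml --seed 1 --out result.json
pepwave knockout --config ko.yaml --out ko.csv
```

with YAML configs selecting the network (`builtin` by default), cluster,
horizon (hours), bounds and budgets; exit codes are 0 / 2 (config error) /
3 (numerical failure).

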