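# graftdyn

An ordinary-differential-equation simulator of the **early innate and
adaptive immune response to ischemia/reperfusion injury (IRI) and solid-organ
allotransplantation**, with tooling for equilibrium and bifurcation analysis,
basin-of-attraction thresholds, limit-cycle detection, and clinical-outcome
classification.

It is aimed at systems-biology and transplant-immunology modellers who want a
tested, scriptable re-implementation of this class of acute-inflammation
model: reproducing its printed thresholds, sweeping the antigenic-mismatch
factor, or extending the scenario library.

## The model

Six dynamic variables interact on a time scale of hours (arbitrary units):

| symbol | meaning |
|--------|---------|
| `I`    | activated innate pro-inflammatory components (M1 macrophages, PMN, NK, TNF-α, …) |
| `D`    | host tissue damage (a proxy for DAMP release) |
| `D_G`  | graft tissue damage |
| `A`    | anti-inflammatory mediators (IL-10, TGF-β1, M2 macrophages) |
| `T_P`  | pro-inflammatory T cells (TH1/TH17/γδ) |
| `T_A`  | anti-inflammatory T cells (Treg/TH2) |

Damage releases DAMPs that activate innate components from a resting pool
`I_R` (eliminated by a quasi-steady-state reduction); activated innate
components inflict further damage through a switch-like sixth-order Hill
function `f(x) = x⁶/(x⁶ + x_half⁶)`, closing a positive feedback loop that
makes the damage/activation core **bistable**: a healthy equilibrium and an
elevated-inflammation failure equilibrium separated by a saddle.
Anti-inflammatory mediators divide every pro-inflammatory drive by
`1 + (A/a_∞)²` (T-cell drives by `1 + (T_A/b_∞)²`). Memory T cells are
recruited from a quasi-steady-state precursor pool `T_0`; every
allo-recognition term is scaled by the **apparent antigenic mismatch factor
α ∈ [0, 1]**. Graft health is the monotone curve

```
G(D_G) = 1 − (1 − e^(−D_G/x_gdg)) / (1 + k_gdg · e^(−D_G/x_gdg)),
```

with `G = 1` for an undamaged graft and `G(1.9) ≈ 20 %`, `G(1.8) ≈ 24 %` at
the default shape constants. Depending on the initial injuries and α, runs
end in clinical quiescence, subclinical (damped) inflammatory flaring,
chronic oscillatory rejection (a limit cycle), or acute rejection at the
failure equilibrium (`G ≈ 13 %`).

## Worked example

```python
from graftdyn import (ModelParameters, SCENARIOS, run_scenario,
                      scan_alpha_origin_stability)

# combined host IRI (D=2) and graft IRI (D_G=1), syngeneic graft (alpha=0)
traj, outcome = run_scenario(SCENARIOS["fig3G"])
print(outcome.label, outcome.final_G, outcome.min_G)
# clinical_quiescence 100.0 57.7

# mismatch sweep at the same initial condition
_, rejected = run_scenario(SCENARIOS["fig4_base"].with_(alpha=1.0))
print(rejected.label, rejected.final_G, round(rejected.time_to_failure))
# acute_rejection 12.7 110

# where does the alloreactive T-cell loop destabilise the healthy graft state?
print(scan_alpha_origin_stability(ModelParameters()).thresholds)
# [0.074]
```

The first run shows the synergy of two individually tolerable insults: graft
function dips transiently to 57.7 % before recovering fully. At full
mismatch the same initial state fails acutely, entering the failure band
(G ≤ 14 %) at ~110 h. The scan confirms that the trivial equilibrium of the
graft-damage/T-cell subsystem is stable exactly up to α = 0.074 on a 0.001
grid (analytic boundary `μ_tp·μ_t0/(k_tpt0g·s_t0) = 0.075`).

The same functionality is exposed on the command line:

```sh
graftdyn simulate --scenario fig3G -o out/
graftdyn sweep --alphas 0,0.1,0.4,1.0
graftdyn equilibria --subsystem dtotal_i
graftdyn scan constant-a
graftdyn reproduce table2
graftdyn list-scenarios
```

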