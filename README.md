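# gradpot

Planning and simulation of **automated gradient equilibration** for
macromolecular crystal soaking.

Moving a protein crystal abruptly into a new solution — a cryoprotectant, a
low-salt buffer, a ligand soak — often cracks it through osmotic shock.
The gentle alternative is gradient equilibration: the crystal sits in a small
well-mixed pot (~40 µl) while a pair of syringe pumps simultaneously
withdraws pot fluid and injects the target solution, sweeping the bath
composition gradually from start to target. `gradpot` is the software side
of that experiment for people who run it (or want to design one): it
synthesizes the pump schedule that realizes a requested concentration
trajectory, quantizes it onto stepper-motor microsteps, checks hardware
feasibility, and simulates the pot's composition over time (including
evaporation) against a virtual pump — so protocols can be designed, checked
and reproduced without hardware attached.

## The model

Under perfect mixing the pot is a continuously stirred tank. With matched
in/out flow `Q` and volume `V`, the exchange fraction `x` (the fraction of
pot contents that is target solution) obeys

    dx/dt = (Q/V)(1 − x)   ⇒   x = 1 − e^{−V_delivered/V}

so exchanging one pot volume reaches only `x = 1 − e⁻¹ ≈ 0.632`, and any
final fraction `f < 1` costs a total inflow of `V·ln(1/(1−f))` no matter how
the delivery is scheduled (119.83 µl for the standard 40 µl pot at
`f = 0.95`). Discrete events use the exact exponential update
`x ← 1 − (1−x)e^{−ΔV/V}`; component concentrations follow the lever rule
between start and target. Two gradient modes are planned: **linear** in time
(`x(t_k) = f·k/n`, growing event volumes) and **equal-volume** (constant
events, exponential-shaped trajectory). Evaporation removes solvent only,
conserving solute mass `V·c`. See `docs/methods.md` for the full model,
numerical choices and limitations.

## Worked example

Three classic protocols ship as configs: lysozyme (8 → 3 %w/v NaCl over
40 min), thermolysin (2 M ammonium sulfate → water over 15 min) and
α-lactalbumin (0 → 25 %v/v glycerol over 50 min). Run one end to end:

```bash
gradpot report --config src/gradpot/examples/lysozyme.yaml --out-dir out/
```

which logs

```
planner mode=linear ticks=847 f=0.95 T=40 min; total inflow 119.829 µl (quantized 119.828 µl, error 0.0009431 µl ≤ q/2 = 0.002243 µl)
feasibility: feasible: total inflow 119.83 µl, peak implied flow 18.8 µl/min, quantum 4.49 nl
verification: [PASS] max |x_sim - x_req| = 1.29e-15 (tol 1e-06); final x = 0.950000 (requested 0.950000); ...
```

and writes `schedule.csv`, `commands.csv`/`commands.txt` (the step stream a
pump adapter replays), `trace.csv` (time series of volume, exchange fraction
and every component) and `report.txt`, which ends with:

```
final composition at f=0.95 (ideal lever rule):
  NaCl: 3.25 %w/v
  lysozyme: 4.75 mg/ml
  sodium acetate: 20 mM
final composition (simulated, quantized schedule):
  NaCl: 3.25001 %w/v
  lysozyme: 4.74999 mg/ml
  sodium acetate: 20 mM
final exchange fraction (simulated): 0.949999
```

Reading: a 0–95% gradient leaves 5% of the start solution behind, so NaCl
ends at `0.05·8 + 0.95·3 = 3.25 %w/v` — the quantized pump run lands within
one part in 10⁵ of that, limited only by the 4.49 nl microstep. Add
`--rerun 2` to see the combined fraction after executing the gradient twice
(0.9975). The same pipeline is available as a library:

```python
from gradpot import GradientSpec, PotState, Solution, Component, plan, execute_schedule

start = Solution((Component("NaCl", 8, "%w/v"),))
target = Solution((Component("NaCl", 3, "%w/v"),))
pot = PotState(volume=40, composition=start)
spec = GradientSpec(start=start, target=target, final_fraction=0.95,
                    duration=40, mode="linear", ticks=40, pot=pot)
trace = execute_schedule(pot, plan(spec), sample_dt=1.0)
print(trace.x[-1])                                # 0.95
print(trace.concentrations[("NaCl", "%w/v")][-1])  # 3.25
```

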