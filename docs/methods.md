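# Methods

## The physical model

A macromolecular crystal sits in a small open reservoir ("pot", an inverted
PCR-tube cap, typically 40 µl) while two syringe pumps simultaneously
withdraw pot fluid and inject a target solution. Under the well-mixed
assumption — the pot's composition is spatially uniform at all times — the
exchange is a continuously stirred tank. With matched in/out flow `Q` (µl/min)
and pot volume `V` (µl), the fraction `x` of pot fluid delivered by the pump
obeys

    dx/dt = (Q/V) (1 − x),

and every solute concentration relaxes exponentially toward the inflow value:
`c(t) = c_in + (c_0 − c_in) e^{−Qt/V}`. Exchanging one pot volume reaches only
`x = 1 − e^{−1} ≈ 0.632`; `x = 1` would need infinite volume, which is why
gradients are specified to a final fraction `f < 1` (0.95 or 0.98 in
practice) and optionally re-executed: two back-to-back runs reach
`1 − (1−f)²` (0.9975 for f = 0.95).

Composition bookkeeping is a lever rule over named components. Each component
keeps the unit it was declared in (`%w/v`, `%v/v`, `M`, `mM`, `mg/ml`); no
cross-unit conversion is attempted because it would need molecular data the
user has not supplied, and none is needed — mixing is linear per component
under ideal-mixing volumes. Non-ideal mixing volumes (e.g. glycerol/water)
are neglected; for the concentration ranges involved the error is small
compared with the f < 1 cutoff itself. Optional per-component density
contributions are pure bookkeeping: reports compare the density of start and
target so the user can offset the crystal from the inflow tube when the
incoming solution is denser. They never enter the mixing math.

## Discrete events

A pump schedule is a list of timed bursts of volume ΔV. Two semantics are
provided (`event_model`):

- `simultaneous` (default): in and out flow run together during the burst,
  giving the exact update `x ← 1 − (1−x) e^{−ΔV/V}`. This is the limit the
  hardware approximates and it makes the discrete and continuous pictures
  agree exactly: final `x` depends only on the summed volume
  (`x = 1 − (1−x₀) e^{−ΣΔV/V}`), so refining a schedule into more, smaller
  events changes nothing.
- `sequential`: withdraw ΔV, then add ΔV, giving the lever update
  `x ← 1 − (1−x)(1 − ΔV/V)`. Per event the two differ by at most
  `(ΔV/V)²/2`; which one a given firmware realizes depends on its motor
  interleaving, so both are exposed.

Unequal in/out volumes are allowed; the closed form for a linearly changing
volume during the burst is used and the pot volume updates by the difference.

Evaporation removes solvent only (solutes are treated as nonvolatile, which
is accurate for salts, PEG, protein; glycerol's volatility is negligible on
these time scales). Between events the update is analytic: volume falls
linearly at the configured rate `E` (µl/h; about 6 for an open pot at 30–40%
relative humidity, about 1 with a cover), and every concentration scales by
`V₀/V(t)` so the solute mass `V·c` is conserved exactly. `x` is defined as
pump-delivered fluid fraction and is unchanged by evaporation; the
composition-based readout (`exchange_fraction_of`, a least-squares projection
onto the mixing line, clamped to [0, 1]) is the independent channel that
reveals evaporation drift.

## Continuous simulation

`simulate_continuous` integrates `dV/dt = Q_in − Q_out − E/60` and
`d(V c_i)/dt = Q_in·c_in,i − Q_out·c_i` with a fixed-step classical
Runge–Kutta scheme, step ≤ min(sample_dt, 0.1 min). A fixed-step scheme was
chosen over an adaptive library integrator deliberately: the right-hand side
is smooth and nearly linear, the cost is trivial, and fixed steps make traces
bit-reproducible across runs, which the pipeline guarantees. On the analytic
test cases the error is ~1e−13, far inside the 1e−9 tolerance the tests
assert.

## Planning

Both gradient modes place `n` events at uniform ticks `t_k = kT/n`, the first
at `T/n` (end-of-interval convention — the crystal starts in pure start
solution):

- **linear**: volumes `ΔV_k = V ln[(1 − f(k−1)/n)/(1 − fk/n)]` make the
  simulated `x(t_k) = f·k/n` exact when E = 0. Volumes grow strictly with
  `k`: late increments fight a pot that is already mostly target solution.
- **equal_volume**: every event delivers `(V/n) ln(1/(1−f))`; the trajectory
  is exponential-shaped, `x(t_k) = 1 − (1−f)^{k/n}`, steepest at the start.

Both sum to `V ln(1/(1−f))` — the total-volume law (119.83 µl for V = 40 µl,
f = 0.95). "Linear over time" can also be read as fixed volume quanta at
variable times; that reading is provided as mode `linear_fixed_quantum`
(constant volumes at `t_k = T·x_k/f` with `x_k = 1 − (1−f)^{k/n}`). The
variable-volume reading is the default because it keeps tick bookkeeping
uniform; both realize the same linear trajectory.

`f = 0` yields an empty schedule rather than an error: a degenerate but
meaningful request.

The default tick count is the largest `n` (capped at 1000) for which the
smallest planned event is at least 10 microstep volumes. The cap bounds
schedule length; the 10× floor keeps per-event quantization error at the
~10% level. (The stated rule fixes the direction of the trade-off: more
ticks are always smoother, so the binding constraint is the per-event
minimum.)

The planner does **not** compensate evaporation: physically the remedy is a
pot cover, not software, and silently inflating volumes would misstate what
the pump did. Instead `verify_schedule` executes the schedule with the pot's
configured evaporation rate and reports the trajectory deviation — e.g. a
3 h, 60-tick, 0–95% gradient at 6 µl/h shows a max |x_sim − x_req| of
~0.086, flagged as a failure at any tight tolerance.

## Pump quantization

One microstep advances the plunger by `lead/(steps_per_rev·microstepping)`
mm, delivering `q = π(d/2)²·lead/(steps_per_rev·microstepping)` µl (mm³ and
µl coincide). The default geometry — BD 1 ml syringe, d = 4.78 mm, 0.8 mm
lead, 200 steps/rev, 16× microstepping — gives q ≈ 4.49 nl; these are
documented vendor/driver values, every one overridable in config, and
`min_injection` may be raised (e.g. to 2 nl) to enforce a coarser floor.

Quantization rounds the *cumulative* ideal volume to the nearest multiple of
the effective quantum and emits the difference as that event's step count (a
carry accumulator). Consequences, all asserted in tests: the running
delivered total never deviates from ideal by more than q/2; sub-quantum
events are merged into the carry (with a warning) rather than lost; inflow
and outflow receive identical counts for constant-volume events, so
quantization cannot change the pot volume; and the end-to-end error in final
`x` decreases monotonically as the quantum shrinks.

The feasibility check flags zero-step events, implied flows above the pump's
`max_flow`, totals above the syringe capacity, and withdrawals larger than
the pot. The virtual pump converts step commands back to volumes and runs
them through the simulator — the hardware contract is the command stream
(CSV, or a one-line-per-command text script), so a serial adapter can be
substituted without touching any tested code.

## Synthetic problems

`gradpot.fixtures.generate_fixture(seed)` draws complete run configurations
from the realistic envelope of the method: V ∈ [10, 100] µl, f ∈ [0.5, 0.99],
T ∈ [5, 180] min, n ∈ [1, 500], 1–4 components with unit-appropriate
concentration ranges, E ∈ {0, 1, 6} µl/h. The draw is deterministic per seed.
These fixtures emulate the *request space*, not real lab noise: they contain
no pump backlash, tubing dead volume, incomplete mixing, density-driven
stratification or temperature drift. Passing the property suite therefore
shows that planning, quantization and the well-mixed simulation are mutually
consistent and numerically exact — not that a physical pot will track the
trajectory to 1e−9.

## Problem sizes and tolerances

The property suites run 100–200 random cases per invariant and the
trajectory-fidelity check runs 1000 random fixtures; the whole suite
completes in a few seconds. Agreement tolerances are 1e−9 where an exact
closed form exists (event algebra, total-volume law, conservation), 1e−6 for
the end-to-end protocol compositions (which traverse quantization), and
bound-based where the quantity is a discretization artifact (quantization
error ≤ q/2, model disagreement ≤ Σ(ΔV/V)²/2).

## Known limitations

- Spatial effects in the pot (inflow plume, density-driven sinking,
  convection) are out of scope; the documentation-level advice is to place
  the inflow tube at the surface and offset the crystal, guided by the
  reported density comparison.
- Intra-crystal diffusion is not modeled: `x(t)` describes the bath, not the
  crystal interior.
- Evaporation is a constant user-supplied rate; real rates vary with ambient
  humidity and pot geometry.
- No unit conversion means the exchange-fraction inverse is computed in
  whatever mixed unit system the user declared; it is scale-dependent by
  design (a least-squares summary, exact on the mixing line).
- The packaged example configs ship with `evaporation_ul_per_h: 0` so their
  reports show the ideal lever-rule endpoints; set 6 (open) or 1 (covered)
  to study evaporation drift on the same protocols.
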