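# Methods

## Model structure and assumptions

The physiology is a deliberately compact composition of four published
model classes, valid for short moderate-intensity (aerobic) exercise:

* The glucose–insulin core is a minimal model: plasma glucose G relaxes
  towards the basal (untreated) level G_b at rate p₁ ("glucose
  effectiveness") and is cleared in proportion to the remote insulin action
  X, which itself follows over-basal plasma insulin ΔI = I_t + I_c − I_b
  with rates p₂ (decay) and p₃ (insulin sensitivity). Therapy is idealized:
  a constant plasma insulin concentration I_t holds fasting glucose exactly
  at the target G_t, and bolus insulin arrives through a two-compartment
  subcutaneous pathway (x₁ → x₂ → plasma I_c).
* Exercise intensity is encoded purely by heart rate. The over-basal heart
  rate drives an energy-expenditure state Y with a 5-min lag; a Hill switch
  f(Y) turns on a state Z once Y exceeds the fraction a = 0.1 of the basal
  heart rate, and Z decays back with τ = 600 min after the session — this
  is what keeps insulin sensitivity elevated into the night. The
  duration-and-intensity dose of a session accumulates in
  W = ∫(HR − HR_b)dt, and insulin action is amplified by the factor
  (1 + αWZ). During activity an insulin-independent clearance βYG adds the
  immediate glucose demand of working muscle.
* Meal glucose appears at the gamma-shaped rate
  Ra(t) = f·D·t·e^(−t/τ_max)/τ_max², which integrates exactly to the
  bioavailable carbohydrates f·D.

Assumptions worth keeping in mind: heart rate is a square wave (constant
session HR, instant transitions); there is no anaerobic/high-intensity
physiology, no glycogen-depletion dynamics, no dawn phenomenon, no CGM
sensor noise, and basal insulin delivery is never modulated within the day.

### The basal-action term X_b

The exercise amplification also applies to the action of basal insulin,
written −αWZ·X_b·G. We define X_b = (p₃/p₂)·I_b, the steady-state remote
action that the basal insulin concentration I_b would produce. This is
dimensionally consistent with X and reproduces the model's characteristic
overnight behaviour after afternoon exercise (a quasi-steady glucose near
100 mg/dl instead of the 120 mg/dl target; see the acceptance checks). The
alternative reading X_b = (p₃/p₂)·I_t behaves similarly but settles
slightly lower; the I_b-based definition is used throughout.

## Parameters

Defaults describe one 'typical' 70-kg adult with resting heart rate 80 bpm,
basal insulin 10 µU/ml, bolus calculator settings ICR = 15 g/U and
CF = 20 mg/dl/U, and target glucose 120 mg/dl.

| group | parameter (unit) | default |
|---|---|---|
| glucose regulation | p₁ (1/min) | 0.0041 |
| | p₂ (1/min) | 0.0155 |
| | p₃ (1/min² per µU/ml) | 6.913·10⁻⁶ |
| | G_b (mg/dl) | 172 |
| | α (–) | 2.59·10⁻⁴ |
| | β (1/bpm) | 3.39·10⁻⁴ |
| | τ_HR (min) | 5 |
| | τ (min) | 600 |
| | a (–), n (–) | 0.1, 4 |
| meal | f (–) | 0.8 |
| | V_g (dl/kg) | 1.6 |
| | τ_max slow / fast (min) | 60 / 20 |
| insulin kinetics | k₂₁, k_d, k_a, k_e (1/min) | 0.0085, 0.0247, 0.011, 0.0357 |
| | V_i (ml/kg) | 104 |

## Simulation machinery

Two integrators share the same equations:

* **Reference engine** (`physiology.Simulator`): event-driven, integrating
  each smooth segment with LSODA at rtol 10⁻⁸ / atol 10⁻¹⁰ and restarting
  at every discrete event (meal, bolus impulse, exercise start/stop,
  strategy action). Output on a 1-min grid over the 1440-min day starting
  at 06:00. Halving the tolerances changes time-in-range by far less than
  0.1 percentage points (tested).
* **Batch engine** (`fastsim.simulate_batch`): a vectorized fixed-step RK4
  integrator (dt = 1 min) that advances tens of thousands of parameter sets
  in lock-step for the sensitivity analysis. It supports no-adjustment
  plans only; heart-rate switch times snap to the step grid so each step
  sees smooth dynamics. The fastest model time constant is τ_HR = 5 min, so
  1-min steps resolve everything; the test suite verifies agreement with
  the reference engine to < 0.01 mg/dl on the nominal day and across
  perturbed subjects.

Strategy mechanics: strategies are polled on a 5-min grid during exercise
(the CGM cadence), with the glucose trend taken as the backward difference
G(t) − G(t−5) on noise-free simulated glucose. Strategy snacks are
fast-acting meals (τ_max = 20 min) and never receive a bolus. Exercise
suspension (CHO algorithm, glucose < 70 mg/dl) terminates the session for
the rest of the day. The consensus onset rule below 90 mg/dl postpones the
start in 5-min steps until glucose exceeds 90 mg/dl, preserving the planned
duration, with a 120-min cap after which the session is cancelled (the cap
never binds in the study scenarios). Hourly during-exercise carbohydrate
rates are discretized into equal portions every 30 min starting 30 min
after onset. Bracket conventions for the guideline tables: heart-rate
brackets are right-open (130 bpm falls in the 130–155 band), the 30–60 min
duration bracket is closed at 60, and a session of at most 30 min takes the
short-session row. The "end of exercise" and "immediately after exercise"
20-g rules are evaluated as a single check at session end. For glucose
between 90 and 110 mg/dl dropping slower than 5.4 mg/dl per 5 min the
intake algorithm's sources are silent; no intake is recommended.

Bolus doses are computed at injection time (15 min before each meal) from
the simulated glucose, rounded to the nearest 0.5 U with exact ties rounded
up, and clamped at zero. No insulin-on-board correction is applied.

## Metrics

All indices are computed on a 5-min subsample of the trajectory, mirroring
CGM readings (refining the grid changes the indices by well under 0.5% on
these smooth trajectories; tested). Glucose is clamped to [20, 600] mg/dl —
the standard domain of the risk function — before evaluating
r(G) = 10·1.5092·[(ln G)^1.084 − 5.381]²; "ln" is the natural logarithm,
which places the minimum at 112.5 mg/dl. LBGI and HBGI average the
below-/above-threshold risk over all readings. TIR counts unclamped
readings in [70, 180] mg/dl, boundaries included. Windowed LBGI restricts
the readings: acute = [session start, session end + 60 min]; late-onset =
19:00 to 06:00.

## Scenario generators

* Standard day: 50 g at 07:00, 70 g at 13:00, 60 g at 19:00, all with
  τ_max = 60 min; boluses 15 min before each meal.
* Timing sweep: 60 min at 120 bpm starting 13:30 … 17:30 in 30-min steps
  (9 starts × 4 strategies).
* Scenario grids: HR ∈ {120, 140, 160} bpm × duration ∈ {30 … 120} min in
  15-min steps × 4 strategies, with exercise at 12:00 (lunch moved to
  14:30; postabsorptive), 14:30 (bolus-reduction / high insulin condition,
  lunch-bolus gap 105 min) or 15:30 (low insulin condition, gap 165 min).
* Virtual population: 100 subjects by default, independently perturbing
  p₁, p₃, α and β with normal noise of SD 20% of nominal (draws ≤ 0
  rejected), all other parameters fixed; default prescription 90 min at
  140 bpm. The generator emulates between-subject variability in the four
  parameters that dominate glucose handling and exercise response; it does
  not emulate within-day variability, meal-composition uncertainty, or
  therapy-setting differences (ICR/CF are population constants), so
  population results speak to parameter spread around one phenotype, not
  to a clinically diverse cohort.

## Sensitivity analysis

Design: Saltelli cross-sampling on a scrambled Sobol' sequence with
second-order blocks (N·(2k+2) evaluations for k inputs), first-order
estimator of Saltelli (2010), total-order estimator of Jansen (1999), and
the standard second-order estimator; 95% confidence half-widths by
bootstrap over base samples (1000 resamples by default). The estimators are
validated against analytic variance decompositions (additive-linear and
Ishigami functions) in the test suite. Responses are TIR and LBGI of the
standard day with an unadjusted 60-min, 120-bpm session at 15:30; in the
timing variant the start time is an extra uniform input on [13:30, 17:30].

Varied inputs: the glucose-regulation parameters (p₁, p₂, p₃, G_b, α, β,
τ_HR, τ, a), the distribution volume V_g, and the insulin-kinetics
parameters (k₂₁, k_d, k_a, k_e, V_i), each uniform within ±20% of nominal
— 15 inputs. The integer Hill exponent n is held fixed (a ±20% range on an
integer exponent is ill-defined), as are the therapy constants (ICR, CF,
BW, HR_b, I_b, G_t) and the meal-shape inputs f and τ_max: the meal
composition defines the scenario rather than the subject, and varying it
lets meal-appearance shape dominate the TIR variance, masking the
physiological signal the analysis is meant to decompose.

Each sampled parameter set is initialized at its own fasting steady state
(glucose at target, I_t and X_b recomputed from the sampled parameters), so
the decomposition measures the response to exercise and meals, not to
inconsistent initial conditions. Non-finite responses would drop the whole
base sample to keep the estimator blocks paired; if more than 0.1% of
simulations failed the run aborts rather than silently biasing the indices
(none fail in practice).

Problem sizes: the package default is base_n = 512, i.e. 16,384
evaluations for the fixed-timing experiment and 17,408 with timing — large
enough that first-order indices are stable to a few points across seeds.
`base_n_for_total` recovers the base size matching any target budget, e.g.
the full-scale 51,000-evaluation experiment.

## Known limitations

* The composed model extends its components beyond their individually
  validated ranges; results are comparative, not predictive, and all the
  caveats of an unvalidated composition apply.
* Only single continuous sessions are exercised by the study scenarios;
  whether W should reset between same-day sessions is left open (W is never
  reset within a day).
* The 24-h LBGI of the unadjusted timing sweep rises with later exercise
  start up to 16:00 but bends down for the latest starts: the hypoglycemic
  dip of a 17:00–17:30 session is cut short by dinner and the shrinking
  dinner-bolus correction raises overnight glucose. The same interplay
  produces the TIR rebound after 16:00 visible in the sweep. Summary
  indices over a full day can therefore rank very similar exercise
  scenarios non-intuitively — a caveat when reading single-number
  comparisons.
* Strategy evaluation uses noise-free glucose; with real CGM noise the
  trend-based rules would trigger differently.
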