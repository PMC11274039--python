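# Methods

## Scope and structure

`ifpace` couples an intuitionistic fuzzy logic controller (IFLC) to a
simplified cardiac pacing plant and simulates heart-rate tracking over
patient activity scenarios. The package is organised along the signal path:

* `ifs_core` — intuitionistic fuzzy numbers (IFNs), triangular
  intuitionistic sets, linguistic term sets;
* `iflc` — fuzzification, rule firing, dual-channel center-of-gravity (COG)
  defuzzification, output combination;
* `pacemaker_plant` — RC membrane model, pulse energetics, the
  period-command actuator and rate sensor;
* `closed_loop` — scenarios, the simulation driver, metrics and reports;
* `cli_io` — YAML configuration, trace CSV round-trips, the `ifpace` CLI.

## Intuitionistic fuzzy algebra

An IFN is a pair (μ, ν) with μ, ν ∈ [0, 1] and μ + ν ≤ 1; hesitancy is
1 − μ − ν. The operational rules are the standard algebraic ones
(⊕: μ₁+μ₂−μ₁μ₂ / ν₁ν₂; ⊗: μ₁μ₂ / ν₁+ν₂−ν₁ν₂; scalar multiple and power as
their n-fold limits). Constraint checks use a construction tolerance of
1e−9; a strict constructor rejects violations and a lenient one clips ν to
1 − μ, absorbing round-off in long operation chains.

Two conventions for the logical connectives ship:

* **as-printed** (default): conjunction and disjunction apply the same
  extremum to *both* degrees — (min μ, min ν) and (max μ, max ν) — and the
  implication is (max(ν_a, μ_b), max(μ_a, ν_b)). The disjunction and
  implication can then produce μ + ν > 1; such results are representable,
  carry a `flagged` marker and log a warning rather than raising, so the
  behaviour is observable rather than silently corrected.
* **standard**: the classical Atanassov t-norm/s-norm pair
  (min μ, max ν) / (max μ, min ν), which always preserves the constraint.

Which convention a published controller used is generally not observable
from its results because rule firing only exercises the conjunction, and for
term sets whose ν-curves are complements of the μ-curves the two conjunction
modes differ only in the ν channel, whose weight σ_c is tiny at the default
operating point. Both are first-class and selectable per controller
(`and_mode`).

A triangular IFS ⟨aˡ, aᵐ, aᵘ; cˡ, aᵐ, cᵘ⟩ requires
cˡ ≤ aˡ ≤ aᵐ ≤ aᵘ ≤ cᵘ. With the ν-support nesting the μ-support, μ + ν ≤ 1
holds everywhere (verified on a dense grid at construction). Degenerate
edges (aˡ = aᵐ or aᵐ = aᵘ) evaluate as one-sided shoulders with the peak
value taken exactly at aᵐ — required by the saturated terms at the universe
edges.

**Default term set** (both inputs and the output, universe [−1, 1]):

| term | μ-triangle | ν-support |
|------|------------|-----------|
| Negative | (−1, −1, 0) | [−1, 0] |
| Zero     | (−1, 0, 1)  | [−1, 1] |
| Positive | (0, 1, 1)   | [0, 1]  |

The μ-triangles tile the universe as a partition of unity and the ν-curves
are their complements within the same support, so pointwise hesitancy is
zero. The geometry is recorded in the configuration document, so alternative
shapes (e.g. ν-supports wider than the μ-supports, giving positive
hesitancy) are directly testable.

## Controller

Inputs: normalized error e and its unit-delay first difference ce = e_k −
e_{k−1} (no division by Δt; the gain K_ce absorbs the time scale). Each is
scaled by its gain and clipped to [−1, 1] before term evaluation. The rule
table is the antisymmetric 3×3 standard for PI-like fuzzy control (N,N→N …
P,P→P); antisymmetry is validated at construction, making the control
surface exactly odd.

Inference follows Mamdani practice applied independently per channel: each
rule min-clips its output term's μ-curve at the rule's μ firing degree, and
its ν-curve at the ν firing degree; curves are aggregated pointwise by max
and defuzzified by COG on a uniform grid. The ν-channel centroid is computed
from the clipped ν-curves directly; a `nu_complement` flag instead
defuzzifies the 1 − ν curves clipped at 1 − firing ν, for users who prefer
the complement reading of the non-membership channel. The default is the
direct reading: the two inference systems are symmetric in their own
curves, and at σ_c = 0.0001 the choice is numerically immaterial (the two
interpretations differ in u by at most σ_c·K_u·2 = 0.02).

Numerical choices:

* **COG grid**: 1001 points, built by mirroring a half-grid so the
  endpoints ±1, the midpoint 0 and the sign symmetry x_i = −x_{n−1−i} are
  exact in floating point. This makes the odd symmetry of the control
  surface exact to ~1e−12 and places the shoulder peaks on the grid.
  1001 vs 10001 points changes centroids by < 1e−3.
* **Zero aggregated mass** (no rule fires on a channel): centroid falls
  back to 0, the universe midpoint, and the event is logged.
* The small-signal gain of the min–max–COG surface is quadratic in the
  input (z ≈ (K_e·e)²/2 near the origin): an intrinsic property of
  three-term Mamdani controllers that shapes the actuation scaling below.

## Plant and actuation

The sinoatrial membrane reduces to C_m dV/dt + V/R_m = I_app
(C_m = 1 μF/cm², a typical membrane value; R_m = 20 Ω). The update is the
closed-form exponential solution, so one step of size T equals any
refinement of it to machine precision; the membrane trace is diagnostic
only and does not feed back into the paced rate.

Per-pulse energy is E = d·V²_pulse/R_pulse with R_pulse = 601 Ω and
V_pulse = 197.8 mV. Stimulus trains are rectangular, ±0.165 mA, width
0.094 s (the per-beat recovery delay), alternating polarity per beat.

**Period-command convention.** The controller's actuation variable is the
pacing *period* d: the documented duration/rate pairs (0.65 s ↔ 92 bpm,
0.59 s ↔ 102 bpm, 0.49 s ↔ 122 bpm, 0.53–0.79 s ↔ 113–76 bpm) all satisfy
rate = 60/d within ±1 bpm of rounding, so that law is adopted and the
0.094 s delay is the intra-beat pulse width. d is bounded to [0.3, 1.2] s
(200–50 bpm).

**Velocity-form actuator.** Each update,
d′ = clip(d − slew·u/1000, d_min, d_max) with slew = 20 ms per output unit:
positive error → positive u → shorter period → higher rate, and the
integration of u gives zero steady-state error. The scale is set so the
loop settles within a few seconds of an activity change: because the
controller's small-signal gain is quadratic, a much smaller scale (e.g.
1 ms/unit) leaves the loop creeping for minutes once the error is small,
while a much larger one (≳100 ms/unit) overshoots at the bradycardic-onset
error of 15 bpm. The value is part of the configuration (`slew_ms_per_unit`).

**Dual sensors.** The activity sensor selects the preset reference; the
rate sensor measures the paced rate with a first-order lag (τ = 1.5 s by
default, 0 disables) and optional seeded Gaussian noise (off by default).

## Closed loop and scenarios

Control update interval dt = 0.05 s; activity segments of 60 s; the run
starts 15 bpm below the first segment's preset (bradycardic onset), with
the commanded period consistent with that starting rate. The normalized
error is (ref − measured)/60 bpm, clipped to [−1, 1] — the 60 bpm span maps
the worst realistic errors into the universe without chronic saturation. A
divergence guard aborts with a diagnostic if the error stays saturated for
more than 30 s.

The six built-in scenarios carry the preset table (three female, three male
patients, 45–66 years; rest presets 80–92, walking 92–103, jogging
103–122 bpm, tolerances ±3 to ±6). A seeded generator draws synthetic
scenarios uniformly within physiological bands (rest 70–95, walking 90–110,
jogging 100–130 bpm) for randomized testing.

**Metrics.** RMSE (bpm) and maximum error (% of preset) are computed over
an evaluation window. The default window is the *steady-state window* — the
final 50% of each segment. A window anchored at first entry into the
tolerance band is also available (`window="settled"`), but a max-error
metric over it is bounded below by roughly the band edge itself (≈5% of
preset at ±5 bpm), since the window's first sample sits at the band
boundary; sub-percent maximum-error figures therefore describe the steady
regime, which is what the steady window isolates. Settle time (first
sustained band entry) is always reported alongside. Enlarging any window to
include more transient can only increase RMSE.

`evaluate_all` reports every scenario × activity × controller variant; the
default variants are the IFLC and its σ_c = 0 classical-fuzzy degenerate
mode. Published results for other controller families (classical fuzzy,
fuzzy-PID, RBF network) ship as a static transcription
(`reference_results()`) for context only and are never recomputed.

## What the simulation does and does not show

The plant is deliberately minimal: rate dynamics are a first-order sensor
lag around an exact period-to-rate law, with no intrinsic rhythm, no
atrioventricular conduction, no ionic-current dynamics (the five-current
sinoatrial ionic model is out of scope; only the RC reduction is used) and
no physiological disturbance. Passing tests therefore demonstrate the
controller's closed-loop behaviour — settling, zero steady-state error,
boundedness, symmetry, robustness of the steady window — on this idealized
plant, not clinical performance. Sensor noise and randomized scenarios
probe robustness but are simplistic white-noise/uniform models.

Problem sizes used by the shipped evaluations: 60 s segments at dt = 0.05 s
(1200 updates per run), 18 scenario–activity combinations, 10⁴ random IFN
pairs and 10³ random input pairs in the invariant batteries.

## Known limitations

* The as-printed disjunction/implication can leave the IFN constraint;
  results are flagged, not repaired.
* The actuation law and its slew scale, the sensor model, segment lengths
  and the initial condition are package conventions — points the underlying
  control problem leaves open — and are all recorded in the configuration
  document so sensitivity runs can vary them.
* With the steady-state window the reported RMSE depends on segment length
  (longer segments → deeper convergence → smaller RMSE under the default
  noise-free sensor).
* The COG fallback value (0) at zero mass is arbitrary but unreachable in
  closed loop with the default term set, where the Zero term always has
  positive firing mass.
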