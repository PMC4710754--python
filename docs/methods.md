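# Methods

## The AP-clamp computation

An action-potential clamp (AP-clamp) applies a previously recorded AP as
the command potential of a voltage clamp; pharmacological subtraction
then isolates one current's time course during the AP. The same waveform
can instead be applied *computationally* to a model of that current,
which is what this package does. A digitized AP is an ordered polyline
of samples (t_i, V_i); adjacent samples are connected by straight lines
and no smoothing is applied, so within each segment the forcing voltage
is exactly

    V(t) = V_i + (V_{i+1} − V_i)(t − t_i)/(t_{i+1} − t_i).

Each Hodgkin–Huxley gating variable x ∈ [0, 1] obeys

    dx/dt = k [ −(α(V) + β(V)) x + α(V) ]  ≡  k [ α(1 − x) − β x ],

with k a dimensionless temperature factor multiplying both rates
uniformly (so it rescales the time constant τ = 1/[k(α+β)] without
moving the steady state x∞ = α/(α+β)). Rates are one of three closed
forms — linoid A(V−V0)/(exp(−(V−V0)/B)−1), exponential A·exp(−(V−V0)/B),
logistic A/(exp(−(V−V0)/B)+1) — stored as data, so any cell's model can
be declared in a YAML file. The shipped `engel_jonas_mfb` preset family
describes the mossy-fiber-bouton (MFB) delayed-rectifier K⁺ current
(n⁴ gating) and fast Na⁺ current (m³h gating), with the K⁺ kinetics
extrapolated from 34 to 37 °C by Q10 = 2.2 (factor 1.27) and the Na⁺
kinetics from 23 to 37 °C (factor 2.8).

Units are fixed repo-wide: mV, ms, ms⁻¹, mS/cm², mA/cm². Because
mS/cm²·mV = µA/cm², the ohmic current expression g·Πxᵖ·(V−E) carries an
explicit 10⁻³ so both driving modes report mA/cm².

## Driving forces

The classical ohmic form I ∝ (V − E) forces equal slope conductance on
both sides of the reversal potential, which is impossible for a
selective channel when internal and external concentrations differ. The
constant-field (GHK) alternative uses the dimensionless factor

    GHK(V, E, Vt) = (V/Vt) · (e^{(V−E)/Vt} − 1)/(e^{V/Vt} − 1),

which rectifies outward for E < 0 and reduces the model's fully
activated I–V relation to a·GHK(V−E) with a single amplitude a in
mA/cm². The removable singularity at V = 0 lies on the data path (every
AP crosses 0 mV), so the implementation evaluates with `expm1` and
substitutes the analytic limit e^{−E/Vt} − 1 inside a |V| < 10⁻⁶ mV
guard band; linoid rate laws get the same treatment at V = V0 (limit
−A·B, band 10⁻⁶ mV). Thermal voltage kT/q and Nernst potentials are
computed from CODATA constants; the familiar 26.7/26.5 mV and
−110/−104 mV arise by rounding, not hard-coding.

## Integration

The gating ODE is solved segment by segment with state continuity at
segment boundaries, so the adaptive solver (DOP853, rtol 10⁻⁹,
atol 10⁻¹²) never steps across a slope discontinuity of the forcing.
Dense output is retained per segment, giving a continuous solution
x(t) evaluable anywhere on the waveform. Tolerances are a package
choice justified by an internal convergence property (halving rtol
changes the result by less than rtol) and by agreement with an
independent fixed-step *exponential Euler* integrator
(x ← x∞ + (x − x∞)e^{−Δt/τ}, rates frozen at the mid-step voltage,
Δt ≤ 10⁻³ ms), which is exact for constant V and second-order in the
voltage variation. On a full synthetic AP the two routes agree to
better than 10⁻⁷ on every gate at Δt = 10⁻⁴ ms. Gate values are
reported at the waveform sample times; excursions below 0 by less than
10⁻¹² (round-off) are clamped.

## Activation-curve renormalization

Activation curves obtained by dividing current families by (V − E_K)
are systematically flattened if the open channel actually follows the
GHK relation. The renormalization pipeline (1) excludes points at
V ≥ +50 mV, where a voltage-dependent block by internal Na⁺ cannot be
ruled out; (2) multiplies by (V − E_lin) to undo the linear
normalization (E_lin = −85 mV in the shipped `geiger_jonas_fig2`
preset); (3) divides by GHK(V − E_ghk) with E_ghk = −104 mV and
kT/q = 26.5 mV and rescales so the most-activated point equals 1. The
max-to-one convention is a package choice: within the revised n⁴ model
n∞⁴(+30 mV) ≈ 0.995, so the rescaled curve saturates at 1 to < 1%; a
`rescale="none"` mode is provided. Points at the reversal potential of
either normalization are rejected (zero driving force cannot be
inverted).

The steepening is captured inside the n⁴ description by the slope
voltage B of β_n = 0.125·exp(−(V+65)/B): B = 80 mV gives the shallow
linear-normalized curve, B = 20 mV the steep GHK-normalized one. The
published revision chose B by inspection; `fit_beta_slope` is this
package's principled surrogate — a Levenberg–Marquardt least-squares
fit of (B, c) in c·n∞⁴(V; B), B parameterized on a log scale, all other
rate constants held fixed. The free amplitude c makes the estimate
exactly invariant to any overall rescaling of the input. Noise-free
synthetic points are recovered to |B̂ − B| < 10⁻³ mV; with Gaussian
noise of sd 0.02 on 11 voltages (−70…+30 mV), the median over 200
seeded replicates recovers B = 20 within a few percent.

## Trajectory analysis

The state (V(t), I(t)) during an AP traces a loop in the I–V plane. If
a single activation gate passes an extremum (ẋ = 0) while V̇ ≠ 0, the
chain rule gives dI/dV along the trajectory = a·xᵖ·G′(V): the
trajectory is tangent to the fixed-gate GHK curve drawn at the extremal
gate value. The package verifies this numerically: `gate_peak` with
`refine=True` polishes the discrete maximum by root-finding ẋ(t) = 0 on
the dense solution, and `tangency_gap` compares the trajectory secant
slope over t* ± h (h = the sample spacing) with a centred-difference
slope of the fixed-gate curve over the same voltage window. Both
differences are second-order, so the gap falls ~4× when the sampling
grid is refined 2×; at the default grid it is below 10⁻³ of the local
slope. Without dense output a grid-only fallback uses centred
differences at the sample nearest t*, whose gap is first-order in the
offset between the discrete and true peak — adequate for inspection,
not for the tangency test.

The Na⁺/K⁺ overlap metric integrates min(|I_Na|, I_K⁺) by the trapezoid
rule over samples where both magnitudes exceed 1% of their respective
peaks (a configurable floor that excludes numerical tails), reporting
charge in µC/cm² (mA/cm² × ms) and its fraction of the total Na⁺
charge — a scalar for the energetic inefficiency of simultaneous
inward and outward flux.

## Synthetic data

No recorded waveform ships with the package; two generators stand in.

* `parametric_ap` — a double-exponential spike (rise τ 0.15 ms, decay τ
  0.45 ms after a 0.3 ms foot), rescaled so the peak is exactly V_peak,
  with an optional alpha-function afterhyperpolarization (default 4 mV,
  τ 0.8 ms). Defaults (rest −80 mV, peak +32 mV, ~0.8 ms half-width,
  dt 0.039 ms, 6 ms duration) emulate the qualitative shape of an MFB
  AP: brief, large overshoot, modest AHP.
* `simulate_membrane_ap` — a self-consistent fixture solving
  C dV/dt = −(ΣI_ion + g_L(V − E_L)) + I_stim with the package's own
  Na⁺ and K⁺ models (fixed-step RK4, dt 10⁻³ ms; it is plumbing, not
  the method, so simplicity beats adaptivity). The leak is solved so
  the ionic currents balance at −80 mV given E_L = −90 mV
  (g_L ≈ 0.27 mS/cm²; the Na⁺ model carries a sizeable window current
  at rest, which the leak must cancel). The default 30 µA/cm² × 0.5 ms
  stimulus elicits a regenerative spike peaking near +20 mV; zero
  stimulus rests exactly; subthreshold stimuli decay without firing.

Neither generator reproduces a recorded MFB AP quantitatively (no
digitization of figures is attempted), so tests built on them certify
the *method* — integration accuracy, tangency, renormalization algebra,
parameter recovery — not agreement with the experimental traces. The
gate maximum of the GHK K⁺ model on the mechanistic synthetic AP
(n* ≈ 0.31) is of the same order as the published value on the
recorded AP (0.283) but is not an acceptance quantity.

All generators are deterministic given their seed argument; the
mechanistic simulator has no stochastic term and accepts the seed only
for interface uniformity.

## Degenerate inputs and edge behaviour

Non-finite voltages, non-positive concentrations, temperatures at or
below absolute zero, α+β = 0, empty point sets after filtering, points
at a normalization reversal potential, non-monotone waveform times, and
mismatched sample grids all raise typed exceptions
(`DomainError`, `DegenerateInputError`, `WaveformValidationError`,
`GridMismatchError`, `SolverError`). Gate-peak ties break to the
earliest time. Waveform input accepts Unicode minus signs (common in
digitized supplementary tables); output is ASCII.

## Known limitations

* Independent-gate HH schemes only; no Markov/multi-state kinetics, so
  the extra activation delay after hyperpolarized holding (Cole–Moore
  effect) is outside the model class, as is any multi-channel (Kv1/Kv3/
  BK) decomposition.
* Single-ion GHK driving factor with valence +1; no permeability-ratio
  flux equations, no divalent block models.
* The tangency analysis assumes a single activation gate dominates the
  current at its extremum; for m³h-type currents the m-peak tangency
  holds only where h is momentarily stationary.
* `fit_beta_slope` varies only the β slope voltage; a genuinely
  different activation mechanism would demand refitting α as well.

## Problem sizes

Default test and acceptance runs use a 6 ms mechanistic AP sampled at
0.039 ms (~155 samples, ~6000 internal RK4 steps), 11-voltage
activation grids, 200 fit replicates, and an exponential-Euler oracle
at 10⁻⁴ ms (~60 000 steps) — sizes at which every documented tolerance
is met with margin on a single CPU in seconds.
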