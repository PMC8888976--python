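# Methods

## The closed-loop model

The circulation is a lumped-parameter (0D) hydraulic network: pressures
in mmHg, volumes in ml, flows in ml/s, time in s. The loop is

left ventricle → ascending aorta → aortic arch → {cerebral branch} →
thoracic aorta → abdominal aorta → iliac → systemic peripheral →
systemic veins → right ventricle → pulmonary arteries → pulmonary veins →
left ventricle.

State variables are the 13 compartment volumes (including the occlusion
reservoir when present) plus the four inductor flows of the aortic
segments. Volume is conserved exactly by construction (every flow leaves
one compartment and enters another); the test suite checks conservation
to < 0.1 % and typically observes it at machine precision.

### Ventricles

The activation waveform

a(t_m) = tanh(5 q t_m) · [tanh(q(t_m − T_a)) − tanh(q(t_m − T_b))] / (2α),
t_m < T_s; 0 otherwise

uses the published constants T_c = 0.8 s, T_s = 0.34 s, T_a = 0.08 s,
T_b = 0.45 s, α = 0.8218, q = 2π s⁻¹. α sits in the denominator: only
then does the printed value normalize the peak to 1 (verified to 1e-3 on
a dense grid). The waveform is genuinely discontinuous at T_s
(a(T_s⁻) ≈ 0.93); the integrator restarts at every cycle start and every
end-of-systole instant rather than smoothing the jump, and output samples
landing exactly on the jump are classified on the post-jump branch.

Chamber pressure follows the elastance convention

P = U₀·a + (E_D + E_S·a)(V − V_u) + φ(V) − r_visc·q_out − k_ej·q_out²

with published U₀ = 50/24 mmHg, E_D = 0.04/0.01, E_S = 1.375/0.23
mmHg/ml (left/right) and unstressed volumes V_u = 10 ml. Three
constitutive elements are this package's own choices:

* **Passive wall stress** φ(V) = A·exp((V − V_knee)/λ) (left: A = 5 mmHg,
  V_knee = 150 ml, λ = 25 ml). It reproduces the exponential
  end-diastolic P-V relationship, prevents unbounded dilation of the very
  compliant diastolic chamber, and — being a function of V only — cancels
  exactly in the stroke-work loop integral.
* **Internal ejection loss** r_visc·q + k_ej·q² between the elastance
  element and the chamber node (left: r_visc = 0.02 mmHg·s/ml,
  k_ej = 1e-4 mmHg·s²/ml²). This is the classic "internal resistance" of
  the ejecting ventricle: measured pressure during ejection is lower than
  the isovolumic pressure at the same volume, which is what makes the
  fitted Ees fall below the isolated maximum elastance E~.
* **Ejection guard**: outflow tapers linearly to zero as chamber volume
  approaches 2 ml. A constant-amplitude isovolumic source would otherwise
  keep ejecting at zero preload (the source term does not know how much
  blood the chamber holds) and drive volumes negative under total caval
  occlusion. The guard never activates during normal operation.

### Valves, arteries, periphery

Valves are forward-conducting ideal diodes with small series resistances,
implemented in the continuous form q = max(ΔP, 0)/R; this preserves
ideal-switch semantics (conduction only under a forward pressure
difference, zero flow otherwise) while keeping the right-hand side
continuous for the stiff integrator.

Arterial segments have series resistance + inertance feeding a
viscoelastic wall: trans-wall pressure (V − V_u)/C + γ·dV/dt. The γ term
produces the pressure-volume hysteresis of real arterial walls. For this
topology the implicit dV/dt couplings reduce to closed-form scalar
solves (the arch and iliac nodes have resistive branches; their node
pressures are solved linearly in place). The aortic root (ascending
aorta) is purely elastic (γ = 0) so the aortic valve law stays explicit —
this is enforced at assembly time.

### Caval occlusion

During [t_start, t_end] (defaults 20–30 s) the venous-return path into
the right ventricle is blocked; a storage compliance C_store = 10 ml/mmHg
remains coupled to the venous node through a small resistance
(0.05 mmHg·s/ml) at all times, so venous blood accumulates in it during
the occlusion and discharges back afterwards. Right-ventricular inflow
is identically zero inside the window; end-diastolic volume then falls
beat by beat as the pulmonary reservoir drains — the preload ramp the
contractility fits need.

### Numerics

LSODA (scipy) with rtol = atol = 1e-6, piecewise between discontinuity
instants; dense uniform output at 1 ms; the first 5 s are discarded as
numerical start-up transient. A 13 s horizon yields ten retained periods
for steady-state analyses; occlusion runs use 40 s. Halving the output
step changes retained-cycle stroke work by < 0.5 % (tested). Without
occlusion the retained solution is periodic to ≪ 1 % of pulse pressure
cycle-over-cycle.

## Calibration

The published constants fix the activation timing and the ventricular
elastance/source parameters. All other element values (arterial R/L/C/γ,
peripheral and venous resistances and compliances, unstressed volumes,
total blood volume) are a documented calibration: the baseline run is
required to look like an adult human at rest — aortic pressure
≈ 120/80 mmHg, stroke volume 70–90 ml, cardiac output 5–6 L/min at
75 beats/min. The shipped set gives 122/87 mmHg, 81 ml, 6.1 L/min
(`scripts/calibrate_baseline.py` prints the verification). Distances for
the BCG synthesis are adult head-positive defaults (ascending aorta +5,
arch +10, thoracic −10, abdominal −25, iliac −40, pulmonary +5, cerebral
+35 cm); blood density 1.05 g/ml. Absolute BCG amplitudes are therefore
convention-dependent; the monotone trends are the scientific surface.

## P-V analysis conventions

End systole is the maximum of P/V within a beat (ties to the earliest
sample), searched over the leading 90 % of the cycle to avoid
late-diastolic ratio artifacts; both the fraction and an optional
unstressed-volume offset in the denominator are configurable. ESPVR and
PRSW use ordinary least squares with a free intercept. Stroke work is
the orientation-independent shoelace area of the sampled loop; an open
loop (endpoint volume gap > 5 % of the range) warns and is closed by
joining the endpoints. Occlusion fits use the beats lying fully inside
the occlusion window, minus the transitional first beat (configurable).
Model traces are segmented at activation onsets; file-based series at
successive end-diastolic volume maxima.

### Known limitation: the contractility-index decreases

With the published chamber law, every end-systolic point detected as
max P/V lies on the constitutive surface
P = a(t*)·(U₀ + E_S(V − V_u)) + E_D(V − V_u) minus the load losses, and
a(t) is a plateau (0.93–1) over the feasible end-systolic instants. The
fitted Ees is therefore pinned near a*·(E_D + E_S,eff), and its percent
decrease under a 50 % E_S cut lands near the isolated-elastance decrease:
this package reports ≈ 51 % for Ees (and ≈ 36 % for PRSW, whose loop-area
geometry is less constrained). Load-loss mechanisms (linear or quadratic
ejection losses, stiff or compliant afterloads, shallower or deeper
occlusion ramps) move baseline and reduced slopes nearly proportionally
and cannot decouple the two by more than a few points. Equally, an
absolute baseline Ees near 0.9 mmHg/ml can only be bought with ejection
losses large enough to distort the PRSW trend. The monotone decrease of
both indices across 0/10/30/50 % reductions — the qualitative claim — is
robust. Similarly, the pointwise bound max P/(V − V_u) ≤ E~ cannot hold
under this convention (the ratio contains a·U₀/(V − V_u), unbounded as
V → V_u); the meaningful and tested statement is Ees < E~ at every
reduction level.

## BCG synthesis and model features

Second derivatives of the nine compartment volumes by central differences
on the 1 ms grid (boundary samples dropped); force in dyne since
ml ≡ cm³. The J peak is the maximum of f_A in (onset, onset + T_s] per
cycle. On steady cycles the features are cycle-invariant to within one
grid sample. The model-side delay is measured from activation onset; the
measured-side TEB is R-peak-to-J-peak — the offset between the two
conventions is constant for a given subject, so trends and differences
are comparable while absolute values are not.

## Measurement pipeline

Butterworth bandpasses of order 6 (three biquads), applied
forward-backward so the effective filter is zero-phase and cannot bias
the timing feature; corners 0.7–40 Hz (ECG) and 1.25–15 Hz (BCG). The
upper corner must sit below 0.4·fs — at the default 200 samples/s both
bands qualify, at 100 samples/s the ECG band is rejected. Accelerometer
z-axis (floor-to-ceiling) → cm/s² (× 980.665) → bandpass → × (−1)
(action-reaction) → × mass in grams → dyne.

R peaks are detected on the rectified filtered ECG with an adaptive
threshold of 8 robust sigmas (MAD-based) and a 250 ms refractory period;
rectification makes inverted QS complexes yield identical fiducials.
QRS deflections stand tens of robust sigmas above background, so the
high threshold costs no sensitivity while returning an empty list on
sub-threshold noise. J peaks are the highest positive local maximum in
(R + 0.05 s, R + 0.30 s], truncated at the next R; the window covers the
whole plausible TEB range (0.095–0.170 s) with margin. Beats without a
positive local maximum are flagged and excluded. Summaries are medians
with 25th/75th percentiles (linear interpolation); heart rate is
60/mean(RR). Mood's median test classifies against the grand median
(ties in the "≤" cell) and uses the 1-df chi-square without continuity
correction by default; a correction flag exists. Statistics are over raw
per-beat values, not ensemble averages.

## Synthetic data

The session generator emulates the acquisition geometry: 200 samples/s,
QRS templates (invertible to QS morphology) at a configured heart rate
with Gaussian RR jitter (default sd 10 ms), and a BCG beat template — a
Gaussian-windowed 7 Hz cosine (envelope sd 80 ms) whose positive peak
sits exactly TEB after each R with the configured amplitude. The carrier
sits mid-band of the 1.25–15 Hz filter, so the peak survives the pipeline
to within ~1.5 % in amplitude and without timing shift; recovery
tolerances in the tests (±5 ms, ±3 %) include this transfer loss.
Respiration is a 0.3 Hz sinusoid (inside the filters' stopbands) and
noise is white Gaussian. What the generator does **not** emulate: beat
morphology variability, motion artifacts, electrode drift, sensor
coupling mechanics, and arrhythmia — so passing recovery tests
demonstrates pipeline correctness on clean-to-moderately-noisy data, not
robustness to real-world artifact.

The P-V generator builds rectangular loops whose end-systolic corner lies
exactly on a configured ESPVR line and whose areas are an exact linear
function of EDV (the stroke volume solves the implied quadratic per
beat), with EDV stepping down beat by beat; optional Gaussian noise on P
and V. Noise-free recovery of both slopes is exact; with ~2 % noise over
8 beats the median absolute slope error across 100 seeds stays below
10 % (tested).

All generators are deterministic functions of (config, seed).

## Problem sizes

Steady-state analyses use 13 s horizons (10 retained cycles), occlusion
analyses 40 s (11 fitted beats), synthetic sessions 3 min at 200
samples/s (~246 beats), and the Monte-Carlo slope study 100 seeds × 8
beats. These sizes make every quantity the package reports statistically
stable while keeping a full test run in the low minutes.
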