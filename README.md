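# cardiobcg

Closed-loop lumped-parameter cardiovascular simulation, pressure-volume
(P-V) loop contractility analysis, and ballistocardiogram (BCG) synthesis
and feature extraction — in one package.

The scientific question it serves: left-ventricular (LV) contractility is
measured invasively from catheter P-V loops, through the slope of the
end-systolic pressure-volume relationship (ESPVR, "Ees", mmHg/ml) and the
pre-load recruitable stroke work (PRSW, mmHg — the slope of stroke work
against end-diastolic volume). The BCG — the tiny whole-body recoil force
generated by blood mass redistribution at every heartbeat — can be
measured with nothing more than an accelerometer. This package implements
the mechanistic chain that connects the two: a 0D electric-analog model of
the circulation predicts how a loss of contractility reshapes both the
P-V loops and the BCG waveform, and a signal pipeline extracts the
corresponding features (R-to-J timing, "TEB", and J-peak amplitude) from
synchronous ECG + accelerometer recordings.

It is intended for physiologists and biosignal researchers who want a
virtual laboratory for BCG-based cardiac monitoring: simulate a
contractility insult, see what the catheter indices do, see what the
non-invasive features do, and process real or synthetic recordings with
the same code path.

## The model in brief

Each ventricle is a time-varying elastance chamber with a series
isovolumic pressure source:

    P_i(t) = U_i0 * a(t_m) + [E_iD + E_iS * a(t_m)] * (V_i - V_u,i) + phi(V_i)

where `a(t_m)` is a normalized activation waveform built from tanh ramps
on the cycle-relative time `t_m = mod(t, Tc)` and truncated to zero at the
end of systole, and `phi` is an exponential passive wall stress. The
maximum elastance of the isolated chamber is `E~ = E_D + E_S`. Heart
valves are ideal diodes; the large arteries (ascending aorta, arch,
thoracic and abdominal aorta, iliac) are RLC segments with viscoelastic
walls; peripheral, venous, cerebral and pulmonary compartments close the
loop. Transient inferior-vena-cava occlusion (a switch plus a storage
compliance upstream of the right ventricle) produces beats of decreasing
pre-load, from which Ees and PRSW are fitted exactly as in catheter
practice: end systole at max P/V per beat, ordinary least squares across
beats.

The BCG force is synthesized from the simulated compartment volumes as

    f_A(t) = rho_b * sum_k y_k * d2V_k/dt2        (9 compartments, dyne)

with `y_k` the signed head-positive distance of compartment `k` from the
valve plane. The measurement pipeline mirrors a 200 samples/s
acquisition: zero-phase 6th-order Butterworth bandpasses (0.7–40 Hz ECG,
1.25–15 Hz BCG), accelerometer-to-force conversion (−1 × mass ×
acceleration), rectified-ECG R detection (robust to QS inversion), per-beat
J detection, median/quartile summaries and Mood's median test.

## Worked example

```
python examples/bcg_waveform.py
```

prints, for systolic-elastance reductions of 0–50 %:

```
reduction   J delay (ms)   J amplitude (10^4 dyne)
    0%        35.0           27.21
   10%        37.0           24.74
   30%        42.0           18.67
   50%        47.6           13.56
```

i.e. as contractility falls the model's J peak arrives later after the
onset of systole and gets smaller — the two BCG features that make
non-invasive contractility tracking plausible. `examples/
occlusion_contractility.py` runs the invasive counterpart (Ees
1.348 → 0.656 mmHg/ml and PRSW 85.2 → 54.8 mmHg for a 50 % elastance
reduction), `examples/simulate_baseline.py` prints the calibrated resting
hemodynamics (122/87 mmHg, stroke volume 81 ml, 6.1 L/min), and
`examples/session_features.py` pushes a synthetic pre/post session pair
through the measurement pipeline (TEB 110 → 145 ms, amplitude
8.26 → 4.67 ×10⁴ dyne, Mood's p ≪ 0.05).

A thin CLI mirrors the library: `cardiobcg simulate|pvloops|bcg|features|
compare|synth|study` (see `cardiobcg --help`).

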