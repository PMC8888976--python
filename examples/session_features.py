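"""ECG+BCG session analysis: per-beat features and pre/post comparison.

Generates a synthetic pre/post pair emulating a contractility insult
(TEB +35 ms, J amplitude x0.565, heart rate 82 -> 99 bpm, QS-inverted
ECG after), runs the measurement pipeline on both and prints the
recovered medians, their differences and Mood's median test on the
per-beat TEB samples.
"""

from cardiobcg import (SyntheticSessionConfig, compare_conditions,
                       extract_features, generate_pre_post_pair,
                       moods_median_test)

base = SyntheticSessionConfig(seed=1)   # 3 min at 82 bpm, TEB 110 ms
(pre, _), (post, _) = generate_pre_post_pair(
    base, teb_shift=0.035, amplitude_factor=0.565, hr_post=99.0)

beats_pre, sum_pre = extract_features(pre)
beats_post, sum_post = extract_features(post)

for name, s in (("pre", sum_pre), ("post", sum_post)):
    print(f"{name:4s}: TEB {s.teb_median * 1000:.0f} ms "
          f"({s.teb_p25 * 1000:.0f}-{s.teb_p75 * 1000:.0f}), "
          f"J {s.amplitude_median / 1e4:.3f}e4 dyne, "
          f"HR {s.heart_rate:.0f} bpm, n={s.n_beats}")

cmp_ = compare_conditions(sum_pre, sum_post)
print(f"\ndelta TEB  : {cmp_.delta_teb * 1000:+.0f} ms")
print(f"delta ampl : {cmp_.delta_amplitude / 1e4:+.3f} x10^4 dyne")

_, p = moods_median_test([b.teb for b in beats_pre if b.accepted],
                         [b.teb for b in beats_post if b.accepted])
print(f"Mood's median test on TEB: p = {p:.2e} "
      f"({'significant' if p < 0.05 else 'not significant'} at 0.05)")
print("The timing feature shifts by the configured 35 ms and the shift "
      "is statistically clear over a 3-minute session.")
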