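"""Build the three stimulus protocols and inspect the optical bookkeeping.

The intensity series steps one third of a log unit per presentation; the
fusion series sweeps flicker frequency at fixed intensity; the
dark-adaptation protocol repeats one dim test flicker every 4 min.
"""

import ergflick as ef

exp1 = ef.build_intensity_series(1e-6, 1 / 3, 15, frequency=10.0)
print(f"exp1: {len(exp1)} stimuli, "
      f"{exp1.stimuli[0].on_intensity:.2e} -> {exp1.stimuli[-1].on_intensity:.2e} µW/cm² "
      f"({14 / 3:.2f} log10 units)")

exp2 = ef.build_exp2_series(0.05)
print(f"exp2: {len(exp2)} stimuli at "
      f"{[int(s.frequency) for s in exp2.stimuli]} Hz "
      f"(50 Hz flagged: {next(s.label for s in exp2.stimuli if s.frequency == 50)})")

exp3 = ef.build_dark_adaptation_protocol()
print(f"exp3: {len(exp3)} probes at minutes {list(exp3.probe_times_min)}")

# optics: two ND layers attenuate ~63x; the stimulus subtends 53 deg
print(f"2x 0.9-OD ND transmission: {ef.nd_transmission(2):.4f}")
print(f"3 cm disc at 3 cm subtends: {ef.angular_subtense(3, 3):.1f} deg")
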