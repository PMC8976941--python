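"""Dark-adaptation time courses: probing the eye slows its own adaptation.

Four crabs dark-adapt for an hour at night and during the day, probed with
a dim test flicker every 4 min, plus endpoint-only controls.  Night runs
rise fast, dip mid-run (each probe light-adapts the eye a little), then
climb again; the probed final amplitude stays well below the uninterrupted
control.
"""

import ergflick as ef

cohort = ef.CohortConfig(n_crabs=4)
ds = ef.simulate_cohort_exp3(cohort, seed=3)
measures = ef.measure_dataset(ds)

night = measures.query("time_of_day == 'night' and probes == 'all'")
curve = night.groupby("probe_time")["amplitude"].mean().sort_index()
print("night cohort-mean probe amplitudes (µV):")
for t, a in curve.items():
    print(f"  {int(t):2d} min  {a:5.2f}  " + "#" * int(round(a * 3)))

feats = ef.adaptation_from_measures(measures)
g = feats.groupby(["time_of_day", "probes"])["final_amp"].mean()
print("\nmean 60-min amplitude (µV):")
print(f"  night control {g['night', 'endpoints_only']:5.2f} > "
      f"night probed {g['night', 'all']:5.2f} > "
      f"day control {g['day', 'endpoints_only']:5.2f} >= "
      f"day probed {g['day', 'all']:5.2f}")
ns = feats.query("time_of_day == 'night' and probes == 'all'")["initial_slope"].mean()
dsl = feats.query("time_of_day == 'day' and probes == 'all'")["initial_slope"].mean()
print(f"initial slope (0-12 min): night {ns:.2f} vs day {dsl:.2f} µV/min")
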