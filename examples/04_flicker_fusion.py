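"""Estimate flicker fusion frequencies on noiseless fixtures.

Each condition is stimulated at the intensity that evokes 3.2 µV at 10 Hz
for that eye (the per-individual normalisation of the fusion experiment),
then swept from 10 to 110 Hz.  The FFF is the last downward crossing of
the 0.6 µV criterion; 50 Hz is excluded (mains).  Lower temporal corner
frequencies (dark adaptation) drag the fusion point down.
"""

import ergflick as ef
from ergflick.synthetic_data import DEFAULT_CONDITION_PARAMS

for cond, p in DEFAULT_CONDITION_PARAMS.items():
    p = p.quiet()  # noise off: isolates the temporal model
    intensity = ef.intensity_for_amplitude(p, 3.2)
    series = ef.build_exp2_series(intensity)
    pts = []
    for stim in series.stimuli:
        rec = ef.simulate_recording(p, stim, seed=0)
        pts.append((stim.frequency,
                    ef.measure_response(rec.samples, rec.fs, stim.frequency)))
    est = ef.estimate_fff(pts, criterion=0.6)
    implied = ef.implied_fff(p, intensity, criterion=0.6)
    print(f"{cond.label:9s} fc={p.fc:5.1f} Hz -> FFF {est.fff:5.1f} Hz "
          f"(model-implied {implied:5.1f} Hz)")
# light-adapted daytime eyes resolve the fastest flicker; dark-adapted eyes
# trade temporal resolution for sensitivity
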