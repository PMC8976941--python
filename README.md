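# ergflick

Analysis pipeline for **flicker electroretinography** (ERG) studies of
circadian changes in visual sensitivity — the kind of experiment in which a
compound eye (e.g. a fiddler crab's) views square-wave flicker stimuli
while the mass retinal potential is recorded, and the questions are: *how
dim a light can the eye detect, how fast a flicker can it resolve, and how
quickly does it dark-adapt — and how do light/dark adaptation and time of
day change the answers?*

The package provides, as importable modules with a thin `ergflick` CLI on
top:

- **protocols** — stimulus-series construction (ascending ⅓-log-unit
  intensity series, 10–120 Hz fusion series, 4-min dark-adaptation probes)
  and optical bookkeeping (ND-filter transmission, irradiance integration
  over 300–600 nm, stimulus visual angle, square-wave synthesis);
- **synthetic_data** — a seeded ERG generator with known ground truth for
  all four adaptation treatments (light/dark × day/night), built on the
  V–log I law `V = clip(m(log₁₀I − log₁₀i₀), 0, V_max)·|H(f)|` with a
  two-pole temporal filter, realistic noise/artifact sources and a
  dark-adaptation state variable with probe-feedback dynamics;
- **preprocess** — 11 ms median filtering and 5-SD artifact rejection;
- **spectral** — single-sided amplitude spectra and the steady-state
  evoked-potential F-test of the response against its local noise floor;
- **sensitivity** — V–log I line fits, criterion-intensity thresholds
  (1 µV), flicker-fusion-frequency estimation (0.6 µV criterion, 50 Hz
  excluded) and dark-adaptation time-course features;
- **stats** — random-intercept models (REML), within-subject permutation
  tests of fixed effects, Welch's t-test, and Holm-adjusted pairwise
  permutation contrasts;
- **io / config / pipeline** — HDF5 dataset containers with integrity
  checks, a strict YAML run configuration, and the end-to-end
  simulate → preprocess → measure → metrics → stats pipeline.

## Worked example

Recover per-animal detection thresholds from a simulated cohort
(`examples/03_intensity_thresholds.py`; every example script in
`examples/` is runnable as-is):

```python
import ergflick as ef

cohort = ef.CohortConfig(n_crabs=3)
ds = ef.simulate_cohort_exp1(cohort, seed=7)      # 3 crabs x 4 treatments x 15 stimuli
measures = ef.measure_dataset(ds)                 # median filter, 5-SD, FFT, F-test
thr = ef.thresholds_from_measures(measures, criterion=1.0)
```

which prints (abridged):

```
crab_id condition  slope  r2  log10_threshold
 crab01    DA-day  5.470 1.0           -1.056
 crab01  DA-night 19.413 1.0           -4.114
 crab01    LA-day  5.445 1.0            0.542
 crab01  LA-night  5.189 1.0           -0.210
 ...
LA-day / LA-night intensity ratio : 5.7
LA-day / DA-night intensity ratio : 4.34e+04
max |recovery error|              : 0.009 log10 units
```

Reading: each row is one eye in one adaptation treatment — the slope of
its V–log I line (µV per log10 unit of irradiance) and the log10 of the
stimulus irradiance (µW cm⁻²) needed to evoke a 1 µV response.
Light-adapted daytime eyes need ~5.7× more light than light-adapted
nighttime eyes and ~4×10⁴ times more than dark-adapted nighttime eyes;
the recovered thresholds match the generator's configured truth to within
0.01 log10 units.

The other examples cover protocol construction, single-recording
measurement, fusion-frequency estimation (`74.1 / 59.3 / 35.4 / 39.9 Hz`
for the four default treatments on noiseless fixtures), the
dark-adaptation time course with its probe-induced mid-run dip, and the
permutation statistics.

The same stages are available from a shell:

```bash
ergflick simulate --experiment exp1 --seed 1 --out exp1.h5
ergflick measure  --in exp1.h5 --out measures.csv
ergflick thresholds --measures measures.csv --criterion 1.0 --out thresholds.csv
ergflick run --experiment exp3 --seed 1 --out run_exp3/   # end-to-end
```

## Documentation

`docs/methods.md` describes the response model and its assumptions, the
calibration of the default treatment parameters, every estimator's exact
rule (including tie-breaks and degenerate cases), the permutation
machinery, and the limits of what synthetic-data tests demonstrate.
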