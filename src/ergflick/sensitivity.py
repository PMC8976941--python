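"""Headline sensitivity metrics from per-recording response measures.

From the spectral measures of an intensity series this module fits the
V-log I line (ordinary least squares of amplitude on log10 intensity over
significant, unsaturated points) and inverts it at a criterion amplitude to
estimate the criterion intensity ("threshold").  From a fusion-frequency
series it locates the flicker fusion frequency (FFF) as the final downward
crossing of the criterion amplitude.  From a dark-adaptation probe series
it extracts the time-course features used to compare day and night runs.

Notes on the FFF rule: response amplitude falls with flicker frequency, so
the fusion point is the highest frequency the eye still resolves at the
criterion.  It is located by linear interpolation between the last tested
frequency whose amplitude is at or above the criterion and the next tested
frequency, skipping excluded (mains-contaminated) frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError, FitError
from .spectral import ResponseMeasure

__all__ = [
    "VlogICurve",
    "ThresholdEstimate",
    "FFFEstimate",
    "AdaptationTimeCourse",
    "fit_v_logI",
    "intensity_at_amplitude",
    "estimate_fff",
    "adaptation_features",
    "thresholds_from_measures",
    "fff_from_measures",
    "adaptation_from_measures",
]

#: Default criterion amplitudes, µV: intensity-threshold comparison, the
#: exp-2 intensity normalisation, and the fusion-frequency criterion.
CRITERION_THRESHOLD = 1.0
CRITERION_NORMALISE = 3.2
CRITERION_FFF = 0.6
#: Frequencies excluded from FFF estimation (mains contamination), Hz.
DEFAULT_EXCLUDED_FREQS = (50.0,)
#: Points above this fraction of the series maximum are treated as
#: saturating and excluded from the line fit.
SATURATION_GUARD = 0.9


@dataclass(frozen=True)
class VlogICurve:
    """Fitted V-log I line: amplitude = slope * log10(I) + intercept."""

    slope: float       # µV per log10(µW cm⁻²)
    intercept: float   # µV at log10 I = 0
    fit_points: tuple[int, ...]
    r2: float
    log10_i_range: tuple[float, float]  # fitted intensity range


@dataclass(frozen=True)
class ThresholdEstimate:
    """Criterion-intensity interpolation on a fitted V-log I line."""

    criterion: float   # µV
    intensity: float   # µW cm⁻²
    extrapolated: bool


@dataclass(frozen=True)
class FFFEstimate:
    """Flicker fusion frequency at a criterion amplitude."""

    criterion: float
    fff: float              # Hz
    bracket: tuple[float, float] | None  # frequencies straddling the crossing
    flag: str = "ok"        # "ok" | "below_range" | "above_range"


@dataclass(frozen=True)
class AdaptationTimeCourse:
    """Probe amplitudes over a dark-adaptation run plus derived features."""

    times: np.ndarray       # min, strictly increasing from 0
    amplitudes: np.ndarray  # µV
    initial_slope: float    # µV min⁻¹, OLS over t in [0, 12]
    mean_12_24: float       # µV, mean over t in (12, 24]
    final_amp: float        # µV at the last probe
    dip_depth: float        # µV, max of (running max before t) - amp(t), t in (12, 28]
    dip_time: float         # min, argmax of the above (nan if no dip window)


def fit_v_logI(
    points: Sequence[tuple[float, ResponseMeasure]],
    *,
    saturation_guard: float = SATURATION_GUARD,
    require_significant: bool = True,
    snr_floor: float = 3.0,
) -> VlogICurve:
    """Fit the V-log I line over selected points of an intensity series.

    Selection: points flagged significant, clearly above the local noise
    floor (amplitude at least ``snr_floor`` times the mean noise-bin
    amplitude; 0 disables) and not exceeding ``saturation_guard`` times the
    series maximum (all configurable).  Because the response sinks into the
    noise floor as intensity falls, the fit additionally keeps only the
    contiguous selectable run walking down in intensity from the brightest
    unsaturated point - an isolated false-positive among the sub-threshold
    presentations would otherwise lever the line.  Ordinary least squares
    of amplitude on log10 intensity.

    Raises
    ------
    FitError
        If fewer than two points survive selection.
    """
    if len(points) < 2:
        raise FitError(f"need >= 2 points, got {len(points)}")
    amps = np.array([m.amplitude for _, m in points])
    sig = np.array([m.significant for _, m in points])
    noise_mean = np.array([m.noise_mean for _, m in points])
    cap = saturation_guard * float(np.max(amps))
    order = np.argsort([p[0] for p in points])  # ascending intensity
    usable = [
        i for i in order
        if (sig[i] or not require_significant)
        and amps[i] >= snr_floor * noise_mean[i]
        and amps[i] <= cap
    ]
    # contiguous run ending at the brightest usable point
    selected: list[int] = []
    pos = {int(i): k for k, i in enumerate(order)}
    for i in reversed(usable):
        if not selected or pos[int(i)] == pos[selected[-1]] - 1:
            selected.append(int(i))
        else:
            break
    selected = sorted(selected)
    if len(selected) < 2:
        raise FitError(
            f"only {len(selected)} selectable points "
            f"({int(sig.sum())} significant, saturation cap {cap:.3g} µV)"
        )
    x = np.log10([points[i][0] for i in selected])
    y = amps[selected]
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return VlogICurve(
        slope=float(slope),
        intercept=float(intercept),
        fit_points=tuple(selected),
        r2=r2,
        log10_i_range=(float(np.min(x)), float(np.max(x))),
    )


def intensity_at_amplitude(curve: VlogICurve, criterion: float) -> ThresholdEstimate:
    """Invert the fitted line at a criterion amplitude.

    ``I = 10**((criterion - intercept) / slope)``; the estimate is flagged
    extrapolated when it falls outside the fitted intensity range.
    """
    if curve.slope <= 0:
        raise EstimationError(f"non-positive slope {curve.slope}; cannot invert")
    log_i = (criterion - curve.intercept) / curve.slope
    lo, hi = curve.log10_i_range
    return ThresholdEstimate(
        criterion=float(criterion),
        intensity=float(10.0**log_i),
        extrapolated=not (lo <= log_i <= hi),
    )


def estimate_fff(
    points: Sequence[tuple[float, ResponseMeasure]],
    criterion: float = CRITERION_FFF,
    exclude: Sequence[float] = DEFAULT_EXCLUDED_FREQS,
) -> FFFEstimate:
    """Locate the fusion frequency: the final downward criterion crossing.

    A response "counts" when it is significant and at or above the
    criterion.  The FFF is interpolated linearly between the highest tested
    frequency that still counts and the next tested frequency.  Excluded
    frequencies never enter.  If no frequency counts the estimate is
    flagged ``below_range`` (reported at the lowest tested frequency); if
    all count it is flagged ``above_range`` (reported at the highest).
    """
    usable = [(f, m) for f, m in points if f not in exclude]
    if len(usable) < 2:
        raise EstimationError(f"only {len(usable)} usable frequencies after exclusion")
    usable.sort(key=lambda fm: fm[0])
    freqs = np.array([f for f, _ in usable])
    amps = np.array([m.amplitude for _, m in usable])
    sig = np.array([m.significant for _, m in usable])
    counts = (amps >= criterion) & sig
    if not counts.any():
        return FFFEstimate(criterion, float(freqs[0]), None, flag="below_range")
    last = int(np.max(np.nonzero(counts)))
    if last == len(usable) - 1:
        return FFFEstimate(criterion, float(freqs[-1]), None, flag="above_range")
    f0, f1 = freqs[last], freqs[last + 1]
    a0, a1 = amps[last], amps[last + 1]
    if a0 == criterion or a0 == a1:
        fff = float(f0)
    else:
        fff = float(f0 + (f1 - f0) * (a0 - criterion) / (a0 - a1))
    return FFFEstimate(criterion, fff, (float(f0), float(f1)))


def adaptation_features(
    times: Sequence[float], amplitudes: Sequence[float]
) -> AdaptationTimeCourse:
    """Derive the three-period features of a dark-adaptation time course.

    initial_slope: OLS slope of amplitude on time over the first 12 min.
    mean_12_24: mean amplitude of probes in (12, 24] min.
    final_amp: amplitude at the last probe.
    dip_depth / dip_time: deepest shortfall below the running maximum
    within (12, 28] min, capturing the probe-induced mid-run dip.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if t.size < 3:
        raise EstimationError("need >= 3 probes for time-course features")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise EstimationError("probe times must be strictly increasing from 0")
    early = t <= 12.0
    if early.sum() >= 2:
        initial_slope = float(np.polyfit(t[early], a[early], 1)[0])
    else:
        initial_slope = float("nan")
    mid = (t > 12.0) & (t <= 24.0)
    mean_12_24 = float(np.mean(a[mid])) if mid.any() else float("nan")
    running_max = np.maximum.accumulate(a)
    win = (t > 12.0) & (t <= 28.0)
    if win.any():
        short = (running_max - a)[win]
        k = int(np.argmax(short))
        dip_depth = float(short[k])
        dip_time = float(t[win][k])
    else:
        dip_depth, dip_time = 0.0, float("nan")
    return AdaptationTimeCourse(
        times=t, amplitudes=a,
        initial_slope=initial_slope, mean_12_24=mean_12_24,
        final_amp=float(a[-1]), dip_depth=dip_depth, dip_time=dip_time,
    )


# ---------------------------------------------------------------------------
# DataFrame-level drivers (one row per crab x condition)
# ---------------------------------------------------------------------------

def _measures_from_rows(rows: pd.DataFrame, xcol: str) -> list[tuple[float, ResponseMeasure]]:
    out = []
    for _, r in rows.iterrows():
        out.append(
            (
                float(r[xcol]),
                ResponseMeasure(
                    amplitude=float(r["amplitude"]),
                    noise_mean=float(r["noise_mean"]),
                    noise_max=float(r["noise_max"]),
                    noise_min=float(r["noise_min"]),
                    alpha=float(r["alpha"]),
                    significant=bool(r["significant"]),
                    n_noise_bins=int(r.get("n_noise_bins", 0)),
                    stim_freq=float(r["frequency"]),
                    frequency_resolution=float(r.get("frequency_resolution", np.nan)),
                ),
            )
        )
    return out


def thresholds_from_measures(
    measures: pd.DataFrame,
    criterion: float = CRITERION_THRESHOLD,
    **fit_kwargs,
) -> pd.DataFrame:
    """Per crab x condition line fits and criterion intensities.

    `measures` is the table produced by the measurement stage (one row per
    recording of an intensity series).  Returns one row per group with the
    fitted slope/intercept/r², the criterion intensity and flags; groups
    whose fit fails are reported with NaNs and the failure reason.
    """
    rows = []
    for (crab, cond), grp in measures.groupby(["crab_id", "condition"], sort=True):
        grp = grp.sort_values("intensity")
        rec = {"crab_id": crab, "condition": cond,
               "adaptation": grp["adaptation"].iloc[0],
               "time_of_day": grp["time_of_day"].iloc[0],
               "sex": grp["sex"].iloc[0],
               "criterion": criterion}
        try:
            curve = fit_v_logI(_measures_from_rows(grp, "intensity"), **fit_kwargs)
            est = intensity_at_amplitude(curve, criterion)
            rec.update(
                slope=curve.slope, intercept=curve.intercept, r2=curve.r2,
                n_fit_points=len(curve.fit_points),
                threshold_intensity=est.intensity,
                log10_threshold=float(np.log10(est.intensity)),
                extrapolated=est.extrapolated, error="",
            )
        except (FitError, EstimationError) as e:
            rec.update(
                slope=np.nan, intercept=np.nan, r2=np.nan, n_fit_points=0,
                threshold_intensity=np.nan, log10_threshold=np.nan,
                extrapolated=False, error=str(e),
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def fff_from_measures(
    measures: pd.DataFrame,
    criterion: float = CRITERION_FFF,
    exclude: Sequence[float] = DEFAULT_EXCLUDED_FREQS,
) -> pd.DataFrame:
    """Per crab x condition fusion-frequency estimates from an exp-2 table."""
    rows = []
    for (crab, cond), grp in measures.groupby(["crab_id", "condition"], sort=True):
        grp = grp.sort_values("frequency")
        est = estimate_fff(_measures_from_rows(grp, "frequency"), criterion, exclude)
        rows.append(
            {
                "crab_id": crab, "condition": cond,
                "adaptation": grp["adaptation"].iloc[0],
                "time_of_day": grp["time_of_day"].iloc[0],
                "sex": grp["sex"].iloc[0],
                "criterion": criterion, "fff": est.fff, "flag": est.flag,
            }
        )
    return pd.DataFrame(rows)


def adaptation_from_measures(measures: pd.DataFrame) -> pd.DataFrame:
    """Per crab x time-of-day x probe-mode dark-adaptation features.

    Endpoint-only control runs have two probes and receive only
    ``final_amp`` (and ``initial_amp``); probed runs get the full feature
    set from `adaptation_features`.
    """
    rows = []
    for (crab, tod, mode), grp in measures.groupby(
        ["crab_id", "time_of_day", "probes"], sort=True
    ):
        grp = grp.sort_values("probe_time")
        t = grp["probe_time"].to_numpy(dtype=float)
        a = grp["amplitude"].to_numpy(dtype=float)
        rec = {
            "crab_id": crab, "time_of_day": tod, "probes": mode,
            "initial_amp": float(a[0]), "final_amp": float(a[-1]),
        }
        if t.size >= 3:
            feats = adaptation_features(t, a)
            rec.update(
                initial_slope=feats.initial_slope, mean_12_24=feats.mean_12_24,
                dip_depth=feats.dip_depth, dip_time=feats.dip_time,
            )
        else:
            rec.update(initial_slope=np.nan, mean_12_24=np.nan,
                       dip_depth=np.nan, dip_time=np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)
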