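"""Raw-trace cleaning ahead of spectral measurement.

Two stages, in this order: an 11 ms median filter (removes impulsive
artifacts such as movement spikes while passing the piecewise-monotone
flicker response almost untouched), then amplitude-threshold artifact
rejection masking every sample further than k standard deviations from the
trace mean (k = 5 by default).  Masked samples are bridged by linear
interpolation so the Fourier transform sees a contiguous record; the mask
is kept so "removed" samples never enter time-domain averages.

The mean and SD of the rejection rule are computed once on the full
median-filtered trace (single-pass).  An iterative option re-estimates them
on the surviving samples until no new sample is masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, UnusableRecordingError

__all__ = ["PreprocessResult", "median_filter", "reject_artifacts", "preprocess_trace"]

log = logging.getLogger(__name__)

#: Masked fractions above this trigger a warning; above `UNUSABLE_FRACTION`
#: the recording is rejected outright.
WARN_FRACTION = 0.20
UNUSABLE_FRACTION = 0.50


@dataclass(frozen=True)
class PreprocessResult:
    """Cleaned trace plus the artifact mask and bookkeeping."""

    trace: np.ndarray          # cleaned samples, µV
    mask: np.ndarray           # True where a sample was rejected
    masked_fraction: float
    window_ms: float
    k_sd: float


def median_filter(trace: np.ndarray, fs: float, window_ms: float = 11.0) -> np.ndarray:
    """Centered running-median filter with reflected edges.

    The window length is ``round(window_ms * fs / 1000)`` samples, forced
    odd so the window is symmetric about each sample.  Constant and
    monotone stretches pass unchanged; isolated impulses shorter than half
    the window are removed.
    """
    x = np.asarray(trace, dtype=float)
    if not window_ms > 0:
        raise ConfigError(f"window_ms must be > 0, got {window_ms}")
    w = int(round(window_ms * fs / 1000.0))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    if w > x.size:
        raise ConfigError(
            f"median window of {w} samples exceeds trace length {x.size}"
        )
    if w == 1:
        return x.copy()
    # "mirror" reflects about the edge sample without repeating it
    return ndimage.median_filter(x, size=w, mode="mirror")


def reject_artifacts(
    trace: np.ndarray, k: float = 5.0, *, iterative: bool = False
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mask samples at least `k` standard deviations from the trace mean.

    Returns ``(cleaned, mask, masked_fraction)`` where masked samples are
    replaced by linear interpolation between their unmasked neighbours.
    With `iterative` the mean/SD are re-estimated on surviving samples
    until the mask stabilises; the default is the single-pass rule.

    Raises
    ------
    UnusableRecordingError
        If more than half of the samples are masked.
    """
    if not k > 0:
        raise ConfigError(f"k must be > 0, got {k}")
    x = np.asarray(trace, dtype=float)
    mask = np.zeros(x.size, dtype=bool)
    while True:
        keep = ~mask
        mu = float(np.mean(x[keep]))
        sd = float(np.std(x[keep]))
        if sd == 0.0:
            break
        new_mask = np.abs(x - mu) >= k * sd
        if iterative:
            if np.array_equal(new_mask, mask):
                break
            mask = new_mask
        else:
            mask = new_mask
            break
    frac = float(np.mean(mask))
    if frac > UNUSABLE_FRACTION:
        raise UnusableRecordingError(
            f"{frac:.0%} of samples masked by the {k}-SD rule; recording unusable"
        )
    if frac > WARN_FRACTION:
        log.warning("%.1f%% of samples masked by the %g-SD rule", 100 * frac, k)
    cleaned = x.copy()
    if mask.any():
        idx = np.arange(x.size)
        cleaned[mask] = np.interp(idx[mask], idx[~mask], x[~mask])
    return cleaned, mask, frac


def preprocess_trace(
    trace: np.ndarray,
    fs: float,
    window_ms: float = 11.0,
    k_sd: float = 5.0,
    *,
    iterative: bool = False,
) -> PreprocessResult:
    """Median filter then k-SD artifact rejection (the standard pipeline order)."""
    filtered = median_filter(trace, fs, window_ms)
    cleaned, mask, frac = reject_artifacts(filtered, k_sd, iterative=iterative)
    return PreprocessResult(
        trace=cleaned, mask=mask, masked_fraction=frac, window_ms=window_ms, k_sd=k_sd
    )
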