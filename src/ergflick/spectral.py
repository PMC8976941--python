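"""Spectral response measurement for steady-state flicker ERGs.

The response to a periodic flicker concentrates at the stimulation frequency
(and its harmonics) in the amplitude spectrum of the recording.  This module
computes a single-sided amplitude spectrum normalised so that a pure
sinusoid of amplitude A µV contributes A µV at its bin, reads off the
response amplitude at the stimulus frequency, summarises the local noise
floor from neighbouring bins, and attaches a significance test.

Significance follows the standard steady-state evoked-potential F statistic:
the power at the signal bin divided by the mean power of 2K flanking noise
bins is F(2, 4K)-distributed under the white-noise null, because each
rectangular-window DFT bin of Gaussian noise contributes an independent
chi-square(2) power.  Bins adjacent to the signal, its harmonics and the
mains frequency are excluded from the noise estimate.  A nonparametric
rank-based alternative is provided for sensitivity analysis.

Records are transformed whole (no windowing, no segment averaging by
default): stimulus frequencies are bin-aligned on 21 s records
(resolution 1/21 Hz), so a taper would only leak amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import stats as sp_stats

from .errors import DataError, MeasurementError

__all__ = [
    "SpectrumResult",
    "NoiseBinConfig",
    "ResponseMeasure",
    "amplitude_spectrum",
    "measure_response",
]


@dataclass(frozen=True)
class SpectrumResult:
    """Single-sided amplitude spectrum of one recording."""

    freqs: np.ndarray      # Hz
    amplitudes: np.ndarray  # µV; a sinusoid of amplitude A yields A at its bin
    resolution: float      # Hz, = 1/duration

    def bin_index(self, freq: float) -> int:
        """Index of the bin nearest to `freq`."""
        return int(round(freq / self.resolution))


@dataclass(frozen=True)
class NoiseBinConfig:
    """Noise-floor estimation settings for `measure_response`.

    k_per_side
        Number of noise bins collected on each side of the signal bin
        (moving outward, skipping excluded bins).
    exclude_half_width
        Bins within this distance of the signal bin, each of its harmonics
        and the mains bin never enter the noise estimate.
    mains_freq
        Mains frequency in Hz (always excluded, with the same half-width).
    exclude_harmonics
        Whether integer harmonics of the stimulus frequency are excluded.
    alpha_level
        Significance level for the `significant` flag.
    method
        "ftest" (default) or "rank" (nonparametric rank of the signal-bin
        power among the noise-bin powers, for sensitivity analysis).
    """

    k_per_side: int = 20
    exclude_half_width: int = 2
    mains_freq: float = 50.0
    exclude_harmonics: bool = True
    alpha_level: float = 0.05
    method: str = "ftest"


@dataclass(frozen=True)
class ResponseMeasure:
    """Response amplitude at the stimulus frequency plus noise statistics."""

    amplitude: float    # µV at the stimulus-frequency bin
    noise_mean: float   # µV, mean over noise bins
    noise_max: float
    noise_min: float
    alpha: float        # probability the response arose from the noise floor
    significant: bool   # alpha < alpha_level
    n_noise_bins: int
    stim_freq: float
    frequency_resolution: float


def amplitude_spectrum(trace: np.ndarray, fs: float) -> SpectrumResult:
    """Single-sided amplitude spectrum with sinusoid-amplitude normalisation.

    A pure sinusoid of amplitude A whose frequency sits on the bin grid
    (an integer number of cycles in the record) yields exactly A at its bin.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DataError("trace must be a 1-d array with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise DataError("trace contains non-finite samples")
    n = x.size
    spec = np.abs(sp_fft.rfft(x)) * (2.0 / n)
    spec[0] /= 2.0
    if n % 2 == 0:
        spec[-1] /= 2.0
    duration = n / fs
    freqs = np.arange(spec.size) / duration
    return SpectrumResult(freqs=freqs, amplitudes=spec, resolution=1.0 / duration)


def _noise_bins(
    sig_bin: int, n_bins: int, cfg: NoiseBinConfig, resolution: float
) -> np.ndarray:
    """Indices of the 2K noise bins flanking `sig_bin`.

    Collected moving outward from the signal bin on each side, skipping the
    exclusion zones around the signal, its harmonics and the mains bin, so
    the count (hence the F degrees of freedom) stays fixed at 2K whenever
    enough usable bins exist.
    """
    hw = cfg.exclude_half_width
    excluded = set()
    mains_bin = int(round(cfg.mains_freq / resolution))
    excluded.update(range(mains_bin - hw, mains_bin + hw + 1))
    if cfg.exclude_harmonics and sig_bin > 0:
        h = sig_bin
        while h < n_bins:
            excluded.update(range(h - hw, h + hw + 1))
            h += sig_bin
    else:
        excluded.update(range(sig_bin - hw, sig_bin + hw + 1))

    def collect(step: int) -> list[int]:
        out: list[int] = []
        b = sig_bin
        while len(out) < cfg.k_per_side:
            b += step
            if b <= 0 or b >= n_bins:
                break
            if b in excluded:
                continue
            out.append(b)
        return out

    bins = collect(-1) + collect(+1)
    if len(bins) < 10:
        raise MeasurementError(
            f"only {len(bins)} usable noise bins around bin {sig_bin}; need >= 10"
        )
    return np.array(sorted(bins), dtype=int)


def measure_response(
    trace: np.ndarray,
    fs: float,
    stim_freq: float,
    cfg: NoiseBinConfig | None = None,
) -> ResponseMeasure:
    """Measure the response at `stim_freq` and test it against the noise floor.

    The stimulus frequency must lie within half a bin of the spectral grid
    (21 s records make every integer frequency exact).  ``alpha`` is the
    upper tail probability of F = (signal-bin power) / (mean noise-bin
    power) under F(2, 4K); scaling the trace leaves it unchanged.
    """
    cfg = cfg or NoiseBinConfig()
    spec = amplitude_spectrum(trace, fs)
    sig_bin = spec.bin_index(stim_freq)
    # a misaligned tone leaks into neighbouring bins and invalidates both
    # the amplitude and the F statistic, so require tight grid alignment
    if abs(sig_bin * spec.resolution - stim_freq) > 0.01 * spec.resolution + 1e-9:
        raise MeasurementError(
            f"stimulus frequency {stim_freq} Hz is not aligned to the "
            f"{spec.resolution:.4g} Hz bin grid"
        )
    if sig_bin <= 0 or sig_bin >= spec.amplitudes.size:
        raise MeasurementError(f"stimulus frequency {stim_freq} Hz out of range")
    bins = _noise_bins(sig_bin, spec.amplitudes.size, cfg, spec.resolution)
    amps = spec.amplitudes
    noise = amps[bins]
    sig_power = amps[sig_bin] ** 2
    noise_power = noise**2
    if cfg.method == "ftest":
        mean_np = float(np.mean(noise_power))
        if mean_np == 0.0:
            alpha = 0.0 if sig_power > 0 else 1.0
        else:
            f_stat = sig_power / mean_np
            alpha = float(sp_stats.f.sf(f_stat, 2, 2 * len(bins)))
    elif cfg.method == "rank":
        # Nonparametric alternative: rank of the signal-bin power among the
        # noise-bin powers; exact level floor is 1/(2K+1).
        r = int(np.sum(noise_power >= sig_power))
        alpha = (r + 1) / (len(bins) + 1)
    else:
        raise MeasurementError(f"unknown significance method {cfg.method!r}")
    return ResponseMeasure(
        amplitude=float(amps[sig_bin]),
        noise_mean=float(np.mean(noise)),
        noise_max=float(np.max(noise)),
        noise_min=float(np.min(noise)),
        alpha=alpha,
        significant=bool(alpha < cfg.alpha_level),
        n_noise_bins=int(len(bins)),
        stim_freq=float(stim_freq),
        frequency_resolution=spec.resolution,
    )


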