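"""Stimulus protocols and optical bookkeeping for flicker-ERG experiments.

The experiments this package analyses present square-wave flicker stimuli to
a compound eye and record the mass retinal potential.  Three protocols are
used:

* an ascending intensity series at a fixed flicker rate (``exp1``), stepping
  intensity by a fixed number of log10 units per presentation;
* a flicker-fusion series at a fixed intensity with increasing flicker
  frequency (``exp2``);
* repeated presentations of one dim test flicker while the eye dark-adapts
  (``exp3``), either probing at regular intervals or only at the endpoints
  (the uninterrupted-control variant).

Intensities are carried everywhere as linear irradiance in µW cm⁻²
(integrated over the 300-600 nm sensitivity band); log10 transforms happen
only inside fitting routines.  All flicker trains start in the ON phase at
t = 0 so that spectral phases are fixed and testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import AliasingError, CoverageError, DomainError, ProtocolError

__all__ = [
    "StimulusSpec",
    "ProtocolSeries",
    "Spectrum",
    "EXP2_NOMINAL_FREQS",
    "EXP3_TEST_INTENSITY",
    "build_intensity_series",
    "build_fff_series",
    "build_exp2_series",
    "build_dark_adaptation_protocol",
    "nd_transmission",
    "integrate_irradiance",
    "angular_subtense",
    "square_wave",
]

#: Nominal flicker frequencies of the fusion-frequency series, Hz.  The
#: series runs 10-120 Hz in 10 Hz steps; the default builder drops one
#: endpoint to yield the 11 presentations actually shown, and 50 Hz is
#: flagged for exclusion from analysis because of mains contamination.
EXP2_NOMINAL_FREQS: tuple[float, ...] = tuple(float(f) for f in range(10, 130, 10))

#: ON-phase irradiance of the dark-adaptation test flicker, µW cm⁻².
EXP3_TEST_INTENSITY: float = 3.84e-4

MAINS_FREQ: float = 50.0


@dataclass(frozen=True)
class StimulusSpec:
    """One flicker presentation.

    Parameters
    ----------
    on_intensity : float
        Irradiance of the ON phase, µW cm⁻² integrated over 300-600 nm.
    frequency : float
        Flicker frequency in Hz.  ``0`` means constant light.
    duty : float
        Fraction of each cycle spent ON, in (0, 1].
    duration : float
        Presentation length in seconds.
    nd_layers : int
        Number of 0.9-OD neutral-density filter layers in the light path
        (bookkeeping only; `on_intensity` is already the attenuated value).
    label : str
        Free text, e.g. ``"excluded-from-analysis"`` for the mains-frequency
        presentation.
    """

    on_intensity: float
    frequency: float
    duty: float = 0.5
    duration: float = 21.0
    nd_layers: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.on_intensity > 0:
            raise ProtocolError(f"on_intensity must be > 0, got {self.on_intensity}")
        if not 0 < self.duty <= 1:
            raise ProtocolError(f"duty must be in (0, 1], got {self.duty}")
        if self.frequency < 0:
            raise ProtocolError(f"frequency must be >= 0, got {self.frequency}")
        if not self.duration > 0:
            raise ProtocolError(f"duration must be > 0, got {self.duration}")
        if self.nd_layers < 0:
            raise ProtocolError(f"nd_layers must be >= 0, got {self.nd_layers}")


MaintenanceMode = Literal["light_adapt_full_on", "dark_off"]
ExperimentTag = Literal["exp1", "exp2", "exp3", "exp3_control"]


@dataclass(frozen=True)
class ProtocolSeries:
    """An ordered series of presentations with inter-stimulus maintenance.

    Between presentations the adaptation state is maintained either by
    leaving the stimulus light on at full intensity (light-adapted
    protocols) or off (dark-adapted protocols).
    """

    stimuli: tuple[StimulusSpec, ...]
    inter_stimulus_interval: float = 60.0
    maintenance_mode: MaintenanceMode = "light_adapt_full_on"
    experiment_tag: ExperimentTag = "exp1"
    probe_times_min: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.stimuli) == 0:
            raise ProtocolError("a protocol series needs at least one stimulus")
        if self.experiment_tag == "exp1":
            ints = [s.on_intensity for s in self.stimuli]
            if any(b <= a for a, b in zip(ints, ints[1:])):
                raise ProtocolError("exp1 intensities must be strictly increasing")
        elif self.experiment_tag == "exp2":
            fr = [s.frequency for s in self.stimuli]
            if any(b <= a for a, b in zip(fr, fr[1:])):
                raise ProtocolError("exp2 frequencies must be strictly increasing")
        elif self.experiment_tag in ("exp3", "exp3_control"):
            first = self.stimuli[0]
            for s in self.stimuli[1:]:
                if s.on_intensity != first.on_intensity or s.frequency != first.frequency:
                    raise ProtocolError(
                        "exp3 stimuli must share one intensity and frequency"
                    )

    def __len__(self) -> int:
        return len(self.stimuli)


@dataclass(frozen=True)
class Spectrum:
    """A measured irradiance spectrum (per-nm density on a wavelength grid)."""

    wavelengths: np.ndarray  # nm, strictly increasing
    irradiance_density: np.ndarray  # µW cm⁻² nm⁻¹, >= 0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        dens = np.asarray(self.irradiance_density, dtype=float)
        if wl.shape != dens.shape or wl.ndim != 1:
            raise DomainError("wavelengths and irradiance_density must be equal-length 1-d")
        if np.any(np.diff(wl) <= 0):
            raise DomainError("wavelengths must be strictly increasing")
        if np.any(dens < 0):
            raise DomainError("irradiance_density must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "irradiance_density", dens)


def build_intensity_series(
    start_intensity: float,
    step_log10: float,
    n: int,
    frequency: float = 10.0,
    duration: float = 21.0,
    *,
    inter_stimulus_interval: float = 60.0,
    maintenance_mode: MaintenanceMode = "light_adapt_full_on",
    duty: float = 0.5,
    nd_layers: int = 0,
) -> ProtocolSeries:
    """Build the ascending intensity series (exp-1 style protocol).

    Presentation *k* (1-based) has ON intensity
    ``start_intensity * 10**((k-1) * step_log10)``.  The canonical protocol
    uses 15 presentations stepping one third of a log unit, 21 s of 10 Hz
    on-off flicker each, one per minute.
    """
    if not start_intensity > 0:
        raise ProtocolError(f"start_intensity must be > 0, got {start_intensity}")
    if n < 1:
        raise ProtocolError(f"n must be >= 1, got {n}")
    stims = tuple(
        StimulusSpec(
            on_intensity=start_intensity * 10.0 ** (k * step_log10),
            frequency=frequency,
            duty=duty,
            duration=duration,
            nd_layers=nd_layers,
        )
        for k in range(n)
    )
    tag: ExperimentTag = "exp1"
    if step_log10 == 0 and n > 1:
        # identical intensities are not a valid strictly-increasing exp1
        # series; tag as exp3-style repeats instead
        tag = "exp3"
    return ProtocolSeries(
        stimuli=stims,
        inter_stimulus_interval=inter_stimulus_interval,
        maintenance_mode=maintenance_mode,
        experiment_tag=tag,
    )


def build_fff_series(
    intensity: float,
    freqs: Sequence[float],
    duration: float = 21.0,
    *,
    drop_endpoint: Literal["low", "high"] | None = None,
    inter_stimulus_interval: float = 60.0,
    maintenance_mode: MaintenanceMode = "light_adapt_full_on",
    mark_mains: bool = True,
) -> ProtocolSeries:
    """Build a flicker-fusion series: one presentation per frequency.

    ``drop_endpoint`` removes the first or last nominal frequency; the
    published protocol names twelve nominal frequencies (10-120 Hz in 10 Hz
    steps) but presented eleven stimuli, so the default exp-2 constructor
    (`build_exp2_series`) passes ``drop_endpoint="high"``.  Which endpoint
    was omitted is configurable rather than guessed.  The 50 Hz presentation
    is labelled ``"excluded-from-analysis"`` (mains contamination).
    """
    if len(freqs) == 0:
        raise ProtocolError("freqs must be non-empty")
    if not intensity > 0:
        raise ProtocolError(f"intensity must be > 0, got {intensity}")
    fr = [float(f) for f in freqs]
    if any(b <= a for a, b in zip(fr, fr[1:])):
        raise ProtocolError("freqs must be strictly increasing")
    if drop_endpoint == "low":
        fr = fr[1:]
    elif drop_endpoint == "high":
        fr = fr[:-1]
    if len(fr) == 0:
        raise ProtocolError("dropping an endpoint left no frequencies")
    stims = tuple(
        StimulusSpec(
            on_intensity=intensity,
            frequency=f,
            duration=duration,
            label="excluded-from-analysis" if (mark_mains and f == MAINS_FREQ) else "",
        )
        for f in fr
    )
    return ProtocolSeries(
        stimuli=stims,
        inter_stimulus_interval=inter_stimulus_interval,
        maintenance_mode=maintenance_mode,
        experiment_tag="exp2",
    )


def build_exp2_series(intensity: float, duration: float = 21.0,
                      drop_endpoint: Literal["low", "high"] = "high",
                      **kwargs) -> ProtocolSeries:
    """The default fusion-frequency protocol: 11 presentations drawn from the
    nominal 10-120 Hz series, with 50 Hz flagged excluded-from-analysis."""
    return build_fff_series(
        intensity, EXP2_NOMINAL_FREQS, duration, drop_endpoint=drop_endpoint, **kwargs
    )


def build_dark_adaptation_protocol(
    test_intensity: float = EXP3_TEST_INTENSITY,
    interval: float = 240.0,
    total: float = 60.0,
    probes: Literal["all", "endpoints_only"] = "all",
    *,
    frequency: float = 10.0,
    duration: float = 21.0,
) -> ProtocolSeries:
    """Build the dark-adaptation probe schedule (exp-3 style protocol).

    Parameters
    ----------
    test_intensity : float
        ON irradiance of the repeated dim test flicker, µW cm⁻².
    interval : float
        Probe spacing in **seconds** (default 240 s = 4 min).
    total : float
        Total dark-adaptation span in **minutes** (default 60).
    probes : {"all", "endpoints_only"}
        ``"all"`` probes at 0, interval, 2*interval, ... up to `total`;
        ``"endpoints_only"`` probes only at 0 and `total` (the
        uninterrupted-dark-adaptation control).
    """
    if not interval > 0:
        raise ProtocolError(f"interval must be > 0, got {interval}")
    if not total > 0:
        raise ProtocolError(f"total must be > 0, got {total}")
    interval_min = interval / 60.0
    if probes == "all":
        n = int(math.floor(total / interval_min + 1e-9)) + 1
        times = tuple(k * interval_min for k in range(n))
        if times[-1] < total and len(times) == 1:
            times = (0.0, float(total))
        tag: ExperimentTag = "exp3"
    elif probes == "endpoints_only":
        times = (0.0, float(total))
        tag = "exp3_control"
    else:  # pragma: no cover - guarded by Literal typing
        raise ProtocolError(f"unknown probes mode {probes!r}")
    if len(times) == 1:
        times = (0.0, float(total))
    stims = tuple(
        StimulusSpec(on_intensity=test_intensity, frequency=frequency,
                     duration=duration)
        for _ in times
    )
    return ProtocolSeries(
        stimuli=stims,
        inter_stimulus_interval=interval,
        maintenance_mode="dark_off",
        experiment_tag=tag,
        probe_times_min=times,
    )


def nd_transmission(layers: int, od_per_layer: float = 0.9) -> float:
    """Fractional transmission of `layers` stacked neutral-density filters.

    Transmission is ``10**(-layers * od_per_layer)``; stacking is
    multiplicative in transmission, additive in optical density.
    """
    if layers < 0 or od_per_layer < 0:
        raise DomainError("layers and od_per_layer must be non-negative")
    return 10.0 ** (-layers * od_per_layer)


def integrate_irradiance(spectrum: Spectrum, lo: float = 300.0, hi: float = 600.0) -> float:
    """Total irradiance (µW cm⁻²) from a per-nm density spectrum.

    Trapezoidal integral of the irradiance density over [`lo`, `hi`] nm,
    with the endpoints interpolated onto the measured grid.
    """
    wl = spectrum.wavelengths
    dens = spectrum.irradiance_density
    if not (lo < hi):
        raise DomainError(f"need lo < hi, got [{lo}, {hi}]")
    if lo < wl[0] or hi > wl[-1]:
        raise CoverageError(
            f"spectrum covers [{wl[0]}, {wl[-1]}] nm, cannot integrate [{lo}, {hi}]"
        )
    inside = (wl > lo) & (wl < hi)
    grid = np.concatenate(([lo], wl[inside], [hi]))
    vals = np.interp(grid, wl, dens)
    return float(np.trapezoid(vals, grid))


def angular_subtense(diameter: float, distance: float) -> float:
    """Visual angle (degrees) subtended by a disc of `diameter` at `distance`.

    Both arguments share any one length unit.  A 3 cm stimulus viewed from
    3 cm subtends 53.13 deg.
    """
    if not (diameter > 0 and distance > 0):
        raise DomainError("diameter and distance must be > 0")
    return math.degrees(2.0 * math.atan2(diameter, 2.0 * distance))


def square_wave(
    frequency: float,
    duty: float,
    duration: float,
    fs: float,
    on_level: float = 1.0,
) -> np.ndarray:
    """Sampled on-off square wave starting ON at t = 0.

    Each cycle is ON (at `on_level`) for the first `duty` fraction and OFF
    (at 0) for the rest.  ``frequency == 0`` returns constant light.  The
    fundamental Fourier amplitude of a 50%-duty wave is ``2 * on_level / pi``.
    """
    if not 0 < duty <= 1:
        raise DomainError(f"duty must be in (0, 1], got {duty}")
    if frequency < 0:
        raise DomainError(f"frequency must be >= 0, got {frequency}")
    if not duration > 0 or not fs > 0:
        raise DomainError("duration and fs must be > 0")
    n = int(round(duration * fs))
    if frequency == 0 or duty == 1.0:
        return np.full(n, float(on_level))
    if fs <= 2.0 * frequency:
        raise AliasingError(
            f"fs = {fs} Hz cannot represent a {frequency} Hz flicker (need fs > 2f)"
        )
    t = np.arange(n) / fs
    phase = (t * frequency) % 1.0
    return np.where(phase < duty, float(on_level), 0.0)
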