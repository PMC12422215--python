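"""Far-field sound estimate and acoustic voice metrics.

The radiated sound is estimated with the compact-monopole law: a fluctuating
volume flux ``Q(t)`` at the mouth radiates a far-field pressure

    p_s(t) = rho / (4 pi r) * dQ/dt

at listener distance ``r`` (5 cm outside the tract exit by default).  On top
of that the module provides the magnitude spectrum with its ``1/record
length`` resolution, formant picking, the closed-form quarter-wave resonances
``F_n = (2n - 1) c / (4 L)`` of a uniform closed–open tract, the sound
intensity level, a harmonic-to-inharmonic signal-to-noise ratio, and vocal
efficiency (radiated acoustic power over aerodynamic power).

No wave propagation inside the tract is computed; by default the mouth flow
is approximated by the glottal flow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import PhaseAveragedCycle, detect_cycles, phase_average

__all__ = [
    "FarfieldSignal",
    "Spectrum",
    "farfield_pressure",
    "spectrum_of",
    "tube_natural_frequencies",
    "sound_intensity_level",
    "vocal_efficiency",
    "snr",
    "formants",
]

REFERENCE_INTENSITY = 1e-12  # W/m²
DEFAULT_DISTANCE = 0.05      # m
DEFAULT_SOUND_SPEED = 351.88  # m/s, warm humid air in the tract
DEFAULT_DENSITY = 1.2        # kg/m³


@dataclass
class FarfieldSignal:
    """Far-field acoustic pressure at a listener distance ``r``."""

    time: np.ndarray
    pressure: np.ndarray
    r: float = DEFAULT_DISTANCE
    air_density: float = DEFAULT_DENSITY
    sound_speed: float = DEFAULT_SOUND_SPEED


@dataclass
class Spectrum:
    """One-sided magnitude spectrum with its frequency resolution (Hz)."""

    frequency: np.ndarray
    magnitude: np.ndarray
    resolution: float

    def band_energy(self) -> float:
        return float(np.sum(self.magnitude**2))


def farfield_pressure(
    time: np.ndarray,
    flow_rate: np.ndarray,
    r: float = DEFAULT_DISTANCE,
    air_density: float = DEFAULT_DENSITY,
    sound_speed: float = DEFAULT_SOUND_SPEED,
) -> FarfieldSignal:
    """Compact-monopole far-field pressure ``rho/(4 pi r) dQ/dt``.

    The flow derivative is taken by central differences on the uniform
    time grid.
    """
    if r <= 0:
        raise ValueError("listener distance r must be positive")
    t = np.asarray(time, dtype=float)
    q = np.asarray(flow_rate, dtype=float)
    dqdt = np.gradient(q, t)
    p = air_density / (4.0 * math.pi * r) * dqdt
    return FarfieldSignal(time=t, pressure=p, r=r,
                          air_density=air_density, sound_speed=sound_speed)


def spectrum_of(
    time: np.ndarray,
    signal: np.ndarray,
    window: str | None = None,
) -> Spectrum:
    """Magnitude spectrum of the full record.

    The frequency resolution is the reciprocal of the record length
    ``N * dt``.  ``window="hann"`` applies a Hann window before the
    transform (used by the SNR estimator).
    """
    t = np.asarray(time, dtype=float)
    x = np.asarray(signal, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    dt = float(t[1] - t[0])
    n = len(x)
    if window == "hann":
        x = x * np.hanning(n)
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, dt)
    return Spectrum(frequency=freqs, magnitude=mag, resolution=1.0 / (n * dt))


def tube_natural_frequencies(
    n_max: int,
    sound_speed: float = DEFAULT_SOUND_SPEED,
    tract_length: float = 0.174,
) -> np.ndarray:
    """Quarter-wave resonances ``F_n = (2n - 1) c / (4 L)`` of a uniform
    closed–open tube, for ``n = 1 .. n_max`` (Hz)."""
    if sound_speed <= 0 or tract_length <= 0:
        raise ValueError("sound speed and tract length must be positive")
    if n_max < 1:
        raise ValueError("n_max must be at least 1")
    n = np.arange(1, n_max + 1)
    return (2 * n - 1) * sound_speed / (4.0 * tract_length)


def sound_intensity_level(
    pressure_cycle: PhaseAveragedCycle | np.ndarray,
    air_density: float = DEFAULT_DENSITY,
    sound_speed: float = DEFAULT_SOUND_SPEED,
) -> float:
    """Sound intensity level ``10 log10(I / I0)`` in dB.

    The pressure amplitude ``Δp_s`` is half the peak-to-trough excursion of
    the phase-averaged pressure waveform and ``I = Δp_s² / (2 rho c)``,
    with ``I0 = 1e-12`` W/m².  A zero signal returns ``-inf`` with a
    warning.
    """
    values = (pressure_cycle.values
              if isinstance(pressure_cycle, PhaseAveragedCycle)
              else np.asarray(pressure_cycle, dtype=float))
    amplitude = 0.5 * (values.max() - values.min())
    if amplitude == 0.0:
        warnings.warn("zero pressure waveform; intensity level is -inf",
                      RuntimeWarning, stacklevel=2)
        return -math.inf
    intensity = amplitude**2 / (2.0 * air_density * sound_speed)
    return 10.0 * math.log10(intensity / REFERENCE_INTENSITY)


def farfield_intensity_level(
    signal: FarfieldSignal, discard_initial: int = 2, n_phases: int = 1000
) -> float:
    """Intensity level of a far-field record, phase-averaged over its
    steady cycles."""
    boundaries = detect_cycles(signal.time, signal.pressure,
                               discard_initial=discard_initial)
    cycle = phase_average(signal.time, signal.pressure, boundaries, n_phases)
    return sound_intensity_level(cycle, signal.air_density, signal.sound_speed)


def vocal_efficiency(
    spl_db: float,
    r: float,
    pulmonary_pressure: float,
    mean_flow: float,
) -> float:
    """Vocal efficiency ``4 pi r² 10^((SPL - 120)/10) / (P_pul U_g)``.

    Radiated acoustic power (from the intensity level at distance ``r``)
    over the aerodynamic power supplied (driving pressure times mean
    glottal flow).
    """
    if pulmonary_pressure <= 0 or mean_flow <= 0:
        raise ValueError("pulmonary pressure and mean flow must be positive")
    if r <= 0:
        raise ValueError("listener distance r must be positive")
    return 4.0 * math.pi * r**2 * 10.0 ** ((spl_db - 120.0) / 10.0) / (
        pulmonary_pressure * mean_flow
    )


def snr(spectrum: Spectrum, f0: float) -> float:
    """Signal-to-noise ratio as a harmonic-to-inharmonic energy split (dB).

    Energy within ±1 bin of every harmonic of ``f0`` up to the Nyquist
    frequency counts as signal; the remaining non-DC energy is noise.
    Spectra should be computed with a Hann window to confine leakage.
    """
    if f0 <= spectrum.resolution:
        raise ValueError("f0 must exceed the spectral resolution")
    energy = spectrum.magnitude**2
    n_bins = len(energy)
    harmonic = np.zeros(n_bins, dtype=bool)
    nyquist = spectrum.frequency[-1]
    k = 1
    while k * f0 <= nyquist:
        center = int(round(k * f0 / spectrum.resolution))
        lo = max(center - 1, 0)
        hi = min(center + 1, n_bins - 1)
        harmonic[lo:hi + 1] = True
        k += 1
    harmonic[0] = False
    signal = float(energy[harmonic].sum())
    noise = float(energy[1:].sum()) - signal
    if noise <= 0:
        return math.inf
    if signal <= 0:
        return -math.inf
    return 10.0 * math.log10(signal / noise)


def formants(spectrum: Spectrum, n_formants: int = 3, span: int = 2
             ) -> np.ndarray:
    """Spectral peaks: local maxima exceeding all neighbours within
    ``±span`` bins, returned in ascending frequency (at most
    ``n_formants``)."""
    mag = spectrum.magnitude
    peaks = []
    for i in range(1, len(mag) - 1):
        lo = max(i - span, 0)
        hi = min(i + span + 1, len(mag))
        if mag[i] >= mag[lo:hi].max() and mag[i] > mag[i - 1] and mag[i] > mag[i + 1]:
            peaks.append(i)
        if len(peaks) >= n_formants:
            break
    return spectrum.frequency[np.asarray(peaks, dtype=int)]
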