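"""Analytic test-signal generators with known ground truth.

Every analysis operation in the package (waveform metrics, acoustics, POD)
can be exercised on signals whose fundamental frequency, skewness and open
quotients, peak flow, mode shapes, energies and phase lags are *planted*,
so round-trip recovery is testable without running any simulation.

Flow/area pulses: each cycle is a closed phase at the floor value followed
by a rise of duration ``tau_o T tau_s / (1 + tau_s)`` and a fall of
duration ``tau_o T / (1 + tau_s)``.  The default segment shape is a
quarter-sine ramp, whose slope is steepest exactly at the open/closed
junctions and zero at the peak: the 2%-of-maximum slope rule then locates
the closure instant crisply at the junction, and the waveform is C¹ at the
peak.  Raised-cosine (C¹ everywhere, but with a soft trigger that smears
the detected closure by a few phase bins) and linear segments are
available as alternatives.

Kinematic fixtures: snapshots are a mean field plus planted orthonormal
modes with planted energies.  The two leading modes share the fundamental
frequency with a planted phase lag; so that their coefficient series are
empirically *uncorrelated* (a requirement for POD to recover the planted
shapes exactly), the shared coefficient waveform carries one higher
harmonic whose weight zeroes the cross-correlation at the planted lag.
Modes beyond the leading pair oscillate at distinct higher harmonics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FixtureSpec", "make_flow_waveform", "make_modal_kinematics"]


@dataclass(frozen=True)
class FixtureSpec:
    """Planted parameters for analytic fixtures.

    Waveform defaults mirror typical phonation values (201 Hz, skewness
    quotient 1.45, open quotient 0.67, 220 mL/s peak flow).
    """

    f0: float = 201.0
    tau_s: float = 1.45
    tau_o: float = 0.67
    q_peak: float = 2.2e-4      # m³/s
    q_floor: float = 5.0e-5     # m³/s, flow during the closed phase
    n_cycles: int = 8
    samples_per_cycle: int = 2000
    noise_std: float = 0.0
    seed: int | None = None
    shape: str = "sine"          # "sine" | "raised_cosine" | "linear"

    # kinematic fixtures
    n_dof: int = 8
    energies: tuple = (0.65, 0.27, 0.08)
    phase_lag: float = 0.38      # fraction of T between the two leading modes
    mode_shapes: np.ndarray | None = field(default=None, compare=False)
    mean_field: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not 0.0 < self.tau_o <= 1.0:
            raise ValueError("tau_o must be in (0, 1]")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.q_peak <= self.q_floor or self.q_floor < 0:
            raise ValueError("need q_peak > q_floor >= 0")
        if self.n_cycles < 1 or self.samples_per_cycle < 8:
            raise ValueError("need at least 1 cycle and 8 samples per cycle")
        if self.shape not in ("sine", "raised_cosine", "linear"):
            raise ValueError(f"unknown segment shape {self.shape!r}")


def _ramp_up(u: np.ndarray, shape: str) -> np.ndarray:
    """Monotone 0 -> 1 ramp on u in [0, 1]."""
    if shape == "sine":
        return np.sin(0.5 * np.pi * u)          # steepest at u=0, flat at u=1
    if shape == "raised_cosine":
        return 0.5 * (1.0 - np.cos(np.pi * u))  # flat at both ends
    return u                                     # linear


def pulse_value(phase: np.ndarray, spec: FixtureSpec) -> np.ndarray:
    """Pulse-train value at cycle phase in [0, 1); cycle starts at opening."""
    rise = spec.tau_o * spec.tau_s / (1.0 + spec.tau_s)
    fall = spec.tau_o / (1.0 + spec.tau_s)
    h = spec.q_peak - spec.q_floor
    ph = np.asarray(phase) % 1.0
    out = np.full(ph.shape, spec.q_floor, dtype=float)
    rising = ph < rise
    out[rising] += h * _ramp_up(ph[rising] / rise, spec.shape)
    falling = (ph >= rise) & (ph < rise + fall)
    out[falling] += h * _ramp_up(1.0 - (ph[falling] - rise) / fall, spec.shape)
    return out


def make_flow_waveform(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pulse train with planted f0, skewness and open quotients.

    Returns ``(time, values)``.  The same generator serves as a glottal
    *area* fixture (the open/closed structure is identical).
    """
    n = spec.n_cycles * spec.samples_per_cycle
    dt = 1.0 / (spec.f0 * spec.samples_per_cycle)
    t = np.arange(n) * dt
    q = pulse_value(t * spec.f0, spec)
    if spec.noise_std > 0:
        rng = np.random.default_rng(spec.seed)
        q = q + rng.normal(0.0, spec.noise_std, size=n)
    return t, q


def _default_mode_shapes(n_dof: int, n_modes: int) -> np.ndarray:
    """Orthonormalized polynomial profiles: lateral, tilt, bend, ..."""
    s = np.linspace(-1.0, 1.0, n_dof)
    raw = np.vstack([s**k for k in range(n_modes)])
    q, _ = np.linalg.qr(raw.T)
    return q.T[:n_modes]


def _lag_harmonic_weight(lag: float) -> tuple[int, float]:
    """Harmonic order m >= 2 and weight gamma making the waveform
    ``cos(theta) + gamma cos(m theta)`` uncorrelated with a copy of itself
    shifted by ``lag`` cycles (gamma² = -cos(2π lag) / cos(2π m lag))."""
    c1 = math.cos(2.0 * math.pi * lag)
    if abs(c1) < 1e-12:
        return 2, 0.0  # quadrature lag: plain cosines are already uncorrelated
    for m in range(2, 12):
        cm = math.cos(2.0 * math.pi * m * lag)
        if abs(cm) > 0.05 and (c1 / cm) < 0:
            return m, math.sqrt(-c1 / cm)
    raise ValueError(f"no decorrelating harmonic found for lag {lag}")


def make_modal_kinematics(
    spec: FixtureSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Snapshot matrix with planted modes, energies and coefficient lag.

    Returns ``(time, snapshots, shapes)`` where ``shapes`` holds the
    planted orthonormal mode shapes (row per mode).  Mode variances equal
    the planted ``energies``, so POD energy fractions are
    ``energies / sum(energies)``; the second mode's coefficient trails the
    first by ``phase_lag`` cycles.
    """
    n_modes = len(spec.energies)
    if n_modes < 1:
        raise ValueError("need at least one planted mode")
    if any(e <= 0 for e in spec.energies):
        raise ValueError("planted energies must be positive")
    if spec.mode_shapes is not None:
        shapes = np.asarray(spec.mode_shapes, dtype=float)
        gram = shapes @ shapes.T
        if not np.allclose(gram, np.eye(n_modes), atol=1e-8):
            raise ValueError("planted mode shapes must be orthonormal")
    else:
        shapes = _default_mode_shapes(spec.n_dof, n_modes)
    n_dof = shapes.shape[1]

    n = spec.n_cycles * spec.samples_per_cycle
    dt = 1.0 / (spec.f0 * spec.samples_per_cycle)
    t = np.arange(n) * dt
    theta = 2.0 * np.pi * spec.f0 * t

    m, gamma = _lag_harmonic_weight(spec.phase_lag)

    def base_waveform(th: np.ndarray) -> np.ndarray:
        w = np.cos(th) + gamma * np.cos(m * th)
        return w / math.sqrt((1.0 + gamma**2) / 2.0)  # unit variance

    coeffs = np.empty((n, n_modes))
    coeffs[:, 0] = math.sqrt(spec.energies[0]) * base_waveform(theta)
    if n_modes > 1:
        shifted = theta - 2.0 * np.pi * spec.phase_lag
        coeffs[:, 1] = math.sqrt(spec.energies[1]) * base_waveform(shifted)
    for k in range(2, n_modes):
        # distinct high harmonics: uncorrelated with every other coefficient
        harm = m + k
        coeffs[:, k] = math.sqrt(2.0 * spec.energies[k]) * np.cos(
            harm * theta + 0.3 * k
        )

    mean = (np.zeros(n_dof) if spec.mean_field is None
            else np.asarray(spec.mean_field, dtype=float))
    snapshots = mean + coeffs @ shapes
    if spec.noise_std > 0:
        rng = np.random.default_rng(spec.seed)
        snapshots = snapshots + rng.normal(0.0, spec.noise_std, size=snapshots.shape)
    return t, snapshots, shapes
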