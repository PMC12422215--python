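"""Glottal waveform metrics.

Cycle detection, phase averaging (default 1000 phases per cycle), and the
standard voice-quality quantities computed from the phase-averaged glottal
flow and area waveforms:

* ``f0`` — fundamental frequency, Hz;
* ``tau_s`` — skewness quotient, flow-acceleration over flow-deceleration
  duration within a cycle;
* ``tau_o`` — open quotient, fraction of the cycle the glottis is open,
  with the closed phase defined by a 2%-of-maximum slope rule combined
  with proximity to the waveform floor;
* ``MFDR`` — maximum flow declination rate, the steepest negative slope of
  the flow waveform;
* cycle-averaged flow resistances ``|mean ΔP| / mean Q`` across the
  glottis and the stenosis, and the glottis-to-stenosis area ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "NonOscillatingError",
    "PhaseAveragedCycle",
    "MetricsReport",
    "ResistanceReport",
    "detect_cycles",
    "phase_average",
    "skewness_quotient",
    "open_quotient",
    "mfdr",
    "flow_resistance",
    "area_ratio",
    "fundamental_frequency",
    "analyze_series",
    "resistance_report",
]

SLOPE_FRACTION = 0.02      # closed phase: |dA/dt| below 2% of its maximum ...
FLOOR_FRACTION = 0.05      # ... while the waveform sits near its floor


class NonOscillatingError(ValueError):
    """Raised when a signal expected to oscillate does not."""


@dataclass
class PhaseAveragedCycle:
    """One cycle resampled onto a uniform phase grid and averaged.

    ``phases`` covers [0, 1); ``values`` holds the per-phase average over
    ``n_cycles_used`` steady cycles of mean period ``period`` seconds.
    """

    phases: np.ndarray
    values: np.ndarray
    period: float
    n_cycles_used: int

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def dt(self) -> float:
        """Time per phase bin."""
        return self.period / self.n_phases

    def derivative(self) -> np.ndarray:
        """Central-difference time derivative on the circular phase grid."""
        return (np.roll(self.values, -1) - np.roll(self.values, 1)) / (2.0 * self.dt)


@dataclass
class MetricsReport:
    """Voice-quality quantities of one run (SI units; MFDR also in L/s²)."""

    f0: float
    tau_s: float
    tau_o: float
    q_peak: float
    q_mean: float
    mfdr: float
    closure_phase: float
    max_area: float
    mean_area: float

    @property
    def mfdr_l_per_s2(self) -> float:
        return self.mfdr * 1e3

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ResistanceReport:
    """Cycle-averaged flow resistances (Pa·s/m³) and the area ratio."""

    r_glottis: float
    r_stenosis: float
    r_total: float
    area_ratio: float

    def to_dict(self) -> dict:
        return asdict(self)


def detect_cycles(
    time: np.ndarray,
    signal: np.ndarray,
    discard_initial: int = 2,
) -> np.ndarray:
    """Cycle boundaries at upward crossings of the steady-state mean level.

    The reference level is the signal mean over the second half of the
    record (to be insensitive to the start-up transient); boundary times are
    linearly interpolated between samples.  The first ``discard_initial``
    cycles are removed.

    Returns the array of boundary times (``len - 1`` usable cycles).
    """
    t = np.asarray(time, dtype=float)
    x = np.asarray(signal, dtype=float)
    if t.shape != x.shape or t.ndim != 1:
        raise ValueError("time and signal must be 1-D arrays of equal length")
    level = x[len(x) // 2:].mean()
    span = x.max() - x.min()
    if span <= 1e-12 * (abs(level) + 1.0):
        raise NonOscillatingError("signal is constant; no cycles to detect")
    below = x[:-1] < level
    above = x[1:] >= level
    idx = np.nonzero(below & above)[0]
    if len(idx) < discard_initial + 3:
        raise NonOscillatingError(
            f"found only {max(len(idx) - 1, 0)} cycles; need at least "
            f"{discard_initial + 2}"
        )
    frac = (level - x[idx]) / (x[idx + 1] - x[idx])
    crossings = t[idx] + frac * (t[idx + 1] - t[idx])
    return crossings[discard_initial:]


def phase_average(
    time: np.ndarray,
    signal: np.ndarray,
    boundaries: np.ndarray,
    n_phases: int = 1000,
) -> PhaseAveragedCycle:
    """Resample each cycle onto ``n_phases`` uniform phases and average.

    Each cycle ``[b_i, b_{i+1})`` is linearly interpolated at phases
    ``k / n_phases`` of its own duration; the arithmetic mean over cycles
    is taken phase by phase.
    """
    if n_phases < 2:
        raise ValueError("n_phases must be at least 2")
    b = np.asarray(boundaries, dtype=float)
    if len(b) < 2:
        raise ValueError("need at least one complete cycle")
    phases = np.arange(n_phases) / n_phases
    acc = np.zeros(n_phases)
    for i in range(len(b) - 1):
        ts = b[i] + phases * (b[i + 1] - b[i])
        acc += np.interp(ts, time, signal)
    n_cycles = len(b) - 1
    period = float(np.diff(b).mean())
    return PhaseAveragedCycle(
        phases=phases, values=acc / n_cycles, period=period, n_cycles_used=n_cycles
    )


def _closed_mask(cycle: PhaseAveragedCycle) -> np.ndarray:
    """Phases classified as closed: slow slope *and* near the floor.

    The slope criterion (|dA/dt| below 2% of its maximum rate of change) is
    evaluated with the *smaller* of the two one-sided differences at each
    phase, so a junction sample flat on its closed side is not pushed into
    the open class by the steep slope on its other side (a central
    difference there would bias the open duration by a bin per edge).  The
    slope rule alone would also fire at the waveform peak, so it is
    combined with a floor-proximity condition; and an isolated tangent
    minimum is not a closed phase, so runs shorter than 1% of the cycle are
    discarded.
    """
    v = cycle.values
    span = v.max() - v.min()
    fwd = (np.roll(v, -1) - v) / cycle.dt
    bwd = (v - np.roll(v, 1)) / cycle.dt
    max_slope = np.abs(cycle.derivative()).max()
    if max_slope == 0.0 or span == 0.0:
        raise ValueError("cycle is flat; open/closed phases are undefined")
    slow = np.minimum(np.abs(fwd), np.abs(bwd)) < SLOPE_FRACTION * max_slope
    near_floor = (v - v.min()) < FLOOR_FRACTION * span
    closed = slow & near_floor
    return _drop_short_runs(closed, max(3, cycle.n_phases // 100))


def _drop_short_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Clear circular True-runs shorter than ``min_run`` samples."""
    n = len(mask)
    if mask.all() or not mask.any():
        return mask
    first_open = int(np.argmax(~mask))
    rolled = np.roll(mask, -first_open)
    out = rolled.copy()
    i = 0
    while i < n:
        if rolled[i]:
            j = i
            while j < n and rolled[j]:
                j += 1
            if j - i < min_run:
                out[i:j] = False
            i = j
        else:
            i += 1
    return np.roll(out, first_open)


def _open_arc(closed: np.ndarray) -> tuple[int, int]:
    """Longest circular run of open phases as (start, length)."""
    n = len(closed)
    open_mask = ~closed
    if open_mask.all():
        return 0, n
    # rotate so index 0 is closed, then scan linear runs
    first_closed = int(np.argmax(closed))
    rolled = np.roll(open_mask, -first_closed)
    best_start = best_len = 0
    i = 0
    while i < n:
        if rolled[i]:
            j = i
            while j < n and rolled[j]:
                j += 1
            if j - i > best_len:
                best_len = j - i
                best_start = i
            i = j
        else:
            i += 1
    return (best_start + first_closed) % n, best_len


def open_quotient(area_cycle: PhaseAveragedCycle) -> float:
    """Open quotient: open duration over cycle duration.

    Returns 1.0 with a ``RuntimeWarning`` when no closed phase is found.
    """
    closed = _closed_mask(area_cycle)
    if not closed.any():
        warnings.warn("no closed phase detected; open quotient set to 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    _, open_len = _open_arc(closed)
    return open_len / area_cycle.n_phases


def closure_phase_of(area_cycle: PhaseAveragedCycle) -> float:
    """Phase (fraction of the cycle) at which glottic closure occurs,
    measured from the opening instant."""
    closed = _closed_mask(area_cycle)
    if not closed.any():
        return 1.0
    _, open_len = _open_arc(closed)
    return open_len / area_cycle.n_phases


def skewness_quotient(flow_cycle: PhaseAveragedCycle) -> float:
    """Skewness quotient: flow-acceleration over flow-deceleration duration.

    The accelerating segment runs from the opening instant (end of the
    closed phase; the waveform minimum when no closed phase exists) to the
    flow peak, the decelerating segment from the peak to the closure
    instant.  Durations are measured circularly on the phase grid.
    """
    v = flow_cycle.values
    n = flow_cycle.n_phases
    if v.max() - v.min() == 0.0:
        raise ValueError("cycle is flat; skewness quotient undefined")
    closed = _closed_mask(flow_cycle)
    if closed.any():
        onset, open_len = _open_arc(closed)
        closure = (onset + open_len) % n
    else:
        onset = closure = int(np.argmin(v))
        open_len = n
    peak = int(np.argmax(v))
    rise = (peak - onset) % n
    fall = (closure - peak) % n
    if closed.any() and rise + fall > open_len:
        raise ValueError("flow peak lies outside the open phase")
    if fall == 0:
        raise ValueError("zero deceleration duration; skewness undefined")
    return rise / fall


def mfdr(flow_cycle: PhaseAveragedCycle) -> float:
    """Maximum flow declination rate: the steepest negative slope of the
    flow waveform, returned as a non-negative number (m³/s² for flow
    input)."""
    v = flow_cycle.values
    if v.max() - v.min() == 0.0:
        raise ValueError("cycle is flat; MFDR undefined")
    return max(0.0, float((-flow_cycle.derivative()).max()))


def _steady_mask(time: np.ndarray, boundaries: np.ndarray | None) -> np.ndarray:
    if boundaries is None:
        return np.ones(len(time), dtype=bool)
    return (time >= boundaries[0]) & (time <= boundaries[-1])


def flow_resistance(
    time: np.ndarray,
    dp: np.ndarray,
    q: np.ndarray,
    boundaries: np.ndarray | None = None,
) -> float:
    """Cycle-averaged flow resistance ``|mean ΔP| / mean Q`` (Pa·s/m³).

    The ratio of cycle means is used (not the mean of instantaneous
    ratios).  ``boundaries`` restricts the averages to steady cycles.
    """
    mask = _steady_mask(np.asarray(time), boundaries)
    q_mean = float(np.mean(np.asarray(q)[mask]))
    if q_mean <= 0:
        raise ValueError("cycle-averaged flow must be positive")
    return abs(float(np.mean(np.asarray(dp)[mask]))) / q_mean


def area_ratio(
    time: np.ndarray,
    glottal_area: np.ndarray,
    sgs_area: float,
    boundaries: np.ndarray | None = None,
) -> float:
    """Cycle-averaged glottal area divided by the stenosis narrowest area."""
    if sgs_area <= 0:
        raise ValueError("sgs_area must be positive")
    mask = _steady_mask(np.asarray(time), boundaries)
    return float(np.mean(np.asarray(glottal_area)[mask])) / sgs_area


def fundamental_frequency(
    time: np.ndarray,
    signal: np.ndarray,
    discard_initial: int = 2,
) -> float:
    """Fundamental frequency from the mean steady-cycle period.

    Cross-checked against the dominant spectral peak of the steady portion;
    a disagreement beyond 5% raises a ``RuntimeWarning`` (aperiodic input).
    """
    t = np.asarray(time, dtype=float)
    x = np.asarray(signal, dtype=float)
    boundaries = detect_cycles(t, x, discard_initial=discard_initial)
    if len(boundaries) < 4:
        raise NonOscillatingError("need at least 3 steady cycles")
    f0 = 1.0 / float(np.diff(boundaries).mean())

    mask = (t >= boundaries[0]) & (t <= boundaries[-1])
    xs = x[mask] - x[mask].mean()
    dt = float(t[1] - t[0])
    mag = np.abs(np.fft.rfft(xs * np.hanning(len(xs))))
    freqs = np.fft.rfftfreq(len(xs), dt)
    peak = float(freqs[1:][np.argmax(mag[1:])])
    if abs(peak - f0) / f0 > 0.05 and abs(peak - f0) > 1.5 / (len(xs) * dt):
        warnings.warn(
            f"cycle-based f0 {f0:.1f} Hz disagrees with spectral peak "
            f"{peak:.1f} Hz by more than 5%", RuntimeWarning, stacklevel=2)
    return f0


# ---------------------------------------------------------------------------
# convenience drivers over a simulation run


def analyze_series(series, n_phases: int = 1000, discard_initial: int = 2
                   ) -> MetricsReport:
    """All waveform metrics of a :class:`~stenovoice.rom.CycleSeries`."""
    boundaries = detect_cycles(series.time, series.glottal_area,
                               discard_initial=discard_initial)
    flow_cycle = phase_average(series.time, series.flow_rate, boundaries, n_phases)
    area_cycle = phase_average(series.time, series.glottal_area, boundaries, n_phases)
    f0 = 1.0 / float(np.diff(boundaries).mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tau_o = open_quotient(area_cycle)
    return MetricsReport(
        f0=f0,
        tau_s=skewness_quotient(flow_cycle),
        tau_o=tau_o,
        q_peak=float(flow_cycle.values.max()),
        q_mean=float(flow_cycle.values.mean()),
        mfdr=mfdr(flow_cycle),
        closure_phase=closure_phase_of(area_cycle),
        max_area=float(area_cycle.values.max()),
        mean_area=float(area_cycle.values.mean()),
    )


def resistance_report(series, discard_initial: int = 2) -> ResistanceReport:
    """Cycle-averaged resistances and area ratio of a simulation run."""
    boundaries = detect_cycles(series.time, series.glottal_area,
                               discard_initial=discard_initial)
    rg = flow_resistance(series.time, series.dp_glottis, series.flow_rate,
                         boundaries)
    rs = flow_resistance(series.time, series.dp_stenosis, series.flow_rate,
                         boundaries)
    ratio = area_ratio(series.time, series.glottal_area, series.area_sgs,
                       boundaries)
    return ResistanceReport(
        r_glottis=rg, r_stenosis=rs, r_total=rg + rs, area_ratio=ratio
    )
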