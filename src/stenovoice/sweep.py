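"""Severity and location sweeps with baseline-relative threshold analysis.

One simulation plus the full analysis chain (waveform metrics, resistances,
area ratio, far-field acoustics, POD summary) is run per
(severity, location) pair; results are collected in a tidy table with
relative deltas against the zero-severity baseline at the same location,
from which per-metric severity thresholds are read off.
"""

from __future__ import annotations

import logging
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acoustics, metrics, pod
from .geometry import SGSSpec
from .rom import ROMParams, simulate, fold_kinematics

__all__ = ["SweepConfig", "SweepResult", "run_single", "run_sweep",
           "threshold_report"]

logger = logging.getLogger("stenovoice")

DEFAULT_SEVERITIES = (0.0, 0.25, 0.50, 0.75, 0.90, 0.96, 0.99)
DEFAULT_LOCATIONS = (0.021, 0.0313)

#: metrics whose baseline-relative change the threshold analysis reports
DELTA_METRICS = (
    "f0", "tau_s", "tau_o", "q_peak", "q_mean", "mfdr",
    "max_area", "mean_area", "spl_db", "r_total",
)


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a severity × location sweep."""

    severities: tuple = DEFAULT_SEVERITIES
    locations: tuple = DEFAULT_LOCATIONS
    sgs_length: float = 0.01
    duration: float = 0.08
    seed: int | None = None
    n_phases: int = 1000
    discard_initial: int = 2
    params: ROMParams = field(default_factory=ROMParams)

    def __post_init__(self) -> None:
        for s in self.severities:
            if not 0.0 <= s < 1.0:
                raise ValueError(f"severity {s} outside [0, 1)")
        for loc in self.locations:
            if loc <= 0:
                raise ValueError("locations must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "params" in data:
            data["params"] = ROMParams(**data["params"])
        for key in ("severities", "locations"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class SweepResult:
    """Tidy per-run table plus baseline-relative deltas.

    ``table`` has one row per (severity, location) run; ``deltas`` holds
    ``(value - baseline) / baseline`` for the metrics in
    :data:`DELTA_METRICS`, where the baseline is the zero-severity run at
    the same location.
    """

    table: pd.DataFrame
    deltas: pd.DataFrame
    config: SweepConfig

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "sweep.csv", index=False, float_format="%.10e")
        self.deltas.to_csv(out / "sweep_deltas.csv", index=False,
                           float_format="%.10e")


def run_single(
    severity: float,
    location: float,
    config: SweepConfig,
) -> dict:
    """Simulate one (severity, location) case and compute all metrics."""
    sgs = (SGSSpec.from_severity(severity, length=config.sgs_length,
                                 location=location)
           if severity > 0 else
           SGSSpec(a=0.0, length=config.sgs_length, location=location))
    t0 = _time.perf_counter()
    series = simulate(config.params, sgs, duration=config.duration,
                      seed=config.seed)
    row: dict = {
        "severity": severity,
        "location": location,
        "a": sgs.a,
        "grade": sgs.grade,
        "oscillating": series.oscillating,
    }
    if not series.oscillating:
        logger.warning("run severity=%.2f location=%.4f did not oscillate",
                       severity, location)
        return row

    report = metrics.analyze_series(series, n_phases=config.n_phases,
                                    discard_initial=config.discard_initial)
    row.update(report.to_dict())
    res = metrics.resistance_report(series, discard_initial=config.discard_initial)
    row.update(res.to_dict())

    far = acoustics.farfield_pressure(series.time, series.flow_rate)
    row["spl_db"] = acoustics.farfield_intensity_level(
        far, discard_initial=config.discard_initial, n_phases=config.n_phases)
    spec = acoustics.spectrum_of(series.time, far.pressure, window="hann")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row["snr_db"] = acoustics.snr(spec, row["f0"])
    row["vocal_efficiency"] = acoustics.vocal_efficiency(
        row["spl_db"], far.r, config.params.driving_pressure, row["q_mean"])

    snapshots = fold_kinematics(series, discard_initial=config.discard_initial)
    decomp = pod.pod_decompose(snapshots)
    for k in range(min(2, decomp.n_modes)):
        row[f"pod_energy_{k + 1}"] = float(decomp.energy_fractions[k])
    logger.info("severity=%.2f location=%.4f done in %.2fs",
                severity, location, _time.perf_counter() - t0)
    return row


def run_sweep(config: SweepConfig | None = None) -> SweepResult:
    """Run every (severity, location) pair of the config sequentially."""
    if config is None:
        config = SweepConfig()
    rows = [
        run_single(severity, location, config)
        for location in config.locations
        for severity in config.severities
    ]
    table = pd.DataFrame(rows)

    delta_rows = []
    for location in config.locations:
        sub = table[table["location"] == location]
        base = sub[sub["severity"] == 0.0]
        if base.empty:
            continue
        base = base.iloc[0]
        for _, r in sub.iterrows():
            d = {"severity": r["severity"], "location": location}
            for m in DELTA_METRICS:
                if m in r and np.isfinite(r.get(m, np.nan)) and base.get(m, 0) != 0:
                    d[f"delta_{m}"] = (r[m] - base[m]) / base[m]
            delta_rows.append(d)
    deltas = pd.DataFrame(delta_rows)
    return SweepResult(table=table, deltas=deltas, config=config)


def threshold_report(
    result: SweepResult,
    metric: str,
    rel_tol: float = 0.01,
    location: float | None = None,
) -> float | None:
    """Smallest severity whose metric deviates from baseline by more than
    ``rel_tol`` (relative), or ``None`` when no severity crosses.

    ``location`` selects the severity sweep to analyse (defaults to the
    first configured location).
    """
    if result.deltas.empty:
        raise ValueError("sweep contains no baseline-relative deltas")
    col = f"delta_{metric}"
    if col not in result.deltas.columns:
        raise KeyError(f"metric {metric!r} not in sweep deltas")
    loc = location if location is not None else result.config.locations[0]
    sub = result.deltas[result.deltas["location"] == loc].sort_values("severity")
    if len(sub) < 3:
        raise ValueError("need at least 3 severities including baseline")
    crossed = sub[np.abs(sub[col]) > rel_tol]
    if crossed.empty:
        return None
    return float(crossed["severity"].iloc[0])


def full_threshold_report(result: SweepResult, rel_tol: float = 0.01) -> dict:
    """Threshold per metric and location, JSON-serializable
    (``"none"`` when a metric never crosses)."""
    out: dict = {"rel_tol": rel_tol, "thresholds": {}}
    for loc in result.config.locations:
        key = f"location_{loc}"
        out["thresholds"][key] = {}
        for m in DELTA_METRICS:
            col = f"delta_{m}"
            if col not in result.deltas.columns:
                continue
            thr = threshold_report(result, m, rel_tol=rel_tol, location=loc)
            out["thresholds"][key][m] = "none" if thr is None else thr
    return out
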