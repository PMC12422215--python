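"""Reduced-order self-oscillating vocal-fold model with a series flow law.

The surrogate couples two sub-models:

* **Tissue** — a symmetric two-mass lumped vocal-fold model (lower and
  upper medial-surface masses connected by linear springs, dampers and a
  coupling spring, one side simulated and mirrored).  The lower mass is
  driven by the intraglottal Bernoulli pressure with jet separation at the
  minimum section, which is the classic mechanism sustaining flow-induced
  oscillation; the lower/upper phase lag produces the convergent–divergent
  (mucosal-wave) alternation of the medial surface.

* **Flow** — a quasi-steady Bernoulli law for two orifices in series: the
  stenosis (fixed area set by SGS severity) and the glottis (time-varying
  minimum glottal area).  A fixed driving pressure ``P`` is partitioned
  between the two constrictions at every instant::

      Q = sqrt(2 P / rho) / sqrt(1/(Cd_s A_s)^2 + 1/(Cd_g A_g)^2)
      dP_i = rho Q^2 / (2 Cd_i^2 A_i^2),   dP_s + dP_g = P exactly.

Glottal closure is handled with a penalty contact force and an artificial
minimum gap (0.2 mm by default) below which the glottal area cannot fall,
so the flow never drops fully to zero during the closed phase.

Units are SI throughout: kg, m, s, Pa, m³/s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .geometry import SGSSpec

__all__ = ["ROMParams", "CycleSeries", "series_flow", "simulate", "fold_kinematics"]


@dataclass(frozen=True)
class ROMParams:
    """Parameters of the two-mass vocal-fold model and the series flow law.

    The defaults are a single calibration (documented in the methods note)
    chosen so the baseline run lands inside the typical physiological ranges
    of f0, peak/mean flow and the open and skewness quotients for a 0.8 kPa
    driving pressure.
    """

    # tissue (per side): lower mass "1" is the inferior, thicker element
    m1: float = 1.25e-4          # kg
    m2: float = 2.5e-5           # kg
    k1: float = 150.0            # N/m
    k2: float = 15.0             # N/m
    kc: float = 85.0             # N/m, body-style coupling between the masses
    r1: float = 0.04             # N·s/m
    r2: float = 0.008            # N·s/m
    contact_stiffness_ratio: float = 3.0   # penalty spring = ratio * k_i
    fold_length: float = 0.014   # m, anterior–posterior glottal length
    d1: float = 2.5e-3           # m, axial thickness of lower element
    d2: float = 5.0e-4           # m, axial thickness of upper element
    rest_area1: float = 3.0e-6   # m², glottal area at rest, lower section
    rest_area2: float = 2.0e-6   # m², upper section

    # aerodynamics
    driving_pressure: float = 800.0   # Pa, lung pressure minus supraglottal
    min_gap: float = 2.0e-4           # m, artificial minimum glottal gap
    air_density: float = 1.2          # kg/m³
    cd_glottis: float = 1.0           # discharge coefficients
    cd_stenosis: float = 1.0

    # airway
    subglottal_area: float = 2.5e-4   # m², unconstricted subglottal tube
    tract_length: float = 0.174       # m, supraglottal tract centerline
    sound_speed: float = 351.88       # m/s (warm humid air)

    # integration
    dt: float = 1.0e-5                # s, fixed RK4 step

    def __post_init__(self) -> None:
        for name in ("m1", "m2", "k1", "k2", "r1", "r2", "fold_length",
                     "d1", "d2", "rest_area1", "rest_area2", "min_gap",
                     "air_density", "subglottal_area", "dt",
                     "cd_glottis", "cd_stenosis"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.driving_pressure < 0:
            raise ValueError("driving_pressure must be non-negative")

    @property
    def floor_area(self) -> float:
        """Smallest admissible glottal area: min_gap × fold length."""
        return self.min_gap * self.fold_length

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ROMParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def replace(self, **kw) -> "ROMParams":
        d = asdict(self)
        d.update(kw)
        return ROMParams(**d)


def series_flow(
    driving_pressure: float,
    area_glottis: float,
    area_sgs: float,
    params: ROMParams,
) -> tuple[float, float, float]:
    """Quasi-steady flow through the stenosis and glottis in series.

    Returns ``(Q, dP_glottis, dP_stenosis)``; the two pressure drops sum to
    the driving pressure exactly (the glottal drop is computed from its
    share of the series impedance and the stenosis drop as the remainder).
    """
    if area_glottis <= 0 or area_sgs <= 0:
        raise ValueError("constriction areas must be positive")
    if driving_pressure < 0:
        raise ValueError("driving_pressure must be non-negative")
    ug = 1.0 / (params.cd_glottis * area_glottis) ** 2
    us = 1.0 / (params.cd_stenosis * area_sgs) ** 2
    q = math.sqrt(2.0 * driving_pressure / params.air_density) / math.sqrt(ug + us)
    dp_glottis = driving_pressure * (ug / (ug + us))
    dp_stenosis = driving_pressure - dp_glottis
    return q, dp_glottis, dp_stenosis


@dataclass
class CycleSeries:
    """Time series produced by one simulation run.

    Attributes
    ----------
    time : (n,) array, uniform grid in seconds
    glottal_area : (n,) array, minimum glottal cross-section, m²
    flow_rate : (n,) array, m³/s
    dp_glottis, dp_stenosis : (n,) arrays, Pa
    displacements : (n, n_dof) array
        Lateral displacement of points along the medial surface
        (inferior → superior), linear blends of the two mass displacements.
    params : ROMParams
    sgs : SGSSpec or None
    oscillating : bool
        Whether sustained oscillation was detected (non-oscillating runs
        are flagged, not raised).
    """

    time: np.ndarray
    glottal_area: np.ndarray
    flow_rate: np.ndarray
    dp_glottis: np.ndarray
    dp_stenosis: np.ndarray
    displacements: np.ndarray
    params: ROMParams
    sgs: SGSSpec | None = None
    oscillating: bool = True

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def area_sgs(self) -> float:
        """Narrowest stenosis area seen by the series flow law."""
        sev = self.sgs.severity if self.sgs is not None else 0.0
        return self.params.subglottal_area * (1.0 - sev)

    def to_frame(self):
        import pandas as pd

        data = {
            "time": self.time,
            "glottal_area": self.glottal_area,
            "flow_rate": self.flow_rate,
            "dp_glottis": self.dp_glottis,
            "dp_stenosis": self.dp_stenosis,
        }
        for j in range(self.displacements.shape[1]):
            data[f"disp_{j}"] = self.displacements[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10e")

    def metadata(self) -> dict:
        meta = {
            "oscillating": bool(self.oscillating),
            "params": asdict(self.params),
            "sgs": None,
        }
        if self.sgs is not None:
            meta["sgs"] = {
                "a": self.sgs.a,
                "severity": self.sgs.severity,
                "length": self.sgs.length,
                "location": self.sgs.location,
            }
        return meta

    def save(self, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.to_csv(csv_path)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(self.metadata(), fh, indent=2, sort_keys=True)


_N_SURFACE_POINTS = 8  # medial-surface sampling for kinematics output


def _surface_weights(n: int) -> np.ndarray:
    """Blend weights from the lower to the upper mass along the surface."""
    s = np.linspace(0.0, 1.0, n)
    return np.column_stack([1.0 - s, s])


def simulate(
    params: ROMParams | None = None,
    sgs: SGSSpec | None = None,
    duration: float = 0.08,
    seed: int | None = None,
    initial_displacement: float = 1.0e-4,
) -> CycleSeries:
    """Integrate the coupled fold/flow model with a fixed-step RK4 scheme.

    Parameters
    ----------
    params : ROMParams, optional
        Model parameters (calibrated defaults if omitted).
    sgs : SGSSpec, optional
        Stenosis; omitted or ``a = 0`` is the unconstricted baseline.
        The stenosis enters only through its narrowest area, so results do
        not depend on its location.
    duration : float
        Simulated time, s.  The default covers >10 cycles at the baseline
        f0 so that 8 cycles survive after discarding the start-up.
    seed : int, optional
        Seeds a small random perturbation added to the deterministic
        initial displacement; omitted runs are exactly reproducible too.
    """
    if params is None:
        params = ROMParams()
    severity = sgs.severity if sgs is not None else 0.0
    a_sgs = params.subglottal_area * (1.0 - severity)
    if a_sgs <= 0:
        raise ValueError("stenosis area must be positive")

    p = params
    floor = p.floor_area
    two_l = 2.0 * p.fold_length
    ld1 = p.fold_length * p.d1
    c1 = p.contact_stiffness_ratio * p.k1
    c2 = p.contact_stiffness_ratio * p.k2
    rho = p.air_density
    pressure = p.driving_pressure
    ug_coeff = 1.0 / p.cd_glottis**2
    us = 1.0 / (p.cd_stenosis * a_sgs) ** 2
    q_coeff = math.sqrt(2.0 * pressure / rho) if pressure > 0 else 0.0

    def flow(area_g: float) -> tuple[float, float, float]:
        ug = ug_coeff / area_g**2
        q = q_coeff / math.sqrt(ug + us)
        dpg = pressure * (ug / (ug + us))
        return q, dpg, pressure - dpg

    def deriv(x1, v1, x2, v2):
        a1 = p.rest_area1 + two_l * x1
        a2 = p.rest_area2 + two_l * x2
        a1f = a1 if a1 > floor else floor
        a2f = a2 if a2 > floor else floor
        ag = a1f if a1f < a2f else a2f
        _, dpg, _ = flow(ag)
        # Bernoulli pressure on the lower element; separation at the minimum
        # section leaves the upper element unloaded (full recovery loss).
        p1 = dpg * (1.0 - (ag / a1f) ** 2)
        f1 = p1 * ld1
        fc1 = c1 * (floor - a1) / two_l if a1 < floor else 0.0
        fc2 = c2 * (floor - a2) / two_l if a2 < floor else 0.0
        acc1 = (f1 + fc1 - p.r1 * v1 - p.k1 * x1 - p.kc * (x1 - x2)) / p.m1
        acc2 = (fc2 - p.r2 * v2 - p.k2 * x2 - p.kc * (x2 - x1)) / p.m2
        return v1, acc1, v2, acc2

    n_steps = int(round(duration / p.dt))
    if n_steps < 10:
        raise ValueError("duration too short for the configured timestep")

    x1 = initial_displacement
    x2 = 0.0
    v1 = v2 = 0.0
    if seed is not None:
        rng = np.random.default_rng(seed)
        x1 += rng.normal(0.0, 0.1 * initial_displacement)
        x2 += rng.normal(0.0, 0.1 * initial_displacement)

    time = np.arange(n_steps + 1) * p.dt
    area = np.empty(n_steps + 1)
    q_out = np.empty(n_steps + 1)
    dpg_out = np.empty(n_steps + 1)
    dps_out = np.empty(n_steps + 1)
    disp = np.empty((n_steps + 1, 2))
    dt = p.dt
    half = dt / 2.0

    for i in range(n_steps + 1):
        a1 = p.rest_area1 + two_l * x1
        a2 = p.rest_area2 + two_l * x2
        a1f = a1 if a1 > floor else floor
        a2f = a2 if a2 > floor else floor
        ag = a1f if a1f < a2f else a2f
        q, dpg, dps = flow(ag)
        area[i] = ag
        q_out[i] = q
        dpg_out[i] = dpg
        dps_out[i] = dps
        disp[i, 0] = x1
        disp[i, 1] = x2
        if i == n_steps:
            break
        k1_ = deriv(x1, v1, x2, v2)
        k2_ = deriv(x1 + half * k1_[0], v1 + half * k1_[1],
                    x2 + half * k1_[2], v2 + half * k1_[3])
        k3_ = deriv(x1 + half * k2_[0], v1 + half * k2_[1],
                    x2 + half * k2_[2], v2 + half * k2_[3])
        k4_ = deriv(x1 + dt * k3_[0], v1 + dt * k3_[1],
                    x2 + dt * k3_[2], v2 + dt * k3_[3])
        x1 += dt / 6.0 * (k1_[0] + 2 * k2_[0] + 2 * k3_[0] + k4_[0])
        v1 += dt / 6.0 * (k1_[1] + 2 * k2_[1] + 2 * k3_[1] + k4_[1])
        x2 += dt / 6.0 * (k1_[2] + 2 * k2_[2] + 2 * k3_[2] + k4_[2])
        v2 += dt / 6.0 * (k1_[3] + 2 * k2_[3] + 2 * k3_[3] + k4_[3])

    # oscillation flag: sustained area excursion over the final quarter
    tail = area[3 * len(area) // 4:]
    oscillating = bool(
        pressure > 0 and (tail.max() - tail.min()) > 0.05 * max(p.rest_area1, floor)
    )

    weights = _surface_weights(_N_SURFACE_POINTS)
    surface = disp @ weights.T

    return CycleSeries(
        time=time,
        glottal_area=area,
        flow_rate=q_out,
        dp_glottis=dpg_out,
        dp_stenosis=dps_out,
        displacements=surface,
        params=p,
        sgs=sgs,
        oscillating=oscillating,
    )


def fold_kinematics(series: CycleSeries, discard_initial: int = 2) -> np.ndarray:
    """Snapshot matrix of medial-surface displacements over steady cycles.

    Rows are time snapshots restricted to the steady cycles of the run
    (the first ``discard_initial`` cycles hold the start-up transient and
    are dropped); columns are displacement degrees of freedom.
    """
    from .metrics import detect_cycles

    boundaries = detect_cycles(series.time, series.glottal_area,
                               discard_initial=discard_initial)
    if len(boundaries) < 3:
        raise ValueError("need at least 2 steady cycles for kinematics")
    mask = (series.time >= boundaries[0]) & (series.time <= boundaries[-1])
    return series.displacements[mask]
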