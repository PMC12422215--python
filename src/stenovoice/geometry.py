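"""Idealized subglottic-stenosis (SGS) geometry.

The stenosis is modelled as a smooth cosine constriction of an otherwise
straight subglottal tube: every surface point inside an axial window of
length ``L`` is pulled toward the centerline by a factor that vanishes at
the window ends and peaks mid-window.  The single shape parameter ``a`` is
the fractional reduction of the transverse dimensions at the narrowest
section, so the narrowest cross-sectional area is reduced by
``severity = 1 - (1 - a)**2``.

Severity maps onto the four-grade clinical scale used for subglottic
stenosis (Grade I below 50% obstruction up to Grade IV, complete
obstruction).

The axial coordinate is ``y`` (inferior–superior); ``x`` and ``z`` span the
cross-section.  All lengths are metres, areas m².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SGSSpec",
    "AirwaySection",
    "apply_sgs",
    "severity_of",
    "diameter_reduction_of",
    "min_cross_section_area",
    "grade_of",
    "circular_section",
    "polygon_area",
    "constricted_area_numeric",
    "export_constricted_surface",
]


def severity_of(a: float) -> float:
    """Fractional area reduction at the narrowest section for diameter
    reduction ``a``.

    Both transverse axes scale by ``(1 - a)`` at the narrowest section, so
    the area scales by ``(1 - a)**2`` and the severity is ``1 - (1 - a)**2``.

    Parameters
    ----------
    a : float
        Fractional reduction of the transverse dimensions, ``0 <= a < 1``.
    """
    if not 0.0 <= a < 1.0:
        raise ValueError(f"diameter reduction a must be in [0, 1), got {a}")
    return 1.0 - (1.0 - a) ** 2


def diameter_reduction_of(severity: float) -> float:
    """Inverse of :func:`severity_of`: the ``a`` producing a given severity."""
    if not 0.0 <= severity < 1.0:
        raise ValueError(f"severity must be in [0, 1), got {severity}")
    return 1.0 - math.sqrt(1.0 - severity)


@dataclass(frozen=True)
class SGSSpec:
    """Parameters of the idealized subglottic constriction.

    Parameters
    ----------
    a : float
        Fractional reduction of the transverse dimensions at the narrowest
        section (``0 <= a < 1``).  ``a = 0`` is the unconstricted baseline.
    length : float
        Axial extent ``L`` of the constriction in metres (default 1.0 cm,
        the most common clinical SGS length).
    location : float
        Distance from the narrowest SGS section to the superior vocal-fold
        surface, metres.  The study sweeps use 2.1 cm and 3.13 cm.
    """

    a: float = 0.0
    length: float = 0.01
    location: float = 0.0313

    def __post_init__(self) -> None:
        if not 0.0 <= self.a < 1.0:
            raise ValueError(f"diameter reduction a must be in [0, 1), got {self.a}")
        if self.length <= 0:
            raise ValueError(f"SGS length must be positive, got {self.length}")
        if self.location <= 0:
            raise ValueError(f"SGS location must be positive, got {self.location}")

    @property
    def severity(self) -> float:
        """Fractional area reduction at the narrowest section."""
        return severity_of(self.a)

    @classmethod
    def from_severity(
        cls, severity: float, length: float = 0.01, location: float = 0.0313
    ) -> "SGSSpec":
        """Build a spec from a target fractional area reduction."""
        return cls(a=diameter_reduction_of(severity), length=length, location=location)

    @property
    def grade(self) -> str:
        return grade_of(self.severity)


@dataclass(frozen=True)
class AirwaySection:
    """One cross-section of the (circular) idealized airway."""

    axial_position: float
    area: float
    hydraulic_diameter: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("section area must be positive")
        if self.hydraulic_diameter == 0.0:
            # circular section: hydraulic diameter equals the diameter
            object.__setattr__(
                self, "hydraulic_diameter", 2.0 * math.sqrt(self.area / math.pi)
            )
        if self.hydraulic_diameter <= 0:
            raise ValueError("hydraulic diameter must be positive")


def _scale_factor(a: float, yc, length: float):
    """Transverse scale factor 1 - (a/2)(1 - cos(2π yc / L))."""
    return 1.0 - (a / 2.0) * (1.0 - np.cos(2.0 * np.pi * np.asarray(yc) / length))


def apply_sgs(
    surface_points: np.ndarray,
    spec: SGSSpec,
    window_start: float = 0.0,
    atol: float = 1e-12,
) -> np.ndarray:
    """Apply the cosine constriction to surface points inside the SGS window.

    Each point ``(x, y, z)`` with axial distance ``yc = y - window_start``
    from the inferior end of the window maps to::

        x -> x * (1 - (a/2) * (1 - cos(2π yc / L)))
        z -> z * (1 - (a/2) * (1 - cos(2π yc / L)))
        y -> y

    so the section at mid-window (``yc = L/2``) shrinks by the full factor
    ``1 - a`` per axis and the window ends are untouched.

    Parameters
    ----------
    surface_points : (n, 3) array
        Points ``(x, y, z)``; the x/z origin must be on the tube centerline.
    spec : SGSSpec
        Constriction parameters.
    window_start : float
        Axial coordinate of the inferior end of the SGS window.

    Returns
    -------
    (n, 3) array of mapped points.
    """
    pts = np.atleast_2d(np.asarray(surface_points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("surface_points must have shape (n, 3)")
    yc = pts[:, 1] - window_start
    if np.any(yc < -atol) or np.any(yc > spec.length + atol):
        raise ValueError(
            "points must lie inside the SGS axial window "
            f"[{window_start}, {window_start + spec.length}]"
        )
    s = _scale_factor(spec.a, yc, spec.length)
    out = pts.copy()
    out[:, 0] *= s
    out[:, 2] *= s
    return out


def min_cross_section_area(spec: SGSSpec, unconstricted_area: float) -> float:
    """Area of the narrowest section: ``unconstricted_area * (1 - severity)``."""
    if unconstricted_area <= 0:
        raise ValueError("unconstricted_area must be positive")
    return unconstricted_area * (1.0 - spec.severity)


def grade_of(severity: float) -> str:
    """Clinical grade (Myer–Cotton style) for a fractional area reduction.

    Grade I covers obstructions up to 50%, Grade II up to 70%, Grade III
    everything short of complete obstruction, and Grade IV a fully occluded
    lumen.  The published ranges leave gaps ("below 50", "51–70"); boundaries
    here are closed on the upper end of each grade.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    if severity <= 0.50:
        return "I"
    if severity <= 0.70:
        return "II"
    if severity < 1.0:
        return "III"
    return "IV"


# ---------------------------------------------------------------------------
# numeric helpers (also the oracle path for the a <-> severity law)


def circular_section(
    radius: float, n_points: int, axial_position: float = 0.0
) -> np.ndarray:
    """Points on a circle of given radius in the plane y = axial_position."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return np.column_stack(
        [
            radius * np.cos(theta),
            np.full(n_points, float(axial_position)),
            radius * np.sin(theta),
        ]
    )


def polygon_area(x: np.ndarray, z: np.ndarray) -> float:
    """Shoelace area of a closed polygon given by vertex coordinates."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    return 0.5 * abs(np.dot(x, np.roll(z, -1)) - np.dot(z, np.roll(x, -1)))


def constricted_area_numeric(
    a: float,
    yc: float | None = None,
    length: float = 0.01,
    radius: float = 0.004,
    n_points: int = 20000,
) -> tuple[float, float]:
    """Numerically integrate the constricted circular section's area.

    Maps a densely sampled circle through :func:`apply_sgs` at axial station
    ``yc`` (default mid-window, the narrowest section) and integrates the
    resulting polygon.  Returns ``(constricted_area, unconstricted_area)``.
    """
    spec = SGSSpec(a=a, length=length)
    if yc is None:
        yc = length / 2.0
    circle = circular_section(radius, n_points, axial_position=yc)
    mapped = apply_sgs(circle, spec)
    area0 = polygon_area(circle[:, 0], circle[:, 2])
    area = polygon_area(mapped[:, 0], mapped[:, 2])
    return area, area0


def export_constricted_surface(
    spec: SGSSpec,
    path: str,
    radius: float = 0.004,
    n_axial: int = 64,
    n_circ: int = 64,
    window_start: float = 0.0,
):
    """Export the constricted tube segment as a triangle mesh (OBJ/STL).

    Requires the optional ``trimesh`` dependency.
    """
    import trimesh  # optional dependency

    ys = np.linspace(0.0, spec.length, n_axial) + window_start
    rings = [
        apply_sgs(circular_section(radius, n_circ, axial_position=y), spec,
                  window_start=window_start)
        for y in ys
    ]
    vertices = np.vstack(rings)
    faces = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a0 = i * n_circ + j
            a1 = i * n_circ + (j + 1) % n_circ
            b0 = a0 + n_circ
            b1 = a1 + n_circ
            faces.append([a0, a1, b1])
            faces.append([a0, b1, b0])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    mesh.export(path)
    return mesh
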