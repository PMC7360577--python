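"""X-ray source models: point, fan and cone beams, multi-view CT arrangements,
and group-wise emission spectra.

Angles follow the CT convention: a cone beam's aperture is the set of
directions within the polar half-angle of the beam axis; a fan beam is
bounded separately by an azimuthal half-angle (in the axial plane containing
the axis) and a polar half-angle (out of that plane).  Aperture boundaries
are inclusive.  Cone and point sources emit uniformly over solid angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .xs import EnergyGroupStructure

__all__ = [
    "SourceSpec",
    "BeamSet",
    "make_point_source",
    "make_cone_beam",
    "make_fan_beam",
    "make_ct_scan",
    "kramers_spectrum",
    "uniform_spectrum",
    "emission_direction_contains",
    "beam_frame",
]

_KINDS = ("point", "fan", "cone")


@dataclass
class SourceSpec:
    """One X-ray source: kind, position (mm), axis, aperture, spectrum."""

    kind: str
    position: np.ndarray
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    azimuthal_half_angle_deg: float = 0.0  # phi; fan only
    polar_half_angle_deg: float = 0.0  # theta; fan and cone
    group_weights: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown source kind '{self.kind}'")
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("axis must be nonzero")
        self.axis = self.axis / n
        gw = np.asarray(self.group_weights, dtype=float)
        if np.any(gw < 0) or gw.sum() <= 0:
            raise ValueError("group_weights must be >= 0 and sum > 0")
        self.group_weights = gw / gw.sum()

    @property
    def solid_angle_fraction(self) -> float:
        """Fraction of 4*pi into which the source emits."""
        if self.kind == "point":
            return 1.0
        th = math.radians(self.polar_half_angle_deg)
        if self.kind == "cone":
            return 0.5 * (1.0 - math.cos(th))
        # fan: integral over |alpha| <= phi, |beta| <= theta of cos(beta)
        ph = math.radians(self.azimuthal_half_angle_deg)
        return (2.0 * ph) * (2.0 * math.sin(th)) / (4.0 * math.pi)


@dataclass
class BeamSet:
    """Ordered sources sharing one source particle in equal shares."""

    sources: list[SourceSpec]

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("BeamSet needs at least one source")

    @property
    def shares(self) -> np.ndarray:
        n = len(self.sources)
        return np.full(n, 1.0 / n)


def make_point_source(position, group_weights) -> SourceSpec:
    return SourceSpec("point", position, group_weights=group_weights)


def make_cone_beam(position, axis, half_angle_deg: float, group_weights) -> SourceSpec:
    return SourceSpec(
        "cone", position, axis, polar_half_angle_deg=half_angle_deg, group_weights=group_weights
    )


def make_fan_beam(position, axis, phi_deg: float, theta_deg: float, group_weights) -> SourceSpec:
    return SourceSpec(
        "fan",
        position,
        axis,
        azimuthal_half_angle_deg=phi_deg,
        polar_half_angle_deg=theta_deg,
        group_weights=group_weights,
    )


def make_ct_scan(
    n_views: int,
    radius_mm: float,
    cone_full_angle_deg: float,
    center_mm,
    group_weights,
) -> BeamSet:
    """Cone beams equally spaced on a circle in the central axial plane.

    ``cone_full_angle_deg`` is the full apex angle (a "30 degree cone" has a
    15 degree half-angle); every beam aims at ``center_mm`` with an equal
    share of one source particle.
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    center = np.asarray(center_mm, dtype=float)
    srcs = []
    for i in range(n_views):
        a = 2.0 * math.pi * i / n_views
        offset = radius_mm * np.array([math.cos(a), math.sin(a), 0.0])
        pos = center + offset
        srcs.append(
            make_cone_beam(pos, center - pos, 0.5 * cone_full_angle_deg, group_weights)
        )
    return BeamSet(srcs)


def kramers_spectrum(peak_keV: float, groups: EnergyGroupStructure) -> np.ndarray:
    """Bremsstrahlung-shaped group weights, intensity per keV ~ (peak - E)/E.

    Weight of group g is the integral of max(0, (peak-E)/E) over the group,
    normalized to 1; groups entirely above the peak get zero.
    """
    b = np.asarray(groups.boundaries)
    if peak_keV <= b[-1]:
        raise ValueError("peak energy below the lowest group boundary")
    hi = np.minimum(b[:-1], peak_keV)
    lo = b[1:]
    w = np.zeros(groups.G)
    ok = hi > lo
    # integral of (peak - E)/E dE = peak*ln(E) - E
    w[ok] = peak_keV * np.log(hi[ok] / lo[ok]) - (hi[ok] - lo[ok])
    w = np.clip(w, 0.0, None)
    return w / w.sum()


def uniform_spectrum(groups: EnergyGroupStructure) -> np.ndarray:
    return np.full(groups.G, 1.0 / groups.G)


def beam_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (u, v, w) with w = axis; u lies in the axial (z=const) plane."""
    w = np.asarray(axis, dtype=float)
    w = w / np.linalg.norm(w)
    zhat = np.array([0.0, 0.0, 1.0])
    u = np.cross(zhat, w)
    nu = np.linalg.norm(u)
    if nu < 1e-12:  # axis parallel to z: any transverse pair works
        u = np.array([1.0, 0.0, 0.0])
    else:
        u = u / nu
    v = np.cross(w, u)
    return u, v, w


def emission_direction_contains(s: SourceSpec, direction) -> bool:
    """True iff ``direction`` lies inside the beam aperture (boundary inside)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if s.kind == "point":
        return True
    if s.kind == "cone":
        cos_th = math.cos(math.radians(s.polar_half_angle_deg))
        return float(d @ s.axis) >= cos_th - 1e-12
    # fan: azimuthal angle in the (w, u) plane, polar out-of-plane angle
    u, v, w = beam_frame(s.axis)
    dw, du, dv = float(d @ w), float(d @ u), float(d @ v)
    if dw <= 0:
        return False
    azim = math.degrees(math.atan2(abs(du), dw))
    polar = math.degrees(math.asin(max(-1.0, min(1.0, abs(dv)))))
    return (
        azim <= s.azimuthal_half_angle_deg + 1e-9
        and polar <= s.polar_half_angle_deg + 1e-9
    )
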