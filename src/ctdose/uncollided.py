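"""Analytic uncollided fluence by voxel ray tracing, and the first-collision
source that drives the collided-fluence transport solve.

The uncollided fluence of an external source can be written in closed form
(inverse-square geometry times Beer-Lambert attenuation along the sight line),
which a ray tracer evaluates exactly on the voxel grid.  Scattering of that
uncollided field produces an emission density — the first-collision source —
which replaces the external source in the discrete-ordinates solve; this is
the standard mitigation for ray effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import uncollided_one_source
from .phantom import VoxelPhantom
from .source import BeamSet, SourceSpec, beam_frame
from .xs import XSLibrary

__all__ = [
    "FluenceField",
    "FirstCollisionSource",
    "trace_path",
    "uncollided_fluence",
    "first_collision_source",
    "voxel_sigma_t",
    "voxel_scale",
    "aperture_mask",
]


@dataclass
class FluenceField:
    """Per-group scalar fluence volumes split into uncollided and collided.

    Units: photons per cm^2 per source particle.  ``total`` is elementwise
    ``uncollided + collided``.
    """

    uncollided: np.ndarray  # (G, nx, ny, nz)
    collided: np.ndarray  # (G, nx, ny, nz)

    def __post_init__(self) -> None:
        self.uncollided = np.asarray(self.uncollided, dtype=float)
        self.collided = np.asarray(self.collided, dtype=float)
        if self.uncollided.shape != self.collided.shape:
            raise ValueError("uncollided/collided shape mismatch")
        for arr, nm in ((self.uncollided, "uncollided"), (self.collided, "collided")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{nm} fluence has non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{nm} fluence has negative values")

    @property
    def G(self) -> int:
        return self.uncollided.shape[0]

    @property
    def total(self) -> np.ndarray:
        return self.uncollided + self.collided


@dataclass
class FirstCollisionSource:
    """Emission-density moments of the first collision of uncollided photons.

    ``q0[g]`` is the angle-integrated emission density (per cm^3); ``q1[g]``
    is the first angular moment as a Cartesian vector field (None for a
    purely isotropic build), accumulated source-by-source so each source's
    own sight-line direction weights its anisotropy.
    """

    q0: np.ndarray  # (G, nx, ny, nz)
    q1: np.ndarray | None = None  # (G, nx, ny, nz, 3)

    @property
    def G(self) -> int:
        return self.q0.shape[0]


# ---------------------------------------------------------------------------
# Media helpers

def voxel_scale(phantom: VoxelPhantom, xslib: XSLibrary) -> np.ndarray:
    """Per-voxel density / reference-density factor for cross-section scaling."""
    ref = np.array([m.reference_density for m in xslib.materials])
    return (phantom.density / ref[phantom.material_index]).astype(np.float64)


def voxel_sigma_t(phantom: VoxelPhantom, xslib: XSLibrary) -> np.ndarray:
    """Per-voxel total macroscopic cross section, shape (G, nx, ny, nz), 1/cm."""
    st = np.array([m.sigma_t for m in xslib.materials])  # (nmat, G)
    scale = voxel_scale(phantom, xslib)
    out = st[phantom.material_index]  # (nx, ny, nz, G)
    out = np.moveaxis(out, -1, 0) * scale[None, :, :, :]
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# Ray tracing

def trace_path(phantom: VoxelPhantom, p0, p1):
    """Exact voxel traversal of the segment p0 -> p1 (mm).

    Returns an ordered list of ``((i, j, k), chord_mm)`` from p0 toward p1;
    chord lengths sum to the in-grid portion of the segment.  A segment
    entirely outside the grid gives an empty list.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    seg = float(np.linalg.norm(d))
    if seg == 0.0:
        raise ValueError("p0 and p1 coincide")
    lo = phantom.origin
    hi = phantom.origin + phantom.extent_mm()
    tmin, tmax = 0.0, 1.0
    for a in range(3):
        if abs(d[a]) < 1e-300:
            if p0[a] < lo[a] or p0[a] >= hi[a]:
                return []
        else:
            t1 = (lo[a] - p0[a]) / d[a]
            t2 = (hi[a] - p0[a]) / d[a]
            if t1 > t2:
                t1, t2 = t2, t1
            tmin = max(tmin, t1)
            tmax = min(tmax, t2)
    if tmax <= tmin:
        return []
    shape = phantom.shape
    sp = phantom.spacing
    out = []
    t = tmin
    eps = 1e-12
    while t < tmax - eps:
        tprobe = t + 1e-9 * (tmax - tmin)
        idx = np.floor((p0 + tprobe * d - lo) / sp).astype(int)
        idx = np.clip(idx, 0, np.asarray(shape) - 1)
        tnext = tmax
        for a in range(3):
            if abs(d[a]) > 1e-300:
                step = 1 if d[a] > 0 else 0
                ta = (lo[a] + (idx[a] + step) * sp[a] - p0[a]) / d[a]
                tnext = min(tnext, ta) if ta > t + eps else tnext
        tnext = min(max(tnext, t + eps), tmax)
        out.append(((int(idx[0]), int(idx[1]), int(idx[2])), (tnext - t) * seg))
        t = tnext
    return out


def aperture_mask(phantom: VoxelPhantom, s: SourceSpec) -> np.ndarray:
    """Boolean (nx, ny, nz) mask of voxel centers inside the beam aperture.

    Vectorized twin of :func:`ctdose.source.emission_direction_contains`
    (boundary voxels included).
    """
    xc, yc, zc = phantom.voxel_centers()
    X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
    D = np.stack([X - s.position[0], Y - s.position[1], Z - s.position[2]])
    norm = np.sqrt((D**2).sum(axis=0))
    if np.any(norm == 0):
        raise ValueError("source position coincides with a voxel center")
    if s.kind == "point":
        return np.ones(phantom.shape, dtype=bool)
    if s.kind == "cone":
        cos_th = np.cos(np.radians(s.polar_half_angle_deg))
        dot = np.tensordot(s.axis, D, axes=1)
        return dot >= norm * (cos_th - 1e-12)
    u, v, w = beam_frame(s.axis)
    dw = np.tensordot(w, D, axes=1)
    du = np.tensordot(u, D, axes=1)
    dv = np.tensordot(v, D, axes=1) / norm
    azim = np.degrees(np.arctan2(np.abs(du), dw))
    polar = np.degrees(np.arcsin(np.clip(np.abs(dv), -1.0, 1.0)))
    return (
        (dw > 0)
        & (azim <= s.azimuthal_half_angle_deg + 1e-9)
        & (polar <= s.polar_half_angle_deg + 1e-9)
    )


def uncollided_fluence(
    phantom: VoxelPhantom,
    beams: BeamSet | SourceSpec,
    xslib: XSLibrary,
    per_source: bool = False,
):
    """Uncollided scalar fluence at voxel centers, per source particle.

    Each source contributes ``share * spectrum_g / (4 pi d_cm^2) *
    exp(-integral sigma_t dl)`` at voxels inside its aperture.  Returns
    (G, nx, ny, nz); with ``per_source=True`` returns (S, G, nx, ny, nz).
    """
    if isinstance(beams, SourceSpec):
        beams = BeamSet([beams])
    sigma_t = voxel_sigma_t(phantom, xslib)
    G = xslib.G
    shares = beams.shares
    shp = phantom.shape
    fields = np.zeros((len(beams.sources), G) + shp)
    for si, s in enumerate(beams.sources):
        if s.group_weights.shape[0] != G:
            raise ValueError("source spectrum length != number of groups")
        mask = aperture_mask(phantom, s)
        ii, jj, kk = np.nonzero(mask)
        spec_share = shares[si] * s.group_weights
        uncollided_one_source(
            np.asarray(s.position, dtype=np.float64),
            phantom.origin.astype(np.float64),
            phantom.spacing.astype(np.float64),
            sigma_t,
            spec_share.astype(np.float64),
            ii.astype(np.int64),
            jj.astype(np.int64),
            kk.astype(np.int64),
            fields[si],
        )
    total = fields.sum(axis=0)
    if per_source:
        return total, fields
    return total


def _material_moment_arrays(xslib: XSLibrary, l: int) -> np.ndarray:
    return np.array([m.scatter_moments[l] for m in xslib.materials])  # (nmat, G, G)


def first_collision_source(
    phantom: VoxelPhantom,
    xslib: XSLibrary,
    phi_u_per_source: np.ndarray,
    source_positions,
    L: int = 0,
    chunk: int = 262144,
) -> FirstCollisionSource:
    """Scattering emission moments of the uncollided field.

    ``q0[g] = sum_s sum_g' sigma_s0[g'->g] phi_u_s[g']``; for ``L >= 1`` the
    vector moment uses each source's per-voxel sight-line direction
    ``u_v = (c_v - pos_s)/|c_v - pos_s|``.
    """
    if L > xslib.legendre_order:
        raise ValueError(f"L={L} exceeds library order {xslib.legendre_order}")
    G = xslib.G
    shp = phantom.shape
    nvox = int(np.prod(shp))
    scale = voxel_scale(phantom, xslib).ravel()
    mat = phantom.material_index.ravel()
    s0 = _material_moment_arrays(xslib, 0)
    phi_tot = phi_u_per_source.sum(axis=0).reshape(G, nvox)
    q0 = np.zeros((G, nvox))
    for lo in range(0, nvox, chunk):
        hi = min(lo + chunk, nvox)
        m0 = s0[mat[lo:hi]] * scale[lo:hi, None, None]  # (v, g', g)
        q0[:, lo:hi] = np.einsum("gv,vgh->hv", phi_tot[:, lo:hi], m0)
    q0 = q0.reshape((G,) + shp)

    q1 = None
    if L >= 1:
        s1 = _material_moment_arrays(xslib, 1)
        xc, yc, zc = phantom.voxel_centers()
        X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
        C = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)  # (v, 3)
        q1 = np.zeros((G, nvox, 3))
        for si, pos in enumerate(source_positions):
            U = C - np.asarray(pos, dtype=float)[None, :]
            U /= np.linalg.norm(U, axis=1)[:, None]
            phis = phi_u_per_source[si].reshape(G, nvox)
            for lo in range(0, nvox, chunk):
                hi = min(lo + chunk, nvox)
                m1 = s1[mat[lo:hi]] * scale[lo:hi, None, None]
                amp = np.einsum("gv,vgh->hv", phis[:, lo:hi], m1)  # (G, v)
                q1[:, lo:hi, :] += amp[:, :, None] * U[None, lo:hi, :]
        q1 = q1.reshape((G,) + shp + (3,))
    return FirstCollisionSource(q0, q1)
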