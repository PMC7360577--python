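"""Discrete-ordinates solution of the collided-fluence transport equation.

Diamond-difference spatial sweeps over all quadrature directions, vacuum
boundary conditions, unaccelerated source iteration on the within-group
scattering source, groups solved in strictly descending energy order
(downscatter-only physics makes a single pass over groups exact).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

from ._kernels import sweep_group_kernel
from .phantom import VoxelPhantom
from .quadrature import QuadratureSet, build_level_symmetric
from .uncollided import FirstCollisionSource, voxel_scale, voxel_sigma_t
from .xs import XSLibrary

__all__ = [
    "SolverConfig",
    "GroupDiagnostics",
    "SolveResult",
    "sweep_group",
    "solve_collided",
    "particle_balance",
]


@dataclass
class SolverConfig:
    """Angular order, anisotropy order and iteration controls."""

    sn: int = 6
    pn: int = 0
    tol: float = 1e-6
    max_iters: int = 200
    fixup: bool = True

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.pn not in (0, 1):
            raise ValueError("pn must be 0 or 1")


@dataclass
class GroupDiagnostics:
    group: int
    iterations: int
    residuals: list[float] = field(default_factory=list)
    converged: bool = True
    leakage: float = 0.0
    fixups: int = 0


@dataclass
class SolveResult:
    """Converged collided fluence with per-group iteration diagnostics."""

    collided: np.ndarray  # (G, nx, ny, nz)
    current: np.ndarray  # (G, nx, ny, nz, 3)
    diagnostics: list[GroupDiagnostics]

    @property
    def converged(self) -> bool:
        return all(d.converged for d in self.diagnostics)

    @property
    def total_leakage(self) -> float:
        return float(sum(d.leakage for d in self.diagnostics))


def _dummy_q1(shape) -> np.ndarray:
    return np.zeros((1, 1, 1, 3))


def sweep_group(
    sigma_t_g: np.ndarray,
    q0: np.ndarray,
    q: QuadratureSet,
    spacing_cm,
    q1: np.ndarray | None = None,
    fixup: bool = True,
    store_angular: bool = False,
):
    """One transport sweep of all directions for a single group.

    ``sigma_t_g`` and ``q0`` are per-voxel (nx, ny, nz); ``q1`` is the vector
    source moment (nx, ny, nz, 3) or None for isotropic.  Returns
    (phi, J, leakage, n_fixups) and, with ``store_angular``, the per-direction
    fluence as a fifth element.
    """
    shp = sigma_t_g.shape
    phi = np.zeros(shp)
    J = np.zeros(shp + (3,))
    use_p1 = q1 is not None
    q1a = q1 if use_p1 else _dummy_q1(shp)
    if store_angular:
        psi = np.zeros((q.n_directions,) + shp)
    else:
        psi = np.zeros((1, 1, 1, 1))
    leak, nfix = sweep_group_kernel(
        np.ascontiguousarray(sigma_t_g),
        np.ascontiguousarray(q0),
        np.ascontiguousarray(q1a),
        use_p1,
        np.ascontiguousarray(q.directions),
        np.ascontiguousarray(q.weights),
        np.asarray(spacing_cm, dtype=float),
        fixup,
        phi,
        J,
        store_angular,
        psi,
    )
    if not np.all(np.isfinite(phi)):
        bad = np.argwhere(~np.isfinite(phi))[0]
        raise FloatingPointError(f"non-finite angular fluence at voxel {tuple(bad)}")
    if store_angular:
        return phi, J, leak, nfix, psi
    return phi, J, leak, nfix


def solve_collided(
    phantom: VoxelPhantom,
    xslib: XSLibrary,
    q: QuadratureSet | None,
    fcs: FirstCollisionSource,
    config: SolverConfig | None = None,
) -> SolveResult:
    """Solve for the collided fluence given a first-collision source.

    Groups are solved in descending energy order; each group's fixed source is
    the first-collision moments plus downscatter from already-solved groups;
    the within-group scattering source is lagged and iterated to a relative
    L-infinity tolerance on the group scalar fluence.  Non-convergence at
    ``max_iters`` is flagged in the diagnostics, not raised.
    """
    config = config or SolverConfig()
    if q is None:
        q = build_level_symmetric(config.sn)
    G = xslib.G
    use_p1 = config.pn >= 1 and xslib.legendre_order >= 1
    shp = phantom.shape
    spacing_cm = phantom.spacing / 10.0
    sigma_t = voxel_sigma_t(phantom, xslib)
    scale = voxel_scale(phantom, xslib)
    mat = phantom.material_index
    s0 = np.array([m.scatter_moments[0] for m in xslib.materials])
    s1 = None
    if use_p1:
        s1 = np.array([m.scatter_moments[1] for m in xslib.materials])

    phi_all = np.zeros((G,) + shp)
    J_all = np.zeros((G,) + shp + (3,))
    diags: list[GroupDiagnostics] = []
    for g in range(G):
        # fixed source: first-collision + downscatter from higher-energy groups
        base_q0 = fcs.q0[g].copy()
        base_q1 = None
        if use_p1:
            base_q1 = fcs.q1[g].copy() if fcs.q1 is not None else np.zeros(shp + (3,))
        for gp in range(g):
            xfer0 = s0[mat, gp, g] * scale
            if np.any(xfer0):
                base_q0 += xfer0 * phi_all[gp]
                if use_p1:
                    base_q1 += (s1[mat, gp, g] * scale)[..., None] * J_all[gp]
        within0 = s0[mat, g, g] * scale
        within1 = (s1[mat, g, g] * scale) if use_p1 else None

        phi = np.zeros(shp)
        J = np.zeros(shp + (3,))
        d = GroupDiagnostics(group=g, iterations=0)
        leak = 0.0
        nfix = 0
        for it in range(config.max_iters):
            q0 = base_q0 + within0 * phi
            q1 = None
            if use_p1:
                q1 = base_q1 + within1[..., None] * J
            phi_new, J, leak, nfix = sweep_group(
                sigma_t[g], q0, q, spacing_cm, q1=q1, fixup=config.fixup
            )
            denom = np.max(np.abs(phi_new))
            res = 1.0 if denom == 0 else float(
                np.max(np.abs(phi_new - phi)) / denom
            )
            phi = phi_new
            d.iterations = it + 1
            d.residuals.append(res)
            logger.debug("sweep group=%d iter=%d residual=%.3e fixups=%d", g, it + 1, res, nfix)
            if res < config.tol or not np.any(within0):
                break
        d.converged = d.residuals[-1] < config.tol or not np.any(within0)
        d.leakage = float(leak)
        d.fixups = int(nfix)
        diags.append(d)
        phi_all[g] = phi
        J_all[g] = J
    return SolveResult(phi_all, J_all, diags)


def particle_balance(
    phantom: VoxelPhantom,
    xslib: XSLibrary,
    collided: np.ndarray,
    fcs: FirstCollisionSource,
    leakage: float,
) -> dict:
    """Global conservation bookkeeping for a converged collided solve.

    emission = sum of first-collision source over volume; absorption uses the
    effective absorption cross section (true absorption plus sub-cutoff
    removal); closure = |emission - absorption - leakage| / emission.
    """
    V = phantom.voxel_volume_cm3
    scale = voxel_scale(phantom, xslib)
    mat = phantom.material_index
    sig_a = np.array([m.sigma_a() for m in xslib.materials])  # (nmat, G)
    emission = float(fcs.q0.sum() * V)
    absorption = 0.0
    for g in range(xslib.G):
        absorption += float(np.sum(sig_a[mat, g] * scale * collided[g]) * V)
    closure = abs(emission - absorption - leakage) / emission if emission > 0 else 0.0
    return {
        "emission": emission,
        "absorption": absorption,
        "leakage": leakage,
        "closure": closure,
    }
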