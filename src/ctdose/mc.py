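"""Analog multigroup Monte Carlo photon transport with track-length tallies.

Shares the phantom, multigroup cross sections and source model with the
deterministic solver, so that deterministic-vs-stochastic discrepancies
isolate the angular and spatial discretization rather than the data.  Volume-
averaged fluence tallies (track length per voxel volume, per source particle)
are split by collision count into uncollided (0 collisions) and collided
(>= 1); batch statistics provide per-voxel relative standard errors.
Scattering samples the outgoing group from the zeroth-moment transfer matrix
and the deflection cosine from the linear (P1-truncated) density
(1 + a mu)/2 with a = 3 sigma_s1/sigma_s0 clipped to [-1, 1]; no variance
reduction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import mc_batch_kernel
from .dosimetry import DoseFactors, DoseMap, default_dose_factors
from .phantom import MAT_AIR, VoxelPhantom
from .source import BeamSet, SourceSpec, beam_frame
from .uncollided import voxel_scale
from .xs import XSLibrary

__all__ = ["MCTally", "run_mc", "mc_uncertainty_map"]

_KIND_CODE = {"point": 0, "cone": 1, "fan": 2}


@dataclass
class MCTally:
    """Batched track-length tallies: means, standard errors, provenance."""

    uncollided: np.ndarray  # (G, nx, ny, nz) mean fluence per source particle
    collided: np.ndarray
    uncollided_se: np.ndarray  # absolute standard error of the mean
    collided_se: np.ndarray
    dose: np.ndarray  # (nx, ny, nz) pSv per source particle (air not yet zeroed)
    dose_se: np.ndarray
    histories: int
    batches: int
    seed: int
    clipped_pairs: int  # (material, g, g') entries with |3 mu_bar| clipped to 1

    @property
    def G(self) -> int:
        return self.uncollided.shape[0]


def _relative_error(mean: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Relative standard error; masked (invalid) where the mean is zero."""
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, se / np.where(mean > 0, mean, 1.0), np.nan)
    return np.ma.masked_invalid(rel)


def mc_uncertainty_map(tally: MCTally):
    """Per-voxel relative standard error volumes, shape (2, G, nx, ny, nz).

    Index 0 is the uncollided component, 1 the collided; zero-mean tallies
    are masked as undefined.
    """
    if tally.batches < 2:
        raise ValueError("need at least 2 batches for uncertainty estimates")
    return np.ma.stack(
        [
            _relative_error(tally.uncollided, tally.uncollided_se),
            _relative_error(tally.collided, tally.collided_se),
        ]
    )


def _material_tables(xslib: XSLibrary):
    nmat = len(xslib.materials)
    G = xslib.G
    sig_t = np.zeros((nmat, G))
    p_survive = np.zeros((nmat, G))
    grp_cdf = np.zeros((nmat, G, G))
    a_coef = np.zeros((nmat, G, G))
    clipped = 0
    for mi, m in enumerate(xslib.materials):
        sig_t[mi] = m.sigma_t
        s0 = m.scatter_moments[0]
        out = s0.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_survive[mi] = np.where(m.sigma_t > 0, out / np.where(m.sigma_t > 0, m.sigma_t, 1.0), 0.0)
        for g in range(G):
            if out[g] > 0:
                grp_cdf[mi, g] = np.cumsum(s0[g]) / out[g]
        if m.legendre_order >= 1:
            s1 = m.scatter_moments[1]
            nz = s0 > 0
            a = np.zeros_like(s0)
            a[nz] = 3.0 * s1[nz] / s0[nz]
            clipped += int(np.sum(np.abs(a) > 1.0))
            a_coef[mi] = np.clip(a, -1.0, 1.0)
    return sig_t, p_survive, grp_cdf, a_coef, clipped


def _source_tables(beams: BeamSet, G: int):
    S = len(beams.sources)
    pos = np.zeros((S, 3))
    au = np.zeros((S, 3))
    av = np.zeros((S, 3))
    aw = np.zeros((S, 3))
    kind = np.zeros(S, dtype=np.int64)
    cos_half = np.zeros(S)
    phi_deg = np.zeros(S)
    theta_deg = np.zeros(S)
    weight = np.zeros(S)
    spec_cdf = np.zeros((S, G))
    for i, s in enumerate(beams.sources):
        pos[i] = s.position
        u, v, w = beam_frame(s.axis)
        au[i], av[i], aw[i] = u, v, w
        kind[i] = _KIND_CODE[s.kind]
        cos_half[i] = np.cos(np.radians(s.polar_half_angle_deg))
        phi_deg[i] = s.azimuthal_half_angle_deg
        theta_deg[i] = s.polar_half_angle_deg
        # aperture-limited sources tally per isotropic-equivalent particle,
        # matching the 1/(4 pi d^2) convention of the ray tracer
        weight[i] = s.solid_angle_fraction
        if s.group_weights.shape[0] != G:
            raise ValueError("source spectrum length != number of groups")
        spec_cdf[i] = np.cumsum(s.group_weights)
    return pos, au, av, aw, kind, cos_half, phi_deg, theta_deg, weight, spec_cdf


def run_mc(
    phantom: VoxelPhantom,
    xslib: XSLibrary,
    beams: BeamSet | SourceSpec,
    n_histories: int,
    seed: int,
    factors: DoseFactors | None = None,
    batches: int = 10,
) -> tuple[MCTally, DoseMap]:
    """Run analog histories and return tallies plus an effective-dose map.

    Histories are split into ``batches`` equal batches, each with its own
    seeded stream derived from ``seed``; reruns with identical arguments are
    bit-identical.  Tallies are normalized per source particle.
    """
    if isinstance(beams, SourceSpec):
        beams = BeamSet([beams])
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    if seed < 0:
        raise ValueError("seed must be >= 0")
    factors = factors or default_dose_factors()
    G = xslib.G
    shp = phantom.shape
    sig_t, p_survive, grp_cdf, a_coef, clipped = _material_tables(xslib)
    src = _source_tables(beams, G)
    dose_factor = factors.per_group(xslib.groups)
    scale = voxel_scale(phantom, xslib)
    V = phantom.voxel_volume_cm3

    per_batch = n_histories // batches
    counts = [per_batch + (1 if b < n_histories % batches else 0) for b in range(batches)]

    sum_u = np.zeros((G,) + shp)
    sum_c = np.zeros((G,) + shp)
    sq_u = np.zeros((G,) + shp)
    sq_c = np.zeros((G,) + shp)
    sum_d = np.zeros(shp)
    sq_d = np.zeros(shp)
    for b, nh in enumerate(counts):
        if nh == 0:
            continue
        tu = np.zeros((G,) + shp)
        tc = np.zeros((G,) + shp)
        td = np.zeros(shp)
        bseed = int((seed * 2654435761 + 40503 * b + 1) % 2147483647)
        mc_batch_kernel(
            bseed,
            nh,
            phantom.origin.astype(np.float64),
            phantom.spacing.astype(np.float64),
            phantom.material_index,
            scale,
            sig_t,
            p_survive,
            grp_cdf,
            a_coef,
            *src,
            dose_factor,
            tu,
            tc,
            td,
        )
        mu_b = tu / (V * nh)
        mc_b = tc / (V * nh)
        md_b = td / (V * nh)
        sum_u += mu_b
        sum_c += mc_b
        sum_d += md_b
        sq_u += mu_b**2
        sq_c += mc_b**2
        sq_d += md_b**2

    B = len([c for c in counts if c > 0])

    def _stats(s, s2):
        mean = s / B
        if B > 1:
            var = np.maximum(s2 / B - mean**2, 0.0) / (B - 1)
        else:
            var = np.zeros_like(mean)
        return mean, np.sqrt(var)

    mean_u, se_u = _stats(sum_u, sq_u)
    mean_c, se_c = _stats(sum_c, sq_c)
    mean_d, se_d = _stats(sum_d, sq_d)
    tally = MCTally(
        mean_u, mean_c, se_u, se_c, mean_d, se_d, n_histories, B, seed, clipped
    )
    air = phantom.material_index == MAT_AIR
    dose = mean_d.copy()
    dose[air] = 0.0
    dose_map = DoseMap(dose, air)
    return tally, dose_map
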