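"""Fluence-to-effective-dose conversion and run-comparison statistics.

Effective dose per voxel is the group fluence weighted by energy-dependent
fluence-to-dose conversion coefficients (pSv cm^2), interpolated linearly at
group midpoints from a reference table.  Dose in air is zeroed: air kerma is
negligible for patient dose and zeroing also removes residual ray-effect
streaks in the air region.  Comparison statistics (relative-difference maps
and percent RMSD over a central slice within a circular field of view) follow
the conventions used when benchmarking deterministic against Monte Carlo
dose engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import MAT_AIR, VoxelPhantom
from .uncollided import FluenceField
from .xs import EnergyGroupStructure

__all__ = [
    "DoseFactors",
    "DoseMap",
    "ComparisonResult",
    "default_dose_factors",
    "load_dose_factors",
    "fluence_to_dose",
    "relative_difference_map",
    "rmsd_percent",
    "fov_mask",
]

# Embedded reference table: photon fluence-to-effective-dose conversion
# coefficients for anterior-posterior irradiation geometry, 10-100 keV
# (pSv cm^2), in the style of the ICRP publication 116 tabulation.
_REF_ENERGIES_KEV = np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 100.0])
_REF_COEFFS = np.array([0.0685, 0.156, 0.225, 0.313, 0.351, 0.370, 0.390, 0.413, 0.444, 0.519])


@dataclass
class DoseFactors:
    """Reference (energy, coefficient) table with per-group interpolation."""

    energies_keV: np.ndarray
    coefficients: np.ndarray  # pSv cm^2

    def __post_init__(self) -> None:
        self.energies_keV = np.asarray(self.energies_keV, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if np.any(np.diff(self.energies_keV) <= 0):
            raise ValueError("reference energies must be strictly increasing")
        if np.any(self.coefficients <= 0):
            raise ValueError("coefficients must be > 0")

    def per_group(self, groups: EnergyGroupStructure) -> np.ndarray:
        """Linear interpolation of the table at group midpoints."""
        return np.interp(groups.midpoints(), self.energies_keV, self.coefficients)


def default_dose_factors() -> DoseFactors:
    return DoseFactors(_REF_ENERGIES_KEV.copy(), _REF_COEFFS.copy())


def load_dose_factors(path) -> DoseFactors:
    """Two-column text file: energy_keV coefficient_pSv_cm2."""
    arr = np.loadtxt(path, ndmin=2)
    return DoseFactors(arr[:, 0], arr[:, 1])


@dataclass
class DoseMap:
    """Per-voxel effective dose (pSv per source particle); zero in air."""

    dose: np.ndarray  # (nx, ny, nz)
    air_mask: np.ndarray
    uncollided_dose: np.ndarray | None = None
    collided_dose: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.dose < 0):
            raise ValueError("dose must be >= 0")
        if np.any(self.dose[self.air_mask] != 0):
            raise ValueError("dose must be zero on air voxels")


def fluence_to_dose(
    fields: FluenceField,
    factors: DoseFactors,
    phantom: VoxelPhantom,
    groups: EnergyGroupStructure,
) -> DoseMap:
    """dose(v) = sum_g factor[g] * total_fluence[g][v], zeroed in air."""
    f = factors.per_group(groups)
    if f.shape[0] != fields.G:
        raise ValueError("factor count != group count")
    air = phantom.material_index == MAT_AIR
    du = np.tensordot(f, fields.uncollided, axes=1)
    dc = np.tensordot(f, fields.collided, axes=1)
    du[air] = 0.0
    dc[air] = 0.0
    return DoseMap(du + dc, air, du, dc)


def fov_mask(shape, spacing_mm, fov_mm: float) -> np.ndarray:
    """Axial circular field-of-view mask (2-D, about the grid center)."""
    nx, ny = shape[0], shape[1]
    x = (np.arange(nx) + 0.5) * spacing_mm[0] - 0.5 * nx * spacing_mm[0]
    y = (np.arange(ny) + 0.5) * spacing_mm[1] - 0.5 * ny * spacing_mm[1]
    r2 = x[:, None] ** 2 + y[None, :] ** 2
    return r2 <= (0.5 * fov_mm) ** 2


def relative_difference_map(
    test: np.ndarray, reference: np.ndarray, spacing_mm=None, fov_mm: float | None = None
) -> np.ma.MaskedArray:
    """100 * (test - reference) / reference, masked where undefined.

    Voxels with zero reference, or outside the circular FOV when ``fov_mm``
    is given, are masked and excluded from downstream statistics.
    """
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape:
        raise ValueError("shape mismatch")
    undef = reference == 0
    if fov_mm is not None:
        fov = fov_mask(test.shape, np.asarray(spacing_mm, dtype=float), fov_mm)
        while fov.ndim < test.ndim:
            fov = fov[..., None]
        undef = undef | ~np.broadcast_to(fov, test.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * (test - reference) / reference
    return np.ma.masked_array(rel, mask=undef)


def rmsd_percent(test, reference, mask=None) -> float:
    """Root-mean-square relative deviation in percent over a mask.

    sqrt(mean((test - reference)^2 / reference^2)) * 100 over voxels where
    the mask is True and the reference is nonzero; normalization is by the
    reference, so the statistic is not symmetric under swapping arguments.
    """
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape:
        raise ValueError("shape mismatch")
    sel = reference != 0
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    if not np.any(sel):
        raise ValueError("empty mask")
    rel = (test[sel] - reference[sel]) / reference[sel]
    return float(np.sqrt(np.mean(rel * rel)) * 100.0)


@dataclass
class ComparisonResult:
    """Per-group and total-dose RMSD between a test run and a reference run."""

    group_labels: list[str]
    collided_rmsd: np.ndarray
    uncollided_rmsd: np.ndarray
    total_dose_rmsd: float
    extras: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("group_keV,collided_rmsd_pct,uncollided_rmsd_pct\n")
            for lbl, c, u in zip(self.group_labels, self.collided_rmsd, self.uncollided_rmsd):
                fh.write(f"{lbl},{c:.4f},{u:.4f}\n")
            fh.write(f"total_dose,{self.total_dose_rmsd:.4f},\n")


def compare_central_slice(
    test_fields: FluenceField,
    ref_fields: FluenceField,
    test_dose: DoseMap,
    ref_dose: DoseMap,
    phantom: VoxelPhantom,
    groups: EnergyGroupStructure,
    fov_mm: float = 350.0,
    ref_rel_err: np.ndarray | None = None,
    max_rel_err: float = 0.05,
    dose_rel_err: np.ndarray | None = None,
) -> ComparisonResult:
    """Percent RMSD of the central axial slice within the FOV.

    Masks out voxels where the reference is zero or (when reference
    uncertainties are supplied, shape (2, G, ...) for uncollided/collided)
    where its relative standard error exceeds ``max_rel_err``.
    """
    kz = phantom.shape[2] // 2
    fov = fov_mask(phantom.shape, phantom.spacing, fov_mm)
    G = groups.G
    col = np.zeros(G)
    unc = np.zeros(G)

    def _safe(test, ref, m):
        # a group can have no reference voxels below the uncertainty cut
        # (low-energy groups are heavily attenuated); report NaN, as such
        # groups are discarded from the comparison
        try:
            return rmsd_percent(test, ref, m)
        except ValueError:
            return float("nan")

    for g in range(G):
        mc = fov.copy()
        mu = fov.copy()
        if ref_rel_err is not None:
            mu &= ref_rel_err[0, g, :, :, kz] <= max_rel_err
            mc &= ref_rel_err[1, g, :, :, kz] <= max_rel_err
        unc[g] = _safe(
            test_fields.uncollided[g, :, :, kz], ref_fields.uncollided[g, :, :, kz], mu
        )
        col[g] = _safe(
            test_fields.collided[g, :, :, kz], ref_fields.collided[g, :, :, kz], mc
        )
    md = fov.copy()
    if dose_rel_err is not None:
        md &= dose_rel_err[:, :, kz] <= max_rel_err
    total = rmsd_percent(test_dose.dose[:, :, kz], ref_dose.dose[:, :, kz], md)
    labels = [
        f"{groups.boundaries[g + 1]:g}-{groups.boundaries[g]:g}" for g in range(G)
    ]
    return ComparisonResult(labels, col, unc, total)
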