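"""Voxelized phantoms: fixture geometries, CT-number mapping, raw-volume I/O.

Conventions: 0-based voxel indices; voxel (i, j, k) occupies the half-open
axis-aligned box ``[origin + (i,j,k)*spacing, origin + (i+1,j+1,k+1)*spacing)``
in mm; membership of a geometric body is decided by the voxel center point.
Material indices refer to an :class:`~ctdose.xs.XSLibrary` by position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "VoxelPhantom",
    "build_water_cylinder",
    "build_abdomen_like",
    "ct_numbers_to_phantom",
    "default_hu_mapping",
    "write_volume",
    "read_volume",
    "AIR_DENSITY",
]

AIR_DENSITY = 0.0012  # g/cm^3; tiny nonzero value instead of true void

# Material slots of the standard library (xs.STANDARD_MATERIALS order).
MAT_AIR, MAT_LUNG, MAT_TISSUE, MAT_WATER, MAT_BONE = range(5)


@dataclass
class VoxelPhantom:
    """Regular 3-D grid of material indices and mass densities."""

    material_index: np.ndarray  # (nx, ny, nz) int16
    density: np.ndarray  # (nx, ny, nz) float32, g/cm^3
    spacing: np.ndarray  # (3,) voxel edge lengths, mm
    origin: np.ndarray  # (3,) low corner of voxel (0,0,0), mm

    def __post_init__(self) -> None:
        self.material_index = np.ascontiguousarray(self.material_index, dtype=np.int16)
        self.density = np.ascontiguousarray(self.density, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.material_index.shape != self.density.shape:
            raise ValueError("material_index and density shapes differ")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be > 0")
        if np.any(self.density < 0):
            raise ValueError("density must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_index.shape

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def extent_mm(self) -> np.ndarray:
        return self.spacing * np.asarray(self.shape)

    def center_mm(self) -> np.ndarray:
        return self.origin + 0.5 * self.extent_mm()

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis center coordinate vectors (mm)."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )


def _grid(shape, domain_cm, center_at_origin: bool = False):
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError("shape must be positive")
    extent = np.asarray(domain_cm, dtype=float) * 10.0  # mm
    if np.any(extent <= 0):
        raise ValueError("domain extents must be positive")
    spacing = extent / np.asarray(shape)
    origin = -0.5 * extent if center_at_origin else np.zeros(3)
    return shape, spacing, origin


def build_water_cylinder(
    shape=(64, 64, 16), domain_cm=(50.0, 50.0, 12.5), diameter_cm: float = 35.0
) -> VoxelPhantom:
    """Axis-aligned z-cylinder of water centered in an air-filled box.

    Defaults reproduce the 35 cm diameter, 12.5 cm long water column in a
    50 x 50 x 12.5 cm domain; voxel membership is by center point.
    """
    shape, spacing, origin = _grid(shape, domain_cm)
    ext = spacing * np.asarray(shape)
    cx, cy = origin[0] + 0.5 * ext[0], origin[1] + 0.5 * ext[1]
    x = origin[0] + (np.arange(shape[0]) + 0.5) * spacing[0]
    y = origin[1] + (np.arange(shape[1]) + 0.5) * spacing[1]
    r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
    inside2d = r2 <= (diameter_cm * 10.0 / 2.0) ** 2
    mat = np.full(shape, MAT_AIR, dtype=np.int16)
    den = np.full(shape, AIR_DENSITY, dtype=np.float32)
    mat[inside2d, :] = MAT_WATER
    den[inside2d, :] = 1.0
    return VoxelPhantom(mat, den, spacing, origin)


def build_abdomen_like(
    shape=(64, 64, 16), domain_cm=(50.0, 50.0, 12.5), seed: int = 0
) -> VoxelPhantom:
    """Synthetic abdomen-like phantom (not a reproduction of any CT data set).

    An elliptical soft-tissue body with mild density texture, a posterior
    bone ellipse (spine surrogate) and 1-3 air pockets (bowel gas surrogate),
    in air.  Deterministic for a given seed.
    """
    shape, spacing, origin = _grid(shape, domain_cm)
    rng = np.random.default_rng(seed)
    ext = spacing * np.asarray(shape)
    cx, cy = 0.5 * ext[0], 0.5 * ext[1]
    x = origin[0] + (np.arange(shape[0]) + 0.5) * spacing[0]
    y = origin[1] + (np.arange(shape[1]) + 0.5) * spacing[1]
    X, Y = np.meshgrid(x, y, indexing="ij")

    # body: ellipse ~ 36 x 24 cm half-axes 180/120 mm => area fraction ~0.27-0.55
    ax_, ay_ = 170.0, 120.0
    body = ((X - cx) / ax_) ** 2 + ((Y - cy) / ay_) ** 2 <= 1.0

    mat2d = np.full(shape[:2], MAT_AIR, dtype=np.int16)
    den2d = np.full(shape[:2], AIR_DENSITY, dtype=np.float32)
    mat2d[body] = MAT_TISSUE
    texture = rng.normal(1.03, 0.01, size=shape[:2]).astype(np.float32)
    den2d[body] = np.clip(texture[body], 1.0, 1.06)

    # posterior bone ellipse (spine), toward +y
    bx, by = cx + rng.normal(0.0, 3.0), cy + 75.0
    bone = ((X - bx) / 22.0) ** 2 + ((Y - by) / 22.0) ** 2 <= 1.0
    mat2d[bone & body] = MAT_BONE
    den2d[bone & body] = 1.5

    # 1-3 anterior air pockets
    for _ in range(int(rng.integers(1, 4))):
        px = cx + rng.uniform(-80.0, 80.0)
        py = cy + rng.uniform(-70.0, -20.0)
        pr = rng.uniform(8.0, 20.0)
        pocket = (X - px) ** 2 + (Y - py) ** 2 <= pr * pr
        mat2d[pocket & body & ~bone] = MAT_AIR
        den2d[pocket & body & ~bone] = AIR_DENSITY

    mat = np.repeat(mat2d[:, :, None], shape[2], axis=2)
    den = np.repeat(den2d[:, :, None], shape[2], axis=2)
    return VoxelPhantom(mat, den, spacing, origin)


def default_hu_mapping() -> list[tuple[float, float, int, float, float]]:
    """Threshold map (hu_lo, hu_hi, material, rho_at_lo, rho_at_hi).

    Contiguous half-open intervals [lo, hi) covering int16 CT numbers;
    density ramps linearly across each interval.
    """
    return [
        (-32768.0, -900.0, MAT_AIR, AIR_DENSITY, AIR_DENSITY),
        (-900.0, -100.0, MAT_LUNG, 0.10, 0.90),
        (-100.0, 150.0, MAT_TISSUE, 0.90, 1.15),
        (150.0, 32768.0, MAT_BONE, 1.15, 2.0),
    ]


def ct_numbers_to_phantom(
    volume: np.ndarray, spacing_mm, mapping=None, origin_mm=(0.0, 0.0, 0.0)
) -> VoxelPhantom:
    """Convert a CT-number (HU) volume to materials and densities.

    Simplified threshold mapping standing in for a full stoichiometric
    calibration: each HU interval maps to one dosimetrically equivalent
    material with a piecewise-linear density ramp.  0 HU maps to soft tissue
    at density 1.0 by construction of the default map.
    """
    mapping = mapping if mapping is not None else default_hu_mapping()
    mapping = sorted(mapping, key=lambda t: t[0])
    for (a, b) in zip(mapping, mapping[1:]):
        if a[1] != b[0]:
            raise ValueError(f"mapping gap/overlap between {a[1]} and {b[0]}")
    hu = np.asarray(volume, dtype=np.float32)
    mat = np.zeros(hu.shape, dtype=np.int16)
    den = np.zeros(hu.shape, dtype=np.float32)
    covered = np.zeros(hu.shape, dtype=bool)
    for (lo, hi, m, rlo, rhi) in mapping:
        sel = (hu >= lo) & (hu < hi)
        mat[sel] = m
        t = (hu[sel] - lo) / (hi - lo)
        den[sel] = rlo + t * (rhi - rlo)
        covered |= sel
    if not covered.all():
        raise ValueError("mapping does not cover the full CT-number range")
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,)).copy()
    return VoxelPhantom(mat, den, spacing, np.asarray(origin_mm, dtype=float))


# The default tissue interval spans HU -100..150 with density 0.90..1.15;
# HU = 0 then gives rho = 0.90 + (100/250)*0.25 = 1.0 exactly.


# ---------------------------------------------------------------------------
# Raw volume I/O: flat little-endian binary + sidecar text metadata

_DTYPES = {"int16": "<i2", "float32": "<f4"}


def write_volume(phantom: VoxelPhantom, stem) -> None:
    """Write ``<stem>.mat.raw``, ``<stem>.den.raw`` and ``<stem>.meta``."""
    stem = Path(stem)
    phantom.material_index.astype("<i2").tofile(stem.with_suffix(".mat.raw"))
    phantom.density.astype("<f4").tofile(stem.with_suffix(".den.raw"))
    with open(stem.with_suffix(".meta"), "w") as fh:
        fh.write(f"shape: {phantom.shape[0]} {phantom.shape[1]} {phantom.shape[2]}\n")
        fh.write("spacing_mm: " + " ".join(f"{s:.9g}" for s in phantom.spacing) + "\n")
        fh.write("origin_mm: " + " ".join(f"{s:.9g}" for s in phantom.origin) + "\n")
        fh.write("dtype: int16 float32\n")
        fh.write("order: C\n")


def read_volume(stem) -> VoxelPhantom:
    stem = Path(stem)
    meta = {}
    with open(stem.with_suffix(".meta")) as fh:
        for ln in fh:
            if ":" in ln:
                k, v = ln.split(":", 1)
                meta[k.strip()] = v.strip()
    shape = tuple(int(x) for x in meta["shape"].split())
    spacing = np.array([float(x) for x in meta["spacing_mm"].split()])
    origin = np.array([float(x) for x in meta.get("origin_mm", "0 0 0").split()])
    mat = np.fromfile(stem.with_suffix(".mat.raw"), dtype="<i2").reshape(shape)
    den = np.fromfile(stem.with_suffix(".den.raw"), dtype="<f4").reshape(shape)
    return VoxelPhantom(mat, den, spacing, origin)


def read_raw_ct(raw_path, meta_path=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a raw int16 CT-number volume with its sidecar metadata file.

    Returns (volume, spacing_mm, origin_mm).
    """
    raw_path = Path(raw_path)
    meta_path = Path(meta_path) if meta_path else raw_path.with_suffix(".meta")
    meta = {}
    with open(meta_path) as fh:
        for ln in fh:
            if ":" in ln:
                k, v = ln.split(":", 1)
                meta[k.strip()] = v.strip()
    shape = tuple(int(x) for x in meta["shape"].split())
    dtype = _DTYPES.get(meta.get("dtype", "int16"), "<i2")
    vol = np.fromfile(raw_path, dtype=dtype).reshape(shape)
    spacing = np.array([float(x) for x in meta["spacing_mm"].split()])
    origin = np.array([float(x) for x in meta.get("origin_mm", "0 0 0").split()])
    return vol, spacing, origin
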