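"""Deterministic generators for test inputs and named scenario bundles.

Every bundle is a pure function of (name, seed): a run configuration plus a
list of machine-checkable expected properties with tolerances.  The bundles
cover the analytic limits (vacuum inverse square, slab attenuation, the
one-group infinite-medium balance) and the desk-scale projection / CT-scan
verification scenarios on the water and abdomen phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import phantom as ph
from . import xs as xsmod
from .source import BeamSet, kramers_spectrum, make_cone_beam, make_ct_scan, make_point_source

__all__ = ["ScenarioBundle", "make_scenario", "SCENARIO_NAMES"]

SCENARIO_NAMES = (
    "vacuum-point-source",
    "absorber-slab",
    "infinite-medium-c05",
    "water-projection-coarse",
    "water-ctscan-coarse",
    "abdomen-ctscan-coarse",
)

#: Source ring radius (mm) used by the CT-scan and projection scenarios;
#: the sources sit outside the 50 cm domain.
SOURCE_RADIUS_MM = 500.0


@dataclass
class ExpectedProperty:
    """A named predicate with a tolerance, evaluated on run results."""

    name: str
    description: str
    tolerance: float


@dataclass
class ScenarioBundle:
    name: str
    seed: int
    phantom: ph.VoxelPhantom
    xslib: xsmod.XSLibrary
    beams: BeamSet
    sn: int
    pn: int
    mc_histories: int  # fixed-seed run for the 3-standard-error agreement check
    mc_histories_reference: int = 0  # well-converged reference for RMSD benchmarks
    expected: list[ExpectedProperty] = field(default_factory=list)
    notes: str = ""


def _one_group_lib(sigma_t: float, c: float, mu_bar: float = 0.0) -> xsmod.XSLibrary:
    groups = xsmod.EnergyGroupStructure((100.0, 10.0))
    mats = [
        xsmod.make_test_material("void", [0.0], 0.0),
        xsmod.make_test_material("medium", [sigma_t], c, 1.0, mu_bar),
    ]
    return xsmod.XSLibrary(groups, mats)


def _uniform_phantom(shape, spacing_mm, mat_idx=1, density=1.0) -> ph.VoxelPhantom:
    shape = tuple(shape)
    mat = np.full(shape, mat_idx, dtype=np.int16)
    den = np.full(shape, density, dtype=np.float32)
    return ph.VoxelPhantom(mat, den, np.full(3, spacing_mm), np.zeros(3))


def make_scenario(name: str, seed: int = 42) -> ScenarioBundle:
    """Build one of the documented scenario bundles (pure in (name, seed))."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario '{name}'; known: {SCENARIO_NAMES}")

    if name == "vacuum-point-source":
        lib = _one_group_lib(1.0, 0.5)
        body = _uniform_phantom((24, 24, 24), 10.0, mat_idx=0, density=0.0)
        src = make_point_source((-200.0, 120.0, 120.0), [1.0])
        return ScenarioBundle(
            name, seed, body, lib, BeamSet([src]), 4, 0, 100_000,
            expected=[
                ExpectedProperty(
                    "inverse_square_max_rel_err",
                    "uncollided fluence matches 1/(4 pi d^2) at voxels with d > 2 edges",
                    1e-9,
                )
            ],
        )

    if name == "absorber-slab":
        lib = _one_group_lib(0.5, 0.0)
        body = _uniform_phantom((40, 10, 10), 5.0, mat_idx=1, density=1.0)
        src = make_point_source((-300.0, 25.0, 25.0), [1.0])
        return ScenarioBundle(
            name, seed, body, lib, BeamSet([src]), 2, 0, 100_000,
            expected=[
                ExpectedProperty(
                    "beer_lambert_max_rel_err",
                    "attenuation along the slab follows exp(-sigma_t * depth)",
                    1e-9,
                )
            ],
        )

    if name == "infinite-medium-c05":
        lib = _one_group_lib(1.0, 0.5)
        body = _uniform_phantom((32, 32, 32), 20.0, mat_idx=1, density=1.0)
        src = make_point_source((-1.0, -1.0, -1.0), [1.0])  # placeholder; solve uses a uniform source
        return ScenarioBundle(
            name, seed, body, lib, BeamSet([src]), 4, 0, 200_000,
            expected=[
                ExpectedProperty(
                    "interior_fluence_rel_err",
                    "interior scalar fluence approaches S/sigma_a = 2 S/sigma_t",
                    0.03,
                )
            ],
        )

    groups = xsmod.seven_group_structure()
    lib = xsmod.standard_library(groups)
    spectrum = kramers_spectrum(100.0, groups)

    if name == "water-projection-coarse":
        body = ph.build_water_cylinder((64, 64, 16), (50.0, 50.0, 12.5))
        center = body.center_mm()
        pos = center + np.array([SOURCE_RADIUS_MM, 0.0, 0.0])
        src = make_cone_beam(pos, center - pos, 15.0, spectrum)
        return ScenarioBundle(
            name, seed, body, lib, BeamSet([src]), 6, 0, 1_000_000,
            mc_histories_reference=16_000_000,
            expected=[
                ExpectedProperty(
                    "collided_within_3se_fraction",
                    "collided fluence within 3 MC standard errors in-phantom",
                    0.95,
                ),
                ExpectedProperty("balance_closure", "particle balance closure", 1e-4),
            ],
        )

    if name == "water-ctscan-coarse":
        body = ph.build_water_cylinder((64, 64, 16), (50.0, 50.0, 12.5))
        beams = make_ct_scan(16, SOURCE_RADIUS_MM, 30.0, body.center_mm(), spectrum)
        return ScenarioBundle(
            name, seed, body, lib, beams, 6, 0, 1_000_000,
            mc_histories_reference=16_000_000,
            expected=[
                ExpectedProperty(
                    "total_dose_rmsd_pct",
                    "central-slice total effective dose RMSD vs MC, 35 cm FOV",
                    6.0,
                ),
                ExpectedProperty("balance_closure", "particle balance closure", 1e-4),
            ],
        )

    # abdomen-ctscan-coarse
    body = ph.build_abdomen_like((64, 64, 16), (50.0, 50.0, 12.5), seed=seed)
    beams = make_ct_scan(16, SOURCE_RADIUS_MM, 30.0, body.center_mm(), spectrum)
    return ScenarioBundle(
        name, seed, body, lib, beams, 6, 0, 1_000_000,
        mc_histories_reference=16_000_000,
        expected=[
            ExpectedProperty(
                "total_dose_rmsd_pct",
                "central-slice total effective dose RMSD vs MC, 35 cm FOV",
                6.0,
            )
        ],
    )
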