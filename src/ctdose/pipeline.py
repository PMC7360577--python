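"""End-to-end runs: uncollided trace -> first-collision source -> S_N solve ->
dose, plus the deterministic-vs-Monte-Carlo comparison workflow."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dosimetry import (
    ComparisonResult,
    DoseFactors,
    DoseMap,
    compare_central_slice,
    default_dose_factors,
    fluence_to_dose,
)
from .mc import MCTally, mc_uncertainty_map, run_mc
from .phantom import VoxelPhantom
from .quadrature import build_level_symmetric
from .solver import SolveResult, SolverConfig, particle_balance, solve_collided
from .source import BeamSet, SourceSpec
from .uncollided import FluenceField, first_collision_source, uncollided_fluence
from .xs import XSLibrary

__all__ = ["DeterministicRun", "run_deterministic", "compare_with_mc"]


@dataclass
class DeterministicRun:
    fields: FluenceField
    dose: DoseMap
    solve: SolveResult
    balance: dict


def run_deterministic(
    phantom: VoxelPhantom,
    xslib: XSLibrary,
    beams: BeamSet | SourceSpec,
    config: SolverConfig | None = None,
    factors: DoseFactors | None = None,
) -> DeterministicRun:
    """Full chain on one phantom/source setup; returns fields, dose, diagnostics."""
    if isinstance(beams, SourceSpec):
        beams = BeamSet([beams])
    config = config or SolverConfig()
    factors = factors or default_dose_factors()
    q = build_level_symmetric(config.sn)
    phi_u, per_source = uncollided_fluence(phantom, beams, xslib, per_source=True)
    fcs = first_collision_source(
        phantom,
        xslib,
        per_source,
        [s.position for s in beams.sources],
        L=min(config.pn, xslib.legendre_order),
    )
    solve = solve_collided(phantom, xslib, q, fcs, config)
    fields = FluenceField(phi_u, solve.collided)
    dose = fluence_to_dose(fields, factors, phantom, xslib.groups)
    balance = particle_balance(
        phantom, xslib, solve.collided, fcs, solve.total_leakage
    )
    return DeterministicRun(fields, dose, solve, balance)


def compare_with_mc(
    phantom: VoxelPhantom,
    xslib: XSLibrary,
    beams: BeamSet | SourceSpec,
    run: DeterministicRun,
    n_histories: int,
    seed: int,
    factors: DoseFactors | None = None,
    fov_mm: float = 350.0,
    batches: int = 10,
) -> tuple[ComparisonResult, MCTally, DoseMap]:
    """Benchmark a deterministic run against the analog MC oracle.

    Returns the central-slice RMSD table (collided / uncollided per group and
    total dose, reference-uncertainty filtered at 5%) plus the raw tally.
    """
    factors = factors or default_dose_factors()
    tally, mc_dose = run_mc(
        phantom, xslib, beams, n_histories, seed, factors, batches=batches
    )
    rel = mc_uncertainty_map(tally).filled(np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        dose_rel = np.where(tally.dose > 0, tally.dose_se / np.where(tally.dose > 0, tally.dose, 1.0), np.inf)
    mc_fields = FluenceField(tally.uncollided, tally.collided)
    comparison = compare_central_slice(
        run.fields,
        mc_fields,
        run.dose,
        mc_dose,
        phantom,
        xslib.groups,
        fov_mm=fov_mm,
        ref_rel_err=rel,
        dose_rel_err=dose_rel,
    )
    return comparison, tally, mc_dose


def within_3se_fraction(
    run_fields: FluenceField, tally: MCTally, in_phantom: np.ndarray, component: str = "collided"
) -> float:
    """Fraction of in-phantom voxels where |S_N - MC| <= 3 standard errors.

    Pools all groups; only voxels with a defined MC standard error (nonzero
    mean, >= 2 batches) enter the denominator.
    """
    if component == "collided":
        det, mc, se = run_fields.collided, tally.collided, tally.collided_se
    else:
        det, mc, se = run_fields.uncollided, tally.uncollided, tally.uncollided_se
    mask = in_phantom[None, ...] & (mc > 0) & (se > 0)
    if not np.any(mask):
        raise ValueError("no comparable voxels")
    ok = np.abs(det[mask] - mc[mask]) <= 3.0 * se[mask]
    return float(np.mean(ok))
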