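import numpy as np
import pytest

from ctdose import seven_group_structure, standard_library
from ctdose.fixtures import make_scenario
from ctdose.pipeline import compare_with_mc, run_deterministic, within_3se_fraction
from ctdose.solver import SolverConfig


@pytest.fixture(scope="session")
def seven_groups():
    return seven_group_structure()


@pytest.fixture(scope="session")
def stdlib():
    return standard_library()


@pytest.fixture(scope="session")
def projection_bundle():
    return make_scenario("water-projection-coarse")


@pytest.fixture(scope="session")
def ctscan_bundle():
    return make_scenario("water-ctscan-coarse")


@pytest.fixture(scope="session")
def projection_run(projection_bundle):
    """Deterministic S6P0 solve of the single-cone water projection."""
    b = projection_bundle
    return run_deterministic(b.phantom, b.xslib, b.beams, SolverConfig(sn=b.sn, pn=b.pn))


@pytest.fixture(scope="session")
def ctscan_run(ctscan_bundle):
    """Deterministic S6P0 solve of the 16-beam water scan."""
    b = ctscan_bundle
    return run_deterministic(b.phantom, b.xslib, b.beams, SolverConfig(sn=b.sn, pn=b.pn))


@pytest.fixture(scope="session")
def projection_mc(projection_bundle, projection_run):
    """Fixed-seed analog MC benchmark of the projection at the bundle's scale."""
    b = projection_bundle
    return compare_with_mc(
        b.phantom, b.xslib, b.beams, projection_run, b.mc_histories, seed=b.seed
    )


@pytest.fixture(scope="session")
def ctscan_mc(ctscan_bundle, ctscan_run):
    b = ctscan_bundle
    return compare_with_mc(
        b.phantom, b.xslib, b.beams, ctscan_run, b.mc_histories, seed=b.seed
    )


@pytest.fixture(scope="session")
def ctscan_mc_reference(ctscan_bundle, ctscan_run):
    """Well-converged MC reference for the RMSD benchmark of the scan."""
    b = ctscan_bundle
    return compare_with_mc(
        b.phantom,
        b.xslib,
        b.beams,
        ctscan_run,
        b.mc_histories_reference,
        seed=b.seed,
        batches=16,
    )
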