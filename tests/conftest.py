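import numpy as np
import pytest

from atrophyfem.mechanics import MaterialParams
from atrophyfem.mesh import SliceSpec, generate_slice
from atrophyfem.morphometry import Morphometer
from atrophyfem.scenarios import focal_schedule, generalized_schedule
from atrophyfem.solver import run_schedule


@pytest.fixture(scope="session")
def material():
    return MaterialParams()


@pytest.fixture(scope="session")
def coronal_coarse():
    """Fast coronal slice for unit tests (~2k elements)."""
    return generate_slice(SliceSpec.coronal(target_edge_length=3.5))


@pytest.fixture(scope="session")
def coronal_mesh():
    """Reference-resolution coronal slice (~10k elements)."""
    return generate_slice(SliceSpec.coronal())


@pytest.fixture(scope="session")
def sagittal_mesh():
    """Reference-resolution sagittal slice (~12k elements)."""
    return generate_slice(SliceSpec.sagittal())


@pytest.fixture(scope="session")
def coronal_generalized(coronal_mesh, material):
    """Full 48-increment generalized run on the coronal slice, with reports."""
    morph = Morphometer(coronal_mesh)
    states, reports = run_schedule(coronal_mesh, generalized_schedule(),
                                   material, report_fn=morph.report)
    return coronal_mesh, morph, states, reports


@pytest.fixture(scope="session")
def sagittal_generalized(sagittal_mesh, material):
    states, reports = run_schedule(sagittal_mesh, generalized_schedule(),
                                   material,
                                   report_fn=Morphometer(sagittal_mesh).report)
    return sagittal_mesh, states, reports


@pytest.fixture(scope="session")
def coronal_focal_gray(coronal_mesh, material):
    """Focal gray-matter atrophy to υ = 0.5 on the coronal slice."""
    morph = Morphometer(coronal_mesh)
    states, reports = run_schedule(coronal_mesh, focal_schedule("gray", -0.50),
                                   material, report_fn=morph.report)
    return coronal_mesh, morph, states, reports


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
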