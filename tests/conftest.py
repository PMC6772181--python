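"""Shared fixtures: a small head model, sensors and simulated data.

Everything is generated programmatically at collection time; session
scope keeps the geometry/forward computations to one pass.
"""

import numpy as np
import pytest

from megdeep.anatomy import AnatomicalModel, TriMesh, build_synthetic_anatomy
from megdeep.forward import (fit_sphere, helmet_sensors, leadfield_sphere,
                             patch_basis, spatial_projector)
from megdeep.preprocess import preprocess, reduce_modes
from megdeep.simulate import (ExperimentDesign, SourceDynamics,
                              simulate_experiment)


@pytest.fixture(scope="session")
def anatomy():
    return build_synthetic_anatomy(seed=0)


@pytest.fixture(scope="session")
def sensors(anatomy):
    center, _ = fit_sphere(anatomy)
    return helmet_sensors(100, radius=55.0, sphere_origin=center)


@pytest.fixture(scope="session")
def leadfield(anatomy, sensors):
    return leadfield_sphere(anatomy, sensors)


@pytest.fixture(scope="session")
def projector(leadfield):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return spatial_projector(leadfield, 120)


@pytest.fixture(scope="session")
def patches(anatomy):
    return patch_basis(anatomy, 0.6)


@pytest.fixture(scope="session")
def small_design():
    # 4 blocks x 10 trials keeps unit tests fast while preserving the
    # block structure
    return ExperimentDesign(blocks_per_phase=4, trials_per_block=10)


@pytest.fixture(scope="session")
def small_epochs(anatomy, leadfield, small_design):
    return simulate_experiment(anatomy, leadfield, small_design,
                               SourceDynamics(), snr_db=0.0,
                               n_participants=1, seed=31)[0]


@pytest.fixture(scope="session")
def small_reduced(small_epochs, projector):
    pp, _ = preprocess(small_epochs)
    return reduce_modes(pp, projector, 4, window=(0.0, 3.5))


@pytest.fixture(scope="session")
def medium_reduced(anatomy, leadfield, projector):
    """One 200-trial maintenance phase: the scale at which model
    evidence comparisons are stable."""
    design = ExperimentDesign(blocks_per_phase=10, trials_per_block=20)
    ep = simulate_experiment(anatomy, leadfield, design, SourceDynamics(),
                             snr_db=0.0, n_participants=1, seed=31)[0]
    pp, _ = preprocess(ep)
    return reduce_modes(pp, projector, 4, window=(0.0, 3.5))


def tetrahedron(label="cortex"):
    """Minimal closed mesh with outward winding."""
    v = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                  [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return TriMesh(v, f, label)


@pytest.fixture
def tetra():
    return tetrahedron()
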