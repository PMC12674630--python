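import numpy as np
import pytest

from optiwrist.geometry import (LabeledTetMesh, WristAnatomySpec,
                                build_cylinder_mesh, build_synthetic_wrist)


@pytest.fixture(scope="session")
def small_cylinder():
    """Reduced canonical cylinder (~3k nodes) shared across tests."""
    return build_cylinder_mesh(27.0, 60.0, 3000)


@pytest.fixture(scope="session")
def unit_cylinder():
    return build_cylinder_mesh(1.0, 1.0, 250)


@pytest.fixture(scope="session")
def labeled_wrist(small_cylinder):
    spec = WristAnatomySpec.canonical(seed=1, jitter=0.1)
    return build_synthetic_wrist(spec, small_cylinder)


@pytest.fixture(scope="session")
def homogeneous_wrist(small_cylinder):
    return LabeledTetMesh(small_cylinder,
                          np.ones(small_cylinder.n_nodes, dtype=int),
                          radius=27.0, height=60.0)


@pytest.fixture(scope="session")
def study_cylinder():
    """Canonical mesh at the default study resolution (~6k nodes)."""
    return build_cylinder_mesh(27.0, 60.0, 6000)


@pytest.fixture(scope="session")
def homogeneous_study_wrist(study_cylinder):
    return LabeledTetMesh(study_cylinder,
                          np.ones(study_cylinder.n_nodes, dtype=int),
                          radius=27.0, height=60.0)


@pytest.fixture(scope="session")
def white_mc():
    """One white Monte Carlo photon set shared by the SFDI tests."""
    from optiwrist.sfdi import white_mc_reflectance
    return white_mc_reflectance(photons=200_000, seed=42)
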