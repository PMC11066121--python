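import numpy as np
import pytest

from emnav.geometry import Point3
from emnav.phantom import generate_phantom
from emnav.registration import FiducialPairSet


def kabsch(moving: np.ndarray, fixed: np.ndarray):
    """Independent SVD (Kabsch) rigid-alignment oracle.

    Kept deliberately separate from the package's Horn implementation:
    solves the same least-squares problem through the polar decomposition
    of the cross-covariance instead of the quaternion eigenproblem.
    """
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    H = (moving - mc).T @ (fixed - fc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = fc - R @ mc
    return R, t


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(seed=0)


@pytest.fixture(scope="session")
def fiducial_points(default_phantom):
    """Image-space positions of the six registration fiducials, (6, 3) mm."""
    return np.array([f.position.as_array() for f in default_phantom.fiducials])


@pytest.fixture()
def identity_pairs(fiducial_points, default_phantom):
    ids = tuple(f.id for f in default_phantom.fiducials)
    return FiducialPairSet(ids, fiducial_points.copy(), fiducial_points.copy())


@pytest.fixture()
def centroid_target(fiducial_points):
    return Point3.from_array(fiducial_points.mean(axis=0))
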