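import numpy as np
import pytest

import g4integrity as g4


@pytest.fixture(scope="session")
def ideal_model():
    """Default ideal three-tetrad parallel G4 (h-telo sequence)."""
    return g4.build_ideal_g4()


@pytest.fixture(scope="session")
def ideal_topology(ideal_model):
    return g4.detect_topology(ideal_model)


@pytest.fixture()
def rigid_motion_rng():
    return np.random.default_rng(20240917)


def random_rigid_motion(rng):
    """A uniform random rotation matrix and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=10.0, size=3)


def brute_force_rotation_rmsd(X, Y, n_samples=3000, seed=0):
    """Independent minimal-RMSD oracle: random rotation search plus a
    Nelder-Mead polish on the rotation vector.  Shares no code with the
    SVD-based Kabsch path it is used to check."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def rmsd_for(matrix):
        return np.sqrt(np.mean(np.sum((Xc @ matrix.T - Yc) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_samples, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    rots = Rotation.from_quat(quats)
    values = [rmsd_for(r.as_matrix()) for r in rots]
    best = rots[int(np.argmin(values))]

    def objective(rotvec):
        return rmsd_for(Rotation.from_rotvec(rotvec).as_matrix())

    result = minimize(objective, best.as_rotvec(), method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12,
                               "maxiter": 4000})
    return float(result.fun)
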