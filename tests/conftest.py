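import numpy as np
import pytest

import afmkin as ak


@pytest.fixture(scope="session")
def template():
    return ak.template_foot()


@pytest.fixture(scope="session")
def template_v(template):
    return ak.add_virtual_midpoints(template)


@pytest.fixture(scope="session")
def static_trial(template):
    return ak.make_static_trial(template, n_frames=5)


@pytest.fixture(scope="session")
def cal(static_trial):
    return ak.calibrate_static(static_trial)


@pytest.fixture(scope="session")
def gait_clean():
    """One default synthetic walk, noise-free (shared; treat as read-only)."""
    return ak.synthesize_gait()


@pytest.fixture(scope="session")
def gait_noisy():
    return ak.synthesize_gait(perturb=ak.PerturbationSpec(noise_sd_mm=0.5, seed=7))


@pytest.fixture(scope="session")
def clean_curves(gait_clean, cal):
    return ak.trial_angles(gait_clean.clean_trial, cal)


def random_rotation(rng):
    """Uniform-ish random rotation matrix from a seeded generator."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
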