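"""Shared fixtures: presets and their stationary states, solved once."""

import numpy as np
import pytest

import oscibin as ob


@pytest.fixture(scope="session")
def single_spec():
    return ob.load_preset("single_inhibitory")


@pytest.fixture(scope="session")
def single_st(single_spec):
    return ob.solve_stationary(single_spec)


@pytest.fixture(scope="session")
def bio_spec():
    return ob.load_preset("biological_ei")


@pytest.fixture(scope="session")
def bio_st(bio_spec):
    return ob.solve_stationary(bio_spec)


@pytest.fixture(scope="session")
def hom_spec():
    return ob.load_preset("homogeneous_ei")


@pytest.fixture(scope="session")
def quarter_single_spec():
    return ob.calibrated(ob.load_preset("single_inhibitory", calibrate=False).scaled(0.25))


@pytest.fixture(scope="session")
def quarter_single_st(quarter_single_spec):
    return ob.solve_stationary(quarter_single_spec)


@pytest.fixture(scope="session")
def quarter_bio_spec():
    return ob.calibrated(ob.load_preset("biological_ei", calibrate=False).scaled(0.25))


@pytest.fixture(scope="session")
def quarter_bio_st(quarter_bio_spec):
    return ob.solve_stationary(quarter_bio_spec)


def random_stable_spec(rng: np.random.Generator) -> ob.NetworkSpec:
    """A random inhibition-dominated two-population network.

    Candidates whose effective connectivity is unstable at the target
    activities (max Re(lambda) >= 0.9) are rejected and redrawn, so the
    returned network has a stable balanced fixed point.
    """
    while True:
        n_e = int(rng.integers(200, 1500))
        n_i = int(rng.integers(100, 600))
        p = rng.uniform(0.05, 0.3, size=(2, 2))
        j_e = rng.uniform(0.05, 0.4)
        sigma = rng.uniform(5.0, 15.0)
        t_e = float(rng.uniform(0.03, 0.3))
        t_i = float(rng.uniform(0.1, 0.4))
        # scale inhibition so the net row feedback is negative
        k_ee, k_ei = p[0, 0] * n_e, p[0, 1] * n_i
        j_i = -rng.uniform(1.5, 4.0) * j_e * max(k_ee / max(k_ei, 1.0), 1.0)
        spec = ob.NetworkSpec(
            populations=(
                ob.Population("E", n_e, sigma_noise=sigma, target_m=t_e),
                ob.Population("I", n_i, sigma_noise=sigma, target_m=t_i),
            ),
            p=p,
            J=np.array([[j_e, j_i], [j_e, j_i]]),
            tau=10.0,
        )
        try:
            st = ob.solve_stationary(ob.calibrated(spec), m0=spec.target_m)
        except ob.ConvergenceError:
            continue
        if st.max_real_eig < 0.9:
            return spec
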