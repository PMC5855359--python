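import numpy as np
import pytest

import tetrafit as tf


@pytest.fixture(scope="session")
def best_fit() -> tf.ThermoParams:
    """The published best-fit parameter set for ztz240 on wild-type KCNQ2."""
    return tf.ZTZ240_KCNQ2_BEST_FIT


@pytest.fixture(scope="session")
def wt_data() -> tf.ResponseDataset:
    return tf.table1_fixture("wt")


@pytest.fixture(scope="session")
def het_data() -> tf.ResponseDataset:
    return tf.table1_fixture("heteromeric")


@pytest.fixture(autouse=True)
def _quiet_underdetermined_warning():
    """The six-point published dataset legitimately underdetermines the
    eight-parameter model; the warning is expected throughout the suite."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="fitting 8 parameters", category=UserWarning
        )
        yield


def random_thermo_params(rng: np.random.Generator) -> tf.ThermoParams:
    """A plausible random parameter draw for property tests."""
    return tf.ThermoParams(
        k_a=10 ** rng.uniform(3.0, 7.0),
        gamma=10 ** rng.uniform(-1.5, 1.5),
        mu=10 ** rng.uniform(-1.5, 1.5),
        nu=10 ** rng.uniform(-1.5, 2.0),
        a=rng.uniform(0.05, 1.0),
        b=rng.uniform(0.05, 1.0),
        c=rng.uniform(0.05, 1.0),
        d=rng.uniform(0.3, 1.0),
    )
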