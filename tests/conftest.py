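import numpy as np
import pytest

import eggcircuit as ec


@pytest.fixture(scope="session")
def quiet_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture()
def small_config():
    """Short recording with deterministic bends for fast unit tests."""
    return ec.default_config(duration=120.0, seed=3, bend_cv=0.0)


@pytest.fixture(scope="session")
def wt_cohort():
    """Pooled wild-type cohort shared by the heavier recovery tests."""
    import warnings

    from eggcircuit import study

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return study.run_cohort(seed=1)


def noise_free_config(**overrides):
    cfg = ec.default_config(**overrides)
    from dataclasses import replace

    return replace(cfg, noise=ec.NoiseParams(gcamp_sd=0.0, mcherry_sd=0.0,
                                             artifact_amplitude=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
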