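import numpy as np
import pytest

from cinetrf import synthetic
from cinetrf.trf import TRFModel


@pytest.fixture(scope="session")
def coupled_session():
    """A small synthetic session: coupled regressors, known kernels, noisy BHA."""
    reg, events = synthetic.generate_regressor_set(600.0, seed=101)
    kernels = synthetic.random_kernels(6, 3, seed=102)
    bha, info, truth = synthetic.generate_bha(reg, kernels, noise_sd=0.5, seed=103)
    return {"regressors": reg, "events": events, "kernels": kernels,
            "bha": bha, "info": info, "truth": truth}


@pytest.fixture(scope="session")
def fitted_session(coupled_session):
    s = coupled_session
    model = TRFModel(s["bha"].envelope, s["regressors"], channel_info=s["info"])
    return {**s, "model": model, "results": model.fit(ridge=0.3)}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
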