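import numpy as np
import pandas as pd
import pytest

from pitchsync import synth
from pitchsync.bglmm.sampler import PosteriorDraws


@pytest.fixture(scope="session")
def battery():
    from pitchsync import mfpsy

    return mfpsy.build_battery(order_seed=7)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study used across pipeline tests."""
    return synth.generate_study(n_subjects=12, seed=42, n_revolutions=200)


def fake_draws(model, theta_rows):
    """PosteriorDraws with hand-set parameter vectors (1 chain)."""
    arr = np.asarray(theta_rows, dtype=float)[None, :, :]
    diag = pd.DataFrame(
        {
            "parameter": model.names,
            "rhat": 1.0,
            "ess_bulk": float(arr.shape[1]),
            "ess_tail": float(arr.shape[1]),
        }
    )
    return PosteriorDraws(
        names=model.names,
        draws=arr,
        seed=0,
        model=model,
        diagnostics=diag,
        divergences=0,
        accept_rate=1.0,
    )
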