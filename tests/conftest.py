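import numpy as np
import pytest
from hypothesis import settings

from planedose import DetectorResponse, ENERGY_MODES, load_builtin_model

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def models():
    """All four shipped Versa HD parameter sets."""
    return {mode: load_builtin_model(mode) for mode in ENERGY_MODES}


@pytest.fixture(scope="session")
def m6fff(models):
    return models["6FFF"]


@pytest.fixture(scope="session")
def m6ff(models):
    return models["6FF"]


@pytest.fixture(scope="session")
def det():
    return DetectorResponse(0.20)


def profile_agreement_1pct_1mm(pos_ref, val_ref, pos_eval, val_eval,
                               dose_tol=0.01, dist_tol=0.1):
    """1%/1 mm agreement check for CAX-normalised profiles.

    A reference sample agrees if the evaluated profile comes within
    ``dose_tol`` (absolute, profiles normalised to 1 on axis) at some
    position within ``dist_tol`` cm.  Returns the fraction of agreeing
    samples.
    """
    ok = 0
    for p, v in zip(pos_ref, val_ref):
        lo, hi = np.searchsorted(pos_eval, [p - dist_tol, p + dist_tol])
        window = val_eval[max(lo - 1, 0):hi + 1]
        if window.size and np.min(np.abs(window - v)) <= dose_tol:
            ok += 1
        elif np.min(np.abs(np.interp(p, pos_eval, val_eval) - v)) <= dose_tol:
            ok += 1
    return ok / len(pos_ref)
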