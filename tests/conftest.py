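import numpy as np
import pytest

from ctlmon import CtlNarx, ParticipantProfile, generate_session_features

Z_DEFAULT = (2.3, 2.7, 3.0)


@pytest.fixture(scope="session")
def synth_sessions():
    """Default synthetic participant: two 540-epoch sessions (train/test)."""
    profile = ParticipantProfile()
    f1, y1, c1 = generate_session_features(profile, seed=0)
    f2, y2, c2 = generate_session_features(profile, seed=1)
    sigma_o = float(np.std(np.concatenate([y1, y2])))
    return {
        "profile": profile,
        "train": (f1, y1, c1),
        "test": (f2, y2, c2),
        "sigma_o": sigma_o,
        "z": Z_DEFAULT,
    }


@pytest.fixture(scope="session")
def fitted_models(synth_sessions):
    """Both NARX variants trained on session 1 with the study's A orders."""
    f1, y1, _ = synth_sessions["train"]
    out = {}
    for variant in ("lssvm1", "lssvm2"):
        out[variant] = CtlNarx(
            y1, f1.to_numpy(), variant=variant, orders=(3, 5)
        ).fit()
    return out
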