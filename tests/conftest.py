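import numpy as np
import pandas as pd
import pytest

from metacog.sdt_core import S1, S2


def make_trials(stim, resp, conf=None, conf_bin=None):
    """Assemble a minimal trial table from parallel label/value sequences."""
    stim = list(stim)
    df = pd.DataFrame(
        {
            "stimulus_side": stim,
            "response_side": list(resp),
            "accuracy": [int(s == r) for s, r in zip(stim, resp)],
        }
    )
    if conf is not None:
        df["confidence_raw"] = list(conf)
    if conf_bin is not None:
        df["confidence_bin"] = list(conf_bin)
    return df


@pytest.fixture
def counts_trials():
    """100 trials per stimulus class: 80/100 'right' hits, 30/100 false alarms."""
    stim = [S2] * 100 + [S1] * 100
    resp = [S2] * 80 + [S1] * 20 + [S2] * 30 + [S1] * 70
    return make_trials(stim, resp)


@pytest.fixture
def ideal_session():
    """A 2000-trial fixed-difficulty SDT-ideal session (confidence = evidence)."""
    rng = np.random.default_rng(1234)
    n = 2000
    sign = np.where(rng.random(n) < 0.5, 1, -1)
    evidence = sign * 0.7 + rng.standard_normal(n)
    resp = np.where(evidence > 0, 1, -1)
    return pd.DataFrame(
        {
            "stimulus_side": np.where(sign > 0, S2, S1),
            "response_side": np.where(resp > 0, S2, S1),
            "accuracy": (sign == resp).astype(int),
            "confidence_raw": resp * evidence,
        }
    )
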