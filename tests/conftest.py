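import numpy as np
import pytest

from aspire import EventMatrix, Hyperparams


@pytest.fixture
def hp1d() -> Hyperparams:
    return Hyperparams(alpha=1.0, gamma=1.0, kappa0=1.0, kappa1=0.05,
                       mu0=[0.0], Sigma0=[[1.0]], m=4)


@pytest.fixture
def hp2d() -> Hyperparams:
    return Hyperparams(alpha=1.0, gamma=1.0, kappa0=1.0, kappa1=0.2,
                       mu0=[0.0, 0.0], Sigma0=np.eye(2), m=5)


@pytest.fixture
def two_blob_batch():
    """Three samples, two well-separated Gaussian clusters shared across
    samples (separation ten standard deviations)."""
    rng = np.random.default_rng(7)
    batch = []
    for j in range(3):
        a = rng.normal([-5.0, 0.0], 0.5, size=(100, 2))
        b = rng.normal([5.0, 0.0], 0.5, size=(100, 2))
        batch.append(EventMatrix(f"s{j}", np.vstack([a, b])))
    return batch


def pooled_chisquare(observed_counts: dict, probs: dict, min_expected=5.0):
    """Chi-square goodness of fit with small expected categories pooled."""
    from scipy.stats import chisquare
    n = sum(observed_counts.values())
    keys = sorted(probs, key=probs.get, reverse=True)
    obs, exp = [], []
    tail_o = tail_e = 0.0
    for k in keys:
        e = probs[k] * n
        o = observed_counts.get(k, 0)
        if e >= min_expected:
            obs.append(o)
            exp.append(e)
        else:
            tail_o += o
            tail_e += e
    if tail_e > 0:
        obs.append(tail_o)
        exp.append(tail_e)
    obs = np.asarray(obs, float)
    exp = np.asarray(exp, float)
    exp *= obs.sum() / exp.sum()
    return chisquare(obs, exp)
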