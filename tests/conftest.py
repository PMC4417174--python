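import numpy as np
import pytest

from etsdyn.bend import MobilityProfile, predict_rf


@pytest.fixture
def x11():
    """Eleven evenly spaced flexure displacements avoiding the exact ends."""
    return np.linspace(0.05, 0.95, 11)


def make_noisefree_profile(x, K, theta_deg, label="noise-free"):
    return MobilityProfile(
        x=x,
        rf_mean=predict_rf(x, K, theta_deg),
        rf_se=np.zeros_like(x),
        n_rep=np.ones_like(x, dtype=int),
        label=label,
    )


def make_noisy_profile(x, K, theta_deg, se=0.005, n_rep=4, seed=0, label="noisy"):
    """Quadruplicate-style profile: replicate SD = se * sqrt(n), pooled SE."""
    rng = np.random.default_rng(seed)
    reps = predict_rf(x, K, theta_deg)[None, :] + rng.normal(
        0.0, se * np.sqrt(n_rep), size=(n_rep, len(x)))
    per_se = reps.std(axis=0, ddof=1) / np.sqrt(n_rep)
    pooled = np.full(len(x), np.sqrt(np.mean(per_se**2)))
    return MobilityProfile(
        x=x, rf_mean=reps.mean(axis=0), rf_se=pooled,
        n_rep=np.full(len(x), n_rep), label=label,
    )


@pytest.fixture
def noisefree_profile(x11):
    return make_noisefree_profile(x11, K=0.95, theta_deg=50.0)
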