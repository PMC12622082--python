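import warnings

import numpy as np
import pytest

import replimix as rm


@pytest.fixture(scope="session")
def manual_fit():
    """A hand-specified symmetric two-cohort model with known parameters."""
    return rm.CsmGmmFit(
        K=2,
        M=1,
        pattern_weights=np.array([0.9, 0.04, 0.04, 0.02]),
        mu=[[3.0], [3.0]],
        tau2=[[1.0], [1.0]],
        lam=[[1.0], [1.0]],
    )


@pytest.fixture(scope="session")
def two_cohort_sim():
    """One moderately sized two-cohort replicate with its ground truth."""
    config = rm.SimulationConfig(
        J=50_000, K=2, causal_proportions=(0.01, 0.01), effect_mean=3.0, seed=5
    )
    truth = rm.generate_truth(config, seed=5)
    Z = rm.generate_z(truth, config.effect_mean, seed=6)
    return config, truth, Z


@pytest.fixture(scope="session")
def fitted_model(two_cohort_sim):
    """EM fit on the shared two-cohort replicate (reused across tests)."""
    _, _, Z = two_cohort_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return rm.fit_em(Z)


def model_generated_z(J, pattern_probs, mu, seed, K=2):
    """Draw (H, Z) directly from the two-group model with balanced signs.

    ``pattern_probs`` maps binary pattern tuples (e.g. (1, 1)) to prior mass;
    unlisted mass goes to the all-null pattern.  Signs are independent fair
    coins per non-null cohort; z ~ Normal(H * mu, 1).
    """
    rng = np.random.default_rng(seed)
    patterns = list(pattern_probs)
    probs = np.array([pattern_probs[p] for p in patterns])
    H = np.zeros((J, K), dtype=np.int8)
    u = rng.random(J)
    edges = np.cumsum(probs)
    which = np.searchsorted(edges, u)  # == len(patterns) -> all-null
    signs = rng.choice([-1, 1], size=(J, K))
    for i, pat in enumerate(patterns):
        rows = which == i
        for k, b in enumerate(pat):
            if b:
                H[rows, k] = signs[rows, k]
    Z = rng.normal(H * float(mu), 1.0)
    return H, Z
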