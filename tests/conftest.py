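import numpy as np
import pytest

from mpdyn import (Factor, HMMSpec, Modality, ObservationRecord, fig_model,
                   random_model, sample_trajectory, validate_model)


@pytest.fixture
def two_factor_model():
    """Small random two-factor model with a sampled sequence."""
    spec = random_model({"levels": (2, 3), "T": 4}, seed=7)
    obs = sample_trajectory(spec, 17)
    return spec, obs


@pytest.fixture
def sticky_fixture():
    """The two-factor sticky demonstration model (3 levels, T=15)."""
    spec = fig_model()
    obs = sample_trajectory(spec, 1)
    return spec, obs


def deterministic_chain(T=3, m=2, start=0):
    """Identity-transition chain with identity likelihood: forced sequence."""
    D = np.zeros(m)
    D[start] = 1.0
    spec = validate_model(HMMSpec([Factor(B=np.eye(m), D=D)],
                                  [Modality(A=np.eye(m), factor=0)], T))
    obs = ObservationRecord(np.full((T, 1), start, dtype=int))
    return spec, obs


def uniform_model(T=3, m=3, n_out=3):
    """Everything uniform: marginals are uniform by symmetry."""
    spec = validate_model(HMMSpec(
        [Factor(B=np.full((m, m), 1.0 / m), D=np.full(m, 1.0 / m))],
        [Modality(A=np.full((n_out, m), 1.0 / n_out), factor=0)], T))
    obs = ObservationRecord(np.zeros((T, 1), dtype=int))
    return spec, obs


def observed_deterministic_model(seed, T=6, sizes=(3, 3)):
    """Permutation transitions, one-hot priors, identity likelihood per factor."""
    r = np.random.default_rng(seed)
    factors, modalities = [], []
    for f, m in enumerate(sizes):
        B = np.eye(m)[r.permutation(m)]
        D = np.zeros(m)
        D[r.integers(m)] = 1.0
        factors.append(Factor(B=B, D=D))
        modalities.append(Modality(A=np.eye(m), factor=f))
    return validate_model(HMMSpec(factors, modalities, T))
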