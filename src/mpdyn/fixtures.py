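"""Seeded generation of models and sampled observation sequences.

The flagship fixture mirrors the structure of the simulated experiment: two
independent hidden factors with three levels each over fifteen time steps, a
single three-outcome modality that depends on the first factor only (so the
second factor is never observed), deterministic initial states and "sticky"
stochastic transitions.  The published matrices are rendered graphically, not
printed, so the fixture is parameterised: ``stickiness`` is the self-transition
mass per column and ``likelihood_acuity`` the mass on the matched outcome;
the defaults (0.7 / 0.8) give informative-but-uncertain likelihoods and
stochastic transitions.  Externally supplied matrices can be loaded through
:mod:`mpdyn.io` for exact reproduction of a published run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Factor, HMMSpec, Modality, ObservationRecord, validate_model

__all__ = ["FixtureParams", "fig_model", "sample_trajectory", "random_model"]


@dataclass
class FixtureParams:
    """Parameters of the two-factor demonstration model."""

    n_factors: int = 2
    levels: tuple[int, ...] = (3, 3)
    T: int = 15
    stickiness: float = 0.7
    likelihood_acuity: float = 0.8
    n_outcomes: int = 3
    observed_factor: int = 0

    def __post_init__(self):
        if not 0.0 <= self.stickiness <= 1.0:
            raise ValueError("stickiness must lie in [0, 1]")
        if not 0.0 <= self.likelihood_acuity <= 1.0:
            raise ValueError("likelihood_acuity must lie in [0, 1]")
        if len(self.levels) != self.n_factors:
            raise ValueError("levels must list one size per factor")


def _sticky(m: int, p: float) -> np.ndarray:
    """Column-stochastic matrix with mass ``p`` on the diagonal."""
    off = (1.0 - p) / (m - 1) if m > 1 else 0.0
    return np.full((m, m), off) + np.eye(m) * (p - off)


def fig_model(params: FixtureParams | None = None) -> HMMSpec:
    """Two-factor sticky-transition model with one partially informative modality.

    Initial states are deterministic (state 1 of each factor); transitions are
    sticky-stochastic with the off-diagonal mass spread evenly; the likelihood
    concentrates ``likelihood_acuity`` on the outcome matched to each state.
    The second factor has no observing modality, so beliefs about it are
    driven purely by the prior and transitions.
    """
    p = params or FixtureParams()
    factors = []
    for m in p.levels:
        D = np.zeros(m)
        D[0] = 1.0
        factors.append(Factor(B=_sticky(m, p.stickiness), D=D))
    m_obs = p.levels[p.observed_factor]
    A = _rect_likelihood(p.n_outcomes, m_obs, p.likelihood_acuity)
    modalities = [Modality(A=A, factor=p.observed_factor)]
    return validate_model(HMMSpec(factors, modalities, p.T))


def _rect_likelihood(n_out: int, m: int, acuity: float) -> np.ndarray:
    """Column-stochastic likelihood with ``acuity`` on outcome ``j % n_out``."""
    A = np.full((n_out, m), (1.0 - acuity) / (n_out - 1) if n_out > 1 else 0.0)
    for j in range(m):
        A[j % n_out, j] = acuity if n_out > 1 else 1.0
    return A


def sample_trajectory(spec: HMMSpec, seed: int) -> ObservationRecord:
    """Ancestral sampling of states and outcomes; deterministic given seed."""
    rng = np.random.default_rng(seed)
    T = spec.T
    states = np.empty((T, spec.n_factors), dtype=int)
    for f, fac in enumerate(spec.factors):
        s = rng.choice(fac.m, p=fac.D)
        states[0, f] = s
        for t in range(1, T):
            s = rng.choice(fac.m, p=fac.B[:, s])
            states[t, f] = s
    outcomes = np.empty((T, spec.n_modalities), dtype=int)
    for g, mod in enumerate(spec.modalities):
        for t in range(T):
            outcomes[t, g] = rng.choice(mod.n_outcomes,
                                        p=mod.A[:, states[t, mod.factor]])
    return ObservationRecord(outcomes, true_states=states)


def random_model(dims: dict | None = None, concentration: float = 1.0,
                 seed: int = 0) -> HMMSpec:
    """Random model with Dirichlet-distributed columns (test-harness models).

    ``dims`` keys: ``levels`` (tuple of factor sizes), ``T``, ``n_outcomes``
    (per modality, one modality per factor by default), ``observed_factors``
    (which factors get a modality).  Every column of ``A`` and ``B`` and the
    prior ``D`` is an independent symmetric ``Dirichlet(concentration)`` draw.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    d = {"levels": (2,), "T": 3, "n_outcomes": None, "observed_factors": None}
    d.update(dims or {})
    rng = np.random.default_rng(seed)
    levels = tuple(d["levels"])
    observed = d["observed_factors"]
    if observed is None:
        observed = tuple(range(len(levels)))
    factors = []
    for m in levels:
        B = rng.dirichlet(np.full(m, concentration), size=m).T
        D = rng.dirichlet(np.full(m, concentration))
        factors.append(Factor(B=B, D=D))
    modalities = []
    for f in observed:
        n_out = d["n_outcomes"] or levels[f]
        A = rng.dirichlet(np.full(n_out, concentration), size=levels[f]).T
        modalities.append(Modality(A=A, factor=f))
    return validate_model(HMMSpec(factors, modalities, int(d["T"])))
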