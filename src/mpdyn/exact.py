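"""Scheduled sum-product inference on the chain, plus a brute-force oracle.

Because every modality depends on a single hidden factor, the posterior
factorises over factors and exact inference runs independently per factor as a
forward--backward sweep.  One forward and one backward pass suffice on this
acyclic graph.  Messages are normalised at every step for numerical stability,
with the forward normalisers retained: their summed logarithms are the log
evidence (the standard filtering identity).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .model import UNOBSERVED, HMMSpec, ObservationRecord, likelihood_message

__all__ = [
    "MessageSet",
    "PosteriorMarginals",
    "ImpossibleObservationError",
    "likelihood_messages",
    "forward_messages",
    "backward_messages",
    "bp_marginals",
    "pairwise_marginals",
    "log_evidence",
    "brute_force_posterior",
    "BRUTE_FORCE_GUARD",
]

#: Largest joint state-sequence count the enumeration oracle will attempt.
BRUTE_FORCE_GUARD = 10**7


class ImpossibleObservationError(ValueError):
    """The model assigns probability zero to the observation sequence."""


@dataclass
class MessageSet:
    """Sum-product messages per factor: likelihood, forward and backward.

    Each entry is a ``(T, m_f)`` array.  ``mu_fwd[0]`` is the prior ``D`` and
    ``mu_bwd[T-1]`` the all-ones vector.  ``log_norms[f][t]`` are the retained
    forward normalisers; their total is the log evidence.
    """

    mu_A: list[np.ndarray]
    mu_fwd: list[np.ndarray]
    mu_bwd: list[np.ndarray]
    log_norms: list[np.ndarray]


@dataclass
class PosteriorMarginals:
    """Singleton (and optionally adjacent-pairwise) posterior marginals.

    ``singles[f]`` is ``(T, m_f)``; ``pairs[f]`` is ``(T-1, m_f, m_f)`` with
    ``pairs[f][t, i, j] = Q(s_t = i, s_{t+1} = j)``.
    """

    singles: list[np.ndarray]
    pairs: list[np.ndarray] | None = None


def likelihood_messages(spec: HMMSpec, obs: ObservationRecord) -> list[np.ndarray]:
    """Combined likelihood message per factor and time step.

    The product over modalities observing the factor of ``P(o_t | s_t)``;
    all-ones where nothing is observed (factors with no modality get ones
    throughout, so they reduce to prior propagation).
    """
    out = []
    for f, fac in enumerate(spec.factors):
        lik = np.ones((spec.T, fac.m))
        for g in spec.modalities_for(f):
            A = spec.modalities[g].A
            for t in range(spec.T):
                lik[t] *= likelihood_message(A, int(obs.outcomes[t, g]),
                                             modality=g, t=t)
        out.append(lik)
    return out


def forward_messages(spec: HMMSpec, obs: ObservationRecord,
                     lik: list[np.ndarray] | None = None
                     ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Forward sweep per factor; returns messages and per-step log-normalisers.

    ``mu_fwd[t] = B @ normalise(mu_fwd[t-1] * mu_A[t-1])`` with
    ``mu_fwd[0] = D``.  The retained normaliser logs sum to the log evidence.
    """
    lik = likelihood_messages(spec, obs) if lik is None else lik
    fwd, log_norms = [], []
    for f, fac in enumerate(spec.factors):
        mu = np.empty((spec.T, fac.m))
        ln_c = np.empty(spec.T)
        mu[0] = fac.D
        for t in range(spec.T):
            a = mu[t] * lik[f][t]
            c = a.sum()
            if c <= 0.0:
                raise ImpossibleObservationError(
                    f"impossible observation sequence (factor {f + 1}, "
                    f"time step {t + 1})"
                )
            ln_c[t] = math.log(c)
            if t + 1 < spec.T:
                mu[t + 1] = fac.B @ (a / c)
        fwd.append(mu)
        log_norms.append(ln_c)
    return fwd, log_norms


def backward_messages(spec: HMMSpec, obs: ObservationRecord,
                      lik: list[np.ndarray] | None = None) -> list[np.ndarray]:
    """Backward sweep per factor: ``mu_bwd[t] = B.T @ (mu_bwd[t+1] * mu_A[t+1])``.

    ``mu_bwd[T-1]`` is the all-ones vector (no future evidence); each step is
    normalised to sum one (marginals are scale-invariant in the messages).
    """
    lik = likelihood_messages(spec, obs) if lik is None else lik
    bwd = []
    for f, fac in enumerate(spec.factors):
        mu = np.empty((spec.T, fac.m))
        mu[-1] = 1.0
        for t in range(spec.T - 2, -1, -1):
            b = fac.B.T @ (mu[t + 1] * lik[f][t + 1])
            s = b.sum()
            if s <= 0.0:
                raise ImpossibleObservationError(
                    f"impossible observation sequence (factor {f + 1}, "
                    f"time step {t + 1})"
                )
            mu[t] = b / s
        bwd.append(mu)
    return bwd


def messages(spec: HMMSpec, obs: ObservationRecord) -> MessageSet:
    """Full scheduled message set (one forward, one backward sweep)."""
    lik = likelihood_messages(spec, obs)
    fwd, log_norms = forward_messages(spec, obs, lik)
    bwd = backward_messages(spec, obs, lik)
    return MessageSet(lik, fwd, bwd, log_norms)


def bp_marginals(spec: HMMSpec, obs: ObservationRecord,
                 msg: MessageSet | None = None) -> PosteriorMarginals:
    """Exact singleton marginals: normalised ``mu_A * mu_fwd * mu_bwd``."""
    msg = messages(spec, obs) if msg is None else msg
    singles = []
    for f in range(spec.n_factors):
        q = msg.mu_A[f] * msg.mu_fwd[f] * msg.mu_bwd[f]
        singles.append(q / q.sum(axis=1, keepdims=True))
    return PosteriorMarginals(singles)


def pairwise_marginals(spec: HMMSpec, obs: ObservationRecord,
                       msg: MessageSet | None = None) -> PosteriorMarginals:
    """Exact adjacent-pair joints alongside the singletons.

    ``Q(s_t=i, s_{t+1}=j) ∝ (mu_fwd*mu_A)[t, i] * B[j, i] * (mu_A*mu_bwd)[t+1, j]``;
    marginalising over either argument recovers the singleton marginal.
    """
    msg = messages(spec, obs) if msg is None else msg
    post = bp_marginals(spec, obs, msg)
    pairs = []
    for f, fac in enumerate(spec.factors):
        fa = msg.mu_fwd[f] * msg.mu_A[f]
        ab = msg.mu_A[f] * msg.mu_bwd[f]
        qp = np.empty((spec.T - 1, fac.m, fac.m)) if spec.T > 1 else \
            np.empty((0, fac.m, fac.m))
        for t in range(spec.T - 1):
            J = fa[t][:, None] * fac.B.T * ab[t + 1][None, :]
            qp[t] = J / J.sum()
        pairs.append(qp)
    post.pairs = pairs
    return post


def log_evidence(spec: HMMSpec, obs: ObservationRecord) -> float:
    """Log evidence ``ln P(o_1..T)`` in nats, summed over factors.

    Computed as the sum of the logs of the forward normalisers.  Factors with
    no observing modality contribute zero.  An impossible sequence yields
    ``-inf`` (an explicit flag, not an overflow).
    """
    try:
        _, log_norms = forward_messages(spec, obs)
    except ImpossibleObservationError:
        return -math.inf
    return float(sum(ln.sum() for ln in log_norms))


def brute_force_posterior(spec: HMMSpec, obs: ObservationRecord
                          ) -> tuple[PosteriorMarginals, float]:
    """Exact posterior by enumerating every state sequence (the oracle).

    Independent of the message-passing code path: accumulates the joint
    probability ``P(s_1..T, o_1..T)`` sequence by sequence.  Guarded at
    ``prod_f m_f ** T`` <= :data:`BRUTE_FORCE_GUARD` joint sequences; beyond
    that use the forward--backward sweep instead.
    """
    total_paths = 1
    for m in spec.sizes:
        total_paths *= m ** spec.T
    if total_paths > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"state-sequence count {total_paths} exceeds the enumeration guard "
            f"({BRUTE_FORCE_GUARD}); use forward-backward inference instead"
        )
    lik = likelihood_messages(spec, obs)
    singles, pairs = [], []
    ln_ev = 0.0
    for f, fac in enumerate(spec.factors):
        m, T = fac.m, spec.T
        q = np.zeros((T, m))
        qp = np.zeros((max(T - 1, 0), m, m))
        total = 0.0
        for seq in itertools.product(range(m), repeat=T):
            p = fac.D[seq[0]]
            for t in range(1, T):
                p *= fac.B[seq[t], seq[t - 1]]
            for t in range(T):
                p *= lik[f][t, seq[t]]
            total += p
            for t in range(T):
                q[t, seq[t]] += p
            for t in range(T - 1):
                qp[t, seq[t], seq[t + 1]] += p
        if total <= 0.0:
            raise ImpossibleObservationError(
                f"impossible observation sequence (factor {f + 1})"
            )
        singles.append(q / total)
        pairs.append(qp / total)
        ln_ev += math.log(total)
    return PosteriorMarginals(singles, pairs), ln_ev
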