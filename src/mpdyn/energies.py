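"""Free-energy functionals for the three approximate posterior families.

All quantities are in nats.  A free energy is energy minus entropy of the
approximate posterior and upper-bounds the negative log evidence:

* variational (mean-field) free energy: the approximate posterior factorises
  over time steps, the energy takes expectations of ``ln B`` under the outer
  product of adjacent singleton beliefs;
* Bethe free energy: the posterior family keeps adjacent pairwise marginals,
  the energy takes true pairwise expectations and the Bethe entropy subtracts
  the mutual information between neighbours — exact on this acyclic chain;
* marginal free energies: per-time-step functionals built from forward and
  backward "marginal models" (the expectation sits inside the log; the
  backward model runs the chain in reverse through ``B†``), mixed in equal
  parts.  Their stationary points are the marginal message-passing beliefs.

Multi-factor models: factors are independent in this model class, so all
free energies sum over factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exact import PosteriorMarginals, brute_force_posterior, log_evidence
from .model import HMMSpec, ObservationRecord, floored_log, reverse_transition
from .exact import likelihood_messages

__all__ = [
    "FreeEnergyReport",
    "entropy",
    "kl_divergence",
    "variational_free_energy",
    "bethe_free_energy",
    "marginal_free_energies",
    "jensen_gap",
    "conjecture_check",
    "free_energy_report",
]

PAIR_CONSISTENCY_TOL = 1e-8


def entropy(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy in nats; ``0 * ln 0 = 0``."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=axis)


def kl_divergence(p: np.ndarray, q: np.ndarray, axis: int = -1) -> np.ndarray:
    """``D_KL[p || q]`` in nats.

    Cells with ``p = 0`` contribute zero; ``p > 0`` against ``q = 0`` yields
    ``+inf`` (an explicit flag).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log(p) - np.log(q)), 0.0)
    return terms.sum(axis=axis)


def _singles(Q) -> list[np.ndarray]:
    if isinstance(Q, PosteriorMarginals):
        return Q.singles
    return [np.asarray(q, dtype=float) for q in Q]


@dataclass
class FreeEnergyReport:
    """All functionals evaluated for one belief state (nats throughout)."""

    F_variational: float
    F_bethe: float | None
    F_forward: np.ndarray   # per time step, summed over factors
    F_backward: np.ndarray
    F_marginal: np.ndarray
    ln_evidence: float
    jensen_gap: float
    conjecture_slack: np.ndarray | None = None


def variational_free_energy(spec: HMMSpec, obs: ObservationRecord, Q) -> float:
    """Mean-field free energy of singleton beliefs ``Q`` (nats).

    Energy: expectations of ``ln B`` under outer products of adjacent
    singletons, ``ln D`` at the first step, plus the expected log likelihood;
    entropy: sum of singleton entropies.  Unobserved steps contribute no
    likelihood term (their message is all ones).
    """
    singles = _singles(Q)
    lik = likelihood_messages(spec, obs)
    F = 0.0
    for f, fac in enumerate(spec.factors):
        q = singles[f]
        lnB = floored_log(fac.B)
        energy = -float(q[0] @ floored_log(fac.D))
        # E_{Q(t)Q(t-1)}[ln B] = sum_t q[t] . (lnB @ q[t-1])
        energy -= float(np.einsum("ti,ij,tj->", q[1:], lnB, q[:-1]))
        energy -= float((q * floored_log(lik[f])).sum())
        F += energy - float(entropy(q, axis=1).sum())
    return F


def bethe_free_energy(spec: HMMSpec, obs: ObservationRecord, Q) -> float:
    """Bethe free energy of a belief state with pairwise marginals (nats).

    Requires pairwise marginals consistent with the singletons (their row and
    column sums must reproduce the singleton marginals).  Exact on this
    acyclic model: at the true posterior it equals ``-ln P(o)``.
    """
    if not isinstance(Q, PosteriorMarginals) or Q.pairs is None:
        raise ValueError("Bethe free energy needs pairwise marginals")
    lik = likelihood_messages(spec, obs)
    F = 0.0
    for f, fac in enumerate(spec.factors):
        q, qp = Q.singles[f], Q.pairs[f]
        for t in range(spec.T - 1):
            err = max(np.abs(qp[t].sum(axis=1) - q[t]).max(),
                      np.abs(qp[t].sum(axis=0) - q[t + 1]).max())
            if err > PAIR_CONSISTENCY_TOL:
                raise ValueError(
                    f"pairwise marginal inconsistent with singletons "
                    f"(factor {f + 1}, pair {t + 1}-{t + 2}, error {err:.3g})"
                )
        lnB = floored_log(fac.B)
        energy = -float(q[0] @ floored_log(fac.D))
        # E_{Q(s_t, s_{t+1})}[ln B]; qp[t, i, j] = Q(s_t=i, s_{t+1}=j)
        energy -= float(np.einsum("tij,ji->", qp, lnB))
        energy -= float((q * floored_log(lik[f])).sum())
        bethe_H = float(entropy(q, axis=1).sum())
        for t in range(spec.T - 1):
            bethe_H -= float(kl_divergence(qp[t].ravel(),
                                           np.outer(q[t], q[t + 1]).ravel()))
        F += energy - bethe_H
    return F


def marginal_free_energies(spec: HMMSpec, obs: ObservationRecord, Q,
                           alpha: float = 0.5
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward, backward, and mixed marginal free energies per time step.

    ``F_F(t)`` uses an empirical prior ``ln(B @ q[t-1])`` from the past
    (``ln D`` at the first step); ``F_B(t)`` uses ``ln(B† @ q[t+1])`` from the
    future (omitted at the last step).  The marginal free energy mixes the two
    directed priors with weight ``alpha`` each while counting the likelihood
    and entropy once.  All arrays are summed over factors.
    """
    singles = _singles(Q)
    lik = likelihood_messages(spec, obs)
    F_F = np.zeros(spec.T)
    F_B = np.zeros(spec.T)
    F_M = np.zeros(spec.T)
    for f, fac in enumerate(spec.factors):
        q = singles[f]
        Bdag = reverse_transition(fac.B)
        ln_lik = floored_log(lik[f])
        H = entropy(q, axis=1)
        ln_past = np.vstack([floored_log(fac.D)[None, :],
                             floored_log(q[:-1] @ fac.B.T)])
        ln_future = np.zeros_like(q)
        if spec.T > 1:
            ln_future[:-1] = floored_log(q[1:] @ Bdag.T)
        e_lik = (q * ln_lik).sum(axis=1)
        e_past = (q * ln_past).sum(axis=1)
        e_future = (q * ln_future).sum(axis=1)
        F_F += -(e_lik + e_past) - H
        F_B += -(e_lik + e_future) - H
        F_M += -(e_lik + alpha * e_past + alpha * e_future) - H
    return F_F, F_B, F_M


def jensen_gap(spec: HMMSpec, obs: ObservationRecord, Q) -> float:
    """``F_variational + ln P(o)`` — the divergence of ``Q`` from the posterior.

    Non-negative for any valid mean-field ``Q`` (Jensen's inequality); equals
    ``D_KL[Q(s_1..T) || P(s_1..T | o)]`` under the mean-field family.
    """
    return variational_free_energy(spec, obs, Q) + log_evidence(spec, obs)


def conjecture_check(spec: HMMSpec, obs: ObservationRecord, Q,
                     ) -> np.ndarray:
    """Per-step slack of the forward+backward free-energy inequality.

    Tests whether ``F_B(t) + F_F(t)`` exceeds
    ``-E_Q[ln P(o_t, s_t | o_{\\t})] - H[Q(s_t)]`` where the reference
    predictive conditions on every other observation; the exact predictive is
    computed by leave-one-out enumeration (size-guarded; no approximate
    fallback).  Negative slack is reported, never clipped: this is an
    empirical check of an unproven conjecture.
    """
    singles = _singles(Q)
    F_F, F_B, _ = marginal_free_energies(spec, obs, Q)
    lik = likelihood_messages(spec, obs)
    rhs = np.zeros(spec.T)
    for t in range(spec.T):
        loo = obs.masked(spec.T)  # full copy
        out = loo.outcomes.copy()
        out[t, :] = -1
        loo = ObservationRecord(out, obs.true_states)
        post_loo, ln_ev_loo = brute_force_posterior(spec, loo)
        for f in range(spec.n_factors):
            # P(o_t, s_t | o_{\t}) = P(s_t | o_{\t}) * P(o_t | s_t)
            ln_pred = floored_log(post_loo.singles[f][t]) + floored_log(lik[f][t])
            q = singles[f][t]
            rhs[t] += -float(q @ ln_pred) - float(entropy(q))
    return (F_F + F_B) - rhs


def free_energy_report(spec: HMMSpec, obs: ObservationRecord, Q,
                       *, with_conjecture: bool = False) -> FreeEnergyReport:
    """Evaluate every functional for one belief state."""
    F_var = variational_free_energy(spec, obs, Q)
    F_bethe = None
    if isinstance(Q, PosteriorMarginals) and Q.pairs is not None:
        F_bethe = bethe_free_energy(spec, obs, Q)
    F_F, F_B, F_M = marginal_free_energies(spec, obs, Q)
    ln_ev = log_evidence(spec, obs)
    slack = conjecture_check(spec, obs, Q) if with_conjecture else None
    return FreeEnergyReport(F_var, F_bethe, F_F, F_B, F_M, ln_ev,
                            F_var + ln_ev, slack)
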