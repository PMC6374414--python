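"""The three message-passing schemes as continuous-time neuronal dynamics.

Each scheme maintains, per hidden factor and time step, a membrane-potential
vector ``v`` (log-space belief parameters), a firing-rate vector
``s = softmax(v)`` (the posterior expectation) and a prediction error
``eps = log-target - v`` (gauge-fixed by mean subtraction).  Beliefs evolve by
explicit Euler on ``dv/dt = eps``, all time steps and factors updated in
parallel (Jacobi style), until ``max |eps| < tol``.

The log-target differs per scheme:

* ``VMP`` (mean field): ``ln mu_A + (ln B) @ s_prev + (ln B).T @ s_next`` —
  expectations of the log transition under neighbouring beliefs.
* ``MMP`` (marginal): ``ln mu_A + a*ln(B @ s_prev) + a*ln(B† @ s_next)`` —
  the expectation sits inside the log, attenuated by a corrective exponent
  ``a`` (default 1/2) that curbs mean-field overconfidence; ``B†`` is the
  flat-prior Bayes inversion of ``B``.
* ``BP`` (belief propagation): the sum-product target, with the forward and
  backward message populations recovered algebraically from the current
  marginals by dividing out the opposing incoming message
  (``mu_fwd ∝ exp(ln s - ln mu_A - ln mu_bwd_incoming)`` and symmetrically) —
  the adiabatic limit of message neurons with much faster time constants.
  An optional ``overcount_lesion`` removes the subtraction of ``ln mu_A``
  from the forward-message computation, so the ascending sensory message
  enters the marginal twice (a circular-inference lesion).

All three are estimators in the scikit-learn sense: construct with a model,
``fit`` on an observation record, read fitted beliefs from ``marginals_``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax as _softmax
from sklearn.base import BaseEstimator

from .exact import PosteriorMarginals, likelihood_messages
from .model import (HMMSpec, ObservationRecord, floored_log,
                    reverse_transition, validate_model)

__all__ = [
    "softmax",
    "NeuronalState",
    "Trajectory",
    "MessagePassingScheme",
    "BeliefPropagation",
    "VariationalMessagePassing",
    "MarginalMessagePassing",
    "SCHEMES",
    "make_scheme",
    "integrate",
    "lesion_overcount",
]


def softmax(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalised exponential along ``axis``; max-subtracted for stability."""
    return _softmax(np.asarray(v, dtype=float), axis=axis)


@dataclass
class NeuronalState:
    """Population activities: potentials, rates, errors, message neurons.

    ``v[f]``, ``s[f]``, ``eps[f]`` are ``(T, m_f)`` arrays; the message
    populations ``msg_fwd``/``msg_bwd`` exist only for the BP circuit.
    """

    v: list[np.ndarray]
    s: list[np.ndarray]
    eps: list[np.ndarray]
    msg_fwd: list[np.ndarray] | None = None
    msg_bwd: list[np.ndarray] | None = None

    def copy(self) -> "NeuronalState":
        return NeuronalState(
            [a.copy() for a in self.v],
            [a.copy() for a in self.s],
            [a.copy() for a in self.eps],
            None if self.msg_fwd is None else [a.copy() for a in self.msg_fwd],
            None if self.msg_bwd is None else [a.copy() for a in self.msg_bwd],
        )


@dataclass
class Trajectory:
    """Recorded belief time courses of one integration run."""

    times: np.ndarray
    snapshots: list[list[np.ndarray]]  # per grid point, per factor (T, m)
    scheme: str
    converged: bool
    n_iter: int

    def path_length(self) -> np.ndarray:
        """Cumulative L1 path length of the beliefs along the grid."""
        steps = np.zeros(len(self.times))
        for k in range(1, len(self.times)):
            steps[k] = sum(
                np.abs(a - b).sum()
                for a, b in zip(self.snapshots[k], self.snapshots[k - 1])
            )
        return np.cumsum(steps)


class MessagePassingScheme(BaseEstimator):
    """Base class: Euler integration of ``dv/dt = eps`` for one scheme.

    Parameters
    ----------
    model : HMMSpec
        The (validated) generative model.
    step_size : float
        Euler step in integration-time units.
    max_time : float
        Integration-time budget; non-convergence is flagged, not raised.
    tol : float
        Convergence threshold on ``max |eps|``.
    record_every : int
        Snapshot the beliefs every this many Euler steps.

    Attributes (after ``fit``)
    --------------------------
    state_ : NeuronalState
    marginals_ : PosteriorMarginals
    trajectory_ : Trajectory
    converged_ : bool
    n_iter_ : int
    """

    scheme = "base"

    def __init__(self, model: HMMSpec, *, step_size: float = 0.1,
                 max_time: float = 500.0, tol: float = 1e-6,
                 record_every: int = 50):
        self.model = model
        self.step_size = step_size
        self.max_time = max_time
        self.tol = tol
        self.record_every = record_every

    # -- scheme-specific pieces -------------------------------------------
    def _prepare(self, lik: list[np.ndarray]) -> dict:
        """Precompute per-factor constants (log matrices etc.)."""
        raise NotImplementedError

    def _log_target(self, f: int, s: list[np.ndarray], aux: dict) -> np.ndarray:
        """The (un-gauged) log-target for factor ``f`` at every time step."""
        raise NotImplementedError

    def _pre_step(self, v: list[np.ndarray], s: list[np.ndarray],
                  aux: dict) -> None:
        """Hook run before each Euler step (BP updates its messages here)."""

    # -- integration ------------------------------------------------------
    def _coerce_obs(self, X) -> ObservationRecord:
        if isinstance(X, ObservationRecord):
            return X
        return ObservationRecord(np.asarray(X, dtype=int))

    def fit(self, X, y=None, init: NeuronalState | None = None):
        """Integrate the belief dynamics on observation record ``X``.

        ``init`` warm-starts the membrane potentials (default: zeros, i.e.
        uniform beliefs).  Deterministic given inputs and parameters.
        """
        spec = validate_model(self.model)
        obs = self._coerce_obs(X)
        if obs.T != spec.T:
            raise ValueError(f"observation record has {obs.T} steps, model horizon is {spec.T}")
        lik = likelihood_messages(spec, obs)
        aux = self._prepare(lik)
        if init is None:
            v = [np.zeros((spec.T, fac.m)) for fac in spec.factors]
        else:
            # gauge-fix at entry: a constant shift of v must not alter s
            v = [a - a.mean(axis=1, keepdims=True) for a in init.v]
        s = [softmax(a, axis=1) for a in v]
        if init is not None and init.msg_fwd is not None:
            aux["msg_fwd"] = [a.copy() for a in init.msg_fwd]
            aux["msg_bwd"] = [a.copy() for a in init.msg_bwd]

        n_steps = max(1, int(round(self.max_time / self.step_size)))
        times, snaps = [], []
        converged = False
        eps = [np.zeros_like(a) for a in v]
        it = 0
        for it in range(n_steps + 1):
            self._pre_step(v, s, aux)
            max_eps = 0.0
            for f in range(spec.n_factors):
                tgt = self._log_target(f, s, aux)
                tgt = tgt - tgt.mean(axis=1, keepdims=True)
                eps[f] = tgt - v[f]
                max_eps = max(max_eps, float(np.abs(eps[f]).max()))
            if it % self.record_every == 0:
                times.append(it * self.step_size)
                snaps.append([a.copy() for a in s])
            if max_eps < self.tol:
                converged = True
                break
            if it == n_steps:
                break
            for f in range(spec.n_factors):
                v[f] += self.step_size * eps[f]
                v[f] -= v[f].mean(axis=1, keepdims=True)
                s[f] = softmax(v[f], axis=1)
        if not times or times[-1] < it * self.step_size:
            times.append(it * self.step_size)
            snaps.append([a.copy() for a in s])

        self.state_ = NeuronalState(v, s, eps,
                                    aux.get("msg_fwd"), aux.get("msg_bwd"))
        self.marginals_ = PosteriorMarginals([a.copy() for a in s])
        self.trajectory_ = Trajectory(np.asarray(times), snaps, self.scheme,
                                      converged, it)
        self.converged_ = converged
        self.n_iter_ = it
        return self

    def predict(self, X=None) -> np.ndarray:
        """MAP state per factor and time step (lowest index breaks ties)."""
        if X is not None:
            self.fit(X)
        return np.stack([q.argmax(axis=1) for q in self.marginals_.singles],
                        axis=1)

    def fixed_point(self, X, *, max_iter: int = 10000, tol: float = 1e-12,
                    damping: float = 0.5, init: NeuronalState | None = None
                    ) -> PosteriorMarginals:
        """Solve the scheme's target map by damped discrete iteration.

        ``v <- (1-damping) v + damping * gauge-fixed target``, all time steps
        in parallel; equivalent attractor to the ODE, useful when only the
        fixed point is wanted.
        """
        saved = (self.step_size, self.max_time, self.tol)
        try:
            self.step_size, self.max_time, self.tol = (
                damping, damping * max_iter, tol)
            self.fit(X, init=init)
        finally:
            self.step_size, self.max_time, self.tol = saved
        return self.marginals_


class VariationalMessagePassing(MessagePassingScheme):
    """Mean-field scheme: log-messages are expectations of log-transitions."""

    scheme = "VMP"

    def _prepare(self, lik):
        spec = self.model
        return {
            "ln_lik": [floored_log(L) for L in lik],
            "lnB": [floored_log(f.B) for f in spec.factors],
            "lnD": [floored_log(f.D) for f in spec.factors],
        }

    def _log_target(self, f, s, aux):
        tgt = aux["ln_lik"][f].copy()
        tgt[0] += aux["lnD"][f]
        tgt[1:] += s[f][:-1] @ aux["lnB"][f].T
        tgt[:-1] += s[f][1:] @ aux["lnB"][f]
        return tgt


class MarginalMessagePassing(MessagePassingScheme):
    """Marginal scheme: expectation inside the log, attenuated by ``alpha``.

    ``alpha`` is the corrective exponent on both directed messages (default
    1/2, the value that mixes the forward and backward marginal models in
    equal parts); it is exposed as a tunable parameter.  The backward message
    runs the chain in reverse through ``B†``.
    """

    scheme = "MMP"

    def __init__(self, model, *, alpha: float = 0.5, step_size: float = 0.1,
                 max_time: float = 500.0, tol: float = 1e-6,
                 record_every: int = 50):
        super().__init__(model, step_size=step_size, max_time=max_time,
                         tol=tol, record_every=record_every)
        self.alpha = alpha

    def _prepare(self, lik):
        spec = self.model
        return {
            "ln_lik": [floored_log(L) for L in lik],
            "B": [f.B for f in spec.factors],
            "Bdag": [reverse_transition(f.B) for f in spec.factors],
            "lnD": [floored_log(f.D) for f in spec.factors],
        }

    def _log_target(self, f, s, aux):
        a = self.alpha
        tgt = aux["ln_lik"][f].copy()
        tgt[0] += a * aux["lnD"][f]
        tgt[1:] += a * floored_log(s[f][:-1] @ aux["B"][f].T)
        tgt[:-1] += a * floored_log(s[f][1:] @ aux["Bdag"][f].T)
        return tgt


class BeliefPropagation(MessagePassingScheme):
    """Sum-product scheme with marginal-coupled message populations.

    ``msg_time_ratio=None`` (default) solves the message populations
    algebraically each step (the adiabatic limit); a positive value relaxes
    them with the given fast-to-slow time-constant ratio instead, for
    neural-mass-style experiments.  ``overcount_lesion=True`` cuts the
    subtractive likelihood connection in the forward-message computation.
    """

    scheme = "BP"

    def __init__(self, model, *, overcount_lesion: bool = False,
                 msg_time_ratio: float | None = None, step_size: float = 0.1,
                 max_time: float = 500.0, tol: float = 1e-6,
                 record_every: int = 50):
        super().__init__(model, step_size=step_size, max_time=max_time,
                         tol=tol, record_every=record_every)
        self.overcount_lesion = overcount_lesion
        self.msg_time_ratio = msg_time_ratio

    def _prepare(self, lik):
        spec = self.model
        return {
            "lik": lik,
            "ln_lik": [floored_log(L) for L in lik],
            "B": [f.B for f in spec.factors],
            "D": [f.D for f in spec.factors],
            "msg_fwd": [np.full((spec.T, fac.m), 1.0 / fac.m)
                        for fac in spec.factors],
            "msg_bwd": [np.full((spec.T, fac.m), 1.0 / fac.m)
                        for fac in spec.factors],
        }

    @staticmethod
    def _incoming(aux, f):
        """Directed messages arriving at each edge from its neighbours.

        ``F[t] = B @ (msg_fwd[t-1] * mu_A[t-1])`` with ``F[0] = D`` and
        ``G[t] = B.T @ (msg_bwd[t+1] * mu_A[t+1])`` with ``G[T-1] = ones`` —
        the sum-product recursion applied once to the message populations.
        """
        lik, B = aux["lik"][f], aux["B"][f]
        T, m = lik.shape
        F = np.empty((T, m))
        F[0] = aux["D"][f]
        if T > 1:
            F[1:] = (aux["msg_fwd"][f][:-1] * lik[:-1]) @ B.T
        G = np.ones((T, m))
        if T > 1:
            G[:-1] = (aux["msg_bwd"][f][1:] * lik[1:]) @ B
        return F, G

    def _pre_step(self, v, s, aux):
        # Message populations recovered from the marginals (the adiabatic /
        # enslaved limit): the forward message divides the incoming future
        # message out of the marginal, mu_fwd ∝ exp(ln s - ln mu_A - ln G),
        # and symmetrically mu_bwd ∝ exp(ln s - ln mu_A - ln F).  Anchored by
        # the boundary terms, the unique joint fixed point is scheduled BP.
        # ln s is the exact log-softmax of v, not floored: beliefs sharper
        # than the log floor must divide out exactly or the ratio explodes.
        for f in range(self.model.n_factors):
            F, G = self._incoming(aux, f)
            ln_s = v[f] - logsumexp(v[f], axis=1, keepdims=True)
            ln_lik = aux["ln_lik"][f]
            ln_fwd = ln_s - ln_lik - floored_log(G)
            if self.overcount_lesion:
                ln_fwd = ln_fwd + ln_lik  # starred connection cut: mu_A not subtracted
            new_fwd = softmax(ln_fwd, axis=1)
            new_bwd = softmax(ln_s - ln_lik - floored_log(F), axis=1)
            if self.msg_time_ratio:
                # fast (but not instantaneous) message relaxation
                kappa = min(1.0, self.step_size / self.msg_time_ratio)
                new_fwd = (1 - kappa) * aux["msg_fwd"][f] + kappa * new_fwd
                new_bwd = (1 - kappa) * aux["msg_bwd"][f] + kappa * new_bwd
            aux["msg_fwd"][f] = new_fwd
            aux["msg_bwd"][f] = new_bwd

    def _log_target(self, f, s, aux):
        F, G = self._incoming(aux, f)
        tgt = aux["ln_lik"][f] + floored_log(F) + floored_log(G)
        return tgt


SCHEMES = {
    "BP": BeliefPropagation,
    "VMP": VariationalMessagePassing,
    "MMP": MarginalMessagePassing,
}


def make_scheme(name: str, model: HMMSpec, **params) -> MessagePassingScheme:
    """Instantiate a scheme by name ("BP", "VMP" or "MMP")."""
    try:
        cls = SCHEMES[name.upper()]
    except KeyError:
        raise ValueError(f"unknown scheme {name!r}; choose from {sorted(SCHEMES)}")
    return cls(model, **params)


def integrate(scheme: str, spec: HMMSpec, obs, params: dict | None = None,
              init: NeuronalState | None = None
              ) -> tuple[Trajectory, NeuronalState]:
    """Functional wrapper: integrate one scheme, return trajectory and state."""
    est = make_scheme(scheme, spec, **(params or {}))
    est.fit(obs, init=init)
    return est.trajectory_, est.state_


def lesion_overcount(params: dict | None = None, scheme: str = "BP") -> dict:
    """Configuration for the circular-inference lesion of the BP circuit.

    Returns ``params`` with ``overcount_lesion=True``; only the BP network
    has the subtractive likelihood connection, so other schemes are refused.
    """
    if scheme.upper() != "BP":
        raise ValueError("the overcounting lesion is defined only for the BP circuit")
    out = dict(params or {})
    out["overcount_lesion"] = True
    return out
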