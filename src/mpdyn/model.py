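"""Discrete hidden Markov model containers, validation and message primitives.

The generative model is a chain of categorical hidden states with one or more
independent hidden *factors*.  Each factor ``f`` has ``m_f`` levels, a
column-stochastic transition matrix ``B`` with ``B[i, j] = P(s_{t+1}=i | s_t=j)``
and an initial prior ``D`` with ``D[i] = P(s_1=i)``.  Observations arrive
through *modalities*: modality ``g`` has a likelihood matrix ``A`` with
``A[i, j] = P(o_t=i | s_t=j)`` and depends on exactly one hidden factor.

All conditional-probability matrices are column-stochastic (columns index the
conditioning variable).  Logarithms throughout the package are floored as
``log(x + 1e-16)`` so that structural zeros (deterministic priors, permutation
transitions) stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UNOBSERVED",
    "LOG_FLOOR",
    "STOCHASTIC_TOL",
    "Factor",
    "Modality",
    "HMMSpec",
    "ObservationRecord",
    "ModelValidationError",
    "floored_log",
    "validate_model",
    "reverse_transition",
    "likelihood_message",
]

#: Sentinel outcome index marking "not yet observed".
UNOBSERVED: int = -1

#: Additive floor inside every logarithm; tolerates structural zeros.
LOG_FLOOR: float = 1e-16

#: Tolerance on column sums of stochastic matrices at validation time.
STOCHASTIC_TOL: float = 1e-10


class ModelValidationError(ValueError):
    """Raised when a model specification violates a stochasticity invariant."""


def floored_log(x) -> np.ndarray:
    """Elementwise ``log(x + LOG_FLOOR)``; finite for non-negative input."""
    return np.log(np.asarray(x, dtype=float) + LOG_FLOOR)


@dataclass
class Factor:
    """One hidden factor: transition matrix ``B`` and initial prior ``D``."""

    B: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        self.D = np.asarray(self.D, dtype=float)

    @property
    def m(self) -> int:
        """Number of levels of this factor."""
        return len(self.D)


@dataclass
class Modality:
    """One outcome modality: likelihood ``A`` and its target hidden factor."""

    A: np.ndarray
    factor: int

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)

    @property
    def n_outcomes(self) -> int:
        return self.A.shape[0]


@dataclass
class HMMSpec:
    """The full generative model: factors, modalities, and horizon ``T``."""

    factors: list[Factor]
    modalities: list[Modality]
    T: int

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(f.m for f in self.factors)

    def modalities_for(self, factor: int) -> list[int]:
        """Indices of modalities observing the given factor."""
        return [g for g, mod in enumerate(self.modalities) if mod.factor == factor]


@dataclass
class ObservationRecord:
    """Outcome indices per time step and modality, with optional true states.

    ``outcomes`` has shape ``(T, n_modalities)``; entries are 0-based outcome
    indices or :data:`UNOBSERVED`.  ``true_states`` (shape ``(T, n_factors)``)
    holds the generating state sequence when known.
    """

    outcomes: np.ndarray
    true_states: np.ndarray | None = None

    def __post_init__(self):
        self.outcomes = np.atleast_2d(np.asarray(self.outcomes, dtype=int))
        if self.true_states is not None:
            self.true_states = np.atleast_2d(np.asarray(self.true_states, dtype=int))

    @property
    def T(self) -> int:
        return self.outcomes.shape[0]

    def masked(self, n_revealed: int) -> "ObservationRecord":
        """Copy with outcomes after the first ``n_revealed`` steps hidden."""
        out = self.outcomes.copy()
        out[n_revealed:, :] = UNOBSERVED
        return ObservationRecord(out, self.true_states)


def _check_columns(M: np.ndarray, what: str, tol: float = STOCHASTIC_TOL) -> np.ndarray:
    if np.any(M < 0):
        raise ModelValidationError(f"{what} has negative entries")
    sums = M.sum(axis=0)
    bad = np.where(np.abs(sums - 1.0) > tol)[0]
    if bad.size:
        raise ModelValidationError(
            f"{what}: column {bad[0] + 1} sums to {sums[bad[0]]:.12g}, expected 1"
        )
    # renormalise drift within tolerance
    return M / sums


def validate_model(spec: HMMSpec) -> HMMSpec:
    """Check all stochasticity invariants of a model specification.

    Columns of every ``B`` and ``A`` and each prior ``D`` must sum to one
    within ``STOCHASTIC_TOL`` (drift within tolerance is renormalised away);
    every modality must point at an existing factor; ``T >= 1``.

    Raises
    ------
    ModelValidationError
        Naming the first offending factor/modality and column.
    """
    if spec.T < 1:
        raise ModelValidationError(f"horizon T must be >= 1, got {spec.T}")
    for f, fac in enumerate(spec.factors):
        m = fac.m
        if fac.B.shape != (m, m):
            raise ModelValidationError(
                f"factor {f + 1}: B has shape {fac.B.shape}, expected {(m, m)}"
            )
        fac.B = _check_columns(fac.B, f"factor {f + 1} transition matrix B")
        if np.any(fac.D < 0) or abs(fac.D.sum() - 1.0) > STOCHASTIC_TOL:
            raise ModelValidationError(
                f"factor {f + 1}: initial prior D sums to {fac.D.sum():.12g}"
            )
        fac.D = fac.D / fac.D.sum()
    for g, mod in enumerate(spec.modalities):
        if not 0 <= mod.factor < spec.n_factors:
            raise ModelValidationError(
                f"modality {g + 1}: target factor {mod.factor + 1} does not exist"
            )
        m = spec.factors[mod.factor].m
        if mod.A.shape[1] != m:
            raise ModelValidationError(
                f"modality {g + 1}: A has {mod.A.shape[1]} columns, factor has {m} levels"
            )
        mod.A = _check_columns(mod.A, f"modality {g + 1} likelihood matrix A")
    return spec


def reverse_transition(B: np.ndarray) -> np.ndarray:
    """Bayes-invert a column-stochastic transition matrix under a flat prior.

    Returns ``B†`` with ``B†[i, j] = B[j, i] / sum_k B[j, k]`` — the transpose
    of ``B`` with renormalised columns, i.e. ``P(s_t | s_{t+1})`` when the
    earlier state is a-priori uniform.  A row of ``B`` that is all zero means
    the corresponding state is unreachable as a successor; its ``B†`` column is
    undefined and is filled with the uniform distribution (with a warning).
    """
    B = np.asarray(B, dtype=float)
    row_sums = B.sum(axis=1)
    dead = row_sums <= 0.0
    if np.any(dead):
        warnings.warn(
            "reverse_transition: state(s) %s are unreachable as successors; "
            "filling the corresponding columns with the uniform distribution"
            % (np.where(dead)[0] + 1).tolist(),
            RuntimeWarning,
            stacklevel=2,
        )
        row_sums = np.where(dead, 1.0, row_sums)
    Bdag = (B / row_sums[:, None]).T
    m = B.shape[0]
    Bdag[:, dead] = 1.0 / m
    return Bdag


def likelihood_message(A: np.ndarray, o: int, *, modality: int | None = None,
                       t: int | None = None) -> np.ndarray:
    """Likelihood message ``P(o_t | s_t)`` as a vector over states.

    Row ``o`` of ``A`` when the outcome is observed; the all-ones vector when
    ``o`` is :data:`UNOBSERVED` (an uninformative message — ones rather than
    uniform, so products of messages remain unnormalised joint terms).
    """
    A = np.asarray(A, dtype=float)
    if o == UNOBSERVED:
        return np.ones(A.shape[1])
    if not 0 <= o < A.shape[0]:
        where = ""
        if modality is not None or t is not None:
            where = " (modality %s, time step %s)" % (
                "?" if modality is None else modality + 1,
                "?" if t is None else t + 1,
            )
        raise IndexError(f"outcome index {o} out of range 0..{A.shape[0] - 1}{where}")
    return A[o, :].copy()
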