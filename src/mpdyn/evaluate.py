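"""Online inference experiments and the scheme-comparison metrics.

The online experiment presents outcomes sequentially: after each new outcome
the remaining steps are marked unobserved, each scheme warm-starts from its
previous beliefs and integrates to convergence, and the beliefs over *all*
time steps are snapshotted.  Belief propagation serves as the gold standard
(its fixed point is exact on this model class); the other schemes are scored
by their KL divergence from it, their inferred-state errors against the
generating sequence, and their posterior-entropy profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import NeuronalState, Trajectory, make_scheme
from .exact import PosteriorMarginals, bp_marginals
from .energies import entropy, kl_divergence
from .fixtures import sample_trajectory
from .model import HMMSpec, ObservationRecord

__all__ = [
    "OnlineResult",
    "ComparisonSummary",
    "online_experiment",
    "kl_to_reference",
    "map_errors",
    "entropy_profile",
    "architecture_cost",
    "comparison_report",
]


@dataclass
class OnlineResult:
    """Per-scheme beliefs after each successive outcome presentation.

    ``beliefs[scheme]`` is a list over presentation count ``t = 1..T`` of
    per-factor ``(T, m)`` arrays; the final entry is the full-data posterior.
    """

    beliefs: dict[str, list[list[np.ndarray]]]
    trajectories: dict[str, list[Trajectory]]
    converged: dict[str, list[bool]]

    def final(self, scheme: str) -> PosteriorMarginals:
        return PosteriorMarginals([a.copy() for a in self.beliefs[scheme][-1]])


@dataclass
class ComparisonSummary:
    """Scheme-comparison metrics for one model/sequence (and replicates)."""

    summed_kl: dict[str, float]
    per_tau_kl: dict[str, np.ndarray]
    map_error_count: dict[str, int]
    error_steps: dict[str, list[int]]
    entropy_profiles: dict[str, list[np.ndarray]]
    update_profile: dict[str, np.ndarray]
    replicates: pd.DataFrame | None = None
    fraction_vmp_further: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Per-scheme scalar metrics as a tidy table."""
        rows = [
            {"scheme": k, "summed_kl_to_bp": self.summed_kl[k],
             "map_errors": self.map_error_count[k],
             "error_steps": ",".join(str(s + 1) for s in self.error_steps[k])}
            for k in self.summed_kl
        ]
        return pd.DataFrame(rows)


def online_experiment(spec: HMMSpec, obs: ObservationRecord,
                      schemes=("BP", "VMP", "MMP"), params: dict | None = None,
                      warm_start: bool = True) -> OnlineResult:
    """Sequential evidence accumulation for each scheme.

    ``params`` may be a dict of shared estimator keyword arguments or a dict
    of per-scheme dicts keyed by scheme name.
    """
    params = params or {}
    beliefs: dict[str, list] = {}
    trajs: dict[str, list] = {}
    conv: dict[str, list] = {}
    for name in schemes:
        kw = params.get(name, params) if any(k in params for k in schemes) \
            else params
        est = make_scheme(name, spec, **kw)
        state: NeuronalState | None = None
        beliefs[name], trajs[name], conv[name] = [], [], []
        for t in range(1, spec.T + 1):
            est.fit(obs.masked(t), init=state if warm_start else None)
            state = est.state_
            beliefs[name].append([a.copy() for a in est.marginals_.singles])
            trajs[name].append(est.trajectory_)
            conv[name].append(est.converged_)
    return OnlineResult(beliefs, trajs, conv)


def kl_to_reference(ref: PosteriorMarginals, Q: PosteriorMarginals
                    ) -> tuple[np.ndarray, float]:
    """Per-step and summed ``D_KL[ref || Q]`` over factors (nats)."""
    per_tau = None
    for rq, qq in zip(ref.singles, Q.singles):
        if rq.shape != qq.shape:
            raise ValueError("marginal shapes do not match")
        kl = kl_divergence(rq, qq, axis=1)
        per_tau = kl if per_tau is None else per_tau + kl
    return per_tau, float(per_tau.sum())


def map_errors(Q: PosteriorMarginals, true_states: np.ndarray
               ) -> tuple[int, list[int]]:
    """Steps where the MAP state (lowest-index tie-break) misses the truth.

    Returns the total mismatch count over factors and the sorted list of
    0-based offending steps (union over factors).
    """
    if true_states is None:
        raise ValueError("true states are required to count MAP errors")
    true_states = np.atleast_2d(np.asarray(true_states, dtype=int))
    count = 0
    steps: set[int] = set()
    for f, q in enumerate(Q.singles):
        guess = q.argmax(axis=1)
        bad = np.where(guess != true_states[:, f])[0]
        count += bad.size
        steps.update(bad.tolist())
    return count, sorted(steps)


def entropy_profile(Q: PosteriorMarginals) -> list[np.ndarray]:
    """Shannon entropy (nats) of each singleton marginal, per factor."""
    return [entropy(q, axis=1) for q in Q.singles]


def architecture_cost(scheme: str, n: int, m: int, t: int) -> int:
    """Neuronal populations needed: ``2 n m t`` for VMP/MMP, ``4 n m t`` for BP.

    The marginal-coupled schemes need one marginal and one error population
    per state, factor and time step; the BP circuit additionally needs the
    two directed message populations.
    """
    if min(n, m, t) < 1:
        raise ValueError("n, m and t must be positive")
    mult = {"BP": 4, "VMP": 2, "MMP": 2}.get(scheme.upper())
    if mult is None:
        raise ValueError(f"unknown scheme {scheme!r}")
    return mult * n * m * t


def _update_profile(trajectories: list[Trajectory]) -> np.ndarray:
    """Cumulative L1 belief path length over the concatenated trial.

    Returns an ``(n, 2)`` array of (integration time, cumulative path-length
    fraction); presentations are laid end to end on the time axis.
    """
    times, cums = [], []
    offset = 0.0
    running = 0.0
    last = None
    for traj in trajectories:
        pl = traj.path_length()
        if last is not None and len(traj.snapshots):
            running += sum(np.abs(a - b).sum()
                           for a, b in zip(traj.snapshots[0], last))
        times.append(offset + np.asarray(traj.times, dtype=float))
        cums.append(running + pl)
        running = cums[-1][-1]
        offset = times[-1][-1]
        last = traj.snapshots[-1]
    t = np.concatenate(times)
    cum = np.concatenate(cums)
    total = cum[-1] if cum[-1] > 0 else 1.0
    return np.column_stack([t, cum / total])


def comparison_report(spec: HMMSpec, obs: ObservationRecord | None = None,
                      params: dict | None = None,
                      seeds=None, schemes=("BP", "VMP", "MMP"),
                      unobserved_factor: int | None = None
                      ) -> ComparisonSummary:
    """Run the full scheme comparison on one sequence (plus replicates).

    For the primary sequence (``obs``, or a sample at the first seed) the
    report holds summed/per-step KL to the BP beliefs, MAP error counts and
    steps, entropy profiles, and the within-trial update-timing profile.
    With ``seeds``, fresh sequences are sampled per seed and the KL ordering
    ``sum KL(BP||VMP) > sum KL(BP||MMP)`` is tallied across replicates.
    """
    seeds = list(seeds) if seeds is not None else []
    if obs is None:
        if not seeds:
            raise ValueError("need an observation record or at least one seed")
        obs = sample_trajectory(spec, seeds[0])

    result = online_experiment(spec, obs, schemes=schemes, params=params)
    finals = {name: result.final(name) for name in schemes}
    ref = finals.get("BP") or bp_marginals(spec, obs)

    summed_kl, per_tau, errs, err_steps, ents, upd = {}, {}, {}, {}, {}, {}
    for name in schemes:
        per_tau[name], summed_kl[name] = kl_to_reference(ref, finals[name])
        if obs.true_states is not None:
            errs[name], err_steps[name] = map_errors(finals[name],
                                                     obs.true_states)
        else:
            errs[name], err_steps[name] = 0, []
        ents[name] = entropy_profile(finals[name])
        upd[name] = _update_profile(result.trajectories[name])

    rep_frame, frac = None, None
    if seeds:
        rows = []
        for seed in seeds:
            o = sample_trajectory(spec, seed)
            res = online_experiment(spec, o, schemes=schemes, params=params)
            f = {name: res.final(name) for name in schemes}
            r = f.get("BP") or bp_marginals(spec, o)
            row = {"seed": seed}
            for name in schemes:
                _, row[f"kl_bp_{name.lower()}"] = kl_to_reference(r, f[name])
                if o.true_states is not None:
                    row[f"errors_{name.lower()}"], _ = map_errors(
                        f[name], o.true_states)
            rows.append(row)
        rep_frame = pd.DataFrame(rows)
        if {"kl_bp_vmp", "kl_bp_mmp"} <= set(rep_frame.columns):
            frac = float((rep_frame["kl_bp_vmp"]
                          > rep_frame["kl_bp_mmp"]).mean())
    return ComparisonSummary(summed_kl, per_tau, errs, err_steps, ents, upd,
                             rep_frame, frac)
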