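"""Plain-text readers and writers for models, sequences and results.

Model files are YAML with ``factors``, ``modalities`` and ``T``; matrices are
stored row-major under the column-stochastic convention (``M[i][j] =
P(child=i | parent=j)``).  A file may declare ``convention: row_stochastic``
to have its matrices transposed on load.  Observation files are delimited
text, one row per time step, one column per modality, 1-based outcome
indices with ``.`` for "not yet observed", and optional ``s<f>`` columns for
the generating states.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exact import PosteriorMarginals
from .dynamics import Trajectory
from .model import (UNOBSERVED, Factor, HMMSpec, Modality, ObservationRecord,
                    validate_model)

__all__ = [
    "load_model", "save_model",
    "load_observations", "save_observations",
    "marginals_to_frame", "save_marginals",
    "trajectory_to_frame", "save_trajectory",
]


def load_model(path) -> HMMSpec:
    """Read and validate a model-specification file (YAML or JSON)."""
    doc = yaml.safe_load(Path(path).read_text())
    convention = doc.get("convention", "column_stochastic")
    if convention not in ("column_stochastic", "row_stochastic"):
        raise ValueError(f"unknown matrix convention {convention!r}")

    def mat(x):
        M = np.asarray(x, dtype=float)
        return M.T if convention == "row_stochastic" else M

    factors = [Factor(B=mat(f["B"]), D=np.asarray(f["D"], dtype=float))
               for f in doc["factors"]]
    modalities = [Modality(A=mat(g["A"]), factor=int(g["factor"]) - 1)
                  for g in doc.get("modalities", [])]
    return validate_model(HMMSpec(factors, modalities, int(doc["T"])))


def save_model(spec: HMMSpec, path) -> None:
    """Write a model to YAML under the column-stochastic convention."""
    doc = {
        "convention": "column_stochastic",
        "T": int(spec.T),
        "factors": [{"B": f.B.tolist(), "D": f.D.tolist()}
                    for f in spec.factors],
        "modalities": [{"A": g.A.tolist(), "factor": g.factor + 1}
                       for g in spec.modalities],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_observations(path, sep: str = "\t") -> ObservationRecord:
    """Read an observation file; outcome columns ``o<g>``, states ``s<f>``."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    o_cols = [c for c in df.columns if c.startswith("o")]
    s_cols = [c for c in df.columns if c.startswith("s")]
    if not o_cols:
        raise ValueError("observation file has no outcome (o*) columns")
    out = np.full((len(df), len(o_cols)), UNOBSERVED, dtype=int)
    for g, c in enumerate(o_cols):
        col = df[c].astype(str).str.strip()
        mask = col != "."
        out[mask.to_numpy(), g] = col[mask].astype(int).to_numpy() - 1
    true_states = None
    if s_cols:
        true_states = df[s_cols].astype(int).to_numpy() - 1
    return ObservationRecord(out, true_states)


def save_observations(obs: ObservationRecord, path, sep: str = "\t") -> None:
    """Write an observation record (1-based indices, ``.`` for unobserved)."""
    cols = {}
    for g in range(obs.outcomes.shape[1]):
        col = obs.outcomes[:, g]
        cols[f"o{g + 1}"] = ["." if v == UNOBSERVED else str(v + 1)
                             for v in col]
    if obs.true_states is not None:
        for f in range(obs.true_states.shape[1]):
            cols[f"s{f + 1}"] = (obs.true_states[:, f] + 1).astype(str)
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def marginals_to_frame(Q: PosteriorMarginals) -> pd.DataFrame:
    """Singleton marginals as a tidy table (factor, tau, state, probability)."""
    rows = []
    for f, q in enumerate(Q.singles):
        for t in range(q.shape[0]):
            for i in range(q.shape[1]):
                rows.append({"factor": f + 1, "tau": t + 1, "state": i + 1,
                             "probability": q[t, i]})
    return pd.DataFrame(rows)


def save_marginals(Q: PosteriorMarginals, path, sep: str = "\t") -> None:
    marginals_to_frame(Q).to_csv(path, sep=sep, index=False)


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Belief time courses as a tidy table (time, factor, tau, state, s)."""
    rows = []
    for k, time in enumerate(traj.times):
        for f, s in enumerate(traj.snapshots[k]):
            for t in range(s.shape[0]):
                for i in range(s.shape[1]):
                    rows.append({"time": float(time), "factor": f + 1,
                                 "tau": t + 1, "state": i + 1,
                                 "s_value": s[t, i]})
    return pd.DataFrame(rows)


def save_trajectory(traj: Trajectory, path, *, metadata: dict | None = None,
                    sep: str = "\t") -> None:
    """Write a trajectory table plus a JSON sidecar with run metadata."""
    path = Path(path)
    trajectory_to_frame(traj).to_csv(path, sep=sep, index=False)
    meta = {"scheme": traj.scheme, "converged": bool(traj.converged),
            "n_iter": int(traj.n_iter)}
    meta.update(metadata or {})
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2))
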