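"""Pearson correlation of enzyme and metabolite time series.

Correlations are computed pairwise over the uniform reporting grid of a
simulated trajectory (no resampling).  A constant series has no defined
correlation with anything; such entries carry NaN as an explicit
"undefined" sentinel (the diagonal stays 1 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_model import ConfigError
from .simulate import Trajectory

__all__ = ["CorrelationMatrix", "correlate"]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson-r matrix with labelled rows/columns."""

    labels: list[str]
    matrix: np.ndarray

    def r(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a),
                                 self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels,
                            columns=self.labels)


def _series(traj: Trajectory, name: str) -> np.ndarray:
    if name in traj.metabolite_ids:
        return traj.metabolite(name)
    if name in traj.reaction_ids:
        return traj.enzyme(name)
    raise ConfigError(f"unknown variable {name!r} (neither metabolite nor "
                      f"enzyme)")


def correlate(traj: Trajectory,
              variables: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson r between the selected series of a trajectory.

    ``variables`` may mix metabolite names (concentration series) and
    reaction names (enzyme-level series); default is every enzyme plus
    every metabolite.
    """
    if variables is None:
        variables = list(traj.reaction_ids) + list(traj.metabolite_ids)
    if traj.t.size < 2:
        raise ConfigError("need at least two time points")
    X = np.vstack([_series(traj, v) for v in variables])
    sd = X.std(axis=1)
    constant = sd < 1e-300
    n = len(variables)
    M = np.full((n, n), np.nan)
    ok = ~constant
    if ok.any():
        M[np.ix_(ok, ok)] = np.corrcoef(X[ok])
    np.fill_diagonal(M, 1.0)
    # clip numerical overshoot beyond [-1, 1]
    M = np.clip(M, -1.0, 1.0, out=M)
    return CorrelationMatrix(labels=list(variables), matrix=M)
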