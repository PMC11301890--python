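"""Time-dependent predictive-performance measures.

Two curves, both evaluated on a common time grid from per-subject
predicted survival probabilities S_i(t):

* Harrell-style concordance truncated at t — over pairs (i, j) with
  T_i < T_j, delta_i = 1 and T_i <= t, the fraction where the earlier-event
  subject has the lower predicted survival (ties count 1/2);
* inverse-probability-of-censoring-weighted (IPCW) Brier score — the
  weighted mean squared error between the event-free indicator 1{T_i > t}
  and S_i(t), with weights 1/G(t) for subjects still at risk and 1/G(T_i-)
  for subjects with an observed event by t, where G is the Kaplan-Meier
  estimate of the censoring distribution. Censored-before-t subjects get
  weight 0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import kaplan_meier
from .data_io import SurvivalData

__all__ = [
    "RiskMatrix",
    "EvaluationCurve",
    "concordance_over_time",
    "prediction_error_over_time",
    "default_grid",
]


@dataclass(frozen=True)
class RiskMatrix:
    """Predicted survival probabilities S_i(t) on a common grid.

    ``values[i, j]`` is subject i's predicted probability of being
    event-free at ``grid[j]`` (common landmark, default s = 0).
    """

    subject_ids: np.ndarray
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "subject_ids", np.asarray(self.subject_ids))
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.subject_ids), len(self.grid)):
            raise ValueError("values must be (n_subjects, n_grid)")
        if ((self.values < -1e-9) | (self.values > 1 + 1e-9)).any():
            raise ValueError("survival probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class EvaluationCurve:
    grid: np.ndarray
    value: np.ndarray  # NaN where the metric is undefined at that time
    n_used: np.ndarray  # usable pairs (concordance) or at-risk count (PE)
    metric_name: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.grid, "value": self.value, "n_used": self.n_used}
        )


def default_grid(surv: SurvivalData, n_points: int = 10) -> np.ndarray:
    """Deciles (or n_points-iles) of the observed event times."""
    ev = surv.records.loc[surv.records["event"] == 1, "observed_time"].to_numpy()
    if ev.size == 0:
        raise ValueError("no events; cannot build an evaluation grid")
    probs = np.arange(1, n_points + 1) / n_points
    return np.unique(np.quantile(ev, probs))


def _align(risk: RiskMatrix, surv: SurvivalData):
    pos = {sid: k for k, sid in enumerate(risk.subject_ids)}
    ids = surv.subject_ids
    missing = [sid for sid in ids if sid not in pos]
    if missing:
        raise ValueError(f"subjects missing from the risk matrix: {missing[:10]}")
    idx = np.array([pos[sid] for sid in ids])
    T = surv.records["observed_time"].to_numpy(dtype=float)
    delta = surv.records["event"].to_numpy(dtype=int)
    return risk.values[idx], T, delta


def concordance_over_time(
    risk: RiskMatrix, surv: SurvivalData, grid=None
) -> EvaluationCurve:
    """Truncated Harrell concordance of S_i(t) against the observed times."""
    if grid is None:
        grid = risk.grid
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    S, T, delta = _align(risk, surv)
    # interpolate the risk matrix onto the requested grid (step-constant)
    col = np.searchsorted(risk.grid, grid, side="left").clip(0, len(risk.grid) - 1)

    values = np.full(grid.size, np.nan)
    n_pairs = np.zeros(grid.size, dtype=int)
    for g, t in enumerate(grid):
        s_t = S[:, col[g]]
        conc = ties = usable = 0
        for i in np.flatnonzero((delta == 1) & (T <= t)):
            comp = T > T[i]
            usable += int(comp.sum())
            diff = s_t[comp] - s_t[i]
            conc += int((diff > 0).sum())
            ties += int((diff == 0).sum())
        n_pairs[g] = usable
        if usable:
            values[g] = (conc + 0.5 * ties) / usable
    return EvaluationCurve(
        grid=grid, value=values, n_used=n_pairs, metric_name="concordance"
    )


def prediction_error_over_time(
    risk: RiskMatrix, surv: SurvivalData, grid=None
) -> EvaluationCurve:
    """IPCW Brier score PE(t) with censoring-Kaplan-Meier weights."""
    if grid is None:
        grid = risk.grid
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    S, T, delta = _align(risk, surv)
    col = np.searchsorted(risk.grid, grid, side="left").clip(0, len(risk.grid) - 1)

    G = kaplan_meier(T, 1 - delta)  # censoring-distribution survival
    n = T.size
    values = np.full(grid.size, np.nan)
    n_at_risk = np.zeros(grid.size, dtype=int)
    for g, t in enumerate(grid):
        s_t = S[:, col[g]]
        at_risk = T > t
        had_event = (T <= t) & (delta == 1)
        n_at_risk[g] = int(at_risk.sum())
        g_t = float(G(t))
        if g_t == 0.0 and at_risk.any():
            warnings.warn(
                f"censoring survival G({t}) = 0; prediction error undefined",
                stacklevel=2,
            )
            continue
        w = np.zeros(n)
        if at_risk.any():
            w[at_risk] = 1.0 / g_t
        g_left = G.left_limit(T[had_event])
        if (g_left == 0).any():
            warnings.warn(
                f"censoring survival G(T-) = 0 for some events before t={t}",
                stacklevel=2,
            )
            continue
        w[had_event] = 1.0 / g_left
        err = (at_risk.astype(float) - s_t) ** 2
        values[g] = float(np.sum(w * err) / n)
    return EvaluationCurve(
        grid=grid, value=values, n_used=n_at_risk, metric_name="prediction_error"
    )
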