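"""One-at-a-time parameter sensitivity over the fitted population.

Each of the 20 healthy free parameters is swept across +/-50% of its fitted
value in 100 uniform steps; the settled state of each area is recorded for
every surviving sweep value (sweeps whose model diverges, loses stability or
leaves the physical box are discarded together with their parameter value).
Sweep values and responses are pooled across subjects, and the index

    I[param, area] = std(A / median(A)) / std(V / median(V))

relates the normalized spread of the area responses A to that of the swept
values V.  The matrix is finally normalized to its maximum entry, so 1 marks
the most influential parameter/area pair and 0 a parameter without effect.
Standard deviations use the population (ddof = 0) convention, which cancels
in the normalized matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._evaluator import ConditionKernel
from .constants import F_MAX_HZ
from .model import AREAS, PARAM_KEYS, ParameterSet, SubjectModel, apply_condition
from .stability import DEFAULT_MARGIN

__all__ = [
    "SensitivityMatrix",
    "parameter_grid",
    "area_responses",
    "sensitivity_index",
    "sensitivity_matrix",
]


def parameter_grid(v: float, n: int = 100) -> np.ndarray:
    """Uniform sweep grid (i/(n-1) + (n-3)/(2(n-1))) * v, i = 1..n.

    Endpoints are exactly 0.5 v and 1.5 v with step v/(n-1).
    """
    if v <= 0:
        raise ValueError("parameter value must be strictly positive")
    if n < 2:
        raise ValueError("grid needs at least two points")
    i = np.arange(1, n + 1, dtype=float)
    return (i / (n - 1) + (n - 3) / (2.0 * (n - 1))) * v


def _sham_params(subject) -> ParameterSet:
    if isinstance(subject, SubjectModel):
        return apply_condition(subject, "SHAM")
    if isinstance(subject, ParameterSet):
        return subject
    raise TypeError("expected a SubjectModel or ParameterSet")


def area_responses(
    subject,
    param_key: str,
    grid: np.ndarray,
    *,
    fmax: float = F_MAX_HZ,
    margin: float = DEFAULT_MARGIN,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Settled per-area values across a sweep of one healthy parameter.

    Returns the surviving sweep values and, per area, the matching settled
    states; diverged, unstable or nonphysical sweeps are removed from both.
    """
    params = _sham_params(subject)
    spec: dict[str, tuple] = {k: ("c", params[k]) for k in PARAM_KEYS}
    spec[param_key] = ("x", 0)
    kernel = ConditionKernel(params.tau, spec)
    X = np.asarray(grid, dtype=float)[:, None]
    ev = kernel.evaluate(X)
    y, lam, ok = ev["y"], ev["lam"], ev["ok"]
    keep = ok & (lam < -margin) & (y.min(axis=1) >= 0.0) & (y.max(axis=1) <= fmax)
    kept = np.asarray(grid, dtype=float)[keep]
    responses = {a: y[keep, i].copy() for i, a in enumerate(AREAS)}
    return kept, responses


def sensitivity_index(area_set: np.ndarray, param_set: np.ndarray) -> float:
    """std(A/median(A)) / std(V/median(V)) for one parameter/area pair."""
    A = np.asarray(area_set, dtype=float)
    V = np.asarray(param_set, dtype=float)
    if A.size == 0 or V.size == 0:
        raise ValueError("response and sweep sets must be non-empty")
    medA, medV = np.median(A), np.median(V)
    if medA == 0.0 or medV == 0.0:
        raise ValueError("zero median; the normalized index is undefined")
    denom = np.std(V / medV)
    if denom == 0.0:
        raise ValueError("sweep values have zero spread")
    return float(np.std(A / medA) / denom)


@dataclass
class SensitivityMatrix:
    """Normalized index table: one row per healthy free parameter, one
    column per area; entries in [0, 1] with the global maximum at 1."""

    table: pd.DataFrame
    raw_max: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="parameter")

    def to_json(self, path=None) -> str:
        text = self.table.to_json(orient="index", indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def heatmap(self, ax=None):
        """Render the matrix as a heatmap (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 8))
        im = ax.imshow(self.table.values, aspect="auto", cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(len(self.table.columns)), self.table.columns, rotation=45)
        ax.set_yticks(range(len(self.table.index)), self.table.index, fontsize=7)
        ax.figure.colorbar(im, ax=ax, label="normalized sensitivity")
        return ax


def sensitivity_matrix(
    subjects: Sequence,
    *,
    param_keys: Sequence[str] = PARAM_KEYS,
    grid_size: int = 100,
    fmax: float = F_MAX_HZ,
    margin: float = DEFAULT_MARGIN,
) -> SensitivityMatrix:
    """Pooled sensitivity matrix of a fitted cohort's healthy models.

    Sweep values and responses are pooled across subjects before the index
    is computed, then the matrix is normalized to its maximum entry.
    """
    pooled_V: Mapping[str, list] = {k: [] for k in param_keys}
    pooled_A: Mapping[tuple[str, str], list] = {(k, a): [] for k in param_keys for a in AREAS}
    for subject in subjects:
        params = _sham_params(subject)
        for key in param_keys:
            v = params[key]
            if v <= 0:
                continue  # a zero parameter has no multiplicative sweep
            grid = parameter_grid(v, grid_size)
            kept, responses = area_responses(params, key, grid, fmax=fmax, margin=margin)
            if kept.size == 0:
                continue
            pooled_V[key].append(kept)
            for a in AREAS:
                pooled_A[(key, a)].append(responses[a])

    raw = pd.DataFrame(0.0, index=list(param_keys), columns=list(AREAS))
    for key in param_keys:
        if not pooled_V[key]:
            continue
        V = np.concatenate(pooled_V[key])
        for a in AREAS:
            A = np.concatenate(pooled_A[(key, a)])
            raw.loc[key, a] = sensitivity_index(A, V)
    raw_max = float(raw.values.max())
    if raw_max <= 0:
        raise ValueError("all sensitivities vanished; nothing to normalize")
    return SensitivityMatrix(raw / raw_max, raw_max)
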