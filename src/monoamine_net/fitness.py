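"""Composed model fitness.

Every fitness figure maps a non-negative penalty into (0, 1] through the
shape 1/(1 + penalty); the figures of one model are combined as

    f = min_i(f_i) * (1/n) * sum_i f_i

so a single failed figure zeroes the whole fitness while the mean rewards
uniform quality.  Area errors use *relative* deviations so that DRN
(~1.4 Hz) and GP (~22 Hz) weigh comparably; range figures penalize the
relative distance to the nearest bound; the stability figure is 1 exactly
when the linearization passes the margin test; a simulation that aborts or
settles outside the physical box scores 0 outright.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import F_MAX_HZ
from .integrate import integrate, steady_state
from .model import (
    AREAS,
    ModelMatrices,
    SubjectModel,
    apply_condition,
    assemble_matrices,
    is_physical,
)
from .population import TargetSet
from .stability import (
    DEFAULT_MARGIN,
    EquilibriumError,
    is_asymptotically_stable,
    physiological_equilibrium,
)

__all__ = [
    "FitnessBreakdown",
    "compose",
    "area_error_fitness",
    "comb_range_fitness",
    "stimulation_constraint",
    "stability_fitness",
    "model_fitness",
    "subject_fitness",
]


@dataclass(frozen=True)
class FitnessBreakdown:
    """Named fitness figures and their min-times-mean composition."""

    components: Mapping[str, float]

    def __post_init__(self) -> None:
        comps = {str(k): float(v) for k, v in dict(self.components).items()}
        if not comps:
            raise ValueError("at least one fitness figure is required")
        for k, v in comps.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"figure {k} outside [0, 1]: {v}")
        object.__setattr__(self, "components", comps)

    @property
    def value(self) -> float:
        vals = np.array(list(self.components.values()))
        return float(vals.min() * vals.mean())

    def to_json(self, path=None) -> str:
        doc = {"components": dict(self.components), "value": self.value}
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def compose(components: Sequence[float]) -> float:
    """min times mean of a list of figures in [0, 1]."""
    vals = np.asarray(components, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot compose an empty figure list")
    if np.any(vals < 0.0) or np.any(vals > 1.0):
        raise ValueError("fitness figures must lie in [0, 1]")
    return float(vals.min() * vals.mean())


def area_error_fitness(sim: float, target: float) -> float:
    """1/(1 + relative-error^2); equals 1 iff the simulation hits the target."""
    if target <= 0:
        raise ValueError("target must be strictly positive")
    r = (sim - target) / target
    return 1.0 / (1.0 + r * r)


def comb_range_fitness(value: float, lo: float, hi: float) -> float:
    """1 inside [lo, hi] (bounds inclusive); decays with the relative
    distance to the nearest bound outside."""
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    if lo <= value <= hi:
        return 1.0
    r = (lo - value) / lo if value < lo else (value - hi) / hi
    return 1.0 / (1.0 + r * r)


def stimulation_constraint(s_sham: float, s_treat: float) -> float:
    """Penalty for inhibiting rather than stimulating: 1/(1 + max(0, S_SHAM - S_treat))."""
    return 1.0 / (1.0 + max(0.0, s_sham - s_treat))


def stability_fitness(m: ModelMatrices, margin: float = DEFAULT_MARGIN) -> float:
    """1 iff the physiological equilibrium is asymptotically stable; else a
    figure strictly decreasing in the leading eigenvalue (0 if no
    equilibrium exists)."""
    try:
        ybar = physiological_equilibrium(m)
    except EquilibriumError:
        return 0.0
    report = is_asymptotically_stable(m, ybar, margin)
    return 1.0 / (1.0 + max(0.0, report.max_real_part + margin))


def _component_names(targets: TargetSet, condition: str) -> list[str]:
    names = [f"err:{a}" for a in AREAS if a in targets.constrained_points(condition)]
    names += [f"range:{a}" for a in targets.constrained_ranges(condition)]
    names += ["stability", "physical"]
    return names


def _failure(names: Sequence[str]) -> FitnessBreakdown:
    return FitnessBreakdown({n: 0.0 for n in names})


def model_fitness(
    subject: SubjectModel,
    condition: str,
    targets: TargetSet,
    *,
    method: str = "equilibrium",
    margin: float = DEFAULT_MARGIN,
    fmax: float = F_MAX_HZ,
    t_end: float = 0.5,
    transient_cut: float = 0.1,
) -> FitnessBreakdown:
    """Fitness figures of one condition of one subject.

    Figures: one relative-error term per labeled point target, one range term
    per range target, the stability figure, and a 0/1 physical-validity
    figure.  ``method="equilibrium"`` reads the settled state off the
    equilibrium (fast path); ``method="integrate"`` runs the BDF simulation
    from silence — both must agree for a stable model and audit tests check
    that they do.  Any aborted or nonphysical simulation scores 0.
    """
    params = apply_condition(subject, condition)
    m = assemble_matrices(params)
    names = _component_names(targets, condition)

    if method == "equilibrium":
        try:
            y = physiological_equilibrium(m)
        except EquilibriumError:
            return _failure(names)
        report = is_asymptotically_stable(m, y, margin)
        stab = 1.0 / (1.0 + max(0.0, report.max_real_part + margin))
    elif method == "integrate":
        traj = integrate(m, t_end=t_end, fmax=fmax)
        if traj.stopped:
            return _failure(names)
        # endpoint extraction: by t_end the slowest mode has decayed ~e^-27,
        # whereas the transient-cut mean still carries an O(1e-4) bias
        y = steady_state(traj, transient_cut, mode="last")
        report = is_asymptotically_stable(m, y, margin)
        stab = 1.0 / (1.0 + max(0.0, report.max_real_part + margin))
    else:
        raise ValueError("method must be 'equilibrium' or 'integrate'")

    comps: dict[str, float] = {}
    points = targets.constrained_points(condition)
    for i, a in enumerate(AREAS):
        if a in points:
            comps[f"err:{a}"] = area_error_fitness(float(y[i]), points[a])
    for a, (lo, hi) in targets.constrained_ranges(condition).items():
        comps[f"range:{a}"] = comb_range_fitness(float(y[AREAS.index(a)]), lo, hi)
    comps["stability"] = stab
    comps["physical"] = 1.0 if is_physical(y, fmax) else 0.0
    return FitnessBreakdown(comps)


def subject_fitness(
    subject: SubjectModel,
    targets: TargetSet,
    conditions: Sequence[str],
    **kwargs,
) -> FitnessBreakdown:
    """Joint breakdown across several conditions (figures prefixed by
    condition label), as composed during the simultaneous fit."""
    comps: dict[str, float] = {}
    for cond in conditions:
        bd = model_fitness(subject, cond, targets, **kwargs)
        for name, v in bd.components.items():
            comps[f"{cond}/{name}"] = v
    return FitnessBreakdown(comps)
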