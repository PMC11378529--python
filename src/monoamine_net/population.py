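"""Synthetic virtual-subject population and per-subject target values.

No joint in-vivo measurement of all six areas exists for a single animal, so
the study conditions are emulated by a synthetic cohort: healthy activation
values are drawn per subject from normal distributions centered on the
literature rest rates with sigma = mu/8 — so the +/-50% truncation band is
4 sigma wide — truncated by resampling, and each subject's lesioned targets
are derived multiplicatively from its own healthy values.  A subject with an
above-average healthy rate therefore stays above average when lesioned.

Time constants get a small per-subject jitter (the +/-0.3 ms spread of the
literature values) and are shared across conditions: lesions are assumed not
to change the neuron-type time constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import (
    COMBINED_RANGE_SCALES,
    LESION_POINT_SCALES,
    MS_PER_S,
    REST_RATES_HZ,
    TAU_JITTER_MS,
    TAU_MS,
)
from .model import (
    AREAS,
    EXPERIMENT_CONDITIONS,
    ParameterSet,
    SubjectModel,
    tau_key,
)

__all__ = [
    "TargetSet",
    "PopulationConfig",
    "PopulationMember",
    "draw_healthy_targets",
    "derive_lesion_targets",
    "draw_time_constants",
    "generate_population",
    "population_manifest",
]

GROUPS: tuple[str, ...] = EXPERIMENT_CONDITIONS


@dataclass(frozen=True)
class TargetSet:
    """Per-condition reference values for one subject.

    ``points`` holds the labeled (constrained) per-area targets of each
    condition; ``ranges`` the range-constrained combined-lesion targets.
    Areas without a labeled target default to the subject's healthy value in
    the full reference matrix but are treated as unconstrained model
    predictions by the fitness.
    """

    healthy: Mapping[str, float]
    points: Mapping[str, Mapping[str, float]]
    ranges: Mapping[str, Mapping[str, tuple[float, float]]]

    @classmethod
    def from_healthy(cls, healthy: Mapping[str, float]) -> "TargetSet":
        healthy = {a: float(healthy[a]) for a in AREAS}
        if any(v <= 0 for v in healthy.values()):
            raise ValueError("healthy targets must be strictly positive")
        points: dict[str, dict[str, float]] = {"SHAM": dict(healthy)}
        for lesion, scales in LESION_POINT_SCALES.items():
            points[lesion] = {a: healthy[a] * s for a, s in scales.items()}
        ranges = {
            cond: {a: (healthy[a] * lo, healthy[a] * hi) for a, (lo, hi) in scales.items()}
            for cond, scales in COMBINED_RANGE_SCALES.items()
        }
        return cls(healthy, points, ranges)

    def constrained_points(self, condition: str) -> dict[str, float]:
        return dict(self.points.get(condition, {}))

    def constrained_ranges(self, condition: str) -> dict[str, tuple[float, float]]:
        return dict(self.ranges.get(condition, {}))

    def reference_vector(self, condition: str) -> np.ndarray:
        """Full per-area reference, unlabeled areas defaulting to SHAM."""
        pts = self.points.get(condition, {})
        return np.array([pts.get(a, self.healthy[a]) for a in AREAS])

    def to_dict(self) -> dict:
        return {
            "healthy": dict(self.healthy),
            "points": {c: dict(v) for c, v in self.points.items()},
            "ranges": {c: {a: list(r) for a, r in v.items()} for c, v in self.ranges.items()},
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "TargetSet":
        return cls(
            dict(doc["healthy"]),
            {c: dict(v) for c, v in doc["points"].items()},
            {c: {a: tuple(r) for a, r in v.items()} for c, v in doc["ranges"].items()},
        )


@dataclass(frozen=True)
class PopulationConfig:
    """Cohort synthesis settings.

    ``rel_sigma`` is sigma/mu of the healthy draws (default 1/8, so that the
    4-sigma band equals the +/-50% truncation half-width); ``trunc_halfwidth``
    the resampling band; ``tau_jitter_ms`` the per-subject time-constant
    spread (set ``jitter_tau=False`` for deterministic time constants).
    """

    n: int = 240
    seed: int = 0
    rel_sigma: float = 0.125
    trunc_halfwidth: float = 0.5
    tau_jitter_ms: float = TAU_JITTER_MS
    jitter_tau: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if self.rel_sigma < 0 or self.trunc_halfwidth < 0 or self.tau_jitter_ms < 0:
            raise ValueError("spreads must be non-negative")


@dataclass
class PopulationMember:
    subject: SubjectModel
    targets: TargetSet
    group: str


def draw_healthy_targets(
    rng: np.random.Generator,
    rel_sigma: float = 0.125,
    trunc_halfwidth: float = 0.5,
) -> dict[str, float]:
    """One subject's healthy per-area rates: truncated normal draws.

    Each area ~ N(mu, mu * rel_sigma), resampled (not clipped, to avoid
    boundary atoms) until inside [mu (1 - h), mu (1 + h)].
    """
    out: dict[str, float] = {}
    for a in AREAS:
        mu = REST_RATES_HZ[a]
        if rel_sigma == 0.0:
            out[a] = mu
            continue
        lo, hi = mu * (1.0 - trunc_halfwidth), mu * (1.0 + trunc_halfwidth)
        while True:
            v = rng.normal(mu, mu * rel_sigma)
            if lo <= v <= hi:
                out[a] = float(v)
                break
    return out


def derive_lesion_targets(healthy: Mapping[str, float]) -> TargetSet:
    """Deterministic multiplicative lesion targets from healthy values."""
    return TargetSet.from_healthy(healthy)


def draw_time_constants(
    rng: np.random.Generator,
    jitter_ms: float = TAU_JITTER_MS,
) -> dict[str, float]:
    """Per-subject time constants in seconds (resampled strictly positive)."""
    out: dict[str, float] = {}
    for a in AREAS:
        mu = TAU_MS[a]
        v = mu
        if jitter_ms > 0.0:
            while True:
                v = rng.normal(mu, jitter_ms)
                if v > 0.0:
                    break
        out[a] = float(v) / MS_PER_S
    return out


def _initial_subject(subject_id: str, tau_s: Mapping[str, float], healthy: Mapping[str, float]) -> SubjectModel:
    # Neutral decoupled start: couplings zero, drives chosen so that each
    # area's rest equilibrium (k * tau) equals its healthy target.
    exts = {a: healthy[a] / tau_s[a] for a in AREAS}
    base = ParameterSet.from_components(tau_s, exts=exts)
    return SubjectModel(subject_id, base)


def generate_population(config: PopulationConfig) -> list[PopulationMember]:
    """Synthesize the cohort: targets, time constants and group labels.

    Subjects are assigned round-robin to the six experimental groups (40 per
    group at the default n = 240); the full per-subject condition set is
    retained regardless of group, so population-level summaries remain
    available.  Fully reproducible from the master seed.
    """
    rng = np.random.default_rng(config.seed)
    members: list[PopulationMember] = []
    for i in range(config.n):
        healthy = draw_healthy_targets(rng, config.rel_sigma, config.trunc_halfwidth)
        tau_s = draw_time_constants(rng, config.tau_jitter_ms if config.jitter_tau else 0.0)
        targets = derive_lesion_targets(healthy)
        subject = _initial_subject(f"S{i:04d}", tau_s, healthy)
        members.append(PopulationMember(subject, targets, GROUPS[i % len(GROUPS)]))
    return members


def population_manifest(members: list[PopulationMember]) -> pd.DataFrame:
    """Flat per-subject table: group, time constants, every target value."""
    rows = []
    for mem in members:
        row: dict[str, object] = {"subject": mem.subject.subject_id, "group": mem.group}
        for a in AREAS:
            row[f"tau_s.{a}"] = mem.subject.base[tau_key(a)]
        for cond, pts in mem.targets.points.items():
            for a, v in pts.items():
                row[f"target.{cond}.{a}"] = v
        for cond, rng_ in mem.targets.ranges.items():
            for a, (lo, hi) in rng_.items():
                row[f"target.{cond}.{a}.lo"] = lo
                row[f"target.{cond}.{a}.hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)
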