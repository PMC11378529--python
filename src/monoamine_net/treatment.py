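"""In-silico treatments: optimized external stimulation of LC and/or DRN on
dopamine-depleted subjects.

A treated model starts from the subject's fitted dopaminergic-lesion (LDA)
parameters and frees only the external drive of the stimulated area(s):
alpha_LC^ext (cLC), alpha_DRN^ext (cDRN) or both (cCOMB).  The treatment
fitness restores the non-stimulated areas to the subject's healthy targets
(the stimulated area is ignored by its own measure), keeps the model
asymptotically stable, and penalizes inhibition through
1/(1 + max(0, S_SHAM - S_treat)) per stimulated drive, so the optimizer can
only stimulate.  A subject whose treated fitness reaches the responder
threshold is a responder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._evaluator import ConditionComponents, ConditionKernel
from .model import (
    AREAS,
    PARAM_KEYS,
    TREATMENT_BASE,
    TREATMENT_FREE,
    SubjectModel,
    apply_condition,
    ext_key,
)
from .optimize import DEConfig, _Objective, _search, _trajectory_audit
from .population import TargetSet

__all__ = [
    "DEFAULT_RESPONDER_THRESHOLD",
    "TreatmentResult",
    "ResponderPartition",
    "optimize_treatment",
    "classify_responders",
    "compare_comb_increments",
]

#: Responder gate on the composed treated fitness: every figure (hence every
#: relative steady-state error) within ~1% of target.
DEFAULT_RESPONDER_THRESHOLD = 1.0 - 1e-4

#: Areas whose own error measure is dropped per mode.
STIMULATED_AREAS: dict[str, tuple[str, ...]] = {
    "LDA+cLC": ("LC",),
    "LDA+cDRN": ("DRN",),
    "LDA+cCOMB": ("LC", "DRN"),
}


@dataclass
class TreatmentResult:
    """Outcome of one treatment optimization for one subject."""

    subject_id: str
    mode: str
    overlay: dict[str, float]
    base_drives: dict[str, float]
    increments_abs: dict[str, float]
    increments_rel: dict[str, float]
    fitness: float
    responder: bool
    threshold: float
    steady_states: dict[str, float] | None
    attempts: int
    seeds: tuple[int, ...]

    def to_dict(self) -> dict:
        doc = {k: getattr(self, k) for k in (
            "subject_id", "mode", "overlay", "base_drives", "increments_abs",
            "increments_rel", "fitness", "responder", "threshold",
            "steady_states", "attempts",
        )}
        doc["seeds"] = list(self.seeds)
        return doc

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def optimize_treatment(
    subject: SubjectModel,
    mode: str,
    targets: TargetSet,
    config: DEConfig | None = None,
    seed: int = 0,
    threshold: float = DEFAULT_RESPONDER_THRESHOLD,
    enforce_stimulation: bool = True,
) -> TreatmentResult:
    """Optimize the stimulated drive(s) of one depleted subject.

    ``enforce_stimulation=False`` removes the stimulation-only constraint
    (both the search-box floor and the penalty figure), a relaxation that can
    only increase the achievable fitness.
    """
    if mode not in TREATMENT_FREE:
        raise ValueError(f"unknown treatment mode {mode!r}")
    cfg = dc_replace(config or DEConfig(), threshold=threshold)
    base = apply_condition(subject, TREATMENT_BASE)
    free = TREATMENT_FREE[mode]

    spec: dict[str, tuple] = {k: ("c", base[k]) for k in PARAM_KEYS}
    for i, k in enumerate(free):
        spec[k] = ("x", i)
    points = {
        a: v for a, v in targets.constrained_points("SHAM").items()
        if a not in STIMULATED_AREAS[mode]
    }
    stim = [(i, base[k]) for i, k in enumerate(free)] if enforce_stimulation else None
    comp = ConditionComponents(
        ConditionKernel(base.tau, spec), points, {},
        fmax=cfg.fmax, margin=cfg.margin, stim_constraints=stim,
    )
    obj = _Objective({mode: comp})
    bounds = [
        (base[k] if enforce_stimulation else cfg.ext_bounds[0], cfg.ext_bounds[1])
        for k in free
    ]
    def accept_fn(x):
        treated = base.replace({k: float(v) for k, v in zip(free, x)}, mode)
        return _trajectory_audit([treated], cfg)

    x, score, seeds, _, _ = _search(obj, bounds, cfg, seed, accept_fn=accept_fn)

    ev = comp.kernel.evaluate(np.asarray(x, dtype=float)[None, :])
    steady = None
    if bool(ev["ok"][0]):
        steady = {a: float(ev["y"][0, i]) for i, a in enumerate(AREAS)}

    overlay = {k: float(v) for k, v in zip(free, x)}
    base_drives = {k: float(base[k]) for k in free}
    inc_abs = {k: overlay[k] - base_drives[k] for k in free}
    inc_rel = {
        k: (inc_abs[k] / base_drives[k]) if base_drives[k] > 0
        else (0.0 if inc_abs[k] == 0.0 else float("inf"))
        for k in free
    }
    return TreatmentResult(
        subject_id=subject.subject_id,
        mode=mode,
        overlay=overlay,
        base_drives=base_drives,
        increments_abs=inc_abs,
        increments_rel=inc_rel,
        fitness=score,
        responder=score >= threshold,
        threshold=threshold,
        steady_states=steady,
        attempts=len(seeds),
        seeds=seeds,
    )


@dataclass
class ResponderPartition:
    responders: list[TreatmentResult]
    non_responders: list[TreatmentResult]

    @property
    def n(self) -> int:
        return len(self.responders) + len(self.non_responders)

    @property
    def counts(self) -> dict[str, int]:
        return {"responders": len(self.responders), "non_responders": len(self.non_responders)}

    @property
    def rate(self) -> float:
        return len(self.responders) / self.n if self.n else float("nan")


def classify_responders(
    results: Sequence[TreatmentResult],
    threshold: float | None = None,
) -> ResponderPartition:
    """Partition treatment results by achieved fitness.

    With ``threshold=None`` the per-result responder flags are used; a
    numeric threshold re-classifies (0 makes everyone a responder).
    """
    resp, non = [], []
    for r in results:
        hit = r.responder if threshold is None else (r.fitness >= threshold)
        (resp if hit else non).append(r)
    return ResponderPartition(resp, non)


def compare_comb_increments(
    results: Sequence[TreatmentResult],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Relative DRN vs LC stimulation increments of combined-mode responders.

    Returns a per-subject table (rel_LC, rel_DRN, ratio = rel_DRN/rel_LC)
    and summary statistics of the ratio distribution.  Ratios are unit-free:
    rescaling the reporting units leaves them unchanged.
    """
    k_lc, k_drn = ext_key("LC"), ext_key("DRN")
    rows = []
    for r in results:
        if r.mode != "LDA+cCOMB" or not r.responder:
            continue
        rel_lc = r.increments_rel[k_lc]
        rel_drn = r.increments_rel[k_drn]
        if rel_drn == 0.0:
            ratio = 0.0
        elif rel_lc == 0.0:
            ratio = float("inf")
        else:
            ratio = rel_drn / rel_lc
        rows.append({"subject": r.subject_id, "rel_LC": rel_lc, "rel_DRN": rel_drn, "ratio": ratio})
    df = pd.DataFrame(rows, columns=["subject", "rel_LC", "rel_DRN", "ratio"])
    if len(df):
        summary = {
            "n": float(len(df)),
            "median_ratio": float(df["ratio"].median()),
            "max_ratio": float(df["ratio"].max()),
        }
    else:
        summary = {"n": 0.0, "median_ratio": float("nan"), "max_ratio": float("nan")}
    return df, summary
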