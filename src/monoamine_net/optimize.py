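"""Differential-evolution fitting of subject models.

The 30 free parameters of a subject (20 healthy rate parameters plus the
4 + 3 + 3 lesion replacements) are optimized simultaneously against a
fitness composed across all six conditions: the labeled point targets of
SHAM and the single lesions, the GP range bands of the combined lesions, and
per-condition stability and physicality figures.  A joint search is
structurally necessary: a lesion's free parameters live entirely in the
lesioned area's equation, so the lesioned steady state of every *other* area
(e.g. GP under the serotonergic lesion) is decided by the healthy couplings,
which must therefore be shaped by the cross-condition targets.

The global stage is DE/best/1/exp with Cr = F = 0.95, Halton-initialized.
Its best vector seeds a bounded trust-region least-squares refinement that
drives the relative steady-state errors to solver precision (the composed
fitness gate is 1 - 1e-8, i.e. every relative error below ~1e-4).  An outer
cycle re-seeds and retries fits that fail the gate.

Fitness evaluation uses the closed-form equilibrium plus the eigenvalue test
(fast path); audit tests verify identical figures from full BDF integration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import differential_evolution, least_squares

from ._evaluator import ConditionComponents, ConditionKernel
from .fitness import FitnessBreakdown
from .model import (
    COMBINED_LESIONS,
    EXPERIMENT_CONDITIONS,
    FITTED_CONDITIONS,
    FREE_PARAMS,
    LESIONS,
    PARAM_KEYS,
    ParameterSet,
    SubjectModel,
)
from .population import PopulationMember, TargetSet
from .constants import F_MAX_HZ

__all__ = [
    "DEConfig",
    "FitResult",
    "SubjectFit",
    "fit_condition",
    "fit_subject",
    "fit_population",
]

DEFAULT_THRESHOLD = 1.0 - 1e-8

#: stability margin (1/s) imposed during fitting: every eigenvalue must beat
#: the decay rate -ln(0.01)/0.1 s, so the slowest mode of an accepted model
#: is 99% settled within the 0.1 s transient window of the 0.5 s simulation
SETTLING_MARGIN = float(np.log(100.0) / 0.1)


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution and refinement settings.

    ``popsize`` follows scipy's convention (total vectors = popsize * dim,
    the standard 15x-dimension heuristic by default).  Parameter bounds are
    wide positive boxes set by the dimensional analysis and the magnitudes
    of the literature rates: couplings in Hz, drives in Hz/s, beta pure.
    """

    strategy: str = "best1exp"
    recombination: float = 0.95
    mutation: float = 0.95
    popsize: int = 15
    init: str = "halton"
    maxiter: int = 40
    threshold: float = DEFAULT_THRESHOLD
    retries: int = 10
    alpha_bounds: tuple[float, float] = (0.0, 1e3)
    ext_bounds: tuple[float, float] = (0.0, 1e5)
    beta_bounds: tuple[float, float] = (0.0, 1e2)
    margin: float = SETTLING_MARGIN
    fmax: float = F_MAX_HZ
    de_stop_fitness: float = 0.95
    refine: bool = True
    refine_max_nfev: int = 600

    def __post_init__(self) -> None:
        if not (0.0 < self.recombination <= 2.0 and 0.0 < self.mutation <= 2.0):
            raise ValueError("Cr and F must lie in (0, 2]")
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0, 1]")
        for b in (self.alpha_bounds, self.ext_bounds, self.beta_bounds):
            if b[0] < 0 or b[1] <= b[0]:
                raise ValueError("bounds must be non-negative and increasing")

    def bounds_for(self, key: str) -> tuple[float, float]:
        if key.endswith(".ext"):
            return self.ext_bounds
        if key.startswith("beta."):
            return self.beta_bounds
        return self.alpha_bounds


@dataclass
class FitResult:
    """Outcome of one condition of one fitted subject."""

    condition: str
    overlay: dict[str, float]
    fitness: float
    converged: bool
    attempts: int
    seeds: tuple[int, ...]
    nit: int = 0
    nfev: int = 0


@dataclass
class SubjectFit:
    """A fully fitted subject with per-condition results."""

    subject: SubjectModel
    targets: TargetSet
    results: dict[str, FitResult]
    joint: FitnessBreakdown
    converged: bool
    attempts: int
    seeds: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject.subject_id,
            "base": self.subject.base.to_dict(),
            "overlays": {c: dict(o) for c, o in self.subject.overlays.items()},
            "targets": self.targets.to_dict(),
            "fitness": {c: r.fitness for c, r in self.results.items()},
            "converged": self.converged,
            "attempts": self.attempts,
            "seeds": list(self.seeds),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def subject_from_dict(cls, doc: Mapping) -> tuple[SubjectModel, TargetSet]:
        subject = SubjectModel(
            doc["subject_id"],
            ParameterSet(doc["base"]),
            {c: dict(o) for c, o in doc.get("overlays", {}).items()},
        )
        return subject, TargetSet.from_dict(doc["targets"])


class _Objective:
    """Composite fitness over one or more conditions, batch-evaluable."""

    def __init__(self, components: Mapping[str, ConditionComponents]):
        self.components = dict(components)

    def figures(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mats, guides = [], []
        for comp in self.components.values():
            m, g = comp.matrix(X)
            mats.append(m)
            guides.append(g)
        return np.hstack(mats), np.sum(guides, axis=0)

    def fitness_values(self, X: np.ndarray) -> np.ndarray:
        figs, _ = self.figures(X)
        return figs.min(axis=1) * figs.mean(axis=1)

    def f_of(self, x: np.ndarray) -> float:
        return float(self.fitness_values(np.asarray(x, dtype=float)[None, :])[0])

    def de_func(self, x: np.ndarray) -> np.ndarray | float:
        # scipy's vectorized interface sends (dim, S); a 1-D vector may
        # arrive for feasibility probes.
        if x.ndim == 1:
            X = x[None, :]
            figs, guide = self.figures(X)
            f = figs.min(axis=1) * figs.mean(axis=1)
            return float((1.0 - f + 0.05 * np.minimum(guide, 10.0))[0])
        X = x.T
        figs, guide = self.figures(X)
        f = figs.min(axis=1) * figs.mean(axis=1)
        return 1.0 - f + 0.05 * np.minimum(guide, 10.0)

    def per_condition(self, x: np.ndarray) -> dict[str, float]:
        X = np.asarray(x, dtype=float)[None, :]
        out = {}
        for cond, comp in self.components.items():
            m, _ = comp.matrix(X)
            out[cond] = float(m.min(axis=1)[0] * m.mean(axis=1)[0])
        return out

    def breakdown(self, x: np.ndarray) -> FitnessBreakdown:
        X = np.asarray(x, dtype=float)[None, :]
        comps: dict[str, float] = {}
        for cond, comp in self.components.items():
            m, _ = comp.matrix(X)
            for name, v in zip(comp.names, m[0]):
                comps[f"{cond}/{name}"] = float(np.clip(v, 0.0, 1.0))
        return FitnessBreakdown(comps)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        return self.residual_matrix(np.asarray(x, dtype=float)[None, :])[0]

    def residual_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.hstack([c.residual_matrix(X) for c in self.components.values()])

    def residual_jac(self, x: np.ndarray) -> np.ndarray:
        """Forward-difference Jacobian via one batched evaluation."""
        x = np.asarray(x, dtype=float)
        h = np.sqrt(np.finfo(float).eps) * np.maximum(1.0, np.abs(x))
        X = np.vstack([x, x[None, :] + np.diag(h)])
        R = self.residual_matrix(X)
        return ((R[1:] - R[0]) / h[:, None]).T


def _run_de(obj: _Objective, bounds: Sequence[tuple], cfg: DEConfig, seed: int):
    def cb(xk, convergence=0.0):
        return obj.f_of(np.asarray(xk)) >= cfg.de_stop_fitness

    res = differential_evolution(
        obj.de_func,
        bounds,
        strategy=cfg.strategy,
        maxiter=cfg.maxiter,
        popsize=cfg.popsize,
        tol=0.0,
        mutation=cfg.mutation,
        recombination=cfg.recombination,
        seed=seed,
        init=cfg.init,
        polish=False,
        updating="deferred",
        vectorized=True,
        callback=cb,
    )
    return np.asarray(res.x, dtype=float), int(res.nit), int(res.nfev)


def _refine(obj: _Objective, x: np.ndarray, bounds: Sequence[tuple], cfg: DEConfig) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x0 = np.clip(x, lo, hi)
    try:
        res = least_squares(
            obj.residuals,
            x0,
            jac=obj.residual_jac,
            bounds=(lo, hi),
            method="trf",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=cfg.refine_max_nfev,
            x_scale=np.maximum(1.0, np.abs(x0)),
        )
    except Exception:
        return x
    return res.x if obj.f_of(res.x) >= obj.f_of(x) else x


def _search(
    obj: _Objective,
    bounds: Sequence[tuple],
    cfg: DEConfig,
    seed: int,
    seed_fn=None,
    accept_fn=None,
):
    """Retry cycle: DE + refinement under fresh seeds until the gate passes.

    Each attempt refines the DE champion; if the gate is still not met and a
    physiological seed generator is available, a second refinement starts
    from a structured guess drawn with the attempt's seed (couplings at
    physiological magnitudes, drives solved from the equilibrium targets).
    A candidate that reaches the gate must additionally pass ``accept_fn``
    (the from-silence trajectory audit); otherwise the attempt is retried.
    """
    rng = np.random.default_rng(seed)
    seeds: list[int] = []
    best = None
    for _ in range(max(1, cfg.retries)):
        s = int(rng.integers(0, 2**31 - 1))
        seeds.append(s)
        x, nit, nfev = _run_de(obj, bounds, cfg, s)
        if cfg.refine:
            x = _refine(obj, x, bounds, cfg)
        score = min(obj.per_condition(x).values())
        if score < cfg.threshold and cfg.refine and seed_fn is not None:
            x2 = _refine(obj, seed_fn(np.random.default_rng(s)), bounds, cfg)
            score2 = min(obj.per_condition(x2).values())
            if score2 > score:
                x, score = x2, score2
        verified = score >= cfg.threshold and (accept_fn is None or accept_fn(x))
        if not verified and score >= cfg.threshold:
            score = 0.0  # gate passed but the trajectory audit failed
        if best is None or score > best[0]:
            best = (score, x, nit, nfev)
        if verified:
            break
    score, x, nit, nfev = best
    return x, score, tuple(seeds), nit, nfev


#: cap on the drive-budget share a single projection term is seeded with;
#: divided by the number of incoming terms of the target equation so the
#: leak/drive balance of each area stays physiological.
_SEED_SHARE_CAP = 0.8

#: area whose equation each lesion's free parameters belong to
_LESION_AREA = {"LDA": "SNcVTA", "L5HT": "DRN", "LNE": "LC"}


def _seed_vector(
    rng: np.random.Generator,
    layout: Sequence[tuple[str, str]],
    base: ParameterSet,
    targets: TargetSet,
    cfg: DEConfig,
) -> np.ndarray:
    """Structured initial guess for the refinement stage.

    Each coupling is drawn so that its term contributes a uniform random
    share of the target area's equilibrium drive budget y/tau (scale-aware
    across the fast and slow areas); every free external drive is then
    solved in closed form so that the condition's constrained area sits on
    its target with the remaining areas at their healthy levels (exact for
    SHAM, approximate for lesions).
    """
    from .model import AREA_INDEX, COUPLING_SIGNS, BETA_EDGE, alpha_key, ext_key

    cols = {pair: i for i, pair in enumerate(layout)}
    x = np.empty(len(layout))
    tau_arr = base.tau
    t_ref = targets.reference_vector("SHAM")
    n_terms = {a: sum(1 for (tg, _) in COUPLING_SIGNS if tg == a) for a in AREA_INDEX}
    n_terms[BETA_EDGE[0]] += 1
    for (scope, key), i in cols.items():
        if key.endswith(".ext"):
            continue
        _, tgt, src = key.split(".")
        budget = t_ref[AREA_INDEX[tgt]] / tau_arr[AREA_INDEX[tgt]]
        share = rng.uniform(0.0, _SEED_SHARE_CAP / n_terms[tgt])
        src_level = t_ref[AREA_INDEX[src]] ** (2 if key.startswith("beta.") else 1)
        x[i] = share * budget / src_level

    def val(scope: str, key: str) -> float:
        if (scope, key) in cols:
            return x[cols[(scope, key)]]
        if ("SHAM", key) in cols:
            return x[cols[("SHAM", key)]]
        return base[key]

    def drive(scope: str, area: str, y: np.ndarray) -> float:
        acc = y[AREA_INDEX[area]] / tau_arr[AREA_INDEX[area]]
        for (tg, src), sign in COUPLING_SIGNS.items():
            if tg == area:
                acc -= sign * val(scope, alpha_key(tg, src)) * y[AREA_INDEX[src]]
        if area == BETA_EDGE[0]:
            acc -= val(scope, "beta.SNcVTA.LC") * y[AREA_INDEX[BETA_EDGE[1]]] ** 2
        return acc

    for a, i in ((a, cols[("SHAM", ext_key(a))]) for a in AREA_INDEX
                 if ("SHAM", ext_key(a)) in cols):
        x[i] = drive("SHAM", a, t_ref)
    for scope, area in _LESION_AREA.items():
        i = cols.get((scope, ext_key(area)))
        if i is None:
            continue
        y = t_ref.copy()
        y[AREA_INDEX[area]] = targets.constrained_points(scope)[area]
        x[i] = drive(scope, area, y)

    lo = np.array([cfg.bounds_for(k)[0] for _, k in layout])
    hi = np.array([cfg.bounds_for(k)[1] for _, k in layout])
    return np.clip(x, lo, hi)


def _subject_from_layout(
    subject: SubjectModel, layout: Sequence[tuple[str, str]], x: np.ndarray
) -> SubjectModel:
    sham = {key: float(x[i]) for i, (scope, key) in enumerate(layout) if scope == "SHAM"}
    fitted = SubjectModel(subject.subject_id, subject.base.replace(sham))
    for cond in LESIONS:
        overlay = {key: float(x[i]) for i, (scope, key) in enumerate(layout) if scope == cond}
        if overlay:
            fitted = fitted.with_overlay(cond, overlay)
    return fitted


def _trajectory_audit(params_list, cfg: DEConfig) -> bool:
    """Accepted models must survive the from-silence 0.5 s simulation: a
    transient leaving the physical box voids the candidate even when its
    equilibrium is interior."""
    from .integrate import integrate
    from .model import assemble_matrices

    for params in params_list:
        if integrate(assemble_matrices(params), fmax=cfg.fmax).stopped:
            return False
    return True


def _joint_layout() -> list[tuple[str, str]]:
    layout = [("SHAM", k) for k in PARAM_KEYS]
    for cond in LESIONS:
        layout += [(cond, k) for k in FREE_PARAMS[cond]]
    return layout


def _joint_components(tau: np.ndarray, targets: TargetSet, cfg: DEConfig) -> dict[str, ConditionComponents]:
    layout = _joint_layout()
    col = {pair: i for i, pair in enumerate(layout)}
    comps = {}
    for cond in EXPERIMENT_CONDITIONS:
        chain = COMBINED_LESIONS.get(cond, (cond,) if cond in LESIONS else ())
        spec = {k: ("x", col[("SHAM", k)]) for k in PARAM_KEYS}
        for part in chain:
            for k in FREE_PARAMS[part]:
                spec[k] = ("x", col[(part, k)])
        comps[cond] = ConditionComponents(
            ConditionKernel(tau, spec),
            targets.constrained_points(cond),
            targets.constrained_ranges(cond),
            fmax=cfg.fmax,
            margin=cfg.margin,
        )
    return comps


def fit_subject(
    subject: SubjectModel | PopulationMember,
    targets: TargetSet | None = None,
    config: DEConfig | None = None,
    seed: int = 0,
) -> SubjectFit:
    """Jointly fit all 30 free parameters of one subject.

    Returns the fitted subject (SHAM base plus lesion overlays; combined
    conditions are overlay compositions with no parameters of their own)
    with per-condition fitness.  Convergence requires every condition to
    reach the fitness gate.
    """
    if isinstance(subject, PopulationMember):
        targets = subject.targets
        subject = subject.subject
    if targets is None:
        raise ValueError("targets are required")
    cfg = config or DEConfig()
    layout = _joint_layout()
    obj = _Objective(_joint_components(subject.base.tau, targets, cfg))
    bounds = [cfg.bounds_for(key) for _, key in layout]
    base = subject.base
    seed_fn = lambda r: _seed_vector(r, layout, base, targets, cfg)  # noqa: E731

    def accept_fn(x):
        candidate = _subject_from_layout(subject, layout, x)
        from .model import apply_condition

        return _trajectory_audit(
            [apply_condition(candidate, c) for c in EXPERIMENT_CONDITIONS], cfg
        )

    x, score, seeds, nit, nfev = _search(
        obj, bounds, cfg, seed, seed_fn=seed_fn, accept_fn=accept_fn
    )
    fitted = _subject_from_layout(subject, layout, x)
    sham_overlay = {key: float(x[i]) for i, (scope, key) in enumerate(layout) if scope == "SHAM"}

    percond = obj.per_condition(x)
    results = {}
    for cond in EXPERIMENT_CONDITIONS:
        if cond == "SHAM":
            overlay = dict(sham_overlay)
        elif cond in LESIONS:
            overlay = dict(fitted.overlays[cond])
        else:
            overlay = {}
        results[cond] = FitResult(
            cond, overlay, percond[cond], percond[cond] >= cfg.threshold,
            len(seeds), seeds, nit, nfev,
        )
    return SubjectFit(
        fitted, targets, results, obj.breakdown(x),
        converged=score >= cfg.threshold, attempts=len(seeds), seeds=seeds,
    )


def fit_condition(
    subject: SubjectModel,
    condition: str,
    targets: TargetSet,
    config: DEConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit a single condition's free parameters, all others frozen.

    SHAM searches its 20 rate parameters; a lesion searches its 3-4
    replacements with everything else pinned to the subject's SHAM values.
    Note the joint `fit_subject` is the primary fitting path: an isolated
    lesion fit can only converge if the SHAM couplings already support the
    lesion's cross-area targets.
    """
    if condition not in FITTED_CONDITIONS:
        raise ValueError(f"{condition!r} is not a fitted condition")
    cfg = config or DEConfig()
    free = FREE_PARAMS[condition]
    base = subject.base
    spec: dict[str, tuple] = {k: ("c", base[k]) for k in PARAM_KEYS}
    for i, k in enumerate(free):
        spec[k] = ("x", i)
    comp = ConditionComponents(
        ConditionKernel(base.tau, spec),
        targets.constrained_points(condition),
        targets.constrained_ranges(condition),
        fmax=cfg.fmax,
        margin=cfg.margin,
    )
    obj = _Objective({condition: comp})
    bounds = [cfg.bounds_for(k) for k in free]
    layout = [(condition, k) for k in free]
    seed_fn = lambda r: _seed_vector(r, layout, base, targets, cfg)  # noqa: E731

    def accept_fn(x):
        candidate = base.replace({k: float(v) for k, v in zip(free, x)}, condition)
        return _trajectory_audit([candidate], cfg)

    x, score, seeds, nit, nfev = _search(
        obj, bounds, cfg, seed, seed_fn=seed_fn, accept_fn=accept_fn
    )
    overlay = {k: float(v) for k, v in zip(free, x)}
    return FitResult(condition, overlay, score, score >= cfg.threshold, len(seeds), seeds, nit, nfev)


def fit_population(
    members: Sequence[PopulationMember],
    config: DEConfig | None = None,
    seed: int = 0,
    progress: bool = False,
) -> list[SubjectFit]:
    """Fit every member of a cohort, one derived seed per subject."""
    rng = np.random.default_rng(seed)
    fits = []
    for mem in members:
        s = int(rng.integers(0, 2**31 - 1))
        fit = fit_subject(mem, config=config, seed=s)
        if progress:
            print(f"{mem.subject.subject_id}: fitness={min(r.fitness for r in fit.results.values()):.10f} attempts={fit.attempts}")
        fits.append(fit)
    return fits
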