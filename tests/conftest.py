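"""Shared fixtures: a hand-built stable reference model and random-instance
generators.

The reference parameter set is constructed so that the literature rest rates
are its exact equilibrium: couplings are fixed by hand at plausible
magnitudes and each external drive absorbs the remainder of the area's
drive budget.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import monoamine_net as mn
from monoamine_net.constants import REST_RATES_HZ, TAU_MS
from monoamine_net.model import AREAS, COUPLING_SIGNS, BETA_EDGE

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

_REFERENCE_ALPHAS = {
    ("GP", "StrD1"): 20.0,
    ("GP", "StrD2"): 20.0,
    ("GP", "DRN"): 50.0,
    ("StrD1", "SNcVTA"): 100.0,
    ("StrD1", "DRN"): 100.0,
    ("StrD2", "SNcVTA"): 50.0,
    ("StrD2", "DRN"): 80.0,
    ("SNcVTA", "DRN"): 40.0,
    ("SNcVTA", "LC"): 30.0,
    ("DRN", "SNcVTA"): 20.0,
    ("DRN", "LC"): 30.0,
    ("LC", "SNcVTA"): 50.0,
    ("LC", "DRN"): 60.0,
}
_REFERENCE_BETA = 10.0


def make_params(alphas, beta, rates=None, tau_s=None) -> mn.ParameterSet:
    """Parameter set whose equilibrium is exactly ``rates``: the external
    drives are solved from the equilibrium condition."""
    rates = dict(REST_RATES_HZ) if rates is None else dict(rates)
    tau_s = tau_s or {a: TAU_MS[a] / 1000.0 for a in AREAS}
    exts = {}
    for a in AREAS:
        acc = rates[a] / tau_s[a]
        for (t, s), sign in COUPLING_SIGNS.items():
            if t == a:
                acc -= sign * alphas.get((t, s), 0.0) * rates[s]
        if a == BETA_EDGE[0]:
            acc -= beta * rates[BETA_EDGE[1]] ** 2
        exts[a] = acc
    if any(v < 0 for v in exts.values()):
        raise ValueError("coupling choice needs negative drives; pick smaller couplings")
    return mn.ParameterSet.from_components(tau_s, alphas, exts, beta)


def random_stable_params(rng: np.random.Generator, max_tries: int = 50) -> mn.ParameterSet:
    """Random positive instance with the rest rates as equilibrium, resampled
    until the equilibrium is asymptotically stable."""
    for _ in range(max_tries):
        alphas = {e: rng.uniform(0.0, 120.0) for e in COUPLING_SIGNS}
        beta = rng.uniform(0.0, 25.0)
        try:
            params = make_params(alphas, beta)
        except ValueError:
            continue
        m = mn.assemble_matrices(params)
        ybar = mn.physiological_equilibrium(m)
        if mn.is_asymptotically_stable(m, ybar).stable and mn.is_physical(ybar):
            return params
    raise RuntimeError("could not draw a stable instance")


@pytest.fixture(scope="session")
def reference_params() -> mn.ParameterSet:
    params = make_params(_REFERENCE_ALPHAS, _REFERENCE_BETA)
    m = mn.assemble_matrices(params)
    assert mn.is_asymptotically_stable(m, mn.physiological_equilibrium(m)).stable
    return params


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def rest_rates() -> np.ndarray:
    return np.array([REST_RATES_HZ[a] for a in AREAS])


@pytest.fixture(scope="session")
def center_member() -> mn.PopulationMember:
    """A single subject at the population centers with unjittered taus."""
    cfg = mn.PopulationConfig(n=1, seed=0, rel_sigma=0.0, jitter_tau=False)
    return mn.generate_population(cfg)[0]


@pytest.fixture(scope="session")
def quick_config() -> mn.DEConfig:
    """Small-budget optimizer settings for unit-level fits."""
    return mn.DEConfig(maxiter=10, retries=3)


@pytest.fixture(scope="session")
def fitted_center(center_member, quick_config) -> mn.SubjectFit:
    fit = mn.fit_subject(center_member, config=quick_config, seed=101)
    assert fit.converged
    return fit
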