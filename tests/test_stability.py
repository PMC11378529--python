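"""Equilibria and stability: root finders, Jacobian, eigenvalue verdicts."""

import numpy as np
import pytest

import monoamine_net as mn
from monoamine_net.constants import TAU_MS
from monoamine_net.model import AREA_INDEX, AREAS
from monoamine_net.stability import EquilibriumError
from conftest import make_params, random_stable_params

TAU_S = {a: TAU_MS[a] / 1000.0 for a in AREAS}


class TestFindEquilibrium:
    def test_linear_case_solves_exactly(self, rng):
        alphas = {e: rng.uniform(0, 50) for e in mn.model.COUPLING_SIGNS}
        params = make_params(alphas, beta=0.0)
        m = mn.assemble_matrices(params)
        ybar = mn.find_equilibrium(m)
        np.testing.assert_allclose(ybar, np.linalg.solve(m.A, -m.b), rtol=1e-10)

    def test_decoupled_equilibrium_is_k_tau(self):
        k = 800.0
        params = mn.ParameterSet.from_components(TAU_S, exts={a: k for a in AREAS})
        ybar = mn.find_equilibrium(mn.assemble_matrices(params))
        np.testing.assert_allclose(ybar, [k * TAU_S[a] for a in AREAS], rtol=1e-12)

    def test_newton_matches_closed_form(self, rng):
        for _ in range(20):
            params = random_stable_params(rng)
            m = mn.assemble_matrices(params)
            newton = mn.find_equilibrium(m)
            closed = mn.physiological_equilibrium(m)
            assert np.abs(newton - closed).max() < 1e-8 * max(1.0, np.abs(closed).max())

    def test_matches_long_integration(self, reference_params):
        m = mn.assemble_matrices(reference_params)
        ybar = mn.find_equilibrium(m)
        settled = mn.steady_state(mn.integrate(m, t_end=0.5), mode="last")
        assert np.abs(ybar - settled).max() < 1e-6 * np.abs(ybar).max()

    def test_residual_tolerance(self, reference_params):
        m = mn.assemble_matrices(reference_params)
        ybar = mn.find_equilibrium(m)
        res = np.abs(m.A @ ybar + m.C @ (ybar * ybar) + m.b).max()
        assert res < 1e-10 * max(1.0, np.abs(m.b).max())

    def test_no_real_equilibrium_raises(self):
        # quadratic LC->SNcVTA->LC feedback too strong for any real fixed point
        params = mn.ParameterSet.from_components(
            TAU_S,
            alphas={("LC", "SNcVTA"): 1000.0},
            exts={a: 2000.0 for a in AREAS},
            beta=100.0,
        )
        m = mn.assemble_matrices(params)
        assert mn.closed_form_equilibria(m) == []
        with pytest.raises(EquilibriumError):
            mn.physiological_equilibrium(m)
        with pytest.raises(EquilibriumError):
            mn.find_equilibrium(m)


class TestJacobian:
    def test_linear_jacobian_is_A(self, rng):
        params = make_params({e: 10.0 for e in mn.model.COUPLING_SIGNS}, beta=0.0)
        m = mn.assemble_matrices(params)
        y = rng.uniform(0, 30, 6)
        np.testing.assert_array_equal(mn.jacobian(m, y), m.A)

    def test_quadratic_entry(self, reference_params):
        m = mn.assemble_matrices(reference_params)
        y = np.arange(1.0, 7.0)
        J = mn.jacobian(m, y)
        i, j = AREA_INDEX["SNcVTA"], AREA_INDEX["LC"]
        beta = reference_params.beta
        assert J[i, j] == pytest.approx(m.A[i, j] + 2.0 * beta * y[j], rel=1e-14)
        mask = np.ones((6, 6), bool)
        mask[i, j] = False
        np.testing.assert_array_equal(J[mask], m.A[mask])

    def test_matches_finite_differences(self, reference_params, rng):
        m = mn.assemble_matrices(reference_params)
        h = 1e-5
        for _ in range(20):
            y = rng.uniform(0.0, 50.0, 6)
            J = mn.jacobian(m, y)
            J_fd = np.empty((6, 6))
            for j in range(6):
                e = np.zeros(6)
                e[j] = h
                J_fd[:, j] = (mn.rhs(y + e, m) - mn.rhs(y - e, m)) / (2 * h)
            scale = max(1.0, np.abs(J).max())
            assert np.abs(J - J_fd).max() < 1e-6 * scale


class TestStabilityVerdict:
    def test_pure_damping_is_stable(self):
        params = mn.ParameterSet.from_components(TAU_S)
        m = mn.assemble_matrices(params)
        report = mn.is_asymptotically_stable(m, np.zeros(6))
        assert report.stable
        np.testing.assert_allclose(
            sorted(report.eigenvalues.real), sorted(-1.0 / np.array([TAU_S[a] for a in AREAS]))
        )

    def test_quadratic_feedback_destabilizes(self):
        # strong mutual excitation SNcVTA <-> LC through the quadratic term
        params = make_params({("LC", "SNcVTA"): 500.0, ("SNcVTA", "LC"): 0.0}, beta=0.0)
        params = params.replace({"beta.SNcVTA.LC": 100.0})
        m = mn.assemble_matrices(params)
        report = mn.is_asymptotically_stable(m, np.array([22, 10, 9, 4.47, 1.41, 50.0]))
        assert not report.stable
        assert report.max_real_part > 0

    def test_margin_semantics(self):
        params = mn.ParameterSet.from_components(TAU_S)
        m = mn.assemble_matrices(params)
        slowest = 1.0 / max(TAU_S.values())
        assert mn.is_asymptotically_stable(m, np.zeros(6), margin=slowest / 2).stable
        assert not mn.is_asymptotically_stable(m, np.zeros(6), margin=2 * slowest).stable

    def test_verdict_agrees_with_perturbation_decay(self, rng):
        """Eigenvalue verdict vs the simulation oracle: 1% kicks die out."""
        for _ in range(5):
            params = random_stable_params(rng)
            m = mn.assemble_matrices(params)
            ybar = mn.physiological_equilibrium(m)
            assert mn.is_asymptotically_stable(m, ybar).stable
            kick = ybar * (1.0 + 0.01 * rng.uniform(-1, 1, 6))
            traj = mn.integrate(m, y0=np.clip(kick, 0, None), t_end=0.5)
            assert not traj.stopped
            final = traj.y[:, -1]
            assert np.abs(final - ybar).max() < 1e-3 * np.abs(ybar).max()

    def test_report_serializes(self, reference_params, tmp_path):
        m = mn.assemble_matrices(reference_params)
        report = mn.is_asymptotically_stable(m, mn.find_equilibrium(m))
        text = report.to_json(tmp_path / "report.json")
        import json

        doc = json.loads(text)
        assert doc["stable"] is True
        assert set(doc["equilibrium_hz"]) == set(AREAS)
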