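"""Evolutionary fitting: search-space wiring, recovery, determinism."""

import numpy as np
import pytest

import monoamine_net as mn
from monoamine_net.model import FREE_PARAMS, PARAM_KEYS, AREAS
from monoamine_net.optimize import _Objective, _joint_components, _joint_layout


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            mn.DEConfig(recombination=0.0)
        with pytest.raises(ValueError):
            mn.DEConfig(mutation=2.5)
        with pytest.raises(ValueError):
            mn.DEConfig(threshold=0.0)
        with pytest.raises(ValueError):
            mn.DEConfig(alpha_bounds=(1.0, 0.5))

    def test_bounds_by_parameter_kind(self):
        cfg = mn.DEConfig()
        assert cfg.bounds_for("alpha.GP.StrD1") == cfg.alpha_bounds
        assert cfg.bounds_for("alpha.GP.ext") == cfg.ext_bounds
        assert cfg.bounds_for("beta.SNcVTA.LC") == cfg.beta_bounds


class TestSearchSpace:
    def test_dimensions(self):
        assert len(FREE_PARAMS["SHAM"]) == 20
        assert len(FREE_PARAMS["LDA"]) == 4
        assert len(FREE_PARAMS["L5HT"]) == 3
        assert len(FREE_PARAMS["LNE"]) == 3
        layout = _joint_layout()
        assert len(layout) == 30  # 30 parameters optimized simultaneously

    def test_objective_recognizes_perfect_vector(self, center_member, fitted_center):
        """A known-perfect parameter vector scores at the gate, so a DE
        population containing it converges in generation zero."""
        cfg = mn.DEConfig()
        obj = _Objective(_joint_components(
            center_member.subject.base.tau, center_member.targets, cfg))
        layout = _joint_layout()
        subject = fitted_center.subject
        x = np.empty(len(layout))
        for i, (scope, key) in enumerate(layout):
            params = subject.base if scope == "SHAM" else subject.base.replace(subject.overlays[scope])
            x[i] = params[key]
        assert obj.f_of(x) >= cfg.threshold

    def test_frozen_parameters_bit_identical(self, fitted_center):
        subject = fitted_center.subject
        sham = mn.apply_condition(subject, "SHAM")
        for cond in ("LDA", "L5HT", "LNE"):
            lesioned = mn.apply_condition(subject, cond)
            for key in PARAM_KEYS:
                if key not in FREE_PARAMS[cond]:
                    assert lesioned[key] == sham[key]


class TestFitSubject:
    def test_every_condition_reaches_gate(self, fitted_center):
        for cond, res in fitted_center.results.items():
            assert res.fitness >= 1.0 - 1e-8, cond
        assert fitted_center.converged

    def test_steady_states_hit_targets(self, fitted_center):
        targets = fitted_center.targets
        for cond in ("SHAM", "LDA", "L5HT", "LNE"):
            m = mn.assemble_matrices(mn.apply_condition(fitted_center.subject, cond))
            y = mn.physiological_equilibrium(m)
            for a, target in targets.constrained_points(cond).items():
                assert abs(y[AREAS.index(a)] - target) <= 1e-4 * target

    def test_combined_conditions_have_no_free_parameters(self, fitted_center):
        assert fitted_center.results["LDA+L5HT"].overlay == {}
        assert fitted_center.results["LDA+LNE"].overlay == {}
        assert "LDA+L5HT" not in fitted_center.subject.overlays

    def test_fixed_seed_reproduces_bitwise(self, center_member, quick_config):
        a = mn.fit_subject(center_member, config=quick_config, seed=77)
        b = mn.fit_subject(center_member, config=quick_config, seed=77)
        assert a.subject.base.values == b.subject.base.values
        assert a.subject.overlays == b.subject.overlays
        assert a.seeds == b.seeds

    def test_serialization_roundtrip(self, fitted_center, tmp_path):
        path = tmp_path / "fit.json"
        fitted_center.to_json(path)
        import json

        subject, targets = mn.SubjectFit.subject_from_dict(json.loads(path.read_text()))
        assert subject.base.values == fitted_center.subject.base.values
        assert subject.overlays == fitted_center.subject.overlays
        assert targets.points == fitted_center.targets.points


class TestFitCondition:
    def test_parameter_recovery_by_steady_state(self, reference_params, quick_config):
        """Refitting targets generated from a ground-truth model recovers its
        steady states (the parameter map itself is many-to-one)."""
        truth = mn.assemble_matrices(reference_params)
        ybar = mn.physiological_equilibrium(truth)
        healthy = {a: float(ybar[i]) for i, a in enumerate(AREAS)}
        targets = mn.derive_lesion_targets(healthy)
        blank = mn.SubjectModel("recover", mn.ParameterSet.from_components(
            {a: reference_params[f"tau.{a}"] for a in AREAS},
            exts={a: healthy[a] / reference_params[f"tau.{a}"] for a in AREAS}))
        res = mn.fit_condition(blank, "SHAM", targets, config=quick_config, seed=5)
        assert res.converged
        assert set(res.overlay) == set(FREE_PARAMS["SHAM"])
        refit = blank.base.replace(res.overlay)
        y = mn.physiological_equilibrium(mn.assemble_matrices(refit))
        np.testing.assert_allclose(y, ybar, rtol=1e-4)

    def test_rejects_unfittable_condition(self, center_member, quick_config):
        with pytest.raises(ValueError):
            mn.fit_condition(center_member.subject, "LDA+L5HT", center_member.targets,
                             config=quick_config)


def test_fit_population_derives_seeds(quick_config):
    members = mn.generate_population(mn.PopulationConfig(n=2, seed=4, rel_sigma=0.0, jitter_tau=False))
    fits = mn.fit_population(members, config=quick_config, seed=8)
    assert len(fits) == 2
    assert all(f.converged for f in fits)
    assert fits[0].seeds != fits[1].seeds
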