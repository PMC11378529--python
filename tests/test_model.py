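"""Model definition: matrix assembly, signs, overlays, serialization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import monoamine_net as mn
from monoamine_net.constants import REST_RATES_HZ, TAU_MS
from monoamine_net.model import (
    AREA_INDEX,
    AREAS,
    COUPLING_SIGNS,
    FREE_PARAMS,
    PARAM_KEYS,
    alpha_key,
    ext_key,
)
from conftest import make_params

TAU_S = {a: TAU_MS[a] / 1000.0 for a in AREAS}


def per_equation_rhs(y, params):
    """Independent oracle: the six equations written out term by term."""
    GP, D1, D2, S, D, L = y
    a = params.alpha
    e = params.ext
    return np.array([
        -GP / params["tau.GP"] - a("GP", "StrD1") * D1 - a("GP", "StrD2") * D2
        + a("GP", "DRN") * D + e("GP"),
        -D1 / params["tau.StrD1"] + a("StrD1", "SNcVTA") * S + a("StrD1", "DRN") * D
        + e("StrD1"),
        -D2 / params["tau.StrD2"] - a("StrD2", "SNcVTA") * S + a("StrD2", "DRN") * D
        + e("StrD2"),
        -S / params["tau.SNcVTA"] - a("SNcVTA", "DRN") * D - a("SNcVTA", "LC") * L
        + params.beta * L * L + e("SNcVTA"),
        -D / params["tau.DRN"] - a("DRN", "SNcVTA") * S + a("DRN", "LC") * L
        + e("DRN"),
        -L / params["tau.LC"] + a("LC", "SNcVTA") * S - a("LC", "DRN") * D + e("LC"),
    ])


def random_params(rng):
    alphas = {e: rng.uniform(0, 500) for e in COUPLING_SIGNS}
    exts = {a: rng.uniform(0, 5e4) for a in AREAS}
    return mn.ParameterSet.from_components(TAU_S, alphas, exts, beta=rng.uniform(0, 50))


class TestAssembly:
    def test_damping_only(self):
        params = mn.ParameterSet.from_components(TAU_S)
        m = mn.assemble_matrices(params)
        np.testing.assert_allclose(
            np.diag(m.A), [-1 / TAU_S[a] for a in AREAS], rtol=1e-15
        )
        assert np.all(m.A == np.diag(np.diag(m.A)))
        assert np.all(m.C == 0) and np.all(m.b == 0)

    def test_sign_pattern(self, reference_params):
        m = mn.assemble_matrices(reference_params)
        i = AREA_INDEX
        assert m.A[i["GP"], i["StrD1"]] <= 0
        assert m.A[i["GP"], i["DRN"]] >= 0
        assert m.A[i["SNcVTA"], i["LC"]] <= 0
        assert m.C[i["SNcVTA"], i["LC"]] >= 0
        assert np.all(np.diag(m.A) < 0)
        for (t, s), sign in COUPLING_SIGNS.items():
            assert np.sign(m.A[i[t], i[s]]) in (0, sign)

    def test_matrix_equals_per_equation_rhs(self, rng):
        for _ in range(1000):
            params = random_params(rng)
            m = mn.assemble_matrices(params)
            y = rng.uniform(0, 100, size=6)
            scale = max(1.0, np.abs(per_equation_rhs(y, params)).max())
            assert np.abs(mn.rhs(y, m) - per_equation_rhs(y, params)).max() < 1e-12 * scale

    def test_rhs_at_zero_is_drive(self, rng):
        params = random_params(rng)
        m = mn.assemble_matrices(params)
        np.testing.assert_array_equal(mn.rhs(np.zeros(6), m), m.b)

    def test_rhs_vanishes_at_equilibrium(self, reference_params, rest_rates):
        # the reference drives were solved so the rest rates are equilibrium
        m = mn.assemble_matrices(reference_params)
        assert np.abs(mn.rhs(rest_rates, m)).max() < 1e-9

    def test_decoupled_rhs_is_leak_plus_drive(self):
        k = 1500.0
        params = mn.ParameterSet.from_components(TAU_S, exts={a: k for a in AREAS})
        m = mn.assemble_matrices(params)
        y = np.full(6, 3.0)
        expected = -3.0 / np.array([TAU_S[a] for a in AREAS]) + k
        np.testing.assert_allclose(mn.rhs(y, m), expected, rtol=1e-14)


class TestValidation:
    def test_nonpositive_tau_rejected(self):
        vals = {k: 1.0 for k in PARAM_KEYS}
        vals.update({f"tau.{a}": 0.001 for a in AREAS})
        vals["tau.GP"] = 0.0
        with pytest.raises(mn.ModelValidationError):
            mn.ParameterSet(vals)

    def test_negative_coefficient_rejected(self):
        params = mn.ParameterSet.from_components(TAU_S)
        with pytest.raises(mn.ModelValidationError):
            params.replace({alpha_key("GP", "DRN"): -1.0})

    def test_unknown_edge_rejected(self):
        with pytest.raises(mn.ModelValidationError):
            mn.ParameterSet.from_components(TAU_S, alphas={("GP", "LC"): 1.0})

    def test_matrix_invariants(self):
        with pytest.raises(mn.ModelValidationError):
            mn.ModelMatrices(np.eye(6), np.zeros((6, 6)), np.zeros(6))
        C = np.zeros((6, 6))
        C[0, 1] = C[2, 3] = 1.0
        with pytest.raises(mn.ModelValidationError):
            mn.ModelMatrices(-np.eye(6), C, np.zeros(6))

    def test_dimensional_audit_passes(self, reference_params):
        mn.dimensional_audit(reference_params)

    def test_is_physical_box(self):
        assert mn.is_physical(np.zeros(6))
        assert mn.is_physical(np.full(6, 500.0))
        assert not mn.is_physical(np.array([-0.1, 1, 1, 1, 1, 1]))
        assert not mn.is_physical(np.array([501.0, 1, 1, 1, 1, 1]))


class TestConditions:
    @pytest.fixture()
    def subject(self, reference_params):
        s = mn.SubjectModel("ref", reference_params)
        s = s.with_overlay("LDA", {k: reference_params[k] * 0.5 + 1.0 for k in FREE_PARAMS["LDA"]})
        s = s.with_overlay("L5HT", {k: reference_params[k] * 0.5 + 2.0 for k in FREE_PARAMS["L5HT"]})
        s = s.with_overlay("LNE", {k: reference_params[k] * 0.5 + 3.0 for k in FREE_PARAMS["LNE"]})
        return s

    def test_free_parameter_counts(self):
        assert len(FREE_PARAMS["SHAM"]) == 20
        assert len(FREE_PARAMS["LDA"]) == 4
        assert len(FREE_PARAMS["L5HT"]) == 3
        assert len(FREE_PARAMS["LNE"]) == 3
        # the three lesions live in different equations: pairwise disjoint
        assert not set(FREE_PARAMS["LDA"]) & set(FREE_PARAMS["L5HT"])
        assert not set(FREE_PARAMS["LDA"]) & set(FREE_PARAMS["LNE"])
        assert not set(FREE_PARAMS["L5HT"]) & set(FREE_PARAMS["LNE"])

    def test_sham_is_identity(self, subject, reference_params):
        assert mn.apply_condition(subject, "SHAM").values == reference_params.values

    @pytest.mark.parametrize("condition,n_diff", [("LDA", 4), ("L5HT", 3), ("LNE", 3), ("LDA+L5HT", 7), ("LDA+LNE", 7)])
    def test_overlay_replaces_exactly_free_params(self, subject, condition, n_diff):
        base = subject.base.values
        lesioned = mn.apply_condition(subject, condition).values
        diff = {k for k in base if base[k] != lesioned[k]}
        assert len(diff) == n_diff

    def test_combined_overlays_commute(self, subject):
        ab = subject.base.replace(subject.overlays["LDA"]).replace(subject.overlays["L5HT"])
        ba = subject.base.replace(subject.overlays["L5HT"]).replace(subject.overlays["LDA"])
        assert ab.values == ba.values
        assert ab.values == mn.apply_condition(subject, "LDA+L5HT").values

    def test_missing_overlay_names_condition(self, reference_params):
        bare = mn.SubjectModel("bare", reference_params)
        with pytest.raises(mn.ConditionError, match="L5HT"):
            mn.apply_condition(bare, "LDA+L5HT")

    def test_overlay_restricted_to_free_params(self, reference_params):
        s = mn.SubjectModel("ref", reference_params)
        with pytest.raises(mn.ModelValidationError):
            s.with_overlay("LDA", {alpha_key("GP", "DRN"): 1.0})
        with pytest.raises(mn.ConditionError):
            s.with_overlay("LDA+L5HT", {ext_key("DRN"): 1.0})

    def test_unknown_condition(self, subject):
        with pytest.raises(mn.ConditionError):
            mn.apply_condition(subject, "L6HT")


class TestSerialization:
    def test_json_roundtrip(self, reference_params, tmp_path):
        path = tmp_path / "params.json"
        reference_params.to_json(path)
        back = mn.ParameterSet.from_json(path)
        assert back.values == reference_params.values
        assert back.condition == reference_params.condition


@given(scale=st.floats(0.1, 10.0))
def test_rhs_matrix_equivalence_scales(scale):
    """Hadamard-product quadratic term matches the explicit beta * LC^2."""
    params = make_params({("SNcVTA", "LC"): 5.0}, beta=3.0)
    m = mn.assemble_matrices(params)
    y = scale * np.array([REST_RATES_HZ[a] for a in AREAS])
    expected = per_equation_rhs(y, params)
    np.testing.assert_allclose(mn.rhs(y, m), expected, rtol=1e-12, atol=1e-9)
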