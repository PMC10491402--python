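"""Model-library construction: wiring, counts, flow structure, fixtures."""

import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

import motif_ident as mi
from motif_ident.motifs import BASIC_CASES, symbol


def _sym(*names):
    return [symbol(n) for n in names]


class TestWorkedExamples:
    def test_motif2_case_b7_equations(self, m2b7):
        """Inflow controller with inhibited compensation and zero-order
        controller degradation: dA/dt = k_i - k_o*A + k_c*K_iE/(K_iE+E),
        dE/dt = k_s*A - k_d."""
        A, E, k_i, k_o, k_c, k_s, k_d, K_iE = _sym(
            "A", "E", "k_i", "k_o", "k_c", "k_s", "k_d", "K_iE")
        dA, dE = m2b7.dynamics
        assert sp.cancel(dA - (k_i - k_o * A + k_c * K_iE / (K_iE + E))) == 0
        assert sp.cancel(dE - (k_s * A - k_d)) == 0
        assert m2b7.params == (k_i, k_o, k_c, k_s, k_d, K_iE)
        assert m2b7.N == 8

    def test_motif3_case_b8_equations(self, m3b8):
        """Activating inflow controller sensed through inhibited synthesis,
        first-order degradation of E; six parameters, N = 8."""
        A, E, k_i, k_o, k_c, k_s, k_d, K_iA = _sym(
            "A", "E", "k_i", "k_o", "k_c", "k_s", "k_d", "K_iA")
        dA, dE = m3b8.dynamics
        assert sp.cancel(dA - (k_i - k_o * A + k_c * E)) == 0
        assert sp.cancel(dE - (k_s * K_iA / (K_iA + A) - k_d * E)) == 0
        assert set(m3b8.params) == {k_i, k_o, k_c, k_s, k_d, K_iA}
        assert m3b8.N == 8

    def test_antithetic_annihilation_in_both_controller_equations(self):
        model = mi.build_model("antithetic", 1, "A1")
        assert model.n == 3
        A, E1, E2, k_a = _sym("A", "E1", "E2", "k_a")
        ja = model.flow_map["j_a"]
        assert sp.cancel(ja - k_a * E1 * E2) == 0
        dE1 = model.dynamics[1]
        dE2 = model.dynamics[2]
        # j_a is subtracted in both controller balances
        assert sp.cancel(sp.diff(dE1, k_a) + E1 * E2) == 0
        assert sp.cancel(sp.diff(dE2, k_a) + E1 * E2) == 0


class TestEnumeration:
    def test_library_counts(self, all_models):
        assert len(all_models) == 128
        assert sum(1 for m in all_models if m.family == "basic") == 96
        assert sum(1 for m in all_models if m.family == "antithetic") == 32

    def test_size_ranges(self, all_models):
        for m in all_models:
            lo, hi = (6, 10) if m.family == "basic" else (8, 11)
            assert lo <= m.N <= hi, m.name
            assert m.n == (2 if m.family == "basic" else 3)

    def test_enumeration_order_is_stable(self, all_models):
        assert [m.name for m in all_models[:3]] == [
            "basic-m1-B1", "basic-m1-B2", "basic-m1-B3"]
        assert all_models[96].name == "antithetic-m1-A1"

    def test_invalid_selection(self):
        with pytest.raises(mi.InvalidSelectionError):
            mi.build_model("basic", 9, "B1")
        with pytest.raises(mi.InvalidSelectionError):
            mi.build_model("basic", 1, "A1")
        with pytest.raises(mi.InvalidSelectionError):
            mi.build_model("antithetic", 1, "B1")

    def test_no_activation_link_motifs_duplicate_saturable_cases(self):
        """Motifs 4 and 8 have two inhibiting links, so the saturable cases
        coincide symbolically with the first-order ones (B1=B4 etc.); they
        are still enumerated as separate entries."""
        pairs = [("B1", "B4"), ("B2", "B5"), ("B3", "B6"),
                 ("B7", "B10"), ("B8", "B11"), ("B9", "B12")]
        for index in (4, 8):
            for a, b in pairs:
                ma = mi.build_model("basic", index, a)
                mb = mi.build_model("basic", index, b)
                assert ma.same_structure(mb), (index, a, b)
        # a motif with an activation link does differ
        assert not mi.build_model("basic", 1, "B1").same_structure(
            mi.build_model("basic", 1, "B4"))


class TestFlowStructure:
    def test_disturbance_expressions(self, all_models):
        k_i, k_o, A = _sym("k_i", "k_o", "A")
        for m in all_models:
            fm = m.flow_map
            if "d_i" in fm:
                assert fm["d_i"] == k_i
            if "d_o" in fm:
                assert sp.cancel(fm["d_o"] - k_o * A) == 0

    def test_one_disturbance_models_keep_main_disturbance(self, all_models):
        for m in all_models:
            one = m.case_id in ("B1", "B2", "B3", "B4", "B5", "B6", "A1", "A2")
            fm = m.flow_map
            if not one:
                assert "d_i" in fm and "d_o" in fm
            elif m.index <= 4:    # inflow: outflow disturbance is the main one
                assert "d_o" in fm and "d_i" not in fm
            else:                 # outflow: inflow disturbance
                assert "d_i" in fm and "d_o" not in fm

    def test_outflow_compensation_is_first_order_in_a(self, all_models):
        A = symbol("A")
        for m in all_models:
            jc = m.flow_map["j_c"]
            ratio = sp.cancel(jc / A)
            if m.index >= 5:
                assert A not in ratio.free_symbols, m.name
            else:
                assert A not in jc.free_symbols, m.name

    def test_every_parameter_appears_in_a_flow(self, all_models):
        for m in all_models:
            used = set().union(*(e.free_symbols for e in m.flow_map.values()))
            assert set(m.params) <= used, m.name


class TestLoopGain:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        family_index=st.integers(0, 127),
        data=st.data(),
    )
    def test_library_loop_gain_negative_at_random_positive_points(
            self, family_index, data):
        model = mi.enumerate_models()[family_index]
        point = {
            el.name: data.draw(st.floats(0.05, 20.0, allow_nan=False))
            for el in model.states + model.params
        }
        assert mi.loop_gain_sign(model, point) == -1

    def test_known_examples_at_ones(self, m2b7):
        ones = lambda m: {el.name: 1.0 for el in m.states + m.params}  # noqa: E731
        assert mi.loop_gain_sign(m2b7, ones(m2b7)) == -1
        m5b2 = mi.build_model("basic", 5, "B2")
        assert mi.loop_gain_sign(m5b2, ones(m5b2)) == -1

    def test_miswired_variant_is_positive(self):
        """An inflow model where E activates j_c and A activates j_s closes
        a positive loop and must be flagged."""
        A, E, k_o, k_c, k_s, k_d = _sym("A", "E", "k_o", "k_c", "k_s", "k_d")
        bad = mi.Model(
            family="basic", index=None, case_id=None,
            states=(A, E), params=(k_o, k_c, k_s, k_d),
            dyn_terms=(None, None),
            raw_dynamics=(-k_o * A + k_c * E, k_s * A - k_d * E),
            flows=(), xtilde=(A, E, k_o, k_c, k_s, k_d),
            species_relation=(), name="miswired",
        )
        point = {el.name: 1.0 for el in bad.xtilde}
        assert mi.loop_gain_sign(bad, point) == 1

    def test_degenerate_point_raises(self):
        decay = mi.toy_models()[0]
        chain = mi.toy_models()[2]
        # chain has no E1/E2; loop gain through x2 -> x1 partial is zero
        with pytest.raises((mi.DegeneratePointError, KeyError, IndexError, ValueError)):
            mi.loop_gain_sign(chain, {el.name: 1.0 for el in chain.xtilde})
        with pytest.raises(ValueError):
            mi.loop_gain_sign(decay, {"x": -1.0, "k": 1.0})


class TestToyModels:
    def test_toy_sizes(self, toys):
        assert toys["decay"].N == 2
        assert toys["scaled"].N == 3
        assert toys["chain"].N == 4

    def test_scaled_decay_admits_scaling_symmetry(self, toys):
        om = mi.build_output_model(toys["scaled"], ("obs",), method=2)
        assert mi.check_symmetry(om, {"x": "x", "c": "-c"}, mode="symbolic")


class TestGrammar:
    def test_text_round_trip(self, m3b8):
        text = mi.model_to_text(m3b8)
        back = mi.model_from_text(text)
        assert back.same_structure(m3b8)
        assert [s.name for s in back.states] == ["A", "E"]
        assert set(p.name for p in back.params) == set(p.name for p in m3b8.params)

    def test_json_round_trip(self, m2b7):
        back = mi.model_from_json(mi.model_to_json(m2b7))
        assert back.same_structure(m2b7)

    def test_user_model_is_analyzable(self):
        text = """
        dx/dt = -k*x
        params: k, c
        flows:
          obs = c*x
        """
        model = mi.model_from_text(text)
        om = mi.build_output_model(model, ("obs",), method=2)
        res = mi.assess(om, mode="symbolic")
        assert (res.rank, res.N) == (2, 3)

    def test_power_caret_notation(self):
        model = mi.model_from_text("dx/dt = -k*x^2\nparams: k\n")
        x, k = _sym("x", "k")
        assert sp.cancel(model.dynamics[0] + k * x**2) == 0
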