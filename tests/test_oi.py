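"""Lie-derivative engine, rank modes, stopping rules, diagnosis, symmetry."""

import pytest
import sympy as sp

import motif_ident as mi
from motif_ident.motifs import symbol
from motif_ident.oi import build_oi, lie_stack, generic_rank


@pytest.fixture(scope="module")
def decay_om():
    decay = mi.toy_models()[0]
    return mi.build_output_model(decay, ("x",), method=2)


class TestJets:
    """Series arithmetic underlying the point-evaluation engine."""

    def test_geometric_series_reciprocal(self):
        from fractions import Fraction
        from motif_ident._jets import Jet
        one_minus_t = Jet([Fraction(1), Fraction(-1)])
        inv = 1 / (one_minus_t + Jet([0] * 5))  # pad to request 6 coefficients
        assert inv.c[:5] == [1, 1, 1, 1, 1]

    def test_product_and_power(self):
        from motif_ident._jets import Jet
        a = Jet([1.0, 2.0, 3.0])
        sq = a * a
        assert sq.c == [1.0, 4.0, 10.0, 12.0, 9.0]
        assert (a ** 2).c == sq.c

    def test_sensitivity_rows_match_symbolic_jacobian(self, m3b8):
        """Order-k jet rows equal the Jacobian of the k-th Lie derivative
        evaluated at the same point (the defining identity of the engine)."""
        from fractions import Fraction
        from motif_ident._jets import SensitivityJets
        om = mi.build_output_model(m3b8, ("A", "E"), method=2)
        sens = SensitivityJets(om)
        point = {s: Fraction(num, 10) for s, num in
                 zip(om.xtilde, (7, 9, 11, 13, 6, 8, 12, 14))}
        state = sens.start(point)
        oi = mi.build_oi(om, 2)
        sym = oi.entries.subs({k: sp.Rational(v.numerator, v.denominator)
                               for k, v in point.items()})
        rows = []
        for k in range(3):
            rows.extend(sens.block(state, k))
        for i in range(sym.rows):
            for j in range(sym.cols):
                assert sp.Rational(rows[i][j].numerator, rows[i][j].denominator) \
                    == sp.nsimplify(sym[i, j]), (i, j)


class TestLieStack:
    def test_order_zero_is_output(self, m3b8):
        om = mi.build_output_model(m3b8, ("A", "E"), method=2)
        st = mi.lie_stack(om, 0)
        assert list(st.orders[0]) == [symbol("A"), symbol("E")]

    def test_first_derivative_of_identity_output_is_dynamics(self, m3b8):
        om = mi.build_output_model(m3b8, ("A",), method=2)
        st = mi.lie_stack(om, 1)
        assert sp.cancel(st.orders[1][0] - m3b8.dynamics[0]) == 0

    def test_decay_orders(self, decay_om):
        x, k = symbol("x"), symbol("k")
        st = mi.lie_stack(decay_om, 2)
        assert sp.cancel(st.orders[1][0] + k * x) == 0
        assert sp.cancel(st.orders[2][0] - k**2 * x) == 0

    def test_parameters_have_zero_dynamics(self, decay_om):
        """Lie derivatives never pick up derivatives with respect to time of
        parameters: the k-th derivative of y = x stays a polynomial in (k, x)
        of degree one in x."""
        st = mi.lie_stack(decay_om, 4)
        x, k = symbol("x"), symbol("k")
        for j, order in enumerate(st.orders):
            assert sp.cancel(order[0] - (-k) ** j * x) == 0


class TestOIMatrix:
    def test_decay_hand_computed_matrix(self, decay_om):
        x, k = symbol("x"), symbol("k")
        oi = mi.build_oi(decay_om, 2)
        expected = sp.Matrix([[1, 0], [-k, -x], [k**2, 2 * k * x]])
        assert sp.simplify(oi.entries - expected) == sp.zeros(3, 2)

    def test_shape(self, m2b7):
        om = mi.build_output_model(m2b7, ("A", "E"), method=2)
        oi = mi.build_oi(om, 1)
        assert oi.shape == (4, 8)
        assert oi.entries.cols == om.N

    def test_first_order_rows_equal_dynamics_jacobian(self, m3b8):
        om = mi.build_output_model(m3b8, ("A", "E"), method=2)
        oi = mi.build_oi(om, 1)
        jac = sp.Matrix(m3b8.dynamics).jacobian(sp.Matrix(om.xtilde))
        assert sp.simplify(oi.entries[2:4, :] - jac) == sp.zeros(2, 8)


class TestGenericRank:
    def test_decay_full_rank(self, decay_om):
        oi = mi.build_oi(decay_om, 2)
        assert mi.generic_rank(oi, mode="symbolic") == 2
        assert mi.generic_rank(oi, mode="numeric", seed=0) == 2

    def test_scaled_decay_rank_deficient(self):
        scaled = mi.toy_models()[1]
        om = mi.build_output_model(scaled, ("obs",), method=2)
        oi = mi.build_oi(om, 2)
        assert mi.generic_rank(oi, mode="symbolic") == 2
        assert om.N == 3

    def test_modes_agree_on_plain_matrix(self):
        x, k = symbol("x"), symbol("k")
        M = sp.Matrix([[x, k * x], [1, k]])  # rank 1: rows proportional
        assert mi.generic_rank(M, mode="symbolic") == 1
        assert mi.generic_rank(M, mode="numeric", seed=1) == 1


class TestAssess:
    def test_decay_identifiable(self, decay_om):
        res = mi.assess(decay_om, mode="symbolic")
        assert res.identifiable and res.rank == res.N == 2
        assert res.stop_condition == "full_rank"

    def test_scaled_decay_unidentifiable(self):
        scaled = mi.toy_models()[1]
        om = mi.build_output_model(scaled, ("obs",), method=2)
        res = mi.assess(om, mode="symbolic")
        assert (res.rank, res.N) == (2, 3)
        assert not res.identifiable
        assert res.stop_condition in ("rank_plateau", "max_order")

    def test_constant_output_stops_on_plateau(self, m3b8):
        res = mi.assess(mi.build_output_model(m3b8, ("d_i",), method=2),
                        mode="symbolic")
        assert res.rank == 1
        assert res.stop_condition == "rank_plateau"
        assert res.k_used == 1

    def test_k_used_bounded(self, m3b8):
        res = mi.assess(mi.build_output_model(m3b8, ("E",), method=2),
                        mode="symbolic")
        assert res.k_used <= res.N - 1

    def test_rank_by_order_monotone(self, m3b8):
        for combo in [("A",), ("j_c",), ("E", "d_i"), ("A", "E")]:
            res = mi.assess(mi.build_output_model(m3b8, combo, method=2),
                            mode="symbolic")
            orders = res.rank_by_order
            assert all(a <= b for a, b in zip(orders, orders[1:]))

    def test_adding_a_measurement_never_lowers_rank(self, m3b8):
        singles = {}
        for token in ("A", "E", "di", "do", "jc", "js", "jd"):
            om = mi.build_output_model(m3b8, (token,), method=2)
            singles[token] = mi.assess(om, mode="symbolic").rank
        for pair in [("A", "E"), ("E", "di"), ("jc", "js"), ("di", "do")]:
            om = mi.build_output_model(m3b8, pair, method=2)
            r = mi.assess(om, mode="symbolic").rank
            assert r >= max(singles[pair[0]], singles[pair[1]])

    def test_numeric_matches_symbolic(self, m3b8):
        for combo in [("d_i",), ("j_c",), ("E", "d_i"), ("A", "E")]:
            om = mi.build_output_model(m3b8, combo, method=2)
            rs = mi.assess(om, mode="symbolic").rank
            rn = mi.assess(om, mode="numeric", seed=7).rank
            assert rs == rn, combo

    def test_method_equivalence(self, m2b7):
        for combo in [("j_c",), ("A", "j_c"), ("E", "d_o"), ("j_c", "j_s")]:
            v1 = mi.assess(mi.build_output_model(m2b7, combo, 1), mode="symbolic")
            v2 = mi.assess(mi.build_output_model(m2b7, combo, 2), mode="symbolic")
            assert v1.identifiable == v2.identifiable, combo
            assert v1.N == v2.N

    def test_auto_mode_selection(self, m3b8):
        model = mi.build_model("basic", 1, "B12")  # N = 10
        res = mi.assess(mi.build_output_model(model, ("A", "E"), 2), mode="auto")
        assert res.mode == "numeric"
        res8 = mi.assess(mi.build_output_model(m3b8, ("A", "E"), 2), mode="auto")
        assert res8.mode == "symbolic"


class TestElementDiagnosis:
    def test_full_rank_flags_everything(self, m3b8):
        om = mi.build_output_model(m3b8, ("A", "E"), method=2)
        d = mi.element_identifiability(om, mode="symbolic")
        assert not d.unidentifiable_params
        assert not d.unobservable_states
        assert len(d.identifiable_params) == m3b8.q
        assert len(d.observable_states) == m3b8.n

    def test_compensatory_flow_only(self, m3b8):
        d = mi.element_identifiability(
            mi.build_output_model(m3b8, ("j_c",), method=2), mode="symbolic")
        out = d.to_dict()
        assert set(out["identifiable_params"]) == {"k_o", "k_d"}
        assert set(out["unidentifiable_params"]) == {"k_i", "k_c", "k_s", "K_iA"}
        assert set(out["unobservable_states"]) == {"A", "E"}

    def test_partition_is_consistent(self, m3b8):
        om = mi.build_output_model(m3b8, ("E", "d_i"), method=2)
        d = mi.element_identifiability(om, mode="symbolic")
        total = (len(d.identifiable_params) + len(d.unidentifiable_params)
                 + len(d.observable_states) + len(d.unobservable_states))
        assert total == om.N


class TestSymmetry:
    def test_translation_symmetry_b7_broken_in_b8(self, m3b7, m3b8):
        gen = {"E": "-1", "k_i": "k_c"}
        om7 = mi.build_output_model(m3b7, ("A", "j_s"), method=2)
        om8 = mi.build_output_model(m3b8, ("A", "j_s"), method=2)
        assert mi.check_symmetry(om7, gen, mode="symbolic")
        assert not mi.check_symmetry(om8, gen, mode="symbolic")
        # numeric mode agrees
        assert mi.check_symmetry(om7, gen, mode="numeric", seed=5)
        assert not mi.check_symmetry(om8, gen, mode="numeric", seed=5)

    def test_symmetry_implies_rank_deficiency(self, m3b7):
        om7 = mi.build_output_model(m3b7, ("A", "j_s"), method=2)
        res = mi.assess(om7, mode="symbolic")
        assert res.rank < res.N

    def test_zero_generator_rejected(self, m3b7):
        om = mi.build_output_model(m3b7, ("A", "j_s"), method=2)
        with pytest.raises(ValueError):
            mi.check_symmetry(om, {"E": "0"})

    def test_dimension_mismatch_rejected(self, m3b7):
        om = mi.build_output_model(m3b7, ("A", "j_s"), method=2)
        with pytest.raises(ValueError):
            mi.check_symmetry(om, ["1", "0"])
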