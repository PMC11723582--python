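"""Expression grammar, dimension inference and evaluation."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from lemslite.dimensions import DIMENSIONS
from lemslite.expressions import (
    Bin,
    Call,
    DimensionInconsistency,
    EvaluationError,
    ExpressionError,
    Lit,
    Sym,
    Un,
    compile_expr,
    evaluate,
    free_symbols,
    infer_dimension,
    parse_expr,
    serialize_expr,
)


class TestGrammar:
    def test_hr_phi_equation_structure(self):
        # y - a*x^3 + b*x^2 associates as (y - a*x^3) + b*x^2
        e = parse_expr("y - a*x^3 + b*x^2")
        assert isinstance(e, Bin) and e.op == "+"
        assert isinstance(e.left, Bin) and e.left.op == "-"
        val = evaluate(e, {"y": 2.0, "a": 1.0, "b": 3.0, "x": 2.0})
        assert val == 2.0 - 1.0 * 8.0 + 3.0 * 4.0

    def test_dotted_dialect_normalises_to_symbolic(self):
        dotted = parse_expr("v .gt. 0 .and. spiking .lt. 0.5")
        symbolic = parse_expr("(v > 0) and (spiking < 0.5)")
        assert dotted == symbolic

    def test_power_is_right_associative(self):
        assert evaluate(parse_expr("2^3^2"), {}) == 512.0

    def test_unary_minus_binds_looser_than_power(self):
        assert evaluate(parse_expr("-2^2"), {}) == -4.0

    def test_comparisons_bind_looser_than_arithmetic(self):
        e = parse_expr("t .lt. delay + duration")
        assert evaluate(e, {"t": 5.0, "delay": 3.0, "duration": 4.0}) == 1.0

    @pytest.mark.parametrize("bad", ["", "1 +", "(a", "a ~ b", "2..3",
                                     "foo(1)", "exp(1, 2)", ".gq. 3"])
    def test_syntax_errors(self, bad):
        with pytest.raises(ExpressionError):
            parse_expr(bad)

    def test_syntax_error_carries_position(self):
        with pytest.raises(ExpressionError, match="position"):
            parse_expr("a + + )")


class TestEvaluation:
    def test_chi_at_zero_state_is_c(self):
        assert evaluate(parse_expr("c - d*x^2 - y"),
                        {"c": -3.0, "d": 5.0, "x": 0.0, "y": 0.0}) == -3.0

    def test_rho_at_zero_state(self):
        val = evaluate(parse_expr("s*(x - x1) - z"),
                       {"s": 4.0, "x": 0.0, "x1": -1.3, "z": 0.0})
        assert val == pytest.approx(-4.0 * -1.3)

    def test_boolean_combination(self):
        assert evaluate(parse_expr("(1>0) and (0.2<0.5)"), {}) == 1.0
        assert evaluate(parse_expr("(1>0) and (0.2>0.5)"), {}) == 0.0
        assert evaluate(parse_expr("not (1>0)"), {}) == 0.0

    def test_unbound_symbol(self):
        with pytest.raises(EvaluationError, match="unbound"):
            evaluate(parse_expr("a + b"), {"a": 1.0})

    def test_domain_error_surfaces_with_context(self):
        with pytest.raises(EvaluationError, match="ln"):
            evaluate(parse_expr("ln(x)"), {"x": -1.0})

    def test_random_is_deterministic_under_seed(self):
        e = parse_expr("random(10)")
        v1 = evaluate(e, {}, rng=random.Random(7))
        v2 = evaluate(e, {}, rng=random.Random(7))
        assert v1 == v2 and 0.0 <= v1 < 10.0

    def test_random_requires_rng(self):
        with pytest.raises(EvaluationError):
            evaluate(parse_expr("random(1)"), {})


# --- random-tree strategies -------------------------------------------------

_NAMES = ["u", "w", "p", "q"]
_SAFE_FUNCS = ["sin", "cos", "tanh", "abs", "exp"]

# non-negative: the grammar has no signed literals (a leading minus
# always parses as unary negation)
_literals = st.floats(min_value=0.0, max_value=4.0,
                      allow_nan=False, allow_infinity=False)


def _expr_trees():
    leaves = st.one_of(
        _literals.map(Lit),
        st.sampled_from(_NAMES).map(Sym),
    )

    def extend(children):
        return st.one_of(
            children.map(lambda e: Un("neg", e)),
            st.tuples(st.sampled_from("+-*/"), children, children).map(
                lambda t: Bin(t[0], t[1], t[2])),
            st.tuples(children, st.integers(0, 3)).map(
                lambda t: Bin("^", t[0], Lit(float(t[1])))),
            st.tuples(st.sampled_from([">", "<", ">=", "<=", "==", "!="]),
                      children, children).map(lambda t: Bin(t[0], t[1], t[2])),
            st.tuples(st.sampled_from(["and", "or"]), children, children).map(
                lambda t: Bin(t[0], t[1], t[2])),
            st.tuples(st.sampled_from(_SAFE_FUNCS), children).map(
                lambda t: Call(t[0], (t[1],))),
        )

    return st.recursive(leaves, extend, max_leaves=12)


@settings(max_examples=300, derandomize=True)
@given(_expr_trees())
def test_serialize_parse_round_trip_is_structural_identity(e):
    assert parse_expr(serialize_expr(e)) == e


@settings(max_examples=1000, derandomize=True)
@given(_expr_trees(), st.integers(0, 2 ** 31 - 1))
def test_compiled_evaluator_agrees_with_reference_to_zero_ulp(e, seed):
    rng = random.Random(seed)
    scope = {n: rng.uniform(-3, 3) for n in _NAMES}
    try:
        ref = evaluate(e, scope)
    except (EvaluationError, ZeroDivisionError, OverflowError):
        return
    if not math.isfinite(ref):
        return
    got = compile_expr(e)(scope)
    assert got == ref  # bit-identical, same operation order


class TestDimensionInference:
    SCOPE = {name: DIMENSIONS[dim] for name, dim in {
        "v": "voltage", "t": "time", "C": "capacitance",
        "iMemb": "current", "iSyn": "current", "v_scaling": "voltage",
        "MSEC": "time", "x": "none", "y": "none", "z": "none",
        "a": "none", "b": "none", "c": "none", "d": "none",
        "s": "none", "r": "none", "x1": "none", "spiking": "none",
    }.items()}

    def test_membrane_equation_has_voltage_per_time(self):
        d = infer_dimension(parse_expr("iMemb / C"), self.SCOPE)
        want = DIMENSIONS["voltage"] / DIMENSIONS["time"]
        assert d == want

    def test_capacitive_current_term_is_current(self):
        e = parse_expr("C * v_scaling * (phi - z) / MSEC + iSyn")
        scope = dict(self.SCOPE, phi=DIMENSIONS["none"])
        assert infer_dimension(e, scope) == DIMENSIONS["current"]

    def test_dropping_the_time_constant_breaks_the_sum(self):
        # without /MSEC the capacitive term is charge, not current: the
        # addition of charge + current must be reported, naming the sum
        e = parse_expr("C * v_scaling * (phi - z) + iSyn")
        scope = dict(self.SCOPE, phi=DIMENSIONS["none"])
        with pytest.raises(DimensionInconsistency, match=r"\+ iSyn"):
            infer_dimension(e, scope)

    def test_dimensionless_sum(self):
        assert infer_dimension(parse_expr("x + x"),
                               self.SCOPE).is_dimensionless

    def test_comparison_requires_equal_dimensions(self):
        with pytest.raises(DimensionInconsistency):
            infer_dimension(parse_expr("v .gt. t"), self.SCOPE)

    def test_comparison_against_literal_zero_is_allowed(self):
        d = infer_dimension(parse_expr("v .gt. 0"), self.SCOPE)
        assert d.is_dimensionless

    def test_transcendental_requires_dimensionless(self):
        with pytest.raises(DimensionInconsistency):
            infer_dimension(parse_expr("exp(v)"), self.SCOPE)

    def test_power_requires_dimensionless_exponent(self):
        with pytest.raises(DimensionInconsistency):
            infer_dimension(parse_expr("x ^ t"), self.SCOPE)

    def test_dimensioned_base_with_integer_exponent(self):
        d = infer_dimension(parse_expr("v ^ 2"), self.SCOPE)
        assert d == DIMENSIONS["voltage"] * DIMENSIONS["voltage"]

    def test_unresolved_symbol_reported(self):
        with pytest.raises(DimensionInconsistency, match="ghost"):
            infer_dimension(parse_expr("ghost + x"), self.SCOPE)

    def test_inference_depends_only_on_dimensions_not_units(self):
        # the same expression checks identically whether values would be
        # entered in mV or V: only the dimension map enters the result
        e = parse_expr("v / v_scaling + x")
        assert infer_dimension(e, self.SCOPE).is_dimensionless


def test_free_symbols():
    assert free_symbols(parse_expr("s*(x - x1) - z")) == {"s", "x", "x1", "z"}
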