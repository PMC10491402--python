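"""Symbolic construction of the basic and antithetic controller-motif ODE models.

Controller motifs are small biomolecular reaction networks in which a
controlled species ``A`` and one or two controller species (``E``, or the
antithetic pair ``E1``/``E2``) are wired into a negative feedback loop that
holds the level of ``A`` at a homeostatic setpoint.  The library covers

* 8 *basic* two-species motifs x 12 kinetic cases (``B1``-``B12``), and
* 8 *antithetic* three-species motifs x 4 kinetic cases (``A1``-``A4``),

for a total of 128 distinct model structures.  Motifs 1-4 are *inflow*
controllers (the compensatory flow ``j_c`` adds ``A``), motifs 5-8 are
*outflow* controllers (``j_c`` removes ``A``).  Within each group the
controller species either activates or inhibits ``j_c``, and ``A`` signals
back to the controller through one of its synthesis/degradation flows, with
the two link signs always combining into a net negative loop.

The cases grade two dimensions of model complexity: model size (one or both
of the disturbances ``d_i = k_i`` and ``d_o = k_o*A``) and kinetic
complexity (first-order versus saturable activation; zero-order,
first-order or Michaelis-Menten degradation of ``E`` for the basic motifs).

All models are plain :mod:`sympy` expressions; nothing here is numeric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import sympy as sp

__all__ = [
    "Model",
    "InvalidSelectionError",
    "DegeneratePointError",
    "BASIC_CASES",
    "ANTITHETIC_CASES",
    "BASIC_WIRING",
    "ANTITHETIC_WIRING",
    "PARAM_ORDER",
    "FLOW_ORDER",
    "FLOW_RATE_CONSTANT",
    "build_model",
    "enumerate_models",
    "loop_gain_sign",
    "toy_models",
    "symbol",
]


class InvalidSelectionError(ValueError):
    """Unknown motif/case/measurement selection."""


class DegeneratePointError(ValueError):
    """Evaluation point at which a structural quantity degenerates to zero."""


# ---------------------------------------------------------------------------
# symbols
# ---------------------------------------------------------------------------

#: canonical ordering of rate constants (flow-table order) then binding constants
PARAM_ORDER = (
    "k_i", "k_o", "k_c", "k_s", "k_d", "k_s1", "k_s2", "k_a",
    "K_aA", "K_aE", "K_iA", "K_iE", "K_ME",
)

#: canonical ordering of the named flows
FLOW_ORDER = ("d_i", "d_o", "j_c", "j_s", "j_d", "j_s1", "j_s2", "j_a")

#: the leading multiplicative rate constant of each flow (the parameter that
#: is eliminated when the flow is promoted to a state, method 1)
FLOW_RATE_CONSTANT = {
    "d_i": "k_i", "d_o": "k_o", "j_c": "k_c", "j_s": "k_s", "j_d": "k_d",
    "j_s1": "k_s1", "j_s2": "k_s2", "j_a": "k_a",
}

_SYMBOLS: dict[str, sp.Symbol] = {}


def symbol(name: str) -> sp.Symbol:
    """Return the canonical (positive) symbol for a state/parameter name."""
    try:
        return _SYMBOLS[name]
    except KeyError:
        _SYMBOLS[name] = sp.Symbol(name, positive=True)
        return _SYMBOLS[name]


def _param_sort_key(p: sp.Symbol):
    name = p.name
    return (PARAM_ORDER.index(name), name) if name in PARAM_ORDER else (len(PARAM_ORDER), name)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class Model:
    """A rational ODE model with named flows.

    ``states`` are the dynamic variables (species, plus any flow promoted to
    a state by method 1); ``params`` the free parameters.  Species dynamics
    are stored as signed compositions of named flows (``dyn_terms``) so that
    flow-to-state substitution is exact; states introduced by augmentation
    carry their dynamics directly in ``raw_dynamics``.

    ``xtilde`` is the canonical augmented-state ordering (species first, then
    parameters in canonical order); when a flow is promoted to a state, the
    new state takes the slot of its eliminated rate constant so that the
    augmented-state length N = n + q is invariant and columnwise comparable
    across the two flow-measurement methods.
    """

    family: str                         # "basic" | "antithetic" | "toy"
    index: Optional[int]
    case_id: Optional[str]
    states: tuple
    params: tuple
    dyn_terms: tuple                    # per state: ((flow, sign), ...) or None
    raw_dynamics: tuple                 # per state: expr or None
    flows: tuple                        # ((name, expr), ...); expr is the new
                                        # state symbol for an augmented flow
    xtilde: tuple
    species_relation: tuple             # ((measurement token, frozenset of species), ...)
    flow_states: tuple = ()             # names of flows promoted to states
    name: str = ""

    # -- derived ----------------------------------------------------------

    @property
    def flow_map(self) -> dict:
        return dict(self.flows)

    @property
    def dynamics(self) -> tuple:
        """Right-hand side f, one expression per state, flows substituted in."""
        fm = self.flow_map
        out = []
        for terms, raw in zip(self.dyn_terms, self.raw_dynamics):
            if terms is None:
                out.append(raw)
            else:
                out.append(sp.Add(*[sign * fm[name] for name, sign in terms]))
        return tuple(out)

    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def q(self) -> int:
        return len(self.params)

    @property
    def N(self) -> int:
        return self.n + self.q

    def measurements(self) -> tuple:
        """Available measurement names: species concentrations then flows."""
        species = tuple(s.name for s in self.states
                        if s.name in ("A", "E", "E1", "E2", "x", "x1", "x2"))
        return species + tuple(name for name, _ in self.flows)

    def relation(self, measurement: str) -> frozenset:
        rel = dict(self.species_relation)
        if measurement not in rel:
            raise InvalidSelectionError(
                f"measurement {measurement!r} not available in model {self.name or self.family}"
            )
        return rel[measurement]

    def same_structure(self, other: "Model") -> bool:
        """Symbolic identity of state/parameter lists and dynamics."""
        if self.states != other.states or self.params != other.params:
            return False
        return all(sp.cancel(a - b) == 0 for a, b in zip(self.dynamics, other.dynamics))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Model {self.name or self.family} n={self.n} q={self.q}>"


# ---------------------------------------------------------------------------
# case tables
# ---------------------------------------------------------------------------

# case -> (disturbances, activation_form, e_degradation)
BASIC_CASES = {
    "B1": ("one", "first_order", "zero"),
    "B2": ("one", "first_order", "first"),
    "B3": ("one", "first_order", "michaelis_menten"),
    "B4": ("one", "saturable", "zero"),
    "B5": ("one", "saturable", "first"),
    "B6": ("one", "saturable", "michaelis_menten"),
    "B7": ("both", "first_order", "zero"),
    "B8": ("both", "first_order", "first"),
    "B9": ("both", "first_order", "michaelis_menten"),
    "B10": ("both", "saturable", "zero"),
    "B11": ("both", "saturable", "first"),
    "B12": ("both", "saturable", "michaelis_menten"),
}

# case -> (disturbances, activation_form)
ANTITHETIC_CASES = {
    "A1": ("one", "first_order"),
    "A2": ("one", "saturable"),
    "A3": ("both", "first_order"),
    "A4": ("both", "saturable"),
}

# motif index -> (controller_type, actuation sign E->j_c, sensing channel, sensing sign)
BASIC_WIRING = {
    1: ("inflow", "activating", "j_d", "activating"),
    2: ("inflow", "inhibiting", "j_s", "activating"),
    3: ("inflow", "activating", "j_s", "inhibiting"),
    4: ("inflow", "inhibiting", "j_d", "inhibiting"),
    5: ("outflow", "activating", "j_s", "activating"),
    6: ("outflow", "inhibiting", "j_d", "activating"),
    7: ("outflow", "activating", "j_d", "inhibiting"),
    8: ("outflow", "inhibiting", "j_s", "inhibiting"),
}

# motif index -> (controller_type, actuation sign E1->j_c, sensing sign A->j_s2);
# the sensing sign closes the negative loop through the annihilation reaction:
# equal to the actuation sign for inflow controllers, opposite for outflow.
ANTITHETIC_WIRING = {
    1: ("inflow", "activating", "activating"),
    2: ("inflow", "inhibiting", "inhibiting"),
    3: ("inflow", "activating", "activating"),
    4: ("inflow", "inhibiting", "inhibiting"),
    5: ("outflow", "activating", "inhibiting"),
    6: ("outflow", "inhibiting", "activating"),
    7: ("outflow", "activating", "inhibiting"),
    8: ("outflow", "inhibiting", "activating"),
}


def _link(sign: str, x: sp.Symbol, form: str) -> sp.Expr:
    """Activation/inhibition kinetics of a signalling link.

    Activating links are either first order (``x``) or saturable
    (``x/(K_aX + x)``); inhibiting links always use ``K_iX/(K_iX + x)``.
    """
    if sign == "activating":
        if form == "saturable":
            K = symbol(f"K_a{x.name[0]}" if x.name in ("E1", "E2") else f"K_a{x.name}")
            return x / (K + x)
        return x
    if sign == "inhibiting":
        K = symbol(f"K_i{x.name[0]}" if x.name in ("E1", "E2") else f"K_i{x.name}")
        return K / (K + x)
    raise InvalidSelectionError(f"unknown link sign {sign!r}")


def _finish(family, index, case_id, states, dyn_terms, flows, species_relation) -> Model:
    flow_exprs = dict(flows)
    params = sorted(
        {p for e in flow_exprs.values() for p in e.free_symbols} - set(states),
        key=_param_sort_key,
    )
    return Model(
        family=family,
        index=index,
        case_id=case_id,
        states=tuple(states),
        params=tuple(params),
        dyn_terms=tuple(dyn_terms),
        raw_dynamics=(None,) * len(states),
        flows=tuple(flows),
        xtilde=tuple(states) + tuple(params),
        species_relation=tuple(species_relation),
        name=f"{family}-m{index}-{case_id}",
    )


def _build_basic(index: int, case_id: str) -> Model:
    disturbances, act_form, e_deg = BASIC_CASES[case_id]
    ctype, act_sign, channel, sens_sign = BASIC_WIRING[index]
    A, E = symbol("A"), symbol("E")

    flows = []
    dA = []
    # disturbances: one-disturbance models keep the motif's main disturbance
    # (d_o for inflow controllers, d_i for outflow controllers)
    if disturbances == "both" or ctype == "outflow":
        flows.append(("d_i", symbol("k_i")))
        dA.append(("d_i", 1))
    if disturbances == "both" or ctype == "inflow":
        flows.append(("d_o", symbol("k_o") * A))
        dA.append(("d_o", -1))

    jc = symbol("k_c") * _link(act_sign, E, act_form)
    if ctype == "outflow":
        jc = jc * A          # removal of A is first order in A
        dA.append(("j_c", -1))
    else:
        dA.append(("j_c", 1))
    flows.append(("j_c", jc))

    a_signal = _link(sens_sign, A, act_form)
    deg = {"zero": sp.Integer(1), "first": E,
           "michaelis_menten": E / (symbol("K_ME") + E)}[e_deg]
    if channel == "j_s":
        js = symbol("k_s") * a_signal
        jd = symbol("k_d") * deg
    else:
        js = symbol("k_s")
        jd = symbol("k_d") * a_signal * deg
    flows.append(("j_s", js))
    flows.append(("j_d", jd))

    relation = [(m, frozenset({"A"})) for m in ("A", "d_i", "d_o", "j_c")]
    relation += [(m, frozenset({"E"})) for m in ("E", "j_s", "j_d")]
    relation = [(m, r) for m, r in relation
                if m in ("A", "E") or m in dict(flows)]

    return _finish("basic", index, case_id, (A, E),
                   (tuple(dA), (("j_s", 1), ("j_d", -1))), flows, relation)


def _build_antithetic(index: int, case_id: str) -> Model:
    disturbances, act_form = ANTITHETIC_CASES[case_id]
    ctype, act_sign, sens_sign = ANTITHETIC_WIRING[index]
    A, E1, E2 = symbol("A"), symbol("E1"), symbol("E2")

    flows = []
    dA = []
    if disturbances == "both" or ctype == "outflow":
        flows.append(("d_i", symbol("k_i")))
        dA.append(("d_i", 1))
    if disturbances == "both" or ctype == "inflow":
        flows.append(("d_o", symbol("k_o") * A))
        dA.append(("d_o", -1))

    jc = symbol("k_c") * _link(act_sign, E1, act_form)
    if ctype == "outflow":
        jc = jc * A
        dA.append(("j_c", -1))
    else:
        dA.append(("j_c", 1))
    flows.append(("j_c", jc))

    flows.append(("j_s1", symbol("k_s1")))                       # constant reference
    flows.append(("j_s2", symbol("k_s2") * _link(sens_sign, A, act_form)))  # sensing
    flows.append(("j_a", symbol("k_a") * E1 * E2))               # annihilation

    relation = [(m, frozenset({"A"})) for m in ("A", "d_i", "d_o", "j_c")]
    relation += [("E1", frozenset({"E1"})), ("j_s1", frozenset({"E1"})),
                 ("E2", frozenset({"E2"})), ("j_s2", frozenset({"E2"})),
                 ("j_a", frozenset({"E1", "E2"}))]
    relation = [(m, r) for m, r in relation
                if m in ("A", "E1", "E2") or m in dict(flows)]

    return _finish("antithetic", index, case_id, (A, E1, E2),
                   (tuple(dA), (("j_s1", 1), ("j_a", -1)), (("j_s2", 1), ("j_a", -1))),
                   flows, relation)


def build_model(family: str, index: int, case_id: str) -> Model:
    """Assemble the symbolic ODE model of one (family, motif, case) selection.

    Deterministic and side-effect free.  Raises
    :class:`InvalidSelectionError` on an unknown combination.
    """
    if family == "basic":
        if index not in BASIC_WIRING or case_id not in BASIC_CASES:
            raise InvalidSelectionError(f"unknown basic selection motif={index} case={case_id}")
        return _build_basic(index, case_id)
    if family == "antithetic":
        if index not in ANTITHETIC_WIRING or case_id not in ANTITHETIC_CASES:
            raise InvalidSelectionError(f"unknown antithetic selection motif={index} case={case_id}")
        return _build_antithetic(index, case_id)
    raise InvalidSelectionError(f"unknown family {family!r}")


def enumerate_models(family: Optional[str] = None) -> list:
    """All library models in stable order: 96 basic then 32 antithetic.

    Cases that coincide symbolically (motifs without any activation link are
    unchanged by the saturable cases) are still enumerated as distinct
    entries, matching the library's count of 128 structures.
    """
    out = []
    if family in (None, "basic"):
        out += [build_model("basic", i, c) for i in range(1, 9) for c in BASIC_CASES]
    if family in (None, "antithetic"):
        out += [build_model("antithetic", i, c) for i in range(1, 9) for c in ANTITHETIC_CASES]
    return out


# ---------------------------------------------------------------------------
# structural self-checks and fixtures
# ---------------------------------------------------------------------------


def loop_gain_sign(model: Model, point: dict) -> int:
    """Sign of the feedback-loop gain at a strictly positive point.

    For a two-species model this is the sign of
    ``(dfE/dA) * (dfA/dE)``; for an antithetic model the loop runs through
    the annihilation reaction, ``(dfE2/dA) * (dfE1/dE2) * (dfA/dE1)``.
    Every library motif closes a negative loop, so the result must be -1.
    """
    subs = {symbol(k) if isinstance(k, str) else k: sp.nsimplify(v) for k, v in point.items()}
    if any(v <= 0 for v in subs.values()):
        raise ValueError("loop gain requires a strictly positive point")
    f = dict(zip(model.states, model.dynamics))
    if model.family == "antithetic":
        A, E1, E2 = symbol("A"), symbol("E1"), symbol("E2")
        path = [(f[E2], A), (f[E1], E2), (f[A], E1)]
    else:
        A = model.states[0]
        E = model.states[1]
        path = [(f[E], A), (f[A], E)]
    gain = sp.Integer(1)
    for expr, var in path:
        d = sp.diff(expr, var).subs(subs)
        d = sp.cancel(d)
        if d == 0:
            raise DegeneratePointError(f"zero partial derivative d/d{var} at the supplied point")
        gain *= d
    return int(sp.sign(gain))


def _toy(name, states, params, dynamics, flows=(), relation=()) -> Model:
    states = tuple(states)
    params = tuple(params)
    return Model(
        family="toy", index=None, case_id=None,
        states=states, params=params,
        dyn_terms=(None,) * len(states),
        raw_dynamics=tuple(dynamics),
        flows=tuple(flows),
        xtilde=states + params,
        species_relation=tuple(relation),
        name=name,
    )


def toy_models() -> list:
    """Small fixture models with known identifiability verdicts.

    * ``decay``: x' = -k*x with y = x; fully observable/identifiable (rank 2).
    * ``scaled-decay``: x' = -k*x observed through y = c*x; the scaling
      symmetry x -> lam*x, c -> c/lam makes it rank 2 of N = 3.
    * ``chain``: linear two-state chain x1 -> x2 with y = x2.
    """
    x, k, c = symbol("x"), symbol("k"), symbol("c")
    x1, x2, k1, k2 = symbol("x1"), symbol("x2"), symbol("k1"), symbol("k2")
    return [
        _toy("decay", (x,), (k,), (-k * x,),
             relation=(("x", frozenset({"x"})),)),
        _toy("scaled-decay", (x,), (k, c), (-k * x,),
             flows=(("obs", c * x),),
             relation=(("x", frozenset({"x"})), ("obs", frozenset({"x"})))),
        _toy("chain", (x1, x2), (k1, k2), (-k1 * x1, k1 * x1 - k2 * x2),
             relation=(("x1", frozenset({"x1"})), ("x2", frozenset({"x2"})))),
    ]
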