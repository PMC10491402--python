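"""Measurement combinations and output-model construction.

A measurement is either a species concentration or one of the model's named
flows.  Structural identifiability is assessed for every combination of one
or two measurements.  Flow measurements enter the model output in one of two
equivalent ways:

* **method 1** — the flow is promoted to a state: its expression is replaced
  everywhere in the dynamics by a new state variable whose ODE is the total
  time derivative of the flow expression, with the flow's leading rate
  constant substituted out.  The eliminated rate constant leaves the
  parameter list, so the augmented-state length N = n + q is unchanged and
  the output is a plain state variable.
* **method 2** — the flow expression is used directly as the output
  function; the model itself is untouched.

Both routes give the same identifiability verdict; they differ only in
where the flow's information sits (a state versus an output expression).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import sympy as sp

from .motifs import (
    FLOW_RATE_CONSTANT,
    InvalidSelectionError,
    Model,
    symbol,
)

__all__ = [
    "TOKENS",
    "MeasurementCombo",
    "OutputModel",
    "UnsupportedFlowError",
    "token_for",
    "name_for",
    "species_relation",
    "enumerate_combos",
    "augment_flow_state",
    "build_output_model",
]

#: measurement name -> short CLI/report token
TOKENS = {
    "A": "A", "E": "E", "E1": "E1", "E2": "E2",
    "d_i": "di", "d_o": "do", "j_c": "jc", "j_s": "js", "j_d": "jd",
    "j_s1": "js1", "j_s2": "js2", "j_a": "ja",
}
_FROM_TOKEN = {v: k for k, v in TOKENS.items()}

_CONCENTRATIONS = ("A", "E", "E1", "E2", "x", "x1", "x2")


class UnsupportedFlowError(ValueError):
    """Flow without an eliminable multiplicative rate constant."""


def token_for(measurement: str) -> str:
    return TOKENS.get(measurement, measurement)


def name_for(token: str) -> str:
    return _FROM_TOKEN.get(token, token)


def _order_key(model: Model, m: str) -> tuple:
    if m in _CONCENTRATIONS:
        return (0, [s.name for s in model.states].index(m))
    flow_names = [name for name, _ in model.flows]
    return (1, flow_names.index(m))


@dataclass(frozen=True)
class MeasurementCombo:
    """An ordered set of one or two measurements (concentrations first,
    then flows in flow-table order)."""

    members: tuple

    def __post_init__(self):
        if not 1 <= len(self.members) <= 2:
            raise InvalidSelectionError("a combo holds one or two measurements")
        if len(set(self.members)) != len(self.members):
            raise InvalidSelectionError("duplicate measurement in combo")

    @classmethod
    def of(cls, model: Model, *measurements: str) -> "MeasurementCombo":
        names = [name_for(m) for m in measurements]
        available = model.measurements()
        for m in names:
            if m not in available:
                raise InvalidSelectionError(
                    f"measurement {m!r} not available in {model.name}"
                )
        names.sort(key=lambda m: _order_key(model, m))
        return cls(tuple(names))

    @property
    def tokens(self) -> tuple:
        return tuple(token_for(m) for m in self.members)

    def __str__(self) -> str:
        return ",".join(self.tokens)


def species_relation(measurement: str, model: Model) -> frozenset:
    """The set of species a measurement is tied to.

    A concentration relates to its own species; a flow relates to the
    species whose balance equation it enters (the annihilation flow of the
    antithetic motifs relates to both controller species).
    """
    return model.relation(name_for(measurement))


def enumerate_combos(model: Model) -> list:
    """All one- and two-measurement combinations, in report order.

    The order mirrors the result grids: concentration singles, concentration
    pairs, flow singles, concentration+flow pairs, flow pairs.  A basic
    model with one (two) disturbance(s) has 6 (7) measurements and hence
    21 (28) combos; an antithetic model 8 (9) measurements and 36 (45)
    combos.
    """
    measurements = model.measurements()
    concs = [m for m in measurements if m in _CONCENTRATIONS]
    flows = [m for m in measurements if m not in _CONCENTRATIONS]
    sections = [
        [(c,) for c in concs],
        list(itertools.combinations(concs, 2)),
        [(f,) for f in flows],
        [(c, f) for c in concs for f in flows],
        list(itertools.combinations(flows, 2)),
    ]
    return [MeasurementCombo(tuple(members))
            for section in sections for members in section]


def _eliminable_constant(model: Model, flow: str, expr: sp.Expr):
    """The leading multiplicative rate constant of a flow and the cofactor."""
    designated = FLOW_RATE_CONSTANT.get(flow)
    for p in model.params:
        if designated is not None and p.name != designated:
            continue
        rest = sp.cancel(expr / p)
        if p in rest.free_symbols:
            continue
        # occurrences of p elsewhere in the model (e.g. inside the dynamics
        # of a previously promoted flow state) are handled by substituting
        # p = J / rest everywhere during augmentation
        return p, rest
    raise UnsupportedFlowError(
        f"flow {flow!r} has no eliminable multiplicative rate constant"
    )


def augment_flow_state(model: Model, flow: str) -> Model:
    """Promote a flow to a state (method 1).

    The flow expression ``j = k * h(x)`` is replaced everywhere in the
    dynamics by a new state ``J``; its ODE is the total derivative of the
    flow expression along the dynamics with ``k`` substituted by ``J/h(x)``.
    ``k`` leaves the parameter list and ``J`` takes its slot in the
    augmented-state ordering, so N is unchanged.
    """
    fm = model.flow_map
    if flow not in fm:
        raise InvalidSelectionError(f"flow {flow!r} not present in {model.name}")
    expr = fm[flow]
    if expr.is_Symbol and expr in model.states:
        raise InvalidSelectionError(f"flow {flow!r} is already a state")
    k, rest = _eliminable_constant(model, flow, expr)

    J = symbol(flow)
    k_sub = sp.cancel(J / rest)

    dynamics = model.dynamics
    dJ = sp.cancel(
        sum(sp.diff(expr, x) * fx for x, fx in zip(model.states, dynamics))
    )
    dJ = sp.cancel(dJ.subs(k, k_sub))

    new_flows = tuple(
        (name, J if name == flow else sp.cancel(e.subs(k, k_sub)))
        for name, e in model.flows
    )
    new_raw = tuple(
        None if r is None else sp.cancel(r.subs(k, k_sub))
        for r in model.raw_dynamics
    ) + (dJ,)
    new_xtilde = tuple(J if el == k else el for el in model.xtilde)

    return Model(
        family=model.family,
        index=model.index,
        case_id=model.case_id,
        states=model.states + (J,),
        params=tuple(p for p in model.params if p != k),
        dyn_terms=model.dyn_terms + (None,),
        raw_dynamics=new_raw,
        flows=new_flows,
        xtilde=new_xtilde,
        species_relation=model.species_relation,
        flow_states=model.flow_states + (flow,),
        name=model.name + f"+{flow}",
    )


@dataclass(frozen=True)
class OutputModel:
    """A model together with its chosen output functions g."""

    model: Model
    outputs: tuple
    method: int
    combo: MeasurementCombo

    @property
    def xtilde(self) -> tuple:
        return self.model.xtilde

    @property
    def N(self) -> int:
        return self.model.N

    @property
    def m(self) -> int:
        return len(self.outputs)


def build_output_model(model: Model, combo, method: int = 2) -> OutputModel:
    """Attach a measurement combination to a model as its output vector.

    Flows are augmented sequentially in combo order under method 1 (the
    flows never share a leading rate constant, so the order is immaterial);
    under method 2 they appear verbatim in the output.  Concentration-only
    combos are identical under both methods.
    """
    if not isinstance(combo, MeasurementCombo):
        combo = MeasurementCombo.of(model, *combo)
    if method not in (1, 2):
        raise InvalidSelectionError(f"method must be 1 or 2, got {method!r}")
    state_names = {s.name for s in model.states}
    for m in combo.members:
        if m not in state_names and m not in model.flow_map:
            raise InvalidSelectionError(f"measurement {m!r} not in {model.name}")

    work = model
    if method == 1:
        for m in combo.members:
            if m not in {s.name for s in work.states}:
                work = augment_flow_state(work, m)
        outputs = tuple(symbol(m) for m in combo.members)
    else:
        fm = work.flow_map
        outputs = tuple(symbol(m) if m in state_names else fm[m]
                        for m in combo.members)
    return OutputModel(model=work, outputs=outputs, method=method, combo=combo)
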