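"""Plain-text and JSON serialization of models.

The text grammar is one line per state ``d<name>/dt = <infix expression>``
(with explicit ``*`` and ``^`` for powers), a ``params:`` line, and a
``flows:`` block naming sub-expressions:

    # model basic-m3-B8
    dA/dt = d_i - d_o + j_c
    dE/dt = j_s - j_d
    params: k_i, k_o, k_c, k_s, k_d, K_iA
    flows:
      d_i = k_i
      d_o = k_o*A
      j_c = k_c*E
      j_s = k_s*K_iA/(K_iA + A)
      j_d = k_d*E

State equations may reference flow names (as above) or spell expressions
out in full.  User-defined models parsed from this grammar can be analyzed
exactly like library models.
"""

from __future__ import annotations

import json

import sympy as sp

from .motifs import Model, symbol

__all__ = ["model_to_text", "model_from_text", "model_to_json", "model_from_json"]

_CONC_NAMES = ("A", "E", "E1", "E2", "x", "x1", "x2")


def _fmt(expr) -> str:
    return sp.sstr(expr).replace("**", "^")


def _parse_expr(text: str, local_names) -> sp.Expr:
    expr = sp.parse_expr(
        text.replace("^", "**"),
        local_dict={n: symbol(n) for n in local_names},
        evaluate=True,
    )
    return sp.cancel(expr)


def model_to_text(model: Model) -> str:
    lines = [f"# model {model.name or model.family}"]
    fm = model.flow_map
    for state, terms, raw in zip(model.states, model.dyn_terms, model.raw_dynamics):
        if terms is not None:
            rhs = " ".join(
                ("- " if sign < 0 else ("+ " if i else "")) + name
                for i, (name, sign) in enumerate(terms)
            ).replace("+ -", "-")
        else:
            rhs = _fmt(raw)
        lines.append(f"d{state.name}/dt = {rhs}")
    lines.append("params: " + ", ".join(p.name for p in model.params))
    if model.flows:
        lines.append("flows:")
        for name, expr in model.flows:
            lines.append(f"  {name} = {_fmt(expr)}")
    return "\n".join(lines) + "\n"


def _decompose(dyn: sp.Expr, flows: dict):
    """Try to write a state equation as a signed sum of named flows.

    Greedy: peel off each flow (either sign) whenever the subtraction
    shortens the expanded expression; succeed only if the remainder is
    exactly zero.
    """
    terms = []
    remaining = dyn
    for name, fexpr in flows.items():
        for sign in (1, -1):
            cand = sp.cancel(remaining - sign * fexpr)
            before = len(sp.Add.make_args(sp.expand(remaining)))
            after = len(sp.Add.make_args(sp.expand(cand)))
            if cand == 0 or after < before:
                terms.append((name, sign))
                remaining = cand
                break
    if terms and sp.cancel(remaining) == 0:
        return tuple(terms)
    return None


def model_from_text(text: str, name: str = "user") -> Model:
    """Parse a model from the plain-text grammar."""
    state_lines: list[tuple[str, str]] = []
    params: list[str] = []
    flow_lines: list[tuple[str, str]] = []
    in_flows = False
    for raw_line in text.splitlines():
        line = raw_line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("params:"):
            params = [p.strip() for p in line[len("params:"):].split(",") if p.strip()]
            in_flows = False
        elif line.startswith("flows:"):
            in_flows = True
        elif in_flows:
            fname, _, fexpr = line.partition("=")
            flow_lines.append((fname.strip(), fexpr.strip()))
        elif line.startswith("d") and "/dt" in line:
            lhs, _, rhs = line.partition("=")
            sname = lhs.strip()[1:].split("/")[0]
            state_lines.append((sname, rhs.strip()))
        else:
            raise ValueError(f"unparseable model line: {raw_line!r}")
    if not state_lines:
        raise ValueError("model text declares no state equations")

    state_names = [s for s, _ in state_lines]
    local = set(state_names) | set(params) | {f for f, _ in flow_lines}
    flows = {fname: _parse_expr(fexpr, local) for fname, fexpr in flow_lines}
    flow_syms = {symbol(f): e for f, e in flows.items()}

    dyn_terms, raw_dynamics = [], []
    for _, rhs in state_lines:
        expr = _parse_expr(rhs, local)
        expr = sp.cancel(expr.xreplace(flow_syms))  # flow names used inline
        terms = _decompose(expr, flows) if flows else None
        if terms is not None:
            dyn_terms.append(terms)
            raw_dynamics.append(None)
        else:
            dyn_terms.append(None)
            raw_dynamics.append(expr)

    states = tuple(symbol(s) for s in state_names)
    param_syms = tuple(symbol(p) for p in params)
    relation = tuple(
        (s, frozenset({s})) for s in state_names if s in _CONC_NAMES
    ) + tuple((f, frozenset()) for f in flows)
    return Model(
        family="user", index=None, case_id=None,
        states=states, params=param_syms,
        dyn_terms=tuple(dyn_terms), raw_dynamics=tuple(raw_dynamics),
        flows=tuple(flows.items()),
        xtilde=states + param_syms,
        species_relation=relation,
        name=name,
    )


def model_to_json(model: Model) -> str:
    payload = {
        "name": model.name,
        "family": model.family,
        "index": model.index,
        "case_id": model.case_id,
        "states": [s.name for s in model.states],
        "params": [p.name for p in model.params],
        "dynamics": [_fmt(d) for d in model.dynamics],
        "flows": {name: _fmt(e) for name, e in model.flows},
        "species_relation": {m: sorted(r) for m, r in model.species_relation},
    }
    return json.dumps(payload, indent=2)


def model_from_json(text: str) -> Model:
    payload = json.loads(text)
    local = set(payload["states"]) | set(payload["params"])
    states = tuple(symbol(s) for s in payload["states"])
    params = tuple(symbol(p) for p in payload["params"])
    flows = tuple(
        (name, _parse_expr(e, local)) for name, e in payload["flows"].items()
    )
    flow_map = dict(flows)
    dyn_terms, raw_dynamics = [], []
    for d in payload["dynamics"]:
        expr = _parse_expr(d, local | set(flow_map))
        terms = _decompose(expr, flow_map) if flow_map else None
        dyn_terms.append(terms if terms is not None else None)
        raw_dynamics.append(None if terms is not None else expr)
    relation = tuple(
        (m, frozenset(r)) for m, r in payload.get("species_relation", {}).items()
    )
    return Model(
        family=payload.get("family", "user"),
        index=payload.get("index"), case_id=payload.get("case_id"),
        states=states, params=params,
        dyn_terms=tuple(dyn_terms), raw_dynamics=tuple(raw_dynamics),
        flows=flows, xtilde=states + params,
        species_relation=relation,
        name=payload.get("name", "user"),
    )
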