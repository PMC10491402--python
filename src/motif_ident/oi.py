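"""Observability-identifiability engine.

Structural identifiability is decided as augmented observability: the
parameters are appended to the state vector as constant states, successive
Lie derivatives of the output functions along the dynamics are stacked, and
the Jacobian of that stack with respect to the augmented state x~ — the
generalized observability-identifiability matrix OI(x~) — is tested for
full generic rank.  rank OI(x~) = N = n + q means the model is locally
observable and structurally identifiable with the chosen outputs.

Derivative orders are added one at a time until one of three stopping
conditions holds: the matrix reaches full rank; the rank stalls between two
consecutive orders (it can then never grow again); or the maximum useful
order N - 1 is reached.

Assessments evaluate OI(x~) at points through sensitivity-jet propagation
(:mod:`._jets`) — the matrix at a point drops out of truncated Taylor
series of the state and its sensitivity, with no high-order symbolic
differentiation.  Two rank modes share that engine.  *Symbolic* mode is
exact rational arithmetic: jets carry Fraction coefficients, the points
are deterministic random rationals from a ~10^6-element value set in
[1/2, 3/2], and the rank over Q is exact, maximized over three
independent points.  By the Schwartz-Zippel lemma a random specialization
underestimates the generic rank only on a measure-zero variety, so this
is the generic rank for all practical purposes, with no floating-point
tolerance anywhere.  *Numeric* mode follows the randomized floating-point
protocol instead: uniformly distributed draws from [0.5, 1.5], SVD rank
with a relative threshold, maximum over the draws (default 10) reported;
degenerate draws are resampled.

The classical symbolic route — :func:`lie_stack` building the Lie
derivatives, :func:`build_oi` assembling the stacked Jacobian, and
:func:`generic_rank` evaluating that matrix directly — is kept alongside
and serves as an independent cross-check of the jet engine.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np
import sympy as sp

from ._jets import SensitivityJets
from .motifs import DegeneratePointError, symbol
from .outputs import OutputModel

__all__ = [
    "LieStack",
    "OIMatrix",
    "RankResult",
    "ElementDiagnosis",
    "DEFAULT_DRAWS",
    "DEFAULT_SYMBOLIC_CEILING",
    "lie_stack",
    "build_oi",
    "generic_rank",
    "assess",
    "element_identifiability",
    "check_symmetry",
]

#: number of random draws used for a numeric generic rank
DEFAULT_DRAWS = 10
#: models up to this many states+parameters default to symbolic rank
DEFAULT_SYMBOLIC_CEILING = 8
_NUMERIC_TOL_FACTOR = 1e-10
_MAX_RESAMPLE = 50


# ---------------------------------------------------------------------------
# Lie derivatives and the OI matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LieStack:
    """Output derivative expressions by order; ``orders[0]`` is g itself."""

    om: OutputModel
    orders: tuple  # tuple of sympy Matrix (m x 1), one per derivative order

    @property
    def k(self) -> int:
        return len(self.orders) - 1


def _lie_step(expr_vec: sp.Matrix, states, dynamics) -> sp.Matrix:
    """Directional derivative of each entry along the dynamics.

    Parameters are constant states, so only true states contribute.  No
    simplification is applied inside the recursion: normalizing the
    growing rational expressions costs far more than evaluating the raw
    derivative trees ever does, and ranks are taken at evaluation points
    anyway.
    """
    return sp.Matrix([
        sum(sp.diff(e, x) * fx for x, fx in zip(states, dynamics))
        for e in expr_vec
    ])


def lie_stack(om: OutputModel, k: int) -> LieStack:
    """Successive Lie derivatives of the outputs up to order ``k``."""
    if k < 0:
        raise ValueError("derivative order must be non-negative")
    states = om.model.states
    dynamics = om.model.dynamics
    orders = [sp.Matrix([sp.cancel(g) for g in om.outputs])]
    for _ in range(k):
        orders.append(_lie_step(orders[-1], states, dynamics))
    return LieStack(om=om, orders=tuple(orders))


def _extend(stack: LieStack, k: int) -> LieStack:
    orders = list(stack.orders)
    states = stack.om.model.states
    dynamics = stack.om.model.dynamics
    while len(orders) - 1 < k:
        orders.append(_lie_step(orders[-1], states, dynamics))
    return LieStack(om=stack.om, orders=tuple(orders))


@dataclass(frozen=True)
class OIMatrix:
    """The stacked Lie-derivative Jacobian with respect to x~.

    Row blocks are ordered by derivative order; columns follow the
    augmented-state ordering of the model.
    """

    om: OutputModel
    k: int
    entries: sp.Matrix  # m*(k+1) rows x N columns

    @property
    def shape(self) -> tuple:
        return self.entries.shape


def build_oi(om: OutputModel, k: int, stack: Optional[LieStack] = None) -> OIMatrix:
    """OI(x~) built from derivative orders 0..k."""
    stack = lie_stack(om, k) if stack is None else _extend(stack, k)
    xt = sp.Matrix(om.xtilde)
    blocks = [order.jacobian(xt) for order in stack.orders[: k + 1]]
    return OIMatrix(om=om, k=k, entries=sp.Matrix.vstack(*blocks))


# ---------------------------------------------------------------------------
# generic rank
# ---------------------------------------------------------------------------


def _symzero(e) -> bool:
    e = sp.cancel(e)
    if e == 0:
        return True
    if e.is_number:
        return False
    return sp.simplify(e) == 0


#: points used by the exact-arithmetic generic rank; three independent
#: specializations from a ~10^6-element rational value set make an
#: underestimated rank astronomically unlikely (Schwartz-Zippel)
EXACT_POINTS = 3
_EXACT_DENOM = 10**6
_EXACT_SEED = 0x5EED


def _cse_specialize(M: sp.Matrix, subs_list) -> list:
    """Evaluate a matrix at several points via its shared-subexpression DAG.

    Walking the expression tree once per point duplicates shared subtrees;
    evaluating the CSE graph instead is linear in the DAG size, which is
    what keeps high-order Lie-derivative blocks cheap to specialize.
    """
    reps, (red,) = sp.cse(M)
    out = []
    for subs in subs_list:
        env = dict(subs)
        for s, e in reps:
            env[s] = e.xreplace(env)
        out.append(red.xreplace(env))
    return out


class _ExactEvaluator:
    """Specialize matrices at fixed random rational points in [1/2, 3/2]."""

    def __init__(self, symbols, points: int = EXACT_POINTS, seed: int = _EXACT_SEED):
        rng = random.Random(seed)
        self.symbols = tuple(symbols)
        self.subs = [
            {s: sp.Rational(rng.randint(_EXACT_DENOM // 2, 3 * _EXACT_DENOM // 2),
                            _EXACT_DENOM)
             for s in self.symbols}
            for _ in range(points)
        ]

    def matrices(self, M: sp.Matrix) -> list:
        return _cse_specialize(M, self.subs)


def _exact_points(symbols, points: int = EXACT_POINTS, seed: int = _EXACT_SEED) -> list:
    rng = random.Random(seed)
    return [
        {s: Fraction(rng.randint(_EXACT_DENOM // 2, 3 * _EXACT_DENOM // 2),
                     _EXACT_DENOM)
         for s in symbols}
        for _ in range(points)
    ]


def _float_points(symbols, draws, low, high, seed) -> list:
    rng = np.random.default_rng(seed)
    return ([{s: float(v) for s, v in zip(symbols, rng.uniform(low, high, len(symbols)))}
             for _ in range(draws)], rng)


def _fraction_rank(rows) -> int:
    """Gaussian elimination over exact fractions."""
    mat = [list(r) for r in rows]
    if not mat:
        return 0
    ncols = len(mat[0])
    pivot = 0
    for c in range(ncols):
        pr = next((r for r in range(pivot, len(mat)) if mat[r][c] != 0), None)
        if pr is None:
            continue
        mat[pivot], mat[pr] = mat[pr], mat[pivot]
        pv = mat[pivot][c]
        for r in range(pivot + 1, len(mat)):
            if mat[r][c] != 0:
                factor = mat[r][c] / pv
                row = mat[r]
                prow = mat[pivot]
                mat[r] = [a - factor * b for a, b in zip(row, prow)]
        pivot += 1
        if pivot == len(mat):
            break
    return pivot


class _JetRankEngine:
    """Per-point OI row accumulation with either exact or float jets."""

    def __init__(self, om, mode, draws, low, high, seed):
        self.om = om
        self.mode = mode
        self.sens = SensitivityJets(om)
        if mode == "symbolic":
            self.points = _exact_points(om.xtilde)
            self.rng = None
        else:
            self.points, self.rng = _float_points(om.xtilde, draws, low, high, seed)
        self.low, self.high = low, high
        self.states = []
        for pt in self.points:
            self.states.append(self.sens.start(pt))
        self.rows = [[] for _ in self.points]
        self.k = -1

    def _resample(self, i) -> None:
        tries = 0
        while True:
            tries += 1
            if tries > _MAX_RESAMPLE:
                raise DegeneratePointError(
                    "persistent singular evaluation points for generic rank")
            if self.mode == "symbolic":
                pt = _exact_points(self.om.xtilde, points=1,
                                   seed=_EXACT_SEED + 17 * tries + i)[0]
            else:
                vals = self.rng.uniform(self.low, self.high, len(self.om.xtilde))
                pt = {s: float(v) for s, v in zip(self.om.xtilde, vals)}
            try:
                st = self.sens.start(pt)
                rows = []
                for k in range(self.k + 1):
                    rows.extend(self.sens.block(st, k))
                self.points[i], self.states[i], self.rows[i] = pt, st, rows
                return
            except ZeroDivisionError:
                continue

    def add_order(self, k: int) -> list:
        """Extend every point to derivative order ``k``; per-point ranks."""
        self.k = k
        for i in range(len(self.points)):
            try:
                self.rows[i].extend(self.sens.block(self.states[i], k))
            except ZeroDivisionError:
                self._resample(i)
        return self.ranks()

    def ranks(self) -> list:
        out = []
        for i, rows in enumerate(self.rows):
            if self.mode == "symbolic":
                out.append(_fraction_rank(rows))
            else:
                arr = np.asarray(rows, dtype=float)
                if not np.all(np.isfinite(arr)):
                    self._resample(i)
                    arr = np.asarray(self.rows[i], dtype=float)
                out.append(_float_rank(arr))
        return out

    def column_ranks(self) -> tuple:
        """Base generic rank and the generic rank with each column removed."""
        base = max(self.ranks())
        deleted = []
        ncols = self.om.N
        for c in range(ncols):
            best = 0
            for rows in self.rows:
                sub = [[v for j, v in enumerate(row) if j != c] for row in rows]
                if self.mode == "symbolic":
                    best = max(best, _fraction_rank(sub))
                else:
                    best = max(best, _float_rank(np.asarray(sub, dtype=float)))
            deleted.append(best)
        return base, deleted


def _exact_rank(Mq: sp.Matrix) -> int:
    return Mq.rank()


def symbolic_rank(M: sp.Matrix, symbols=None, points: int = EXACT_POINTS,
                  seed: int = _EXACT_SEED) -> int:
    """Generic rank of a rational-function matrix, in exact arithmetic."""
    if symbols is None:
        symbols = sorted(M.free_symbols, key=lambda s: s.name)
    if not symbols:
        return M.rank()
    ev = _ExactEvaluator(symbols, points=points, seed=seed)
    return max(_exact_rank(Mq) for Mq in ev.matrices(M))


def _numeric_points(symbols, draws, low, high, seed) -> list:
    rng = np.random.default_rng(seed)
    return [dict(zip(symbols, rng.uniform(low, high, size=len(symbols))))
            for _ in range(draws)]


def _float_rank(arr: np.ndarray) -> int:
    if arr.size == 0:
        return 0
    s = np.linalg.svd(arr, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    tol = s[0] * max(arr.shape) * _NUMERIC_TOL_FACTOR
    return int(np.sum(s > tol))


def generic_rank(
    M: Union[OIMatrix, sp.Matrix],
    mode: str = "symbolic",
    draws: int = DEFAULT_DRAWS,
    low: float = 0.5,
    high: float = 1.5,
    seed: Optional[int] = None,
    symbols: Optional[Sequence] = None,
) -> int:
    """Generic rank of an OI matrix.

    Symbolic mode is exact; numeric mode substitutes random values from
    U(low, high) for every symbol and returns the maximum floating-point
    rank over ``draws`` independent draws.
    """
    entries = M.entries if isinstance(M, OIMatrix) else M
    if mode == "symbolic":
        syms = (M.om.xtilde if isinstance(M, OIMatrix) else symbols)
        return symbolic_rank(entries, symbols=syms)
    if mode != "numeric":
        raise ValueError(f"unknown rank mode {mode!r}")
    if symbols is None:
        if isinstance(M, OIMatrix):
            symbols = M.om.xtilde
        else:
            symbols = sorted(entries.free_symbols, key=lambda s: s.name)
    points = _numeric_points(tuple(symbols), draws, low, high, seed)
    subs_list = [{s: sp.Float(v) for s, v in pt.items()} for pt in points]
    best = 0
    for Mf in _cse_specialize(entries, subs_list):
        try:
            arr = np.asarray(Mf, dtype=float)
        except (ZeroDivisionError, TypeError):
            continue
        if not np.all(np.isfinite(arr)):
            continue
        best = max(best, _float_rank(arr))
    return best


# ---------------------------------------------------------------------------
# assessment with the stopping rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankResult:
    """Outcome of a structural identifiability assessment."""

    rank: int
    N: int
    n: int
    q: int
    identifiable: bool
    k_used: int
    stop_condition: str      # full_rank | rank_plateau | max_order
    mode: str                # symbolic | numeric
    seed: Optional[int] = None
    draws: Optional[int] = None
    draw_ranks: tuple = ()   # per-draw ranks at the stopping order (numeric)
    rank_by_order: tuple = ()

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "N": self.N,
            "n": self.n,
            "q": self.q,
            "identifiable": self.identifiable,
            "k_used": self.k_used,
            "stop_condition": self.stop_condition,
            "mode": self.mode,
            "seed": self.seed,
            "draws": self.draws,
            "draw_ranks": list(self.draw_ranks),
            "rank_by_order": list(self.rank_by_order),
        }


def _resolve_mode(mode: str, N: int, ceiling: int) -> str:
    if mode == "auto":
        return "symbolic" if N <= ceiling else "numeric"
    if mode not in ("symbolic", "numeric"):
        raise ValueError(f"unknown mode {mode!r}")
    return mode


def assess(
    om: OutputModel,
    mode: str = "auto",
    draws: int = DEFAULT_DRAWS,
    low: float = 0.5,
    high: float = 1.5,
    seed: Optional[int] = None,
    symbolic_ceiling: int = DEFAULT_SYMBOLIC_CEILING,
    max_k: Optional[int] = None,
) -> RankResult:
    """Assess structural identifiability of an output model.

    Derivative orders are added one at a time, re-evaluating the generic
    rank after each, and iteration stops at the first satisfied stopping
    condition.  The model is identifiable (and observable) iff the final
    rank equals N = n + q.
    """
    N = om.N
    mode = _resolve_mode(mode, N, symbolic_ceiling)
    k_max = N - 1 if max_k is None else max_k

    engine = _JetRankEngine(om, mode, draws, low, high, seed)
    ranks = []
    draw_ranks: tuple = ()
    k = 0
    while True:
        per_rank = engine.add_order(k)
        r = max(per_rank)
        if mode == "numeric":
            draw_ranks = tuple(per_rank)
        ranks.append(r)
        if r == N:
            stop = "full_rank"
            break
        if k > 0 and r == ranks[-2]:
            stop = "rank_plateau"
            break
        if k >= k_max:
            stop = "max_order"
            break
        k += 1

    return RankResult(
        rank=ranks[-1],
        N=N,
        n=om.model.n,
        q=om.model.q,
        identifiable=ranks[-1] == N,
        k_used=k,
        stop_condition=stop,
        mode=mode,
        seed=seed if mode == "numeric" else None,
        draws=draws if mode == "numeric" else None,
        draw_ranks=draw_ranks,
        rank_by_order=tuple(ranks),
    )


# ---------------------------------------------------------------------------
# per-element diagnosis and symmetry verification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementDiagnosis:
    """Identifiable/observable verdict per element of x~.

    An element is identifiable (parameter) or observable (state) iff
    deleting its column drops the generic rank of the OI matrix by one; a
    rank-neutral column means no output derivative pins that element.
    """

    result: RankResult
    identifiable_params: tuple
    unidentifiable_params: tuple
    observable_states: tuple
    unobservable_states: tuple

    def to_dict(self) -> dict:
        return {
            "rank": self.result.rank,
            "N": self.result.N,
            "identifiable_params": [s.name for s in self.identifiable_params],
            "unidentifiable_params": [s.name for s in self.unidentifiable_params],
            "observable_states": [s.name for s in self.observable_states],
            "unobservable_states": [s.name for s in self.unobservable_states],
        }


def element_identifiability(
    om: OutputModel,
    mode: str = "auto",
    draws: int = DEFAULT_DRAWS,
    low: float = 0.5,
    high: float = 1.5,
    seed: Optional[int] = None,
    symbolic_ceiling: int = DEFAULT_SYMBOLIC_CEILING,
) -> ElementDiagnosis:
    """Column-deletion diagnosis of which states/parameters are pinned."""
    res = assess(om, mode=mode, draws=draws, low=low, high=high, seed=seed,
                 symbolic_ceiling=symbolic_ceiling)
    mode = res.mode
    engine = _JetRankEngine(om, mode, draws, low, high, seed)
    for k in range(res.k_used + 1):
        engine.add_order(k)
    base_rank, deleted = engine.column_ranks()

    states = set(om.model.states)
    flagged = [r == base_rank - 1 for r in deleted]

    ident_p, unident_p, obs_s, unobs_s = [], [], [], []
    for el, ok in zip(om.xtilde, flagged):
        if el in states:
            (obs_s if ok else unobs_s).append(el)
        else:
            (ident_p if ok else unident_p).append(el)
    return ElementDiagnosis(
        result=res,
        identifiable_params=tuple(ident_p),
        unidentifiable_params=tuple(unident_p),
        observable_states=tuple(obs_s),
        unobservable_states=tuple(unobs_s),
    )


def _canonical_expr(e) -> sp.Expr:
    e = sp.sympify(e)
    return e.xreplace({s: symbol(s.name) for s in e.free_symbols})


def _generator_vector(om: OutputModel, v) -> sp.Matrix:
    if isinstance(v, dict):
        comp = {symbol(k) if isinstance(k, str) else k: _canonical_expr(e)
                for k, e in v.items()}
        unknown = set(comp) - set(om.xtilde)
        if unknown:
            raise ValueError(f"generator components for unknown elements: {unknown}")
        return sp.Matrix([comp.get(el, 0) for el in om.xtilde])
    v = list(v)
    if len(v) != om.N:
        raise ValueError(f"generator has {len(v)} components, expected N={om.N}")
    return sp.Matrix([_canonical_expr(e) for e in v])


def check_symmetry(
    om: OutputModel,
    v,
    mode: str = "auto",
    draws: int = DEFAULT_DRAWS,
    low: float = 0.5,
    high: float = 1.5,
    seed: Optional[int] = None,
    symbolic_ceiling: int = DEFAULT_SYMBOLIC_CEILING,
    tol: float = 1e-8,
) -> bool:
    """Verify an infinitesimal symmetry generator.

    ``v`` assigns one component expression per element of x~ (a dict of
    name -> expression, missing entries zero, or a full vector).  The
    generator is a symmetry iff OI(x~)·v = 0 with the matrix built to the
    stopping order — the one-parameter transformation it generates then
    leaves every output derivative invariant, certifying unidentifiability.
    """
    vec = _generator_vector(om, v)
    if all(sp.cancel(c) == 0 for c in vec):
        raise ValueError("symmetry generator must not be identically zero")
    res = assess(om, mode=mode, draws=draws, low=low, high=high, seed=seed,
                 symbolic_ceiling=symbolic_ceiling)
    if res.mode == "symbolic":
        oi = build_oi(om, res.k_used)
        return all(_symzero(e) for e in oi.entries * vec)
    engine = _JetRankEngine(om, "numeric", draws, low, high, seed)
    for k in range(res.k_used + 1):
        engine.add_order(k)
    vfns = [sp.lambdify(om.xtilde, comp, modules="math") for comp in vec]
    for pt, rows in zip(engine.points, engine.rows):
        args = [pt[s] for s in om.xtilde]
        vv = np.asarray([fn(*args) for fn in vfns], dtype=float)
        arr = np.asarray(rows, dtype=float)
        wv = arr @ vv
        scale = max(1.0, float(np.abs(arr).max()))
        if not np.all(np.isfinite(wv)) or np.abs(wv).max() > tol * scale:
            return False
    return True
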