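"""Truncated Taylor-series (jet) propagation of output sensitivities.

The k-th row block of the observability-identifiability matrix is the
Jacobian of the k-th Lie derivative of the outputs with respect to the
augmented state x~ = (x0, p).  Writing y(t) for the output along the
solution started at x0, that Jacobian equals

    d(y^(k)(0))/dx~  =  k! * [t^k] d(y(t))/dx~,

the k-th Taylor coefficient of the output sensitivity.  The sensitivity
S(t) = dx(t)/dx~ obeys the variational equation

    S' = (df/dx) S + [0 | df/dp],      S(0) = [I | 0],

so the whole OI matrix can be evaluated at a point by propagating truncated
power series of x(t) and S(t) through the model's *first-order* Jacobians
— no high-order symbolic differentiation, and therefore none of the
expression swell a symbolic Lie recursion suffers.  With exact
(rational) coefficients the resulting matrix is exactly OI(x~) at the
point; with floats it matches to roundoff.
"""

from __future__ import annotations

from fractions import Fraction

import sympy as sp

__all__ = ["Jet", "SensitivityJets"]


class Jet:
    """A truncated power series; coefficient arithmetic only.

    Coefficients may be floats or :class:`fractions.Fraction` (exact).
    Arithmetic mixes transparently with plain scalars.  The truncation
    order is implicit: operations keep ``min`` of the operand lengths for
    sums and the full convolution for products, which is always enough
    coefficients for the propagation loop below.
    """

    __slots__ = ("c",)

    def __init__(self, coeffs):
        self.c = list(coeffs)

    # -- helpers --------------------------------------------------------

    @staticmethod
    def _coeffs(obj, length):
        if isinstance(obj, Jet):
            return obj.c[:length] + [0] * max(0, length - len(obj.c))
        return [obj] + [0] * (length - 1)

    def coeff(self, k):
        return self.c[k] if k < len(self.c) else 0

    # -- ring operations ------------------------------------------------

    def __add__(self, other):
        n = max(len(self.c), len(other.c) if isinstance(other, Jet) else 1)
        a = Jet._coeffs(self, n)
        b = Jet._coeffs(other, n)
        return Jet([x + y for x, y in zip(a, b)])

    __radd__ = __add__

    def __neg__(self):
        return Jet([-x for x in self.c])

    def __sub__(self, other):
        return self + (-other)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if not isinstance(other, Jet):
            return Jet([x * other for x in self.c])
        n = len(self.c) + len(other.c) - 1
        out = [0] * n
        for i, x in enumerate(self.c):
            if x == 0:
                continue
            for j, y in enumerate(other.c):
                if y != 0:
                    out[i + j] += x * y
        return Jet(out)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if not isinstance(other, Jet):
            if isinstance(other, float):
                return Jet([x / other for x in self.c])
            return Jet([_div(x, 1) / other if not isinstance(x, float) else x / other
                        for x in self.c])
        return self * other._reciprocal(max(len(self.c), len(other.c)))

    def __rtruediv__(self, other):
        return other * self._reciprocal(len(self.c))

    def _reciprocal(self, n):
        b0 = self.c[0]
        if b0 == 0:
            raise ZeroDivisionError("series with zero constant term")
        b = Jet._coeffs(self, n)
        inv = [1 / b0 if isinstance(b0, float) else Fraction(1, 1) / b0]
        for k in range(1, n):
            acc = 0
            for j in range(1, k + 1):
                acc += b[j] * inv[k - j]
            inv.append(-acc / b0)
        return Jet(inv)

    def __pow__(self, exponent):
        if not isinstance(exponent, int):
            if isinstance(exponent, float) and exponent.is_integer():
                exponent = int(exponent)
            else:
                raise TypeError(f"jet power must be an integer, got {exponent!r}")
        if exponent < 0:
            return (self._reciprocal(len(self.c))) ** (-exponent)
        result = Jet([1])
        base = self
        e = exponent
        while e:
            if e & 1:
                result = result * base
            base = base * base
            e >>= 1
        return result


def _coeff_of(obj, k):
    return obj.coeff(k) if isinstance(obj, Jet) else (obj if k == 0 else 0)


def _div(v, m):
    """Divide a coefficient by an integer without losing exactness: ints
    and Fractions stay rational, floats stay floats."""
    if isinstance(v, float):
        return v / m
    return Fraction(v) / m


def _lambdify_entries(args, exprs):
    """One scalar function per expression; plain-operator code so that the
    arguments may be :class:`Jet` instances."""
    fns = [sp.lambdify(args, e, modules="math") for e in exprs]
    return fns


class SensitivityJets:
    """Propagate x(t) and S(t) = dx/dx~ jets for one output model at points."""

    def __init__(self, om):
        model = om.model
        self.states = model.states
        self.params = model.params
        self.n = len(self.states)
        self.q = len(self.params)
        self.N = self.n + self.q
        self.m = len(om.outputs)
        self.xtilde = om.xtilde
        # positions of states/params inside x~ (flow states sit in the slot
        # of their eliminated rate constant)
        self.state_cols = [om.xtilde.index(s) for s in self.states]
        self.param_cols = [om.xtilde.index(p) for p in self.params]

        args = list(self.states) + list(self.params)
        f = list(model.dynamics)
        g = list(om.outputs)
        sx = sp.Matrix(self.states)
        pv = sp.Matrix(self.params) if self.params else None
        fM, gM = sp.Matrix(f), sp.Matrix(g)
        self._f = _lambdify_entries(args, f)
        self._Jx = _lambdify_entries(args, list(fM.jacobian(sx)))
        self._Jp = _lambdify_entries(args, list(fM.jacobian(pv))) if self.q else []
        self._g = _lambdify_entries(args, g)
        self._gx = _lambdify_entries(args, list(gM.jacobian(sx)))
        self._gp = _lambdify_entries(args, list(gM.jacobian(pv))) if self.q else []

    # -- per-point propagation -----------------------------------------

    def start(self, point):
        """Initial jet state at a point (mapping symbol -> value)."""
        xvals = [point[s] for s in self.states]
        pvals = [point[p] for p in self.params]
        x = [Jet([v]) for v in xvals]
        one = 1 if not isinstance(xvals[0], float) else 1.0
        S = [[Jet([one if self.state_cols[i] == j else 0]) for j in range(self.N)]
             for i in range(self.n)]
        return {"x": x, "S": S, "p": pvals, "order": 0}

    def _eval(self, fns, state):
        args = state["x"] + state["p"]
        return [fn(*args) for fn in fns]

    def extend(self, state, order):
        """Grow the jets so coefficients through ``order`` are valid."""
        n, N, q = self.n, self.N, self.q
        while state["order"] < order:
            m = state["order"] + 1
            fx = self._eval(self._f, state)
            Jx = self._eval(self._Jx, state)
            Jp = self._eval(self._Jp, state) if q else []
            newx = [_coeff_of(fx[i], m - 1) for i in range(n)]
            newS = [[0] * N for _ in range(n)]
            for i in range(n):
                for j in range(N):
                    acc = 0
                    for l in range(n):
                        a = Jx[i * n + l]
                        b = state["S"][l][j]
                        # coefficient m-1 of a*b
                        for t in range(m):
                            ca = _coeff_of(a, t)
                            if ca != 0:
                                cb = b.coeff(m - 1 - t)
                                if cb != 0:
                                    acc += ca * cb
                    newS[i][j] = acc
                if q:
                    for jj, col in enumerate(self.param_cols):
                        newS[i][col] += _coeff_of(Jp[i * q + jj], m - 1)
            for i in range(n):
                state["x"][i].c.append(_div(newx[i], m))
                for j in range(N):
                    state["S"][i][j].c.append(_div(newS[i][j], m))
            state["order"] = m

    def block(self, state, k):
        """OI row block of derivative order ``k`` at this point:
        k! * [t^k] (dg/dx * S + [0 | dg/dp])."""
        self.extend(state, k)
        n, N, q = self.n, self.N, self.q
        gx = self._eval(self._gx, state)
        gp = self._eval(self._gp, state) if q else []
        fact = 1
        for i in range(2, k + 1):
            fact *= i
        rows = []
        for out in range(self.m):
            row = [0] * N
            for j in range(N):
                acc = 0
                for l in range(n):
                    a = gx[out * n + l]
                    b = state["S"][l][j]
                    for t in range(k + 1):
                        ca = _coeff_of(a, t)
                        if ca != 0:
                            cb = b.coeff(k - t)
                            if cb != 0:
                                acc += ca * cb
                row[j] = acc * fact
            if q:
                for jj, col in enumerate(self.param_cols):
                    row[col] += _coeff_of(gp[out * q + jj], k) * fact
            rows.append(row)
        return rows
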