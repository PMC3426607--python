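"""Minimal forward-mode Taylor arithmetic to second order in a few variables.

A jet is a dict mapping multi-indices (tuples of per-variable powers, total
degree <= 2) to coefficients (scalars or numpy arrays).  This is enough to
propagate exact first and second derivatives of the discrete-state evolution
operator -- and of everything computed from it (equilibrium distribution,
firing rate, ISI variance) -- with respect to coupling strengths, the
vesicle parameter and the input probability, without finite differencing.

Coefficient convention: jet[alpha] is the raw Taylor coefficient, i.e. the
partial derivative divided by alpha! (so d2f/dx2 = 2 * jet[(2, 0, ...)]).
"""

from __future__ import annotations

import numpy as np

ORDER = 2


def _keys(nvars: int):
    out = []
    def rec(prefix, remaining, budget):
        if remaining == 0:
            out.append(tuple(prefix))
            return
        for k in range(budget + 1):
            rec(prefix + [k], remaining - 1, budget - k)
    rec([], nvars, ORDER)
    return out


def const(value, nvars: int) -> dict:
    return {tuple([0] * nvars): value}


def variable(value, index: int, nvars: int) -> dict:
    key = [0] * nvars
    key[index] = 1
    return {tuple([0] * nvars): value, tuple(key): 1.0}


def add(a: dict, b: dict) -> dict:
    out = dict(a)
    for k, v in b.items():
        out[k] = out[k] + v if k in out else v
    return out


def scale(a: dict, c) -> dict:
    return {k: c * v for k, v in a.items()}


def _combine(a: dict, b: dict, prod) -> dict:
    out: dict = {}
    for ka, va in a.items():
        for kb, vb in b.items():
            k = tuple(x + y for x, y in zip(ka, kb))
            if sum(k) > ORDER:
                continue
            term = prod(va, vb)
            out[k] = out[k] + term if k in out else term
    return out


def mul(a: dict, b: dict) -> dict:
    """Elementwise/scalar product of two jets."""
    return _combine(a, b, lambda x, y: x * y)


def matmul(a: dict, b: dict) -> dict:
    """Matrix product of two jets with array coefficients."""
    return _combine(a, b, lambda x, y: x @ y)


def exp(a: dict) -> dict:
    """exp of a scalar jet: exp(a0) * (1 + u + u^2/2), u = a - a0."""
    nvars = len(next(iter(a.keys())))
    zero = tuple([0] * nvars)
    a0 = a.get(zero, 0.0)
    u = {k: v for k, v in a.items() if k != zero}
    out = const(1.0, nvars)
    out = add(out, u)
    out = add(out, scale(mul(u, u), 0.5))
    return scale(out, float(np.exp(a0)))


def inv(a: dict) -> dict:
    """1/a for a scalar jet with nonzero value part."""
    nvars = len(next(iter(a.keys())))
    zero = tuple([0] * nvars)
    a0 = a[zero]
    if a0 == 0:
        raise ZeroDivisionError("jet has zero value part")
    u = scale({k: v for k, v in a.items() if k != zero}, 1.0 / a0)
    out = const(1.0, nvars)
    out = add(out, scale(u, -1.0))
    out = add(out, mul(u, u))
    return scale(out, 1.0 / a0)


def value(a: dict):
    zero = tuple([0] * len(next(iter(a.keys()))))
    return a.get(zero, 0.0)


def deriv(a: dict, index: int):
    """First partial derivative with respect to one variable."""
    nvars = len(next(iter(a.keys())))
    key = tuple(1 if i == index else 0 for i in range(nvars))
    return a.get(key, 0.0)


def deriv2(a: dict, i: int, j: int):
    """Second partial derivative d2a/dxi dxj (with the factorial restored)."""
    nvars = len(next(iter(a.keys())))
    key = [0] * nvars
    key[i] += 1
    key[j] += 1
    coeff = a.get(tuple(key), 0.0)
    return 2.0 * coeff if i == j else coeff
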