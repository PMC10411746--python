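"""Independent oracles used by the tests (never by the package itself)."""

from __future__ import annotations

import numpy as np
import sympy as sp


def taylor_coefficients_sympy(initial, params, order: int) -> np.ndarray:
    """Taylor coefficients of the exact solution at t=0, via symbolic
    differentiation of the vector field (exact rational arithmetic).

    Returns shape (3, order+1); row i, column k is (1/k!) d^k u_i/dt^k at 0.
    Independent of the package's convolution recurrences: derivatives are
    obtained by repeatedly differentiating the right-hand side with sympy
    and substituting lower-order derivatives.
    """
    t = sp.Symbol("t")
    x, y, z = (sp.Function(n)(t) for n in "xyz")
    b = [sp.nsimplify(v, rational=True) for v in params.as_array()]
    fx = b[0]*x - b[1]*x - b[2]*x**2 - b[3]*x*y - b[4]*x*y**2 \
        - b[5]*x*z**2 - b[6]*x*z
    fy = b[7]*y + b[3]*x*y - b[8]*y - b[9]*y**2 + b[4]*x*y**2
    fz = b[10]*z + b[6]*x*z - b[11]*z - b[12]*z**2 + b[5]*x*z**2
    first = {sp.Derivative(x, t): fx, sp.Derivative(y, t): fy,
             sp.Derivative(z, t): fz}
    point = {x: sp.nsimplify(initial[0], rational=True),
             y: sp.nsimplify(initial[1], rational=True),
             z: sp.nsimplify(initial[2], rational=True)}
    coeffs = np.zeros((3, order + 1))
    derivs = [x, y, z]
    for k in range(order + 1):
        for i in range(3):
            coeffs[i, k] = float(derivs[i].subs(point)) / sp.factorial(k)
        derivs = [sp.expand(d.diff(t).subs(first)) for d in derivs]
    return coeffs
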