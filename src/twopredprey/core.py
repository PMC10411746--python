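"""Two-predator-one-prey dynamics during the predator mating period.

The model couples one prey density ``X`` with two predator densities ``Y``
and ``Z`` through logistic self-limitation, bilinear predation (``XY``,
``XZ``) and cubic mating-period predation terms (``XY^2``, ``XZ^2``) that
arise when a male-female predator pair feeds jointly on one prey::

    X' = b1*X - b2*X - b3*X^2 - b4*X*Y - b5*X*Y^2 - b6*X*Z^2 - b7*X*Z
    Y' = b8*Y + b4*X*Y - b9*Y - b10*Y^2 + b5*X*Y^2
    Z' = b11*Z + b7*X*Z - b12*Z - b13*Z^2 + b6*X*Z^2

All thirteen rates are nonnegative.  The module is laid out in the order the
method runs:

1.  model definition  — parameters, state validation, right-hand side,
    positivity/boundedness certificate, parameter sampler;
2.  equilibria and stability — axial equilibria, Jacobian, numerical local
    stability, closed-form local-stability conditions, Volterra-type Lyapunov
    function and its closed-form time derivative, global-stability premises;
3.  multistage differential transform solver (MsDTM) — Cauchy-product
    recurrences for the Taylor coefficients on each subdomain and the
    subdomain-stepping driver;
4.  reference Runge-Kutta oracle and trajectory comparison;
5.  run configuration, orchestration, and serialization used by the CLI.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "PRESETS",
    "BoundednessCertificate",
    "validate_state",
    "rhs",
    "boundedness_certificate",
    "sample_parameters",
    "EquilibriumPoint",
    "StabilityReport",
    "LyapunovEvaluation",
    "find_equilibria",
    "jacobian",
    "local_stability",
    "local_stability_conditions",
    "lyapunov",
    "lyapunov_derivative",
    "lyapunov_derivative_numeric",
    "evaluate_lyapunov",
    "global_stability_conditions",
    "TaylorSegment",
    "Trajectory",
    "cauchy_product",
    "nested_product",
    "dtm_coefficients",
    "msdtm_solve",
    "rk4_solve",
    "rk4_ensemble",
    "trajectory_distance",
    "RunConfig",
    "run_simulation",
    "stability_report",
]

logger = logging.getLogger("twopredprey")

# Round-off tolerance: solver outputs may dip this far below zero and are
# clamped to 0 for reporting, never for internal arithmetic.
NEGATIVE_CLAMP = 1e-9
# Eigenvalue real-part threshold below which stability is "inconclusive".
STABILITY_TOL = 1e-9
# Sampler margin enforcing strict versions of the non-strict condition sets.
SAMPLER_MARGIN = 1e-3
# Floor on self-limitation rates where a constraint set needs them nonzero,
# keeping sampled systems well conditioned (bounds and eigenvalues O(1)).
SAMPLER_SELF_LIMIT_FLOOR = 0.02


# ---------------------------------------------------------------------------
# 1. Model definition
# ---------------------------------------------------------------------------

_BETA_NAMES = tuple(f"beta{i}" for i in range(1, 14))


@dataclass(frozen=True)
class ModelParameters:
    """The thirteen nonnegative rate constants of the model.

    Growth: ``beta1`` (prey), ``beta8`` (predator I), ``beta11`` (predator II).
    Natural death: ``beta2``, ``beta9``, ``beta12``.
    Intraspecific competition: ``beta3``, ``beta10``, ``beta13``.
    One-predator-one-prey predation: ``beta4`` (I), ``beta7`` (II).
    Mating-period (pair) predation: ``beta5`` (I), ``beta6`` (II).
    """

    beta1: float
    beta2: float
    beta3: float
    beta4: float
    beta5: float
    beta6: float
    beta7: float
    beta8: float
    beta9: float
    beta10: float
    beta11: float
    beta12: float
    beta13: float

    def __post_init__(self) -> None:
        for name in _BETA_NAMES:
            value = float(getattr(self, name))
            if not math.isfinite(value) or value < 0.0:
                raise ValueError(
                    f"{name} must be a finite nonnegative rate, got {value!r}"
                )
            object.__setattr__(self, name, value)

    def as_array(self) -> np.ndarray:
        """Return the rates as a length-13 float array (beta1 ... beta13)."""
        return np.array([getattr(self, n) for n in _BETA_NAMES], dtype=float)

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in _BETA_NAMES}

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ModelParameters":
        values = list(values)
        if len(values) != 13:
            raise ValueError(f"expected 13 rates, got {len(values)}")
        return cls(*map(float, values))

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParameters":
        return cls(**{n: float(mapping[n]) for n in _BETA_NAMES})

    @classmethod
    def from_preset(cls, name: str) -> "ModelParameters":
        try:
            return PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; valid presets: {sorted(PRESETS)}"
            ) from None


#: The four built-in parameter cases.  Cases "case1" and "case3" are
#: intentionally identical; the duplication is preserved as given rather
#: than "corrected".
PRESETS: dict[str, ModelParameters] = {
    "case1": ModelParameters(0.5, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1,
                             0.3, 0.2, 0.1, 0.3, 0.2, 0.1),
    "case2": ModelParameters(0.8, 0.2, 0.1, 0.1, 0.2, 0.2, 0.1,
                             0.3, 0.95, 0.1, 0.1, 0.95, 0.1),
    "case3": ModelParameters(0.5, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1,
                             0.3, 0.2, 0.1, 0.3, 0.2, 0.1),
    "case4": ModelParameters(0.8, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1,
                             0.1, 0.5, 0.1, 0.1, 0.5, 0.1),
}

#: Initial densities used throughout the built-in scenarios.
DEFAULT_INITIAL_STATE = (5.0, 3.0, 2.0)


def validate_state(state) -> np.ndarray:
    """Coerce ``state`` to a nonnegative float array of trailing length 3."""
    arr = np.asarray(state, dtype=float)
    if arr.shape[-1:] != (3,):
        raise ValueError(f"state must have trailing dimension 3, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("state components must be finite")
    if np.any(arr < 0.0):
        raise ValueError(f"state components must be nonnegative, got {arr!r}")
    return arr


def _rhs_arrays(x, y, z, b):
    """Right-hand side on (broadcastable) arrays; b is a length-13 sequence
    indexed so that b[i] is beta_{i+1}.  No validation."""
    xp = b[0] * x - b[1] * x - b[2] * x * x - b[3] * x * y \
        - b[4] * x * y * y - b[5] * x * z * z - b[6] * x * z
    yp = b[7] * y + b[3] * x * y - b[8] * y - b[9] * y * y + b[4] * x * y * y
    zp = b[10] * z + b[6] * x * z - b[11] * z - b[12] * z * z + b[5] * x * z * z
    return xp, yp, zp


def rhs(state, params: ModelParameters, *, validate: bool = True) -> np.ndarray:
    """Evaluate (X', Y', Z') at ``state``.

    ``state`` may be a single triple or an array of shape (..., 3); the
    derivative has the same shape.  Negative components raise ``ValueError``
    unless ``validate=False`` (used internally by the integrators, whose
    intermediate stages may transiently leave the orthant by round-off).
    """
    arr = validate_state(state) if validate else np.asarray(state, dtype=float)
    b = params.as_array()
    xp, yp, zp = _rhs_arrays(arr[..., 0], arr[..., 1], arr[..., 2], b)
    return np.stack(np.broadcast_arrays(xp, yp, zp), axis=-1)


def _rhs_floats(x: float, y: float, z: float, b: tuple) -> tuple:
    """Scalar right-hand side on plain floats (hot path of the integrators)."""
    return (
        b[0] * x - b[1] * x - b[2] * x * x - b[3] * x * y
        - b[4] * x * y * y - b[5] * x * z * z - b[6] * x * z,
        b[7] * y + b[3] * x * y - b[8] * y - b[9] * y * y + b[4] * x * y * y,
        b[10] * z + b[6] * x * z - b[11] * z - b[12] * z * z + b[5] * x * z * z,
    )


@dataclass(frozen=True)
class BoundednessCertificate:
    """Asymptotic-bound certificate for the positive orthant.

    When prey and both predators have growth exceeding natural death and all
    three self-limitation rates are positive, summing the three equations
    gives d(X+Y+Z)/dt <= gamma1*(X+Y+Z) - gamma2*(X^2+Y^2+Z^2) with
    ``gamma1 = max(b1-b2, b8-b9, b11-b12)`` and
    ``gamma2 = min(b3, b10, b13)``, so trajectories asymptotically enter the
    box 0 <= X, Y, Z <= gamma1/gamma2.
    """

    gamma1: float
    gamma2: float
    bound: float  # gamma1/gamma2; NaN when gamma2 == 0
    applicable: bool

    def to_dict(self) -> dict:
        return asdict(self)


def boundedness_certificate(params: ModelParameters) -> BoundednessCertificate:
    """Compute the asymptotic box bound; marked inapplicable when the
    premises (growth > death for each species, positive self-limitation)
    fail.  No division is performed when ``gamma2 == 0``."""
    g1 = max(params.beta1 - params.beta2,
             params.beta8 - params.beta9,
             params.beta11 - params.beta12)
    g2 = min(params.beta3, params.beta10, params.beta13)
    applicable = (
        params.beta1 > params.beta2
        and params.beta8 > params.beta9
        and params.beta11 > params.beta12
        and g2 > 0.0
    )
    bound = g1 / g2 if g2 > 0.0 else math.nan
    return BoundednessCertificate(gamma1=g1, gamma2=g2, bound=bound,
                                  applicable=applicable)


_SAMPLER_CONSTRAINTS = (
    "none",
    "boundedness-premises",
    "local-stability-P2", "local-stability-P3", "local-stability-P4",
    "global-stability-P1", "global-stability-P2", "global-stability-P3", "global-stability-P4",
)


def _satisfies(b: np.ndarray, constraints: str, m: float, floor: float) -> bool:
    """b[i] = beta_{i+1}.  Strict inequalities carry margin ``m``; rates that
    a constraint set needs nonzero must clear ``floor``."""
    b1, b2, b3, b4, b5, b6, b7, b8, b9, b10, b11, b12, b13 = b
    if constraints == "none":
        return True
    if constraints == "boundedness-premises":
        return (b1 - b2 >= m and b8 - b9 >= m and b11 - b12 >= m
                and min(b3, b10, b13) >= floor)
    if constraints == "local-stability-P2":
        if not (b9 - b8 >= m and b11 - b12 >= m and b13 >= floor):
            return False
        d = b11 - b12
        limit = (b6 * d * d + b13 * (b7 * d + b2 * b13)) / (b13 * b13)
        return limit - b1 >= m
    if constraints == "local-stability-P3":
        if not (b8 - b9 >= m and b12 - b11 >= m and b10 >= floor):
            return False
        d = b8 - b9
        limit = (b5 * d * d + b10 * (b4 * d + b2 * b10)) / (b10 * b10)
        return limit - b1 >= m
    if constraints == "local-stability-P4":
        if not (b1 - b2 >= m and b3 >= floor):
            return False
        return (b9 - ((b1 - b2) * b4 / b3 + b8) >= m
                and b12 - ((b1 - b2) * b7 / b3 + b11) >= m)
    if constraints == "global-stability-P1":
        return (b8 - b9 >= m and b11 - b12 >= m
                and b10 >= floor and b13 >= floor and b2 - b1 >= 0.0)
    if constraints == "global-stability-P2":
        return (b11 - b12 >= m and b13 >= floor
                and b2 - b1 >= 0.0 and b9 - b8 >= 0.0)
    if constraints == "global-stability-P3":
        return (b8 - b9 >= m and b10 >= floor
                and b2 - b1 >= 0.0 and b12 - b11 >= 0.0)
    if constraints == "global-stability-P4":
        # interaction rates are forced to zero by construction before this
        return (b1 - b2 >= m and b3 >= floor
                and b9 - b8 >= 0.0 and b12 - b11 >= 0.0)
    raise AssertionError(constraints)


def sample_parameters(seed: int, constraints: str = "none",
                      max_attempts: int = 100_000) -> ModelParameters:
    """Draw a random parameter set satisfying a named premise set.

    Each rate is uniform on [0, 1]; constraint sets are enforced by rejection
    (except exact equalities, which are imposed by construction).  The draw
    is deterministic in ``seed``.  Valid constraint names: "none",
    "boundedness-premises", "local-stability-P{2,3,4}",
    "global-stability-P{1,2,3,4}".
    """
    if constraints == "local-stability-P1":
        raise ValueError(
            "local-stability-P1 has no closed-form condition set (no unambiguous "
            "inequality exists for P1); sample global-stability-P1 or certify "
            "P1 stability numerically via local_stability"
        )
    if constraints not in _SAMPLER_CONSTRAINTS:
        raise ValueError(
            f"unknown constraint set {constraints!r}; "
            f"valid: {_SAMPLER_CONSTRAINTS}"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        b = rng.uniform(0.0, 1.0, size=13)
        if constraints == "global-stability-P4":
            b[[3, 4, 5, 6]] = 0.0  # beta4..beta7: premises require exactly 0
        if _satisfies(b, constraints, SAMPLER_MARGIN, SAMPLER_SELF_LIMIT_FLOOR):
            return ModelParameters.from_array(b)
    raise RuntimeError(
        f"no parameter set satisfying {constraints!r} found in "
        f"{max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# 2. Equilibria and stability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibriumPoint:
    """A stationary state of the model.

    Tags: ``P1`` = (0, (b8-b9)/b10, (b11-b12)/b13), ``P2`` = (0, 0,
    (b11-b12)/b13), ``P3`` = (0, (b8-b9)/b10, 0), ``P4`` = ((b1-b2)/b3, 0, 0)
    and ``trivial`` = (0, 0, 0).  ``admissible`` means every coordinate is
    finite and nonnegative.  ``excluded_by_analysis`` marks points the
    stability analysis deliberately leaves aside (the trivial point; the
    coexistence point is never constructed at all).
    """

    tag: str
    coords: tuple
    admissible: bool
    excluded_by_analysis: bool = False

    def as_array(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    def to_dict(self) -> dict:
        return {"tag": self.tag, "coords": list(self.coords),
                "admissible": self.admissible,
                "excluded_by_analysis": self.excluded_by_analysis}


def find_equilibria(params: ModelParameters,
                    include_trivial: bool = True) -> list[EquilibriumPoint]:
    """Return the trivial point and the four axial equilibria.

    Points whose defining self-limitation rate is zero are omitted with a
    logged notice.  The coexistence (interior) equilibrium is not computed:
    for the regimes of interest it has negative coordinates, and its
    exclusion is logged once per call.
    """
    points: list[EquilibriumPoint] = []
    if include_trivial:
        points.append(EquilibriumPoint("trivial", (0.0, 0.0, 0.0),
                                       admissible=True,
                                       excluded_by_analysis=True))

    def axial(tag: str, coords: tuple) -> None:
        arr = np.asarray(coords, dtype=float)
        admissible = bool(np.all(np.isfinite(arr)) and np.all(arr >= 0.0))
        points.append(EquilibriumPoint(tag, tuple(arr), admissible))

    y_star = ((params.beta8 - params.beta9) / params.beta10
              if params.beta10 > 0.0 else None)
    z_star = ((params.beta11 - params.beta12) / params.beta13
              if params.beta13 > 0.0 else None)
    x_star = ((params.beta1 - params.beta2) / params.beta3
              if params.beta3 > 0.0 else None)

    if y_star is not None and z_star is not None:
        axial("P1", (0.0, y_star, z_star))
    else:
        logger.info("P1 omitted: beta10 or beta13 is zero")
    if z_star is not None:
        axial("P2", (0.0, 0.0, z_star))
    else:
        logger.info("P2 omitted: beta13 is zero")
    if y_star is not None:
        axial("P3", (0.0, y_star, 0.0))
    else:
        logger.info("P3 omitted: beta10 is zero")
    if x_star is not None:
        axial("P4", (x_star, 0.0, 0.0))
    else:
        logger.info("P4 omitted: beta3 is zero")
    logger.debug("coexistence equilibrium not computed (excluded: negative "
                 "coordinates in the regimes of interest)")
    return points


def jacobian(state, params: ModelParameters) -> np.ndarray:
    """Jacobian of the right-hand side at ``state`` (any finite triple).

    Diagonal entries::

        A1 = b1 - b2 - 2*b3*X - b5*Y^2 - b4*Y - b6*Z^2 - b7*Z
        A2 = b8 - b9 + b4*X + 2*b5*X*Y - 2*b10*Y
        A3 = b11 - b12 + b7*X + 2*b6*X*Z - 2*b13*Z

    The (2,3) and (3,2) entries are zero: the two predators interact only
    through the prey.
    """
    x, y, z = (float(v) for v in np.asarray(state, dtype=float))
    p = params
    a1 = p.beta1 - p.beta2 - 2 * p.beta3 * x - p.beta5 * y * y \
        - p.beta4 * y - p.beta6 * z * z - p.beta7 * z
    a2 = p.beta8 - p.beta9 + p.beta4 * x + 2 * p.beta5 * x * y \
        - 2 * p.beta10 * y
    a3 = p.beta11 - p.beta12 + p.beta7 * x + 2 * p.beta6 * x * z \
        - 2 * p.beta13 * z
    return np.array([
        [a1, -p.beta4 * x - 2 * p.beta5 * x * y,
             -p.beta7 * x - 2 * p.beta6 * x * z],
        [p.beta5 * y * y + p.beta4 * y, a2, 0.0],
        [p.beta6 * z * z + p.beta7 * z, 0.0, a3],
    ])


def local_stability_conditions(tag: str, params: ModelParameters) -> dict | None:
    """Printed local-stability condition set for an axial equilibrium.

    Returns a dict of named boolean conditions plus key ``"all"``, or
    ``None`` for ``P1`` (no unambiguous closed-form inequality is encoded for
    it; certify P1 by numerical eigenvalues instead) and for the trivial
    point.
    """
    p = params
    if tag in ("P1", "trivial"):
        return None
    if tag == "P2":
        if p.beta13 == 0.0:
            return {"beta13_nonzero": False, "all": False}
        d = p.beta11 - p.beta12
        limit = (p.beta6 * d * d
                 + p.beta13 * (p.beta7 * d + p.beta2 * p.beta13)) \
            / (p.beta13 * p.beta13)
        conds = {
            "beta8_le_beta9": p.beta8 <= p.beta9,
            "beta11_ge_beta12": p.beta11 >= p.beta12,
            "beta1_le_limit": p.beta1 <= limit,
            "beta13_nonzero": True,
        }
    elif tag == "P3":
        if p.beta10 == 0.0:
            return {"beta10_nonzero": False, "all": False}
        d = p.beta8 - p.beta9
        limit = (p.beta5 * d * d
                 + p.beta10 * (p.beta4 * d + p.beta2 * p.beta10)) \
            / (p.beta10 * p.beta10)
        conds = {
            "beta8_ge_beta9": p.beta8 >= p.beta9,
            "beta11_le_beta12": p.beta11 <= p.beta12,
            "beta1_le_limit": p.beta1 <= limit,
            "beta10_nonzero": True,
        }
    elif tag == "P4":
        if p.beta3 == 0.0:
            return {"beta3_nonzero": False, "all": False}
        ratio = (p.beta1 - p.beta2) / p.beta3
        conds = {
            "beta1_ge_beta2": p.beta1 >= p.beta2,
            "beta9_ge_bound": p.beta9 >= ratio * p.beta4 + p.beta8,
            "beta12_ge_bound": p.beta12 >= ratio * p.beta7 + p.beta11,
            "beta3_nonzero": True,
        }
    else:
        raise ValueError(f"unknown equilibrium tag {tag!r}")
    conds["all"] = all(conds.values())
    return conds


@dataclass
class StabilityReport:
    """Local/global stability verdicts for one equilibrium point."""

    point: EquilibriumPoint
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    locally_stable_numeric: bool
    verdict: str  # "stable" | "unstable" | "inconclusive"
    local_conditions_hold: bool | None
    global_conditions_hold: bool
    lyapunov_derivative_sign_checked: bool = False

    def to_dict(self) -> dict:
        return {
            "point": self.point.to_dict(),
            "jacobian": self.jacobian.tolist(),
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "locally_stable_numeric": self.locally_stable_numeric,
            "verdict": self.verdict,
            "local_conditions_hold": self.local_conditions_hold,
            "global_conditions_hold": self.global_conditions_hold,
            "lyapunov_derivative_sign_checked":
                self.lyapunov_derivative_sign_checked,
        }


def local_stability(point: EquilibriumPoint, params: ModelParameters,
                    tol: float = STABILITY_TOL) -> StabilityReport:
    """Numerical local-stability classification at an admissible equilibrium.

    The verdict is "stable" when every eigenvalue real part is below -tol,
    "unstable" when some real part exceeds +tol, and "inconclusive" when the
    largest real part lies within the tolerance band (non-hyperbolic up to
    numerics).  ``locally_stable_numeric`` is the strict stable verdict.
    """
    if not point.admissible:
        raise ValueError(f"equilibrium {point.tag} is not admissible")
    jac = jacobian(point.coords, params)
    eig = np.linalg.eigvals(jac)
    max_re = float(np.max(eig.real))
    stable = bool(np.all(eig.real < -tol))
    if stable:
        verdict = "stable"
    elif max_re > tol:
        verdict = "unstable"
    else:
        verdict = "inconclusive"
    t2 = local_stability_conditions(point.tag, params)
    t3_ok, _ = global_stability_conditions(point.tag, params)
    return StabilityReport(
        point=point, jacobian=jac, eigenvalues=eig,
        locally_stable_numeric=stable, verdict=verdict,
        local_conditions_hold=None if t2 is None else bool(t2["all"]),
        global_conditions_hold=t3_ok,
    )


@dataclass(frozen=True)
class LyapunovEvaluation:
    """Value and time derivative of the Volterra-type Lyapunov function."""

    V: float
    dVdt: float
    at_state: tuple
    reference_point: EquilibriumPoint


def _lyap_terms(w, w_star: float):
    """Per-component summand w - w* - w*log(w/w*); limit form w when w* = 0."""
    w = np.asarray(w, dtype=float)
    if w_star == 0.0:
        return w
    if np.any(w <= 0.0):
        raise ValueError(
            "Lyapunov function diverges: state component is zero where the "
            "reference coordinate is positive"
        )
    return w - w_star - w_star * np.log(w / w_star)


def lyapunov(state, point: EquilibriumPoint) -> float:
    """Volterra-type Lyapunov function V = sum_w (w - w* - w* ln(w/w*)).

    Components whose reference coordinate ``w*`` is zero contribute the
    limiting summand ``w``.  V is zero exactly at the reference point and
    positive elsewhere (convexity of each summand).
    """
    arr = validate_state(state)
    ref = point.as_array()
    return float(sum(_lyap_terms(arr[..., i], float(ref[i]))
                     for i in range(3)))


def _lyap_gradient(arr: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Gradient of V: component i is 1 - w*_i/w_i (just 1 when w*_i = 0)."""
    grad = np.ones_like(arr)
    for i in range(3):
        if ref[i] > 0.0:
            if np.any(arr[..., i] <= 0.0):
                raise ValueError(
                    "Lyapunov gradient diverges at a zero component with "
                    "positive reference coordinate"
                )
            grad[..., i] = 1.0 - ref[i] / arr[..., i]
    return grad


def lyapunov_derivative_numeric(state, point: EquilibriumPoint,
                                params: ModelParameters):
    """Chain-rule dV/dt = grad(V) . F(state); independent of the closed forms."""
    arr = validate_state(state)
    grad = _lyap_gradient(arr, point.as_array())
    f = rhs(arr, params, validate=False)
    return np.sum(grad * f, axis=-1)


def lyapunov_derivative(state, point: EquilibriumPoint,
                        params: ModelParameters):
    """Closed-form dV/dt along trajectories, per equilibrium tag.

    Each form is obtained from the chain rule after substituting the
    equilibrium identities (e.g. ``b8 = b9 + b10*Y1*`` at P1) and agrees
    with :func:`lyapunov_derivative_numeric` to round-off.  ``state`` may be
    a triple or an array of shape (..., 3).  The trivial point has no closed
    form; use the numeric chain rule for it.
    """
    arr = validate_state(state)
    x, y, z = arr[..., 0], arr[..., 1], arr[..., 2]
    p = params
    xs, ys, zs = (float(v) for v in point.as_array())
    if point.tag == "P1":
        out = (
            -x * (-p.beta1 + p.beta2 + p.beta3 * x + p.beta5 * ys * y
                  + p.beta6 * zs * z + p.beta4 * ys + p.beta7 * zs)
            - p.beta10 * (ys - y) ** 2 - p.beta13 * (zs - z) ** 2
        )
    elif point.tag == "P2":
        out = (
            -x * (-p.beta1 + p.beta2 + p.beta3 * x + p.beta6 * zs * z
                  + p.beta7 * zs)
            - p.beta10 * y * y + y * (p.beta8 - p.beta9)
            - p.beta13 * (zs - z) ** 2
        )
    elif point.tag == "P3":
        out = (
            -x * (-p.beta1 + p.beta2 + p.beta3 * x + p.beta5 * ys * y
                  + p.beta4 * ys)
            - p.beta10 * (ys - y) ** 2
            - p.beta13 * z * z + z * (p.beta11 - p.beta12)
        )
    elif point.tag == "P4":
        out = (
            -p.beta3 * (xs - x) ** 2
            + xs * y * (p.beta5 * y + p.beta4)
            + xs * z * (p.beta6 * z + p.beta7)
            - p.beta10 * y * y + y * (p.beta8 - p.beta9)
            - p.beta13 * z * z + z * (p.beta11 - p.beta12)
        )
    else:
        raise ValueError(
            f"no closed-form dV/dt for tag {point.tag!r}; use "
            "lyapunov_derivative_numeric (chain rule) instead"
        )
    return out if out.ndim else float(out)


def evaluate_lyapunov(state, point: EquilibriumPoint,
                      params: ModelParameters) -> LyapunovEvaluation:
    """Bundle V and closed-form dV/dt (numeric chain rule for the trivial
    point) at one state."""
    arr = validate_state(state)
    try:
        dvdt = float(lyapunov_derivative(arr, point, params))
    except ValueError:
        dvdt = float(lyapunov_derivative_numeric(arr, point, params))
    return LyapunovEvaluation(V=lyapunov(arr, point), dVdt=dvdt,
                              at_state=tuple(arr), reference_point=point)


def global_stability_conditions(tag: str,
                                params: ModelParameters) -> tuple[bool, dict]:
    """Premise sets under which dV/dt <= 0 holds on the positive orthant.

    P1: b8>=b9, b11>=b12, b10!=0, b13!=0, b1<=b2.
    P2: b11>=b12, b13!=0, b1<=b2, b8<=b9.
    P3: b8>=b9, b10!=0, b1<=b2, b11<=b12.
    P4: b1>=b2, b3!=0, b8<=b9, b11<=b12, b4=b5=b6=b7=0.
    """
    p = params
    if tag == "P1":
        conds = {
            "beta8_ge_beta9": p.beta8 >= p.beta9,
            "beta11_ge_beta12": p.beta11 >= p.beta12,
            "beta10_nonzero": p.beta10 != 0.0,
            "beta13_nonzero": p.beta13 != 0.0,
            "beta1_le_beta2": p.beta1 <= p.beta2,
        }
    elif tag == "P2":
        conds = {
            "beta11_ge_beta12": p.beta11 >= p.beta12,
            "beta13_nonzero": p.beta13 != 0.0,
            "beta1_le_beta2": p.beta1 <= p.beta2,
            "beta8_le_beta9": p.beta8 <= p.beta9,
        }
    elif tag == "P3":
        conds = {
            "beta8_ge_beta9": p.beta8 >= p.beta9,
            "beta10_nonzero": p.beta10 != 0.0,
            "beta1_le_beta2": p.beta1 <= p.beta2,
            "beta11_le_beta12": p.beta11 <= p.beta12,
        }
    elif tag == "P4":
        conds = {
            "beta1_ge_beta2": p.beta1 >= p.beta2,
            "beta3_nonzero": p.beta3 != 0.0,
            "beta8_le_beta9": p.beta8 <= p.beta9,
            "beta11_le_beta12": p.beta11 <= p.beta12,
            "no_predation": (p.beta4 == 0.0 and p.beta5 == 0.0
                             and p.beta6 == 0.0 and p.beta7 == 0.0),
        }
    elif tag == "trivial":
        conds = {"no_closed_form": False}
    else:
        raise ValueError(f"unknown equilibrium tag {tag!r}")
    return all(conds.values()), conds


# ---------------------------------------------------------------------------
# 3. Multistage differential transform solver
# ---------------------------------------------------------------------------
#
# The differential transform of u(t) about t_i is U(k) = (1/k!) d^k u / dt^k,
# so u(t) = sum_k U(k) (t - t_i)^k.  Transform rules used by this model:
# sums map to sums, constants scale, a product maps to the Cauchy convolution
# sum_p U(p) V(k-p), and du/dt maps to (k+1) U(k+1).  (Rules for higher
# derivatives and monomial sources t^n exist but this first-order autonomous
# system never needs them.)  The multistage driver restarts the expansion on
# each subdomain from the previous endpoint, extending validity beyond one
# Taylor radius.


def cauchy_product(a: Sequence[float], b: Sequence[float], k: int) -> float:
    """k-th Taylor coefficient of the product of two series:
    sum_{p=0}^{k} a_p * b_{k-p}.

    The inputs are polynomial coefficient lists: entries beyond the stored
    length are zero, so any ``k >= 0`` is defined (and vanishes beyond the
    sum of the two degrees).
    """
    if k < 0:
        raise IndexError(f"coefficient index must be nonnegative, got {k}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = max(0, k + 1 - len(b))
    hi = min(k + 1, len(a))
    if lo >= hi:
        return 0.0
    return float(np.dot(a[lo:hi], b[k - hi + 1: k - lo + 1][::-1]))


def nested_product(a: Sequence[float], b: Sequence[float],
                   c: Sequence[float], k: int) -> float:
    """k-th Taylor coefficient of the triple product a*b*c:
    sum_{j=0}^{k} c_{k-j} * sum_{l=0}^{j} a_l b_{j-l}.

    Identical to ``cauchy_product(cauchy_product(a, b, .), c, k)``; written
    as the nested double sum so the cubic terms transform in one pass.
    Coefficients beyond a stored length are zero, as in
    :func:`cauchy_product`.
    """
    if k < 0:
        raise IndexError(f"coefficient index must be nonnegative, got {k}")
    total = 0.0
    for j in range(k + 1):
        if k - j >= len(c):
            continue
        inner = 0.0
        for l in range(max(0, j + 1 - len(b)), min(j + 1, len(a))):
            inner += a[l] * b[j - l]
        total += c[k - j] * inner
    return total


def dtm_coefficients(initial, params: ModelParameters, N: int) -> np.ndarray:
    """Taylor coefficients of the solution about one expansion point.

    Returns an array of shape (3, N+1): rows are the coefficient sequences
    (X^k), (Y^k), (Z^k) with (X^0, Y^0, Z^0) = ``initial``.  Each recurrence
    divides by (k+1) — the k!/(k+1)! factor of the derivative rule — and
    transforms the quadratic terms with a single Cauchy convolution and the
    cubic mating terms with the nested double convolution.
    """
    if N < 1:
        raise ValueError(f"iteration count N must be >= 1, got {N}")
    x0 = validate_state(initial)
    return _dtm_coefficients_raw(tuple(x0), params.as_array(), N)


def _dtm_coefficients_raw(initial: tuple, b: np.ndarray, N: int) -> np.ndarray:
    coeffs = np.zeros((3, N + 1))
    coeffs[:, 0] = initial
    X, Y, Z = coeffs
    for k in range(N):
        xx = cauchy_product(X, X, k)
        xy = cauchy_product(X, Y, k)
        xz = cauchy_product(X, Z, k)
        xyy = nested_product(X, Y, Y, k)
        xzz = nested_product(X, Z, Z, k)
        X[k + 1] = (b[0] * X[k] - b[1] * X[k] - b[2] * xx - b[3] * xy
                    - b[4] * xyy - b[5] * xzz - b[6] * xz) / (k + 1)
        Y[k + 1] = (b[7] * Y[k] - b[8] * Y[k] - b[9] * cauchy_product(Y, Y, k)
                    + b[3] * xy + b[4] * xyy) / (k + 1)
        Z[k + 1] = (b[10] * Z[k] - b[11] * Z[k]
                    - b[12] * cauchy_product(Z, Z, k)
                    + b[5] * xzz + b[6] * xz) / (k + 1)
    return coeffs


@dataclass(frozen=True)
class TaylorSegment:
    """Per-subdomain Taylor expansion anchored at ``t_start``.

    ``coeffs`` has shape (3, N+1); evaluating the three degree-N polynomials
    at offset ``tau`` in [0, length] gives the state at ``t_start + tau``.
    """

    t_start: float
    length: float
    coeffs: np.ndarray

    def evaluate(self, tau: float) -> np.ndarray:
        """Horner evaluation of the segment polynomials at offset ``tau``."""
        out = self.coeffs[:, -1].copy()
        for k in range(self.coeffs.shape[1] - 2, -1, -1):
            out = out * tau + self.coeffs[:, k]
        return out


@dataclass
class Trajectory:
    """Time-ordered samples of a solution plus solver metadata.

    ``states`` rows are clamped to zero where a component lies within
    round-off (1e-9) below zero; the raw values are what the solver stepped
    with.  MsDTM trajectories carry their segments, enabling dense
    evaluation between subdomain endpoints.
    """

    times: np.ndarray
    states: np.ndarray
    method: str  # "msdtm" | "rk4"
    h: float
    N: int | None = None
    segments: list[TaylorSegment] | None = field(default=None, repr=False)

    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def evaluate(self, t: float) -> np.ndarray:
        """Dense evaluation at time ``t`` using the stored segments."""
        if self.segments is None:
            raise ValueError(
                f"{self.method} trajectory has no dense segments"
            )
        if not (self.times[0] <= t <= self.times[-1] + 1e-12):
            raise ValueError(f"time {t} outside [{self.times[0]}, {self.times[-1]}]")
        idx = min(np.searchsorted(self.times, t, side="right") - 1,
                  len(self.segments) - 1)
        idx = max(idx, 0)
        seg = self.segments[idx]
        return seg.evaluate(t - seg.t_start)

    def to_csv(self, path, significant_digits: int = 12) -> None:
        """Write t,X,Y,Z rows in plain decimal."""
        fmt = f"{{:.{significant_digits}g}}"
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["t", "X", "Y", "Z"])
            for t, s in zip(self.times, self.states):
                writer.writerow([fmt.format(t)] + [fmt.format(v) for v in s])

    def to_json_dict(self) -> dict:
        return {
            "method": self.method, "h": self.h, "N": self.N,
            "times": self.times.tolist(),
            "states": self.states.tolist(),
        }


def _clamp_roundoff(states: np.ndarray) -> np.ndarray:
    return np.where((states < 0.0) & (states >= -NEGATIVE_CLAMP), 0.0, states)


def msdtm_solve(initial, params: ModelParameters, T: float,
                h: float = 0.01, N: int = 10,
                keep_segments: bool = True) -> Trajectory:
    """Multistage differential transform solution on [0, T].

    [0, T] is partitioned into ceil(T/h) subdomains of width ``h`` (the last
    possibly shorter).  On each, a fresh degree-``N`` Taylor expansion is
    built from the state at the left endpoint via :func:`dtm_coefficients`
    and evaluated at the subdomain width to step; every subdomain endpoint is
    recorded.
    """
    if T <= 0:
        raise ValueError(f"horizon T must be positive, got {T}")
    if h <= 0:
        raise ValueError(f"subdomain length h must be positive, got {h}")
    if N < 1:
        raise ValueError(f"iteration count N must be >= 1, got {N}")
    state = validate_state(initial)
    b = params.as_array()
    n_sub = max(1, math.ceil(T / h - 1e-12))
    times = np.minimum(np.arange(n_sub + 1) * h, T)
    states = np.empty((n_sub + 1, 3))
    states[0] = state
    segments: list[TaylorSegment] | None = [] if keep_segments else None
    current = tuple(float(v) for v in state)
    for i in range(n_sub):
        width = times[i + 1] - times[i]
        coeffs = _dtm_coefficients_raw(current, b, N)
        if segments is not None:
            segments.append(TaylorSegment(float(times[i]), float(width), coeffs))
        seg = TaylorSegment(float(times[i]), float(width), coeffs)
        nxt = seg.evaluate(width)
        if not np.all(np.isfinite(nxt)):
            raise FloatingPointError(
                f"nonfinite state on subdomain {i} "
                f"[{times[i]:.6g}, {times[i + 1]:.6g}]: {nxt}"
            )
        states[i + 1] = nxt
        current = tuple(float(v) for v in nxt)
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug("msdtm subdomain %d: t=%.6g state=%s", i,
                         times[i + 1], nxt)
    return Trajectory(times=times, states=_clamp_roundoff(states),
                      method="msdtm", h=h, N=N, segments=segments)


# ---------------------------------------------------------------------------
# 4. Reference Runge-Kutta oracle
# ---------------------------------------------------------------------------

def rk4_solve(initial, params: ModelParameters, T: float,
              step: float) -> Trajectory:
    """Classical fixed-step fourth-order Runge-Kutta integration on [0, T].

    Serves as the independent correctness oracle for the MsDTM solver; every
    step is recorded.  A tight reference uses ``step = 1e-4``, ten- to
    hundred-fold finer than the solver under test.
    """
    if T <= 0:
        raise ValueError(f"horizon T must be positive, got {T}")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    x, y, z = (float(v) for v in validate_state(initial))
    b = tuple(params.as_array())
    n = max(1, math.ceil(T / step - 1e-12))
    times = np.minimum(np.arange(n + 1) * step, T)
    states = np.empty((n + 1, 3))
    states[0] = (x, y, z)
    for i in range(n):
        hh = times[i + 1] - times[i]
        k1 = _rhs_floats(x, y, z, b)
        k2 = _rhs_floats(x + 0.5 * hh * k1[0], y + 0.5 * hh * k1[1],
                         z + 0.5 * hh * k1[2], b)
        k3 = _rhs_floats(x + 0.5 * hh * k2[0], y + 0.5 * hh * k2[1],
                         z + 0.5 * hh * k2[2], b)
        k4 = _rhs_floats(x + hh * k3[0], y + hh * k3[1], z + hh * k3[2], b)
        x += hh * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
        y += hh * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
        z += hh * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]) / 6.0
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
            raise FloatingPointError(
                f"nonfinite state at step {i} (t={times[i + 1]:.6g})"
            )
        states[i + 1] = (x, y, z)
    return Trajectory(times=times, states=_clamp_roundoff(states),
                      method="rk4", h=step)


def rk4_ensemble(initials, params_batch, T: float,
                 step: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized RK4 over a batch of systems.

    ``initials`` has shape (n, 3) and ``params_batch`` shape (n, 13); system
    i is integrated with its own parameter row.  Returns ``(times, states)``
    with ``states`` of shape (n_steps+1, n, 3) (raw values, no clamping) —
    used for Monte-Carlo positivity/boundedness sweeps where a Python-level
    per-trajectory loop would dominate runtime.
    """
    s = np.array(initials, dtype=float)
    b = np.asarray(params_batch, dtype=float).T  # (13, n) for broadcasting
    if s.ndim != 2 or s.shape[1] != 3 or b.shape[0] != 13:
        raise ValueError("initials must be (n, 3) and params_batch (n, 13)")
    n_steps = max(1, math.ceil(T / step - 1e-12))
    times = np.minimum(np.arange(n_steps + 1) * step, T)
    out = np.empty((n_steps + 1,) + s.shape)
    out[0] = s

    def f(state):
        xp, yp, zp = _rhs_arrays(state[:, 0], state[:, 1], state[:, 2], b)
        return np.stack([xp, yp, zp], axis=1)

    for i in range(n_steps):
        hh = times[i + 1] - times[i]
        k1 = f(s)
        k2 = f(s + 0.5 * hh * k1)
        k3 = f(s + 0.5 * hh * k2)
        k4 = f(s + hh * k3)
        s = s + hh * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        if not np.all(np.isfinite(s)):
            raise FloatingPointError(f"nonfinite state at ensemble step {i}")
        out[i + 1] = s
    return times, out


def trajectory_distance(a: Trajectory, b: Trajectory,
                        time_tol: float = 1e-9) -> float:
    """Max over shared sample times of the infinity-norm state difference.

    If the grids differ but ``b`` carries dense segments, ``b`` is evaluated
    on ``a``'s grid; otherwise the comparison runs over the times the two
    grids share (matched within ``time_tol``).  Disjoint grids without dense
    output raise ``ValueError``.
    """
    if len(a.times) == len(b.times) and np.allclose(a.times, b.times,
                                                    rtol=0.0, atol=time_tol):
        return float(np.max(np.abs(a.states - b.states)))
    if b.segments is not None:
        other = np.stack([b.evaluate(t) for t in a.times])
        return float(np.max(np.abs(a.states - other)))
    if a.segments is not None:
        return trajectory_distance(b, a, time_tol)
    idx = np.searchsorted(b.times, a.times)
    idx = np.clip(idx, 0, len(b.times) - 1)
    left = np.clip(idx - 1, 0, len(b.times) - 1)
    take = np.where(np.abs(b.times[left] - a.times)
                    < np.abs(b.times[idx] - a.times), left, idx)
    shared = np.abs(b.times[take] - a.times) <= time_tol
    if not np.any(shared):
        raise ValueError(
            "trajectories share no sample times and neither has dense output"
        )
    return float(np.max(np.abs(a.states[shared] - b.states[take[shared]])))


# ---------------------------------------------------------------------------
# 5. Run configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One simulation/analysis run.

    Exactly one of ``case`` (a preset name) or ``betas`` (13 explicit rates)
    selects the parameters.  ``method`` is "msdtm", "rk4" or "both".
    """

    case: str | None = None
    betas: list[float] | None = None
    x0: float = DEFAULT_INITIAL_STATE[0]
    y0: float = DEFAULT_INITIAL_STATE[1]
    z0: float = DEFAULT_INITIAL_STATE[2]
    T: float = 100.0
    h: float = 0.01
    N: int = 10
    method: str = "msdtm"
    out: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.case is None) == (self.betas is None):
            raise ValueError(
                "exactly one of 'case' and 'betas' must be given"
            )
        if self.method not in ("msdtm", "rk4", "both"):
            raise ValueError(f"method must be msdtm|rk4|both, got {self.method!r}")

    def parameters(self) -> ModelParameters:
        if self.case is not None:
            return ModelParameters.from_preset(self.case)
        return ModelParameters.from_array(self.betas)

    def initial_state(self) -> tuple:
        return (self.x0, self.y0, self.z0)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def run_simulation(config: RunConfig) -> dict:
    """Run the configured solver(s); write CSVs when ``config.out`` is set.

    Returns a summary dict: per-method final state and per-component
    extrema, the boundedness certificate, and (for ``method="both"``) the
    trajectory distance between the two solvers.
    """
    params = config.parameters()
    initial = config.initial_state()
    methods = ["msdtm", "rk4"] if config.method == "both" else [config.method]
    trajectories: dict[str, Trajectory] = {}
    for m in methods:
        if m == "msdtm":
            trajectories[m] = msdtm_solve(initial, params, config.T,
                                          h=config.h, N=config.N)
        else:
            trajectories[m] = rk4_solve(initial, params, config.T,
                                        step=config.h)
    summary: dict = {
        "config": asdict(config),
        "boundedness": boundedness_certificate(params).to_dict(),
        "methods": {},
    }
    for m, traj in trajectories.items():
        summary["methods"][m] = {
            "final_state": traj.final_state().tolist(),
            "min": traj.states.min(axis=0).tolist(),
            "max": traj.states.max(axis=0).tolist(),
            "n_samples": int(len(traj.times)),
        }
        if config.out:
            path = f"{config.out}.{m}.csv" if len(methods) > 1 \
                else f"{config.out}.csv" if not str(config.out).endswith(".csv") \
                else str(config.out)
            traj.to_csv(path)
            summary["methods"][m]["csv"] = path
            logger.info("wrote %s trajectory to %s", m, path)
    if len(methods) == 2:
        summary["trajectory_distance"] = trajectory_distance(
            trajectories["msdtm"], trajectories["rk4"])
    return summary


def stability_report(params: ModelParameters, tol: float = STABILITY_TOL,
                     sweep_states: int = 200, seed: int = 0) -> dict:
    """Full equilibrium/stability report as a JSON-serializable dict.

    For each admissible axial equilibrium: coordinates, Jacobian
    eigenvalues, the numerical verdict, the closed-form local-stability
    condition checks, and the global-stability premise checks.  When the
    global premises hold, the sign of the closed-form dV/dt is swept at
    ``sweep_states`` random positive states and the result recorded.
    """
    rng = np.random.default_rng(seed)
    cert = boundedness_certificate(params)
    scale = cert.bound if (cert.applicable and np.isfinite(cert.bound)
                           and cert.bound > 0) else 1.0
    report: dict = {"parameters": params.to_dict(),
                    "boundedness": cert.to_dict(), "equilibria": []}
    for point in find_equilibria(params):
        entry = point.to_dict()
        if point.admissible and point.tag != "trivial":
            rep = local_stability(point, params, tol=tol)
            t2 = local_stability_conditions(point.tag, params)
            t3_ok, t3 = global_stability_conditions(point.tag, params)
            if t3_ok:
                states = rng.uniform(1e-6, scale, size=(sweep_states, 3))
                dvdt = lyapunov_derivative(states, point, params)
                rep.lyapunov_derivative_sign_checked = True
                entry["dVdt_sweep_max"] = float(np.max(dvdt))
            entry.update(rep.to_dict())
            entry["local_condition_detail"] = t2
            entry["global_condition_detail"] = t3
        report["equilibria"].append(entry)
    residuals = [
        float(np.max(np.abs(rhs(p.coords, params))))
        for p in find_equilibria(params) if p.admissible
    ]
    report["max_equilibrium_residual"] = max(residuals)
    return report


def plot_trajectory(trajectory: Trajectory, path) -> None:
    """Convenience plot of X, Y, Z against t (PNG); requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for i, label in enumerate(["X (prey)", "Y (predator I)", "Z (predator II)"]):
        ax.plot(trajectory.times, trajectory.states[:, i], label=label)
    ax.set_xlabel("t")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
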