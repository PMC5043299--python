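"""Linear stability analysis of the reduced system.

The linearization is 3-dimensional in (Sg, Ig, Ip); the justice-system
compartment contributes a decoupled eigenvalue -mu3 and is excluded from
classification, and Sp is slaved to Ip by force conservation.

Besides the numeric eigenvalue classification, the closed-form threshold
inequalities for the boundary equilibria are exposed as named checks:

* E0 stable against gang invasion iff a'*P/(1-c*P) > b - mu1.
* E1 stable against gang invasion iff a'*P*(1-Omega*(1-r))/(1-c*P) > b - mu1.
* E2 stable iff h*a'*P/(1+h*Sg-c*P)^2 < 1/K and beta1 < b.
* E3 stable iff the same with effective predators, i.e. an extra factor
  (1 - Omega*(1-r)).

These inequalities govern the eigenvalues in the gang directions.  The
corruption direction carries its own threshold: at any corruption-free
state (Ip = 0) the eigenvalue of the Ip equation is beta3 - mu2, so E0 and
E2 are additionally unstable whenever beta3 > mu2 (corruption invades and
the endemic branches E1/E3 take over as candidates).  ``condition_E0`` and
``condition_E2`` implement the gang-direction inequalities only, matching
the closed-form thresholds used for the bifurcation analysis; the
corruption threshold is reported separately in ``condition_checks``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import StateReduced, rhs_reduced
from .parameters import ModelParameters, derive

__all__ = [
    "StabilityReport",
    "HopfExclusion",
    "jacobian_reduced",
    "stability_report",
    "condition_E0",
    "condition_E1",
    "condition_E2",
    "condition_E3",
    "corruption_invades",
    "hopf_excluded_no_criminal",
    "hopf_excluded_core_free",
]

#: Real parts within this of zero are classified "marginal".
MARGINAL_TOL = 1e-9


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalue analysis of one equilibrium of the reduced system."""

    jacobian: np.ndarray
    eigenvalues: np.ndarray
    char_poly: tuple[float, float, float]  # (a1, a2, a3) of l^3 + a1 l^2 + a2 l + a3
    max_real: float
    classification: str  # stable | unstable | marginal
    condition_checks: dict[str, bool]

    @property
    def routh_hurwitz(self) -> tuple[float, float, float, float]:
        """(a1, a2, a3, a1*a2 - a3); all positive iff stable."""
        a1, a2, a3 = self.char_poly
        return (a1, a2, a3, a1 * a2 - a3)


def jacobian_reduced(
    state: StateReduced | tuple[float, float, float], params: ModelParameters
) -> np.ndarray:
    """Analytic Jacobian of ``rhs_reduced`` at ``state``, order (Sg, Ig, Ip).

    At an empty gang population (Ng = 0) the derivatives of the
    standard-incidence term are taken as their one-sided limits along the
    axes (both quadratic ratio terms -> 0), which reproduces the boundary
    eigenvalues of the extinction and criminal-free states.
    """
    Sg, Ig, Ip = state
    p = params
    d = derive(p)
    Ng = Sg + Ig
    D = 1.0 + d.h * (Sg + p.lam * Ig) - p.c * p.P
    if D <= 0:
        raise ValueError(f"nonpositive capture denominator D = {D}")
    E = p.P - (1.0 - p.r) * Ip
    ap = d.a_prime
    if Ng > 0:
        ri = Ig * Ig / (Ng * Ng)  # d(Sg*Ig/Ng)/dSg
        rs = Sg * Sg / (Ng * Ng)  # d(Sg*Ig/Ng)/dIg
    else:
        ri = rs = 0.0
    J = np.empty((3, 3))
    J[0, 0] = p.b - (2 * Sg + Ig) / p.K - p.beta1 * ri - ap * E * (D - Sg * d.h) / D**2 - p.mu1
    J[0, 1] = p.b - Sg / p.K - p.beta1 * rs + ap * Sg * E * d.h * p.lam / D**2
    J[0, 2] = ap * Sg * (1.0 - p.r) / D
    J[1, 0] = p.beta1 * ri - Ig / p.K + ap * Ig * E * d.h / D**2
    J[1, 1] = p.beta1 * rs - (Sg + 2 * Ig) / p.K - ap * E * (D - Ig * d.h * p.lam) / D**2 - p.mu1
    J[1, 2] = ap * Ig * (1.0 - p.r) / D
    J[2, 0] = 0.0
    J[2, 1] = p.beta2 * (p.P - Ip) / p.P
    J[2, 2] = -p.beta2 * Ig / p.P + p.beta3 * (p.P - 2 * Ip) / p.P - p.mu2
    return J


def _characteristic_coefficients(J: np.ndarray) -> tuple[float, float, float]:
    a1 = -float(np.trace(J))
    # sum of principal 2x2 minors
    a2 = float(
        J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        + J[0, 0] * J[2, 2] - J[0, 2] * J[2, 0]
        + J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1]
    )
    a3 = -float(np.linalg.det(J))
    return (a1, a2, a3)


def stability_report(
    state: StateReduced | tuple[float, float, float],
    params: ModelParameters,
    label: str | None = None,
    residual_tol: float = 1e-6,
) -> StabilityReport:
    """Eigenvalues and classification at an equilibrium of the reduced system.

    Raises ValueError if ``state`` is not an equilibrium (residual above
    ``residual_tol`` relative to population scale).
    """
    res = max(abs(v) for v in rhs_reduced(state, params))
    scale = 1.0 + max(abs(v) for v in state)
    if res > residual_tol * scale:
        raise ValueError(f"state {tuple(state)} is not an equilibrium (residual {res:.3e})")
    J = jacobian_reduced(state, params)
    eig = np.linalg.eigvals(J)
    max_real = float(np.max(eig.real))
    if max_real < -MARGINAL_TOL:
        cls = "stable"
    elif max_real > MARGINAL_TOL:
        cls = "unstable"
    else:
        cls = "marginal"
    checks: dict[str, bool] = {}
    if label in ("E0", "E1", "E2", "E3"):
        d = derive(params)
        if label == "E0":
            checks["predation_exceeds_net_entry"] = condition_E0(params)
            checks["corruption_dies_out"] = not corruption_invades(params)
        elif label == "E1" and d.Omega is not None:
            checks["predation_exceeds_net_entry"] = condition_E1(params)
        elif label == "E2":
            checks["saturation_below_crowding"] = condition_E2(params, state[0])
            checks["recruitment_below_entry"] = params.beta1 < params.b
            checks["corruption_dies_out"] = not corruption_invades(params)
        elif label == "E3" and d.Omega is not None:
            checks["saturation_below_crowding"] = condition_E3(params, state[0])
            checks["recruitment_below_entry"] = params.beta1 < params.b
    return StabilityReport(
        jacobian=J,
        eigenvalues=eig,
        char_poly=_characteristic_coefficients(J),
        max_real=max_real,
        classification=cls,
        condition_checks=checks,
    )


def corruption_invades(params: ModelParameters) -> bool:
    """Corruption invades a corruption-free state iff beta3 > mu2."""
    return params.beta3 > params.mu2


def condition_E0(params: ModelParameters) -> bool:
    """Gang-invasion threshold at extinction: a'*P/(1-c*P) > b - mu1."""
    d = derive(params)
    return d.a_prime * params.P / (1.0 - params.c * params.P) > params.b - params.mu1


def condition_E1(params: ModelParameters) -> bool:
    """Gang-invasion threshold at the criminal-free state:
    a'*P*(1-Omega*(1-r))/(1-c*P) > b - mu1.  Requires beta3 > mu2."""
    d = derive(params)
    if d.Omega is None:
        raise ValueError("condition_E1 requires beta3 > mu2 (Omega defined)")
    peff_frac = 1.0 - d.Omega * (1.0 - params.r)
    return d.a_prime * params.P * peff_frac / (1.0 - params.c * params.P) > params.b - params.mu1


def condition_E2(params: ModelParameters, Sg_at_E2: float) -> bool:
    """Core-free/corruption-free stability: handling saturation weaker than
    crowding, h*a'*P/(1+h*Sg-c*P)^2 < 1/K, together with beta1 < b."""
    d = derive(params)
    D = 1.0 + d.h * Sg_at_E2 - params.c * params.P
    return (d.h * d.a_prime * params.P / D**2 < 1.0 / params.K) and (params.beta1 < params.b)


def condition_E3(params: ModelParameters, Sg_at_E3: float) -> bool:
    """Core-free stability with endemic corruption: as for E2 with the
    reduced effective force, factor (mu2 + r*beta3 - r*mu2)/beta3
    = 1 - Omega*(1-r)."""
    d = derive(params)
    if d.Omega is None:
        raise ValueError("condition_E3 requires beta3 > mu2 (Omega defined)")
    D = 1.0 + d.h * Sg_at_E3 - params.c * params.P
    peff_frac = 1.0 - d.Omega * (1.0 - params.r)
    return (d.a_prime * d.h * params.P * peff_frac / D**2 < 1.0 / params.K) and (
        params.beta1 < params.b
    )


@dataclass(frozen=True)
class HopfExclusion:
    """Result of a Hopf-exclusion argument at boundary equilibria."""

    excluded: bool
    applicable: bool
    trace_terms: dict[str, float]
    explanation: str


def hopf_excluded_no_criminal(params: ModelParameters) -> HopfExclusion:
    """No Hopf bifurcation is possible at the no-criminal states E0/E1.

    A purely imaginary pair in the (Ig, Ip) sub-block would need its trace
    term mu1 + mu2 + a'*(P-(1-r)*Ip)/(1-c*P) + 2*beta3*Ip/P to vanish; every
    summand is nonnegative and mu1 + mu2 + a'*P terms are positive, so the
    pair is impossible.
    """
    d = derive(params)
    terms: dict[str, float] = {}
    for lbl, Ip in (("E0", 0.0), ("E1", (d.Omega or 0.0) * params.P)):
        if lbl == "E1" and d.Omega is None:
            continue
        peff = params.P - (1.0 - params.r) * Ip
        terms[lbl] = (
            params.mu1
            + params.mu2
            + d.a_prime * peff / (1.0 - params.c * params.P)
            + 2.0 * params.beta3 * Ip / params.P
        )
    excluded = all(t > 0 for t in terms.values())
    return HopfExclusion(
        excluded=excluded,
        applicable=True,
        trace_terms=terms,
        explanation="trace of the (Ig, Ip) sub-block is strictly positive; "
        "a purely imaginary eigenvalue pair is impossible",
    )


def hopf_excluded_core_free(params: ModelParameters) -> HopfExclusion:
    """No Hopf bifurcation at the core-free states E2/E3 in their stability
    regime beta1 < b: the sub-block trace term b - beta1 + mu2 + 2*beta3*Ip/P
    is strictly positive there."""
    if params.beta1 >= params.b:
        return HopfExclusion(
            excluded=False,
            applicable=False,
            trace_terms={},
            explanation="not applicable: beta1 >= b, the core-free states are "
            "unstable in the gang direction and no Hopf scenario arises",
        )
    d = derive(params)
    terms = {"E2": params.b - params.beta1 + params.mu2}
    if d.Omega is not None:
        terms["E3"] = (
            params.b - params.beta1 + params.mu2 + 2.0 * params.beta3 * d.Omega
        )
    return HopfExclusion(
        excluded=all(t > 0 for t in terms.values()),
        applicable=True,
        trace_terms=terms,
        explanation="linear coefficient b - beta1 + mu2 + 2*beta3*Ip/P of the "
        "sub-block characteristic polynomial is strictly positive for beta1 < b",
    )
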