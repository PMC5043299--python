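"""Cooperative Beddington-De Angelis capture terms.

Police teams of size U search for gang members at attack rate a.  Handling
each arrest costs time (t_h per susceptible member, lam*t_h per core
member), while pre-planned cooperation among the P officers saves search
time (coefficient c per officer).  The resulting per-officer capture rate is

    a * X / (U * D),    D = 1 + h*(Sg + lam*Ig) - c*P,   h = a*t_h,

for prey class X, multiplied by the effective predator abundance
P - (1-r)*Ip: corrupt officers hunt at the reduced fraction r.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ModelParameters

__all__ = [
    "CaptureRates",
    "capture_denominator",
    "effective_predators",
    "capture_rates",
]


class CaptureDenominatorError(ValueError):
    """Raised when the cooperative time saving exceeds total effort (D <= 0)."""


@dataclass(frozen=True)
class CaptureRates:
    """Capture fluxes and per-capita rates at one state.

    ``flux_susceptible = per_capita_s * Sg`` and ``flux_core =
    per_capita_i * Ig``; both per-capita rates equal
    ``a * (P - (1-r)*Ip) / (U * D)`` — the vulnerability asymmetry of core
    members enters only through lam in the shared denominator.
    """

    D: float
    flux_susceptible: float
    flux_core: float
    per_capita_s: float
    per_capita_i: float


def capture_denominator(Sg: float, Ig: float, params: ModelParameters) -> float:
    """Dimensionless denominator D = 1 + h*(Sg + lam*Ig) - c*P.

    Raises :class:`CaptureDenominatorError` if D <= 0: the time budget
    T = search + handling - cooperation saving is then meaningless and the
    model breaks down (no clamping).
    """
    h = params.a * params.t_h
    D = 1.0 + h * (Sg + params.lam * Ig) - params.c * params.P
    if D <= 0:
        raise CaptureDenominatorError(
            f"nonpositive capture denominator D = {D} at Sg={Sg}, Ig={Ig}"
        )
    return D


def effective_predators(Ip: float, params: ModelParameters) -> float:
    """Effective predator abundance P - (1-r)*Ip.

    Corrupt officers contribute at the reduced rate r; with r = 1 the whole
    force hunts at full strength.
    """
    if not (0.0 <= Ip <= params.P):
        raise ValueError(f"Ip must lie in [0, P={params.P}], got {Ip}")
    return params.P - (1.0 - params.r) * Ip


def capture_rates(Sg: float, Ig: float, Ip: float, params: ModelParameters) -> CaptureRates:
    """Evaluate the functional response at state (Sg, Ig, Ip)."""
    if Sg < 0 or Ig < 0:
        raise ValueError(f"prey populations must be nonnegative, got Sg={Sg}, Ig={Ig}")
    D = capture_denominator(Sg, Ig, params)
    peff = effective_predators(Ip, params)
    per_capita = params.a * peff / (params.U * D)
    return CaptureRates(
        D=D,
        flux_susceptible=per_capita * Sg,
        flux_core=per_capita * Ig,
        per_capita_s=per_capita,
        per_capita_i=per_capita,
    )
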