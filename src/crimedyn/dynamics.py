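"""Right-hand sides of the governing ODEs.

The canonical object is the reduced 3-state system (Sg, Ig, Ip): the police
force is constant (Sp = P - Ip) and the justice-system occupancy Z is slaved
to the capture flux.  The full 5-state form exists to verify the reduction
and for time integration with Z tracked explicitly.

Gang recruitment and police corruption use standard incidence (beta*S*I/N);
the ratio Sg*Ig/(Sg+Ig) is defined as 0 at Sg+Ig = 0 (its continuous limit),
which makes the extinct state a genuine fixed point.
"""

from __future__ import annotations

from typing import NamedTuple

from .functional_response import capture_rates
from .parameters import ModelParameters

__all__ = [
    "StateFull",
    "StateReduced",
    "rhs_reduced",
    "rhs_full",
    "z_equilibrium",
    "ng_logistic_residual",
]


class StateFull(NamedTuple):
    """(Sg, Ig, Sp, Ip, Z): gang susceptible/core, police susceptible/corrupt,
    justice-system occupancy."""

    Sg: float
    Ig: float
    Sp: float
    Ip: float
    Z: float


class StateReduced(NamedTuple):
    """(Sg, Ig, Ip): the three dynamically independent components."""

    Sg: float
    Ig: float
    Ip: float

    def to_full(self, params: ModelParameters) -> StateFull:
        """Lift to the full state with Sp = P - Ip and Z at its slaved value."""
        return StateFull(
            self.Sg,
            self.Ig,
            params.P - self.Ip,
            self.Ip,
            z_equilibrium(self.Sg, self.Ig, self.Ip, params),
        )


def _incidence(Sg: float, Ig: float) -> float:
    """Standard-incidence ratio Sg*Ig/(Sg+Ig), 0 at the empty population."""
    Ng = Sg + Ig
    return Sg * Ig / Ng if Ng > 0 else 0.0


def rhs_reduced(
    state: StateReduced | tuple[float, float, float], params: ModelParameters
) -> tuple[float, float, float]:
    """Time derivatives (dSg/dt, dIg/dt, dIp/dt) of the reduced system."""
    Sg, Ig, Ip = state
    Ng = Sg + Ig
    cr = capture_rates(Sg, Ig, Ip, params)
    inc = params.beta1 * _incidence(Sg, Ig)
    dSg = params.b * Ng - Sg * Ng / params.K - inc - cr.flux_susceptible - params.mu1 * Sg
    dIg = inc - Ig * Ng / params.K - cr.flux_core - params.mu1 * Ig
    dIp = (
        params.beta2 * (params.P - Ip) * Ig / params.P
        + params.beta3 * (params.P - Ip) * Ip / params.P
        - params.mu2 * Ip
    )
    return (dSg, dIg, dIp)


def rhs_full(
    state: StateFull | tuple[float, float, float, float, float],
    params: ModelParameters,
) -> tuple[float, float, float, float, float]:
    """Time derivatives of the 5-state system.

    With gamma = mu2 and Sp = P - Ip, the force is conserved exactly:
    dSp/dt + dIp/dt = 0.
    """
    Sg, Ig, Sp, Ip, Z = state
    dSg, dIg, dIp = rhs_reduced((Sg, Ig, Ip), params)
    P = params.P
    dSp = (
        params.gamma * P
        - params.beta2 * Sp * Ig / P
        - params.beta3 * Sp * Ip / P
        - params.mu2 * Sp
    )
    cr = capture_rates(Sg, Ig, Ip, params)
    dZ = cr.flux_susceptible + cr.flux_core - params.mu3 * Z
    return (dSg, dIg, dSp, dIp, dZ)


def z_equilibrium(Sg: float, Ig: float, Ip: float, params: ModelParameters) -> float:
    """Slaved justice-system occupancy: total capture flux over mu3.

    This is the unique Z with dZ/dt = 0 at fixed (Sg, Ig, Ip).
    """
    if params.mu3 <= 0:
        raise ValueError("mu3 must be positive to slave Z")
    cr = capture_rates(Sg, Ig, Ip, params)
    return (cr.flux_susceptible + cr.flux_core) / params.mu3


def ng_logistic_residual(Sg: float, Ig: float, params: ModelParameters) -> float:
    """Auxiliary logistic expression (b-mu1)*Ng - Ng^2/K for Ng = Sg + Ig.

    Diagnostic only: it is NOT the sum of the two gang equations whenever
    capture flux is nonzero — it omits predation losses.  The difference
    (sum of gang rates) - (this expression) equals minus the total capture
    flux, an identity exercised in the tests.
    """
    Ng = Sg + Ig
    return (params.b - params.mu1) * Ng - Ng * Ng / params.K
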