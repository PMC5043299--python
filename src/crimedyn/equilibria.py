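"""Equilibria of the reduced system.

Five families of steady states:

* E0 — extinction: no gang members, no corrupt police.
* E1 — criminal-free with endemic corruption: Ip = Omega*P, requires
  beta3 > mu2.
* E2 — core-free and corruption-free: Sg > 0 solves a quadratic (the
  logistic growth balanced against predation), Ig = Ip = 0.
* E3 — core-free with endemic corruption: same quadratic with the
  effective predator abundance P - (1-r)*Omega*P.
* E4 — coexistence: all compartments positive.  Solved two independent
  ways that must agree: (A) bracketed root finding in Ip on the per-capita
  core-growth residual, and (B) the real roots of a quartic in Ip obtained
  by polynomial elimination.

At coexistence the corrupt-police balance gives
``Ig = ((mu2*P - beta3*(P-Ip)) / (beta2*(P-Ip))) * Ip`` (positive exactly
when Ip > Omega*P), and equating the per-capita growth of the two gang
compartments forces ``Sg = b*Ig/(beta1 - b)`` (possible only when
beta1 > b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.optimize import brentq

from .dynamics import StateFull, StateReduced, rhs_full, z_equilibrium
from .parameters import ModelParameters, derive

__all__ = [
    "EquilibriumRecord",
    "equilibrium_E0",
    "equilibrium_E1",
    "equilibrium_E2",
    "equilibrium_E3",
    "ig_of_ip",
    "sg_of_ig",
    "coexistence_quartic_coefficients",
    "equilibrium_E4",
    "find_all_equilibria",
    "round_half_away",
]

#: Relative residual tolerance for admissible records.
RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class EquilibriumRecord:
    """A labelled equilibrium with its full state and fixed-point residual."""

    label: str
    state: StateFull
    residual_norm: float
    admissible: bool

    def rounded(self) -> tuple[int, int, int, int, int]:
        """State rounded to whole persons (half away from zero)."""
        return tuple(round_half_away(x) for x in self.state)  # type: ignore[return-value]


def round_half_away(x: float) -> int:
    """Round to nearest integer with ties away from zero."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _residual_norm(state: StateFull, params: ModelParameters) -> float:
    return max(abs(v) for v in rhs_full(state, params))


def _record(label: str, state: StateFull, params: ModelParameters, admissible: bool) -> EquilibriumRecord:
    res = _residual_norm(state, params)
    if admissible:
        scale = max(abs(v) for v in state)
        if res >= RESIDUAL_TOL * (1.0 + scale):
            raise RuntimeError(
                f"{label} residual {res:.3e} exceeds tolerance at state {state}"
            )
    return EquilibriumRecord(label=label, state=state, residual_norm=res, admissible=admissible)


def equilibrium_E0(params: ModelParameters) -> EquilibriumRecord:
    """Extinction state (0, 0, P, 0, 0); always an equilibrium."""
    state = StateFull(0.0, 0.0, params.P, 0.0, 0.0)
    return _record("E0", state, params, admissible=True)


def equilibrium_E1(params: ModelParameters) -> EquilibriumRecord:
    """Criminal-free state with endemic corruption, Ip = Omega*P.

    Inadmissible (flagged, not raised) when beta3 <= mu2: corruption cannot
    sustain itself without gang members.
    """
    d = derive(params)
    if d.Omega is None:
        state = StateFull(0.0, 0.0, params.P, 0.0, 0.0)
        return EquilibriumRecord("E1", state, _residual_norm(state, params), admissible=False)
    Ip = d.Omega * params.P
    state = StateFull(0.0, 0.0, params.P - Ip, Ip, 0.0)
    return _record("E1", state, params, admissible=True)


def _core_free_roots(params: ModelParameters, peff: float) -> list[float]:
    """Positive admissible Sg roots of ((b-mu1) - Sg/K)*(1 + h*Sg - c*P) = a'*peff."""
    d = derive(params)
    # quadratic in Sg, ascending coefficients
    poly = npoly.polymul(
        [params.b - params.mu1, -1.0 / params.K],
        [1.0 - params.c * params.P, d.h],
    )
    poly = npoly.polysub(poly, [d.a_prime * peff])
    roots = npoly.polyroots(poly)
    out = []
    for z in roots:
        if abs(z.imag) > 1e-9:
            continue
        Sg = float(z.real)
        denom = 1.0 + d.h * Sg - params.c * params.P
        if Sg > 0 and denom > 0 and Sg <= (params.b - params.mu1) * params.K:
            out.append(Sg)
    return sorted(out)


def _core_free_record(label: str, Sg: float, Ip: float, params: ModelParameters) -> EquilibriumRecord:
    Z = ((params.b - params.mu1) * Sg - Sg * Sg / params.K) / params.mu3
    state = StateFull(Sg, 0.0, params.P - Ip, Ip, Z)
    return _record(label, state, params, admissible=True)


def equilibrium_E2(params: ModelParameters) -> list[EquilibriumRecord]:
    """Core-free, corruption-free states (Ig = Ip = 0, Sg > 0)."""
    return [
        _core_free_record("E2", Sg, 0.0, params)
        for Sg in _core_free_roots(params, peff=params.P)
    ]


def equilibrium_E3(params: ModelParameters) -> list[EquilibriumRecord]:
    """Core-free states with endemic corruption (Ig = 0, Ip = Omega*P).

    Empty when beta3 <= mu2.  With r = 1 the effective predator abundance
    equals P and E3 coincides with E2.
    """
    d = derive(params)
    if d.Omega is None:
        return []
    Ip = d.Omega * params.P
    peff = params.P - (1.0 - params.r) * Ip
    return [_core_free_record("E3", Sg, Ip, params) for Sg in _core_free_roots(params, peff)]


def ig_of_ip(Ip: float, params: ModelParameters) -> float:
    """Core gang population forced by the corrupt-police balance at Ip.

    ``Ig = ((mu2*P - beta3*(P-Ip)) / (beta2*(P-Ip))) * Ip``; positive
    exactly when Ip > Omega*P.
    """
    if Ip >= params.P:
        raise ValueError(f"Ip must be < P = {params.P}, got {Ip}")
    if Ip < 0:
        raise ValueError(f"Ip must be nonnegative, got {Ip}")
    sp = params.P - Ip
    return (params.mu2 * params.P - params.beta3 * sp) / (params.beta2 * sp) * Ip


def sg_of_ig(Ig: float, params: ModelParameters) -> float:
    """Susceptible gang population at coexistence: Sg = b*Ig/(beta1 - b).

    Requires beta1 > b — otherwise recruitment cannot balance entry and no
    positive coexistence exists.
    """
    if params.beta1 <= params.b:
        raise ValueError(
            f"coexistence requires beta1 > b (got beta1={params.beta1}, b={params.b})"
        )
    if Ig < 0:
        raise ValueError(f"Ig must be nonnegative, got {Ig}")
    return params.b * Ig / (params.beta1 - params.b)


def _coexistence_residual(Ip: float, params: ModelParameters) -> float:
    """Per-capita growth residual of the core compartment at the forced
    (Sg(Ip), Ig(Ip), Ip); zero exactly at a coexistence equilibrium."""
    d = derive(params)
    Ig = ig_of_ip(Ip, params)
    Sg = sg_of_ig(Ig, params)
    Ng = Sg + Ig
    D = 1.0 + d.h * (Sg + params.lam * Ig) - params.c * params.P
    peff = params.P - (1.0 - params.r) * Ip
    return params.beta1 * Sg / Ng - Ng / params.K - d.a_prime * peff / D - params.mu1


def coexistence_quartic_coefficients(params: ModelParameters) -> np.ndarray:
    """Ascending coefficients of the quartic in Ip whose roots in
    (Omega*P, P) are the coexistence equilibria.

    Obtained by clearing denominators in the per-capita core balance: with
    k = b/(beta1-b), Ig = n(Ip)/d(Ip) where
    ``n = beta3*Ip^2 + (mu2-beta3)*P*Ip`` and ``d = beta2*(P-Ip)``, the
    capture denominator becomes q/d with
    ``q = (1-c*P)*d + h*(k+lam)*n``, and the balance times d*q is

        (b-mu1)*d*q - ((1+k)/K)*n*q - a'*(P-(1-r)*Ip)*d^2 = 0.

    (The recruitment term collapses: beta1*Sg/Ng = beta1*k/(1+k) = b.)
    """
    if params.beta1 <= params.b:
        raise ValueError("quartic defined only for beta1 > b")
    d0 = derive(params)
    k = params.b / (params.beta1 - params.b)
    n = np.array([0.0, (params.mu2 - params.beta3) * params.P, params.beta3])
    d = np.array([params.beta2 * params.P, -params.beta2])
    q = npoly.polyadd((1.0 - params.c * params.P) * d, d0.h * (k + params.lam) * n)
    poly = npoly.polysub(
        npoly.polysub(
            npoly.polymul((params.b - params.mu1) * d, q),
            npoly.polymul(((1.0 + k) / params.K) * n, q),
        ),
        d0.a_prime * npoly.polymul(
            np.array([params.P, -(1.0 - params.r)]), npoly.polymul(d, d)
        ),
    )
    return np.asarray(poly, dtype=float)


def _e4_window(params: ModelParameters) -> tuple[float, float]:
    """Open admissibility window (Omega*P + eps, P - eps) for the Ip root."""
    d = derive(params)
    assert d.Omega is not None
    eps = 1e-9 * params.P
    return d.Omega * params.P + eps, params.P - eps


def _e4_roots_bracketed(params: ModelParameters, n_grid: int = 400) -> list[float]:
    """Method A: sign-change scan + Brent refinement on the Ip window.

    The grid is uniform over the window plus geometrically refined near the
    lower edge, where the coexistence branch emerges from the core-free
    branch (Ig -> 0 as Ip -> Omega*P) and roots can sit arbitrarily close
    to the boundary.
    """
    lo, hi = _e4_window(params)
    if lo >= hi:
        return []
    base = lo - 1e-9 * params.P  # = Omega*P
    offsets = np.concatenate(
        [
            np.geomspace(lo - base, hi - base, n_grid // 2),
            np.linspace(lo - base, hi - base, n_grid),
        ]
    )
    grid = np.unique(base + offsets)
    vals = np.array([_coexistence_residual(x, params) for x in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(
                float(
                    brentq(
                        _coexistence_residual,
                        grid[i],
                        grid[i + 1],
                        args=(params,),
                        xtol=1e-13,
                        rtol=1e-14,
                    )
                )
            )
    return roots


def _e4_roots_quartic(params: ModelParameters) -> list[float]:
    """Method B: admissible real roots of the eliminated quartic.

    Each raw polynomial root is polished against the per-capita residual
    (the quartic's coefficients span many orders of magnitude, so raw roots
    carry rounding error near degeneracies).
    """
    lo, hi = _e4_window(params)
    coeffs = coexistence_quartic_coefficients(params)
    roots = npoly.polyroots(coeffs)
    out: list[float] = []
    for z in roots:
        if abs(z.imag) > 1e-7 * (1 + abs(z)):
            continue
        x = float(z.real)
        if not (lo - 1e-6 * (1 + abs(lo)) < x < hi):
            continue
        for width in (1e-9, 1e-7, 1e-5, 1e-3):
            w = width * (1.0 + abs(x))
            a, b = max(x - w, lo), min(x + w, hi)
            if a < b:
                fa, fb = _coexistence_residual(a, params), _coexistence_residual(b, params)
                if fa * fb <= 0:
                    x = float(
                        brentq(
                            _coexistence_residual, a, b, args=(params,),
                            xtol=1e-13, rtol=1e-14,
                        )
                    )
                    break
        if lo < x < hi:
            out.append(x)
    return sorted(out)


def _match_root_sets(
    roots_a: list[float], roots_b: list[float], params: ModelParameters
) -> list[float] | None:
    """Greedily match the two root lists to 1e-6 relative.

    Unmatched roots lying within numerical resolution of the window edges
    (where the coexistence branch exchanges with a boundary branch and the
    two methods can legitimately disagree about membership) are discarded;
    any other mismatch returns None.
    """
    lo, hi = _e4_window(params)
    band_lo = 1e-6 * (1.0 + abs(lo))
    band_hi = 1e-6 * (1.0 + abs(hi))
    a, b = sorted(roots_a), sorted(roots_b)
    matched: list[float] = []
    while a or b:
        if a and b and abs(a[0] - b[0]) <= 1e-6 * (1.0 + abs(b[0])):
            matched.append(a.pop(0))
            b.pop(0)
            continue
        # drop the smallest unmatched root if it hugs a window edge
        pool, x = (a, a[0]) if (not b or (a and a[0] <= b[0])) else (b, b[0])
        if abs(x - lo) <= band_lo or abs(x - hi) <= band_hi:
            pool.pop(0)
            continue
        return None
    return matched


def equilibrium_E4(params: ModelParameters) -> list[EquilibriumRecord]:
    """Coexistence equilibria, cross-validated between both solution paths.

    Empty when beta1 <= b or beta3 <= mu2.  Raises RuntimeError if the
    bracketed root-finder and the quartic disagree beyond 1e-6 relative —
    that would indicate an internal derivation error, not a property of the
    parameters.
    """
    d = derive(params)
    if params.beta1 <= params.b or d.Omega is None:
        return []
    roots_a = sorted(_e4_roots_bracketed(params))
    roots_b = _e4_roots_quartic(params)
    matched = _match_root_sets(roots_a, roots_b, params)
    if matched is None:
        raise RuntimeError(
            "coexistence solvers disagree: "
            f"bracketed {roots_a} vs quartic {roots_b}"
        )
    records = []
    for Ip in matched:
        Ig = ig_of_ip(Ip, params)
        Sg = sg_of_ig(Ig, params)
        state = StateReduced(Sg, Ig, Ip).to_full(params)
        records.append(_record("E4", state, params, admissible=True))
    return records


def find_all_equilibria(params: ModelParameters) -> list[EquilibriumRecord]:
    """All admissible equilibria E0..E4 for this parameter set."""
    out = [equilibrium_E0(params)]
    e1 = equilibrium_E1(params)
    if e1.admissible:
        out.append(e1)
    out.extend(equilibrium_E2(params))
    out.extend(equilibrium_E3(params))
    out.extend(equilibrium_E4(params))
    return out
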