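"""Transcritical bifurcation thresholds and parameter scans.

The long-run regime is labelled by the unique stable admissible
equilibrium.  Five parameters admit closed-form critical values at which
two equilibrium branches exchange stability (all transcritical — a single
real eigenvalue crosses zero, oscillatory onset being excluded at the
boundary equilibria):

* beta1 = b — core-free E3 gives way to coexistence E4;
* mu1 = b - a'*P*(1-Omega*(1-r))/(1-c*P) — coexistence gives way to the
  criminal-free E1;
* P = (b-mu1)/(a'*(1-Omega*(1-r)) + c*(b-mu1)) — enough officers eliminate
  the gang (E4 -> E1);
* a = U*(b-mu1)*(1-c*P)/(P*(1-Omega*(1-r))) — a high enough search rate
  eliminates the gang (E4 -> E1);
* b in (mu1 + a'*P*(1-Omega*(1-r))/(1-c*P), beta1) — the coexistence
  window: below it E1, above it E3.

Numerical scans recompute equilibria and eigenvalues on a grid and refine
detected regime changes by root finding on the stability margin, providing
an independent check of every closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibria import EquilibriumRecord, find_all_equilibria
from .parameters import ModelParameters, derive, validate, with_overrides
from .stability import stability_report

__all__ = [
    "BifurcationResult",
    "ScanTable",
    "critical_beta1",
    "critical_mu1",
    "critical_P",
    "critical_a",
    "critical_b",
    "closed_form_thresholds",
    "scan",
    "detect_transitions",
]

EQUILIBRIUM_LABELS = ("E0", "E1", "E2", "E3", "E4")


@dataclass(frozen=True)
class BifurcationResult:
    parameter: str
    critical_value: float
    regime_below: str
    regime_above: str
    method: str  # "closed_form" | "scan"
    bifurcation_type: str = "transcritical"


@dataclass
class ScanTable:
    """Grid of parameter values with per-equilibrium stability margins.

    ``frame`` has one row per grid value with columns ``value``,
    ``max_real_<label>`` (largest eigenvalue real part of the most stable
    admissible record of that label, NaN when absent) and ``regime``
    (label of the unique stable equilibrium, else ``indeterminate``).
    """

    parameter: str
    frame: pd.DataFrame = field(repr=False)

    def to_csv(self, path_or_buf) -> None:
        # %.17g guarantees float64 values survive the text round trip
        self.frame.to_csv(path_or_buf, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, parameter: str, path_or_buf) -> "ScanTable":
        return cls(
            parameter=parameter,
            frame=pd.read_csv(path_or_buf, float_precision="round_trip"),
        )

    def transitions_bracketed(self) -> list[tuple[float, float, str, str]]:
        """(lo, hi, regime_lo, regime_hi) for consecutive determinate rows
        whose regime labels differ."""
        rows = self.frame[self.frame["regime"] != "indeterminate"]
        out = []
        prev = None
        for _, row in rows.iterrows():
            if prev is not None and row["regime"] != prev["regime"]:
                out.append(
                    (float(prev["value"]), float(row["value"]), prev["regime"], row["regime"])
                )
            prev = row
        return out


def _omega_terms(params: ModelParameters) -> tuple[float, float]:
    d = derive(params)
    if d.Omega is None:
        raise ValueError("threshold requires beta3 > mu2 (endemic corrupt fraction defined)")
    return d.a_prime, 1.0 - d.Omega * (1.0 - params.r)


def critical_beta1(params: ModelParameters) -> float:
    """Recruitment threshold: the core-free branch is stable for beta1 < b,
    coexistence takes over above.  Equals b."""
    return params.b


def critical_mu1(params: ModelParameters) -> float:
    """Gang exit rate above which the criminal-free state E1 is stable:
    mu1 > b - a'*P*(1-Omega*(1-r))/(1-c*P)."""
    ap, peff_frac = _omega_terms(params)
    return params.b - ap * params.P * peff_frac / (1.0 - params.c * params.P)


def critical_P(params: ModelParameters) -> float:
    """Police force size above which the gang is eliminated (E1 stable):
    the E1 threshold solved as an equality for P."""
    ap, peff_frac = _omega_terms(params)
    if params.b <= params.mu1:
        raise ValueError("critical_P requires b > mu1")
    denom = ap * peff_frac + params.c * (params.b - params.mu1)
    if denom <= 0:
        raise ValueError("nonpositive denominator in critical_P")
    return (params.b - params.mu1) / denom


def critical_a(params: ModelParameters) -> float:
    """Search rate above which the gang is eliminated (E1 stable)."""
    _, peff_frac = _omega_terms(params)
    return (
        params.U
        * (params.b - params.mu1)
        * (1.0 - params.c * params.P)
        / (params.P * peff_frac)
    )


def critical_b(params: ModelParameters) -> tuple[float, float]:
    """Coexistence window in the gang entry rate: (lower, upper).

    Below the lower value predation wins and E1 is stable; above the upper
    value (= beta1) recruitment cannot keep up and E3 takes over.
    """
    ap, peff_frac = _omega_terms(params)
    lower = params.mu1 + ap * params.P * peff_frac / (1.0 - params.c * params.P)
    return (lower, params.beta1)


def closed_form_thresholds(params: ModelParameters) -> list[BifurcationResult]:
    """All closed-form transcritical points at this parameter set."""
    b_lo, b_hi = critical_b(params)
    return [
        BifurcationResult("beta1", critical_beta1(params), "E3", "E4", "closed_form"),
        BifurcationResult("mu1", critical_mu1(params), "E4", "E1", "closed_form"),
        BifurcationResult("P", critical_P(params), "E4", "E1", "closed_form"),
        BifurcationResult("a", critical_a(params), "E4", "E1", "closed_form"),
        BifurcationResult("b", b_lo, "E1", "E4", "closed_form"),
        BifurcationResult("b", b_hi, "E4", "E3", "closed_form"),
    ]


def _stability_margins(params: ModelParameters) -> tuple[dict[str, float], str]:
    """Per-label best stability margin and the regime label at ``params``."""
    records = find_all_equilibria(params)
    margins: dict[str, float] = {}
    stable: list[EquilibriumRecord] = []
    any_marginal = False
    for rec in records:
        rep = stability_report(
            (rec.state.Sg, rec.state.Ig, rec.state.Ip), params, label=rec.label
        )
        prev = margins.get(rec.label)
        if prev is None or rep.max_real < prev:
            margins[rec.label] = rep.max_real
        if rep.classification == "stable":
            stable.append(rec)
        elif rep.classification == "marginal":
            any_marginal = True
    regime = stable[0].label if len(stable) == 1 and not any_marginal else "indeterminate"
    return margins, regime


def scan(
    parameter_name: str,
    lo: float,
    hi: float,
    n_points: int,
    params: ModelParameters,
) -> ScanTable:
    """Equilibria and stability on a uniform grid over one parameter."""
    if not lo < hi:
        raise ValueError(f"scan range must satisfy lo < hi, got [{lo}, {hi}]")
    if n_points < 3:
        raise ValueError(f"scan needs at least 3 grid points, got {n_points}")
    if parameter_name not in ModelParameters.__dataclass_fields__:
        raise ValueError(f"unknown parameter {parameter_name!r}")
    rows = []
    for value in np.linspace(lo, hi, n_points):
        p = with_overrides(params, **{parameter_name: float(value)})
        problems = validate(p)
        if problems:
            raise ValueError(
                f"{parameter_name} = {value} leaves validity: " + "; ".join(problems)
            )
        margins, regime = _stability_margins(p)
        row = {"value": float(value), "regime": regime}
        for lbl in EQUILIBRIUM_LABELS:
            row[f"max_real_{lbl}"] = margins.get(lbl, np.nan)
        rows.append(row)
    cols = ["value"] + [f"max_real_{l}" for l in EQUILIBRIUM_LABELS] + ["regime"]
    return ScanTable(parameter=parameter_name, frame=pd.DataFrame(rows, columns=cols))


def _margin_of_label(
    params: ModelParameters, parameter_name: str, value: float, label: str
) -> float | None:
    p = with_overrides(params, **{parameter_name: float(value)})
    margins, _ = _stability_margins(p)
    m = margins.get(label)
    return None if m is None or np.isnan(m) else m


def detect_transitions(table: ScanTable, params: ModelParameters) -> list[BifurcationResult]:
    """Refine every regime change in ``table`` to a critical parameter value.

    For each bracketing pair of grid rows, a bridging equilibrium label —
    one admissible on both sides whose stability margin changes sign — is
    located and its margin driven to zero by Brent's method (absolute
    tolerance 1e-8 on the parameter).  A bracket with no sign-changing
    bridge is reported as an error rather than guessed at.
    """
    name = table.parameter
    results = []
    for lo, hi, reg_lo, reg_hi in table.transitions_bracketed():
        bridge = None
        candidates = [reg_hi, reg_lo] + [l for l in EQUILIBRIUM_LABELS if l not in (reg_lo, reg_hi)]
        for lbl in candidates:
            m_lo = _margin_of_label(params, name, lo, lbl)
            m_hi = _margin_of_label(params, name, hi, lbl)
            if m_lo is not None and m_hi is not None and m_lo * m_hi < 0:
                bridge = lbl
                break
        if bridge is None:
            raise RuntimeError(
                f"no sign-changing equilibrium branch bridges [{lo}, {hi}] "
                f"for {name} ({reg_lo} -> {reg_hi})"
            )
        critical = float(
            brentq(
                lambda v: _margin_of_label(params, name, v, bridge),
                lo,
                hi,
                xtol=1e-10,
                rtol=8.9e-16,
            )
        )
        results.append(
            BifurcationResult(name, critical, reg_lo, reg_hi, method="scan")
        )
    return results
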