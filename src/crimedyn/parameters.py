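"""Model parameters: definition, validation, derived quantities, sampling, config I/O.

The model couples a gang population (prey) and a constant-size police force
(predator), each split into susceptible and "infected" (committed / corrupt)
compartments, with police capturing gang members through a cooperative
Beddington-De Angelis functional response.  All rates are per unit time;
populations are persons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "DerivedParameters",
    "make_default_parameters",
    "validate",
    "derive",
    "sample_parameters",
    "with_overrides",
    "load_config",
    "DEFAULT_SAMPLING_BOUNDS",
]


@dataclass(frozen=True)
class ModelParameters:
    """Full rate/shape parameter set of the police-gang model.

    Attributes
    ----------
    b : gang entry rate (per unit time).
    mu1 : gang exit rate.
    mu2 : police exit rate.
    mu3 : justice-system processing rate.
    gamma : police entry rate; constrained equal to ``mu2`` (constant force).
    beta1 : recruitment rate of susceptible youth into the committed core.
    beta2 : corruption rate of susceptible police by core gang members.
    beta3 : corruption rate of susceptible police by corrupt police.
    a : police search/attack rate.
    U : police team size (count, >= 1).
    r : hunting-efficiency factor of corrupt police, in [0, 1].
    lam : handling-time multiplier for core members (core members take
        ``lam`` times as long to process as susceptible ones).
    t_h : handling time per captured gang member.
    c : cooperation/communication time saving coefficient (= b'*t_c,
        supplied directly as a single parameter).
    K : gang carrying-capacity parameter (persons).
    P : constant police force size (persons).
    """

    b: float = 0.2
    mu1: float = 0.12
    mu2: float = 0.0476
    mu3: float = 0.2
    gamma: float = 0.0476
    beta1: float = 0.21
    beta2: float = 0.105
    beta3: float = 0.0525
    a: float = 0.001
    U: float = 10.0
    r: float = 0.75
    lam: float = 1.5
    t_h: float = 0.01
    c: float = 0.001
    K: float = 50000.0
    P: float = 300.0


@dataclass(frozen=True)
class DerivedParameters:
    """Quantities derived from :class:`ModelParameters`.

    ``h = a*t_h`` is the composite handling coefficient, ``a_prime = a/U``
    the per-officer attack coefficient, ``Omega = (beta3-mu2)/beta3`` the
    endemic corrupt fraction of the force (defined only when beta3 > mu2,
    else ``None``), and ``k_cap = (b-mu1)*K`` the logistic fixed point of
    the total gang population in the absence of predation.
    """

    h: float
    a_prime: float
    Omega: float | None
    k_cap: float

    @property
    def omega_defined(self) -> bool:
        return self.Omega is not None


def make_default_parameters() -> ModelParameters:
    """Return the base parameter set used for all numerical results."""
    return ModelParameters()


def validate(params: ModelParameters) -> list[str]:
    """Check every invariant; return a list of violation descriptions.

    An empty list means the parameter set is admissible.  Reporting rather
    than raising lets callers surface all problems at once.
    """
    v: list[str] = []
    for f in fields(params):
        x = getattr(params, f.name)
        if not math.isfinite(x):
            v.append(f"{f.name} must be finite, got {x}")
        elif x < 0:
            v.append(f"{f.name} must be nonnegative, got {x}")
    if params.U < 1:
        v.append(f"U must be >= 1 (team size), got {params.U}")
    if not (0 <= params.r <= 1):
        v.append(f"r must lie in [0, 1], got {params.r}")
    if params.K <= 0:
        v.append(f"K must be positive, got {params.K}")
    if params.P <= 0:
        v.append(f"P must be positive, got {params.P}")
    if params.c * params.P >= 1:
        v.append(
            "c*P must be < 1 (cooperation saving may not exceed total "
            f"effort with no gang members present): c*P = {params.c * params.P}"
        )
    if not math.isclose(params.gamma, params.mu2, rel_tol=1e-12, abs_tol=1e-15):
        v.append(
            "gamma must equal mu2 (constant police force): "
            f"gamma = {params.gamma}, mu2 = {params.mu2}"
        )
    return v


def derive(params: ModelParameters) -> DerivedParameters:
    """Compute derived coefficients; requires ``validate(params) == []``."""
    Omega = (params.beta3 - params.mu2) / params.beta3 if params.beta3 > params.mu2 else None
    return DerivedParameters(
        h=params.a * params.t_h,
        a_prime=params.a / params.U,
        Omega=Omega,
        k_cap=(params.b - params.mu1) * params.K,
    )


def with_overrides(params: ModelParameters, **overrides: float) -> ModelParameters:
    """Copy with fields replaced, keeping gamma slaved to mu2."""
    new = replace(params, **overrides)
    if "mu2" in overrides and "gamma" not in overrides:
        new = replace(new, gamma=new.mu2)
    return new


# Sampling intervals around the base values, chosen so every draw stays in
# a regime where the capture denominator is positive and all invariants hold.
DEFAULT_SAMPLING_BOUNDS: dict[str, tuple[float, float]] = {
    "b": (0.05, 0.4),
    "mu1": (0.02, 0.3),
    "mu2": (0.01, 0.1),
    "mu3": (0.05, 0.5),
    "beta1": (0.05, 0.5),
    "beta2": (0.02, 0.3),
    "beta3": (0.01, 0.15),
    "a": (1e-4, 5e-3),
    "U": (1.0, 30.0),
    "r": (0.0, 1.0),
    "lam": (1.0, 3.0),
    "t_h": (1e-3, 5e-2),
    "c": (1e-4, 2e-3),
    "K": (1e4, 1e5),
    "P": (100.0, 490.0),
}


def sample_parameters(
    seed: int,
    n: int,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> list[ModelParameters]:
    """Draw ``n`` valid parameter sets uniformly within ``bounds``.

    Reproducible given ``seed``; ``gamma`` is always set to the drawn
    ``mu2``.  Draws violating an invariant (e.g. ``c*P >= 1`` for an
    unlucky corner of the box) are rejected and redrawn.

    Raises
    ------
    ValueError
        If the bounds are unsatisfiable (rejection does not terminate).
    """
    box = dict(DEFAULT_SAMPLING_BOUNDS)
    if bounds:
        unknown = set(bounds) - set(box)
        if unknown:
            raise ValueError(f"unknown bound keys: {sorted(unknown)}")
        box.update(bounds)
    rng = np.random.default_rng(seed)
    out: list[ModelParameters] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 1000 * n + 1000:
            raise ValueError("sampling bounds appear unsatisfiable")
        draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in box.items()}
        draw["gamma"] = draw["mu2"]
        p = ModelParameters(**draw)
        if not validate(p):
            out.append(p)
    return out


def load_config(path: str | Path) -> ModelParameters:
    """Load a YAML or JSON config mapping parameter names to values.

    Missing keys fall back to the base defaults; unknown keys are an error.
    If ``mu2`` is given without ``gamma``, ``gamma`` is slaved to it.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(ModelParameters)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    params = with_overrides(make_default_parameters(), **{k: float(v) for k, v in data.items()})
    problems = validate(params)
    if problems:
        raise ValueError(f"invalid configuration {path}: " + "; ".join(problems))
    return params
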