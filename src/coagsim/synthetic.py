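"""Synthetic fixtures: toy networks with closed-form equilibria, perturbed
parameter ensembles, and synthetic thrombin curves.

These generators make every pipeline stage testable without any external
data: the toy binding network validates the integrator against an analytic
equilibrium, log-normal ensembles drive robustness checks, and logistic
thrombin curves exercise the lag-time metric against a closed-form
crossing time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace, fields as dc_fields
import math

import numpy as np

from .flow import LagTime, ThrombinTimecourse
from .reaction_system import (
    MassActionReaction,
    ReactionNetwork,
    SpeciesDecl,
    Trajectory,
)

__all__ = [
    "ToyBindingSpec",
    "make_toy_binding",
    "perturb_parameters",
    "synthetic_thrombin_curve",
]


@dataclass(frozen=True)
class ToyBindingSpec:
    """A + B <-> AB with rates in internal units (nM^-1 s^-1, s^-1)."""

    k_on: float = 1e-3
    k_off: float = 1e-2
    A0: float = 10.0
    B0: float = 5.0

    def __post_init__(self):
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rates must be positive")
        if self.A0 < 0 or self.B0 < 0:
            raise ValueError("initial concentrations must be non-negative")

    @property
    def analytic_AB_eq(self) -> float:
        """Root of ``(A0-x)(B0-x) k_on = x k_off`` in ``[0, min(A0, B0)]``."""
        kd = self.k_off / self.k_on
        b = self.A0 + self.B0 + kd
        disc = b * b - 4.0 * self.A0 * self.B0
        x = 0.5 * (b - math.sqrt(disc))
        return min(max(x, 0.0), min(self.A0, self.B0))


def make_toy_binding(spec: ToyBindingSpec) -> tuple[ReactionNetwork, float]:
    """Build the toy network and return it with its analytic equilibrium."""
    net = ReactionNetwork(
        [
            SpeciesDecl("A", "plasma", spec.A0),
            SpeciesDecl("B", "plasma", spec.B0),
            SpeciesDecl("AB", "plasma", 0.0),
        ],
        [
            MassActionReaction(
                "bind", (("A", 1), ("B", 1)), (("AB", 1),),
                k_forward=spec.k_on, k_reverse=spec.k_off,
            )
        ],
        conserved_pools={"A_total": {"A": 1, "AB": 1}, "B_total": {"B": 1, "AB": 1}},
    )
    return net, spec.analytic_AB_eq


def perturb_parameters(base, rel_sigma: float, seed: int, n: int = 10):
    """Log-normal multiplicative perturbations of a parameter dataclass.

    Every positive float field is multiplied by ``exp(sigma * z)`` with
    ``z ~ N(0, 1)``; zeros (structural absences) are preserved.  The seed is
    mandatory — reproducibility is part of the contract.
    """
    if not (0.0 < rel_sigma <= 0.5):
        raise ValueError("rel_sigma must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    out = []
    float_fields = [
        f.name for f in dc_fields(base)
        if isinstance(getattr(base, f.name), (int, float))
        and not isinstance(getattr(base, f.name), bool)
    ]
    for _ in range(n):
        changes = {}
        for name in float_fields:
            v = getattr(base, name)
            if v > 0:
                changes[name] = v * math.exp(rel_sigma * rng.standard_normal())
        out.append(dc_replace(base, **changes))
    return out


def synthetic_thrombin_curve(
    lag_min: float,
    ceiling_nM: float = 250.0,
    steepness: float = 1.0,
    duration_min: float = 40.0,
    dt_s: float = 1.0,
    threshold: float = 1.0,
) -> ThrombinTimecourse:
    """Logistic thrombin curve whose analytic 1 nM crossing equals ``lag_min``.

    ``x(t) = ceiling / (1 + exp(-steepness (t - t0)))`` with ``t0`` chosen so
    that ``x(lag_min) = threshold`` exactly (when the ceiling exceeds the
    threshold; otherwise the curve never crosses and the lag is censored).
    """
    if not (0.0 < lag_min < duration_min):
        raise ValueError("lag must lie inside the simulated window")
    t = np.arange(0.0, duration_min * 60.0 + dt_s, dt_s)
    t_min = t / 60.0
    if ceiling_nM > threshold:
        t0 = lag_min + math.log(ceiling_nM / threshold - 1.0) / steepness
    else:
        t0 = duration_min * 10.0  # pushed far out: never crosses
    z = np.clip(-steepness * (t_min - t0), -700.0, 700.0)
    x = ceiling_nM / (1.0 + np.exp(z))
    traj = Trajectory(t, x[:, None], ["IIa"])
    return ThrombinTimecourse(traj, "IIa", duration_min, threshold=threshold)
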