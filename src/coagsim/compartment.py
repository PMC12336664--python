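"""Well-mixed compartment model of concizumab binding TFPIα and TFPIβ.

Concizumab (C) is a bivalent antibody against the Kunitz-2 domain of TFPI.
Each molecule can engage one or two TFPIα molecules in plasma, one TFPIβ on
the endothelium, or bridge one of each, sequestering plasma TFPIα onto the
endothelial surface as the ternary complex TFPIα:C:TFPIβ.  Five reversible
reactions describe this:

    C1  C + TFPIα            <->  C:TFPIα              (kα)
    C2  C:TFPIα + TFPIα      <->  TFPIα:C:TFPIα        (kα)
    C3  C + TFPIβ            <->  C:TFPIβ              (kβ)
    C4  C:TFPIα + TFPIβ      <->  TFPIα:C:TFPIβ        (kβ)
    C5  TFPIα + C:TFPIβ      <->  TFPIα:C:TFPIβ        (kα)

The model answers: for a given total intravascular dose of concizumab, how
much drug remains in plasma (free plus TFPIα-bound) at steady state, and how
is TFPIα partitioned?  The *plasma* concizumab pool is free C + C:TFPIα +
TFPIα:C:TFPIα; dose inversion finds the intravascular dose producing a
clinically observed plasma level (4 nM).

Steady state follows the "negligible change over a trailing five-minute
window" rule; see :func:`coagsim.reaction_system.find_steady_state` and the
methods note for why the default threshold is an absolute 0.2 nM.  The slow
internal redistribution between TFPIα:C:TFPIα and TFPIα:C:TFPIβ continues
for hours beyond this point without materially moving the plasma pools.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .reaction_system import (
    MassActionReaction,
    ReactionNetwork,
    SpeciesDecl,
    conserved_totals,
    find_steady_state,
)

__all__ = [
    "CompartmentParams",
    "SteadyStatePartition",
    "build_compartment_network",
    "steady_state_partition",
    "dose_sweep",
    "find_dose_for_plasma_target",
    "flow_inputs_from_partition",
    "SPECIES_ORDER",
]

SPECIES_ORDER = ("C", "TFPIa", "TFPIb", "C:TFPIa", "TFPIa:C:TFPIa", "C:TFPIb", "TFPIa:C:TFPIb")


@dataclass(frozen=True)
class CompartmentParams:
    """Rates (literature scale, M^-1 s^-1 / s^-1) and totals (nM)."""

    ka_on: float = 4.48e6
    ka_off: float = 1e-4
    kb_on: float = 8.21e5
    kb_off: float = 1e-4
    total_TFPIa: float = 2.5
    total_TFPIb: float = 18.0
    dose: float = 0.0

    def __post_init__(self):
        for r in (self.ka_on, self.ka_off, self.kb_on, self.kb_off):
            if r <= 0:
                raise ValueError("all rate constants must be > 0")
        if self.total_TFPIa < 0 or self.total_TFPIb < 0 or self.dose < 0:
            raise ValueError("concentrations must be >= 0")

    @property
    def kd_alpha_pm(self) -> float:
        """Concizumab-TFPIα dissociation constant in pM."""
        return self.ka_off / self.ka_on * 1e12

    @property
    def kd_beta_pm(self) -> float:
        return self.kb_off / self.kb_on * 1e12

    def with_kd(self, kd_alpha_pm: float | None = None, kd_beta_pm: float | None = None,
                mode: str = "on") -> "CompartmentParams":
        """Realize new K_D values by scaling one rate of each pair.

        ``mode='on'`` (default) varies the association rate holding the
        dissociation rate fixed; ``mode='off'`` varies the dissociation rate.
        """
        p = self
        if kd_alpha_pm is not None:
            if mode == "on":
                p = replace(p, ka_on=p.ka_off / (kd_alpha_pm * 1e-12))
            else:
                p = replace(p, ka_off=p.ka_on * kd_alpha_pm * 1e-12)
        if kd_beta_pm is not None:
            if mode == "on":
                p = replace(p, kb_on=p.kb_off / (kd_beta_pm * 1e-12))
            else:
                p = replace(p, kb_off=p.kb_on * kd_beta_pm * 1e-12)
        return p


@dataclass(frozen=True)
class SteadyStatePartition:
    """Steady-state concentrations (nM) of all concizumab/TFPI pools."""

    free_C: float
    free_TFPIa: float
    free_TFPIb: float
    C_TFPIa: float
    TFPIa_C_TFPIa: float
    C_TFPIb: float
    TFPIa_C_TFPIb: float
    dose: float
    total_TFPIa: float
    total_TFPIb: float
    converged: bool
    time_to_steady: float

    @property
    def total_plasma_C(self) -> float:
        """Free C plus C bound to one or two plasma TFPIα molecules."""
        return self.free_C + self.C_TFPIa + self.TFPIa_C_TFPIa

    @property
    def C_bound_plasma_TFPIa(self) -> float:
        """Concizumab molecules carrying plasma TFPIα only (C:TFPIα + TFPIα:C:TFPIα)."""
        return self.C_TFPIa + self.TFPIa_C_TFPIa

    @property
    def sequestered_TFPIa_fraction(self) -> float:
        if self.total_TFPIa == 0:
            return 0.0
        return self.TFPIa_C_TFPIb / self.total_TFPIa

    @property
    def plasma_TFPIa_pool(self) -> float:
        """TFPIα molecules in plasma: free + C:TFPIα + 2·TFPIα:C:TFPIα."""
        return self.free_TFPIa + self.C_TFPIa + 2 * self.TFPIa_C_TFPIa

    def as_dict(self) -> dict[str, float]:
        d = {
            "free_C": self.free_C,
            "free_TFPIa": self.free_TFPIa,
            "free_TFPIb": self.free_TFPIb,
            "C_TFPIa": self.C_TFPIa,
            "TFPIa_C_TFPIa": self.TFPIa_C_TFPIa,
            "C_TFPIb": self.C_TFPIb,
            "TFPIa_C_TFPIb": self.TFPIa_C_TFPIb,
            "total_plasma_C": self.total_plasma_C,
            "C_bound_plasma_TFPIa": self.C_bound_plasma_TFPIa,
            "sequestered_TFPIa_fraction": self.sequestered_TFPIa_fraction,
            "dose": self.dose,
            "time_to_steady_s": self.time_to_steady,
            "converged": self.converged,
        }
        return d


def build_compartment_network(params: CompartmentParams) -> ReactionNetwork:
    """Seven species, five reversible reactions, three conserved pools."""
    sp = [
        SpeciesDecl("C", "plasma", params.dose),
        SpeciesDecl("TFPIa", "plasma", params.total_TFPIa),
        SpeciesDecl("TFPIb", "endothelium", params.total_TFPIb),
        SpeciesDecl("C:TFPIa", "plasma", 0.0),
        SpeciesDecl("TFPIa:C:TFPIa", "plasma", 0.0),
        SpeciesDecl("C:TFPIb", "endothelium", 0.0),
        SpeciesDecl("TFPIa:C:TFPIb", "endothelium", 0.0),
    ]
    mk = MassActionReaction.from_molar
    rxns = [
        mk("C1", [("C", 1), ("TFPIa", 1)], [("C:TFPIa", 1)], params.ka_on, params.ka_off),
        mk("C2", [("C:TFPIa", 1), ("TFPIa", 1)], [("TFPIa:C:TFPIa", 1)], params.ka_on, params.ka_off),
        mk("C3", [("C", 1), ("TFPIb", 1)], [("C:TFPIb", 1)], params.kb_on, params.kb_off),
        mk("C4", [("C:TFPIa", 1), ("TFPIb", 1)], [("TFPIa:C:TFPIb", 1)], params.kb_on, params.kb_off),
        mk("C5", [("TFPIa", 1), ("C:TFPIb", 1)], [("TFPIa:C:TFPIb", 1)], params.ka_on, params.ka_off),
    ]
    pools = {
        "concizumab": {
            "C": 1, "C:TFPIa": 1, "TFPIa:C:TFPIa": 1, "C:TFPIb": 1, "TFPIa:C:TFPIb": 1,
        },
        "TFPIa": {"TFPIa": 1, "C:TFPIa": 1, "TFPIa:C:TFPIa": 2, "TFPIa:C:TFPIb": 1},
        "TFPIb": {"TFPIb": 1, "C:TFPIb": 1, "TFPIa:C:TFPIb": 1},
    }
    return ReactionNetwork(sp, rxns, pools)


def steady_state_partition(params: CompartmentParams, **ss_kwargs) -> SteadyStatePartition:
    """Run the compartment network to steady state and report all pools.

    Keyword arguments are passed to
    :func:`coagsim.reaction_system.find_steady_state` (e.g. ``abs_tol``,
    ``horizon``).
    """
    net = build_compartment_network(params)
    state, t_ss = find_steady_state(net, **ss_kwargs)
    state = np.clip(state, 0.0, None)
    vals = dict(zip(SPECIES_ORDER, state))
    return SteadyStatePartition(
        free_C=vals["C"],
        free_TFPIa=vals["TFPIa"],
        free_TFPIb=vals["TFPIb"],
        C_TFPIa=vals["C:TFPIa"],
        TFPIa_C_TFPIa=vals["TFPIa:C:TFPIa"],
        C_TFPIb=vals["C:TFPIb"],
        TFPIa_C_TFPIb=vals["TFPIa:C:TFPIb"],
        dose=params.dose,
        total_TFPIa=params.total_TFPIa,
        total_TFPIb=params.total_TFPIb,
        converged=True,
        time_to_steady=t_ss,
    )


def dose_sweep(params: CompartmentParams, doses, **ss_kwargs) -> pd.DataFrame:
    """Steady-state partitions across intravascular doses (one row each)."""
    rows = []
    for d in doses:
        part = steady_state_partition(replace(params, dose=float(d)), **ss_kwargs)
        rows.append(part.as_dict())
    return pd.DataFrame(rows)


def find_dose_for_plasma_target(
    params: CompartmentParams,
    target: float = 4.0,
    bracket: tuple[float, float] = (0.0, 30.0),
    tol: float = 0.01,
    **ss_kwargs,
) -> float:
    """Bisect the monotone dose -> plasma-concizumab map for ``target``.

    Returns the intravascular dose whose steady-state plasma concizumab pool
    equals ``target`` to within the dose tolerance ``tol`` (nM).
    """
    lo, hi = bracket

    def plasma(dose: float) -> float:
        if dose == 0.0:
            return 0.0
        return steady_state_partition(replace(params, dose=dose), **ss_kwargs).total_plasma_C

    if target == 0.0:
        return 0.0
    f_lo, f_hi = plasma(lo) - target, plasma(hi) - target
    if f_lo * f_hi > 0:
        raise ValueError(
            f"target {target} nM not bracketed by doses {bracket} "
            f"(plasma range [{f_lo + target:.3g}, {f_hi + target:.3g}] nM)"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if (plasma(mid) - target) * f_lo <= 0:
            hi = mid
        else:
            lo, f_lo = mid, plasma(mid) - target
    return 0.5 * (lo + hi)


def flow_inputs_from_partition(
    partition: SteadyStatePartition, free_fraction: float = 0.2
) -> dict[str, float]:
    """Plasma initial conditions for the flow model.

    Only about 20% of plasma TFPIα circulates as the free full-length form
    (the rest is C-terminally truncated and lipoprotein-bound, which the
    flow model neglects), so every plasma TFPIα-containing species is scaled
    by ``free_fraction``.  Free concizumab passes through unscaled, and
    endothelial species are dropped: TFPIβ acts on the flow model only
    through these plasma levels.
    """
    if not partition.converged:
        raise ValueError("partition did not converge; refusing to derive flow inputs")
    return {
        "TFPIa": partition.free_TFPIa * free_fraction,
        "C": partition.free_C,
        "C:TFPIa": partition.C_TFPIa * free_fraction,
        "TFPIa:C:TFPIa": partition.TFPIa_C_TFPIa * free_fraction,
    }
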