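"""Flow-mediated reaction-zone model of TF-initiated coagulation.

The model tracks coagulation chemistry in a well-mixed reaction zone (RZ)
just above a small (10 x 10 um) injury exposing tissue factor (TF) on the
subendothelium.  Flow enters as a single first-order mass-transfer exchange
between the RZ and bulk plasma: zymogens are resupplied and locally
generated enzymes are carried away.  Three platelet classes are modelled -
quiescent platelets in plasma, activated platelets adhered to the
subendothelium, and activated platelets bound into the aggregate.  Adhered
platelets progressively cover the injury and attenuate all subendothelial
chemistry; plasma platelets activate on contact with activated platelets
and, above a 1 nM thrombin threshold, by thrombin itself.

The concizumab extension adds the antibody's reactions with TFPIα in every
context it occurs: free in plasma, bound to FV-h in plasma or on platelet
membranes, and inside the early prothrombinase complex.  TFPIβ is not an
explicit flow-model variable; its whole effect enters through the plasma
initial conditions supplied by the compartment model.

The base (non-concizumab) reaction set is a reduced reconstruction of the
predecessor reaction-zone model; its parameter file
(``data/flow_base.yaml``) tags every entry as printed or estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .reaction_system import (
    IntegrationError,
    MassActionReaction,
    ReactionNetwork,
    SpeciesDecl,
    Trajectory,
    build_rhs,
)

__all__ = [
    "FlowParams",
    "ThrombinTimecourse",
    "LagTime",
    "load_base_params",
    "assemble_flow_network",
    "simulate_injury",
    "lag_time",
    "extract_fig4_series",
    "BASELINE_TFPIA_PLASMA",
]

#: plasma free TFPIα input without concizumab: 20 % of the 2.5 nM total
BASELINE_TFPIA_PLASMA = 0.5


def _coerce_numbers(obj):
    # YAML 1.1 treats "1.0e7" (no signed exponent) as a string; be lenient.
    if isinstance(obj, dict):
        return {k: _coerce_numbers(v) for k, v in obj.items()}
    if isinstance(obj, str):
        try:
            return float(obj)
        except ValueError:
            return obj
    return obj


def load_base_params() -> dict:
    """Load the packaged base-model parameter file."""
    text = resources.files("coagsim.data").joinpath("flow_base.yaml").read_text()
    return _coerce_numbers(yaml.safe_load(text))


@dataclass(frozen=True)
class LagTime:
    """Time to 1 nM thrombin; ``censored`` when never reached in-run."""

    minutes: float
    censored: bool

    def __float__(self) -> float:
        return self.minutes


@dataclass(frozen=True)
class FlowParams:
    """Configuration of a single injury simulation.

    ``FVIII_level`` follows the convention of 1 nM at 100 % of normal, so
    hemophilia A at 1 % is 0.01 nM.  ``plasma_inputs`` carries the
    compartment-model steady state (free C, free TFPIα and its concizumab
    complexes, already scaled to the 20 % free full-length fraction); when
    omitted, the no-concizumab baseline (0.5 nM free plasma TFPIα) is used.

    ``disabled_tags`` zeroes the association rate of every reaction carrying
    one of the tags; ``rate_scales`` multiplies association rates by tag.
    Both preserve the species layout, so scenario runs stay comparable.
    """

    TF_density: float = 9.0  # fmol/cm^2
    FVIII_level: float = 0.01  # nM
    duration_min: float = 40.0
    plasma_inputs: Mapping[str, float] | None = None
    disabled_tags: frozenset[str] = frozenset()
    rate_scales: Mapping[str, float] = field(default_factory=dict)
    rate_overrides: Mapping[str, float] = field(default_factory=dict)
    thrombin_species: str = "IIa"
    base: Mapping | None = None

    def __post_init__(self):
        if self.TF_density < 0:
            raise ValueError("TF_density must be >= 0")
        if not (0.0 <= self.FVIII_level <= 1.0):
            raise ValueError("FVIII_level must lie in [0, 1] nM")

    def base_params(self) -> dict:
        return dict(self.base) if self.base is not None else load_base_params()


@dataclass
class ThrombinTimecourse:
    """Thrombin (and tracked species) versus time, with the lag metric."""

    trajectory: Trajectory
    thrombin_species: str
    duration_min: float
    threshold: float = 1.0

    @property
    def times_min(self) -> np.ndarray:
        return self.trajectory.times / 60.0

    @property
    def thrombin(self) -> np.ndarray:
        return np.clip(self.trajectory[self.thrombin_species], 0.0, None)

    @property
    def lag(self) -> LagTime:
        return lag_time(self, self.threshold)

    @property
    def thrombin_at_end(self) -> float:
        return float(self.thrombin[-1])

    def species(self, name: str) -> np.ndarray:
        return np.clip(self.trajectory[name], 0.0, None)

    def to_frame(self) -> pd.DataFrame:
        return self.trajectory.to_frame()


# -- network assembly ---------------------------------------------------------

SE_SPECIES = [
    "TF", "TF:FVII", "TF:FVIIa", "TF:FVIIa:FX", "TF:FVIIa:FXa",
    "TF:FVIIa:FIX", "TF:FVIIa:FXa:TFPIa",
]
PLASMA_SPECIES = [
    "FVII", "FVIIa", "FX", "FIX", "FII", "FV", "FVIII", "TFPIa", "C", "C:TFPIa",
    "TFPIa:C:TFPIa", "FXa", "FIXa", "IIa", "FVa", "FVh", "FVIIIa",
    "TFPIa:FXa", "TFPIa:FVh", "C:TFPIa:FVh", "PLq",
]
MEMBRANE_SPECIES = [
    "PLse", "PLa", "FXa_m", "FIXa_m", "FVa_m", "FVh_m", "FVIIIa_m",
    "Tenase", "Tenase:FX", "Ptase_Va", "Ptase_Vh", "PtaseVa:FII",
    "PtaseVh:FII", "TFPIa:FXa_m", "TFPIa:FVh_m", "C:TFPIa:FVh_m",
    "TFPIa:FVh:FXa_m", "C:TFPIa:FVh:FXa_m",
]

#: membrane site occupancy by site class (complexes count in each class of
#: their anchored constituents)
SITE_OCCUPANCY = {
    "xa": ["FXa_m", "TFPIa:FXa_m", "Ptase_Va", "Ptase_Vh", "PtaseVa:FII",
           "PtaseVh:FII", "TFPIa:FVh:FXa_m", "C:TFPIa:FVh:FXa_m"],
    "ix": ["FIXa_m", "Tenase", "Tenase:FX"],
    "v": ["FVa_m", "FVh_m", "Ptase_Va", "Ptase_Vh", "PtaseVa:FII",
          "PtaseVh:FII", "TFPIa:FVh_m", "C:TFPIa:FVh_m",
          "TFPIa:FVh:FXa_m", "C:TFPIa:FVh:FXa_m"],
    "viii": ["FVIIIa_m", "Tenase", "Tenase:FX"],
}


def _reactions(rates: Mapping[str, float]) -> list[MassActionReaction]:
    mk = MassActionReaction.from_molar
    R = rates
    rxns = [
        # subendothelium -- all attenuated by platelet coverage
        mk("se_viia", [("TF", 1), ("FVIIa", 1)], [("TF:FVIIa", 1)],
           R["tf_viia_on"], R["tf_viia_off"], surface=True),
        # zymogen FVII competes with FVIIa for TF and throttles initiation
        mk("se_vii", [("TF", 1), ("FVII", 1)], [("TF:FVII", 1)],
           R["tf_viia_on"], R["tf_viia_off"], surface=True),
        mk("se_vii_act", [("TF:FVII", 1), ("FXa", 1)],
           [("TF:FVIIa", 1), ("FXa", 1)], R["tf_vii_act_xa"], surface=True),
        mk("r1a", [("TF:FVIIa", 1), ("FX", 1)], [("TF:FVIIa:FX", 1)],
           R["kX_on"], R["kX_off"], surface=True),
        MassActionReaction("r1b", (("TF:FVIIa:FX", 1),), (("TF:FVIIa:FXa", 1),),
                           k_cat=R["kX_cat"], surface=True),
        mk("r2", [("TF:FVIIa", 1), ("FXa", 1)], [("TF:FVIIa:FXa", 1)],
           R["kXa_on"], R["kXa_off"], surface=True),
        mk("se_ix", [("TF:FVIIa", 1), ("FIX", 1)], [("TF:FVIIa:FIX", 1)],
           R["se_ix_on"], R["se_ix_off"], surface=True),
        MassActionReaction("se_ix_cat", (("TF:FVIIa:FIX", 1),),
                           (("TF:FVIIa", 1), ("FIXa", 1)),
                           k_cat=R["se_ix_cat"], surface=True),
        mk("r3", [("TF:FVIIa:FXa", 1), ("TFPIa", 1)], [("TF:FVIIa:FXa:TFPIa", 1)],
           R["kaXa_on"], R["kaXa_off"], surface=True, tags=("se_inhibition",)),
        mk("se_tfpixa", [("TFPIa:FXa", 1), ("TF:FVIIa", 1)],
           [("TF:FVIIa:FXa:TFPIa", 1)],
           R["tfpixa_se_on"], R["tfpixa_se_off"], surface=True,
           tags=("se_inhibition",)),
        # plasma
        mk("tfpi_xa", [("TFPIa", 1), ("FXa", 1)], [("TFPIa:FXa", 1)],
           R["tfpi_xa_on"], R["tfpi_xa_off"], tags=("plasma_fxa_inhibition",)),
        mk("iia_fv", [("IIa", 1), ("FV", 1)], [("IIa", 1), ("FVa", 1)], R["iia_fv"]),
        mk("iia_fvh", [("IIa", 1), ("FVh", 1)], [("IIa", 1), ("FVa", 1)], R["iia_fvh"]),
        mk("iia_fviii", [("IIa", 1), ("FVIII", 1)], [("IIa", 1), ("FVIIIa", 1)],
           R["iia_fviii"]),
        mk("xa_fv", [("FXa", 1), ("FV", 1)], [("FXa", 1), ("FVh", 1)], R["xa_fv"]),
        mk("tfpia_fvh", [("TFPIa", 1), ("FVh", 1)], [("TFPIa:FVh", 1)],
           R["kVh_on"], R["kVh_off"]),
        mk("tfpia_fvh_m", [("TFPIa", 1), ("FVh_m", 1)], [("TFPIa:FVh_m", 1)],
           R["kVh_on"], R["kVh_off"]),
        # concizumab extension (reactions 4-10)
        mk("r4", [("C", 1), ("TFPIa", 1)], [("C:TFPIa", 1)],
           R["ka_on"], R["ka_off"], tags=("concizumab",)),
        mk("r5", [("C:TFPIa", 1), ("TFPIa", 1)], [("TFPIa:C:TFPIa", 1)],
           R["ka_on"], R["ka_off"], tags=("concizumab",)),
        mk("r6", [("C", 1), ("TFPIa:FVh", 1)], [("C:TFPIa:FVh", 1)],
           R["ka_on"], R["ka_off"], tags=("concizumab",)),
        mk("r7", [("C:TFPIa", 1), ("FVh", 1)], [("C:TFPIa:FVh", 1)],
           R["kVh_on"], R["kVh_off"], tags=("concizumab", "c_tfpia_fvh")),
        mk("r8", [("C", 1), ("TFPIa:FVh_m", 1)], [("C:TFPIa:FVh_m", 1)],
           R["ka_on"], R["ka_off"], tags=("concizumab",)),
        mk("r9", [("C:TFPIa", 1), ("FVh_m", 1)], [("C:TFPIa:FVh_m", 1)],
           R["kVh_on"], R["kVh_off"], tags=("concizumab", "c_tfpia_fvh")),
        mk("r10", [("C", 1), ("TFPIa:FVh:FXa_m", 1)], [("C:TFPIa:FVh:FXa_m", 1)],
           R["ka_on"], R["ka_off"], tags=("concizumab",)),
        # platelet membrane: TFPIα inhibition of FXa (protein-S-sensitive set)
        mk("p1", [("TFPIa", 1), ("FXa_m", 1)], [("TFPIa:FXa_m", 1)],
           R["tfpi_xam_on"], R["tfpi_xam_off"],
           tags=("platelet_fxa_inhibition", "protein_s")),
        mk("p2", [("TFPIa:FVh", 1), ("FXa_m", 1)], [("TFPIa:FVh:FXa_m", 1)],
           R["tfpifvh_xam_on"], R["tfpifvh_xam_off"], tags=("protein_s",)),
        mk("p3", [("TFPIa", 1), ("Ptase_Vh", 1)], [("TFPIa:FVh:FXa_m", 1)],
           R["tfpi_xam_on"], R["tfpi_xam_off"],
           tags=("platelet_fxa_inhibition", "protein_s")),
        mk("p4", [("FXa", 1), ("TFPIa:FVh_m", 1)], [("TFPIa:FVh:FXa_m", 1)],
           R["tfpifvh_xam_on"], R["tfpifvh_xam_off"], tags=("protein_s",)),
        # tenase and prothrombinase
        mk("tenase_asm", [("FVIIIa_m", 1), ("FIXa_m", 1)], [("Tenase", 1)],
           R["tenase_on"], R["tenase_off"]),
        mk("tenase_fx", [("Tenase", 1), ("FX", 1)], [("Tenase:FX", 1)],
           R["tenase_fx_on"], R["tenase_fx_off"]),
        MassActionReaction("tenase_cat", (("Tenase:FX", 1),),
                           (("Tenase", 1), ("FXa_m", 1)), k_cat=R["tenase_cat"]),
        mk("ptase_va", [("FXa_m", 1), ("FVa_m", 1)], [("Ptase_Va", 1)],
           R["ptase_on"], R["ptase_off"]),
        mk("ptase_vh", [("FXa_m", 1), ("FVh_m", 1)], [("Ptase_Vh", 1)],
           R["ptase_on"], R["ptase_off"]),
        mk("pva_ii", [("Ptase_Va", 1), ("FII", 1)], [("PtaseVa:FII", 1)],
           R["ptase_ii_on"], R["ptase_ii_off"]),
        MassActionReaction("pva_cat", (("PtaseVa:FII", 1),),
                           (("Ptase_Va", 1), ("IIa", 1)), k_cat=R["ptase_va_cat"]),
        mk("pvh_ii", [("Ptase_Vh", 1), ("FII", 1)], [("PtaseVh:FII", 1)],
           R["ptase_ii_on"], R["ptase_ii_off"]),
        MassActionReaction("pvh_cat", (("PtaseVh:FII", 1),),
                           (("Ptase_Vh", 1), ("IIa", 1)), k_cat=R["ptase_vh_cat"]),
        # pseudo-first-order inhibition (antithrombin and kin)
        MassActionReaction("decay_iia", (("IIa", 1),), (), k_forward=R["decay_iia"],
                           tags=("sink",)),
        MassActionReaction("decay_xa", (("FXa", 1),), (), k_forward=R["decay_xa"],
                           tags=("sink",)),
        MassActionReaction("decay_ixa", (("FIXa", 1),), (), k_forward=R["decay_ixa"],
                           tags=("sink",)),
        MassActionReaction("decay_fviiia", (("FVIIIa", 1),), (),
                           k_forward=R["decay_fviiia"], tags=("sink",)),
    ]
    return rxns


def assemble_flow_network(params: FlowParams) -> ReactionNetwork:
    """Build the full flow network for one scenario configuration.

    Raises :class:`KeyError` naming the missing entry when the base
    parameter file is incomplete.
    """
    base = params.base_params()
    rates = dict(base["rates"])
    rates.update(params.rate_overrides)

    tf0 = params.TF_density * base["geometry"]["tf_nM_per_fmol_cm2"]
    plasma = dict(base["plasma"])
    plasma["FVIII"] = params.FVIII_level
    inputs = {"TFPIa": BASELINE_TFPIA_PLASMA, "C": 0.0, "C:TFPIa": 0.0,
              "TFPIa:C:TFPIa": 0.0}
    if params.plasma_inputs is not None:
        inputs.update(params.plasma_inputs)

    pl = base["platelets"]
    species: list[SpeciesDecl] = []
    for name in SE_SPECIES:
        species.append(SpeciesDecl(name, "subendothelium",
                                   tf0 if name == "TF" else 0.0))
    for name in PLASMA_SPECIES:
        if name == "PLq":
            c0 = pl["quiescent_nM"]
        elif name in plasma:
            c0 = plasma[name]
        else:
            c0 = inputs.get(name, 0.0)
        species.append(SpeciesDecl(name, "plasma", c0, transported=True))
    for name in MEMBRANE_SPECIES:
        species.append(SpeciesDecl(name, "platelet_surface", 0.0))

    rxns = _reactions(rates)
    scaled = []
    for rxn in rxns:
        factor = 1.0
        for tag, s in params.rate_scales.items():
            if rxn.has_tag(tag):
                factor *= s
        if any(rxn.has_tag(t) for t in params.disabled_tags):
            factor = 0.0
        if factor != 1.0:
            rxn = MassActionReaction(
                rxn.rid, rxn.reactants, rxn.products,
                k_forward=rxn.k_forward * factor,
                k_reverse=rxn.k_reverse,
                k_cat=rxn.k_cat * (0.0 if factor == 0.0 else 1.0),
                surface=rxn.surface, tags=rxn.tags)
        scaled.append(rxn)

    net = ReactionNetwork(species, scaled)
    net.set_transport({
        **{n: base["flow"]["k_protein"] for n in PLASMA_SPECIES if n != "PLq"},
        "PLq": base["flow"]["k_platelet"],
    })
    net.set_coverage(["PLse"], pl["monolayer_nM"])
    net.add_extra_term(_platelet_terms(net, base))
    return net


def _platelet_terms(net: ReactionNetwork, base: Mapping):
    """Platelet deposition/activation and saturable membrane binding.

    Returned callable computes dy contributions.  The thrombin-dependent
    activation switch is a hard threshold; the attribute
    ``thrombin_switch`` is toggled externally by the two-phase integration
    in :func:`simulate_injury` so the integrator never has to step across
    the discontinuity.
    """
    ix = net.index
    pl = base["platelets"]
    sites = base["binding_sites"]
    mb = base["membrane_binding"]
    kon = mb["k_on"] * 1e-9  # nM^-1 s^-1
    monolayer = pl["monolayer_nM"]
    agg_cap = pl["aggregate_cap_nM"]
    k_adh = pl["k_adhesion"]
    k_act_iia = pl["k_activation_thrombin"]
    k_act_pp = pl["k_activation_contact"]

    occupancy = {cls: [ix[s] for s in names] for cls, names in SITE_OCCUPANCY.items()}
    capacity = {"xa": sites["N_Xa"], "ix": sites["N_IX"], "v": sites["N_V"],
                "viii": sites["N_VIII"]}
    # (plasma species, membrane species, site class, koff)
    bindings = [
        ("FXa", "FXa_m", "xa", mb["koff_Xa"]),
        ("FIXa", "FIXa_m", "ix", mb["koff_IXa"]),
        ("FVa", "FVa_m", "v", mb["koff_V"]),
        ("FVh", "FVh_m", "v", mb["koff_V"]),
        ("FVIIIa", "FVIIIa_m", "viii", mb["koff_VIII"]),
        ("TFPIa:FVh", "TFPIa:FVh_m", "v", mb["koff_V"]),
        ("C:TFPIa:FVh", "C:TFPIa:FVh_m", "v", mb["koff_V"]),
    ]
    bindings = [(ix[a], ix[b], cls, koff) for a, b, cls, koff in bindings]
    i_plq, i_plse, i_pla = ix["PLq"], ix["PLse"], ix["PLa"]

    def terms(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        plq, plse, pla = y[i_plq], y[i_plse], y[i_pla]
        coverage = min(max(plse / monolayer, 0.0), 1.0)
        active = plse + pla
        adh = k_adh * plq * (1.0 - coverage)
        act = (k_act_pp * active + (k_act_iia if terms.thrombin_switch else 0.0)) * plq
        act *= max(1.0 - pla / agg_cap, 0.0)
        dy[i_plq] -= adh + act
        dy[i_plse] += adh
        dy[i_pla] += act

        free = {}
        for cls, idxs in occupancy.items():
            bound = sum(y[i] for i in idxs)
            free[cls] = max(capacity[cls] * active - bound, 0.0)
        for ia, ib, cls, koff in bindings:
            flux = kon * y[ia] * free[cls] - koff * y[ib]
            dy[ia] -= flux
            dy[ib] += flux
        return dy

    terms.thrombin_switch = False
    return terms


def simulate_injury(
    params: FlowParams,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    output_dt: float = 1.0,
) -> ThrombinTimecourse:
    """Integrate an injury simulation and return the thrombin time course.

    The hard platelet-activation threshold at 1 nM thrombin is handled by
    two-phase integration: the solver runs with the switch off until an
    event detects the upward crossing, then restarts with thrombin-driven
    activation enabled.  Output is reported on a 1 s grid.
    """
    net = assemble_flow_network(params)
    threshold = params.base_params()["platelets"]["thrombin_threshold_nM"]
    i_iia = net.index[params.thrombin_species]
    switch_term = net.extra_terms[-1]
    rhs = build_rhs(net)
    t_end = params.duration_min * 60.0
    t_grid = np.arange(0.0, t_end + output_dt, output_dt)

    def crossing(t, y):
        return y[i_iia] - threshold

    crossing.terminal = True
    crossing.direction = 1.0

    switch_term.thrombin_switch = False
    sol1 = solve_ivp(rhs, (0.0, t_end), net.initial_state(), method="LSODA",
                     t_eval=t_grid, rtol=rtol, atol=atol, events=crossing)
    if not sol1.success:
        raise IntegrationError(
            f"flow integration failed: {sol1.message}",
            last_time=sol1.t[-1] if sol1.t.size else None)
    if sol1.t_events[0].size == 0:
        traj = Trajectory(sol1.t, sol1.y.T, net.names)
    else:
        t_x = sol1.t_events[0][0]
        y_x = sol1.y_events[0][0]
        switch_term.thrombin_switch = True
        rest = t_grid[t_grid > t_x]
        t_eval2 = np.concatenate(([t_x], rest))
        sol2 = solve_ivp(rhs, (t_x, t_end), y_x, method="LSODA",
                         t_eval=t_eval2, rtol=rtol, atol=atol)
        if not sol2.success:
            raise IntegrationError(
                f"flow integration failed after threshold: {sol2.message}",
                last_time=sol2.t[-1] if sol2.t.size else None)
        keep1 = sol1.t <= t_x
        times = np.concatenate((sol1.t[keep1], sol2.t[1:]))
        states = np.vstack((sol1.y.T[keep1], sol2.y.T[1:]))
        traj = Trajectory(times, states, net.names)
    switch_term.thrombin_switch = False
    return ThrombinTimecourse(traj, params.thrombin_species, params.duration_min,
                              threshold=threshold)


def lag_time(timecourse: ThrombinTimecourse, threshold: float = 1.0) -> LagTime:
    """First upward crossing of ``threshold`` nM thrombin, in minutes.

    Linear interpolation between the bracketing output times; censored at
    the run duration when the threshold is never reached.
    """
    t = timecourse.times_min
    x = timecourse.thrombin
    above = x >= threshold
    if not above.any():
        return LagTime(timecourse.duration_min, censored=True)
    i = int(np.argmax(above))
    if i == 0:
        return LagTime(float(t[0]), censored=False)
    t0, t1 = t[i - 1], t[i]
    x0, x1 = x[i - 1], x[i]
    if x1 == x0:
        return LagTime(float(t1), censored=False)
    return LagTime(float(t0 + (threshold - x0) / (x1 - x0) * (t1 - t0)),
                   censored=False)


def extract_fig4_series(tc: ThrombinTimecourse) -> dict[str, pd.Series]:
    """Four tracked read-outs of the injury simulation.

    free plasma TFPIα; the subendothelial TF:FVIIa:FXa:TFPIα quaternary
    complex; total FXa (plasma plus platelet-bound, including FXa engaged
    in prothrombinase); and prothrombinase (FXa:FVa plus FXa:FV-h forms).
    """
    idx = pd.Index(tc.times_min, name="time_min")
    ptase = (tc.species("Ptase_Va") + tc.species("Ptase_Vh")
             + tc.species("PtaseVa:FII") + tc.species("PtaseVh:FII"))
    total_fxa = tc.species("FXa") + tc.species("FXa_m") + ptase
    return {
        "free_plasma_TFPIa": pd.Series(tc.species("TFPIa"), index=idx),
        "TF:FVIIa:FXa:TFPIa": pd.Series(tc.species("TF:FVIIa:FXa:TFPIa"), index=idx),
        "total_FXa": pd.Series(total_fxa, index=idx),
        "prothrombinase": pd.Series(ptase, index=idx),
    }
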