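"""Mass-action reaction networks and stiff ODE integration.

This module is the shared engine for both the well-mixed concizumab/TFPI
compartment model and the flow-mediated coagulation model.  A network is a
declarative list of species and reversible/catalytic mass-action reactions;
from it we construct a right-hand-side function, integrate it with a stiff
solver, detect steady states, and audit conserved moiety pools.

Unit conventions (internal, everywhere):
    concentrations in nM, time in seconds.
Bimolecular rate constants quoted in the literature in M^-1 s^-1 must be
converted by 1e-9 at network construction time (see
:meth:`MassActionReaction.from_molar`); this keeps the state vector within a
few orders of magnitude of unity and avoids needless stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "SpeciesDecl",
    "MassActionReaction",
    "ReactionNetwork",
    "Trajectory",
    "NetworkError",
    "IntegrationError",
    "SteadyStateError",
    "build_rhs",
    "integrate",
    "find_steady_state",
    "conserved_totals",
]

PHASES = ("plasma", "platelet_surface", "subendothelium", "endothelium")

#: conversion from M^-1 s^-1 to nM^-1 s^-1
MOLAR_TO_NM = 1e-9


class NetworkError(ValueError):
    """Raised for an ill-formed network (undeclared species, bad rates...)."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class SteadyStateError(RuntimeError):
    """Raised when no steady state is reached within the horizon."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SpeciesDecl:
    """A chemical species in the network.

    Parameters
    ----------
    name : str
        Unique identifier within a network.
    phase : str
        One of ``plasma``, ``platelet_surface``, ``subendothelium``,
        ``endothelium``.
    initial_conc : float
        Initial concentration in nM; must be non-negative.
    transported : bool
        Whether the species is subject to flow-mediated supply/removal in
        the flow model.  Endothelium-phase species are never transported.
    upstream_conc : float, optional
        Bulk (upstream) concentration used by the transport term; defaults
        to ``initial_conc``.
    """

    name: str
    phase: str = "plasma"
    initial_conc: float = 0.0
    transported: bool = False
    upstream_conc: float | None = None

    def __post_init__(self):
        if self.phase not in PHASES:
            raise NetworkError(f"unknown phase {self.phase!r} for species {self.name!r}")
        if self.initial_conc < 0:
            raise NetworkError(f"negative initial concentration for species {self.name!r}")
        if self.phase == "endothelium" and self.transported:
            raise NetworkError(f"endothelium species {self.name!r} cannot be transported")

    @property
    def bulk(self) -> float:
        return self.initial_conc if self.upstream_conc is None else self.upstream_conc


@dataclass(frozen=True)
class MassActionReaction:
    """A reversible and/or catalytic mass-action step.

    ``flux = k_forward * prod(reactants) - k_reverse * prod(products)
    + k_cat * prod(reactants)`` where the ``k_cat`` term is irreversible
    (enzyme-substrate complex releasing enzyme and product).

    Rates are in internal units: nM^-1 s^-1 per bimolecular order, s^-1 for
    unimolecular.  Use :meth:`from_molar` for literature (M-based) rates.
    """

    rid: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    k_forward: float = 0.0
    k_reverse: float = 0.0
    k_cat: float = 0.0
    surface: bool = False
    tags: tuple[str, ...] = ()

    def __post_init__(self):
        for k, label in ((self.k_forward, "k_forward"), (self.k_reverse, "k_reverse"), (self.k_cat, "k_cat")):
            if k < 0:
                raise NetworkError(f"reaction {self.rid!r}: {label} must be >= 0, got {k}")
        object.__setattr__(self, "reactants", tuple((s, int(n)) for s, n in self.reactants))
        object.__setattr__(self, "products", tuple((s, int(n)) for s, n in self.products))
        if self.k_cat and sum(n for _, n in self.reactants) != 1:
            raise NetworkError(f"reaction {self.rid!r}: k_cat requires a single (complex) reactant")

    @classmethod
    def from_molar(
        cls,
        rid: str,
        reactants: Sequence[tuple[str, int]],
        products: Sequence[tuple[str, int]],
        k_forward: float = 0.0,
        k_reverse: float = 0.0,
        k_cat: float = 0.0,
        **kw,
    ) -> "MassActionReaction":
        """Build a reaction from rates quoted on the molar scale.

        ``k_forward``/``k_reverse`` in M^(1-n) s^-1 are converted to the
        internal nM basis according to the total order of each side.
        """
        n_f = sum(n for _, n in reactants)
        n_r = sum(n for _, n in products)
        return cls(
            rid,
            tuple(reactants),
            tuple(products),
            k_forward=k_forward * MOLAR_TO_NM ** max(n_f - 1, 0),
            k_reverse=k_reverse * MOLAR_TO_NM ** max(n_r - 1, 0),
            k_cat=k_cat,
            **kw,
        )

    def has_tag(self, tag: str) -> bool:
        return tag in self.tags

    def scaled(self, forward: float = 1.0, reverse: float = 1.0) -> "MassActionReaction":
        """Return a copy with association/dissociation rates multiplied."""
        return MassActionReaction(
            self.rid, self.reactants, self.products,
            k_forward=self.k_forward * forward,
            k_reverse=self.k_reverse * reverse,
            k_cat=self.k_cat, surface=self.surface, tags=self.tags,
        )


class ReactionNetwork:
    """An ordered collection of species and mass-action reactions.

    Species ordering is the declaration order; the state vector, the
    stoichiometry matrix and all trajectories follow it, so runs are
    bit-reproducible at fixed solver tolerances.

    Optional structure used by the flow model:

    * per-species first-order transport (``k_flow * (upstream - y)``),
    * a coverage rule attenuating ``surface``-flagged reactions by
      ``(1 - coverage)`` where coverage is a saturating function of listed
      species,
    * extra right-hand-side terms (``f(t, y) -> dy``) for physics that is
      not mass action (platelet deposition, saturable membrane binding).
    """

    def __init__(
        self,
        species: Iterable[SpeciesDecl],
        reactions: Iterable[MassActionReaction],
        conserved_pools: Mapping[str, Mapping[str, float]] | None = None,
    ):
        self.species: list[SpeciesDecl] = list(species)
        self.reactions: list[MassActionReaction] = list(reactions)
        self.conserved_pools: dict[str, dict[str, float]] = {
            k: dict(v) for k, v in (conserved_pools or {}).items()
        }
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise NetworkError(f"duplicate species names: {dup}")
        self.index: dict[str, int] = {n: i for i, n in enumerate(names)}
        for rxn in self.reactions:
            for sname, _ in (*rxn.reactants, *rxn.products):
                if sname not in self.index:
                    raise NetworkError(
                        f"reaction {rxn.rid!r} references undeclared species {sname!r}"
                    )
        for pool, counts in self.conserved_pools.items():
            for sname in counts:
                if sname not in self.index:
                    raise NetworkError(f"pool {pool!r} references undeclared species {sname!r}")
            self._check_pool_balance(pool, counts)

        # optional flow-model structure
        self.transport_rates: np.ndarray = np.zeros(len(self.species))
        self.upstream: np.ndarray = np.array([s.bulk for s in self.species])
        self.coverage_species: list[str] = []
        self.coverage_capacity: float | None = None
        self.extra_terms: list[Callable[[float, np.ndarray], np.ndarray]] = []

    # -- construction helpers -------------------------------------------------

    def _check_pool_balance(self, pool: str, counts: Mapping[str, float]) -> None:
        for rxn in self.reactions:
            lhs = sum(counts.get(s, 0.0) * n for s, n in rxn.reactants)
            rhs = sum(counts.get(s, 0.0) * n for s, n in rxn.products)
            if abs(lhs - rhs) > 1e-12 and not rxn.has_tag("sink"):
                raise NetworkError(
                    f"pool {pool!r} is not conserved by reaction {rxn.rid!r} "
                    f"(lhs={lhs}, rhs={rhs})"
                )

    def set_transport(self, rate: float | Mapping[str, float]) -> None:
        """Enable flow supply/removal for all ``transported`` species.

        ``rate`` is either a single first-order exchange rate (s^-1) or a
        map species -> rate overriding the default of 0.
        """
        k = np.zeros(len(self.species))
        if isinstance(rate, Mapping):
            for name, r in rate.items():
                sp = self.species[self.index[name]]
                if not sp.transported:
                    raise NetworkError(f"species {name!r} is not flagged transported")
                k[self.index[name]] = r
        else:
            for i, sp in enumerate(self.species):
                if sp.transported:
                    k[i] = rate
        self.transport_rates = k

    def set_coverage(self, species: Sequence[str], capacity: float) -> None:
        """Attenuate ``surface`` reactions by ``1 - sum(species)/capacity``."""
        for s in species:
            if s not in self.index:
                raise NetworkError(f"coverage species {s!r} undeclared")
        self.coverage_species = list(species)
        self.coverage_capacity = float(capacity)

    def add_extra_term(self, f: Callable[[float, np.ndarray], np.ndarray]) -> None:
        self.extra_terms.append(f)

    # -- introspection --------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_conc for s in self.species], dtype=float)

    def stoichiometry_matrix(self) -> np.ndarray:
        """Species x reactions net stoichiometry matrix."""
        N = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for s, n in rxn.reactants:
                N[self.index[s], j] -= n
            for s, n in rxn.products:
                N[self.index[s], j] += n
        return N

    def coverage(self, y: np.ndarray) -> float:
        if self.coverage_capacity is None:
            return 0.0
        total = sum(y[self.index[s]] for s in self.coverage_species)
        return min(max(total / self.coverage_capacity, 0.0), 1.0)

    def reaction(self, rid: str) -> MassActionReaction:
        for rxn in self.reactions:
            if rxn.rid == rid:
                return rxn
        raise KeyError(rid)

    def with_reactions(self, reactions: Iterable[MassActionReaction]) -> "ReactionNetwork":
        """Copy of the network with a replaced reaction list (same species)."""
        net = ReactionNetwork(self.species, reactions, self.conserved_pools)
        net.transport_rates = self.transport_rates.copy()
        net.upstream = self.upstream.copy()
        net.coverage_species = list(self.coverage_species)
        net.coverage_capacity = self.coverage_capacity
        net.extra_terms = list(self.extra_terms)
        return net


@dataclass
class Trajectory:
    """Integration output: a time grid and one concentration row per time."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    names: list[str]

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, self.names.index(species)]

    def final(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self, clamp: bool = True) -> pd.DataFrame:
        """DataFrame with a ``time_s`` column; round-off negatives clamped."""
        vals = np.clip(self.states, 0.0, None) if clamp else self.states
        df = pd.DataFrame(vals, columns=self.names)
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# -- operations ---------------------------------------------------------------


def build_rhs(
    network: ReactionNetwork,
    transport: bool = True,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the network into a derivative function ``f(t, y) -> dy/dt``.

    Each reaction contributes ``k_forward * prod(reactant concs)`` minus
    ``k_reverse * prod(product concs)``, plus an irreversible ``k_cat``
    release term for catalytic steps.  Transport and extra terms are added
    when enabled on the network.
    """
    n = len(network.species)
    nr = len(network.reactions)
    pad = n  # index of the constant-1 padding slot

    def side_indices(side: Sequence[tuple[str, int]]) -> list[int]:
        idx: list[int] = []
        for s, m in side:
            idx.extend([network.index[s]] * m)
        if len(idx) > 2:
            raise NetworkError("mass-action sides of order > 2 are not supported")
        while len(idx) < 2:
            idx.append(pad)
        return idx

    R = np.empty((nr, 2), dtype=np.intp)
    P = np.empty((nr, 2), dtype=np.intp)
    kf = np.empty(nr)
    kr = np.empty(nr)
    kc = np.empty(nr)
    surf = np.zeros(nr, dtype=bool)
    for j, rxn in enumerate(network.reactions):
        R[j] = side_indices(rxn.reactants)
        P[j] = side_indices(rxn.products)
        kf[j], kr[j], kc[j] = rxn.k_forward, rxn.k_reverse, rxn.k_cat
        surf[j] = rxn.surface
    N = network.stoichiometry_matrix()
    has_surface = surf.any() and network.coverage_capacity is not None
    has_transport = transport and network.transport_rates.any()
    k_t = network.transport_rates
    upstream = network.upstream
    extra = list(network.extra_terms)
    yy = np.empty(n + 1)
    yy[pad] = 1.0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        yy[:n] = y
        flux = (kf + kc) * yy[R[:, 0]] * yy[R[:, 1]] - kr * yy[P[:, 0]] * yy[P[:, 1]]
        if has_surface:
            factor = 1.0 - network.coverage(y)
            flux = np.where(surf, flux * factor, flux)
        dy = N @ flux
        if has_transport:
            dy = dy + k_t * (upstream - y)
        for f in extra:
            dy = dy + f(t, y)
        return dy

    return rhs


def integrate(
    network: ReactionNetwork,
    state0: np.ndarray | None = None,
    t_grid: np.ndarray | Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
    transport: bool = True,
    events=None,
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate the network over ``t_grid`` (seconds, strictly increasing).

    Uses a stiff implicit solver by default (rate constants span many orders
    of magnitude).  Raises :class:`IntegrationError` carrying the last valid
    time on solver failure.
    """
    y0 = network.initial_state() if state0 is None else np.asarray(state0, dtype=float)
    if (y0 < 0).any():
        raise NetworkError("initial state must be non-negative")
    t_grid = np.asarray(t_grid if t_grid is not None else [0.0, 3600.0], dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise NetworkError("t_grid must be strictly increasing with >= 2 points")
    rhs = build_rhs(network, transport=transport)
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        method=method,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
        events=events,
        max_step=max_step,
    )
    if not sol.success:
        last = sol.t[-1] if sol.t.size else None
        raise IntegrationError(f"integrator failed: {sol.message}", last_time=last)
    return Trajectory(sol.t, sol.y.T, network.names)


def find_steady_state(
    network: ReactionNetwork,
    state0: np.ndarray | None = None,
    window: float = 300.0,
    abs_tol: float = 0.2,
    rel_tol: float | None = None,
    floor: float = 1e-12,
    horizon: float = 48 * 3600.0,
    dt: float = 30.0,
    rtol: float = 1e-10,
    atol: float = 1e-13,
    transport: bool = True,
) -> tuple[np.ndarray, float]:
    """Integrate until every species has negligible change over ``window``.

    The criterion checks the change of each species across the trailing
    window (sampled every ``dt`` seconds): the default declares steady state
    when no species moves by more than ``abs_tol`` nM.  If ``rel_tol`` is
    given, the relative criterion ``|dy| / max(|y|, floor) < rel_tol`` is
    used instead (for toy-network equilibrium studies use a tight
    ``rel_tol`` such as 1e-9).

    Returns ``(state, time_of_detection)``.  Raises
    :class:`SteadyStateError` with the residual change if the horizon is
    exhausted.
    """
    t_grid = np.arange(0.0, horizon + dt, dt)
    traj = integrate(
        network, state0=state0, t_grid=t_grid, rtol=rtol, atol=atol, transport=transport
    )
    k = max(int(round(window / dt)), 1)
    Y = traj.states
    residual = np.inf
    for i in range(k, Y.shape[0]):
        d = np.abs(Y[i] - Y[i - k])
        if rel_tol is not None:
            metric = d / np.maximum(np.abs(Y[i]), floor)
            ok = metric.max() < rel_tol
        else:
            metric = d
            ok = metric.max() < abs_tol
        residual = min(residual, metric.max())
        if ok:
            return Y[i].copy(), traj.times[i]
    raise SteadyStateError(
        f"no steady state within {horizon} s (best residual {residual:.3g})",
        residual=residual,
    )


def conserved_totals(network: ReactionNetwork, state: np.ndarray) -> dict[str, float]:
    """Dot each conserved moiety pool against the state vector."""
    state = np.asarray(state, dtype=float)
    if state.shape != (len(network.species),):
        raise NetworkError("state dimension does not match species list")
    out = {}
    for pool, counts in network.conserved_pools.items():
        out[pool] = float(sum(c * state[network.index[s]] for s, c in counts.items()))
    return out
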