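"""Mass-action reaction networks and stiff ODE simulation.

The coagulation cascade is represented as a plain mass-action network:
every rate law is a signed sum of monomial terms, each term being a
product of rate constants and species concentrations.  This covers both
irreversible conversions (e.g. Xa-catalysed prothrombin activation,
``k16*Xa*II``) and the reversible inhibitor-binding pattern
``kf*(A*B - Ki*AB)`` used for the anticoagulant mechanisms.  No general
expression parser exists on purpose: the monomial restriction keeps the
right-hand side compilable to a handful of numpy gathers and lets the
Jacobian be assembled analytically, which matters because the network is
stiff (rate constants span 1e-4 .. 4e8 in mol/l and seconds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "SpeciesDef",
    "RateTerm",
    "RateLaw",
    "ReactionDef",
    "ParameterSet",
    "NetworkModel",
    "Trajectory",
    "SimControls",
    "ModelValidationError",
    "SimulationError",
    "NO_CROSSING",
    "eval_rate",
    "assemble_rhs",
    "simulate",
    "first_crossing_time",
    "conserved_moiety_residual",
    "write_trajectory_csv",
]


class ModelValidationError(ValueError):
    """A model definition references unknown species/symbols or is inconsistent."""


class SimulationError(RuntimeError):
    """The ODE integrator failed; carries the solver diagnostics message."""


#: sentinel returned by :func:`first_crossing_time` when the threshold is
#: never reached within the simulated horizon.
NO_CROSSING = None


@dataclass(frozen=True)
class SpeciesDef:
    """One chemical species.

    ``mobile`` marks species exchanged with the blood pool under flow
    coupling; tissue-factor complexes and the fibrin product stay put.
    ``constant`` marks pool species (e.g. the dimensionless albumin pool)
    whose concentration appears in rate laws but is never integrated.
    """

    name: str
    initial_concentration: float = 0.0  # mol/l
    mobile: bool = True
    lipid_bound: bool = False
    constant: bool = False

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ModelValidationError(
                f"species {self.name!r}: negative initial concentration"
            )


@dataclass(frozen=True)
class RateTerm:
    sign: int  # +1 or -1
    constants: tuple[str, ...]  # parameter symbols, multiplied
    species: tuple[str, ...]  # species names, multiplied (repeats allowed)

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ModelValidationError("rate term sign must be +1 or -1")
        if not self.constants:
            raise ModelValidationError("rate term needs at least one constant symbol")


@dataclass(frozen=True)
class RateLaw:
    """Signed sum of mass-action monomials."""

    terms: tuple[RateTerm, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ModelValidationError("rate law needs at least one term")

    @staticmethod
    def mass_action(constants: Sequence[str], species: Sequence[str]) -> "RateLaw":
        """Single forward monomial ``+k1*k2*...*[A]*[B]*...``."""
        return RateLaw((RateTerm(+1, tuple(constants), tuple(species)),))

    @staticmethod
    def reversible(
        kf: Sequence[str],
        reactants: Sequence[str],
        kr: Sequence[str],
        products: Sequence[str],
    ) -> "RateLaw":
        """The ``kf*prod(reactants) - kr*prod(products)`` pattern."""
        return RateLaw(
            (
                RateTerm(+1, tuple(kf), tuple(reactants)),
                RateTerm(-1, tuple(kr), tuple(products)),
            )
        )


@dataclass(frozen=True)
class ReactionDef:
    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: RateLaw
    group: str = ""  # e.g. extrinsic / intrinsic / adsorption / drug:<name>

    def __post_init__(self) -> None:
        for name, coeff in (*self.reactants, *self.products):
            if coeff < 1:
                raise ModelValidationError(
                    f"reaction {self.id!r}: stoichiometric coefficient of "
                    f"{name!r} must be >= 1"
                )


class ParameterSet:
    """Symbol -> value mapping (base units mol/l, s) with provenance tags.

    Provenance distinguishes values transcribed from the model's own
    supplement-style tables (``supplement``) from values taken from the
    published source models (``source-model``), standard references
    (``external-constant``) or calibrated here (``fitted-here``).
    """

    def __init__(
        self,
        values: Mapping[str, float],
        provenance: Mapping[str, str] | None = None,
    ) -> None:
        self.values: dict[str, float] = dict(values)
        self.provenance: dict[str, str] = dict(provenance or {})
        for sym, val in self.values.items():
            if not math.isfinite(val):
                raise ModelValidationError(f"parameter {sym!r} is not finite")

    def __getitem__(self, symbol: str) -> float:
        try:
            return self.values[symbol]
        except KeyError:
            raise ModelValidationError(f"unknown parameter symbol {symbol!r}") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.values

    def __len__(self) -> int:
        return len(self.values)

    def updated(self, extra: Mapping[str, float], provenance: str = "fitted-here") -> "ParameterSet":
        values = dict(self.values)
        values.update(extra)
        prov = dict(self.provenance)
        for sym in extra:
            prov.setdefault(sym, provenance)
        return ParameterSet(values, prov)


class NetworkModel:
    """Species, reactions and parameters plus the stoichiometric matrix.

    Validation is total: any dangling species or parameter symbol raises
    :class:`ModelValidationError` at construction, so no partially built
    model escapes.
    """

    def __init__(
        self,
        species: Sequence[SpeciesDef],
        reactions: Sequence[ReactionDef],
        parameters: ParameterSet,
    ) -> None:
        self.species: tuple[SpeciesDef, ...] = tuple(species)
        self.reactions: tuple[ReactionDef, ...] = tuple(reactions)
        self.parameters = parameters
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ModelValidationError(f"duplicate species names: {dupes}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dupes = sorted({r for r in rids if rids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        self.index: dict[str, int] = {n: i for i, n in enumerate(names)}
        self._validate()
        self.stoichiometric_matrix = self._build_stoichiometry()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        for rxn in self.reactions:
            for name, _ in (*rxn.reactants, *rxn.products):
                if name not in self.index:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r}: undeclared species {name!r}"
                    )
            for term in rxn.rate.terms:
                for sym in term.constants:
                    if sym not in self.parameters:
                        raise ModelValidationError(
                            f"reaction {rxn.id!r}: missing rate constant {sym!r}"
                        )
                for name in term.species:
                    if name not in self.index:
                        raise ModelValidationError(
                            f"reaction {rxn.id!r}: rate law references undeclared "
                            f"species {name!r}"
                        )

    def _build_stoichiometry(self) -> np.ndarray:
        S = np.zeros((len(self.species), len(self.reactions)), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for name, coeff in rxn.reactants:
                S[self.index[name], j] -= coeff
            for name, coeff in rxn.products:
                S[self.index[name], j] += coeff
        return S

    # -- convenience ----------------------------------------------------------

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def initial_state(self) -> dict[str, float]:
        return {s.name: s.initial_concentration for s in self.species}

    def initial_vector(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], dtype=float)

    def reaction(self, rid: str) -> ReactionDef:
        for rxn in self.reactions:
            if rxn.id == rid:
                return rxn
        raise KeyError(rid)

    def with_initials(self, initials: Mapping[str, float]) -> "NetworkModel":
        """Copy of the model with replaced initial concentrations."""
        unknown = set(initials) - set(self.index)
        if unknown:
            raise ModelValidationError(f"unknown species in initials: {sorted(unknown)}")
        new_species = tuple(
            replace(s, initial_concentration=float(initials.get(s.name, s.initial_concentration)))
            for s in self.species
        )
        return NetworkModel(new_species, self.reactions, self.parameters)

    def structurally_equal(self, other: "NetworkModel") -> bool:
        return (
            self.species == other.species
            and self.reactions == other.reactions
            and self.parameters.values == other.parameters.values
            and self.parameters.provenance == other.parameters.provenance
        )


@dataclass
class Trajectory:
    """Simulated time course: times [s], concentrations [mol/l] (time x species)."""

    times: np.ndarray
    concentrations: np.ndarray
    species_names: tuple[str, ...]
    dense: Callable[[np.ndarray], np.ndarray] | None = None  # t -> state
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {n: i for i, n in enumerate(self.species_names)}

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[:, self.index[species]]

    def final_state(self) -> dict[str, float]:
        return dict(zip(self.species_names, self.concentrations[-1]))


@dataclass(frozen=True)
class SimControls:
    """Integrator controls.

    The network mixes nM-scale activated factors with uM-scale zymogens
    and near-diffusion-limited binding, so an implicit stiff method is
    the default.  Tiny negative excursions (round-off below
    ``negative_floor``) are clipped to zero; anything more negative is a
    genuine model/parameter error and raises.
    """

    rtol: float = 1e-8
    atol: float = 1e-14  # mol/l
    method: str = "BDF"
    max_step: float = math.inf
    negative_floor: float = 1e-12  # mol/l
    n_points: int = 400  # output grid size (dense interpolant is kept anyway)


# ---------------------------------------------------------------------------
# rate-law evaluation and RHS compilation
# ---------------------------------------------------------------------------


def eval_rate(
    rate: RateLaw,
    state: Mapping[str, float],
    params: ParameterSet,
) -> float:
    """Evaluate one rate law at a state (mol/l) -> mol/(l*s).

    Pure function; raises :class:`ModelValidationError` naming the first
    unresolvable symbol or species.
    """
    total = 0.0
    for term in rate.terms:
        value = float(term.sign)
        for sym in term.constants:
            value *= params[sym]
        for name in term.species:
            try:
                value *= state[name]
            except KeyError:
                raise ModelValidationError(f"unknown species {name!r} in rate law") from None
        total += value
    return total


class CompiledNetwork:
    """Vectorised RHS and analytic Jacobian for one model.

    Every monomial term is flattened to (coefficient, up-to-MAXORD species
    indices); a padding slot holding the constant 1.0 fills unused factor
    positions.  ``dc/dt = M @ v`` where ``v`` are term values and ``M``
    folds the stoichiometric column of each term's reaction.
    """

    MAXORD = 4

    def __init__(self, model: NetworkModel) -> None:
        self.model = model
        n_sp = len(model.species)
        self.n_species = n_sp
        pad = n_sp  # index of the constant-1.0 slot
        coeffs: list[float] = []
        idx_rows: list[list[int]] = []
        cols: list[np.ndarray] = []  # per-term stoichiometric column
        for j, rxn in enumerate(model.reactions):
            col = model.stoichiometric_matrix[:, j].astype(float)
            for term in rxn.rate.terms:
                c = float(term.sign)
                for sym in term.constants:
                    c *= model.parameters[sym]
                ids = [model.index[name] for name in term.species]
                if len(ids) > self.MAXORD:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r}: monomial order {len(ids)} exceeds "
                        f"{self.MAXORD}"
                    )
                ids = ids + [pad] * (self.MAXORD - len(ids))
                coeffs.append(c)
                idx_rows.append(ids)
                cols.append(col)
        self.coeff = np.asarray(coeffs)
        self.slots = np.asarray(idx_rows, dtype=np.intp)  # (terms, MAXORD)
        self.M = np.column_stack(cols) if cols else np.zeros((n_sp, 0))
        # frozen concentrations of constant pool species
        self.constant_mask = np.array([s.constant for s in model.species])
        self._const_values = model.initial_vector()[self.constant_mask]

    def _extended(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.constant_mask.any():
            y = y.copy()
            y[self.constant_mask] = self._const_values
        return np.concatenate([y, [1.0]])

    def term_values(self, y: np.ndarray) -> np.ndarray:
        ye = self._extended(y)
        f = ye[self.slots]  # (terms, MAXORD)
        return self.coeff * f.prod(axis=1)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = self.M @ self.term_values(y)
        dy[self.constant_mask] = 0.0
        return dy

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        ye = self._extended(y)
        f = ye[self.slots]  # (terms, MAXORD)
        n_terms, maxord = f.shape
        dV = np.zeros((n_terms, self.n_species))
        for a in range(maxord):
            others = self.coeff * np.prod(np.delete(f, a, axis=1), axis=1)
            sl = self.slots[:, a]
            real = sl < self.n_species
            np.add.at(dV, (np.nonzero(real)[0], sl[real]), others[real])
        J = self.M @ dV
        J[self.constant_mask, :] = 0.0
        J[:, self.constant_mask] = 0.0
        return J


def assemble_rhs(model: NetworkModel) -> Callable[[Mapping[str, float]], dict[str, float]]:
    """Return a derivative evaluator ``state -> d state/dt`` (dict in/out).

    ``dc/dt = S @ v(c)``: the deterministic mass-action right-hand side.
    """
    compiled = CompiledNetwork(model)
    names = model.species_names

    def deriv(state: Mapping[str, float]) -> dict[str, float]:
        y = np.array([state[n] for n in names], dtype=float)
        dy = compiled.rhs(0.0, y)
        return dict(zip(names, dy))

    return deriv


def simulate(
    model: NetworkModel,
    horizon: float,
    controls: SimControls | None = None,
    initials: Mapping[str, float] | None = None,
    stop_species: str | None = None,
    stop_threshold: float | None = None,
    stop_conditions: Sequence[tuple[str, float]] | None = None,
) -> Trajectory:
    """Integrate the model over ``[0, horizon]`` seconds.

    ``stop_species``/``stop_threshold`` (or a list of ``(species,
    threshold)`` pairs in ``stop_conditions``) install terminal events
    that halt integration the first time any species reaches its
    threshold from below — the virtual clotting assays use this so that
    a clot ends the run early.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    controls = controls or SimControls()
    work = model.with_initials(initials) if initials else model
    compiled = CompiledNetwork(work)
    y0 = work.initial_vector()

    conditions = list(stop_conditions or [])
    if stop_species is not None:
        if stop_threshold is None:
            raise ValueError("stop_threshold required with stop_species")
        conditions.append((stop_species, stop_threshold))
    events = None
    if conditions:
        events = []
        for name, thr in conditions:
            k = work.index[name]

            def crossing(t: float, y: np.ndarray, k: int = k, thr: float = thr) -> float:
                return y[k] - thr

            crossing.terminal = True  # type: ignore[attr-defined]
            crossing.direction = 1.0  # type: ignore[attr-defined]
            events.append(crossing)

    t_eval = np.linspace(0.0, horizon, controls.n_points)
    sol = solve_ivp(
        compiled.rhs,
        (0.0, horizon),
        y0,
        method=controls.method,
        jac=compiled.jac,
        rtol=controls.rtol,
        atol=controls.atol,
        max_step=controls.max_step,
        dense_output=True,
        t_eval=t_eval,
        events=events,
    )
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}")

    times = sol.t
    conc = sol.y.T
    if sol.status == 1 and events is not None:
        # append the event point so the threshold crossing is inside the grid
        hits = [(te[0], ye[0]) for te, ye in zip(sol.t_events, sol.y_events)
                if len(te)]
        if hits:
            te, ye = min(hits, key=lambda h: h[0])
            if times.size == 0 or te > times[-1]:
                times = np.append(times, te)
                conc = np.vstack([conc, ye])
    if times.size == 0 or times[0] > 0.0:
        times = np.concatenate([[0.0], times])
        conc = np.vstack([y0, conc])

    low = conc.min(initial=0.0)
    if low < -controls.negative_floor:
        worst = np.unravel_index(np.argmin(conc), conc.shape)
        raise SimulationError(
            f"species {work.species_names[worst[1]]!r} reached {low:.3e} mol/l "
            f"(< -negative_floor); check parameters or tighten tolerances"
        )
    conc = np.clip(conc, 0.0, None)
    conc[0] = y0  # first row is exactly the initial condition

    return Trajectory(times, conc, work.species_names, dense=sol.sol)


def first_crossing_time(
    traj: Trajectory,
    species: str,
    threshold: float,
) -> float | None:
    """Earliest time the species reaches ``threshold`` from below.

    Linear interpolation between output points, refined with a root
    polish on the solver's dense interpolant when available.  Returns
    :data:`NO_CROSSING` (``None``) if the threshold is never reached.
    """
    k = traj.index[species]
    c = traj.concentrations[:, k]
    t = traj.times
    # tolerate interpolation round-off when a terminal event stopped at threshold
    eps = 1e-7 * abs(threshold)
    if c[0] >= threshold - eps:
        return float(t[0])
    above = np.nonzero(c >= threshold - eps)[0]
    if above.size == 0:
        return NO_CROSSING
    i = int(above[0])
    t0, t1 = t[i - 1], t[i]
    c0, c1 = c[i - 1], c[i]
    # linear interpolation fallback
    tc = t0 + (threshold - c0) / (c1 - c0) * (t1 - t0) if c1 > c0 else t1
    if traj.dense is not None and t1 > t0:
        f = lambda x: float(traj.dense(x)[k]) - threshold
        try:
            if f(t0) < 0.0 <= f(t1):
                tc = brentq(f, t0, t1, xtol=1e-9 * max(t1, 1.0))
        except ValueError:
            pass
    return float(tc)


def conserved_moiety_residual(
    traj: Trajectory,
    weights: Mapping[str, float],
    model: NetworkModel,
) -> float:
    """Max over time of |w.c(t) - w.c(0)| for a conserved moiety.

    ``weights`` must be a left null-vector of the model's stoichiometric
    matrix (e.g. the prothrombin moiety II + IIa + mIIa + complexes);
    otherwise the moiety is not conserved by construction and the call
    raises.  Flow-coupled (open) models contain transport reactions whose
    columns break closure, so they are rejected here.
    """
    w = np.zeros(len(model.species))
    for name, weight in weights.items():
        w[model.index[name]] = weight
    if np.max(np.abs(w @ model.stoichiometric_matrix)) != 0:
        raise ModelValidationError(
            "weights are not a left null-vector of the stoichiometric matrix; "
            "not a conserved moiety of this (possibly open) model"
        )
    wt = np.zeros(len(traj.species_names))
    for name, weight in weights.items():
        wt[traj.index[name]] = weight
    totals = traj.concentrations @ wt
    return float(np.max(np.abs(totals - totals[0])))


def write_trajectory_csv(traj: Trajectory, path: str) -> None:
    """Tidy CSV: one row per (time, species); units in the header."""
    with open(path, "w") as fh:
        fh.write("time_s,species,concentration_mol_per_l\n")
        for i, t in enumerate(traj.times):
            for j, name in enumerate(traj.species_names):
                fh.write(f"{t!r},{name},{traj.concentrations[i, j]!r}\n")
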