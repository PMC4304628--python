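"""Selenium-metabolism reaction kinetics.

A small mass-action / saturating-kinetics reaction-network layer: species,
reactions with structured rate laws, deterministic ODE simulation, robust
steady-state solving, and dose-response curves of relative mutation rate
versus extracellular selenium.

The bundled reference network captures the trade-off at the heart of the
selenium chemoprevention question: selenide (HSe) damages DNA both directly
and by amplifying peroxide-mediated damage through redox cycling, while
methylselenol (MeSeH), produced from selenide by methylation, is protective
because it catalyses peroxide reduction.  Raising extracellular selenium
therefore pushes the damaged-DNA steady state in a direction that depends on
the balance of rate constants — the mechanistic uncertainty the downstream
trial-simulation machinery propagates.

Units: concentrations in mM; time in years.  The genomic pool is normalized
(DNA + dmDNA = 1), so damaged DNA is a dimensionless fraction.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "KineticsError",
    "IntegrationError",
    "SteadyStateError",
    "Species",
    "RateTerm",
    "Reaction",
    "ReactionNetwork",
    "RateParameterSet",
    "Trajectory",
    "DoseResponse",
    "SELENIUM_SPECIES",
    "DAMAGED_DNA_SPECIES",
    "DNA_SPECIES",
    "BASELINE_SELENIUM_MM",
    "reference_selenium_network",
    "nominal_parameters",
    "validate_parameters",
    "simulate",
    "steady_state",
    "steady_state_dmDNA",
    "dose_response",
    "import_sbml_subset",
    "export_sbml",
]

# Canonical species names used by the reference network and by the
# selenium-level plumbing (clamped extracellular pool, damaged-DNA readout).
SELENIUM_SPECIES = "Se_ext"
DAMAGED_DNA_SPECIES = "dmDNA"
DNA_SPECIES = "DNA"

#: Baseline (unsupplemented) extracellular selenium, mM.
BASELINE_SELENIUM_MM = 1.7

#: Steady state declared when max |dC/dt| < STEADY_STATE_TOL * max(C).
STEADY_STATE_TOL = 1e-9


class KineticsError(Exception):
    """Base class for kinetics-layer failures."""


class IntegrationError(KineticsError):
    """ODE integration failed; carries the last valid state reached."""

    def __init__(self, message: str, last_time: float | None = None,
                 last_state: np.ndarray | None = None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


class SteadyStateError(KineticsError):
    """No steady state found within the budget; carries residual derivatives."""

    def __init__(self, message: str, residual: np.ndarray | None = None):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# Network data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    """One chemical species.

    ``clamped`` species are held fixed during integration (boundary
    conditions), e.g. the extracellular selenium pool set by diet or
    supplementation.
    """

    name: str
    initial_concentration: float = 0.0
    clamped: bool = False

    def __post_init__(self):
        if self.initial_concentration < 0:
            raise ValueError(
                f"species {self.name!r}: initial concentration must be >= 0")


@dataclass(frozen=True)
class RateTerm:
    """One additive term of a rate law.

    rate contribution = constant * prod([S] for S in linear)
                                 * prod([S] / (Km + [S]) for (S, Km) in saturating)

    ``linear`` entries multiply the term by a concentration (mass-action
    factors, including catalytic modifiers); ``saturating`` entries are
    Michaelis-Menten style factors with a named half-saturation constant.
    Factor tuples are stored sorted so structurally equal laws compare equal.
    """

    constant: str
    linear: tuple[str, ...] = ()
    saturating: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "linear", tuple(sorted(self.linear)))
        object.__setattr__(self, "saturating", tuple(sorted(self.saturating)))

    @property
    def constant_names(self) -> tuple[str, ...]:
        return (self.constant,) + tuple(km for _, km in self.saturating)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(self.linear) + tuple(s for s, _ in self.saturating)


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry plus a structured rate law.

    ``modifiers`` are species that appear in the rate law without being
    consumed or produced (catalysts, e.g. methylselenol in peroxide
    reduction).
    """

    id: str
    reactants: tuple[tuple[str, int], ...] = ()
    products: tuple[tuple[str, int], ...] = ()
    modifiers: tuple[str, ...] = ()
    terms: tuple[RateTerm, ...] = ()

    def __post_init__(self):
        def norm(stoich):
            items = tuple(sorted(dict(stoich).items()))
            for name, count in items:
                if int(count) != count or count < 0:
                    raise ValueError(
                        f"reaction {self.id!r}: stoichiometric coefficient for "
                        f"{name!r} must be a non-negative integer")
            return tuple((n, int(c)) for n, c in items if c > 0)

        object.__setattr__(self, "reactants", norm(self.reactants))
        object.__setattr__(self, "products", norm(self.products))
        object.__setattr__(self, "modifiers", tuple(sorted(set(self.modifiers))))
        object.__setattr__(self, "terms",
                           tuple(sorted(self.terms, key=lambda t: t.constant)))
        if not self.terms:
            raise ValueError(f"reaction {self.id!r}: rate law has no terms")

    @property
    def law_kind(self) -> str:
        """'saturating' if any term has a half-saturation factor, else 'mass_action'."""
        return "saturating" if any(t.saturating for t in self.terms) else "mass_action"

    @property
    def constant_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for t in self.terms:
            names.extend(t.constant_names)
        return tuple(names)

    def net_stoichiometry(self) -> Dict[str, int]:
        net: Dict[str, int] = {}
        for name, c in self.reactants:
            net[name] = net.get(name, 0) - c
        for name, c in self.products:
            net[name] = net.get(name, 0) + c
        return net


RateParameterSet = Dict[str, float]


@dataclass(frozen=True)
class ReactionNetwork:
    """A reaction network: species, reactions and the ordered constant list."""

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    parameter_names: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "parameter_names", tuple(self.parameter_names))
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        known = set(names)
        seen_constants: list[str] = []
        for rxn in self.reactions:
            for name in itertools.chain(
                    (n for n, _ in rxn.reactants),
                    (n for n, _ in rxn.products),
                    rxn.modifiers):
                if name not in known:
                    raise ValueError(
                        f"reaction {rxn.id!r} references unknown species {name!r}")
            for term in rxn.terms:
                for sp in term.species_names:
                    if sp not in known:
                        raise ValueError(
                            f"reaction {rxn.id!r} rate law references unknown "
                            f"species {sp!r}")
            seen_constants.extend(rxn.constant_names)
        if len(set(seen_constants)) != len(seen_constants):
            dupes = sorted({c for c in seen_constants
                            if seen_constants.count(c) > 1})
            raise ValueError(f"rate constants shared between terms: {dupes}")
        if set(seen_constants) != set(self.parameter_names):
            raise ValueError(
                "parameter_names must list exactly the constants used by the "
                f"rate laws; missing={sorted(set(seen_constants) - set(self.parameter_names))} "
                f"extra={sorted(set(self.parameter_names) - set(seen_constants))}")
        if len(set(self.parameter_names)) != len(self.parameter_names):
            raise ValueError("parameter_names contains duplicates")

    # -- helpers ------------------------------------------------------------
    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"no species named {name!r}") from None

    def get_species(self, name: str) -> Species:
        return self.species[self.species_index(name)]

    def initial_state(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        x0 = np.array([s.initial_concentration for s in self.species], float)
        if overrides:
            for name, value in overrides.items():
                x0[self.species_index(name)] = value
        return x0

    def stoichiometric_matrix(self) -> np.ndarray:
        """Net stoichiometry, species x reactions; zero rows for clamped species."""
        S = np.zeros((len(self.species), len(self.reactions)))
        idx = {s.name: i for i, s in enumerate(self.species)}
        clamped = {s.name for s in self.species if s.clamped}
        for j, rxn in enumerate(self.reactions):
            for name, c in rxn.net_stoichiometry().items():
                if name not in clamped:
                    S[idx[name], j] = c
        return S

    def conservation_laws(self, tol: float = 1e-10) -> np.ndarray:
        """Rows spanning the left null space of the stoichiometric matrix.

        Each row w gives a conserved linear combination w . C(t) (clamped
        species excluded by construction, their columns being zero).
        """
        S = self.stoichiometric_matrix()
        u, s, vt = np.linalg.svd(S.T)
        rank = int(np.sum(s > tol * (s[0] if s.size else 1.0)))
        null = vt[rank:]
        return null

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": [
                {"name": s.name,
                 "initial_concentration": s.initial_concentration,
                 "clamped": s.clamped}
                for s in self.species],
            "reactions": [
                {"id": r.id,
                 "reactants": {n: c for n, c in r.reactants},
                 "products": {n: c for n, c in r.products},
                 "modifiers": list(r.modifiers),
                 "terms": [
                     {"constant": t.constant,
                      "linear": list(t.linear),
                      "saturating": [list(p) for p in t.saturating]}
                     for t in r.terms]}
                for r in self.reactions],
            "parameter_names": list(self.parameter_names),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ReactionNetwork":
        species = tuple(Species(**s) for s in data["species"])
        reactions = tuple(
            Reaction(
                id=r["id"],
                reactants=tuple(r["reactants"].items()),
                products=tuple(r["products"].items()),
                modifiers=tuple(r["modifiers"]),
                terms=tuple(
                    RateTerm(constant=t["constant"],
                             linear=tuple(t["linear"]),
                             saturating=tuple(tuple(p) for p in t["saturating"]))
                    for t in r["terms"]))
            for r in data["reactions"])
        return cls(species, reactions, tuple(data["parameter_names"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ReactionNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Reference network (Se_ext -> selenide -> methylselenol; peroxide; DNA pools)
# ---------------------------------------------------------------------------

def reference_selenium_network() -> ReactionNetwork:
    """The bundled 18-constant selenium-metabolism network.

    Species: clamped extracellular selenium (Se_ext), intracellular selenide
    (HSe), methylselenol (MeSeH), hydrogen peroxide (H2O2), and the conserved
    genomic pool DNA + dmDNA (normalized to 1).

    Reactions (18 rate constants, named ``Rn_km``):

    ======  =======================================================  ==========
    id      process                                                  constants
    ======  =======================================================  ==========
    R1      selenide-mediated DNA damage (saturating in HSe)         R1_k0, R1_k1
    R2      MeSeH-catalysed peroxide reduction (saturating in H2O2)  R2_k0, R2_k1
    R3      peroxide-mediated DNA damage; linear term plus a
            selenide-amplified redox-cycling term                    R3_k0, R3_k1, R3_k2
    R4      methylation of selenide to methylselenol (saturating)    R4_k0, R4_k1
    R5      methylselenol clearance                                  R5_k0
    R6      constitutive peroxide production                         R6_k0
    R7      saturating repair of damaged DNA                         R7_k0, R7_k1
    R8      import of extracellular selenium as selenide             R8_k0, R8_k1
    R9      selenide clearance into selenoprotein synthesis          R9_k0
    R10     selenide redox cycling producing peroxide                R10_k0
    R11     basal peroxide decay                                     R11_k0
    ======  =======================================================  ==========

    R3's rate is (R3_k0*[H2O2] + R3_k2*[H2O2]*[HSe]/(R3_k1+[HSe]))*[DNA]:
    R3_k0 sets selenium-independent oxidative damage while R3_k2 scales the
    component amplified by selenide, so a small R3_k2 attenuates
    selenium-driven harm.
    """
    se, hse, mseh, h2o2, dna, dmdna = (
        SELENIUM_SPECIES, "HSe", "MeSeH", "H2O2", DNA_SPECIES, DAMAGED_DNA_SPECIES)
    species = (
        Species(se, initial_concentration=BASELINE_SELENIUM_MM, clamped=True),
        Species(hse, 0.0),
        Species(mseh, 0.0),
        Species(h2o2, 0.0),
        Species(dna, 1.0),
        Species(dmdna, 0.0),
    )
    reactions = (
        Reaction("R1", reactants=((dna, 1),), products=((dmdna, 1),),
                 modifiers=(hse,),
                 terms=(RateTerm("R1_k0", linear=(dna,),
                                 saturating=((hse, "R1_k1"),)),)),
        Reaction("R2", reactants=((h2o2, 1),), products=(),
                 modifiers=(mseh,),
                 terms=(RateTerm("R2_k0", linear=(mseh,),
                                 saturating=((h2o2, "R2_k1"),)),)),
        Reaction("R3", reactants=((dna, 1),), products=((dmdna, 1),),
                 modifiers=(h2o2, hse),
                 terms=(RateTerm("R3_k0", linear=(dna, h2o2)),
                        RateTerm("R3_k2", linear=(dna, h2o2),
                                 saturating=((hse, "R3_k1"),)))),
        Reaction("R4", reactants=((hse, 1),), products=((mseh, 1),),
                 terms=(RateTerm("R4_k0", saturating=((hse, "R4_k1"),)),)),
        Reaction("R5", reactants=((mseh, 1),), products=(),
                 terms=(RateTerm("R5_k0", linear=(mseh,)),)),
        Reaction("R6", reactants=(), products=((h2o2, 1),),
                 terms=(RateTerm("R6_k0"),)),
        Reaction("R7", reactants=((dmdna, 1),), products=((dna, 1),),
                 terms=(RateTerm("R7_k0", saturating=((dmdna, "R7_k1"),)),)),
        Reaction("R8", reactants=((se, 1),), products=((hse, 1),),
                 terms=(RateTerm("R8_k0", saturating=((se, "R8_k1"),)),)),
        Reaction("R9", reactants=((hse, 1),), products=(),
                 terms=(RateTerm("R9_k0", linear=(hse,)),)),
        Reaction("R10", reactants=(), products=((h2o2, 1),),
                 modifiers=(hse,),
                 terms=(RateTerm("R10_k0", linear=(hse,)),)),
        Reaction("R11", reactants=((h2o2, 1),), products=(),
                 terms=(RateTerm("R11_k0", linear=(h2o2,)),)),
    )
    parameter_names = (
        "R1_k0", "R1_k1", "R2_k0", "R2_k1", "R3_k0", "R3_k1", "R3_k2",
        "R4_k0", "R4_k1", "R5_k0", "R6_k0", "R7_k0", "R7_k1",
        "R8_k0", "R8_k1", "R9_k0", "R10_k0", "R11_k0",
    )
    return ReactionNetwork(species, reactions, parameter_names)


def nominal_parameters(network: ReactionNetwork,
                       bounds: Mapping[str, tuple[float, float]] | None = None
                       ) -> RateParameterSet:
    """Geometric-mean-of-bounds parameter set (log-space centre).

    With the default (1e-6, 1e6) bounds every constant is 1.0.
    """
    out: RateParameterSet = {}
    for name in network.parameter_names:
        lo, hi = (1e-6, 1e6) if bounds is None else bounds[name]
        out[name] = math.sqrt(lo * hi)
    return out


def validate_parameters(network: ReactionNetwork, params: Mapping[str, float],
                        bounds: Mapping[str, tuple[float, float]] | None = None
                        ) -> None:
    for name in network.parameter_names:
        if name not in params:
            raise ValueError(f"missing rate constant {name!r}")
        v = params[name]
        if not (v > 0) or not math.isfinite(v):
            raise ValueError(f"rate constant {name!r} must be strictly positive")
        if bounds is not None:
            lo, hi = bounds[name]
            if not (lo <= v <= hi):
                raise ValueError(
                    f"rate constant {name!r}={v:g} outside bounds [{lo:g}, {hi:g}]")


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------

class _CompiledNetwork:
    """Index-based evaluator for rates and species derivatives."""

    def __init__(self, network: ReactionNetwork, params: Mapping[str, float]):
        validate_parameters(network, params)
        self.network = network
        idx = {s.name: i for i, s in enumerate(network.species)}
        self.n = len(network.species)
        self.clamped = np.array([s.clamped for s in network.species])
        # terms: (k, linear indices, [(sp_idx, Km)])
        self.rxn_terms: list[list[tuple[float, list[int], list[tuple[int, float]]]]] = []
        self.net_stoich: list[list[tuple[int, float]]] = []
        for rxn in network.reactions:
            terms = []
            for t in rxn.terms:
                terms.append((
                    float(params[t.constant]),
                    [idx[s] for s in t.linear],
                    [(idx[s], float(params[km])) for s, km in t.saturating]))
            self.rxn_terms.append(terms)
            self.net_stoich.append(
                [(idx[name], float(c))
                 for name, c in rxn.net_stoichiometry().items()
                 if not network.species[idx[name]].clamped])

    def rates(self, x: np.ndarray) -> np.ndarray:
        xe = np.maximum(x, 0.0)  # guard tiny negative excursions
        out = np.empty(len(self.rxn_terms))
        for j, terms in enumerate(self.rxn_terms):
            r = 0.0
            for k, lin, sat in terms:
                v = k
                for i in lin:
                    v *= xe[i]
                for i, km in sat:
                    v *= xe[i] / (km + xe[i])
                r += v
            out[j] = r
        return out

    def __call__(self, t: float, x: np.ndarray) -> np.ndarray:
        rates = self.rates(x)
        dx = np.zeros(self.n)
        for j, stoich in enumerate(self.net_stoich):
            r = rates[j]
            for i, c in stoich:
                dx[i] += c * r
        return dx


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Simulated time course: time grid x species concentrations."""

    times: np.ndarray
    concentrations: np.ndarray  # (n_times, n_species)
    species_names: tuple[str, ...]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.species_names.index(name)]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.concentrations, index=self.times,
                            columns=list(self.species_names))

    @property
    def final_state(self) -> np.ndarray:
        return self.concentrations[-1]


def simulate(network: ReactionNetwork, params: Mapping[str, float],
             initial_override: Mapping[str, float] | None = None,
             t_end: float = 10.0, n_points: int = 200,
             rtol: float = 1e-8, atol: float = 1e-12) -> Trajectory:
    """Integrate the network ODEs over [0, t_end] (years).

    Clamped species are held at their (possibly overridden) initial values.
    Raises :class:`IntegrationError` carrying the last valid state on solver
    failure.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    rhs = _CompiledNetwork(network, params)
    x0 = network.initial_state(initial_override)
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), x0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        last_x = sol.y[:, -1] if sol.t.size else x0
        raise IntegrationError(
            f"integration failed at t={last_t:.3g}: {sol.message}",
            last_time=last_t, last_state=last_x)
    return Trajectory(sol.t, sol.y.T.copy(), network.species_names)


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------

def _steady_residual_system(rhs: _CompiledNetwork, network: ReactionNetwork,
                            x_ref: np.ndarray):
    """Residual for refinement: derivatives of free species plus conservation
    constraints anchored at x_ref (overdetermined but consistent)."""
    free = ~rhs.clamped
    cons = network.conservation_laws()
    totals = cons @ x_ref if cons.size else np.zeros(0)

    def residual(x_free: np.ndarray) -> np.ndarray:
        x = x_ref.copy()
        x[free] = x_free
        parts = [rhs(0.0, x)[free]]
        if cons.size:
            parts.append(cons @ x - totals)
        return np.concatenate(parts)

    return residual, free


def _is_reference_topology(network: ReactionNetwork) -> bool:
    global _REFERENCE_CACHE
    if _REFERENCE_CACHE is None:
        _REFERENCE_CACHE = reference_selenium_network()
    ref = _REFERENCE_CACHE
    return (network.parameter_names == ref.parameter_names
            and network.species_names == ref.species_names
            and network.reactions == ref.reactions)


_REFERENCE_CACHE: ReactionNetwork | None = None


def _fast_reference_steady_state(network: ReactionNetwork,
                                 params: Mapping[str, float],
                                 x0: np.ndarray) -> np.ndarray:
    """Exact steady state of the reference network via its cascade structure.

    The damage reactions treat selenide and peroxide as modifiers, so the
    upstream subsystem HSe -> MeSeH -> H2O2 is independent of the DNA pools
    and each balance is a monotone scalar equation solved by bisection; the
    damaged-DNA balance then closes on the conserved genomic pool.  Orders of
    magnitude faster than stiff integration and used automatically whenever
    the network matches the bundled topology.
    """
    from scipy.optimize import brentq
    p = params
    se = x0[network.species_index(SELENIUM_SPECIES)]
    total_dna = (x0[network.species_index(DNA_SPECIES)]
                 + x0[network.species_index(DAMAGED_DNA_SPECIES)])
    r8 = p["R8_k0"] * se / (p["R8_k1"] + se)

    def hse_balance(h):
        return r8 - p["R4_k0"] * h / (p["R4_k1"] + h) - p["R9_k0"] * h

    if r8 <= 0:
        hse = 0.0
    else:
        hi = r8 / p["R9_k0"] * (1 + 1e-12)
        hse = brentq(hse_balance, 0.0, hi, xtol=1e-300, rtol=1e-15)
    mseh = p["R4_k0"] * hse / (p["R4_k1"] + hse) / p["R5_k0"]
    h2o2_in = p["R6_k0"] + p["R10_k0"] * hse

    def h2o2_balance(x):
        return (h2o2_in - p["R2_k0"] * mseh * x / (p["R2_k1"] + x)
                - p["R11_k0"] * x)

    if h2o2_in <= 0:
        h2o2 = 0.0
    else:
        hi = h2o2_in / p["R11_k0"] * (1 + 1e-12)
        h2o2 = brentq(h2o2_balance, 0.0, hi, xtol=1e-300, rtol=1e-15)
    lam = (p["R1_k0"] * hse / (p["R1_k1"] + hse) + p["R3_k0"] * h2o2
           + p["R3_k2"] * h2o2 * hse / (p["R3_k1"] + hse))

    def dmdna_balance(d):
        return lam * (total_dna - d) - p["R7_k0"] * d / (p["R7_k1"] + d)

    if lam <= 0 or total_dna <= 0:
        dmdna = 0.0
    else:
        dmdna = brentq(dmdna_balance, 0.0, total_dna, xtol=1e-300, rtol=1e-15)
    out = np.array(x0, float)
    for name, value in (("HSe", hse), ("MeSeH", mseh), ("H2O2", h2o2),
                        (DAMAGED_DNA_SPECIES, dmdna),
                        (DNA_SPECIES, total_dna - dmdna)):
        out[network.species_index(name)] = value
    return out


def steady_state(network: ReactionNetwork, params: Mapping[str, float],
                 initial_override: Mapping[str, float] | None = None,
                 tol: float = STEADY_STATE_TOL,
                 t_max: float = 1e7,
                 x0: np.ndarray | None = None) -> np.ndarray:
    """Full steady-state vector.

    For the bundled reference topology the cascade structure gives the exact
    steady state by scalar root finding; any other network is integrated to
    quasi-equilibrium and refined with a bounded least-squares solve on the
    derivative/conservation system.  Converged when
    ``max |dC/dt| < tol * max(C)`` over non-clamped species.  Deterministic
    for fixed inputs; ``x0`` may supply a warm start for the generic path.
    """
    if _is_reference_topology(network):
        validate_parameters(network, params)
        base = network.initial_state(initial_override)
        return _fast_reference_steady_state(network, params, base)
    rhs = _CompiledNetwork(network, params)
    x = network.initial_state(initial_override) if x0 is None else np.array(x0, float)
    free = ~rhs.clamped

    def converged(xv: np.ndarray) -> bool:
        d = rhs(0.0, xv)
        scale = max(np.max(np.abs(xv)), 1e-300)
        return float(np.max(np.abs(d[free]))) < tol * scale

    def try_refine(xv: np.ndarray) -> np.ndarray | None:
        residual, _ = _steady_residual_system(rhs, network, xv)
        lo = np.zeros(int(free.sum()))
        try:
            res = least_squares(residual, np.maximum(xv[free], 0.0),
                                bounds=(lo, np.inf), xtol=1e-14, ftol=1e-14,
                                gtol=1e-14, max_nfev=400)
        except Exception:
            return None
        x_new = xv.copy()
        x_new[free] = res.x
        return x_new if converged(x_new) else None

    t = 1.0
    last = x
    while t <= t_max:
        try:
            sol = solve_ivp(rhs, (0.0, t), last, method="LSODA",
                            rtol=1e-9, atol=1e-13)
        except Exception as exc:  # pragma: no cover - defensive
            raise SteadyStateError(f"integration toward steady state failed: {exc}")
        if sol.success:
            last = sol.y[:, -1]
            if converged(last):
                return np.maximum(last, 0.0)
            refined = try_refine(last)
            if refined is not None:
                return np.maximum(refined, 0.0)
        t *= 10.0
    refined = try_refine(last)
    if refined is not None:
        return np.maximum(refined, 0.0)
    raise SteadyStateError(
        "no steady state within the time budget; residual derivatives attached",
        residual=rhs(0.0, last))


def steady_state_dmDNA(network: ReactionNetwork, params: Mapping[str, float],
                       selenium_level: float,
                       selenium_species: str = SELENIUM_SPECIES,
                       damaged_species: str = DAMAGED_DNA_SPECIES,
                       x0: np.ndarray | None = None,
                       tol: float = STEADY_STATE_TOL) -> float:
    """Steady-state damaged-DNA level at a clamped extracellular selenium level."""
    if not selenium_level > 0:
        raise ValueError("selenium_level must be positive")
    x = steady_state(network, params,
                     initial_override={selenium_species: selenium_level},
                     tol=tol, x0=x0)
    return float(x[network.species_index(damaged_species)])


# ---------------------------------------------------------------------------
# Dose response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponse:
    """Relative mutation rate (dmDNA steady state vs baseline) over a selenium grid."""

    selenium_levels: np.ndarray
    relative_mutation_rate: np.ndarray
    baseline: float = BASELINE_SELENIUM_MM

    def __post_init__(self):
        self.selenium_levels = np.asarray(self.selenium_levels, float)
        self.relative_mutation_rate = np.asarray(self.relative_mutation_rate, float)
        if np.any(self.relative_mutation_rate < 0):
            raise ValueError("relative mutation rates must be >= 0")

    def at(self, level: float) -> float:
        i = int(np.argmin(np.abs(self.selenium_levels - level)))
        if abs(self.selenium_levels[i] - level) > 1e-9:
            return float(np.interp(level, self.selenium_levels,
                                   self.relative_mutation_rate))
        return float(self.relative_mutation_rate[i])

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"selenium_mM": self.selenium_levels,
                      "relative_mutation_rate": self.relative_mutation_rate}
                     ).to_csv(path, index=False)


def dose_response(network: ReactionNetwork, params: Mapping[str, float],
                  selenium_grid: Sequence[float],
                  baseline: float = BASELINE_SELENIUM_MM) -> DoseResponse:
    """Relative mutation rate versus selenium level.

    Ratios are dmDNA steady states normalized by the baseline level, so the
    value at ``baseline`` is exactly 1.0.  The baseline is added to the grid
    if absent.  Steady states are warm-started along the grid.
    """
    grid = np.asarray(sorted(set(float(v) for v in selenium_grid) | {float(baseline)}))
    values = np.empty_like(grid)
    guess = None
    # evaluate baseline first (also the warm start anchor)
    try:
        base_x = steady_state(network, params,
                              initial_override={SELENIUM_SPECIES: baseline})
    except SteadyStateError as exc:
        raise SteadyStateError(
            f"steady state failed at baseline selenium {baseline} mM: {exc}",
            residual=exc.residual)
    base = float(base_x[network.species_index(DAMAGED_DNA_SPECIES)])
    if base <= 0:
        raise SteadyStateError(
            "baseline damaged-DNA steady state is zero; relative dose response undefined")
    guess = base_x
    for i, level in enumerate(grid):
        if abs(level - baseline) < 1e-12:
            values[i] = 1.0
            continue
        try:
            x = steady_state(network, params,
                             initial_override={SELENIUM_SPECIES: level},
                             x0=_with_level(network, guess, level))
        except SteadyStateError as exc:
            raise SteadyStateError(
                f"steady state failed at selenium level {level} mM: {exc}",
                residual=exc.residual)
        guess = x
        values[i] = float(x[network.species_index(DAMAGED_DNA_SPECIES)]) / base
    return DoseResponse(grid, values, baseline=float(baseline))


def _with_level(network: ReactionNetwork, x: np.ndarray, level: float) -> np.ndarray:
    out = np.array(x, float)
    out[network.species_index(SELENIUM_SPECIES)] = level
    return out


# SBML I/O lives in _sbml; re-exported here as part of the kinetics surface.
def import_sbml_subset(path):
    """Read a restricted-subset SBML file; see :mod:`trialvoi._sbml`."""
    from ._sbml import import_sbml_subset as _impl
    return _impl(path)


def export_sbml(network: ReactionNetwork, params: Mapping[str, float], path) -> None:
    """Write the network and constants as SBML Level 3 Version 1."""
    from ._sbml import export_sbml as _impl
    return _impl(network, params, path)
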