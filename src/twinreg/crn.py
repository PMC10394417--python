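"""Mass-action chemical reaction networks and their deterministic rate equations.

A :class:`ReactionNetwork` is the single in-memory representation used for
open-loop plants, controller motifs, and closed-loop compositions.  Kinetics
are strictly mass action: the propensity of a reaction is its rate constant
times the product of reactant concentrations raised to their stoichiometric
coefficients.  Units are fixed to nanomolar (nM) and minutes throughout, so a
zeroth-order rate constant carries nM min^-1, a first-order one min^-1 and a
second-order one nM^-1 min^-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "CRNStructureError",
    "stoichiometry_matrix",
    "rate_vector",
    "ode_rhs",
    "network_to_json",
    "network_from_json",
]

#: annotation tags a reaction may carry; purely descriptive
REACTION_KINDS = (
    "transformation",
    "catalytic_production",
    "catalytic_inhibition",
    "annihilation",
    "zeroth_order",
)


class CRNStructureError(ValueError):
    """Raised when a network violates a structural invariant."""


@dataclass(frozen=True)
class Species:
    """A chemical species with a name and an initial concentration in nM."""

    name: str
    initial_concentration: float = 0.0

    def __post_init__(self) -> None:
        if not self.name:
            raise CRNStructureError("species name must be non-empty")
        if self.initial_concentration < 0:
            raise CRNStructureError(
                f"species {self.name!r}: initial concentration must be >= 0, "
                f"got {self.initial_concentration}"
            )


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction.

    ``reactants`` and ``products`` are multisets encoded as tuples of
    ``(species_name, coefficient)`` with positive integer coefficients.  An
    empty reactant tuple encodes zeroth-order production (∅→X); an empty
    product tuple encodes pure consumption (X→∅ or annihilation to ∅).
    ``rate_parameter`` names an entry of the owning network's parameter table.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_parameter: str
    kind: str | None = None

    def __post_init__(self) -> None:
        for name, coeff in self.reactants + self.products:
            if not isinstance(coeff, int) or coeff < 1:
                raise CRNStructureError(
                    f"reaction {self!s}: stoichiometric coefficient for "
                    f"{name!r} must be a positive integer, got {coeff!r}"
                )
        if self.kind is not None and self.kind not in REACTION_KINDS:
            raise CRNStructureError(f"unknown reaction kind {self.kind!r}")

    @property
    def order(self) -> int:
        """Total reaction order (sum of reactant coefficients)."""
        return sum(c for _, c in self.reactants)

    def __str__(self) -> str:
        def side(terms: tuple[tuple[str, int], ...]) -> str:
            if not terms:
                return "∅"
            return " + ".join(n if c == 1 else f"{c} {n}" for n, c in terms)

        return f"{side(self.reactants)} → {side(self.products)} @ {self.rate_parameter}"


def _units_for_order(order: int) -> str:
    if order == 0:
        return "nM min^-1"
    if order == 1:
        return "min^-1"
    return f"nM^-{order - 1} min^-1"


@dataclass
class ReactionNetwork:
    """Species, mass-action reactions and a shared parameter table.

    The parameter table is a plain dict shared by reference with any
    composition built from this network, so a timed disturbance that rebinds
    one entry is seen by every reaction referencing it without recompilation.
    """

    species: list[Species]
    reactions: list[Reaction]
    parameters: dict[str, float]
    outputs: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CRNStructureError(f"duplicate species names: {dupes}")
        declared = set(names)
        for rxn in self.reactions:
            for sp, _ in rxn.reactants + rxn.products:
                if sp not in declared:
                    raise CRNStructureError(
                        f"reaction {rxn!s} references undeclared species {sp!r}"
                    )
            if rxn.rate_parameter not in self.parameters:
                raise CRNStructureError(
                    f"reaction {rxn!s}: rate parameter {rxn.rate_parameter!r} "
                    "missing from parameter table"
                )
        for pname, value in self.parameters.items():
            if not value > 0:
                raise CRNStructureError(
                    f"parameter {pname!r} must be strictly positive, got {value}"
                )
        for out in self.outputs:
            if out not in declared:
                raise CRNStructureError(f"designated output {out!r} not declared")

    # -- convenience -------------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"no species named {name!r}") from None

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], float)

    def parameter_units(self) -> dict[str, str]:
        """Units of each rate constant, inferred from reaction order."""
        units: dict[str, str] = {}
        for rxn in self.reactions:
            units[rxn.rate_parameter] = _units_for_order(rxn.order)
        return units

    def __str__(self) -> str:
        lines = [f"ReactionNetwork {self.name or '<anonymous>'}"]
        lines += [f"  species: {', '.join(self.species_names)}"]
        lines += [f"  {r}" for r in self.reactions]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# rate equations


def stoichiometry_matrix(net: ReactionNetwork) -> np.ndarray:
    """Integer net-change matrix, shape (n_species, n_reactions).

    Entry (i, j) is the net production of species i by one firing of
    reaction j (products minus reactants); a catalyst appearing on both
    sides with equal coefficients contributes zero.
    """
    index = {s.name: i for i, s in enumerate(net.species)}
    S = np.zeros((len(net.species), len(net.reactions)), dtype=int)
    for j, rxn in enumerate(net.reactions):
        for sp, coeff in rxn.reactants:
            S[index[sp], j] -= coeff
        for sp, coeff in rxn.products:
            S[index[sp], j] += coeff
    return S


def rate_vector(net: ReactionNetwork, state: Sequence[float]) -> np.ndarray:
    """Mass-action propensities of every reaction at ``state`` (nM min^-1).

    A zeroth-order reaction returns its bare rate constant; a reaction with a
    zero-concentration reactant returns exactly 0.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (len(net.species),):
        raise ValueError(
            f"state has shape {x.shape}, expected ({len(net.species)},)"
        )
    if np.any(x < 0):
        bad = [net.species_names[i] for i in np.flatnonzero(x < 0)]
        raise ValueError(f"negative concentration for species {bad}")
    index = {s.name: i for i, s in enumerate(net.species)}
    rates = np.empty(len(net.reactions))
    for j, rxn in enumerate(net.reactions):
        r = net.parameters[rxn.rate_parameter]
        for sp, coeff in rxn.reactants:
            r *= x[index[sp]] ** coeff
        rates[j] = r
    return rates


def ode_rhs(net: ReactionNetwork) -> Callable[[Sequence[float]], np.ndarray]:
    """Deterministic rate equations, d(state)/dt = S · v(state).

    The returned callable closes over the network's parameter table by
    reference: rebinding a parameter changes the dynamics immediately (this
    is how timed disturbances are applied).
    """
    S = stoichiometry_matrix(net)

    def rhs(state: Sequence[float]) -> np.ndarray:
        return S @ rate_vector(net, state)

    return rhs


def ode_jacobian(net: ReactionNetwork) -> Callable[[Sequence[float]], np.ndarray]:
    """Analytic Jacobian of the mass-action right-hand side.

    Mass-action rates are polynomial, so the partial derivatives are exact:
    d(rate_j)/dx_m = k_j * c_mj * x_m^(c_mj - 1) * Π_{s≠m} x_s^(c_sj).
    """
    S = stoichiometry_matrix(net)
    index = {s.name: i for i, s in enumerate(net.species)}
    n = len(net.species)

    def jac(state: Sequence[float]) -> np.ndarray:
        x = np.asarray(state, dtype=float)
        dv = np.zeros((len(net.reactions), n))
        for j, rxn in enumerate(net.reactions):
            k = net.parameters[rxn.rate_parameter]
            for sp_m, c_m in rxn.reactants:
                m = index[sp_m]
                term = k * c_m * x[m] ** (c_m - 1)
                for sp_s, c_s in rxn.reactants:
                    if sp_s != sp_m:
                        term *= x[index[sp_s]] ** c_s
                dv[j, m] = term
        return S @ dv

    return jac


# ---------------------------------------------------------------------------
# serialization (plain JSON; round-trips losslessly)


def network_to_json(net: ReactionNetwork) -> str:
    units = net.parameter_units()
    doc = {
        "name": net.name,
        "species": [
            {"name": s.name, "initial": s.initial_concentration} for s in net.species
        ],
        "reactions": [
            {
                "reactants": [[n, c] for n, c in r.reactants],
                "products": [[n, c] for n, c in r.products],
                "rate_parameter": r.rate_parameter,
                "kind": r.kind,
            }
            for r in net.reactions
        ],
        "parameters": [
            {"name": n, "value": v, "units": units.get(n, "")}
            for n, v in net.parameters.items()
        ],
        "outputs": list(net.outputs),
    }
    return json.dumps(doc, indent=2, ensure_ascii=False)


def network_from_json(text: str) -> ReactionNetwork:
    doc = json.loads(text)
    return ReactionNetwork(
        species=[
            Species(s["name"], float(s["initial"])) for s in doc["species"]
        ],
        reactions=[
            Reaction(
                reactants=tuple((n, int(c)) for n, c in r["reactants"]),
                products=tuple((n, int(c)) for n, c in r["products"]),
                rate_parameter=r["rate_parameter"],
                kind=r.get("kind"),
            )
            for r in doc["reactions"]
        ],
        parameters={p["name"]: float(p["value"]) for p in doc["parameters"]},
        outputs=tuple(doc.get("outputs", ())),
        name=doc.get("name", ""),
    )
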