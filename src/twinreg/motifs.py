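"""Plant and regulator motif factories, and the loop-closing composition.

The plant is a pair of mutually activating birth-death species Y1, Y2.  Five
controller families built on molecular sequestration (annihilation) are
provided:

``R``
    Ratio regulator: two controller species produced catalytically by the
    outputs and annihilating each other; guarantees Y1*/Y2* = k2/k1.
``R_PRODUCT``
    Product variant of ``R``: constitutive Z1 production and joint
    Y1+Y2-driven Z2 production; guarantees Y1*·Y2* = k1/k2.
``LC``
    Linear-combination regulator: ``R`` plus constitutive production of both
    controller species; guarantees k1·Y1* − k2·Y2* = θ2 − θ1.
``D1``, ``D2``
    Decoupling regulators built from two independent sequestration loops;
    both drive (Y1*, Y2*) = (θ1/k1, θ2/k2).  They share the same controller
    ODEs but differ in how actuation enters the plant, so transients differ.
``D3``
    Centralised decoupling regulator with a sequestration complex C; drives
    (Y1*, Y2*) = (θ1/k1, θ1/k2).
``D2_MISPAIRED``
    ``D2`` with the annihilation pairs swapped (Z1–Z4, Z2–Z3); its nominal
    set-point is never reached because the closed loop is unstable for any
    positive parameters (see :mod:`twinreg.stability`).

Regulator fragments are written against placeholder targets Y1/Y2 and bound
to a plant's designated outputs by :func:`close_loop`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .crn import CRNStructureError, Reaction, ReactionNetwork, Species

__all__ = [
    "RegulatorSpec",
    "ClosedLoopNetwork",
    "Setpoint",
    "FAMILIES",
    "make_plant",
    "plant_steady_state",
    "make_regulator",
    "close_loop",
    "predicted_setpoint",
]

#: required rate constants per controller family
FAMILIES: dict[str, frozenset[str]] = {
    "R": frozenset({"k1", "k2", "k3", "eta"}),
    "R_PRODUCT": frozenset({"k1", "k2", "k3", "eta"}),
    "LC": frozenset({"k1", "k2", "k3", "eta", "theta1", "theta2"}),
    "D1": frozenset({"k1", "k2", "k3", "k4", "eta1", "eta2", "theta1", "theta2"}),
    "D2": frozenset({"k1", "k2", "k3", "k4", "eta1", "eta2", "theta1", "theta2"}),
    "D2_MISPAIRED": frozenset(
        {"k1", "k2", "k3", "k4", "eta1", "eta2", "theta1", "theta2"}
    ),
    "D3": frozenset({"k1", "k2", "k3", "k4", "eta1", "eta2", "theta1"}),
}

_CONTROLLER_SPECIES: dict[str, tuple[str, ...]] = {
    "R": ("Z1", "Z2"),
    "R_PRODUCT": ("Z1", "Z2"),
    "LC": ("Z1", "Z2"),
    "D1": ("Z1", "Z2", "Z3", "Z4"),
    "D2": ("Z1", "Z2", "Z3", "Z4"),
    "D2_MISPAIRED": ("Z1", "Z2", "Z3", "Z4"),
    "D3": ("Z1", "Z2", "Z3", "C"),
}


@dataclass(frozen=True)
class RegulatorSpec:
    """A controller family plus its rate constants and optional augmentations.

    ``extra_inhibition_on_Y1`` adds the reaction Y1+Z1→Z1 at rate k4 so that
    control action is exerted on both outputs; only meaningful for the R and
    LC families (it leaves their controller ODEs unchanged).
    ``controller_degradation_rate`` appends first-order decay X→∅ at a shared
    rate (min^-1) to every controller species, emulating dilution in a
    growing host; the ideal motifs correspond to rate 0.
    """

    family: str
    parameters: dict[str, float]
    extra_inhibition_on_Y1: bool = False
    controller_degradation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise CRNStructureError(
                f"unknown regulator family {self.family!r}; "
                f"choose one of {sorted(FAMILIES)}"
            )
        required = set(FAMILIES[self.family])
        if self.extra_inhibition_on_Y1:
            if self.family not in ("R", "LC"):
                raise CRNStructureError(
                    "extra_inhibition_on_Y1 is only valid for families R and LC"
                )
            required.add("k4")
        missing = required - set(self.parameters)
        if missing:
            raise CRNStructureError(
                f"family {self.family}: missing parameters {sorted(missing)}"
            )
        for name in required:
            if not self.parameters[name] > 0:
                raise CRNStructureError(
                    f"family {self.family}: parameter {name!r} must be "
                    f"strictly positive, got {self.parameters[name]}"
                )
        if self.controller_degradation_rate < 0:
            raise CRNStructureError("controller_degradation_rate must be >= 0")

    @property
    def controller_species(self) -> tuple[str, ...]:
        return _CONTROLLER_SPECIES[self.family]


@dataclass
class ClosedLoopNetwork(ReactionNetwork):
    """A plant with a regulator bound to its designated outputs.

    ``target_map`` records which plant species play the abstract roles Y1 and
    Y2; ``spec`` is the regulator that was composed on.
    """

    target_map: dict[str, str] = field(default_factory=dict)
    spec: RegulatorSpec | None = None
    plant_species: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# plant


def make_plant(
    b1: float,
    b2: float,
    d1: float,
    d2: float,
    alpha1: float,
    alpha2: float,
    name: str = "mutual-activation plant",
) -> ReactionNetwork:
    """Two mutually activating birth-death species.

    Y1 and Y2 are produced constitutively (b1, b2, nM min^-1), degrade with
    first-order rates d1, d2 (min^-1), and each catalyses production of the
    other (alpha1 is the rate at which Y2 makes Y1, alpha2 the converse,
    min^-1), giving the rate equations
    dY1/dt = b1 − d1·Y1 + α1·Y2 and dY2/dt = b2 − d2·Y2 + α2·Y1.
    """
    params = {
        "b1": b1, "b2": b2, "d1": d1, "d2": d2,
        "alpha1": alpha1, "alpha2": alpha2,
    }
    for pname, value in params.items():
        if not value > 0:
            raise CRNStructureError(
                f"plant parameter {pname!r} must be strictly positive, got {value}"
            )
    return ReactionNetwork(
        species=[Species("Y1"), Species("Y2")],
        reactions=[
            Reaction((), (("Y1", 1),), "b1", kind="zeroth_order"),
            Reaction((), (("Y2", 1),), "b2", kind="zeroth_order"),
            Reaction((("Y1", 1),), (), "d1", kind="transformation"),
            Reaction((("Y2", 1),), (), "d2", kind="transformation"),
            Reaction((("Y1", 1),), (("Y1", 1), ("Y2", 1)), "alpha2",
                     kind="catalytic_production"),
            Reaction((("Y2", 1),), (("Y1", 1), ("Y2", 1)), "alpha1",
                     kind="catalytic_production"),
        ],
        parameters=params,
        outputs=("Y1", "Y2"),
        name=name,
    )


def plant_steady_state(
    b1: float, b2: float, d1: float, d2: float, alpha1: float, alpha2: float
) -> tuple[float, float]:
    """Closed-form open-loop steady state.

    Valid (unique, positive, globally exponentially stable) whenever
    d1·d2 > α1·α2:

        Y1* = (α1·b2 + b1·d2) / (d1·d2 − α1·α2)
        Y2* = (α2·b1 + b2·d1) / (d1·d2 − α1·α2)
    """
    det = d1 * d2 - alpha1 * alpha2
    if not det > 0:
        raise ValueError(
            "plant has no unique positive steady state: requires "
            f"d1*d2 > alpha1*alpha2, got {d1 * d2} <= {alpha1 * alpha2}"
        )
    return (alpha1 * b2 + b1 * d2) / det, (alpha2 * b1 + b2 * d1) / det


# ---------------------------------------------------------------------------
# regulator fragments

def _cat(src: str, made: str, rate: str) -> Reaction:
    # A → A + B
    return Reaction(((src, 1),), ((src, 1), (made, 1)), rate,
                    kind="catalytic_production")


def _inhib(target: str, by: str, rate: str) -> Reaction:
    # A + B → A  (B removed, catalyst A conserved)
    return Reaction(((target, 1), (by, 1)), ((by, 1),), rate,
                    kind="catalytic_inhibition")


def _annihilate(a: str, b: str, rate: str, into: str | None = None) -> Reaction:
    products = ((into, 1),) if into else ()
    return Reaction(((a, 1), (b, 1)), products, rate, kind="annihilation")


def _zeroth(made: str, rate: str) -> Reaction:
    return Reaction((), ((made, 1),), rate, kind="zeroth_order")


def _family_reactions(spec: RegulatorSpec) -> list[Reaction]:
    f = spec.family
    if f == "R":
        return [
            _cat("Y1", "Z1", "k1"),
            _cat("Y2", "Z2", "k2"),
            _inhib("Y2", "Z2", "k3"),
            _annihilate("Z1", "Z2", "eta"),
        ]
    if f == "R_PRODUCT":
        return [
            _zeroth("Z1", "k1"),
            Reaction((("Y1", 1), ("Y2", 1)), (("Z2", 1),), "k2",
                     kind="transformation"),
            _inhib("Y2", "Z2", "k3"),
            _annihilate("Z1", "Z2", "eta"),
        ]
    if f == "LC":
        return [
            _zeroth("Z1", "theta1"),
            _zeroth("Z2", "theta2"),
            _cat("Y1", "Z1", "k1"),
            _cat("Y2", "Z2", "k2"),
            _inhib("Y2", "Z2", "k3"),
            _annihilate("Z1", "Z2", "eta"),
        ]
    if f == "D1":
        return [
            _cat("Y1", "Z1", "k1"),
            _cat("Y2", "Z2", "k2"),
            _inhib("Y1", "Z1", "k3"),
            _inhib("Y2", "Z2", "k4"),
            _zeroth("Z3", "theta1"),
            _zeroth("Z4", "theta2"),
            _annihilate("Z1", "Z3", "eta1"),
            _annihilate("Z2", "Z4", "eta2"),
        ]
    if f in ("D2", "D2_MISPAIRED"):
        rxns = [
            _cat("Y1", "Z1", "k1"),
            _cat("Y2", "Z2", "k2"),
            _zeroth("Z3", "theta1"),
            _zeroth("Z4", "theta2"),
            _cat("Z3", "Y1", "k3"),
            _cat("Z4", "Y2", "k4"),
        ]
        if f == "D2":
            rxns += [_annihilate("Z1", "Z3", "eta1"),
                     _annihilate("Z2", "Z4", "eta2")]
        else:  # swapped actuator-sensor pairing
            rxns += [_annihilate("Z1", "Z4", "eta1"),
                     _annihilate("Z2", "Z3", "eta2")]
        return rxns
    if f == "D3":
        return [
            _cat("Y1", "Z1", "k1"),
            _cat("Y2", "Z2", "k2"),
            _zeroth("Z3", "theta1"),
            _cat("Z3", "Y1", "k3"),
            _inhib("Y2", "Z2", "k4"),
            _annihilate("Z1", "Z3", "eta1", into="C"),
            _annihilate("Z2", "C", "eta2"),
        ]
    raise AssertionError(f"unhandled family {f}")  # pragma: no cover


def make_regulator(spec: RegulatorSpec) -> ReactionNetwork:
    """Controller fragment written against placeholder targets Y1, Y2.

    The fragment is itself a valid network (placeholders are declared with
    zero initial concentration and designated as outputs) so the controller
    sub-dynamics can be inspected in isolation; :func:`close_loop` rebinds
    the placeholders to a concrete plant's outputs.
    """
    reactions = _family_reactions(spec)
    if spec.extra_inhibition_on_Y1:
        reactions.append(_inhib("Y1", "Z1", "k4"))
    params = {
        name: spec.parameters[name]
        for name in sorted({r.rate_parameter for r in reactions})
    }
    if spec.controller_degradation_rate > 0:
        for z in spec.controller_species:
            reactions.append(
                Reaction(((z, 1),), (), "delta", kind="transformation")
            )
        params["delta"] = spec.controller_degradation_rate
    return ReactionNetwork(
        species=[Species("Y1"), Species("Y2")]
        + [Species(z) for z in spec.controller_species],
        reactions=reactions,
        parameters=params,
        outputs=("Y1", "Y2"),
        name=f"{spec.family} regulator",
    )


def close_loop(plant: ReactionNetwork, spec: RegulatorSpec) -> ClosedLoopNetwork:
    """Bind a regulator's sensing and actuation to a plant's outputs.

    The plant must designate exactly two outputs (in the order Y1-role,
    Y2-role).  Controller parameters that collide with a plant parameter name
    are namespaced with a ``ctrl.`` prefix; none of the built-in scenarios
    collide, so printed names are normally preserved.
    """
    if len(plant.outputs) != 2:
        raise CRNStructureError(
            f"plant must designate exactly two outputs, has {plant.outputs!r}"
        )
    fragment = make_regulator(spec)
    target_map = {"Y1": plant.outputs[0], "Y2": plant.outputs[1]}

    clash = set(spec.controller_species) & set(plant.species_names)
    if clash:
        raise CRNStructureError(
            f"controller species {sorted(clash)} collide with plant species"
        )

    param_rename: dict[str, str] = {}
    merged_params = dict(plant.parameters)
    for pname, value in fragment.parameters.items():
        key = pname
        if key in merged_params:
            key = f"ctrl.{pname}"
        param_rename[pname] = key
        merged_params[key] = value

    def bind(terms: tuple[tuple[str, int], ...]) -> tuple[tuple[str, int], ...]:
        return tuple((target_map.get(n, n), c) for n, c in terms)

    bound = [
        replace(
            r,
            reactants=bind(r.reactants),
            products=bind(r.products),
            rate_parameter=param_rename[r.rate_parameter],
        )
        for r in fragment.reactions
    ]
    return ClosedLoopNetwork(
        species=list(plant.species) + [Species(z) for z in spec.controller_species],
        reactions=list(plant.reactions) + bound,
        parameters=merged_params,
        outputs=plant.outputs,
        name=f"{plant.name} + {spec.family}",
        target_map=target_map,
        spec=spec,
        plant_species=tuple(plant.species_names),
    )


# ---------------------------------------------------------------------------
# steady-state objectives


@dataclass(frozen=True)
class Setpoint:
    """The steady-state objective a regulator family guarantees.

    ``kind`` is one of ``ratio`` (Y1*/Y2*), ``product`` (Y1*·Y2*),
    ``lincomb`` (w1·Y1* + w2·Y2*, with ``weights``), or ``setpoints``
    (independent targets for Y1* and Y2*).  ``value`` is the guaranteed
    number, or a pair for ``setpoints``.
    """

    kind: str
    value: float | tuple[float, float]
    weights: tuple[float, float] | None = None


def predicted_setpoint(spec: RegulatorSpec) -> Setpoint:
    """The steady-state objective implied by the family's rate constants.

    These are exact consequences of the controller memory variables reaching
    equilibrium, independent of the plant, provided the closed loop is
    asymptotically stable.
    """
    p = spec.parameters
    if spec.family == "R":
        return Setpoint("ratio", p["k2"] / p["k1"])
    if spec.family == "R_PRODUCT":
        return Setpoint("product", p["k1"] / p["k2"])
    if spec.family == "LC":
        return Setpoint(
            "lincomb", p["theta2"] - p["theta1"], weights=(p["k1"], -p["k2"])
        )
    if spec.family in ("D1", "D2"):
        return Setpoint(
            "setpoints", (p["theta1"] / p["k1"], p["theta2"] / p["k2"])
        )
    if spec.family == "D2_MISPAIRED":
        # nominal equilibrium of the swapped pairing; unstable in practice
        return Setpoint(
            "setpoints", (p["theta2"] / p["k1"], p["theta1"] / p["k2"])
        )
    if spec.family == "D3":
        return Setpoint(
            "setpoints", (p["theta1"] / p["k1"], p["theta1"] / p["k2"])
        )
    raise AssertionError(f"unhandled family {spec.family}")  # pragma: no cover
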