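"""Named simulation scenarios with all rate constants from the study figures.

Each scenario couples the mutual-activation plant (b1=2, b2=1, d1=d2=1,
α1=0.1, α2=0.4 in nM/min units) with one regulator family and the standard
step disturbance b1: 2→4 at t = 50 min.  Scenario ids mirror the figure
labels of the source study for traceability:

========  =========================  =========================================
id        architecture               guaranteed objective
========  =========================  =========================================
fig3b     plant only (open loop)     none — both outputs shift with b1
fig4a     R-Regulator                Y1*/Y2* = k2/k1 = 2
fig4b     LC-Regulator               Y1* − 3·Y2* = θ2 − θ1 = 1 nM
fig5a     D-Regulator I              (Y1*, Y2*) = (0.6, 1) nM
fig5b     D-Regulator II             (Y1*, Y2*) = (10, 10) nM
fig5c     D-Regulator III            (Y1*, Y2*) = (16, 4) nM
fig6      D-Regulator II mispaired   nominally (8, 12.5) nM — unstable
========  =========================  =========================================
"""

from __future__ import annotations

from dataclasses import dataclass

from .crn import ReactionNetwork
from .motifs import ClosedLoopNetwork, RegulatorSpec, close_loop, make_plant
from .simulate import DisturbanceSchedule

__all__ = ["Scenario", "PLANT_PARAMS", "SCENARIOS", "get_scenario", "list_scenarios"]

#: open-loop plant rate constants shared by every scenario
PLANT_PARAMS: dict[str, float] = {
    "b1": 2.0, "b2": 1.0, "d1": 1.0, "d2": 1.0, "alpha1": 0.1, "alpha2": 0.4,
}

#: the standard disturbance: b1 steps from 2 to 4 nM/min at t = 50 min
STANDARD_DISTURBANCE = DisturbanceSchedule.single(50.0, "b1", 4.0)

_REGULATOR_PARAMS: dict[str, tuple[str, dict[str, float]]] = {
    "fig4a": ("R", {"k1": 0.5, "k2": 1.0, "k3": 2.0, "eta": 10.0}),
    "fig4b": ("LC", {"k1": 1.0, "k2": 3.0, "k3": 2.0, "eta": 10.0,
                     "theta1": 4.0, "theta2": 5.0}),
    "fig5a": ("D1", {"k1": 2.5, "k2": 0.5, "k3": 2.0, "k4": 2.0,
                     "eta1": 10.0, "eta2": 10.0, "theta1": 1.5, "theta2": 0.5}),
    "fig5b": ("D2", {"k1": 1.0, "k2": 0.8, "k3": 0.5, "k4": 0.5,
                     "eta1": 0.5, "eta2": 0.5, "theta1": 10.0, "theta2": 8.0}),
    "fig5c": ("D3", {"k1": 0.5, "k2": 2.0, "k3": 0.5, "k4": 2.0,
                     "eta1": 0.5, "eta2": 10.0, "theta1": 8.0}),
    "fig6": ("D2_MISPAIRED", {"k1": 1.0, "k2": 0.8, "k3": 0.5, "k4": 0.5,
                              "eta1": 0.5, "eta2": 0.5,
                              "theta1": 10.0, "theta2": 8.0}),
}


@dataclass(frozen=True)
class Scenario:
    """A fully parameterized architecture plus its disturbance schedule."""

    id: str
    description: str
    spec: RegulatorSpec | None          # None for the open-loop plant
    schedule: DisturbanceSchedule
    t_end: float = 500.0                # default horizon, minutes

    def plant(self) -> ReactionNetwork:
        return make_plant(**PLANT_PARAMS)

    def network(self) -> ReactionNetwork | ClosedLoopNetwork:
        """A fresh network instance (parameter tables are never shared
        between calls, so runs cannot contaminate each other)."""
        plant = self.plant()
        if self.spec is None:
            return plant
        return close_loop(plant, self.spec)


def _build_registry() -> dict[str, Scenario]:
    registry = {
        "fig3b": Scenario(
            id="fig3b",
            description="open-loop plant; the b1 step shifts both outputs",
            spec=None,
            schedule=STANDARD_DISTURBANCE,
        )
    }
    descriptions = {
        "fig4a": "R-Regulator holds Y1*/Y2* = 2 through the disturbance",
        "fig4b": "LC-Regulator holds Y1* - 3*Y2* = 1 nM through the disturbance",
        "fig5a": "D-Regulator I pins (Y1*, Y2*) = (0.6, 1) nM",
        "fig5b": "D-Regulator II pins (Y1*, Y2*) = (10, 10) nM",
        "fig5c": "D-Regulator III pins (Y1*, Y2*) = (16, 4) nM",
        "fig6": "mispaired D-Regulator II; closed loop is unstable",
    }
    for sid, (family, params) in _REGULATOR_PARAMS.items():
        registry[sid] = Scenario(
            id=sid,
            description=descriptions[sid],
            spec=RegulatorSpec(family, dict(params)),
            schedule=STANDARD_DISTURBANCE,
        )
    return registry


SCENARIOS: dict[str, Scenario] = _build_registry()


def get_scenario(scenario_id: str) -> Scenario:
    try:
        return SCENARIOS[scenario_id]
    except KeyError:
        raise KeyError(
            f"unknown scenario {scenario_id!r}; available: {sorted(SCENARIOS)}"
        ) from None


def list_scenarios() -> list[Scenario]:
    return [SCENARIOS[k] for k in sorted(SCENARIOS)]
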