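"""Equilibria and local asymptotic stability of closed-loop networks.

The eigenvalues of the analytic Jacobian are the authoritative stability
test; the Routh–Hurwitz criterion on the characteristic polynomial is
computed as an independent cross-check (a disagreement between the two on a
clearly-signed case indicates numerical pathology and raises).  The module
also provides the exhaustive parameter scan that demonstrates the
infeasibility of the mispaired decoupling regulator, and the positive-real
balance condition k2·k4·Z1* = k1·k3·Z2* for the doubly-inhibiting ratio and
linear-combination motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root
from scipy.stats import qmc

from .crn import ReactionNetwork, ode_jacobian, ode_rhs
from .motifs import ClosedLoopNetwork, RegulatorSpec, close_loop, make_plant
from .simulate import SimOptions, run

__all__ = [
    "StabilityReport",
    "EquilibriumNotFound",
    "find_equilibrium",
    "jacobian",
    "routh_hurwitz",
    "assess",
    "pairing_scan",
    "pr_balance_check",
]

#: eigenvalue real parts within ±_MARGIN of zero are reported as marginal
_MARGIN = 1e-9


class EquilibriumNotFound(RuntimeError):
    """No non-negative root of the rate equations was found from the seed.

    A convergence pre-run (``simulate.run``) usually supplies a good seed for
    stable loops; unstable loops may need an analytic or hand-picked seed.
    """


@dataclass
class StabilityReport:
    """Equilibrium, spectrum, characteristic polynomial and verdicts."""

    equilibrium: np.ndarray                   # nM, ordered as net.species
    species_names: list[str]
    jacobian_eigenvalues: np.ndarray          # complex
    char_poly: np.ndarray                     # monic, descending powers
    routh_verdict: str                        # stable | unstable | marginal
    eigen_verdict: str                        # authoritative
    residual: float                           # ‖rhs(equilibrium)‖∞
    notes: list[str] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return self.eigen_verdict

    @property
    def stable(self) -> bool:
        return self.eigen_verdict == "stable"

    def equilibrium_of(self, name: str) -> float:
        return float(self.equilibrium[self.species_names.index(name)])


def find_equilibrium(
    net: ReactionNetwork,
    seed_state: np.ndarray | None = None,
    root_tol: float = 1e-10,
) -> np.ndarray:
    """Solve rhs(x) = 0 for a non-negative equilibrium near ``seed_state``.

    Default seed is the endpoint of a convergence run of the network, which
    lands in the right basin for any asymptotically stable loop.  Roots with
    a meaningfully negative component are refused.
    """
    rhs = ode_rhs(net)
    jac = ode_jacobian(net)
    if seed_state is None:
        seed_state = _default_seed(net)
    seed = np.asarray(seed_state, dtype=float)
    if seed.shape != (len(net.species),) or not np.all(np.isfinite(seed)):
        raise ValueError("seed_state must be a finite vector of length n_species")

    # mass-action rhs is polynomial, hence defined for (slightly) negative
    # iterates too; evaluate the polynomials directly rather than through
    # rate_vector's non-negativity guard
    def f(x: np.ndarray) -> np.ndarray:
        return _polynomial_rhs(net, x)

    sol = root(f, seed, jac=jac, method="hybr", options={"xtol": 1e-12})
    # judge by residual, not the solver's progress flag: a seed that already
    # sits on the root can make hybr report stalled progress
    x = sol.x
    if np.any(x < -root_tol):
        raise EquilibriumNotFound(
            f"root {x} has negative components; no non-negative equilibrium "
            "reachable from seed {seed}"
        )
    x = np.maximum(x, 0.0)
    resid = float(np.max(np.abs(rhs(x))))
    if resid > root_tol:
        raise EquilibriumNotFound(
            f"no equilibrium found from seed {seed} (residual {resid:.3g} > "
            f"{root_tol:.3g}); try a simulation pre-run or an analytic seed"
        )
    return x


def _default_seed(net: ReactionNetwork) -> np.ndarray:
    """Seed for the root solve when the caller gives none.

    A convergence run works for any stable loop.  Dual-rail decoupling loops
    (correctly paired or mispaired) have a closed-form equilibrium on the
    standard plant, which also covers the unstable mispaired case where a
    trajectory endpoint would be useless.
    """
    if (
        isinstance(net, ClosedLoopNetwork)
        and net.spec is not None
        and net.spec.family in ("D2", "D2_MISPAIRED")
        and {"b1", "b2", "d1", "d2", "alpha1", "alpha2"} <= set(net.parameters)
    ):
        plant_params = {k: net.parameters[k]
                        for k in ("b1", "b2", "d1", "d2", "alpha1", "alpha2")}
        eq = _dual_rail_equilibrium(plant_params, net.spec)
        if eq is not None:
            return eq
    return run(net, t_end=500.0).state_array(net.species_names)[:, -1]


def _polynomial_rhs(net: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """rhs evaluated as raw polynomials (no non-negativity guard)."""
    from .crn import stoichiometry_matrix

    S = stoichiometry_matrix(net)
    index = {s.name: i for i, s in enumerate(net.species)}
    v = np.empty(len(net.reactions))
    for j, rxn in enumerate(net.reactions):
        r = net.parameters[rxn.rate_parameter]
        for sp, coeff in rxn.reactants:
            r *= x[index[sp]] ** coeff
        v[j] = r
    return S @ v


def jacobian(net: ReactionNetwork, state: np.ndarray) -> np.ndarray:
    """Exact Jacobian of the mass-action rate equations at ``state``."""
    return ode_jacobian(net)(np.asarray(state, dtype=float))


def characteristic_polynomial(J: np.ndarray) -> np.ndarray:
    """Monic characteristic polynomial, coefficients in descending powers.

    Built from the eigenvalues rather than by determinant expansion, which
    stays well-conditioned at the dimensions that arise here (≤ 6).
    """
    coeffs = np.poly(np.linalg.eigvals(J))
    return np.real_if_close(coeffs, tol=1e6).astype(float)


def routh_hurwitz(coefficients) -> str:
    """Routh–Hurwitz verdict for a real polynomial (descending powers).

    ``stable`` iff every first-column entry of the Routh array is strictly
    positive; a sign change means ``unstable``.  An all-zero row (roots
    symmetric about the origin) is replaced by the derivative of the
    auxiliary polynomial as usual, and rules out strict stability: the
    verdict is then ``unstable`` on a sign change, else ``marginal``.  An
    exact zero *first-column entry* with a nonzero row is reported as
    ``marginal`` honestly — no epsilon perturbation.
    """
    c = np.asarray(coefficients, dtype=float)
    if c.ndim != 1 or c.size < 1:
        raise ValueError("need at least one polynomial coefficient")
    c = np.trim_zeros(c, "f")
    if c.size == 0:
        raise ValueError("zero polynomial has no stability verdict")
    if c[0] < 0:
        c = -c
    n = c.size - 1  # degree
    if n == 0:
        return "stable"

    width = n // 2 + 1
    prev = np.zeros(width + 1)
    curr = np.zeros(width + 1)
    prev[: (n // 2) + 1] = c[0::2]
    curr[: ((n + 1) // 2)] = c[1::2]
    first_column = [prev[0]]
    zero_row_seen = False
    power = n - 1  # s-power of `curr`
    while power >= 0:
        if np.all(curr == 0.0):
            # auxiliary polynomial lives in `prev` at power+1, power-1, ...
            zero_row_seen = True
            aux_powers = power + 1 - 2 * np.arange(width + 1)
            curr = np.where(aux_powers >= 1, prev * aux_powers, 0.0)
        if curr[0] == 0.0:
            return "marginal"
        first_column.append(curr[0])
        nxt = np.zeros(width + 1)
        nxt[:width] = (curr[0] * prev[1:] - prev[0] * curr[1:]) / curr[0]
        prev, curr = curr, nxt
        power -= 1

    col = np.array(first_column)
    sign_change = np.any(col[:-1] * col[1:] < 0)
    if zero_row_seen:
        return "unstable" if sign_change else "marginal"
    return "unstable" if sign_change else "stable"


def _eigen_verdict(eigenvalues: np.ndarray, margin: float = _MARGIN) -> str:
    re = eigenvalues.real
    if np.any(re > margin):
        return "unstable"
    if np.all(re < -margin):
        return "stable"
    return "marginal"


def assess(
    net: ReactionNetwork,
    seed_state: np.ndarray | None = None,
    equilibrium: np.ndarray | None = None,
) -> StabilityReport:
    """Full local-stability report at the network's equilibrium.

    Pass ``equilibrium`` directly to skip the root solve (used by the
    parameter scan, which has closed-form equilibria).  The eigenvalue test
    decides; Routh–Hurwitz cross-validates, and a contradiction between two
    clearly-signed verdicts is a hard error.
    """
    if equilibrium is None:
        equilibrium = find_equilibrium(net, seed_state)
    eq = np.asarray(equilibrium, dtype=float)
    rhs = ode_rhs(net)
    residual = float(np.max(np.abs(rhs(np.maximum(eq, 0.0)))))
    J = jacobian(net, eq)
    eigs = np.linalg.eigvals(J)
    char = characteristic_polynomial(J)
    r_verdict = routh_hurwitz(char)
    e_verdict = _eigen_verdict(eigs)
    notes = []
    if "marginal" in (r_verdict, e_verdict):
        notes.append(
            "near-marginal spectrum; Routh–Hurwitz cross-check not enforced"
        )
    elif r_verdict != e_verdict:
        raise RuntimeError(
            "stability cross-check failed: eigenvalues say "
            f"{e_verdict}, Routh–Hurwitz says {r_verdict} "
            f"(char poly {char}, eigenvalues {eigs}) — numerical pathology"
        )
    return StabilityReport(
        equilibrium=eq,
        species_names=net.species_names,
        jacobian_eigenvalues=eigs,
        char_poly=char,
        routh_verdict=r_verdict,
        eigen_verdict=e_verdict,
        residual=residual,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# actuator–sensor pairing scan


def _dual_rail_equilibrium(
    plant_params: dict[str, float], spec: RegulatorSpec
) -> np.ndarray | None:
    """Closed-form equilibrium of D2 / mispaired D2 on the standard plant.

    At equilibrium the two memory variables force the outputs to their
    nominal targets; the actuation balances then fix Z3*, Z4* and the
    annihilation balances fix Z1*, Z2*.  Returns None when any component
    would be non-positive (no positive equilibrium exists).
    Order: Y1, Y2, Z1, Z2, Z3, Z4.
    """
    p = spec.parameters
    pp = plant_params
    if spec.family == "D2":
        y1, y2 = p["theta1"] / p["k1"], p["theta2"] / p["k2"]
    elif spec.family == "D2_MISPAIRED":
        y1, y2 = p["theta2"] / p["k1"], p["theta1"] / p["k2"]
    else:
        raise ValueError("closed-form equilibrium only for D2-type loops")
    z3 = (pp["d1"] * y1 - pp["alpha1"] * y2 - pp["b1"]) / p["k3"]
    z4 = (pp["d2"] * y2 - pp["alpha2"] * y1 - pp["b2"]) / p["k4"]
    if z3 <= 0 or z4 <= 0:
        return None
    if spec.family == "D2":
        z1 = p["theta1"] / (p["eta1"] * z3)
        z2 = p["theta2"] / (p["eta2"] * z4)
    else:
        z1 = p["theta2"] / (p["eta1"] * z4)
        z2 = p["theta1"] / (p["eta2"] * z3)
    return np.array([y1, y2, z1, z2, z3, z4])


_SCAN_PARAMS = ("k1", "k2", "k3", "k4", "theta1", "theta2", "eta1", "eta2")


def pairing_scan(
    plant_params: dict[str, float] | None = None,
    family: str = "D2_MISPAIRED",
    low: float = 1e-2,
    high: float = 1e2,
    points_per_decade: int = 4,
    max_points: int = 10_000,
) -> pd.DataFrame:
    """Stability verdicts for a log grid of controller parameter sets.

    The eight controller rate constants are varied over ``[low, high]`` on a
    grid with ``points_per_decade`` values per decade per axis.  A full
    factorial would be astronomically large, so grid points are selected by
    a deterministic Halton low-discrepancy sequence snapped to the axis
    values (fixed enumeration order; no seeds), capped at ``max_points``.

    Returns one row per point with the parameter values, a ``verdict``
    column (``stable`` / ``unstable`` / ``no_equilibrium``), and the leading
    eigenvalue real part where an equilibrium exists.  For the mispaired
    decoupling regulator the expected stable fraction is exactly zero.
    """
    plant_params = dict(plant_params or {
        "b1": 2.0, "b2": 1.0, "d1": 1.0, "d2": 1.0,
        "alpha1": 0.1, "alpha2": 0.4,
    })
    n_axis = int(round(points_per_decade * np.log10(high / low))) + 1
    axis = np.logspace(np.log10(low), np.log10(high), n_axis)

    sampler = qmc.Halton(d=len(_SCAN_PARAMS), scramble=False)
    unit = sampler.random(max_points)
    indices = np.minimum((unit * n_axis).astype(int), n_axis - 1)

    plant = make_plant(**plant_params)
    rows = []
    for idx in indices:
        params = {p: float(axis[i]) for p, i in zip(_SCAN_PARAMS, idx)}
        spec = RegulatorSpec(family, params)
        row: dict[str, float | str] = dict(params)
        eq = _dual_rail_equilibrium(plant_params, spec)
        if eq is None:
            row["verdict"] = "no_equilibrium"
            row["max_re_eig"] = np.nan
        else:
            net = close_loop(plant, spec)
            report = assess(net, equilibrium=eq)
            row["verdict"] = report.verdict
            row["max_re_eig"] = float(report.jacobian_eigenvalues.real.max())
        rows.append(row)
    return pd.DataFrame(rows)


def pr_balance_check(
    net: ClosedLoopNetwork, equilibrium: np.ndarray | None = None
) -> float:
    """Residual of the positive-real balance condition k2·k4·Z1* − k1·k3·Z2*.

    Applies to the R or LC family with the extra inhibition on Y1 (so that
    both outputs receive control action).  A zero residual at equilibrium
    flags the configuration whose controller block is a positive-real
    system, giving a sufficient local stability certificate when the plant
    block is weakly strictly positive real.  A nonzero residual draws no
    stability conclusion by itself.
    """
    spec = net.spec
    if spec is None or spec.family not in ("R", "LC"):
        raise ValueError("pr_balance_check applies to R or LC closed loops")
    if not spec.extra_inhibition_on_Y1:
        raise ValueError(
            "pr_balance_check requires the extra inhibition on Y1 "
            "(control action on both outputs)"
        )
    if equilibrium is None:
        equilibrium = find_equilibrium(net)
    eq = np.asarray(equilibrium, dtype=float)
    z1 = eq[net.species_index("Z1")]
    z2 = eq[net.species_index("Z2")]
    p = spec.parameters
    return float(p["k2"] * p["k4"] * z1 - p["k1"] * p["k3"] * z2)
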