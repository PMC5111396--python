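"""Linear-programming core: flux balance analysis with dual extraction.

The primal problem maximizes an objective flux (usually biomass) subject
to the steady-state mass balance ``S v = b`` (``b = 0`` at steady state;
nonzero entries force net accumulation of a metabolite) and flux bounds
``LB <= v <= UB``.  It is solved with the HiGHS dual simplex through
:func:`scipy.optimize.linprog`, and the metabolite duals (shadow prices,
lambda) and bound duals (q1 for lower, q2 for upper bounds) are taken
from the same optimal basis.

Sign conventions
----------------
``lambda_i = dZ/db_i`` where ``b_i`` forces accumulation of metabolite
*i*: a negative shadow price therefore marks a growth-limiting
metabolite (producing a little extra of it costs growth).  With HiGHS
minimizing ``-Z`` this means ``lambda = -eqlin.marginals``; the
orientation is pinned against a finite-difference probe by
:func:`calibrate_dual_sign`.  Bound duals satisfy ``q1 <= 0`` and
``q2 >= 0``, and strong duality reads
``Z = lambda.b + q1.LB + q2.UB``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .core import Model, ModelError, build_matrices

__all__ = [
    "MediumSpec",
    "FbaSolution",
    "solve_fba",
    "shadow_prices",
    "flux_sum",
    "flux_sums",
    "elemental_turnover",
    "ElementalTurnover",
    "calibrate_dual_sign",
    "apply_medium",
]

FEASIBILITY_TOL = 1e-9


@dataclass
class MediumSpec:
    """Exchange-bound overrides defining a growth medium."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    name: str = "medium"

    def __post_init__(self) -> None:
        for ex, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise ModelError(f"medium {self.name}: {ex} lb > ub")

    def with_bound(self, exchange_id: str, lb: float, ub: float) -> "MediumSpec":
        new = dict(self.bounds)
        new[exchange_id] = (lb, ub)
        return MediumSpec(new, self.name)


def apply_medium(model: Model, medium: MediumSpec | None) -> None:
    """Set exchange bounds in place from a medium specification."""
    if medium is None:
        return
    for ex, (lb, ub) in medium.bounds.items():
        if ex not in model.reactions:
            raise ModelError(f"medium references unknown exchange {ex!r}")
        rxn = model.reactions[ex]
        rxn.lower_bound, rxn.upper_bound = lb, ub


@dataclass
class FbaSolution:
    status: str  # optimal | infeasible | unbounded
    objective: float
    fluxes: dict[str, float]
    lambdas: dict[str, float]
    q1: dict[str, float]
    q2: dict[str, float]
    accumulation: dict[str, float]
    objective_id: str
    model: Model | None = None
    dual_degenerate: set[str] = field(default_factory=set)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


def _status_name(status_code: int) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(status_code, "failed")


def solve_fba(
    model: Model,
    medium: MediumSpec | None = None,
    objective: str | None = None,
    maximize: bool = True,
    steady_state: bool = True,
    accumulation: dict[str, float] | None = None,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
    check_degenerate_duals: bool = False,
) -> FbaSolution:
    """Solve the FBA linear program and return primal and dual variables.

    ``accumulation`` maps metabolite ids to forced net accumulation
    rates (the right-hand side b); it requires ``steady_state`` handling
    of all other metabolites and defaults to empty.  ``extra_bounds``
    overrides reaction bounds for this solve only (used by screens and
    scans without copying the model).
    """
    objective = objective or model.objective_id
    if objective not in model.reactions:
        raise ModelError(f"objective reaction {objective!r} not in model")
    if not steady_state and not accumulation:
        accumulation = {}
    S, _, met_ids, rxn_ids = build_matrices(model)
    n = len(rxn_ids)
    met_index = {m: i for i, m in enumerate(met_ids)}
    b = np.zeros(len(met_ids))
    for met_id, rate in (accumulation or {}).items():
        if met_id not in met_index:
            raise ModelError(f"unknown metabolite {met_id!r} in accumulation")
        b[met_index[met_id]] = rate

    bounds_map = {}
    if medium is not None:
        for ex, (lb, ub) in medium.bounds.items():
            if ex not in model.reactions:
                raise ModelError(f"medium references unknown exchange {ex!r}")
            bounds_map[ex] = (lb, ub)
    if extra_bounds:
        bounds_map.update(extra_bounds)
    bounds = []
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        lb, ub = bounds_map.get(rid, (rxn.lower_bound, rxn.upper_bound))
        bounds.append((None if math.isinf(lb) else lb, None if math.isinf(ub) else ub))

    c = np.zeros(n)
    c[rxn_ids.index(objective)] = -1.0 if maximize else 1.0
    res = linprog(
        c,
        A_eq=S,
        b_eq=b,
        bounds=bounds,
        method="highs-ds",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    status = _status_name(res.status)
    if status != "optimal":
        return FbaSolution(
            status=status,
            objective=float("nan"),
            fluxes={},
            lambdas={},
            q1={},
            q2={},
            accumulation=dict(accumulation or {}),
            objective_id=objective,
            model=model,
        )

    sign = 1.0 if maximize else -1.0
    # lambda = dZ/db; for the minimized problem -Z the marginals carry
    # the opposite sign (see module docstring / calibrate_dual_sign).
    lam = -sign * res.eqlin.marginals
    q1 = -sign * res.lower.marginals
    q2 = -sign * res.upper.marginals
    solution = FbaSolution(
        status="optimal",
        objective=-res.fun if maximize else res.fun,
        fluxes=dict(zip(rxn_ids, res.x)),
        lambdas=dict(zip(met_ids, lam)),
        q1=dict(zip(rxn_ids, q1)),
        q2=dict(zip(rxn_ids, q2)),
        accumulation=dict(accumulation or {}),
        objective_id=objective,
        model=model,
    )
    if check_degenerate_duals:
        solution.dual_degenerate = _probe_degenerate_duals(
            model, medium, objective, maximize, accumulation, extra_bounds, solution
        )
    return solution


def _probe_degenerate_duals(
    model, medium, objective, maximize, accumulation, extra_bounds, solution,
    delta: float = 1e-7, tol: float = 1e-4,
) -> set[str]:
    """Flag metabolites whose dual changes under a small b perturbation.

    A degenerate optimum has non-unique duals; re-solving with the
    right-hand side perturbed by ``delta`` in a fixed direction exposes
    metabolites whose reported lambda is basis-dependent.
    """
    rng = np.random.default_rng(0)
    perturbed = dict(accumulation or {})
    for i, met_id in enumerate(solution.lambdas):
        if abs(solution.lambdas[met_id]) > 1e-9:
            perturbed[met_id] = perturbed.get(met_id, 0.0) + delta * (
                1 if rng.random() < 0.5 else -1
            )
    alt = solve_fba(
        model, medium, objective, maximize,
        accumulation=perturbed, extra_bounds=extra_bounds,
    )
    if not alt.optimal:
        return set()
    return {
        m
        for m in solution.lambdas
        if abs(solution.lambdas[m] - alt.lambdas[m]) > tol
    }


def shadow_prices(
    solution: FbaSolution, rank: bool = False
) -> dict[str, float] | list[tuple[str, float]]:
    """Metabolite shadow prices, negative lambda marking growth-limiting
    metabolites.  With ``rank=True`` return metabolites sorted by
    descending ``|-lambda|``."""
    if not solution.optimal:
        raise ModelError("shadow prices require an optimal solution")
    if rank:
        return sorted(
            solution.lambdas.items(), key=lambda kv: -abs(kv[1])
        )
    return dict(solution.lambdas)


def calibrate_dual_sign() -> int:
    """Verify the shadow-price orientation on a two-reaction chain.

    Builds uptake->biomass limited by the uptake bound, compares the
    reported lambda of the limiting metabolite against a central finite
    difference of Z over the accumulation right-hand side, and returns
    +1 if they agree (the library's convention) or -1 if the installed
    solver reports the opposite orientation.
    """
    from .core import Metabolite, Reaction

    model = Model(id="calibration")
    model.metabolites["a[c]"] = Metabolite(id="a[c]", formula={"C": 1})
    model.reactions["EX_a"] = Reaction(
        id="EX_a", stoichiometry={"a[c]": -1}, lower_bound=-10, upper_bound=0,
        kind="exchange",
    )
    model.reactions["BIO"] = Reaction(
        id="BIO", stoichiometry={"a[c]": -1}, lower_bound=0, upper_bound=math.inf,
        pseudo=True,
    )
    model.objective_id = "BIO"
    base = solve_fba(model)
    delta = 1e-6
    up = solve_fba(model, accumulation={"a[c]": delta})
    down = solve_fba(model, accumulation={"a[c]": -delta})
    fd = (up.objective - down.objective) / (2 * delta)
    lam = base.lambdas["a[c]"]
    return 1 if abs(lam - fd) < 1e-4 else -1


# ---------------------------------------------------------------------------
# Flux sums and elemental turnover

def flux_sums(
    solution: FbaSolution, internal_only: bool = False
) -> dict[str, float]:
    """Turnover ``Phi_i = 1/2 sum_j |S_ij v_j|`` for every metabolite."""
    if not solution.optimal:
        raise ModelError("flux sums require an optimal solution")
    model = solution.model
    totals = {m: 0.0 for m in model.metabolites}
    for rid, rxn in model.reactions.items():
        if internal_only and (rxn.kind != "internal" or rxn.pseudo):
            continue
        v = solution.fluxes[rid]
        for met_id, coeff in rxn.stoichiometry.items():
            totals[met_id] += abs(coeff * v)
    return {m: 0.5 * t for m, t in totals.items()}


def flux_sum(solution: FbaSolution, metabolite_id: str) -> float:
    """Turnover of a single metabolite (mmol/gDW/h)."""
    if metabolite_id not in solution.model.metabolites:
        raise ModelError(f"unknown metabolite {metabolite_id!r}")
    return flux_sums(solution)[metabolite_id]


@dataclass
class ElementalTurnover:
    flux_sum: dict[str, float]  # element -> Phi, mmol atoms/gDW/h
    per_growth: dict[str, float | None]  # Phi / (mu * quota)
    per_transport: dict[str, float | None]  # Phi / net element influx


def elemental_turnover(
    model: Model,
    solution: FbaSolution,
    quotas: dict[str, float] | None = None,
) -> ElementalTurnover:
    """Element-wise turnover aggregating atom-weighted metabolite flux
    sums over internal reactions only.

    ``quotas`` maps elements to cellular content (mmol atoms/gDW) for
    the growth-normalized variant; normalization by the net transport
    influx of each element uses the exchange fluxes of the same
    solution.  Undefined normalizations (zero quota or zero influx) are
    reported as None.
    """
    if not solution.optimal:
        raise ModelError("elemental turnover requires an optimal solution")
    sums = flux_sums(solution, internal_only=True)
    from .core import element_rows

    elements = element_rows(model)
    phi = {e: 0.0 for e in elements}
    for met_id, met in model.metabolites.items():
        for e, count in met.formula.items():
            phi[e] += count * sums[met_id]

    # net element influx through exchanges: coeff * v is the production
    # rate of the exchanged metabolite inside the system boundary.
    influx = {e: 0.0 for e in elements}
    for rxn in model.reactions.values():
        if rxn.kind != "exchange":
            continue
        v = solution.fluxes[rxn.id]
        (met_id, coeff), = rxn.stoichiometry.items()
        for e, count in model.metabolites[met_id].formula.items():
            influx[e] += coeff * v * count

    mu = solution.objective
    per_growth: dict[str, float | None] = {}
    per_transport: dict[str, float | None] = {}
    for e in elements:
        quota = (quotas or {}).get(e)
        per_growth[e] = (
            phi[e] / (mu * quota) if quota and mu > 0 else None
        )
        per_transport[e] = phi[e] / influx[e] if abs(influx[e]) > 1e-12 else None
    return ElementalTurnover(phi, per_growth, per_transport)
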