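"""Flux balance analysis primitives on top of scipy's HiGHS LP solver.

All flux computations in the package route through :func:`solve_lp`:
steady-state mass balance S.v = 0, bound constraints, and a linear
objective over reaction fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from .errors import InfeasibleError
from .model import Model

#: numerical tolerance on LP objectives/fluxes
LP_TOL = 1e-9


@dataclass
class LPResult:
    status: str  # 'optimal' | 'infeasible' | 'unbounded'
    objective: float
    fluxes: Dict[str, float]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _bounds_vector(
    model: Model,
    rids,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]],
    allowed: Optional[Iterable[str]],
):
    allowed_set = set(allowed) if allowed is not None else None
    bounds = []
    for rid in rids:
        r = model.reactions[rid]
        lb, ub = r.lb, r.ub
        if extra_bounds and rid in extra_bounds:
            lb, ub = extra_bounds[rid]
        if allowed_set is not None and rid not in allowed_set:
            lb, ub = 0.0, 0.0
        bounds.append((None if lb == -np.inf else lb, None if ub == np.inf else ub))
    return bounds


def solve_lp(
    model: Model,
    objective: Mapping[str, float],
    maximize: bool = True,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    allowed: Optional[Iterable[str]] = None,
) -> LPResult:
    """Solve max/min of a linear flux objective subject to S.v = 0 and bounds.

    ``allowed`` restricts the network: every reaction outside it is fixed to
    zero flux (used for subnetwork feasibility checks).
    """
    S, mids, rids = model.stoichiometric_matrix()
    c = np.zeros(len(rids))
    ridx = {rid: j for j, rid in enumerate(rids)}
    for rid, coef in objective.items():
        c[ridx[rid]] = coef
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=_bounds_vector(model, rids, extra_bounds, allowed),
        method="highs",
    )
    if res.status == 2:
        return LPResult("infeasible", float("nan"), {})
    if res.status == 3:
        return LPResult("unbounded", float("inf") if maximize else float("-inf"), {})
    if not res.success:
        raise InfeasibleError(f"LP solver failure: {res.message}")
    fluxes = {rid: float(res.x[j]) for rid, j in ridx.items()}
    return LPResult("optimal", float(sign * res.fun), fluxes)


def fba(
    model: Model,
    objective_id: Optional[str] = None,
    maximize: bool = True,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    allowed: Optional[Iterable[str]] = None,
) -> Tuple[float, Dict[str, float]]:
    """Flux balance analysis: optimize one reaction's flux.

    Raises InfeasibleError with a diagnostic when no steady state exists.
    """
    rid = objective_id or model.objective_id or model.biomass_id
    if rid is None or rid not in model.reactions:
        raise InfeasibleError(f"objective reaction {rid!r} not in model")
    res = solve_lp(model, {rid: 1.0}, maximize=maximize,
                   extra_bounds=extra_bounds, allowed=allowed)
    if res.status == "infeasible":
        raise InfeasibleError(
            f"model {model.id!r} infeasible while optimizing {rid!r} "
            "(check medium bounds and maintenance demands)"
        )
    return res.objective, res.fluxes


def feasible(
    model: Model,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    allowed: Optional[Iterable[str]] = None,
) -> bool:
    """Does any steady-state flux distribution satisfy all constraints?"""
    res = solve_lp(model, {}, maximize=False,
                   extra_bounds=extra_bounds, allowed=allowed)
    return res.status == "optimal"


def flux_ranges(
    model: Model,
    reaction_ids: Optional[Iterable[str]] = None,
    fraction_of_optimum: float = 0.0,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> Dict[str, Tuple[float, float]]:
    """Flux variability: per-reaction [min, max] flux.

    When ``fraction_of_optimum`` > 0 the objective reaction is constrained to
    at least that fraction of its optimum first.  Unbounded directions are
    reported as +-inf.
    """
    bounds: Dict[str, Tuple[float, float]] = dict(extra_bounds or {})
    if fraction_of_optimum > 0:
        opt, _ = fba(model, extra_bounds=extra_bounds)
        rid = model.objective_id or model.biomass_id
        lo, hi = bounds.get(rid, (model.reactions[rid].lb, model.reactions[rid].ub))
        bounds[rid] = (fraction_of_optimum * opt, hi)
    rids = list(reaction_ids) if reaction_ids is not None else list(model.reactions)
    out: Dict[str, Tuple[float, float]] = {}
    for rid in rids:
        lo = solve_lp(model, {rid: 1.0}, maximize=False, extra_bounds=bounds)
        hi = solve_lp(model, {rid: 1.0}, maximize=True, extra_bounds=bounds)
        if lo.status == "infeasible" or hi.status == "infeasible":
            raise InfeasibleError(f"FVA infeasible for reaction {rid!r}")
        out[rid] = (lo.objective, hi.objective)
    return out
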