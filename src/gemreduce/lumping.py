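"""Minimal balanced biosynthesis subnetworks and lumped reactions.

For every biomass building block (BBB) a sink demand of n_gem * mu_max is
imposed and a MILP picks the smallest set of non-core reactions that can
carry steady-state flux to meet it: each reaction's flux is split into
non-negative forward/backward parts, every non-core reaction gets a binary
switch z with the big-M coupling F + B + C*z <= C (z = 1 means off), and
the objective maximizes the number of switched-off reactions.  Alternative
minimal subnetworks are enumerated with integer cuts.  Each subnetwork is
collapsed into a lumped reaction: the flux-weighted net stoichiometry
normalized to one unit of the BBB, with all non-core intermediates
cancelling and a conjunctive GPR over the member reactions.

Lumping here is purely stoichiometric (FBA-based); no thermodynamic
feasibility screening is applied, and every report carries that caveat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .errors import BalanceError, ConfigError, InfeasibleError, UnreachableBBBError
from .expand import CoreNetwork
from .gpr import GPR, conjoin, disjoin
from .lp import fba
from .model import CofactorSpec, MediumSpec, Model, Reaction, apply_medium

FLUX_CAP = 1000.0  # replaces infinite bounds inside the MILP


@dataclass(frozen=True)
class BBBDemand:
    """One biomass building block with its demand coefficient (mmol/gDW)."""

    bbb_id: str
    n_gem: float
    sink_id: str

    def __post_init__(self):
        if self.n_gem <= 0:
            raise ConfigError(f"BBB {self.bbb_id!r} must have positive coefficient")


@dataclass
class LumpingConfig:
    """Tunable parameters of the subnetwork MILP.

    ``big_m`` is the flux cap coupling the on/off binaries; by default the
    carbon uptake flux times the carbon atoms of the substrate (60 for
    glucose at 10 mmol/gDWhr).  ``size_margin`` enumerates subnetworks up to
    S_min + margin; ``flux_tol_rel`` decides subnetwork membership relative
    to big_m.
    """

    big_m: Optional[float] = None
    mu_max: Optional[float] = None
    flux_tol_rel: float = 1e-9
    size_margin: int = 0
    max_alternatives: int = 50
    time_limit: Optional[float] = None


@dataclass
class Subnetwork:
    """A minimal(+margin) set of active non-core reactions producing a BBB."""

    bbb_id: str
    reactions: Dict[str, float]  # reaction id -> flux at the MILP optimum
    condition: str = ""

    @property
    def size(self) -> int:
        return len(self.reactions)

    @property
    def reaction_ids(self) -> FrozenSet[str]:
        return frozenset(self.reactions)


@dataclass
class LumpedReaction:
    """Net stoichiometry of a subnetwork normalized to +1 of its BBB."""

    id: str
    bbb_id: str
    net_stoich: Dict[str, Fraction]
    gpr: GPR
    conditions: Tuple[str, ...] = ()
    source_subnetworks: Tuple[FrozenSet[str], ...] = ()

    @property
    def canonical_key(self) -> Tuple[Tuple[str, Fraction], ...]:
        return tuple(sorted(self.net_stoich.items()))

    def to_reaction(self) -> Reaction:
        return Reaction(
            id=self.id,
            stoich={m: float(c) for m, c in self.net_stoich.items()},
            lb=0.0,
            ub=FLUX_CAP,
            subsystem="Lumped biosynthesis",
            gpr=self.gpr,
            name=f"lumped synthesis of {self.bbb_id}",
        )


# ---------------------------------------------------------------------------
# Biomass decomposition and physiology
# ---------------------------------------------------------------------------

def decompose_biomass(model: Model) -> List[BBBDemand]:
    """One demand per biomass substrate; released products are not BBBs."""
    if not model.biomass_id or model.biomass_id not in model.reactions:
        raise ConfigError("model has no biomass reaction to decompose")
    biomass = model.reactions[model.biomass_id]
    out = []
    for mid, coef in sorted(biomass.stoich.items()):
        if coef < 0:
            out.append(BBBDemand(mid, -coef, f"SINK_{mid}"))
    return out


def compute_mu_max(model: Model, medium: Optional[MediumSpec] = None) -> float:
    """FBA optimum of the biomass objective under the medium."""
    m = apply_medium(model, medium) if medium is not None else model
    try:
        mu, _ = fba(m, m.biomass_id)
    except InfeasibleError:
        blocked = [d.bbb_id for d in decompose_biomass(model)]
        raise InfeasibleError(
            f"biomass optimization infeasible; biomass demands: {blocked}"
        )
    return mu


def default_big_m(model: Model, medium: MediumSpec) -> float:
    """Carbon uptake flux x carbon atoms of the substrate (fallback 100)."""
    total = 0.0
    for ex in medium.carbon_sources:
        lb, _ = medium.uptakes.get(ex, (0.0, 0.0))
        rxn = model.reactions.get(ex)
        carbons = 0
        if rxn is not None:
            (mid,) = rxn.metabolite_ids
            f = model.metabolites[mid].formula
            carbons = f.get("C", 0) if f else 0
        total += abs(lb) * carbons
    return total if total > 0 else 100.0


def non_core_reactions(
    model: Model, core: CoreNetwork, medium: MediumSpec
) -> List[str]:
    """R^nC: reactions outside the core, excluding the declared medium's
    exchanges, the biomass reaction and maintenance demand."""
    keep_free = set(medium.uptakes) | {model.biomass_id, model.atpm_id}
    return sorted(
        rid
        for rid in model.reactions
        if rid not in core.reactions and rid not in keep_free
    )


# ---------------------------------------------------------------------------
# The MILP
# ---------------------------------------------------------------------------

class _SplitFluxMILP:
    """Split-flux MILP over a model with one sink demand.

    Variables: F_r, B_r >= 0 per reaction (v = F - B) and a binary z_r per
    non-core reaction with F_r + B_r + C*z_r <= C.  Integer cuts accumulate
    across solves.
    """

    def __init__(self, model: Model, noncore: Sequence[str], big_m: float,
                 time_limit: Optional[float] = None):
        self.model = model
        self.noncore = list(noncore)
        self.big_m = float(big_m)
        self.time_limit = time_limit
        S, mids, rids = model.stoichiometric_matrix()
        self.rids = rids
        self.ridx = {rid: j for j, rid in enumerate(rids)}
        n = len(rids)
        k = len(self.noncore)
        self.n, self.k = n, k
        # columns: F (n), B (n), z (k)
        self.A_eq = sparse.hstack([S, -S, sparse.csr_matrix((S.shape[0], k))]).tocsr()
        lo = np.zeros(2 * n + k)
        hi = np.empty(2 * n + k)
        for j, rid in enumerate(rids):
            r = model.reactions[rid]
            hi[j] = min(max(r.ub, 0.0), FLUX_CAP)
            hi[n + j] = min(max(-r.lb, 0.0), FLUX_CAP)
            # a strictly positive lb (maintenance, sink demand) forces the
            # forward part, since the backward part is then bounded at 0;
            # symmetrically for a strictly negative ub
            if r.lb > 0:
                lo[j] = min(r.lb, FLUX_CAP)
            if r.ub < 0:
                lo[n + j] = min(-r.ub, FLUX_CAP)
        hi[2 * n:] = 1.0
        self.lo, self.hi = lo, hi
        rows, cols, data = [], [], []
        for i, rid in enumerate(self.noncore):
            j = self.ridx[rid]
            rows += [i, i, i]
            cols += [j, n + j, 2 * n + i]
            data += [1.0, 1.0, self.big_m]
        self.A_couple = sparse.csr_matrix(
            (data, (rows, cols)), shape=(k, 2 * n + k)
        )
        self.cuts: List[np.ndarray] = []
        self.c = np.zeros(2 * n + k)
        self.c[2 * n:] = -1.0  # maximize sum of z
        self.integrality = np.zeros(2 * n + k)
        self.integrality[2 * n:] = 1.0

    def add_cut(self, reaction_ids: FrozenSet[str]) -> None:
        """Require at least one of the given non-core reactions to switch off."""
        row = np.zeros(2 * self.n + self.k)
        for i, rid in enumerate(self.noncore):
            if rid in reaction_ids:
                row[2 * self.n + i] = 1.0
        self.cuts.append(row)

    def solve(self) -> Optional[Tuple[Dict[str, float], Dict[str, int]]]:
        """Returns (net fluxes, z values) at the optimum, or None if infeasible."""
        constraints = [LinearConstraint(self.A_eq, 0.0, 0.0),
                       LinearConstraint(self.A_couple, -np.inf, self.big_m)]
        if self.cuts:
            constraints.append(
                LinearConstraint(np.vstack(self.cuts), 1.0, np.inf)
            )
        options = {}
        if self.time_limit:
            options["time_limit"] = self.time_limit
        res = milp(
            self.c,
            constraints=constraints,
            bounds=Bounds(self.lo, self.hi),
            integrality=self.integrality,
            options=options,
        )
        if res.status != 0 or res.x is None:
            return None
        x = res.x
        fluxes = {
            rid: float(x[j] - x[self.n + j]) for rid, j in self.ridx.items()
        }
        zvals = {
            rid: int(round(x[2 * self.n + i]))
            for i, rid in enumerate(self.noncore)
        }
        return fluxes, zvals


def _prepare_model(model: Model, demand: BBBDemand, mu_max: float) -> Model:
    """Copy of the model with the BBB sink added and biomass switched off.

    The maintenance (ATPM) lower bound and medium bounds are untouched.
    """
    m = model.copy()
    m.add_reaction(
        Reaction(
            id=demand.sink_id,
            stoich={demand.bbb_id: -1.0},
            lb=demand.n_gem * mu_max,
            ub=FLUX_CAP,
            subsystem="Sink",
            name=f"biosynthetic sink for {demand.bbb_id}",
        )
    )
    bio = m.reactions[m.biomass_id]
    bio.lb, bio.ub = 0.0, 0.0
    return m


def min_subnetwork(
    model: Model,
    core: CoreNetwork,
    demand: BBBDemand,
    cfg: LumpingConfig,
    medium: MediumSpec,
    condition: str = "",
) -> Subnetwork:
    """Smallest set of non-core reactions meeting the BBB sink demand.

    The model must already carry the medium bounds.  Raises
    UnreachableBBBError when no steady state can meet the demand.
    """
    subs, _ = _solve_subnetworks(model, core, demand, cfg, medium, condition,
                                 first_only=True)
    return subs[0]


def enumerate_subnetworks(
    model: Model,
    core: CoreNetwork,
    demand: BBBDemand,
    cfg: LumpingConfig,
    medium: MediumSpec,
    condition: str = "",
) -> List[Subnetwork]:
    """All distinct subnetworks of size <= S_min + margin via integer cuts."""
    subs, _ = _solve_subnetworks(model, core, demand, cfg, medium, condition,
                                 first_only=False)
    return subs


def _solve_subnetworks(
    model: Model,
    core: CoreNetwork,
    demand: BBBDemand,
    cfg: LumpingConfig,
    medium: MediumSpec,
    condition: str,
    first_only: bool,
) -> Tuple[List[Subnetwork], bool]:
    mu_max = cfg.mu_max if cfg.mu_max is not None else compute_mu_max(model)
    big_m = cfg.big_m if cfg.big_m is not None else default_big_m(model, medium)
    noncore = non_core_reactions(model, core, medium)
    prepared = _prepare_model(model, demand, mu_max)
    prob = _SplitFluxMILP(prepared, noncore, big_m, cfg.time_limit)
    tol = max(cfg.flux_tol_rel * big_m, 1e-12)
    found: List[Subnetwork] = []
    s_min: Optional[int] = None
    truncated = False
    while True:
        sol = prob.solve()
        if sol is None:
            if not found:
                raise UnreachableBBBError(demand.bbb_id)
            break
        fluxes, zvals = sol
        active = {
            rid: fluxes[rid]
            for rid in noncore
            if zvals[rid] == 0 and abs(fluxes[rid]) > tol
        }
        size = len(active)
        if s_min is None:
            s_min = size
        elif size > s_min + cfg.size_margin:
            break
        found.append(Subnetwork(demand.bbb_id, active, condition))
        if first_only or size == 0:
            break
        if len(found) >= cfg.max_alternatives:
            truncated = True
            break
        prob.add_cut(frozenset(active))
    return found, truncated


# ---------------------------------------------------------------------------
# Lumped reactions
# ---------------------------------------------------------------------------

def _witness_fluxes(
    model: Model,
    core: CoreNetwork,
    subnet: Subnetwork,
    demand: BBBDemand,
    medium: MediumSpec,
    mu_max: float,
) -> Dict[str, float]:
    """Deterministic flux witness: minimize total |v| over core + subnetwork
    with the sink fixed at the demand."""
    prepared = _prepare_model(model, demand, mu_max)
    allowed = (
        set(core.reactions)
        | set(subnet.reactions)
        | set(medium.uptakes)
        | {demand.sink_id}
    )
    if model.atpm_id:
        allowed.add(model.atpm_id)
    rids = [rid for rid in prepared.reactions if rid in allowed]
    S, mids, rids = prepared.stoichiometric_matrix(rids)
    n = len(rids)
    A_eq = sparse.hstack([S, -S]).tocsr()
    target = demand.n_gem * mu_max
    bounds = []
    for rid in rids:
        r = prepared.reactions[rid]
        if rid == demand.sink_id:
            lbF, ubF, lbB, ubB = target, target, 0.0, 0.0
        else:
            ubF = min(max(r.ub, 0.0), FLUX_CAP)
            ubB = min(max(-r.lb, 0.0), FLUX_CAP)
            lbF = max(r.lb, 0.0) if r.lb > 0 else 0.0
            lbB = 0.0
        bounds.append((lbF, ubF))
    for rid in rids:
        r = prepared.reactions[rid]
        if rid == demand.sink_id:
            bounds.append((0.0, 0.0))
        else:
            bounds.append((0.0, min(max(-r.lb, 0.0), FLUX_CAP)))
    res = linprog(
        np.ones(2 * n),
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise InfeasibleError(
            f"subnetwork for {demand.bbb_id!r} lost feasibility in LP re-check"
        )
    return {rid: float(res.x[j] - res.x[n + j]) for j, rid in enumerate(rids)}


def _rationalize(x: float, max_den: int = 10**6) -> Fraction:
    return Fraction(x).limit_denominator(max_den)


def lump_from_subnetwork(
    subnet: Subnetwork,
    model: Model,
    core: CoreNetwork,
    cof: Optional[CofactorSpec],
    demand: BBBDemand,
    medium: MediumSpec,
    mu_max: float,
    lump_id: Optional[str] = None,
    tol: float = 1e-7,
) -> Optional[LumpedReaction]:
    """Collapse a subnetwork into its normalized net reaction.

    Returns None for a size-0 subnetwork (the core alone makes the BBB).
    Raises BalanceError if a non-core intermediate fails to cancel.
    """
    if subnet.size == 0:
        return None
    fluxes = _witness_fluxes(model, core, subnet, demand, medium, mu_max)
    v_sink = demand.n_gem * mu_max
    net: Dict[str, float] = {}
    for rid in sorted(subnet.reactions):
        v = fluxes.get(rid, 0.0)
        for mid, coef in model.reactions[rid].stoich.items():
            net[mid] = net.get(mid, 0.0) + (v / v_sink) * coef
    bbb_coef = net.get(demand.bbb_id, 0.0)
    if bbb_coef <= tol:
        raise BalanceError(
            f"subnetwork for {demand.bbb_id!r} does not net-produce its BBB"
        )
    allowed_nonzero = set(core.metabolites) | (cof.excluded if cof else set())
    stoich: Dict[str, Fraction] = {}
    for mid, raw in net.items():
        val = raw / bbb_coef
        if abs(val) <= tol:
            continue
        if mid != demand.bbb_id and mid not in allowed_nonzero:
            raise BalanceError(
                f"non-core intermediate {mid!r} does not cancel in the lump "
                f"for {demand.bbb_id!r} (net {val:.3g})"
            )
        stoich[mid] = _rationalize(val)
    stoich[demand.bbb_id] = Fraction(1)
    gpr = conjoin(model.reactions[rid].gpr for rid in sorted(subnet.reactions))
    return LumpedReaction(
        id=lump_id or f"LMP_{demand.bbb_id}",
        bbb_id=demand.bbb_id,
        net_stoich=stoich,
        gpr=gpr,
        conditions=(subnet.condition,) if subnet.condition else (),
        source_subnetworks=(subnet.reaction_ids,),
    )


def dedupe_lumps(lumps: Sequence[LumpedReaction]) -> List[LumpedReaction]:
    """Merge lumps with identical canonical net stoichiometry.

    GPRs are OR-combined across merged sources; output order is stable by
    BBB id then stoichiometry.
    """
    groups: Dict[Tuple, List[LumpedReaction]] = {}
    for lump in lumps:
        groups.setdefault((lump.bbb_id, lump.canonical_key), []).append(lump)
    out: List[LumpedReaction] = []
    counters: Dict[str, int] = {}
    for (bbb, _key), members in sorted(
        groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
    ):
        counters[bbb] = counters.get(bbb, 0) + 1
        first = members[0]
        out.append(
            LumpedReaction(
                id=f"LMP_{bbb}_{counters[bbb]}",
                bbb_id=bbb,
                net_stoich=dict(first.net_stoich),
                gpr=disjoin(m.gpr for m in members),
                conditions=tuple(
                    sorted({c for m in members for c in m.conditions})
                ),
                source_subnetworks=tuple(
                    s for m in members for s in m.source_subnetworks
                ),
            )
        )
    return out


@dataclass
class BalanceReport:
    """Element/charge closure of a lumped reaction. Report-only: UNKNOWN when
    a participant lacks a formula, never silently repaired."""

    lump_id: str
    element_net: Dict[str, float]
    charge_net: float
    unknown_formula: List[str]
    status: str  # PASS | FAIL | UNKNOWN


def check_elemental_balance(
    lump: LumpedReaction, model: Model, tol: float = 1e-6
) -> BalanceReport:
    net: Dict[str, float] = {}
    charge = 0.0
    unknown: List[str] = []
    for mid, coef in lump.net_stoich.items():
        met = model.metabolites[mid]
        if met.formula is None:
            unknown.append(mid)
            continue
        for el, count in met.formula.items():
            net[el] = net.get(el, 0.0) + float(coef) * count
        if met.charge is not None:
            charge += float(coef) * met.charge
    net = {el: v for el, v in net.items() if abs(v) > tol}
    if unknown:
        status = "UNKNOWN"
    elif net or abs(charge) > tol:
        status = "FAIL"
    else:
        status = "PASS"
    return BalanceReport(lump.id, net, charge, sorted(unknown), status)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class LumpingResult:
    subnetworks: List[Subnetwork]
    lumps: List[LumpedReaction]
    core_producible: List[str]
    unreachable: List[str]
    mu_max: float
    condition: str
    note: str = "FBA-only lumping: no thermodynamic feasibility screening applied"


def generate_lumps(
    model: Model,
    core: CoreNetwork,
    medium: MediumSpec,
    cof: Optional[CofactorSpec],
    cfg: Optional[LumpingConfig] = None,
    condition: str = "",
) -> LumpingResult:
    """Run the per-BBB MILP over the whole biomass under one condition."""
    cfg = cfg or LumpingConfig()
    m = apply_medium(model, medium)
    mu_max = cfg.mu_max if cfg.mu_max is not None else compute_mu_max(m)
    cfg = LumpingConfig(
        big_m=cfg.big_m if cfg.big_m is not None else default_big_m(model, medium),
        mu_max=mu_max,
        flux_tol_rel=cfg.flux_tol_rel,
        size_margin=cfg.size_margin,
        max_alternatives=cfg.max_alternatives,
        time_limit=cfg.time_limit,
    )
    subnetworks: List[Subnetwork] = []
    lumps: List[LumpedReaction] = []
    core_producible: List[str] = []
    unreachable: List[str] = []
    for demand in decompose_biomass(m):
        try:
            subs = enumerate_subnetworks(m, core, demand, cfg, medium, condition)
        except UnreachableBBBError:
            unreachable.append(demand.bbb_id)
            continue
        if subs and subs[0].size == 0:
            core_producible.append(demand.bbb_id)
            continue
        for idx, sn in enumerate(subs, start=1):
            subnetworks.append(sn)
            lump = lump_from_subnetwork(
                sn, m, core, cof, demand, medium, mu_max,
                lump_id=f"LMP_{demand.bbb_id}_{idx}",
            )
            if lump is not None:
                lumps.append(lump)
    return LumpingResult(
        subnetworks=subnetworks,
        lumps=dedupe_lumps(lumps),
        core_producible=core_producible,
        unreachable=unreachable,
        mu_max=mu_max,
        condition=condition,
    )
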