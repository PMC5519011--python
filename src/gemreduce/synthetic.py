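"""Deterministic toy metabolic models with planted, known structure.

The generator builds a compartmentalized toy network that structurally
mimics a GEM: labelled subsystems (linear conversion chains), a cofactor
pool threaded through some reactions, a glucose-like substrate with
transport and exchange, per-subsystem secretion, an ATP maintenance demand,
planted inter-subsystem connector paths ("bridges") of chosen lengths,
planted intra-subsystem detours, and biomass building blocks with planted
minimal biosynthesis routes plus longer decoys.  Every enzymatic reaction is
elementally balanced (C/P/N bookkeeping), so lumped reactions can be audited
for mass balance.

Ground truth is recorded during construction: expected pair connections per
degree (exact when no random extra wiring is requested), minimal subnetwork
size and witnesses per building block, expected lump stoichiometries for
unique routes, genes that must (not) be essential, and the hand-computable
maximum growth rate uptake / sum(biomass coefficients).

Fixtures are structural, not biological: no attempt is made to reproduce
genome-scale statistics.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from .errors import ConfigError, OracleSizeError, UnreachableBBBError
from .expand import CoreNetwork, PairConnection, Subsystem, SubsystemSelection
from .lp import solve_lp
from .lumping import BBBDemand
from .model import CofactorSpec, MediumSpec, Metabolite, Model, Reaction, apply_medium

FORMULA_C = {"C": 1}


@dataclass(frozen=True)
class ToyGemSpec:
    """Recipe for a planted toy model; every field is deterministic in seed.

    ``bridges`` are (source subsystem, target subsystem, path length);
    ``intra_detours`` are (subsystem, path length) with length 1 meaning a
    direct mislabelled interconversion; ``bbbs`` are (anchor subsystem,
    route length, decoy length or None) with decoy length >= route length.
    """

    seed: int = 0
    n_subsystems: int = 3
    mets_per_subsystem: int = 4
    bridges: Tuple[Tuple[int, int, int], ...] = ((0, 1, 1), (0, 2, 2))
    intra_detours: Tuple[Tuple[int, int], ...] = ((0, 2), (0, 1))
    bbbs: Tuple[Tuple[int, int, Optional[int]], ...] = ((0, 2, 4), (1, 3, None))
    use_cofactors: bool = True
    uptake_rate: float = 10.0
    atpm_lb: float = 0.5
    random_extra_reactions: int = 0

    def __post_init__(self):
        if self.mets_per_subsystem < 3:
            raise ConfigError("chains need at least 3 metabolites")
        for i, j, d in self.bridges:
            if d < 1:
                raise ConfigError("planted bridge lengths must be >= 1")
            if not (0 <= i < self.n_subsystems and 0 <= j < self.n_subsystems):
                raise ConfigError("bridge endpoints out of range")
        for _, length, decoy in self.bbbs:
            if decoy is not None and decoy < length:
                raise ConfigError("decoy routes must not be shorter than the planted route")


@dataclass
class GroundTruth:
    """What the generator planted, in the vocabulary of the expansion step.

    ``exact_pairs`` is True when the planted bridges are provably the only
    inter-subsystem connections (star topology, no random extras); only then
    may ``pair_reactions`` be asserted directly instead of via the
    brute-force oracle.
    """

    selection: SubsystemSelection
    cofactors: CofactorSpec
    medium: MediumSpec
    pair_reactions: Dict[Tuple[str, str], Dict[int, FrozenSet[str]]]
    pair_intermediates: Dict[Tuple[str, str], Dict[int, FrozenSet[str]]]
    intra_reactions: Dict[str, Dict[int, FrozenSet[str]]]
    s_min: Dict[str, int]
    min_witnesses: Dict[str, FrozenSet[FrozenSet[str]]]
    lump_stoich: Dict[str, Dict[str, float]]
    rt_initial: Dict[str, FrozenSet[str]]
    rt_final: FrozenSet[str]
    must_be_essential: Set[str]
    must_not_be_essential: Set[str]
    mu_max: float
    exact_pairs: bool
    bbb_coefficients: Dict[str, float] = field(default_factory=dict)


def _sub(i: int) -> str:
    return f"SS{i}"


def make_toy_gem(spec: ToyGemSpec) -> Tuple[Model, GroundTruth]:
    """Build the toy model and its ground truth; same seed, same bytes."""
    rng = random.Random(spec.seed)
    L = spec.mets_per_subsystem
    model = Model(id=f"toy_seed{spec.seed}")

    def met(mid: str, formula=FORMULA_C, compartment="c"):
        if mid not in model.metabolites:
            model.add_metabolite(
                Metabolite(mid, compartment=compartment,
                           formula=dict(formula), charge=0)
            )
        return mid

    # cofactor pool (P/N bookkeeping keeps every enzymatic reaction balanced)
    cof = CofactorSpec()
    if spec.use_cofactors:
        met("atp_c", {"P": 3})
        met("adp_c", {"P": 2})
        met("pi_c", {"P": 1})
        met("nad_c", {"N": 1})
        met("nadh_c", {"N": 1})
        cof = CofactorSpec(
            cofactor_pairs=[("atp_c", "adp_c"), ("nad_c", "nadh_c")],
            inorganics={"pi_c"},
        )

    # subsystem chains
    for i in range(spec.n_subsystems):
        for k in range(L):
            met(f"s{i}_m{k}")
        for k in range(L - 1):
            stoich = {f"s{i}_m{k}": -1.0, f"s{i}_m{k+1}": 1.0}
            if spec.use_cofactors and rng.random() < 0.5:
                stoich.update({"atp_c": -1.0, "adp_c": 1.0, "pi_c": 1.0})
            gpr = f"g_R{i}_{k}"
            if i == 0 and k == 0:
                gpr = "g_iso_a or g_iso_b"
            model.add_reaction(
                Reaction(f"R{i}_{k}", stoich, lb=0.0, subsystem=_sub(i), gpr=gpr)
            )
    if spec.use_cofactors:
        # ATP recharge inside SS0 keeps the energy pool closed and core
        model.add_reaction(
            Reaction("RECHARGE", {"adp_c": -1.0, "pi_c": -1.0, "atp_c": 1.0},
                     lb=0.0, subsystem=_sub(0), gpr="g_RECHARGE")
        )
        # pure cofactor interconversion, unlabelled: final transfer-reaction bait
        model.add_reaction(
            Reaction("NADTRANS", {"nadh_c": -1.0, "nad_c": 1.0},
                     lb=-1000.0, subsystem="Unassigned", gpr="g_NADTRANS")
        )

    # substrate entry: extracellular glucose-like carbon with transport
    met("glc_e", FORMULA_C, "e")
    model.add_reaction(Reaction("EX_glc_e", {"glc_e": -1.0},
                                lb=-spec.uptake_rate, subsystem="Exchange"))
    model.add_reaction(
        Reaction("TRANS_glc", {"glc_e": -1.0, "s0_m0": 1.0}, lb=0.0,
                 subsystem="Transport", gpr="g_cplx_a and g_cplx_b")
    )
    # per-subsystem secretion so chains can drain
    for i in range(spec.n_subsystems):
        met(f"sec{i}_e", FORMULA_C, "e")
        model.add_reaction(
            Reaction(f"T_sec{i}", {f"s{i}_m{L-1}": -1.0, f"sec{i}_e": 1.0},
                     lb=0.0, subsystem="Transport", gpr=f"g_T_sec{i}")
        )
        model.add_reaction(Reaction(f"EX_sec{i}_e", {f"sec{i}_e": -1.0},
                                    lb=0.0, subsystem="Exchange"))

    # planted bridges: irreversible connector chains between subsystems
    pair_rxns: Dict[Tuple[str, str], Dict[int, Set[str]]] = {}
    pair_mets: Dict[Tuple[str, str], Dict[int, Set[str]]] = {}
    for idx, (i, j, d) in enumerate(spec.bridges):
        a = rng.randrange(1, L)
        prev = f"s{i}_m{a}"
        rids = []
        for t in range(1, d):
            mid = met(f"br{idx}_{t}")
            model.add_reaction(
                Reaction(f"BR{idx}_{t}", {prev: -1.0, mid: 1.0}, lb=0.0,
                         gpr=f"g_BR{idx}_{t}")
            )
            rids.append(f"BR{idx}_{t}")
            prev = mid
        model.add_reaction(
            Reaction(f"BR{idx}_{d}", {prev: -1.0, f"s{j}_m0": 1.0}, lb=0.0,
                     gpr=f"g_BR{idx}_{d}")
        )
        rids.append(f"BR{idx}_{d}")
        key = (_sub(min(i, j)), _sub(max(i, j)))
        pair_rxns.setdefault(key, {}).setdefault(d, set()).update(rids)
        pair_mets.setdefault(key, {}).setdefault(d, set()).update(
            f"br{idx}_{t}" for t in range(1, d)
        )

    # planted intra-subsystem detours (length 1 = mislabelled interconversion)
    intra_rxns: Dict[str, Dict[int, Set[str]]] = {}
    rt_initial: Dict[str, Set[str]] = {}
    for idx, (i, d) in enumerate(spec.intra_detours):
        p = rng.randrange(0, L - 1)
        q = rng.randrange(p + 1, L)
        prev = f"s{i}_m{p}"
        rids = []
        for t in range(1, d):
            mid = met(f"dt{idx}_{t}")
            model.add_reaction(
                Reaction(f"DT{idx}_{t}", {prev: -1.0, mid: 1.0}, lb=0.0,
                         gpr=f"g_DT{idx}_{t}")
            )
            rids.append(f"DT{idx}_{t}")
            prev = mid
        model.add_reaction(
            Reaction(f"DT{idx}_{d}", {prev: -1.0, f"s{i}_m{q}": 1.0}, lb=0.0,
                     gpr=f"g_DT{idx}_{d}")
        )
        rids.append(f"DT{idx}_{d}")
        intra_rxns.setdefault(_sub(i), {}).setdefault(d, set()).update(rids)
        if d == 1:
            rt_initial.setdefault(_sub(i), set()).add(f"DT{idx}_{d}")

    # biomass building blocks: planted route (+ optional decoy) to each BBB
    s_min: Dict[str, int] = {}
    witnesses: Dict[str, Set[FrozenSet[str]]] = {}
    lump_truth: Dict[str, Dict[str, float]] = {}
    bbb_coef: Dict[str, float] = {}
    biomass_stoich: Dict[str, float] = {}
    route_essential: Set[str] = set()
    route_nonessential: Set[str] = set()
    for t, (anchor_sub, length, decoy_len) in enumerate(spec.bbbs):
        bbb = met(f"bbb{t}_c")
        anchor = f"s{anchor_sub}_m{rng.randrange(1, L)}"
        prev = anchor
        rids = []
        coupled = 0
        for k in range(1, length):
            mid = met(f"rb{t}_{k}")
            stoich = {prev: -1.0, mid: 1.0}
            if spec.use_cofactors and k == 1:
                stoich.update({"atp_c": -1.0, "adp_c": 1.0, "pi_c": 1.0})
                coupled += 1
            model.add_reaction(
                Reaction(f"RB{t}_{k}", stoich, lb=0.0, gpr=f"g_RB{t}_{k}")
            )
            rids.append(f"RB{t}_{k}")
            prev = mid
        stoich = {prev: -1.0, bbb: 1.0}
        if spec.use_cofactors and length == 1:
            stoich.update({"atp_c": -1.0, "adp_c": 1.0, "pi_c": 1.0})
            coupled += 1
        model.add_reaction(
            Reaction(f"RB{t}_{length}", stoich, lb=0.0, gpr=f"g_RB{t}_{length}")
        )
        rids.append(f"RB{t}_{length}")
        s_min[bbb] = length
        witnesses[bbb] = {frozenset(rids)}
        lump = {anchor: -1.0, bbb: 1.0}
        if coupled:
            lump.update({"atp_c": -float(coupled), "adp_c": float(coupled),
                         "pi_c": float(coupled)})
        if decoy_len is not None:
            d_sub = rng.randrange(0, spec.n_subsystems)
            d_anchor = f"s{d_sub}_m{rng.randrange(1, L)}"
            prev = d_anchor
            drids = []
            for k in range(1, decoy_len):
                mid = met(f"dc{t}_{k}")
                model.add_reaction(
                    Reaction(f"DC{t}_{k}", {prev: -1.0, mid: 1.0}, lb=0.0,
                             gpr=f"g_DC{t}_{k}")
                )
                drids.append(f"DC{t}_{k}")
                prev = mid
            model.add_reaction(
                Reaction(f"DC{t}_{decoy_len}", {prev: -1.0, bbb: 1.0}, lb=0.0,
                         gpr=f"g_DC{t}_{decoy_len}")
            )
            drids.append(f"DC{t}_{decoy_len}")
            if decoy_len == length:
                witnesses[bbb].add(frozenset(drids))
            route_nonessential.update(f"g_{r}" for r in rids + drids)
        else:
            route_essential.update(f"g_{r}" for r in rids)
        if len(witnesses[bbb]) == 1:
            lump_truth[bbb] = lump
        n_coef = [1.0, 0.5, 0.25][t % 3]
        biomass_stoich[bbb] = -n_coef
        bbb_coef[bbb] = n_coef

    model.add_reaction(
        Reaction("BIOMASS", biomass_stoich, lb=0.0, subsystem="Biomass")
    )
    model.biomass_id = model.objective_id = "BIOMASS"
    if spec.use_cofactors:
        model.add_reaction(
            Reaction("ATPM", {"atp_c": -1.0, "adp_c": 1.0, "pi_c": 1.0},
                     lb=spec.atpm_lb, subsystem="Maintenance")
        )
        model.atpm_id = "ATPM"

    # optional random wiring between chain metabolites (topology variety for
    # oracle comparisons; carbon-balanced, so the growth optimum is untouched)
    chain_mets = [f"s{i}_m{k}" for i in range(spec.n_subsystems) for k in range(L)]
    for x in range(spec.random_extra_reactions):
        a, b = rng.sample(chain_mets, 2)
        lb = -1000.0 if rng.random() < 0.3 else 0.0
        model.add_reaction(
            Reaction(f"XR{x}", {a: -1.0, b: 1.0}, lb=lb, gpr=f"g_XR{x}")
        )

    selection = SubsystemSelection(
        subsystems=[_sub(i) for i in range(spec.n_subsystems)],
        extracellular_mets=["glc_e"]
        + [f"sec{i}_e" for i in range(spec.n_subsystems)],
        D=max([d for _, _, d in spec.bridges] + [1]),
        n_extracellular=0,
    )
    medium = MediumSpec(
        uptakes={"EX_glc_e": (-spec.uptake_rate, math.inf),
                 **{f"EX_sec{i}_e": (0.0, math.inf)
                    for i in range(spec.n_subsystems)}},
        carbon_sources=["EX_glc_e"],
        oxygen_allowed=False,
    )
    rt_final = frozenset({"NADTRANS", "ATPM"} if spec.use_cofactors else ())
    truth = GroundTruth(
        selection=selection,
        cofactors=cof,
        medium=medium,
        pair_reactions={
            k: {d: frozenset(v) for d, v in dd.items()} for k, dd in pair_rxns.items()
        },
        pair_intermediates={
            k: {d: frozenset(v) for d, v in dd.items()} for k, dd in pair_mets.items()
        },
        intra_reactions={
            k: {d: frozenset(v) for d, v in dd.items()} for k, dd in intra_rxns.items()
        },
        s_min=s_min,
        min_witnesses={k: frozenset(v) for k, v in witnesses.items()},
        lump_stoich=lump_truth,
        rt_initial={k: frozenset(v) for k, v in rt_initial.items()},
        rt_final=rt_final,
        must_be_essential={"g_cplx_a", "g_cplx_b"} | route_essential,
        must_not_be_essential={"g_iso_a", "g_iso_b"} | route_nonessential,
        mu_max=spec.uptake_rate / sum(bbb_coef.values()),
        exact_pairs=spec.random_extra_reactions == 0,
        bbb_coefficients=bbb_coef,
    )
    return model, truth


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_paths(
    model: Model,
    cof: Optional[CofactorSpec],
    sub_i: Subsystem,
    sub_j: Subsystem,
    D: int,
    max_reactions: int = 40,
) -> PairConnection:
    """Exhaustive simple-path enumeration straight off the stoichiometry.

    Independent of the graph machinery: traversable directions are re-derived
    from coefficient signs and bounds here.  Exponential; refuses models
    above ``max_reactions``.
    """
    if len(model.reactions) > max_reactions:
        raise OracleSizeError(
            f"path oracle limited to {max_reactions} reactions"
        )
    excluded = cof.excluded if cof else set()
    intra = sub_i.name == sub_j.name
    if intra:
        forbidden_mets = set(sub_i.metabolites)
        forbidden_rxns = set(sub_i.reactions)
    else:
        forbidden_mets = set(sub_i.metabolites | sub_j.metabolites)
        forbidden_rxns = set(sub_i.reactions | sub_j.reactions)

    steps: Dict[str, List[Tuple[str, str]]] = {}  # met -> [(rxn, next met)]
    for r in model.reactions.values():
        if r.id in forbidden_rxns:
            continue
        subs = [m for m, c in r.stoich.items() if c < 0 and m not in excluded]
        prods = [m for m, c in r.stoich.items() if c > 0 and m not in excluded]
        if r.ub > 0:
            for m in subs:
                for m2 in prods:
                    steps.setdefault(m, []).append((r.id, m2))
        if r.lb < 0:
            for m in prods:
                for m2 in subs:
                    steps.setdefault(m, []).append((r.id, m2))

    rxns_per_d: Dict[int, Set[str]] = {d: set() for d in range(1, D + 1)}
    mets_per_d: Dict[int, Set[str]] = {d: set() for d in range(1, D + 1)}
    l_min = math.inf

    def endpoints():
        if intra:
            for m0 in sub_i.metabolites:
                yield m0, sub_i.metabolites - {m0}
        else:
            src = sub_i.metabolites - sub_j.metabolites
            dst = sub_j.metabolites - sub_i.metabolites
            for m0 in src:
                yield m0, dst
            for m0 in dst:
                yield m0, src

    def walk(m, targets, depth, rpath, mpath, seen):
        nonlocal l_min
        if depth == D:
            return
        for rid, m2 in steps.get(m, ()):
            if rid in seen or m2 in seen:
                continue
            if m2 in targets:
                d = depth + 1
                rxns_per_d[d].update(rpath + [rid])
                mets_per_d[d].update(mpath)
                l_min = min(l_min, d)
            elif m2 not in forbidden_mets and depth + 1 < D:
                walk(m2, targets, depth + 1, rpath + [rid], mpath + [m2],
                     seen | {rid, m2})

    for m0, targets in endpoints():
        walk(m0, set(targets), 0, [], [], {m0})
    return PairConnection(
        sub_i.name, sub_j.name,
        {d: frozenset(v) for d, v in rxns_per_d.items()},
        {d: frozenset(v) for d, v in mets_per_d.items()},
        l_min,
    )


def brute_force_min_subnetwork(
    model: Model,
    core: CoreNetwork,
    demand: BBBDemand,
    medium: MediumSpec,
    mu_max: float,
    max_noncore: int = 12,
) -> Tuple[int, FrozenSet[FrozenSet[str]]]:
    """Subset search: smallest non-core reaction sets meeting the sink demand.

    Every candidate subset is tested by LP feasibility of the demand over
    core + subset + medium exchanges.  Exponential; refuses problems with
    more than ``max_noncore`` candidate reactions.
    """
    keep_free = set(medium.uptakes) | {model.biomass_id, model.atpm_id}
    candidates = sorted(
        rid for rid in model.reactions
        if rid not in core.reactions and rid not in keep_free
    )
    if len(candidates) > max_noncore:
        raise OracleSizeError(
            f"subnetwork oracle limited to {max_noncore} non-core reactions"
        )
    m = model.copy()
    m.add_reaction(
        Reaction(demand.sink_id, {demand.bbb_id: -1.0},
                 lb=demand.n_gem * mu_max, ub=1000.0)
    )
    bio = m.reactions[m.biomass_id]
    bio.lb, bio.ub = 0.0, 0.0
    base_allowed = (
        (set(m.reactions) - set(candidates))
    )

    def ok(subset) -> bool:
        res = solve_lp(m, {}, maximize=False, allowed=base_allowed | set(subset))
        return res.status == "optimal"

    for k in range(len(candidates) + 1):
        found = [
            frozenset(c) for c in itertools.combinations(candidates, k) if ok(c)
        ]
        if found:
            return k, frozenset(found)
    raise UnreachableBBBError(demand.bbb_id)
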