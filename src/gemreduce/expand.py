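"""Core-network construction by bounded graph expansion.

Starting from user-selected subsystems, the expansion (i) pulls in reactions
that only interconvert metabolites already inside one subsystem, (ii) searches
a cofactor-free bipartite metabolite-reaction digraph for all directed paths
of length d = 1..D between the non-shared metabolites of every subsystem pair
and within each subsystem, (iii) attaches extracellular metabolites through
their shortest routes (+ a user slack n), and (iv) sweeps up transfer
reactions whose participants are all core metabolites or excluded
cofactors/small metabolites/inorganics.  The union is the degree-D core
network with full provenance per reaction and metabolite.

Path semantics: paths are simple (no repeated node), run
metabolite -> reaction -> metabolite -> ..., respect reaction directionality
from the flux bounds, and never touch an excluded metabolite.  Intermediates
must lie outside the two endpoint subsystems but may belong to any other
subsystem; path reactions must lie outside both endpoint subsystems' reaction
sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import networkx as nx
import pandas as pd

from .errors import ConfigError
from .model import CofactorSpec, Model, Reaction, UNASSIGNED

logger = logging.getLogger(__name__)

EXTRACELLULAR = "Extracellular"


@dataclass
class SubsystemSelection:
    """The user's choice of starting subsystems and expansion parameters.

    ``pool_augmentations`` maps a subsystem name to metabolite ids whose every
    reaction is pulled into that subsystem (e.g. the quinone/quinol pool into
    oxidative phosphorylation).  ``n_extracellular`` is the slack on top of
    the shortest-path length used when attaching extracellular metabolites.
    """

    subsystems: List[str]
    pool_augmentations: Dict[str, List[str]] = field(default_factory=dict)
    extracellular_mets: List[str] = field(default_factory=list)
    D: int = 1
    n_extracellular: int = 0

    def __post_init__(self):
        if self.D < 0:
            raise ConfigError("degree of connection D must be >= 0")
        if self.n_extracellular < 0:
            raise ConfigError("n_extracellular must be >= 0")


@dataclass(frozen=True)
class Subsystem:
    """A resolved subsystem: its reaction set and non-excluded metabolites."""

    name: str
    metabolites: FrozenSet[str]
    reactions: FrozenSet[str]


@dataclass
class PairConnection:
    """Connections between two subsystems, per path length d.

    ``reactions[d]`` / ``intermediates[d]`` are all reactions / intermediate
    metabolites on paths of exactly d reactions.  Paths of one reaction have
    no intermediates by construction.
    """

    i: str
    j: str
    reactions: Dict[int, FrozenSet[str]] = field(default_factory=dict)
    intermediates: Dict[int, FrozenSet[str]] = field(default_factory=dict)
    l_min: float = math.inf

    def unique_reactions(self, d: int) -> FrozenSet[str]:
        """Reactions first appearing at degree d (not on any shorter path)."""
        seen: Set[str] = set()
        for dd in sorted(self.reactions):
            if dd < d:
                seen |= self.reactions[dd]
        return frozenset(self.reactions.get(d, frozenset()) - seen)

    @property
    def all_reactions(self) -> FrozenSet[str]:
        out: Set[str] = set()
        for s in self.reactions.values():
            out |= s
        return frozenset(out)

    @property
    def all_intermediates(self) -> FrozenSet[str]:
        out: Set[str] = set()
        for s in self.intermediates.values():
            out |= s
        return frozenset(out)


# Intra-subsystem connections share the container; i == j.
IntraConnection = PairConnection


# ---------------------------------------------------------------------------
# Subsystem resolution
# ---------------------------------------------------------------------------

def _non_excluded(rxn: Reaction, excluded: Set[str]) -> Set[str]:
    return rxn.metabolite_ids - excluded


def augment_subsystems(
    model: Model,
    sel: SubsystemSelection,
    cof: Optional[CofactorSpec] = None,
) -> Dict[str, Subsystem]:
    """Resolve each selected subsystem to its reactions and metabolites.

    Pool augmentation pulls every reaction touching a listed pool metabolite
    into the subsystem regardless of its original label; a reaction may end
    up in several subsystems.  Subsystem metabolites are the non-excluded
    participants of the subsystem's reactions.
    """
    excluded = cof.excluded if cof else set()
    unknown = {
        m for mets in sel.pool_augmentations.values() for m in mets
    } - set(model.metabolites)
    if unknown:
        raise ConfigError(f"pool augmentation references unknown metabolites {sorted(unknown)}")
    out: Dict[str, Subsystem] = {}
    for name in sel.subsystems:
        rxns = {r.id for r in model.reactions.values() if r.subsystem == name}
        for pool_met in sel.pool_augmentations.get(name, []):
            rxns |= {
                r.id for r in model.reactions.values() if pool_met in r.stoich
            }
        if not rxns:
            raise ConfigError(f"subsystem {name!r} resolves to no reactions")
        mets: Set[str] = set()
        for rid in rxns:
            mets |= _non_excluded(model.reactions[rid], excluded)
        out[name] = Subsystem(name, frozenset(mets), frozenset(rxns))
    return out


def initial_intra_expansion(
    model: Model,
    subsystems: Dict[str, Subsystem],
    cof: Optional[CofactorSpec] = None,
) -> Tuple[Dict[str, FrozenSet[str]], Dict[str, Subsystem]]:
    """Pull in mislabelled interconversions (first transfer-reaction stage).

    A reaction outside every selected subsystem whose non-excluded
    participants all lie within a single subsystem's metabolite set is added
    to that subsystem's reaction set.  Exchange reactions are left to the
    medium machinery.  Returns (tags per subsystem, updated subsystems).
    """
    excluded = cof.excluded if cof else set()
    member = {rid for s in subsystems.values() for rid in s.reactions}
    added: Dict[str, Set[str]] = {name: set() for name in subsystems}
    for rxn in model.reactions.values():
        if rxn.id in member or rxn.is_exchange:
            continue
        parts = _non_excluded(rxn, excluded)
        if not parts:
            continue  # pure cofactor interconversions belong to the final stage
        for name, sub in subsystems.items():
            if parts <= sub.metabolites:
                added[name].add(rxn.id)
    updated = {
        name: Subsystem(
            name, sub.metabolites, frozenset(sub.reactions | added[name])
        )
        for name, sub in subsystems.items()
    }
    return {name: frozenset(v) for name, v in added.items()}, updated


# ---------------------------------------------------------------------------
# Graph construction and path search
# ---------------------------------------------------------------------------

def build_graph(model: Model, cof: Optional[CofactorSpec] = None) -> nx.DiGraph:
    """Bipartite metabolite/reaction digraph without excluded metabolites.

    Arcs run substrate -> reaction -> product in every direction the bounds
    allow; a reaction whose non-excluded participant set is empty has no node.
    """
    excluded = cof.excluded if cof else set()
    g = nx.DiGraph()
    for rxn in model.reactions.values():
        parts = _non_excluded(rxn, excluded)
        if not parts:
            continue
        fwd = rxn.ub > 0
        bwd = rxn.lb < 0
        if not (fwd or bwd):
            continue
        g.add_node(rxn.id, kind="rxn")
        for mid in parts:
            g.add_node(mid, kind="met")
            coef = rxn.stoich[mid]
            if coef < 0:  # substrate in forward direction
                if fwd:
                    g.add_edge(mid, rxn.id)
                if bwd:
                    g.add_edge(rxn.id, mid)
            else:
                if fwd:
                    g.add_edge(rxn.id, mid)
                if bwd:
                    g.add_edge(mid, rxn.id)
    return g


def _enumerate_paths(
    graph: nx.DiGraph,
    sources: Iterable[str],
    targets: Set[str],
    forbidden_mets: Set[str],
    forbidden_rxns: Set[str],
    D: int,
) -> Tuple[Dict[int, Set[str]], Dict[int, Set[str]], float]:
    """DFS over all simple paths m0 -> r1 -> ... -> rd -> md with d <= D.

    ``forbidden_mets`` may not appear as intermediates (targets terminate a
    path; sources only start one); ``forbidden_rxns`` may not appear at all.
    Returns (reactions per d, intermediates per d, shortest length found).
    """
    rxns_per_d: Dict[int, Set[str]] = {d: set() for d in range(1, D + 1)}
    mets_per_d: Dict[int, Set[str]] = {d: set() for d in range(1, D + 1)}
    l_min = math.inf

    def dfs(met: str, depth: int, rpath: List[str], mpath: List[str],
            visited: Set[str]):
        nonlocal l_min
        if depth == D:
            return
        for rxn in graph.successors(met):
            if rxn in forbidden_rxns or rxn in visited:
                continue
            for nxt in graph.successors(rxn):
                if nxt in visited:
                    continue
                if nxt in targets:
                    d = depth + 1
                    rxns_per_d[d].update(rpath + [rxn])
                    mets_per_d[d].update(mpath)
                    l_min = min(l_min, d)
                elif nxt not in forbidden_mets and depth + 1 < D:
                    visited.add(rxn)
                    visited.add(nxt)
                    dfs(nxt, depth + 1, rpath + [rxn], mpath + [nxt], visited)
                    visited.discard(rxn)
                    visited.discard(nxt)

    for src in sources:
        if src in graph:
            dfs(src, 0, [], [], {src})
    return rxns_per_d, mets_per_d, l_min


def pairwise_connect(
    graph: nx.DiGraph, sub_i: Subsystem, sub_j: Subsystem, D: int
) -> PairConnection:
    """All paths of length d <= D between the non-shared metabolites of i, j."""
    if sub_i.name == sub_j.name:
        raise ConfigError("pairwise_connect requires two distinct subsystems")
    src = set(sub_i.metabolites - sub_j.metabolites)
    dst = set(sub_j.metabolites - sub_i.metabolites)
    forbidden_mets = set(sub_i.metabolites | sub_j.metabolites)
    forbidden_rxns = set(sub_i.reactions | sub_j.reactions)
    # paths are collected in both directions: i -> j and j -> i
    r_fwd, m_fwd, l_fwd = _enumerate_paths(graph, src, dst, forbidden_mets,
                                           forbidden_rxns, D)
    r_bwd, m_bwd, l_bwd = _enumerate_paths(graph, dst, src, forbidden_mets,
                                           forbidden_rxns, D)
    reactions = {d: frozenset(r_fwd[d] | r_bwd[d]) for d in range(1, D + 1)}
    intermediates = {d: frozenset(m_fwd[d] | m_bwd[d]) for d in range(1, D + 1)}
    return PairConnection(sub_i.name, sub_j.name, reactions, intermediates,
                          min(l_fwd, l_bwd))


def intra_connect(graph: nx.DiGraph, sub: Subsystem, D: int) -> IntraConnection:
    """Paths of length d <= D between two distinct metabolites of the same
    subsystem that detour outside it."""
    mets = set(sub.metabolites)
    rxns_per_d: Dict[int, Set[str]] = {d: set() for d in range(1, D + 1)}
    mets_per_d: Dict[int, Set[str]] = {d: set() for d in range(1, D + 1)}
    l_min = math.inf
    for src in mets:
        r_d, m_d, l = _enumerate_paths(
            graph, [src], mets - {src}, mets, set(sub.reactions), D
        )
        for d in range(1, D + 1):
            rxns_per_d[d] |= r_d[d]
            mets_per_d[d] |= m_d[d]
        l_min = min(l_min, l)
    return PairConnection(
        sub.name, sub.name,
        {d: frozenset(v) for d, v in rxns_per_d.items()},
        {d: frozenset(v) for d, v in mets_per_d.items()},
        l_min,
    )


def connect_extracellular(
    graph: nx.DiGraph,
    extracellular: Subsystem,
    subsystems: Mapping[str, Subsystem],
    n: int = 0,
    max_depth: int = 8,
) -> Tuple[List[PairConnection], List[Tuple[str, str]]]:
    """Attach each extracellular metabolite to every internal subsystem.

    For each metabolite the shortest connecting path length L_min to the
    subsystem is found (in either direction), then all connecting paths of
    length <= L_min + n are collected under the pairwise membership rules.
    Metabolites with no route within ``max_depth`` are reported unconnected.
    """
    out: List[PairConnection] = []
    unconnected: List[Tuple[str, str]] = []
    for name, sub in subsystems.items():
        reactions: Dict[int, Set[str]] = {}
        intermediates: Dict[int, Set[str]] = {}
        pair_lmin = math.inf
        for met in sorted(extracellular.metabolites):
            if met in sub.metabolites:
                continue  # already shared; no connector needed
            forbidden_mets = set(extracellular.metabolites | sub.metabolites)
            forbidden_rxns = set(extracellular.reactions | sub.reactions)
            targets = set(sub.metabolites - extracellular.metabolites)
            # probe both directions for the shortest connection
            r_f, m_f, l_f = _enumerate_paths(graph, [met], targets,
                                             forbidden_mets, forbidden_rxns,
                                             max_depth)
            r_b, m_b, l_b = _enumerate_paths(graph, targets, {met},
                                             forbidden_mets, forbidden_rxns,
                                             max_depth)
            l_min = min(l_f, l_b)
            if math.isinf(l_min):
                logger.warning(
                    "extracellular metabolite %r unreachable from subsystem %r",
                    met, name,
                )
                unconnected.append((met, name))
                continue
            pair_lmin = min(pair_lmin, l_min)
            depth = min(int(l_min) + n, max_depth)
            for d in range(1, depth + 1):
                reactions.setdefault(d, set()).update(r_f[d] | r_b[d])
                intermediates.setdefault(d, set()).update(m_f[d] | m_b[d])
        out.append(
            PairConnection(
                EXTRACELLULAR, name,
                {d: frozenset(v) for d, v in reactions.items()},
                {d: frozenset(v) for d, v in intermediates.items()},
                pair_lmin,
            )
        )
    return out, unconnected


def final_intra_expansion(
    model: Model,
    core_metabolites: Set[str],
    core_reactions: Set[str],
    cof: Optional[CofactorSpec] = None,
) -> FrozenSet[str]:
    """Second transfer-reaction stage.

    Every non-exchange reaction not yet in the core all of whose participants
    are core metabolites or excluded cofactors/small metabolites/inorganics
    is swept in; this captures pure cofactor interconversions (kinases,
    phosphatases, maintenance-style reactions).
    """
    excluded = cof.excluded if cof else set()
    allowed = core_metabolites | excluded
    out = set()
    for rxn in model.reactions.values():
        if rxn.id in core_reactions or rxn.is_exchange:
            continue
        if rxn.metabolite_ids and rxn.metabolite_ids <= allowed:
            out.add(rxn.id)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class CoreNetwork:
    """The assembled degree-D core with provenance for every member.

    ``provenance`` maps reaction id -> sorted tag list; a reaction can carry
    several tags (subsystem membership, connector at degree d, transfer
    reaction).  ``met_pairs`` maps an intermediate metabolite to, per degree,
    the set of subsystem pairs it connects.
    """

    D: int
    metabolites: FrozenSet[str]
    reactions: FrozenSet[str]
    provenance: Dict[str, Tuple[str, ...]]
    met_pairs: Dict[str, Dict[int, FrozenSet[Tuple[str, str]]]]
    subsystems: Dict[str, Subsystem]
    pair_connections: List[PairConnection]
    intra_connections: List[IntraConnection]
    extracellular_connections: List[PairConnection]
    rt_initial: Dict[str, FrozenSet[str]]
    rt_final: FrozenSet[str]
    unconnected_extracellular: List[Tuple[str, str]] = field(default_factory=list)

    def connecting_metabolite_report(self) -> pd.DataFrame:
        """Per intermediate metabolite, number of subsystem pairs connected
        at each degree."""
        degrees = list(range(1, self.D + 1))
        rows = []
        for met in sorted(self.met_pairs):
            row = {"metabolite": met}
            for d in degrees:
                row[f"D={d}"] = len(self.met_pairs[met].get(d, ()))
            rows.append(row)
        return pd.DataFrame(rows, columns=["metabolite"] + [f"D={d}" for d in degrees])

    def connecting_subsystem_report(self, model: Model) -> pd.DataFrame:
        """Origin (GEM-labelled) subsystem of each connector, per pair per
        degree."""
        rows = []
        for pc in self.pair_connections:
            for d in sorted(pc.reactions):
                for rid in sorted(pc.unique_reactions(d)):
                    rows.append(
                        {
                            "pair": f"{pc.i}|{pc.j}",
                            "D": d,
                            "reaction": rid,
                            "origin_subsystem": model.reactions[rid].subsystem,
                        }
                    )
        return pd.DataFrame(rows, columns=["pair", "D", "reaction", "origin_subsystem"])

    def summary(self) -> pd.DataFrame:
        """Subsystem-level counts (reactions, metabolites, transfer reactions)."""
        rows = []
        for name, sub in self.subsystems.items():
            rows.append(
                {
                    "subsystem": name,
                    "metabolites": len(sub.metabolites),
                    "reactions": len(sub.reactions),
                    "intra_expansion_reactions": len(self.rt_initial.get(name, ())),
                }
            )
        return pd.DataFrame(rows)

    def provenance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"reaction_id": rid, "tags": ";".join(tags)}
                for rid, tags in sorted(self.provenance.items())
            ]
        )


def assemble_core(
    model: Model,
    sel: SubsystemSelection,
    subsystems: Dict[str, Subsystem],
    pair_connections: List[PairConnection],
    intra_connections: List[IntraConnection],
    extracellular_connections: List[PairConnection],
    rt_initial: Dict[str, FrozenSet[str]],
    rt_final: FrozenSet[str],
    cof: Optional[CofactorSpec] = None,
    unconnected: Optional[List[Tuple[str, str]]] = None,
) -> CoreNetwork:
    """Union all expansion products into a CoreNetwork with provenance."""
    excluded = cof.excluded if cof else set()
    provenance: Dict[str, Set[str]] = {}

    def tag(rid: str, t: str):
        provenance.setdefault(rid, set()).add(t)

    core_mets: Set[str] = set()
    for name, sub in subsystems.items():
        core_mets |= sub.metabolites
        for rid in sub.reactions:
            tag(rid, f"RS@{name}")
        for rid in rt_initial.get(name, ()):
            tag(rid, f"RT-initial@{name}")
    core_mets |= {m for m in sel.extracellular_mets if m not in excluded}

    met_pairs: Dict[str, Dict[int, Set[Tuple[str, str]]]] = {}
    for pc in pair_connections + extracellular_connections:
        kind = "Rex" if pc.i == EXTRACELLULAR or pc.j == EXTRACELLULAR else "Rij"
        for d in sorted(pc.reactions):
            for rid in pc.reactions[d]:
                tag(rid, f"{kind}@{pc.i}|{pc.j}@d{d}")
            for mid in pc.intermediates.get(d, ()):
                core_mets.add(mid)
                met_pairs.setdefault(mid, {}).setdefault(d, set()).add((pc.i, pc.j))
    for ic in intra_connections:
        for d in sorted(ic.reactions):
            for rid in ic.reactions[d]:
                tag(rid, f"Rii@{ic.i}@d{d}")
            core_mets |= ic.intermediates.get(d, frozenset())
    for rid in rt_final:
        tag(rid, "RT-final")

    core_rxns = set(provenance)
    # excluded metabolites that actually occur in core reactions are core too
    for rid in core_rxns:
        core_mets |= model.reactions[rid].metabolite_ids & excluded

    return CoreNetwork(
        D=sel.D,
        metabolites=frozenset(core_mets),
        reactions=frozenset(core_rxns),
        provenance={rid: tuple(sorted(t)) for rid, t in provenance.items()},
        met_pairs={
            m: {d: frozenset(p) for d, p in dd.items()} for m, dd in met_pairs.items()
        },
        subsystems=dict(subsystems),
        pair_connections=pair_connections,
        intra_connections=intra_connections,
        extracellular_connections=extracellular_connections,
        rt_initial=rt_initial,
        rt_final=rt_final,
        unconnected_extracellular=list(unconnected or []),
    )


def build_core_network(
    model: Model, sel: SubsystemSelection, cof: Optional[CofactorSpec] = None
) -> CoreNetwork:
    """Run the full expansion workflow and return the degree-D core."""
    if cof is not None:
        cof.validate_against(model)
    subs = augment_subsystems(model, sel, cof)
    rt_initial, subs_expanded = initial_intra_expansion(model, subs, cof)
    graph = build_graph(model, cof)
    names = list(sel.subsystems)
    # path searches run against the augmented (pre-intra-expansion) subsystem
    # sets so a mislabelled interconversion can be captured both as an
    # intra-connection and as a transfer reaction; it then carries both tags
    pair_conns: List[PairConnection] = []
    intra_conns: List[IntraConnection] = []
    if sel.D >= 1:
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                pair_conns.append(
                    pairwise_connect(graph, subs[names[a]], subs[names[b]], sel.D)
                )
            intra_conns.append(intra_connect(graph, subs[names[a]], sel.D))
    extra_conns: List[PairConnection] = []
    unconnected: List[Tuple[str, str]] = []
    if sel.extracellular_mets:
        excluded = cof.excluded if cof else set()
        es = Subsystem(
            EXTRACELLULAR,
            frozenset(set(sel.extracellular_mets) - excluded),
            frozenset(),
        )
        extra_conns, unconnected = connect_extracellular(
            graph, es, subs, sel.n_extracellular
        )
    core_mets: Set[str] = set()
    for sub in subs_expanded.values():
        core_mets |= sub.metabolites
    core_mets |= {
        m for m in sel.extracellular_mets if not cof or m not in cof.excluded
    }
    for pc in pair_conns + intra_conns + extra_conns:
        core_mets |= pc.all_intermediates
    core_rxns: Set[str] = set()
    for sub in subs_expanded.values():
        core_rxns |= sub.reactions
    for pc in pair_conns + intra_conns + extra_conns:
        core_rxns |= pc.all_reactions
    rt_final = final_intra_expansion(model, core_mets, core_rxns, cof)
    return assemble_core(
        model, sel, subs_expanded, pair_conns, intra_conns, extra_conns,
        rt_initial, rt_final, cof, unconnected,
    )
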