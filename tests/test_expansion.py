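"""Core-network expansion: graph build, path capture, transfer reactions,
extracellular attachment and assembly provenance."""

import math

import pytest

from gemreduce import (
    CofactorSpec,
    Metabolite,
    Model,
    Reaction,
    SubsystemSelection,
    build_core_network,
)
from gemreduce.errors import ConfigError
from gemreduce.expand import (
    EXTRACELLULAR,
    Subsystem,
    augment_subsystems,
    build_graph,
    connect_extracellular,
    final_intra_expansion,
    initial_intra_expansion,
    intra_connect,
    pairwise_connect,
)


def _mk(mets, rxns, **kw):
    m = Model(**kw)
    for mid in mets:
        m.add_metabolite(Metabolite(mid, compartment=mid.rsplit("_", 1)[-1]))
    for r in rxns:
        m.add_reaction(r)
    return m


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def test_graph_excludes_cofactors_from_arcs():
    model = _mk(
        ["a_c", "b_c", "atp_c", "adp_c"],
        [Reaction("R1", {"a_c": -1, "atp_c": -1, "b_c": 1, "adp_c": 1}, lb=0)],
    )
    g = build_graph(model, CofactorSpec(cofactor_pairs=[("atp_c", "adp_c")]))
    assert set(g.edges) == {("a_c", "R1"), ("R1", "b_c")}


def test_graph_direction_follows_bounds():
    model = _mk(
        ["a_c", "b_c"],
        [Reaction("FWD", {"a_c": -1, "b_c": 1}, lb=0),
         Reaction("REV", {"a_c": -1, "b_c": 1}, lb=-1000)],
    )
    g = build_graph(model, None)
    assert ("b_c", "FWD") not in g.edges
    assert {("b_c", "REV"), ("REV", "a_c")} <= set(g.edges)


def test_graph_arc_count_matches_participation_table(toy):
    """Each (reaction, non-excluded metabolite) pair yields exactly one arc
    per allowed direction; count re-derived from the stoichiometry maps."""
    model, truth = toy
    excluded = truth.cofactors.excluded
    expected = 0
    for r in model.reactions.values():
        parts = [m for m in r.stoich if m not in excluded]
        if not parts:
            continue
        per_direction = (1 if r.ub > 0 else 0) + (1 if r.lb < 0 else 0)
        expected += len(parts) * per_direction
    g = build_graph(model, truth.cofactors)
    assert g.number_of_edges() == expected
    assert not set(g.nodes) & excluded


def test_cofactor_only_reaction_absent_from_graph(toy):
    model, truth = toy
    g = build_graph(model, truth.cofactors)
    assert "NADTRANS" not in g
    assert "ATPM" not in g


# ---------------------------------------------------------------------------
# subsystem resolution and transfer reactions
# ---------------------------------------------------------------------------

def test_pool_augmentation_pulls_in_foreign_reactions():
    """Every reaction touching a pool metabolite joins the subsystem."""
    model = _mk(
        ["q_c", "a_c", "b_c", "c_c", "d_c"],
        [
            Reaction("E1", {"a_c": -1, "q_c": 1}, lb=0, subsystem="ETC"),
            Reaction("F1", {"q_c": -1, "b_c": 1}, lb=0, subsystem="Foreign1"),
            Reaction("F2", {"c_c": -1, "q_c": -1, "d_c": 1}, lb=0, subsystem="Foreign2"),
            Reaction("F3", {"b_c": -1, "c_c": 1}, lb=0, subsystem="Foreign1"),
        ],
    )
    sel = SubsystemSelection(subsystems=["ETC"], pool_augmentations={"ETC": ["q_c"]})
    subs = augment_subsystems(model, sel)
    assert subs["ETC"].reactions == {"E1", "F1", "F2"}
    assert subs["ETC"].metabolites == {"a_c", "b_c", "c_c", "d_c", "q_c"}
    # empty augmentation is a no-op
    sel0 = SubsystemSelection(subsystems=["ETC"])
    assert augment_subsystems(model, sel0)["ETC"].reactions == {"E1"}


def test_unresolvable_subsystem_is_config_error(toy):
    model, _ = toy
    with pytest.raises(ConfigError, match="Ghost"):
        augment_subsystems(model, SubsystemSelection(subsystems=["Ghost"]))


def test_initial_intra_expansion_captures_mislabelled_interconversion(toy):
    model, truth = toy
    sel, cof = truth.selection, truth.cofactors
    subs = augment_subsystems(model, sel, cof)
    added, updated = initial_intra_expansion(model, subs, cof)
    assert added == {k: truth.rt_initial.get(k, frozenset()) for k in added}
    for name in added:
        assert added[name] <= updated[name].reactions
        # participants of added reactions lie inside the subsystem
        for rid in added[name]:
            parts = model.reactions[rid].metabolite_ids - cof.excluded
            assert parts <= updated[name].metabolites


def test_final_intra_expansion_cofactor_only(toy):
    model, truth = toy
    core = build_core_network(model, truth.selection, truth.cofactors)
    assert core.rt_final == truth.rt_final
    # the pure interconversion is captured only because its participants are
    # in the excluded cofactor set: with non-cofactor core metabolites alone
    # it stays out
    non_cof_core = set(core.metabolites) - truth.cofactors.excluded
    assert "NADTRANS" not in final_intra_expansion(model, non_cof_core, set(), None)


# ---------------------------------------------------------------------------
# pairwise / intra connections
# ---------------------------------------------------------------------------

def test_planted_bridges_found_exactly(toy, toy_core):
    model, truth = toy
    assert truth.exact_pairs
    found = {
        (pc.i, pc.j): {d: set(r) for d, r in pc.reactions.items() if r}
        for pc in toy_core.pair_connections
    }
    expected = {
        k: {d: set(v) for d, v in dd.items()} for k, dd in truth.pair_reactions.items()
    }
    for key, dd in expected.items():
        assert found.get(key) == dd
    # pairs without planted bridges stay empty
    for key, dd in found.items():
        if key not in expected:
            assert not dd


def test_degree_one_paths_have_no_intermediates(toy_core):
    for pc in toy_core.pair_connections + toy_core.intra_connections:
        assert not pc.intermediates.get(1)


def test_unique_reactions_disjoint_across_degrees(toy_core):
    for pc in toy_core.pair_connections:
        seen = set()
        for d in sorted(pc.reactions):
            uniq = pc.unique_reactions(d)
            assert not uniq & seen
            seen |= uniq


def test_intra_detours_found(toy, toy_core):
    _, truth = toy
    found = {ic.i: {d: set(r) for d, r in ic.reactions.items() if r}
             for ic in toy_core.intra_connections}
    for name, dd in truth.intra_reactions.items():
        assert found[name] == {d: set(v) for d, v in dd.items()}


def test_pair_connection_symmetric_in_argument_order(toy):
    model, truth = toy
    g = build_graph(model, truth.cofactors)
    subs = augment_subsystems(model, truth.selection, truth.cofactors)
    a, b = subs["SS0"], subs["SS1"]
    ab = pairwise_connect(g, a, b, 2)
    ba = pairwise_connect(g, b, a, 2)
    assert ab.reactions == ba.reactions
    assert ab.intermediates == ba.intermediates
    assert ab.l_min == ba.l_min


def test_single_metabolite_subsystem_has_no_intra_paths(toy):
    model, truth = toy
    g = build_graph(model, truth.cofactors)
    lone = Subsystem("Lone", frozenset({"s0_m1"}), frozenset())
    ic = intra_connect(g, lone, 3)
    assert not ic.all_reactions and math.isinf(ic.l_min)


# ---------------------------------------------------------------------------
# extracellular attachment
# ---------------------------------------------------------------------------

def _porin_model():
    """Two-step uptake chain: outer porin then inner transporter."""
    return _mk(
        ["glc_e", "glc_p", "glc_c", "x_c"],
        [
            Reaction("PORIN", {"glc_e": -1, "glc_p": 1}, lb=-1000),
            Reaction("PTS", {"glc_p": -1, "glc_c": 1}, lb=0),
            Reaction("G1", {"glc_c": -1, "x_c": 1}, lb=0, subsystem="GLY"),
        ],
    )


def test_two_step_transport_chain_attached_at_n0():
    model = _porin_model()
    g = build_graph(model, None)
    es = Subsystem(EXTRACELLULAR, frozenset({"glc_e"}), frozenset())
    subs = {"GLY": Subsystem("GLY", frozenset({"glc_c", "x_c"}), frozenset({"G1"}))}
    conns, unconnected = connect_extracellular(g, es, subs, n=0)
    assert not unconnected
    (pc,) = conns
    assert pc.l_min == 2
    assert pc.reactions[2] == {"PORIN", "PTS"}
    assert pc.intermediates[2] == {"glc_p"}


def test_shared_extracellular_metabolite_needs_no_connector():
    model = _porin_model()
    g = build_graph(model, None)
    es = Subsystem(EXTRACELLULAR, frozenset({"glc_e"}), frozenset())
    subs = {"S": Subsystem("S", frozenset({"glc_e", "x_c"}), frozenset())}
    conns, unconnected = connect_extracellular(g, es, subs, n=0)
    assert not unconnected
    assert not conns[0].all_reactions  # L_min = 0: nothing to add


def test_extracellular_slack_is_monotone(toy):
    model, truth = toy
    g = build_graph(model, truth.cofactors)
    subs = augment_subsystems(model, truth.selection, truth.cofactors)
    es = Subsystem(
        EXTRACELLULAR,
        frozenset(truth.selection.extracellular_mets) - truth.cofactors.excluded,
        frozenset(),
    )
    c0, _ = connect_extracellular(g, es, subs, n=0)
    c1, _ = connect_extracellular(g, es, subs, n=1)
    for pc0, pc1 in zip(c0, c1):
        assert pc0.all_reactions <= pc1.all_reactions
        assert pc0.all_intermediates <= pc1.all_intermediates


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def test_provenance_covers_every_core_member(toy, toy_core):
    model, truth = toy
    assert set(toy_core.provenance) == set(toy_core.reactions)
    assert all(len(tags) >= 1 for tags in toy_core.provenance.values())
    # every core reaction's non-excluded participants are core metabolites
    for rid in toy_core.reactions:
        parts = model.reactions[rid].metabolite_ids - truth.cofactors.excluded
        assert parts <= toy_core.metabolites


def test_mislabelled_interconversion_carries_both_tags(toy, toy_core):
    """A direct interconversion inside one subsystem is captured by the
    transfer-reaction stage and the degree-1 intra search simultaneously."""
    _, truth = toy
    (rid,) = truth.rt_initial["SS0"] & truth.intra_reactions["SS0"][1]
    tags = set(toy_core.provenance[rid])
    assert any(t.startswith("RT-initial") for t in tags)
    assert any(t.startswith("Rii@SS0@d1") for t in tags)


def test_core_is_nested_in_degree(toy):
    model, truth = toy
    prev_r, prev_m = frozenset(), frozenset()
    for D in (1, 2, 3):
        sel = SubsystemSelection(
            subsystems=truth.selection.subsystems,
            extracellular_mets=truth.selection.extracellular_mets,
            D=D,
        )
        core = build_core_network(model, sel, truth.cofactors)
        assert prev_r <= core.reactions and prev_m <= core.metabolites
        prev_r, prev_m = core.reactions, core.metabolites


def test_degree_zero_core_is_starting_subsystems_plus_transfer(toy):
    model, truth = toy
    sel = SubsystemSelection(subsystems=truth.selection.subsystems, D=0)
    core = build_core_network(model, sel, truth.cofactors)
    for tags in core.provenance.values():
        assert all(t.startswith(("RS@", "RT-")) for t in tags)
    labelled = {
        r.id for r in model.reactions.values()
        if r.subsystem in sel.subsystems
    }
    assert labelled <= core.reactions


def test_connecting_metabolite_report(toy, toy_core):
    _, truth = toy
    df = toy_core.connecting_metabolite_report().set_index("metabolite")
    # the planted two-step bridge metabolite connects exactly one pair at d=2
    (bridge_met,) = truth.pair_intermediates[("SS0", "SS2")][2]
    assert df.loc[bridge_met, "D=2"] == 1
    assert df.loc[bridge_met, "D=1"] == 0


def test_no_excluded_metabolite_in_connections(toy_core, toy):
    _, truth = toy
    excluded = truth.cofactors.excluded
    for pc in toy_core.pair_connections + toy_core.intra_connections:
        assert not pc.all_intermediates & excluded
    assert not set(toy_core.met_pairs) & excluded
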