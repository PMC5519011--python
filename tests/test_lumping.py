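"""Biomass decomposition, subnetwork MILP, lump construction and auditing."""

from fractions import Fraction

import pytest

from gemreduce import apply_medium, build_core_network
from gemreduce.errors import BalanceError, ConfigError, UnreachableBBBError
from gemreduce.gpr import GPR
from gemreduce.lumping import (
    BBBDemand,
    LumpedReaction,
    LumpingConfig,
    Subnetwork,
    check_elemental_balance,
    compute_mu_max,
    decompose_biomass,
    dedupe_lumps,
    default_big_m,
    enumerate_subnetworks,
    lump_from_subnetwork,
    min_subnetwork,
)
from gemreduce.model import MediumSpec, Metabolite, Model, Reaction
from gemreduce.synthetic import ToyGemSpec, make_toy_gem


def test_decompose_biomass_substrates_only(toy):
    model, truth = toy
    demands = decompose_biomass(model)
    got = {d.bbb_id: d.n_gem for d in demands}
    assert got == truth.bbb_coefficients
    assert all(d.sink_id == f"SINK_{d.bbb_id}" for d in demands)


def test_decompose_excludes_product_side():
    m = Model(biomass_id="BIO")
    for mid in ("a_c", "b_c", "waste_c"):
        m.add_metabolite(Metabolite(mid))
    m.add_reaction(Reaction("BIO", {"a_c": -0.5, "b_c": -0.2, "waste_c": 0.3}, lb=0))
    got = {d.bbb_id: d.n_gem for d in decompose_biomass(m)}
    assert got == {"a_c": 0.5, "b_c": 0.2}
    with pytest.raises(ConfigError):
        decompose_biomass(Model())


def test_mu_max_matches_hand_lp(toy, toy_fed):
    """The toy is carbon limited: mu = uptake / sum of BBB coefficients."""
    _, truth = toy
    assert compute_mu_max(toy_fed) == pytest.approx(truth.mu_max, rel=1e-9)


def test_mu_max_on_three_reaction_chain():
    """uptake 4 -> A -> B -> biomass(2 B per unit): mu = 4 / 2 = 2."""
    m = Model(biomass_id="BIO", objective_id="BIO")
    for mid in ("a_c", "b_c"):
        m.add_metabolite(Metabolite(mid))
    m.add_reaction(Reaction("EX_a", {"a_c": -1}, lb=-4.0))
    m.add_reaction(Reaction("CONV", {"a_c": -1, "b_c": 1}, lb=0))
    m.add_reaction(Reaction("BIO", {"b_c": -2}, lb=0))
    assert compute_mu_max(m) == pytest.approx(2.0)


def test_default_big_m_uses_carbon_atoms(toy):
    model, truth = toy
    # toy substrate carries one carbon at uptake 10
    assert default_big_m(model, truth.medium) == pytest.approx(10.0)


def test_min_subnetwork_finds_planted_route(toy, toy_core, toy_fed):
    model, truth = toy
    mu = compute_mu_max(toy_fed)
    cfg = LumpingConfig(mu_max=mu)
    for demand in decompose_biomass(toy_fed):
        sn = min_subnetwork(toy_fed, toy_core, demand, cfg, truth.medium)
        assert sn.size == truth.s_min[demand.bbb_id]
        assert sn.reaction_ids in truth.min_witnesses[demand.bbb_id]


def test_core_metabolite_demand_needs_empty_subnetwork(toy, toy_core, toy_fed):
    """A building block that is itself a core metabolite costs no non-core
    reactions."""
    _, truth = toy
    mu = compute_mu_max(toy_fed)
    demand = BBBDemand("s0_m1", 0.1, "SINK_s0_m1")
    sn = min_subnetwork(toy_fed, toy_core, demand, LumpingConfig(mu_max=mu),
                        truth.medium)
    assert sn.size == 0


def test_unreachable_bbb_raises(toy, toy_core, toy_fed):
    _, truth = toy
    m = toy_fed.copy()
    m.add_metabolite(Metabolite("orphan_c"))
    m.add_reaction(Reaction("ORPHAN_USE", {"orphan_c": -1}, lb=0, ub=0))
    demand = BBBDemand("orphan_c", 0.1, "SINK_orphan_c")
    with pytest.raises(UnreachableBBBError):
        min_subnetwork(m, toy_core, demand, LumpingConfig(mu_max=1.0), truth.medium)


def test_enumeration_returns_both_equal_alternatives():
    """Planted route and equal-length decoy are both minimal; a third
    solution does not exist at S_min."""
    model, truth = make_toy_gem(ToyGemSpec(seed=5, bbbs=((0, 2, 2),)))
    core = build_core_network(model, truth.selection, truth.cofactors)
    fed = apply_medium(model, truth.medium)
    mu = compute_mu_max(fed)
    (demand,) = decompose_biomass(fed)
    subs = enumerate_subnetworks(fed, core, demand, LumpingConfig(mu_max=mu),
                                 truth.medium)
    assert {sn.reaction_ids for sn in subs} == set(truth.min_witnesses[demand.bbb_id])
    assert len(subs) == 2


def test_unique_optimum_yields_single_subnetwork(toy, toy_core, toy_fed):
    _, truth = toy
    mu = compute_mu_max(toy_fed)
    demand = next(
        d for d in decompose_biomass(toy_fed)
        if len(truth.min_witnesses[d.bbb_id]) == 1
    )
    subs = enumerate_subnetworks(toy_fed, toy_core, demand,
                                 LumpingConfig(mu_max=mu), truth.medium)
    assert len(subs) == 1


def test_lump_matches_hand_summed_stoichiometry(toy, toy_core, toy_fed):
    """For a linear planted route the lump is anchor -> BBB plus the planted
    cofactor costs, exactly as summed by hand."""
    model, truth = toy
    mu = compute_mu_max(toy_fed)
    cfg = LumpingConfig(mu_max=mu)
    for demand in decompose_biomass(toy_fed):
        if demand.bbb_id not in truth.lump_stoich:
            continue
        sn = min_subnetwork(toy_fed, toy_core, demand, cfg, truth.medium)
        lump = lump_from_subnetwork(sn, toy_fed, toy_core, truth.cofactors,
                                    demand, truth.medium, mu)
        got = {m: float(c) for m, c in lump.net_stoich.items()}
        assert got == pytest.approx(truth.lump_stoich[demand.bbb_id])
        # conjunctive GPR over members
        assert lump.gpr.genes == {
            g for rid in sn.reactions for g in model.reactions[rid].gpr.genes
        }


def test_size_zero_subnetwork_emits_no_lump(toy, toy_core, toy_fed):
    _, truth = toy
    demand = BBBDemand("s0_m1", 0.1, "SINK_s0_m1")
    sn = Subnetwork(demand.bbb_id, {})
    assert lump_from_subnetwork(sn, toy_fed, toy_core, truth.cofactors,
                                demand, truth.medium, 1.0) is None


def test_non_cancelling_intermediate_is_balance_error(toy, toy_core, toy_fed):
    """Dropping one route reaction leaves an intermediate unbalanced: the
    witness LP fails feasibility rather than emitting a bad lump."""
    from gemreduce.errors import InfeasibleError

    model, truth = toy
    mu = compute_mu_max(toy_fed)
    demand = next(d for d in decompose_biomass(toy_fed)
                  if truth.s_min[d.bbb_id] >= 2)
    sn = min_subnetwork(toy_fed, toy_core, demand, LumpingConfig(mu_max=mu),
                        truth.medium)
    broken = Subnetwork(sn.bbb_id, dict(list(sn.reactions.items())[:-1]))
    with pytest.raises((BalanceError, InfeasibleError)):
        lump_from_subnetwork(broken, toy_fed, toy_core, truth.cofactors,
                             demand, truth.medium, mu)


def test_dedupe_merges_identical_stoichiometry():
    stoich = {"a_c": Fraction(-1), "bbb_c": Fraction(1)}
    l1 = LumpedReaction("L1", "bbb_c", dict(stoich), GPR.from_string("g1 and g2"),
                        ("aerobic",), (frozenset({"R1"}),))
    l2 = LumpedReaction("L2", "bbb_c", dict(stoich), GPR.from_string("g3"),
                        ("anaerobic",), (frozenset({"R2"}),))
    l3 = LumpedReaction("L3", "bbb_c", {"b_c": Fraction(-1), "bbb_c": Fraction(1)},
                        GPR.from_string("g4"))
    out = dedupe_lumps([l1, l2, l3])
    assert len(out) == 2
    merged = next(l for l in out if len(l.source_subnetworks) == 2)
    # OR across merged sources: either isozyme route suffices
    assert merged.gpr.evaluate({"g1"}) is True
    assert merged.gpr.evaluate({"g1", "g3"}) is False
    assert merged.conditions == ("aerobic", "anaerobic")
    assert dedupe_lumps([]) == []


def test_elemental_balance_pass_fail_unknown(toy, toy_lumping):
    model, _ = toy
    lump = toy_lumping.lumps[0]
    assert check_elemental_balance(lump, model).status == "PASS"
    # corrupt one coefficient: carbon no longer closes
    bad = LumpedReaction(lump.id, lump.bbb_id, dict(lump.net_stoich), lump.gpr)
    anchor = next(m for m, c in bad.net_stoich.items() if c < 0)
    bad.net_stoich[anchor] *= 2
    report = check_elemental_balance(bad, model)
    assert report.status == "FAIL" and "C" in report.element_net
    # unknown formula downgrades to UNKNOWN, never FAIL
    m2 = model.copy()
    m2.metabolites[anchor].formula = None
    assert check_elemental_balance(lump, m2).status == "UNKNOWN"


def test_generate_lumps_summary(toy, toy_lumping):
    _, truth = toy
    res = toy_lumping
    assert res.mu_max == pytest.approx(truth.mu_max)
    assert {l.bbb_id for l in res.lumps} == set(truth.s_min)
    assert not res.unreachable
    assert "thermodynamic" in res.note  # FBA-only caveat travels with results
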