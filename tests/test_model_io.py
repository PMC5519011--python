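"""Model container, medium application, and dialect round-trips."""

import math

import pytest

from gemreduce import (
    CofactorSpec,
    FormatError,
    IntegrityError,
    MediumSpec,
    Metabolite,
    Model,
    Reaction,
    apply_medium,
)
from gemreduce.errors import ConfigError
from gemreduce.io import (
    model_to_dict,
    read_cofactors,
    read_medium,
    read_model,
    write_cofactors,
    write_medium,
    write_model,
)
from gemreduce.lp import fba
from gemreduce.model import format_formula, parse_formula


@pytest.mark.parametrize(
    "text,expected",
    [
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("H2O", {"H": 2, "O": 1}),
        ("C10H12N5O13P3", {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}),
        ("Fe", {"Fe": 1}),
        ("", None),
    ],
)
def test_formula_parse(text, expected):
    assert parse_formula(text) == expected


def test_formula_parse_rejects_garbage():
    with pytest.raises(ValueError):
        parse_formula("c6h12")
    assert parse_formula(format_formula({"C": 6, "H": 12})) == {"C": 6, "H": 12}


def test_duplicate_ids_rejected():
    m = Model()
    m.add_metabolite(Metabolite("a_c"))
    with pytest.raises(IntegrityError):
        m.add_metabolite(Metabolite("a_c"))
    m.add_reaction(Reaction("R1", {"a_c": -1.0}))
    with pytest.raises(IntegrityError):
        m.add_reaction(Reaction("R1", {"a_c": 1.0}))


def test_reaction_drops_zero_coefficients_and_checks_bounds():
    r = Reaction("R", {"a": -1.0, "b": 0.0, "c": 2.0})
    assert set(r.stoich) == {"a", "c"}
    with pytest.raises(IntegrityError):
        Reaction("bad", {"a": -1.0}, lb=1.0, ub=-1.0)


def test_exchange_is_single_metabolite_convention():
    ex = Reaction("EX_a", {"a": -1.0}, lb=-10.0)
    internal = Reaction("R", {"a": -1.0, "b": 1.0})
    assert ex.is_exchange and not internal.is_exchange


def test_apply_medium_sets_and_closes_uptakes(toy):
    model, truth = toy
    fed = apply_medium(model, truth.medium)
    assert fed.reactions["EX_glc_e"].lb == -10.0
    # secretion stays open, uptake closed for unlisted exchanges
    for ex in fed.exchanges:
        if ex.id not in truth.medium.uptakes:
            assert ex.lb >= 0.0
    with pytest.raises(ConfigError):
        apply_medium(model, MediumSpec(uptakes={"EX_nonsense": (-1, 1)}))


def test_all_uptakes_closed_means_zero_growth(toy):
    model, _ = toy
    starved = apply_medium(model, MediumSpec(uptakes={}))
    # maintenance cycles alone cannot make biomass without carbon entry
    mu, _ = fba(starved, "BIOMASS", extra_bounds={"ATPM": (0.0, 0.0)})
    assert mu == pytest.approx(0.0, abs=1e-9)


def test_anaerobic_variant_closes_oxygen_bound():
    med = MediumSpec(
        uptakes={"EX_o2_e": (-1000.0, math.inf)}, oxygen_exchange="EX_o2_e"
    )
    ana = med.anaerobic()
    assert ana.uptakes["EX_o2_e"][0] == 0.0 and not ana.oxygen_allowed


@pytest.mark.parametrize("dialect,suffix", [("json", ".json"), ("sbml-fbc", ".xml")])
def test_model_round_trip(tmp_path, toy, dialect, suffix):
    """Write-read preserves stoichiometry, bounds, subsystems and GPR truth
    tables in both dialects."""
    model, _ = toy
    path = tmp_path / f"toy{suffix}"
    write_model(model, path, dialect)
    back = read_model(path, dialect)
    assert set(back.reactions) == set(model.reactions)
    assert set(back.metabolites) == set(model.metabolites)
    for rid, r in model.reactions.items():
        b = back.reactions[rid]
        assert b.stoich == pytest.approx(r.stoich)
        assert (b.lb, b.ub) == (r.lb, r.ub)
        assert b.subsystem == r.subsystem
        genes = sorted(r.gpr.genes)
        for k in range(len(genes) + 1):
            deleted = set(genes[:k])
            assert b.gpr.evaluate(deleted) == r.gpr.evaluate(deleted)
    for mid, met in model.metabolites.items():
        assert back.metabolites[mid].formula == met.formula
        assert back.metabolites[mid].compartment == met.compartment
    assert back.biomass_id == model.biomass_id


def test_empty_model_round_trip(tmp_path):
    path = tmp_path / "empty.json"
    write_model(Model(id="empty"), path)
    back = read_model(path)
    assert not back.reactions and not back.metabolites


def test_read_model_errors(tmp_path):
    with pytest.raises(FormatError):
        read_model(tmp_path / "missing.json")
    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    with pytest.raises(FormatError):
        read_model(bad)


def test_medium_and_cofactor_tsv_round_trip(tmp_path, toy):
    _, truth = toy
    mp = tmp_path / "medium.tsv"
    write_medium(truth.medium, mp)
    med = read_medium(mp)
    assert med.carbon_sources == ["EX_glc_e"]
    assert med.uptakes["EX_glc_e"][0] == -10.0
    cp = tmp_path / "cof.tsv"
    write_cofactors(truth.cofactors, cp)
    cof = read_cofactors(cp)
    assert cof.excluded == truth.cofactors.excluded


def test_element_balance_reported_not_fixed(toy):
    model, _ = toy
    net, charge, unknown = model.reactions["R0_0"].element_balance(model.metabolites)
    assert net == {} and charge == 0 and not unknown
    # deliberately corrupt a coefficient: imbalance must surface
    bad = model.reactions["R0_0"].copy()
    first = sorted(bad.stoich)[0]
    bad.stoich[first] *= 2
    net, _, _ = bad.element_balance(model.metabolites)
    assert net  # nonzero element totals reported


def test_cofactor_spec_union_and_validation(toy):
    model, truth = toy
    cof = truth.cofactors
    assert {"atp_c", "adp_c", "nad_c", "nadh_c", "pi_c"} <= cof.excluded
    with pytest.raises(ConfigError):
        CofactorSpec(small_metabolites={"ghost_c"}).validate_against(model)


def test_json_dict_is_stable(toy):
    model, _ = toy
    assert model_to_dict(model) == model_to_dict(model.copy())
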