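"""Reading and writing models and configuration files.

Two model dialects are supported: SBML Level 3 + FBC (the interchange format
published GEMs ship in, handled through cobrapy/libsbml) and a JSON dialect
that mirrors the in-memory schema one-to-one.  Configs are small tab-separated
or YAML files: medium (exchange_id, lb, ub), cofactor classes
(id, class in {cofactor, small, inorganic}) and the subsystem selection.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError, FormatError, IntegrityError
from .gpr import GPR
from .model import (
    CofactorSpec,
    MediumSpec,
    Metabolite,
    Model,
    Reaction,
    format_formula,
    parse_formula,
)

_INF = 1e6  # JSON has no Infinity; bounds at or beyond this round-trip as inf


def _num(x: float) -> float:
    if x >= _INF:
        return math.inf
    if x <= -_INF:
        return -math.inf
    return x


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: Model) -> dict:
    return {
        "id": model.id,
        "biomass_id": model.biomass_id,
        "objective_id": model.objective_id,
        "atpm_id": model.atpm_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": format_formula(m.formula),
                "charge": m.charge,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoich": dict(sorted(r.stoich.items())),
                "lb": min(max(r.lb, -_INF), _INF),
                "ub": min(max(r.ub, -_INF), _INF),
                "subsystem": r.subsystem,
                "gpr": r.gpr.to_string(),
            }
            for r in model.reactions.values()
        ],
    }


def model_from_dict(data: dict) -> Model:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=parse_formula(m.get("formula") or None),
                charge=m.get("charge"),
            )
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoich={k: float(v) for k, v in r["stoich"].items()},
                lb=_num(float(r.get("lb", -1000.0))),
                ub=_num(float(r.get("ub", 1000.0))),
                name=r.get("name", ""),
                subsystem=r.get("subsystem") or "Unassigned",
                gpr=GPR.from_string(r.get("gpr", "")),
            )
            for r in data["reactions"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed model JSON: {exc}") from exc
    return Model(
        id=data.get("id", "model"),
        metabolites=mets,
        reactions=rxns,
        biomass_id=data.get("biomass_id"),
        objective_id=data.get("objective_id"),
        atpm_id=data.get("atpm_id"),
    )


# ---------------------------------------------------------------------------
# SBML (via cobrapy)
# ---------------------------------------------------------------------------

def _from_cobra(cmodel) -> Model:
    # subsystem labels travel as SBML groups; reaction.subsystem ("notes"
    # style annotation) is the fallback for models written that way
    group_of = {}
    for group in getattr(cmodel, "groups", []):
        for member in group.members:
            group_of.setdefault(member.id, group.name or group.id)
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            formula=parse_formula(m.formula or None),
            charge=m.charge,
        )
        for m in cmodel.metabolites
    ]
    rxns = []
    biomass_id = None
    for r in cmodel.reactions:
        if r.objective_coefficient:
            biomass_id = r.id
        rxns.append(
            Reaction(
                id=r.id,
                stoich={m.id: c for m, c in r.metabolites.items()},
                lb=float(r.lower_bound),
                ub=float(r.upper_bound),
                name=r.name or "",
                subsystem=group_of.get(r.id) or r.subsystem or "Unassigned",
                gpr=GPR.from_string(r.gene_reaction_rule),
            )
        )
    atpm_id = next((r.id for r in cmodel.reactions if r.id.upper() == "ATPM"), None)
    return Model(
        id=cmodel.id or "model",
        metabolites=mets,
        reactions=rxns,
        biomass_id=biomass_id,
        objective_id=biomass_id,
        atpm_id=atpm_id,
    )


def _to_cobra(model: Model):
    import cobra

    cmodel = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites.values():
        cm = cobra.Metabolite(
            m.id,
            name=m.name,
            compartment=m.compartment,
            formula=format_formula(m.formula) or None,
            charge=m.charge,
        )
        cmets[m.id] = cm
    cmodel.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(
            r.id,
            name=r.name,
            lower_bound=max(r.lb, -1e6),
            upper_bound=min(r.ub, 1e6),
        )
        cr.subsystem = r.subsystem
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for r in model.reactions.values():
        cr = cmodel.reactions.get_by_id(r.id)
        cr.add_metabolites({cmets[mid]: c for mid, c in r.stoich.items()})
        if not r.gpr.is_empty:
            cr.gene_reaction_rule = r.gpr.to_string()
    if model.objective_id:
        cmodel.objective = model.objective_id
    by_subsystem: dict[str, list] = {}
    for r in model.reactions.values():
        by_subsystem.setdefault(r.subsystem, []).append(
            cmodel.reactions.get_by_id(r.id)
        )
    cmodel.add_groups(
        [
            cobra.core.Group(
                id=name.replace(" ", "_"), name=name, members=members,
                kind="partonomy",
            )
            for name, members in sorted(by_subsystem.items())
        ]
    )
    return cmodel


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def read_model(path: str | Path, dialect: Optional[str] = None) -> Model:
    """Read a model from SBML-FBC or the JSON dialect.

    ``dialect`` is 'sbml-fbc' or 'json'; inferred from the extension when
    omitted (.xml/.sbml -> SBML, .json -> JSON).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file not found: {path}")
    if dialect is None:
        dialect = "sbml-fbc" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if dialect == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid JSON in {path}: {exc}") from exc
        return model_from_dict(data)
    if dialect == "sbml-fbc":
        import cobra

        try:
            cmodel = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml raises a zoo of types
            raise FormatError(f"cannot parse SBML {path}: {exc}") from exc
        return _from_cobra(cmodel)
    raise FormatError(f"unknown model dialect {dialect!r}")


def write_model(model: Model, path: str | Path, dialect: Optional[str] = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "sbml-fbc" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if dialect == "json":
        path.write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=False))
        return
    if dialect == "sbml-fbc":
        import cobra

        cobra.io.write_sbml_model(_to_cobra(model), str(path))
        return
    raise FormatError(f"unknown model dialect {dialect!r}")


def read_medium(path: str | Path) -> MediumSpec:
    """Read a medium TSV with columns exchange_id, lb, ub (header optional)."""
    uptakes = {}
    carbon: list[str] = []
    oxygen_exchange = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] in ("exchange_id", "id"):
            continue
        if len(parts) < 3:
            raise FormatError(f"medium line needs 3 columns: {line!r}")
        ex, lb, ub = parts[0], float(parts[1]), float(parts[2])
        uptakes[ex] = (lb, ub)
        if len(parts) > 3:
            if "carbon" in parts[3]:
                carbon.append(ex)
            if "oxygen" in parts[3]:
                oxygen_exchange = ex
    return MediumSpec(
        uptakes=uptakes,
        carbon_sources=carbon,
        oxygen_exchange=oxygen_exchange,
        oxygen_allowed=oxygen_exchange is None
        or uptakes.get(oxygen_exchange, (0, 0))[0] < 0,
    )


def write_medium(medium: MediumSpec, path: str | Path) -> None:
    lines = ["exchange_id\tlb\tub\trole"]
    for ex, (lb, ub) in sorted(medium.uptakes.items()):
        roles = []
        if ex in medium.carbon_sources:
            roles.append("carbon")
        if ex == medium.oxygen_exchange:
            roles.append("oxygen")
        lines.append(f"{ex}\t{min(lb, _INF)}\t{min(ub, _INF)}\t{'+'.join(roles)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cofactors(path: str | Path) -> CofactorSpec:
    """Read a cofactor TSV with columns id, class in {cofactor, small, inorganic}.

    Cofactor rows may give a pair as 'atp_c,adp_c' in the id column.
    """
    pairs, small, inorg = [], set(), set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("id\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"cofactor line needs 2 columns: {line!r}")
        ids, cls = parts[0], parts[1]
        if cls == "cofactor":
            members = ids.split(",")
            if len(members) == 2:
                pairs.append((members[0], members[1]))
            else:
                small.update(members)
        elif cls == "small":
            small.update(ids.split(","))
        elif cls == "inorganic":
            inorg.update(ids.split(","))
        else:
            raise FormatError(f"unknown cofactor class {cls!r}")
    return CofactorSpec(cofactor_pairs=pairs, small_metabolites=small, inorganics=inorg)


def write_cofactors(cof: CofactorSpec, path: str | Path) -> None:
    lines = ["id\tclass"]
    for a, b in cof.cofactor_pairs:
        lines.append(f"{a},{b}\tcofactor")
    for mid in sorted(cof.small_metabolites):
        lines.append(f"{mid}\tsmall")
    for mid in sorted(cof.inorganics):
        lines.append(f"{mid}\tinorganic")
    Path(path).write_text("\n".join(lines) + "\n")


def read_selection(path: str | Path):
    """Read a SubsystemSelection from YAML.

    Expected keys: subsystems (list), pool_augmentations (map name -> id
    list), extracellular_mets (list), D (int), n_extracellular (int).
    """
    from .expand import SubsystemSelection

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "subsystems" not in data:
        raise ConfigError(f"selection YAML must define 'subsystems': {path}")
    return SubsystemSelection(
        subsystems=list(data["subsystems"]),
        pool_augmentations={
            k: list(v) for k, v in (data.get("pool_augmentations") or {}).items()
        },
        extracellular_mets=list(data.get("extracellular_mets") or []),
        D=int(data.get("D", 1)),
        n_extracellular=int(data.get("n_extracellular", 0)),
    )
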