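"""In-memory representation of a constraint-based metabolic model.

The model is a plain stoichiometric network: metabolites with elemental
formulas and compartments, reactions with flux bounds (mmol/gDWhr), subsystem
labels and GPR rules.  Exchange reactions follow the dominant GEM convention:
a single-metabolite reaction with no explicit boundary species, negative flux
meaning uptake and positive flux meaning secretion.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
from scipy import sparse

from .errors import ConfigError, IntegrityError
from .gpr import GPR

UNASSIGNED = "Unassigned"

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | None) -> Optional[Dict[str, int]]:
    """Parse a Hill-notation formula string ('C6H12O6') to an element map."""
    if formula is None or formula == "":
        return None
    counts: Dict[str, int] = {}
    consumed = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != consumed:
            raise ValueError(f"cannot parse formula {formula!r}")
        consumed = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if consumed != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def format_formula(counts: Optional[Mapping[str, int]]) -> str:
    if not counts:
        return ""
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(counts.items()) if n
    )


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[Dict[str, int]] = None
    charge: Optional[int] = None

    def __post_init__(self):
        if not self.compartment:
            raise IntegrityError(f"metabolite {self.id!r} has empty compartment")
        if self.formula is not None and any(v < 0 for v in self.formula.values()):
            raise IntegrityError(f"metabolite {self.id!r} has negative formula count")


@dataclass
class Reaction:
    """A reaction: stoich maps metabolite id -> coefficient (negative = consumed)."""

    id: str
    stoich: Dict[str, float]
    lb: float = -1000.0
    ub: float = 1000.0
    name: str = ""
    subsystem: str = UNASSIGNED
    gpr: GPR = field(default_factory=lambda: GPR(None))

    def __post_init__(self):
        self.stoich = {m: c for m, c in self.stoich.items() if c != 0}
        if isinstance(self.gpr, str):
            self.gpr = GPR.from_string(self.gpr)
        if not self.subsystem:
            self.subsystem = UNASSIGNED
        if self.lb > self.ub:
            raise IntegrityError(f"reaction {self.id!r} has lb > ub")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoich) == 1

    @property
    def reversible(self) -> bool:
        return self.lb < 0 and self.ub > 0

    @property
    def metabolite_ids(self) -> Set[str]:
        return set(self.stoich)

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id, stoich=dict(self.stoich), lb=self.lb, ub=self.ub,
            name=self.name, subsystem=self.subsystem, gpr=self.gpr,
        )

    def element_balance(
        self, metabolites: Mapping[str, Metabolite]
    ) -> Tuple[Dict[str, float], float, List[str]]:
        """Net elemental/charge balance of the reaction.

        Returns (per-element net, net charge, metabolites with unknown
        formula).  Imbalance is reported, never silently repaired.
        """
        net: Dict[str, float] = {}
        charge = 0.0
        unknown: List[str] = []
        for mid, coef in self.stoich.items():
            met = metabolites[mid]
            if met.formula is None:
                unknown.append(mid)
                continue
            for el, count in met.formula.items():
                net[el] = net.get(el, 0.0) + coef * count
            if met.charge is not None:
                charge += coef * met.charge
        return {el: v for el, v in net.items() if abs(v) > 1e-9}, charge, unknown


class Model:
    """A constraint-based model: metabolites, reactions, genes and objective."""

    def __init__(
        self,
        id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        biomass_id: Optional[str] = None,
        objective_id: Optional[str] = None,
        atpm_id: Optional[str] = None,
    ):
        self.id = id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)
        self.biomass_id = biomass_id
        self.objective_id = objective_id or biomass_id
        self.atpm_id = atpm_id

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise IntegrityError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise IntegrityError(f"duplicate reaction id {rxn.id!r}")
        missing = rxn.metabolite_ids - set(self.metabolites)
        if missing:
            raise IntegrityError(
                f"reaction {rxn.id!r} references unknown metabolites {sorted(missing)}"
            )
        self.reactions[rxn.id] = rxn

    def copy(self) -> "Model":
        m = Model(
            id=self.id,
            metabolites=[replace(mm, formula=dict(mm.formula) if mm.formula else None)
                         for mm in self.metabolites.values()],
            reactions=[r.copy() for r in self.reactions.values()],
            biomass_id=self.biomass_id,
            objective_id=self.objective_id,
            atpm_id=self.atpm_id,
        )
        return m

    # -- views ------------------------------------------------------------
    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for r in self.reactions.values():
            out |= r.gpr.genes
        return out

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    @property
    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    def stoichiometric_matrix(
        self, reaction_ids: Optional[List[str]] = None
    ) -> Tuple[sparse.csr_matrix, List[str], List[str]]:
        """S with shape |metabolites| x |reactions| plus row/column id orders."""
        rids = list(reaction_ids) if reaction_ids is not None else list(self.reactions)
        mids = list(self.metabolites)
        mindex = {m: i for i, m in enumerate(mids)}
        rows, cols, data = [], [], []
        for j, rid in enumerate(rids):
            for mid, coef in self.reactions[rid].stoich.items():
                rows.append(mindex[mid])
                cols.append(j)
                data.append(coef)
        S = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(mids), len(rids))
        )
        return S, mids, rids

    def validate(self) -> None:
        """Check structural invariants; raises IntegrityError on violation."""
        if self.biomass_id is not None and self.biomass_id not in self.reactions:
            raise IntegrityError(f"biomass reaction {self.biomass_id!r} missing")
        for r in self.reactions.values():
            if r.lb > r.ub:
                raise IntegrityError(f"reaction {r.id!r} has lb > ub")


@dataclass
class MediumSpec:
    """Exchange bounds defining a growth medium.

    ``uptakes`` maps exchange reaction id -> (lb, ub); every exchange not
    listed gets its uptake closed (lb = 0) while secretion stays open.
    """

    uptakes: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    oxygen_allowed: bool = True
    carbon_sources: List[str] = field(default_factory=list)
    oxygen_exchange: Optional[str] = None

    def with_carbon_source(self, exchange_id: str, rate: float = 10.0) -> "MediumSpec":
        """Swap the carbon source, keeping mineral/oxygen uptakes."""
        uptakes = {
            ex: b for ex, b in self.uptakes.items() if ex not in self.carbon_sources
        }
        uptakes[exchange_id] = (-abs(rate), math.inf)
        return MediumSpec(
            uptakes=uptakes,
            oxygen_allowed=self.oxygen_allowed,
            carbon_sources=[exchange_id],
            oxygen_exchange=self.oxygen_exchange,
        )

    def anaerobic(self) -> "MediumSpec":
        if self.oxygen_exchange is None:
            return replace(self, oxygen_allowed=False)
        uptakes = dict(self.uptakes)
        uptakes[self.oxygen_exchange] = (0.0, math.inf)
        return MediumSpec(
            uptakes=uptakes,
            oxygen_allowed=False,
            carbon_sources=list(self.carbon_sources),
            oxygen_exchange=self.oxygen_exchange,
        )


def apply_medium(model: Model, medium: MediumSpec) -> Model:
    """Return a copy of the model with exchange bounds set by the medium.

    Unlisted exchange uptakes are closed; secretion is left open unless the
    medium explicitly bounds it.
    """
    unknown = set(medium.uptakes) - set(model.reactions)
    if unknown:
        raise ConfigError(f"medium references unknown exchanges {sorted(unknown)}")
    out = model.copy()
    for rxn in out.reactions.values():
        if not rxn.is_exchange:
            continue
        if rxn.id in medium.uptakes:
            lb, ub = medium.uptakes[rxn.id]
            rxn.lb, rxn.ub = float(lb), float(ub)
        else:
            rxn.lb = max(rxn.lb, 0.0)
    return out


@dataclass
class CofactorSpec:
    """Cofactor pairs, small metabolites and inorganics removed from graphs."""

    cofactor_pairs: List[Tuple[str, str]] = field(default_factory=list)
    small_metabolites: Set[str] = field(default_factory=set)
    inorganics: Set[str] = field(default_factory=set)

    @property
    def excluded(self) -> Set[str]:
        out: Set[str] = set()
        for a, b in self.cofactor_pairs:
            out |= {a, b}
        return out | set(self.small_metabolites) | set(self.inorganics)

    def validate_against(self, model: Model) -> None:
        missing = self.excluded - set(model.metabolites)
        if missing:
            raise ConfigError(
                f"cofactor spec references unknown metabolites {sorted(missing)}"
            )
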