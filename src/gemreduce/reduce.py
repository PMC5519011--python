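"""Assembly of the reduced model from core network, lumps and environment."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from .errors import IntegrityError
from .expand import CoreNetwork
from .lumping import LumpedReaction
from .model import MediumSpec, Metabolite, Model, apply_medium


class ReducedModel(Model):
    """A reduced model: core reactions + lumped biosynthesis + biomass,
    maintenance and medium exchanges, with provenance per reaction."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.provenance: Dict[str, str] = {}
        self.parent_id: Optional[str] = None
        self.D: Optional[int] = None
        self.conditions: Tuple[str, ...] = ()
        self.pruned: List[str] = []


def build_rgem(
    core: CoreNetwork,
    lumps: Sequence[LumpedReaction],
    model: Model,
    medium: MediumSpec,
    prune_blocked: bool = False,
) -> ReducedModel:
    """Assemble the reduced model.

    The original biomass reaction is retained (its building blocks are now
    supplied by the core plus the lumps), the maintenance bound is copied
    from the parent, and every parent exchange whose metabolite survives in
    the reduced network is kept with the medium's bounds.  Raises
    IntegrityError when a biomass building block has no producing route.
    """
    rgem = ReducedModel(
        id=f"{model.id}_reduced_D{core.D}",
        biomass_id=model.biomass_id,
        objective_id=model.objective_id,
        atpm_id=model.atpm_id,
    )
    rgem.parent_id = model.id
    rgem.D = core.D
    rgem.conditions = tuple(sorted({c for l in lumps for c in l.conditions}))

    keep: Dict[str, str] = {}
    for rid in sorted(core.reactions):
        keep[rid] = ";".join(core.provenance[rid])
    if model.biomass_id:
        keep.setdefault(model.biomass_id, "biomass")
    if model.atpm_id and model.atpm_id in model.reactions:
        keep.setdefault(model.atpm_id, "maintenance")

    met_ids = set()
    for rid in keep:
        met_ids |= model.reactions[rid].metabolite_ids
    lump_rxns = [l.to_reaction() for l in lumps]
    for lr in lump_rxns:
        met_ids |= lr.metabolite_ids

    # parent exchanges whose metabolite survives stay in, under medium bounds
    for ex in model.exchanges:
        (mid,) = ex.metabolite_ids
        if mid in met_ids and ex.id not in keep:
            keep[ex.id] = "exchange"

    for mid in sorted(met_ids):
        src = model.metabolites[mid]
        rgem.add_metabolite(
            Metabolite(src.id, src.name, src.compartment,
                       dict(src.formula) if src.formula else None, src.charge)
        )
    for rid in sorted(keep):
        rgem.add_reaction(model.reactions[rid].copy())
        rgem.provenance[rid] = keep[rid]
    for lr, lump in zip(lump_rxns, lumps):
        rgem.add_reaction(lr)
        rgem.provenance[lr.id] = f"lump:{lump.bbb_id}"

    _check_orphan_bbbs(rgem)
    out = apply_medium(rgem, medium)
    out.__class__ = ReducedModel
    out.provenance = dict(rgem.provenance)
    out.parent_id = rgem.parent_id
    out.D = rgem.D
    out.conditions = rgem.conditions
    out.pruned = []

    if prune_blocked:
        from .lp import flux_ranges

        ranges = flux_ranges(out)
        blocked = [
            rid for rid, (lo, hi) in ranges.items()
            if abs(lo) < 1e-9 and abs(hi) < 1e-9
            and rid not in (out.biomass_id, out.atpm_id)
        ]
        for rid in blocked:
            del out.reactions[rid]
            out.provenance[rid] = out.provenance.get(rid, "") + ";pruned-blocked"
        out.pruned = sorted(blocked)
    return out


def _check_orphan_bbbs(rgem: ReducedModel) -> None:
    if not rgem.biomass_id:
        return
    biomass = rgem.reactions[rgem.biomass_id]
    orphans = []
    for mid, coef in biomass.stoich.items():
        if coef >= 0:
            continue
        producible = any(
            (r.stoich.get(mid, 0) > 0 and r.ub > 0)
            or (r.stoich.get(mid, 0) < 0 and r.lb < 0)
            for r in rgem.reactions.values()
            if r.id != rgem.biomass_id and mid in r.stoich
        )
        if not producible:
            orphans.append(mid)
    if orphans:
        raise IntegrityError(
            f"biomass building blocks with no producing route in the reduced "
            f"model: {sorted(orphans)}"
        )


def extract_core_model(model: Model, core: CoreNetwork) -> Model:
    """The bare core network as a standalone model (no lumps, no biomass)."""
    met_ids = set()
    for rid in core.reactions:
        met_ids |= model.reactions[rid].metabolite_ids
    sub = Model(id=f"{model.id}_core_D{core.D}")
    for mid in sorted(met_ids):
        src = model.metabolites[mid]
        sub.add_metabolite(
            Metabolite(src.id, src.name, src.compartment,
                       dict(src.formula) if src.formula else None, src.charge)
        )
    for rid in sorted(core.reactions):
        sub.add_reaction(model.reactions[rid].copy())
    return sub
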