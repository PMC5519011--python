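"""Consistency checks between a parent model and its reduction.

Three checks, mirroring how reduced models are accepted in practice:
FBA growth on a panel of carbon sources, flux-variability range containment
on the common reactions, and single-gene essentiality agreement on the
shared genes.  Discrepancies are classified and reported, never hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .errors import InfeasibleError, IntegrityError
from .lp import fba as _fba_lp
from .lp import flux_ranges
from .model import MediumSpec, Model, apply_medium

#: a gene is essential when growth drops below this fraction of wild type
ESSENTIALITY_THRESHOLD = 1e-2
#: growth rates within this absolute tolerance (1/hr) count as equal
GROWTH_TOL = 5e-3


def fba(
    model: Model,
    medium: Optional[MediumSpec] = None,
    objective_id: Optional[str] = None,
) -> Tuple[float, Dict[str, float]]:
    """FBA optimum of the (biomass) objective under a medium."""
    m = apply_medium(model, medium) if medium is not None else model
    return _fba_lp(m, objective_id)


def fva(
    model: Model,
    medium: Optional[MediumSpec] = None,
    fraction_of_optimum: float = 0.0,
    reactions: Optional[Iterable[str]] = None,
    fix_uptake: bool = True,
) -> pd.DataFrame:
    """Flux variability under a medium, substrate uptake fixed by default.

    Fixing the carbon uptake keeps every carbon-carrying flux within
    uptake x (carbon atoms of the substrate), which is what makes parent
    and reduced ranges comparable.
    """
    m = apply_medium(model, medium) if medium is not None else model
    extra = {}
    if fix_uptake and medium is not None:
        for ex in medium.carbon_sources:
            lb, _ = medium.uptakes[ex]
            if math.isfinite(lb):
                extra[ex] = (lb, lb)
    ranges = flux_ranges(
        m, reaction_ids=reactions, fraction_of_optimum=fraction_of_optimum,
        extra_bounds=extra or None,
    )
    return pd.DataFrame(
        [{"reaction": rid, "lb": lo, "ub": hi} for rid, (lo, hi) in ranges.items()]
    ).set_index("reaction")


def single_gene_deletions(
    model: Model,
    medium: Optional[MediumSpec] = None,
    essentiality_threshold: float = ESSENTIALITY_THRESHOLD,
) -> pd.DataFrame:
    """Knock out each gene, disable reactions whose GPR goes false, re-FBA.

    Returns a frame indexed by gene with columns growth and essential.
    """
    m = apply_medium(model, medium) if medium is not None else model
    mu_wt, _ = _fba_lp(m)
    rows = []
    gene_rxns: Dict[str, List[str]] = {}
    for r in m.reactions.values():
        for g in r.gpr.genes:
            gene_rxns.setdefault(g, []).append(r.id)
    for gene in sorted(m.genes):
        deleted = {gene}
        off = {
            rid: (0.0, 0.0)
            for rid in gene_rxns.get(gene, [])
            if not m.reactions[rid].gpr.evaluate(deleted)
        }
        if not off:
            mu = mu_wt
        else:
            try:
                mu, _ = _fba_lp(m, extra_bounds=off)
            except InfeasibleError:
                mu = 0.0
        rows.append(
            {
                "gene": gene,
                "growth": mu,
                "essential": bool(mu < essentiality_threshold * mu_wt),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "growth", "essential"]).set_index("gene")


@dataclass
class ConsistencyReport:
    """Parent-vs-reduced comparison tables with classified discrepancies."""

    growth: pd.DataFrame
    fva: pd.DataFrame
    essentiality: pd.DataFrame
    discrepancies: Dict[str, List[str]] = field(default_factory=dict)
    growth_tol: float = GROWTH_TOL

    @property
    def passed(self) -> bool:
        return not self.discrepancies.get("growth_mismatch") and not \
            self.discrepancies.get("fva_containment_violation")

    def to_json_dict(self) -> dict:
        return {
            "growth": self.growth.reset_index().to_dict(orient="records"),
            "fva": self.fva.reset_index().to_dict(orient="records"),
            "essentiality": self.essentiality.reset_index().to_dict(orient="records"),
            "discrepancies": self.discrepancies,
            "passed": self.passed,
        }


def compare_models(
    gem: Model,
    rgem: Model,
    medium: MediumSpec,
    carbon_sources: Optional[Sequence[Tuple[str, str]]] = None,
    essentiality_threshold: float = ESSENTIALITY_THRESHOLD,
    growth_tol: float = GROWTH_TOL,
    fva_fraction: float = 0.0,
    containment_tol: float = 1e-6,
) -> ConsistencyReport:
    """Full consistency report between a model and its reduction.

    ``carbon_sources`` is a list of (label, exchange id); each swaps the
    medium's carbon source at the same uptake rate.  Raises IntegrityError
    when the models share no reactions.
    """
    common = sorted(set(gem.reactions) & set(rgem.reactions))
    if not common:
        raise IntegrityError("models share no reactions; nothing to compare")
    shared_genes = sorted(gem.genes & rgem.genes)
    disc: Dict[str, List[str]] = {
        "growth_mismatch": [],
        "essentiality_conflict": [],
        "directionality_flip": [],
        "range_shrink": [],
        "fva_containment_violation": [],
    }

    # -- growth on the carbon source panel ------------------------------
    panel: List[Tuple[str, MediumSpec]] = [("base", medium)]
    rate = abs(min(
        (medium.uptakes[ex][0] for ex in medium.carbon_sources
         if ex in medium.uptakes), default=-10.0,
    ))
    for label, ex in carbon_sources or []:
        panel.append((label, medium.with_carbon_source(ex, rate)))
    growth_rows = []
    for label, med in panel:
        mus = {}
        for tag, mdl in (("gem", gem), ("rgem", rgem)):
            try:
                mu, _ = fba(mdl, med)
            except InfeasibleError:
                mu = 0.0
            mus[tag] = mu
        growth_rows.append({"carbon_source": label, **mus})
        if abs(mus["gem"] - mus["rgem"]) > growth_tol:
            disc["growth_mismatch"].append(label)
    growth = pd.DataFrame(
        growth_rows, columns=["carbon_source", "gem", "rgem"]
    ).set_index("carbon_source")

    # -- FVA containment on common reactions ----------------------------
    fva_gem = fva(gem, medium, fva_fraction, reactions=common)
    fva_rgem = fva(rgem, medium, fva_fraction, reactions=common)
    fva_table = pd.DataFrame(
        {
            "gem_lb": fva_gem["lb"],
            "gem_ub": fva_gem["ub"],
            "rgem_lb": fva_rgem["lb"],
            "rgem_ub": fva_rgem["ub"],
        }
    )
    for rid, row in fva_table.iterrows():
        if (row.rgem_lb < row.gem_lb - containment_tol
                or row.rgem_ub > row.gem_ub + containment_tol):
            disc["fva_containment_violation"].append(rid)
        shrunk = (row.rgem_lb > row.gem_lb + containment_tol
                  or row.rgem_ub < row.gem_ub - containment_tol)
        if shrunk:
            disc["range_shrink"].append(rid)
            gem_bidir = row.gem_lb < -containment_tol < containment_tol < row.gem_ub
            rgem_onedir = not (
                row.rgem_lb < -containment_tol < containment_tol < row.rgem_ub
            )
            if gem_bidir and rgem_onedir:
                disc["directionality_flip"].append(rid)

    # -- essentiality on shared genes ------------------------------------
    ess_gem = single_gene_deletions(gem, medium, essentiality_threshold)
    ess_rgem = single_gene_deletions(rgem, medium, essentiality_threshold)
    ess = pd.DataFrame(
        {
            "gem": ess_gem.loc[shared_genes, "essential"],
            "rgem": ess_rgem.loc[shared_genes, "essential"],
        }
    )
    disc["essentiality_conflict"] = sorted(ess.index[ess.gem != ess.rgem])

    return ConsistencyReport(
        growth=growth,
        fva=fva_table,
        essentiality=ess,
        discrepancies=disc,
        growth_tol=growth_tol,
    )
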