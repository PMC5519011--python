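# Methods

This note records the modelling assumptions, parameter semantics, numerical
choices and known limitations of `gemreduce`. It documents how results are
computed; every number it mentions is produced by the test suite or by
`scripts/acceptance.py` at run time.

## Model representation

A model is a stoichiometric network: metabolites with compartment, elemental
formula (Hill-notation map) and charge; reactions with a sparse coefficient
map (negative = consumed), flux bounds in mmol/gDWhr, a subsystem label and
a GPR rule. Exchange reactions follow the single-metabolite convention with
no explicit boundary species: negative flux is uptake, positive is
secretion. Unlabelled reactions get the subsystem `Unassigned`. An empty GPR
means "always catalysable" — the conservative choice for essentiality, since
missing gene data must not create spurious knockout effects.

Two dialects are supported: SBML Level 3 + FBC (through cobrapy/libsbml;
subsystem labels travel as SBML groups, with notes-style annotation as
fallback) and a JSON dialect that mirrors the in-memory schema. Media are
TSVs of `exchange_id, lb, ub[, role]`; cofactor classes are TSVs of
`id, class ∈ {cofactor, small, inorganic}`. Applying a medium sets the listed
exchange bounds and closes all unlisted uptakes while leaving secretion open.

Elemental imbalance of any reaction is computable and *reported*, never
silently repaired.

## Core-network expansion

**Graph.** The search graph is bipartite and directed: arcs run
substrate → reaction → product in every direction the bounds allow
(lb < 0 adds the reverse orientation). All members of the cofactor ∪ small ∪
inorganic union are absent from the graph, so they can never serve as path
endpoints or intermediates; reactions whose non-excluded participant set is
empty have no node at all (they can still join the core as transfer
reactions).

**Path semantics.** Paths are simple — no repeated node of either kind
within one path. Endpoints of a pair search are the *non-shared* metabolites
of the two subsystems; intermediates are excluded from the two endpoint
subsystems only (they may belong to any third subsystem), and path reactions
are excluded from the two endpoint subsystems' reaction sets only. Both
traversal directions are enumerated, so the pair relation is symmetric in
argument order. Degree-1 paths have no intermediates by construction. The
core is cumulative over d = 1..D, which makes core membership monotone
non-decreasing in D and in the extracellular slack n (property-tested).

**Subsystem resolution.** Pool augmentation pulls every reaction touching a
listed pool metabolite (e.g. a quinone/quinol pool) into the subsystem
regardless of its original label. Subsystem metabolite sets are the
non-excluded participants of the subsystem's reactions; metabolites in
different compartments are distinct nodes and transporters are ordinary
reactions.

**Transfer reactions.** Two sweeps: before the graph search, any non-exchange
reaction outside all selected subsystems whose non-excluded participants fit
inside a single subsystem's metabolite set joins that subsystem
(`RT-initial`); after the search, any remaining non-exchange reaction whose
participants are all core metabolites or excluded cofactors joins the core
(`RT-final` — this is what captures kinases, phosphatases and the ATP
maintenance reaction). The path searches run against the *pre-expansion*
subsystem sets, so a mislabelled interconversion can be captured both as a
degree-1 intra-connection and as a transfer reaction and then carries both
provenance tags. Exchange reactions are deliberately left to the
medium/extracellular machinery rather than either sweep.

**Extracellular attachment.** Each extracellular metabolite is attached to
each subsystem along all connecting paths of length ≤ L_min + n, where L_min
is its shortest connection in either direction and n is a user slack
(default 0). The shortest-path probe is capped at depth 8; metabolites with
no route within the cap are reported as unconnected, with a warning, and the
run continues.

**Determinism.** No randomness anywhere in expansion; set outputs are
reported in lexicographic order, so reports are bit-reproducible.

## Lumped biosynthesis

**Decomposition.** One demand per biomass *substrate*; product-side species
of the biomass reaction are not building blocks. Each BBB gets a sink
consuming only it, with lower bound n_j · μ_max, where μ_max is the FBA
biomass optimum under the lumping medium and n_j the biomass coefficient.

**MILP.** Over the medium-constrained model with the biomass reaction fixed
to zero and the maintenance bound preserved: per reaction F, B ≥ 0 with
v = F − B; per non-core reaction a binary z with F + B + C·z ≤ C; mass
balance S·v = 0; objective max Σz. Maximizing the switched-off count is the
same as minimizing the active non-core count, but is implemented as stated
so the integer-cut form (Σ_{k∈S_min} z_k ≥ 1 per found subnetwork) composes
directly. Non-core means: not in the core reaction set, excluding the
declared medium's exchanges, the biomass and maintenance reactions, and the
created sinks — the MILP penalizes metabolic steps, not environment
exchange. Enumeration stops when the subnetwork size exceeds S_min + p
(margin p, default 0), the MILP goes infeasible, or the alternatives cap
(default 50) is reached. An infeasible first solve marks the BBB
unreachable under that medium — the signal that lumping must be re-run
under a different condition (e.g. anaerobically). Solved with HiGHS via
scipy; the optimum Σz (hence S_min) is solver-independent even where the
witness subnetwork is not.

**Numerics.** C defaults to carbon-uptake flux × carbon atoms of the
substrate (60 for glucose at 10 mmol/gDWhr; fallback 100 when the substrate
formula is unknown); infinite bounds are capped at 1000 inside the MILP, the
standard GEM convention. Subnetwork membership requires z = 0 *and*
|v| > 10⁻⁹·C, since MILP solvers return ε-fluxes; a switched-on reaction
carrying no flux is not part of the subnetwork.

**Lump construction.** A deterministic flux witness is obtained by
minimizing total |v| over core + subnetwork with the sink fixed at the
demand; the lump is Σ_k (v_k / v_sink) × stoich_k over the subnetwork
reactions, normalized to +1 BBB. Coefficients are rationalized by
continued-fraction reconstruction with denominator cap 10⁶ so canonical
stoichiometries are reproducible for deduplication. Any non-core,
non-cofactor metabolite with a non-cancelling net coefficient raises a
balance error naming it. The lump GPR is the conjunction of the member
reactions' GPRs; lumps with identical canonical stoichiometry merge, with
GPRs OR-combined across merged sources. Per-BBB solves are independent of
each other and of execution order.

**Not applied:** thermodynamic feasibility screening of subnetworks. Every
lumping result carries the note that lumping ran FBA-only.

## Reduced model and validation

The reduced model keeps the original biomass reaction (BBBs now supplied by
core + lumps), copies the maintenance lower bound, and retains every parent
exchange whose metabolite survives, under the medium's bounds. A biomass
building block with no producing route raises an assembly error listing the
orphans. Pruning of reactions that cannot carry flux under the medium is
off by default and recorded in provenance when on. All lumps from all
conditions can be included so one reduced model serves several oxygen
regimes; lumping is not automatically re-run when the medium changes — a
medium under which the reduction cannot grow is reported, and the user
re-lumps.

Validation: (1) FBA growth on a panel of carbon sources, equal within
5×10⁻³ 1/hr (three printed decimals); (2) FVA with fraction-of-optimum 0 and
the substrate uptake fixed, which bounds every carbon-carrying flux by
uptake × substrate carbon count, checking that each common reaction's range
in the reduction is contained in the parent's; (3) single-gene deletions
with essentiality threshold μ < 10⁻² μ_max (configurable; no canonical value
exists). Essentiality conflicts are expected by construction — conjunctive
lump GPRs couple genes whose alternative routes were lumped away — so they
are classified and reported, never asserted away.

## Synthetic fixtures and oracles

The generator plants: labelled linear chains as subsystems; an ATP/ADP/Pi
and NAD/NADH cofactor pool threaded through random chain steps with a
closing recharge reaction; a one-carbon substrate with exchange + transport;
per-subsystem secretion; inter-subsystem bridges of chosen lengths;
intra-subsystem detours (length 1 = a mislabelled direct interconversion);
and biomass building blocks with a planted minimal route plus optionally a
longer or equal-length decoy. All enzymatic reactions balance in C/P/N, so
lump balance audits are meaningful. Because every reaction is carbon
balanced, the growth optimum is exactly uptake / Σ(biomass coefficients),
giving a hand-computable μ_max even when random extra wiring is added for
topological variety.

What the fixtures do *not* emulate: realistic network statistics, genuine
thermodynamics (the ATP recharge is free), multi-carbon stoichiometry, or
compartment-specific proton/charge bookkeeping. Passing tests demonstrate
algorithmic correctness against exhaustive oracles, not biological fidelity
on real reconstructions.

Oracles: a brute-force simple-path enumerator working directly off
coefficient signs and bounds (guard: ≤ 40 reactions), and a brute-force
subnetwork search testing every candidate subset by LP feasibility of the
sink demand (guard: ≤ 12 non-core reactions). Property tests compare the
production graph search and MILP against these on 20 seeded topologies
each; problem sizes were chosen so the whole suite runs desk-scale in
seconds to a few minutes.

## Known limitations

- Thermodynamic analyses (TFA/TVA/CVA) are out of scope; only FBA-based
  quantities are computed.
- The choice of cofactor/small-metabolite list materially changes connector
  counts on real GEMs; the package requires it as explicit input and never
  infers it.
- Published-model reproduction needs the iJO1366 SBML supplied by the user
  (`scratch/iJO1366.xml`); reported counts may also shift by a few reactions
  between model distributions.
- The extracellular shortest-path probe is depth-capped (8); deeply buried
  extracellular metabolites are reported unconnected rather than searched
  exhaustively.
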