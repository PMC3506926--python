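# Methods

`heteropath` implements an in silico platform for heterologous pathway
design: given a host genome-scale metabolic model and a database of known
enzymatic reactions in KEGG compound space, it finds the reactions that
must be added to the host so that a nonnative target metabolite becomes
connected to the network, and then judges whether the augmented network can
actually carry flux to that target — both when production is the objective
and when it must ride along with maximal growth.

## Network expansion

The host contributes a native compound set M0 (the KEGG IDs of its mapped
metabolites, collapsed over compartments) and a native reaction-signature
set R0. Candidate database reactions whose canonical stoichiometric
signature already occurs in R0 are never heterologous additions and are
excluded up front. Expansion proceeds in synchronous rounds: at round *i*
every candidate is tried in both directions (all database reactions are
treated as reversible — directionality annotations are too sparse to trust,
and a wrongly assumed irreversibility silently loses pathways; plausibility
of the predicted direction is left to downstream physiological judgement).
A direction fires when its substrate requirement is met by the accumulated
compound set; a firing reaction is admitted to layer Ri if it is new by
signature and produces at least one unconnected compound, and those
compounds form Mi. Rounds repeat until no new compound appears. Layers are
disjoint by construction and the procedure terminates after at most as many
rounds as there are compounds.

Two firing rules are provided:

* `all_substrates` (default): every substrate of the firing direction must
  be available. This is the stoichiometrically meaningful rule — a reaction
  cannot run without all of its inputs — and it reproduces every worked
  example in the fixture suite.
* `any_substrate`: one available substrate suffices. This permissive
  reachability variant connects a superset of compounds, never later (a
  tested invariant). Under this rule a reaction admitted in one direction
  can become fireable in the other direction at a later round; its products
  still connect then, while the reaction keeps its original layer.

For each connected compound a producer map records the (reaction,
direction, round) that first produced it; ties within a round are broken by
lexicographically smallest reaction ID, purely for determinism.
Backtracing a target walks this map: the target's producer is included,
then recursively the producer of every nonnative substrate of every
included reaction. The result is one deterministic pathway, minimal in
connection depth. It is *not* guaranteed to be minimum-cardinality over all
conceivable reaction subsets — no mixed-integer search is performed — and
sufficiency (replaying the returned reactions from M0 produces the target)
is verified by simulation in the test suite.

## Flux balance analysis

The augmented network is assembled as a sparse stoichiometric matrix:
host reactions keep their bounds; heterologous reactions are placed in the
cytosol (the model states no inter-compartment transport rule for added
enzymes, so a cytosolic placement is the least-assuming choice) with
symmetric bounds ±1000 mmol/gDW/h; a demand column exports the target.
Compounds unknown to the host get fresh balance rows. Under the
steady-state constraint S·v = 0 and the box bounds, objectives are solved
with the HiGHS simplex/IPM backend behind `scipy.optimize.linprog`.

The medium is an exchange-bound policy: one carbon source (glucose,
C00031, default uptake cap 10 mmol/gDW/h), an oxygen cap implementing the
aeration level (default 2 mmol/gDW/h, a micro-aerobic setting; 0 is
anaerobic), free transport for CO2, H2O, sulfate/sulfite, ammonia, proton
and phosphate, and closed uptake (open secretion) for everything else.
The uptake and oxygen numbers are package defaults — the modelled
condition is "sole glucose source, micro-aerobic", and both caps are
configurable.

* **Producibility**: a target is producible when its maximum demand flux
  exceeds the zero-flux tolerance (1e−6); a maximum of numerical zero
  classifies it non-producible under the medium.
* **Growth-coupled production**: biomass flux is maximized first; because
  that optimum is usually degenerate in the target direction, the biomass
  column is then pinned at its optimum and the demand flux re-maximized,
  yielding a unique production flux at maximal growth. The pin is exact;
  only if the solver rejects the degenerate equality is it relaxed to a
  relative 1e−6 band. Stage-2 biomass equals the stage-1 optimum within
  that tolerance on every fixture (a tested contract).
* **Yield**: 100 × (demand flux)/(carbon uptake flux), mol target per mol
  carbon source. A target counts as *produced* at a threshold of 1 % by
  default. Mol/mol is the simplest defensible basis; nothing downstream
  depends on the basis choice and the threshold is a parameter.

## Screening and enrichment

`screen` runs expansion once per host, backtraces every connected
compound, and solves both FBA questions per target, emitting deterministic,
byte-stable TSV reports ordered by compound ID. Production mechanisms are
reported descriptively — the net O2 production and net NADH oxidation of
the heterologous subnetwork at the coupled optimum — because the two
known coupling routes (O2 released by the added reactions feeding
respiration; NADH oxidation relieving an NAD+-regeneration-limited
glycolysis) are recognizable from those two numbers without committing to
a hard classification rule.

`category_enrichment` compares hosts within functional categories using
Pearson's chi-square (no continuity correction) on a hosts ×
{produced, not-produced} contingency table, with (rows−1)(cols−1) degrees
of freedom. Categories with an all-zero margin have undefined expected
counts and are excluded. Significance uses a raw alpha (default 0.001)
with no multiple-testing correction, matching the screening tradition this
follows; a one-vs-rest 2×2 design per host is available as an option, and
both designs are labelled in the output.

## Synthetic fixtures: what they emulate, what they do not

The fixture module generates every test input programmatically and writes
it through the package's own on-disk dialects, so fixtures double as format
coverage.

The worked-example micro-hosts pair the literature equations for one
target (pentane-2,4-dione in two host variants, vanillin,
(R)-propane-1,2-diol, 2-propyn-1-al, adipate semialdehyde,
1,3-propanediol) with a minimal backbone: lumped glycolysis
(glucose + 2 NAD+ + 2 ADP + 2 Pi → 2 precursor + 2 NADH + 2 ATP),
respiration that regenerates NAD+ only, a non-growth ATP hydrolysis
column (without it, ATP/ADP cycling couples biomass 1:1 to glycolytic flux
and starves every precursor drain), a biomass drain on precursor + ATP,
and exactly the native precursor-synthesis reactions each case requires.
Making respiration ATP-free keeps the column count small and makes
micro-aerobic growth NAD+-regeneration-limited — precisely the condition
under which NADH-oxidizing heterologous reactions become growth-coupled.
These hosts reproduce the literature pathway *lengths* and the qualitative
coupling mechanisms; their absolute fluxes, yields and growth rates are
properties of the toy backbone, not of any real organism, and carbon is
not elementally balanced in the lumped columns. Nothing here emulates
genome-scale network density, compartmental transport limits, or
KEGG-scale database redundancy, so passing tests say nothing quantitative
about real hosts.

Analytic LP toys provide closed-form anchors: a linear chain (maximum
demand = uptake bound, 100 % yield), a 2:1 branch (half the uptake, 50 %),
a strict 1:1 biomass-competition toy (target flux 0 at the biomass
optimum), and an NAD-coupling toy whose optima (biomass 4, target 16 at
uptake 10 and O2 cap 2) follow from the NADH and precursor balances in
two lines of algebra.

Random expansion instances (≤ 30 compounds, ≤ 25 reactions, seeded) carry
layer labels from an independently coded brute-force BFS oracle; the
expansion must reproduce them exactly under both firing rules.

Compound identities in fixtures use well-established KEGG IDs for
cofactors, central metabolites and targets with unambiguous IDs; other
compounds named in prose become deterministic synthetic IDs in the
reserved `X__` namespace. Identity accuracy affects no computed quantity.

## Numerical choices and degenerate inputs

* LP backend HiGHS; solver statuses (infeasible/unbounded) are returned,
  never raised. Steady-state residual ‖S·v‖∞ ≤ 1e−6 is asserted on every
  optimum in the tests.
* Zero-flux tolerance 1e−6; biomass-fix relative tolerance 1e−6;
  closed-form toy assertions at 1e−8.
* Signature coefficients are rounded to 9 decimals before comparison;
  compounds appearing on both sides of an equation cancel their common
  part during canonicalization.
* Reactions with symbolic/polymer coefficients ("n", "(n+1)") have no
  defined stoichiometry for FBA and are excluded with a logged reason —
  a choice, since generic-reaction handling is genuinely open; an empty
  database yields a terminated, zero-layer expansion; a native target
  backtraces to an empty pathway; an unconnected target is a distinct
  status, not an error.
* Duplicate reaction signatures in a database collapse to the
  lexicographically smallest ID, keeping the union of EC/gene/organism
  annotations, so heterologous additions are never double-counted.

## Known limitations

* One pathway per target; no enumeration of alternatives and no
  minimum-cardinality guarantee (depth-minimal only).
* Universal reversibility can propose thermodynamically implausible
  directions by design; filtering is deferred to the user.
* Heterologous reactions ignore compartment assignment beyond the cytosol
  convention, and transport capability between compartments is not
  modelled.
* The chi-square comparison assumes independent category membership
  counts; heavily overlapping categories share targets.
* Km annotation picks the minimum over EC-matched rows (wildcards match on
  defined digits); it is a source-organism suggestion, not a kinetic model.
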