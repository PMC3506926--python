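# heteropath

**Heterologous pathway design by metabolic network expansion and flux
balance analysis.**

Metabolic engineers produce nonnative compounds — diols, aromatics,
polymer precursors — by grafting foreign enzymatic reactions onto a
well-characterized host such as *Escherichia coli*, *Corynebacterium
glutamicum* or *Saccharomyces cerevisiae*. Choosing *which* reactions to
graft is hard: the candidate space is every known enzymatic reaction, and
a pathway that connects on paper may carry no flux once the host's
cofactor and growth demands are respected. `heteropath` answers both
questions for any host model and reaction database:

1. **Connection** — iterative network expansion. Starting from the host's
   native metabolite set M0 and reaction set R0, round *i* admits the
   database reactions (treated as reversible, fired in either direction)
   whose substrates are already reachable and which produce at least one
   new compound; these form Ri and their new products Mi. The rounds
   repeat until nothing more connects. Backtracing the producer map then
   yields, for any connected target, the depth-minimal set of heterologous
   reactions with firing directions.
2. **Feasibility** — flux balance analysis on the augmented network: with
   stoichiometric matrix S and flux vector v, solve
   max c·v subject to S·v = 0 and bounds, under a defined medium
   (sole glucose carbon source, micro-aerobic oxygen cap). A target is
   *producible* if its maximum demand flux is nonzero, and *produced under
   growth* if, after maximizing biomass and re-maximizing the target at
   the fixed biomass optimum (the degenerate-optimum resolution), its
   molar yield on glucose reaches a threshold (default 1 %).

A screening layer runs this per-target pipeline genome-wide and compares
hosts by functional category with Pearson's chi-square; a reaction-table
layer parses KEGG-ligand-style equations, deduplicates them by canonical
stoichiometric signature, and annotates each reaction with the
minimum-Km ortholog organism from a Michaelis-constant table.

## Worked example

```python
from heteropath import backtrace, expand, iteration_curve, native_sets
from heteropath.fixtures import table2_fixture

case = table2_fixture("vanillin")          # micro-host + 4 candidate reactions
m0, r0 = native_sets(case.host)
result = expand(m0, r0, case.db)
for it, n_new, cum in iteration_curve(result):
    print(it, n_new, cum)
pathway = backtrace(result, case.target)
print(pathway.connection_iteration, pathway.n_reactions)
```

prints

```
1 2 2
2 1 3
3 1 4
3 4
```

— two compounds connect in round 1 (formaldehyde and
3,4-dihydroxybenzoate, both reachable from the host's
3-dehydroshikimate/formate pool), vanillate in round 2, vanillin in
round 3, and the backtraced pathway needs all **4** heterologous
reactions. Feasibility of the single-reaction pentane-2,4-dione case:

```python
from heteropath import (biomass_coupled_production, build_flux_model,
                        producibility, yield_percent)
case = table2_fixture("pentanedione_ecoli")
m0, r0 = native_sets(case.host)
pw = backtrace(expand(m0, r0, case.db), case.target)
fm = build_flux_model(case.host, pw, case.db, case.medium, case.target)
print(producibility(fm))                       # (True, 10.0)
s1, s2 = biomass_coupled_production(fm)
print(s1.objective_value, s2.objective_value)  # 4.0 8.0
print(yield_percent(s2, fm))                   # (80.0, True)
```

The target is producible (maximum demand flux 10 mmol/gDW/h), and at the
biomass optimum of 4 it still carries 8 mmol/gDW/h — an 80 % molar yield
on glucose, far above the 1 % "produced" threshold — because the added
reaction runs in reverse and releases O2 that feeds respiration
(growth-coupled production). The `examples/` scripts walk through each
capability with commentary, and a thin CLI (`heteropath expand|backtrace|
fba|screen|enrich|fixtures`) exposes the same pipeline on files.

## Layout

```
src/heteropath/
  reaction_db.py   equation parsing, signatures, dedup, Km annotation
  host_model.py    model TSV/SBML readers, native sets (M0, R0)
  expansion.py     layered expansion, backtrace, iteration curves
  fba.py           flux model assembly, LP objectives, yields
  screening.py     per-host screening, reports, chi-square enrichment
  fixtures.py      micro-hosts, LP toys, random instances + BFS oracle
  cli.py           command-line entry points
docs/methods.md    model assumptions, parameters, numerical choices
examples/          one narrative script per capability
```
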