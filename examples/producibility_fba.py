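"""Evaluate pathway feasibility with flux balance analysis.

Takes the single-reaction pentane-2,4-dione pathway, grafts it onto the
micro-host, and asks two questions: can the network produce the target at
all (maximum demand flux), and does it still produce the target when
growth is maximized first (lexicographic biomass-then-target optimization,
micro-aerobic glucose medium)?
"""

from heteropath import (
    backtrace,
    biomass_coupled_production,
    build_flux_model,
    expand,
    native_sets,
    producibility,
    yield_percent,
)
from heteropath.fixtures import table2_fixture

case = table2_fixture("pentanedione_ecoli")
m0, r0 = native_sets(case.host)
pathway = backtrace(expand(m0, r0, case.db), case.target)
fm = build_flux_model(case.host, pathway, case.db, case.medium, case.target)

producible, max_flux = producibility(fm)
print(f"max target production flux : {max_flux:.3f} mmol/gDW/h "
      f"({'producible' if producible else 'non-producible'})")

stage1, stage2 = biomass_coupled_production(fm)
pct, produced = yield_percent(stage2, fm, threshold=1.0)
print(f"biomass optimum            : {stage1.objective_value:.3f} /h-equivalent")
print(f"target flux at that optimum: {stage2.objective_value:.3f} mmol/gDW/h")
print(f"molar yield on glucose     : {pct:.1f} %  "
      f"({'above' if produced else 'below'} the 1% threshold)")

# The dione-cleaving reaction runs in reverse (acetate + methylglyoxal ->
# target + O2); the O2 byproduct feeds respiration, so production is
# growth-coupled: target flux stays positive even at the biomass optimum.
o2_flux = stage2.fluxes["HET_PD1"]
print(f"heterologous reaction flux : {o2_flux:.3f} (negative = reverse firing)")
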