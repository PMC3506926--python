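"""Connect vanillin to a minimal host by network expansion, then backtrace
the heterologous pathway.

The host natively makes 3-dehydroshikimate and formate; the candidate
database holds four vanillin-related enzyme reactions.  The expansion adds
reactions layer by layer until nothing more connects, and the backtrace
pulls out exactly the reactions needed for the target.
"""

from heteropath import backtrace, expand, iteration_curve, native_sets
from heteropath.fixtures import table2_fixture

case = table2_fixture("vanillin")
m0, r0 = native_sets(case.host)
result = expand(m0, r0, case.db, firing_rule="all_substrates")

print("iteration  new  cumulative")
for it, n_new, cum in iteration_curve(result):
    print(f"{it:>9}  {n_new:>3}  {cum:>10}")

pathway = backtrace(result, case.target)
print(f"\ntarget {case.target} connects at iteration {pathway.connection_iteration}")
print(f"heterologous reactions required: {pathway.n_reactions}")
for rid, direction in pathway.reactions:
    rxn = case.db.reactions[rid]
    ec = ",".join(rxn.ec_numbers)
    print(f"  {rid} ({ec}) fired {direction}")

# Four reactions, target reached in three layers: two enzymes fire in the
# first round (both their substrate sets are native), vanillate appears in
# the second, vanillin in the third.
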