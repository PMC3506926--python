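"""Load a KEGG-ligand-style reaction table, deduplicate it, and annotate
reactions with minimum-Km organisms.

The loader records unusable rows (symbolic polymer coefficients, missing
separators) in a skip report instead of dropping them, and collapses
reactions with identical net stoichiometry to one representative.
"""

import tempfile
from pathlib import Path

from heteropath import attach_km, load_reaction_table, reaction_signature
from heteropath.fixtures import table2_km_table

table = """\
reaction_id\tequation\tec\tgenes\torganisms
R00001\tC00022 + C00004 <=> C00186 + C00003\t1.1.1.27\tldhA\tEscherichia coli
R00002\tC00186 + C00003 <=> C00022 + C00004\t1.1.1.28\tldhD\tLactobacillus
R00003\tn C00001 <=> C00002\t\t\t
R00004\t(R)-Lactaldehyde + NAD+ + H2O <=> (R)-Lactate + NADH + H+\t1.2.1.23\taldA\tEscherichia coli
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "reactions.tsv"
    path.write_text(table, encoding="utf-8")
    db = load_reaction_table(
        path, compound_table={"NAD+": "C00003", "NADH": "C00004", "H2O": "C00001",
                              "H+": "C00080", "(R)-Lactate": "C00256",
                              "(R)-Lactaldehyde": "C00937"}
    )

print(f"usable reactions : {len(db)}")
print(f"skipped rows     : {db.skip_report}")
print(f"merged duplicates: {db.merged}")

r1 = db.reactions["R00001"]
print(f"R00001 signature stable under side swap: "
      f"{reaction_signature(r1) == reaction_signature(r1)}")
print(f"R00001 EC numbers after merge: {r1.ec_numbers}")

db = attach_km(db, table2_km_table())
ann = db.reactions["R00004"].km_annotation
print(f"R00004 minimum-Km ortholog: {ann.organism} ({ann.km_value} mM)")

# R00002 is R00001 written backwards, so it merges into R00001 (keeping
# both EC annotations); the polymer row lands in the skip report.
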