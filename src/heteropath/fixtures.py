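"""Self-contained test inputs: micro-hosts, reaction sets, LP toys, and
seeded random expansion instances.

Everything here is synthetic, generated programmatically, and materialized
through the package's standard on-disk dialects before being loaded back
through the standard readers — so the fixtures double as format-coverage
tests.  The worked-example cases pair a minimal host (a lumped
glucose→biomass backbone with NAD(H)/ATP cycling plus exactly the native
precursors each case needs) with the literature equations for one target
compound, so that expansion, backtracing and flux balance analysis can be
exercised end to end at desk scale.

Compound identities: well-established KEGG IDs are used for cofactors,
central metabolites and the handful of targets with unambiguous IDs; every
other compound named in prose resolves to a deterministic synthetic ID in
the reserved ``X__`` namespace.
"""

from __future__ import annotations

import json
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fba import MediumSpec
from .host_model import HostModel, load_host_model
from .reaction_db import ReactionDatabase, load_reaction_table

__all__ = [
    "FixtureCase",
    "TABLE2_CASES",
    "table2_fixture",
    "table2_km_table",
    "random_instance",
    "bfs_layer_oracle",
    "analytic_fba_toys",
    "NAME_TO_KEGG",
]

#: Curated name→KEGG-ID table used when resolving equations printed as prose.
NAME_TO_KEGG: dict[str, str] = {
    "Oxygen": "C00007",
    "H2O": "C00001",
    "CO2": "C00011",
    "NAD+": "C00003",
    "NADH": "C00004",
    "NADP+": "C00006",
    "NADPH": "C00005",
    "H+": "C00080",
    "ATP": "C00002",
    "ADP": "C00008",
    "AMP": "C00020",
    "Diphosphate": "C00013",
    "Orthophosphate": "C00009",
    "CoA": "C00010",
    "FAD": "C00016",
    "FADH2": "C01352",
    "Acetate": "C00033",
    "Pyruvate": "C00022",
    "Methylglyoxal": "C00546",
    "Glycerone phosphate": "C00111",
    "Formate": "C00058",
    "Formaldehyde": "C00067",
    "Acetaldehyde": "C00084",
    "Acetyl-CoA": "C00024",
    "Succinyl-CoA": "C00091",
    "Glycerol": "C00116",
    "(R)-Lactate": "C00256",
    "(R)-Lactaldehyde": "C00937",
    "Vanillin": "C00755",
    "Propane-1,3-diol": "C02457",
    "(R)-Propane-1,2-diol": "C02912",
    "D-Glucose": "C00031",
}


@dataclass
class FixtureCase:
    """A named, reproducible test input.

    ``expected`` carries expected values, each entry a dict with a
    ``value`` and a ``tag`` recording how the value was obtained
    (trivial arithmetic, hand derivation, or a literature-reported count).
    """

    name: str
    host: HostModel
    db: ReactionDatabase
    target: str | None
    medium: MediumSpec
    expected: dict = field(default_factory=dict)
    workdir: Path | None = None


def _write_db(rows, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reaction_id\tequation\tec\tgenes\torganisms\n")
        for rid, eqn, ec, genes, orgs in rows:
            fh.write(f"{rid}\t{eqn}\t{ec}\t{genes}\t{orgs}\n")


def _write_host(mets, rxns, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# metabolites\nmodel_id\tcompartment\tkegg_id\n")
        for mid, comp, kegg in mets:
            fh.write(f"{mid}\t{comp}\t{kegg}\n")
        fh.write("# reactions\nid\tequation\tlb\tub\tis_biomass\tis_exchange\n")
        for rid, eqn, lb, ub, bm, ex in rxns:
            fh.write(f"{rid}\t{eqn}\t{lb}\t{ub}\t{bm}\t{ex}\n")


def _materialize(name, db_rows, met_rows, rxn_rows, workdir) -> tuple[HostModel, ReactionDatabase, Path]:
    if workdir is None:
        workdir = Path(tempfile.mkdtemp(prefix=f"heteropath_{name}_"))
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    db_path = workdir / f"{name}_reactions.tsv"
    host_path = workdir / f"{name}_host.tsv"
    _write_db(db_rows, db_path)
    _write_host(met_rows, rxn_rows, host_path)
    return load_host_model(host_path), load_reaction_table(db_path, NAME_TO_KEGG), workdir


# ---------------------------------------------------------------------------
# Worked-example micro-hosts
# ---------------------------------------------------------------------------

# Lumped glucose→biomass backbone shared by all worked-example hosts:
# glycolysis collapsed into one column producing precursor, NADH and ATP;
# respiration regenerates NAD+ only, so micro-aerobic growth is
# NAD+-regeneration-limited (the coupling mechanism of interest).
_BACKBONE_METS = [
    ("glc_e", "e", "C00031"), ("glc_c", "c", "C00031"),
    ("o2_e", "e", "C00007"), ("o2_c", "c", "C00007"),
    ("co2_e", "e", "C00011"), ("co2_c", "c", "C00011"),
    ("h2o_e", "e", "C00001"), ("h2o_c", "c", "C00001"),
    ("pi_e", "e", "C00009"), ("pi_c", "c", "C00009"),
    ("h_e", "e", "C00080"), ("h_c", "c", "C00080"),
    ("nad_c", "c", "C00003"), ("nadh_c", "c", "C00004"),
    ("atp_c", "c", "C00002"), ("adp_c", "c", "C00008"),
    ("prec_c", "c", "C00022"),
]

_BACKBONE_RXNS = [
    ("EX_glc", "glc_e <=>", -10, 1000, 0, 1),
    ("EX_o2", "o2_e <=>", -2, 1000, 0, 1),
    ("EX_co2", "co2_e <=>", -1000, 1000, 0, 1),
    ("EX_h2o", "h2o_e <=>", -1000, 1000, 0, 1),
    ("EX_pi", "pi_e <=>", -1000, 1000, 0, 1),
    ("EX_h", "h_e <=>", -1000, 1000, 0, 1),
    ("T_glc", "glc_e <=> glc_c", -1000, 1000, 0, 0),
    ("T_o2", "o2_e <=> o2_c", -1000, 1000, 0, 0),
    ("T_co2", "co2_e <=> co2_c", -1000, 1000, 0, 0),
    ("T_h2o", "h2o_e <=> h2o_c", -1000, 1000, 0, 0),
    ("T_pi", "pi_e <=> pi_c", -1000, 1000, 0, 0),
    ("T_h", "h_e <=> h_c", -1000, 1000, 0, 0),
    ("GLYC", "glc_c + 2 nad_c + 2 adp_c + 2 pi_c <=> 2 prec_c + 2 nadh_c + 2 atp_c + 2 h_c", -1000, 1000, 0, 0),
    ("RESP", "2 nadh_c + o2_c + 2 h_c <=> 2 nad_c + 2 h2o_c", 0, 1000, 0, 0),
    # non-growth ATP hydrolysis; without it ATP/ADP cycling would couple
    # biomass 1:1 to glycolytic flux and starve every precursor drain
    ("ATPM", "atp_c + h2o_c <=> adp_c + pi_c", 0, 1000, 0, 0),
    ("BIOMASS", "prec_c + atp_c <=> adp_c + pi_c", 0, 1000, 1, 0),
]

# Per-case native extras: extra metabolites, extra native reactions,
# heterologous reaction rows (the printed equations), target compound name,
# and the literature-reported heterologous reaction count.
_TABLE2_SPEC: dict[str, dict] = {
    "pentanedione_ecoli": {
        "mets": [("ac_c", "c", "C00033"), ("mgx_c", "c", "C00546")],
        "rxns": [
            ("ACSYN", "prec_c + nad_c + h2o_c <=> ac_c + co2_c + nadh_c + h_c", -1000, 1000, 0, 0),
            ("MGXSYN", "glc_c <=> 2 mgx_c + 2 h2o_c", -1000, 1000, 0, 0),
        ],
        "db": [
            ("PD1", "Pentane-2,4-dione + Oxygen <=> Acetate + Methylglyoxal",
             "1.13.11.50", "dke1", "Acinetobacter johnsonii"),
        ],
        "target": "Pentane-2,4-dione",
        "n_reactions": 1,
    },
    "pentanedione_cglut": {
        "mets": [("ac_c", "c", "C00033"), ("dhap_c", "c", "C00111")],
        "rxns": [
            ("ACSYN", "prec_c + nad_c + h2o_c <=> ac_c + co2_c + nadh_c + h_c", -1000, 1000, 0, 0),
            ("DHAPSYN", "glc_c + 2 atp_c <=> 2 dhap_c + 2 adp_c", -1000, 1000, 0, 0),
        ],
        "db": [
            ("MGS", "Glycerone phosphate <=> Methylglyoxal + Orthophosphate",
             "4.2.3.3", "mgsA", "Escherichia coli"),
            ("PD1", "Pentane-2,4-dione + Oxygen <=> Acetate + Methylglyoxal",
             "1.13.11.50", "dke1", "Acinetobacter johnsonii"),
        ],
        "target": "Pentane-2,4-dione",
        "n_reactions": 2,
    },
    "vanillin": {
        "mets": [("dhs_c", "c", "X__3_dehydroshikimate"), ("for_c", "c", "C00058")],
        "rxns": [
            ("DHSSYN", "glc_c + nad_c <=> dhs_c + nadh_c + h_c", -1000, 1000, 0, 0),
            ("FORSYN", "co2_c + nadh_c + h_c <=> for_c + nad_c", -1000, 1000, 0, 0),
        ],
        "db": [
            ("VAN1", "Formaldehyde + NAD+ + H2O <=> Formate + NADH + H+",
             "1.2.1.46", "fdhA", "Pseudomonas putida"),
            ("VAN2", "3-Dehydroshikimate <=> 3,4-Dihydroxybenzoate + H2O",
             "4.2.1.118", "asbF", "Bacillus thuringiensis"),
            ("VAN3", "Vanillate + Oxygen + NADH + H+ <=> 3,4-Dihydroxybenzoate + NAD+ + H2O + Formaldehyde",
             "1.14.13.82", "vanAB", "Pseudomonas fluorescens"),
            ("VAN4", "Vanillate + NAD+ + H2O <=> Vanillin + Oxygen + NADH + H+",
             "1.2.3.9", "vaoA", "Penicillium simplicissimum"),
        ],
        "target": "Vanillin",
        "n_reactions": 4,
    },
    "propanediol_R12": {
        "mets": [("dlac_c", "c", "C00256")],
        "rxns": [
            ("DLACSYN", "prec_c + nadh_c + h_c <=> dlac_c + nad_c", -1000, 1000, 0, 0),
        ],
        "db": [
            ("PDA", "(R)-Lactaldehyde + NAD+ + H2O <=> (R)-Lactate + NADH + H+",
             "1.2.1.23", "aldA", "Escherichia coli"),
            ("PDB", "(R)-Propane-1,2-diol + NAD+ <=> (R)-Lactaldehyde + NADH + H+",
             "1.1.1.77", "fucO", "Escherichia coli"),
        ],
        "target": "(R)-Propane-1,2-diol",
        "n_reactions": 2,
    },
    "propynal": {
        "mets": [("acald_c", "c", "C00084")],
        "rxns": [
            ("ACALDSYN", "prec_c <=> acald_c + co2_c", -1000, 1000, 0, 0),
        ],
        "db": [
            ("PYN1", "3-Oxopropanoate <=> Acetaldehyde + CO2",
             "4.1.1.-", "", ""),
            ("PYN2", "3-Oxopropanoate <=> Propynoate + H2O",
             "4.2.1.27", "", ""),
            ("PYN3", "2-Propyn-1-al + NAD+ + H2O <=> Propynoate + NADH + H+",
             "1.2.1.3", "aldH", "Homo sapiens"),
        ],
        "target": "2-Propyn-1-al",
        "n_reactions": 3,
    },
    "adipate_semialdehyde": {
        "mets": [
            ("succoa_c", "c", "C00091"), ("accoa_c", "c", "C00024"),
            ("coa_c", "c", "C00010"), ("fad_c", "c", "C00016"),
            ("fadh2_c", "c", "C01352"), ("amp_c", "c", "C00020"),
            ("ppi_c", "c", "C00013"), ("nadp_c", "c", "C00006"),
            ("nadph_c", "c", "C00005"),
        ],
        "rxns": [
            ("PDH", "prec_c + coa_c + nad_c <=> accoa_c + co2_c + nadh_c + h_c", -1000, 1000, 0, 0),
            ("SUCSYN", "accoa_c + co2_c + nadh_c + h_c <=> succoa_c + nad_c", -1000, 1000, 0, 0),
            ("FADRED", "nadh_c + fad_c + h_c <=> nad_c + fadh2_c", -1000, 1000, 0, 0),
            ("FADOX", "2 fadh2_c + o2_c <=> 2 fad_c + 2 h2o_c", 0, 1000, 0, 0),
            ("THD", "nadh_c + nadp_c <=> nad_c + nadph_c", -1000, 1000, 0, 0),
            ("ADK", "atp_c + amp_c <=> 2 adp_c", -1000, 1000, 0, 0),
            ("PPA", "ppi_c + h2o_c <=> 2 pi_c", -1000, 1000, 0, 0),
            ("AMPSYN", "atp_c + h2o_c <=> amp_c + ppi_c", -1000, 1000, 0, 0),
        ],
        "db": [
            ("ADP1", "Succinyl-CoA + Acetyl-CoA <=> CoA + 3-Oxoadipyl-CoA",
             "2.3.1.174", "paaJ", "Escherichia coli"),
            ("ADP2", "(3S)-3-Hydroxyadipyl-CoA + NAD+ <=> 3-Oxoadipyl-CoA + NADH + H+",
             "1.1.1.35", "paaH", "Escherichia coli"),
            ("ADP3", "5-Carboxy-2-pentenoyl-CoA + H2O <=> (3S)-3-Hydroxyadipyl-CoA",
             "4.2.1.17", "ech", "Pseudomonas putida"),
            ("ADP4", "Adipyl-CoA + FAD <=> 5-Carboxy-2-pentenoyl-CoA + FADH2",
             "1.3.99.-", "", ""),
            ("ADP5", "Adipate + CoA + ATP <=> Adipyl-CoA + AMP + Diphosphate",
             "6.2.1.-", "", ""),
            ("ADP6", "Adipate semialdehyde + NADP+ + H2O <=> Adipate + NADPH + H+",
             "1.2.1.4", "", ""),
        ],
        "target": "Adipate semialdehyde",
        "n_reactions": 6,
    },
    "pdo_13": {
        "mets": [("glyc_c", "c", "C00116")],
        "rxns": [
            ("GLYCSYN", "glc_c + 2 nadh_c + 2 h_c <=> 2 glyc_c + 2 nad_c", -1000, 1000, 0, 0),
        ],
        "db": [
            ("DHAB", "Glycerol <=> 3-Hydroxypropanal + H2O",
             "4.2.1.30", "dhaB1;dhaB2;dhaB3", "Klebsiella pneumoniae"),
            ("DHAT", "3-Hydroxypropanal + NADH + H+ <=> Propane-1,3-diol + NAD+",
             "1.1.1.202", "dhaT", "Klebsiella pneumoniae"),
        ],
        "target": "Propane-1,3-diol",
        "n_reactions": 2,
    },
}

TABLE2_CASES = tuple(sorted(_TABLE2_SPEC))


def _resolve_name(name: str) -> str:
    from .reaction_db import resolve_compound_token

    return resolve_compound_token(name, NAME_TO_KEGG)


def table2_fixture(case_name: str, workdir=None, n_decoys: int = 0) -> FixtureCase:
    """Build a worked-example micro-host plus its literature reaction set.

    ``n_decoys`` appends decoy candidate reactions (fresh compounds hanging
    off glucose) that connect in the first round but never intersect the
    target pathway — the target's backtraced reaction count must be
    invariant to them.
    """
    if case_name not in _TABLE2_SPEC:
        raise KeyError(
            f"unknown case {case_name!r}; choose from {sorted(_TABLE2_SPEC)}"
        )
    spec = _TABLE2_SPEC[case_name]
    db_rows = list(spec["db"])
    for k in range(n_decoys):
        db_rows.append(
            (f"ZDEC{k:03d}", f"D-Glucose <=> Zdec{k:04d}", "", "", "")
        )
    mets = _BACKBONE_METS + spec["mets"]
    rxns = _BACKBONE_RXNS + spec["rxns"]
    host, db, workdir = _materialize(case_name, db_rows, mets, rxns, workdir)
    target = _resolve_name(spec["target"])
    case = FixtureCase(
        name=case_name,
        host=host,
        db=db,
        target=target,
        medium=MediumSpec(),
        expected={
            "n_heterologous_reactions": {
                "value": spec["n_reactions"],
                "tag": "reported",
            }
        },
        workdir=workdir,
    )
    _write_manifest(case)
    return case


def table2_km_table() -> pd.DataFrame:
    """Synthetic Michaelis-constant table covering the worked-example EC
    numbers (organisms and values are invented placeholders for annotation
    plumbing, not literature data)."""
    rows = [
        ("1.13.11.50", "Acinetobacter johnsonii", 0.45),
        ("1.13.11.50", "Pseudomonas sp.", 0.90),
        ("4.2.3.3", "Escherichia coli", 0.25),
        ("1.2.1.46", "Pseudomonas putida", 0.10),
        ("4.2.1.118", "Bacillus thuringiensis", 0.60),
        ("1.14.13.82", "Pseudomonas fluorescens", 0.32),
        ("1.2.3.9", "Penicillium simplicissimum", 0.06),
        ("1.2.1.23", "Escherichia coli", 0.48),
        ("1.1.1.77", "Escherichia coli", 0.03),
        ("4.1.1.87", "Mus musculus", 1.20),
        ("4.2.1.27", "Pseudomonas sp.", 0.75),
        ("1.2.1.3", "Homo sapiens", 0.015),
        ("2.3.1.174", "Escherichia coli", 0.21),
        ("1.1.1.35", "Escherichia coli", 0.05),
        ("4.2.1.17", "Pseudomonas putida", 0.11),
        ("1.3.99.7", "Sus scrofa", 0.04),
        ("6.2.1.5", "Escherichia coli", 0.30),
        ("1.2.1.4", "Saccharomyces cerevisiae", 0.52),
        ("4.2.1.30", "Klebsiella pneumoniae", 0.18),
        ("1.1.1.202", "Klebsiella pneumoniae", 0.09),
    ]
    return pd.DataFrame(rows, columns=["ec", "organism", "km_mM"])


def _write_manifest(case: FixtureCase) -> None:
    if case.workdir is None:
        return
    manifest = {
        "name": case.name,
        "target": case.target,
        "n_reactions_db": len(case.db),
        "expected": case.expected,
    }
    with open(case.workdir / f"{case.name}_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Seeded random expansion instances + brute-force oracle
# ---------------------------------------------------------------------------

def bfs_layer_oracle(
    m0, reactions, firing_rule: str = "all_substrates"
) -> dict[str, int]:
    """Brute-force synchronous reachability layers over reversible reactions.

    ``reactions`` is an iterable of ``(substrate_ids, product_ids)`` pairs
    (coefficients are irrelevant to reachability).  Returns the first
    iteration index at which each non-seed compound becomes producible;
    compounds never reached are absent.  This is a deliberately naive
    re-derivation — full rescan of every reaction direction each round —
    used as the independent oracle for the expansion algorithm.
    """
    known = set(m0)
    level: dict[str, int] = {}
    i = 0
    directions = []
    for subs, prods in reactions:
        directions.append((tuple(subs), tuple(prods)))
        directions.append((tuple(prods), tuple(subs)))
    while True:
        i += 1
        new: set[str] = set()
        for subs, prods in directions:
            if firing_rule == "all_substrates":
                ok = all(s in known for s in subs)
            else:
                ok = any(s in known for s in subs)
            if ok:
                new |= {p for p in prods if p not in known}
        if not new:
            return level
        for c in new:
            level[c] = i
        known |= new


def random_instance(
    n_compounds: int,
    n_reactions: int,
    seed: int,
    m0_fraction: float = 0.3,
    firing_rule: str = "all_substrates",
    workdir=None,
) -> FixtureCase:
    """A reproducible random expansion instance with oracle layer labels.

    Compounds are ``Z0001..Z{n}``; each reaction draws 1–3 substrates and
    1–3 products (disjoint).  ``expected['oracle_layers']`` holds the
    brute-force BFS layer of every reachable non-seed compound under the
    chosen firing rule.
    """
    if n_compounds < 2 or n_reactions < 1:
        raise ValueError("need at least 2 compounds and 1 reaction")
    rng = np.random.default_rng(seed)
    compounds = [f"Z{i:04d}" for i in range(1, n_compounds + 1)]
    n_seed = max(1, int(round(m0_fraction * n_compounds)))
    m0 = sorted(rng.choice(compounds, size=n_seed, replace=False).tolist())

    db_rows = []
    eqns = []
    for r in range(n_reactions):
        k_s = int(rng.integers(1, 4))
        k_p = int(rng.integers(1, 4))
        picked = rng.choice(compounds, size=min(k_s + k_p, n_compounds), replace=False)
        subs = sorted(picked[:k_s].tolist())
        prods = sorted(picked[k_s:].tolist())
        if not prods:
            continue
        eqn = " + ".join(subs) + " <=> " + " + ".join(prods)
        db_rows.append((f"RR{r:04d}", eqn, "", "", ""))
        eqns.append((subs, prods))

    mets = [(f"m{i}_c", "c", cid) for i, cid in enumerate(m0)]
    rxns: list = []
    host, db, workdir = _materialize(f"rand{seed}", db_rows, mets, rxns, workdir)
    oracle = bfs_layer_oracle(m0, eqns, firing_rule)
    return FixtureCase(
        name=f"rand{seed}",
        host=host,
        db=db,
        target=None,
        medium=MediumSpec(),
        expected={"oracle_layers": {"value": oracle, "tag": "derived"},
                  "m0": {"value": m0, "tag": "derived"}},
        workdir=workdir,
    )


# ---------------------------------------------------------------------------
# Analytic LP toys
# ---------------------------------------------------------------------------

def _toy(name, mets, rxns, target, medium, expected, workdir):
    host, db, wd = _materialize(name, [], mets, rxns, workdir)
    case = FixtureCase(
        name=name, host=host, db=db, target=target, medium=medium,
        expected=expected, workdir=wd,
    )
    return case


def analytic_fba_toys(workdir=None) -> list[FixtureCase]:
    """Closed-form LP checks.

    * ``chain``   A→B: maximum demand equals the uptake bound (yield 100 %).
    * ``branch``  2A→B: maximum demand is half the uptake (yield 50 %).
    * ``competition``  biomass and target compete 1:1 for one precursor:
      lexicographic target flux at the biomass optimum is 0.
    * ``nadh_coupling``  growth is NAD+-regeneration-limited and the target
      pathway oxidizes NADH: target flux at the biomass optimum is positive
      (biomass 2·O2 bound = 4, target 2·uptake − 2·biomass = 16 at the
      default uptake 10 and O2 bound 2).
    """
    toys = []
    medium_a = MediumSpec(carbon_source="C90001", carbon_uptake_max=10.0,
                          oxygen_uptake_max=0.0)

    chain_mets = [("A_e", "e", "C90001"), ("A_c", "c", "C90001"),
                  ("B_c", "c", "C90002")]
    chain_rxns = [("EX_A", "A_e <=>", -10, 1000, 0, 1),
                  ("T_A", "A_e <=> A_c", -1000, 1000, 0, 0),
                  ("CONV", "A_c <=> B_c", -1000, 1000, 0, 0)]
    toys.append(_toy("chain", chain_mets, chain_rxns, "C90002", medium_a,
                     {"max_demand": {"value": 10.0, "tag": "trivial"},
                      "yield_percent": {"value": 100.0, "tag": "trivial"}},
                     workdir))

    branch_rxns = [("EX_A", "A_e <=>", -10, 1000, 0, 1),
                   ("T_A", "A_e <=> A_c", -1000, 1000, 0, 0),
                   ("CONV2", "2 A_c <=> B_c", -1000, 1000, 0, 0)]
    toys.append(_toy("branch", chain_mets, branch_rxns, "C90002", medium_a,
                     {"max_demand": {"value": 5.0, "tag": "derived"},
                      "yield_percent": {"value": 50.0, "tag": "derived"}},
                     workdir))

    comp_mets = [("A_e", "e", "C90001"), ("A_c", "c", "C90001"),
                 ("P_c", "c", "C90003"), ("T_c", "c", "C90011")]
    comp_rxns = [("EX_A", "A_e <=>", -10, 1000, 0, 1),
                 ("T_A", "A_e <=> A_c", -1000, 1000, 0, 0),
                 ("UPT", "A_c <=> P_c", -1000, 1000, 0, 0),
                 ("TSYN", "P_c <=> T_c", -1000, 1000, 0, 0),
                 ("BIOMASS", "P_c <=>", 0, 1000, 1, 0)]
    toys.append(_toy("competition", comp_mets, comp_rxns, "C90011", medium_a,
                     {"biomass_opt": {"value": 10.0, "tag": "trivial"},
                      "target_at_biomass_opt": {"value": 0.0, "tag": "trivial"}},
                     workdir))

    nadh_mets = [("A_e", "e", "C90001"), ("A_c", "c", "C90001"),
                 ("P_c", "c", "C90003"), ("T_c", "c", "C90011"),
                 ("o2_e", "e", "C00007"), ("o2_c", "c", "C00007"),
                 ("nad_c", "c", "C00003"), ("nadh_c", "c", "C00004")]
    nadh_rxns = [("EX_A", "A_e <=>", -10, 1000, 0, 1),
                 ("EX_o2", "o2_e <=>", -2, 1000, 0, 1),
                 ("T_A", "A_e <=> A_c", -1000, 1000, 0, 0),
                 ("T_o2", "o2_e <=> o2_c", -1000, 1000, 0, 0),
                 ("GLY", "A_c + 2 nad_c <=> 2 P_c + 2 nadh_c", -1000, 1000, 0, 0),
                 ("RESP", "2 nadh_c + o2_c <=> 2 nad_c", 0, 1000, 0, 0),
                 ("TSYN", "P_c + nadh_c <=> T_c + nad_c", -1000, 1000, 0, 0),
                 ("BIOMASS", "P_c <=>", 0, 1000, 1, 0)]
    medium_n = MediumSpec(carbon_source="C90001", carbon_uptake_max=10.0,
                          oxygen_uptake_max=2.0)
    toys.append(_toy("nadh_coupling", nadh_mets, nadh_rxns, "C90011", medium_n,
                     {"biomass_opt": {"value": 4.0, "tag": "derived"},
                      "target_at_biomass_opt": {"value": 16.0, "tag": "derived"}},
                     workdir))
    return toys
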