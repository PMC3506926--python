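"""Genome-wide screening: expansion → pathway → FBA per target, plus the
chi-square category-enrichment comparison across hosts.

:func:`screen` connects every reachable nonnative compound, backtraces its
heterologous pathway and runs flux balance analysis twice per target —
maximizing the target production flux directly (producibility) and
lexicographically after biomass (growth-coupled production).  Results are
deterministic and ordered by compound ID so reports are byte-stable.

:func:`category_enrichment` compares produced/not-produced counts across
hosts within functional categories using Pearson's chi-square on the
hosts × outcome contingency table (no continuity correction, no
multiple-testing correction by default, significance at a raw alpha).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expansion import backtrace, expand
from .fba import (
    MediumSpec,
    ZERO_FLUX_TOL,
    biomass_coupled_production,
    build_flux_model,
    maximize,
    producibility,
    yield_percent,
)
from .host_model import HostModel, native_sets
from .reaction_db import ReactionDatabase

__all__ = [
    "TargetRecord",
    "EnrichmentRow",
    "screen",
    "category_enrichment",
    "write_report",
    "read_report",
    "summary_json",
]


@dataclass
class TargetRecord:
    """Screening outcome for one nonnative target compound."""

    target: str
    connection_iteration: int
    n_heterologous_reactions: int
    reaction_ids: tuple[str, ...]
    directions: tuple[str, ...]
    producible_max_target: bool = False
    max_target_flux: float = 0.0
    yield_max_target: float = 0.0
    producible_max_biomass: bool = False
    biomass_opt: float = 0.0
    target_flux_at_biomass_opt: float = 0.0
    yield_max_biomass: float = 0.0
    ec_numbers: str = ""
    genes: str = ""
    min_km_organism: str = ""
    net_o2_heterologous: float = 0.0
    net_nadh_oxidation_heterologous: float = 0.0
    solver_note: str = ""


@dataclass
class EnrichmentRow:
    """Per-category contingency comparison across hosts."""

    category: str
    counts: dict[str, tuple[int, int]]  # host -> (produced, not_produced)
    statistic: float
    p_value: float
    significant: bool
    design: str = "hosts_x_outcome"
    host: str | None = None  # set in one-vs-rest mode


def _heterologous_byproducts(fm, fluxes) -> tuple[float, float]:
    """Net O2 production and net NADH oxidation (NAD+ regeneration) by the
    heterologous columns at a flux optimum — descriptive mechanism tags."""
    o2_rows = {i for i, rid in enumerate(fm.row_ids)
               if fm.row_kegg.get(rid) == "C00007"}
    nadh_rows = {i for i, rid in enumerate(fm.row_ids)
                 if fm.row_kegg.get(rid) == "C00004"}
    S = fm.S.tocsc()
    net_o2 = net_nadh = 0.0
    for j, cid in enumerate(fm.col_ids):
        if fm.col_kind.get(cid) != "heterologous":
            continue
        v = float(fluxes[cid])
        col = S[:, j].tocoo()
        for i, coeff in zip(col.row, col.data):
            if i in o2_rows:
                net_o2 += coeff * v
            if i in nadh_rows:
                net_nadh -= coeff * v  # positive = net NADH consumed (oxidized)
    return net_o2, net_nadh


def screen(
    host: HostModel,
    db: ReactionDatabase,
    medium: MediumSpec | None = None,
    modes: tuple[str, ...] = ("max_target", "max_biomass"),
    max_reactions: int | None = None,
    firing_rule: str = "all_substrates",
    yield_threshold: float = 1.0,
) -> list[TargetRecord]:
    """Screen every connectable nonnative compound of a host.

    Returns one record per connected compound, ordered by compound ID,
    optionally keeping only pathways with at most ``max_reactions``
    heterologous reactions.  Per-target solver failures are recorded in
    the record's ``solver_note``, never raised.
    """
    medium = medium or MediumSpec()
    m0, r0 = native_sets(host)
    result = expand(m0, r0, db, firing_rule=firing_rule)
    records: list[TargetRecord] = []
    for target in sorted(result.connected_compounds):
        pathway = backtrace(result, target)
        if max_reactions is not None and pathway.n_reactions > max_reactions:
            continue
        rec = TargetRecord(
            target=target,
            connection_iteration=pathway.connection_iteration,
            n_heterologous_reactions=pathway.n_reactions,
            reaction_ids=tuple(r for r, _ in pathway.reactions),
            directions=tuple(d for _, d in pathway.reactions),
        )
        ecs, genes, kms = [], [], []
        for rid, _ in pathway.reactions:
            rxn = db.reactions[rid]
            ecs.extend(rxn.ec_numbers)
            genes.extend(g for g, _ in rxn.sources if g)
            if rxn.km_annotation:
                kms.append(rxn.km_annotation.organism)
        rec.ec_numbers = ";".join(dict.fromkeys(ecs))
        rec.genes = ";".join(dict.fromkeys(genes))
        rec.min_km_organism = ";".join(dict.fromkeys(kms))

        try:
            fm = build_flux_model(host, pathway, db, medium, target)
        except KeyError as exc:
            rec.solver_note = f"model build failed: {exc}"
            records.append(rec)
            continue

        if "max_target" in modes:
            producible, max_flux = producibility(fm)
            rec.producible_max_target = producible
            rec.max_target_flux = max_flux
            if producible:
                res = maximize(fm, fm.demand_col)
                rec.yield_max_target, _ = yield_percent(res, fm, yield_threshold)

        if "max_biomass" in modes and fm.biomass_col is not None:
            stage1, stage2 = biomass_coupled_production(fm)
            if not stage1.optimal:
                rec.solver_note = f"biomass stage: {stage1.status}"
            elif not stage2.optimal:
                rec.solver_note = f"coupled stage: {stage2.status}"
            else:
                rec.biomass_opt = stage1.objective_value
                rec.target_flux_at_biomass_opt = stage2.objective_value
                pct, produced = yield_percent(stage2, fm, yield_threshold)
                rec.yield_max_biomass = pct
                rec.producible_max_biomass = (
                    produced and rec.max_target_flux > ZERO_FLUX_TOL
                    if "max_target" in modes
                    else produced
                )
                o2, nadh = _heterologous_byproducts(fm, stage2.fluxes)
                rec.net_o2_heterologous = o2
                rec.net_nadh_oxidation_heterologous = nadh
        records.append(rec)
    return records


_REPORT_COLUMNS = [
    "target", "iteration", "n_reactions", "reactions", "directions", "ec",
    "genes", "min_km_organism", "producible_max_target", "max_target_flux",
    "yield_max_target", "producible_max_biomass", "biomass_opt",
    "target_flux_at_biomass_opt", "yield_max_biomass",
    "net_o2_heterologous", "net_nadh_oxidation_heterologous", "solver_note",
]


def write_report(records: list[TargetRecord], path) -> None:
    """Write a screening report TSV, byte-stable for fixed inputs."""
    rows = []
    for r in records:
        rows.append({
            "target": r.target,
            "iteration": r.connection_iteration,
            "n_reactions": r.n_heterologous_reactions,
            "reactions": ";".join(r.reaction_ids),
            "directions": ";".join(r.directions),
            "ec": r.ec_numbers,
            "genes": r.genes,
            "min_km_organism": r.min_km_organism,
            "producible_max_target": int(r.producible_max_target),
            "max_target_flux": f"{r.max_target_flux:.6f}",
            "yield_max_target": f"{r.yield_max_target:.6f}",
            "producible_max_biomass": int(r.producible_max_biomass),
            "biomass_opt": f"{r.biomass_opt:.6f}",
            "target_flux_at_biomass_opt": f"{r.target_flux_at_biomass_opt:.6f}",
            "yield_max_biomass": f"{r.yield_max_biomass:.6f}",
            "net_o2_heterologous": f"{r.net_o2_heterologous:.6f}",
            "net_nadh_oxidation_heterologous": f"{r.net_nadh_oxidation_heterologous:.6f}",
            "solver_note": r.solver_note,
        })
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_report(path) -> pd.DataFrame:
    """Read a screening report back; numeric fields restored as floats/ints."""
    return pd.read_csv(
        path, sep="\t", keep_default_na=False,
        dtype={"target": str, "reactions": str, "directions": str},
    )


def summary_json(records_per_host: dict[str, list[TargetRecord]], path=None) -> str:
    """Per-host producible counts and fractions as JSON."""
    out = {}
    for host_name, records in sorted(records_per_host.items()):
        n = len(records)
        n_prod = sum(r.producible_max_target for r in records)
        n_bio = sum(r.producible_max_biomass for r in records)
        out[host_name] = {
            "n_connected": n,
            "n_producible_max_target": n_prod,
            "n_producible_max_biomass": n_bio,
            "fraction_producible_max_target": (n_prod / n) if n else 0.0,
            "fraction_producible_max_biomass": (n_bio / n) if n else 0.0,
        }
    text = json.dumps(out, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


def category_enrichment(
    records_per_host: dict[str, list[TargetRecord]],
    category_map: dict[str, list[str]] | pd.DataFrame,
    alpha: float = 0.001,
    produced_attr: str = "producible_max_biomass",
    design: str = "hosts_x_outcome",
) -> list[EnrichmentRow]:
    """Chi-square enrichment of produced metabolites by functional category.

    ``category_map`` maps compound ID → categories (many-to-many; a TSV-
    derived DataFrame with columns ``compound_id``, ``category`` is also
    accepted).  For each category a hosts × {produced, not-produced}
    contingency table is built from the per-host records; Pearson's
    chi-square statistic (no continuity correction) with
    (rows−1)(cols−1) degrees of freedom gives the p-value.  Categories
    with an all-zero margin are excluded.  ``design='one_vs_rest'``
    instead emits one 2×2 row per host (this host vs the others pooled).
    Rows are sorted by p-value then category.
    """
    if isinstance(category_map, pd.DataFrame):
        cmap: dict[str, list[str]] = {}
        for row in category_map.itertuples(index=False):
            cmap.setdefault(str(row.compound_id), []).append(str(row.category))
        category_map = cmap

    categories = sorted({c for cats in category_map.values() for c in cats})
    hosts = sorted(records_per_host)
    rows: list[EnrichmentRow] = []
    for cat in categories:
        counts: dict[str, tuple[int, int]] = {}
        for host_name in hosts:
            produced = not_produced = 0
            for rec in records_per_host[host_name]:
                if cat not in category_map.get(rec.target, []):
                    continue
                if getattr(rec, produced_attr):
                    produced += 1
                else:
                    not_produced += 1
            counts[host_name] = (produced, not_produced)
        table = np.array([list(counts[h]) for h in hosts], dtype=float)
        if design == "hosts_x_outcome":
            tables = [(None, table)]
        elif design == "one_vs_rest":
            tables = []
            for i, host_name in enumerate(hosts):
                rest = table.sum(axis=0) - table[i]
                tables.append((host_name, np.vstack([table[i], rest])))
        else:
            raise ValueError(f"unknown design {design!r}")
        for host_name, tab in tables:
            if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
                continue  # degenerate margin: expected counts undefined
            stat, p, _, _ = stats.chi2_contingency(tab, correction=False)
            rows.append(
                EnrichmentRow(
                    category=cat,
                    counts=counts,
                    statistic=float(stat),
                    p_value=float(p),
                    significant=bool(p < alpha),
                    design=design,
                    host=host_name,
                )
            )
    rows.sort(key=lambda r: (r.p_value, r.category, r.host or ""))
    return rows
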