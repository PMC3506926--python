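"""Host genome-scale metabolic models with KEGG-compatible metabolite IDs.

The reference on-disk dialect is a two-section TSV (hand-writable for
fixtures):

.. code-block:: text

    # metabolites
    model_id<TAB>compartment<TAB>kegg_id
    glc__D_c<TAB>c<TAB>C00031
    ...
    # reactions
    id<TAB>equation<TAB>lb<TAB>ub<TAB>is_biomass<TAB>is_exchange
    GLCt<TAB>glc__D_e <=> glc__D_c<TAB>-1000<TAB>1000<TAB>0<TAB>0
    EX_glc<TAB>glc__D_e <=><TAB>-10<TAB>1000<TAB>0<TAB>1

Reaction equations are over model metabolite IDs; exchange reactions may
have an empty product side (the boundary).  Flux bounds are in mmol/gDW/h.
An optional mapping TSV (``model_id``, ``kegg_id``, ``manual_flag``) links
model metabolites to KEGG compound IDs; the link may also be given inline
in the metabolite section.  SBML (FBC bounds) can be imported as sugar on
top of this representation when python-libsbml is available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .reaction_db import Reaction, reaction_signature

__all__ = [
    "HostMetabolite",
    "HostReaction",
    "HostModel",
    "HostModelError",
    "load_host_model",
    "load_host_model_sbml",
    "write_host_model",
    "native_sets",
]


class HostModelError(ValueError):
    """Structural problem in a host model file."""


@dataclass(frozen=True)
class HostMetabolite:
    model_id: str
    compartment: str = "c"
    kegg_id: str | None = None


@dataclass(frozen=True)
class HostReaction:
    """A model reaction: signed stoichiometry over model metabolite IDs."""

    reaction_id: str
    stoichiometry: tuple[tuple[str, float], ...]  # (model_id, signed coeff)
    lower_bound: float
    upper_bound: float
    is_biomass: bool = False
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise HostModelError(
                f"{self.reaction_id}: lower bound exceeds upper bound"
            )


@dataclass
class HostModel:
    """In-memory host model: metabolites, reactions, biomass designation."""

    metabolites: dict[str, HostMetabolite] = field(default_factory=dict)
    reactions: dict[str, HostReaction] = field(default_factory=dict)
    biomass_reaction_id: str | None = None

    @property
    def exchange_reaction_ids(self) -> list[str]:
        return [r.reaction_id for r in self.reactions.values() if r.is_exchange]

    def add_metabolite(self, met: HostMetabolite) -> None:
        if met.model_id in self.metabolites:
            raise HostModelError(f"duplicate metabolite id {met.model_id!r}")
        self.metabolites[met.model_id] = met

    def add_reaction(self, rxn: HostReaction) -> None:
        if rxn.reaction_id in self.reactions:
            raise HostModelError(f"duplicate reaction id {rxn.reaction_id!r}")
        for mid, _ in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise HostModelError(
                    f"reaction {rxn.reaction_id!r} references undeclared "
                    f"metabolite {mid!r}"
                )
        self.reactions[rxn.reaction_id] = rxn
        if rxn.is_biomass:
            if self.biomass_reaction_id not in (None, rxn.reaction_id):
                raise HostModelError("more than one biomass reaction designated")
            self.biomass_reaction_id = rxn.reaction_id

    def mapping_report(self) -> dict[str, int]:
        mapped = sum(1 for m in self.metabolites.values() if m.kegg_id)
        return {
            "n_metabolites": len(self.metabolites),
            "n_mapped": mapped,
            "n_unmapped": len(self.metabolites) - mapped,
        }

    def exchange_for_kegg(self, kegg_id: str) -> list[str]:
        """IDs of exchange reactions whose metabolite maps to ``kegg_id``."""
        out = []
        for rxn in self.reactions.values():
            if not rxn.is_exchange:
                continue
            mids = [m for m, _ in rxn.stoichiometry]
            if len(mids) == 1 and self.metabolites[mids[0]].kegg_id == kegg_id:
                out.append(rxn.reaction_id)
        return sorted(out)


def _parse_model_equation(
    text: str, is_exchange: bool, is_biomass: bool = False
) -> tuple[tuple[str, float], ...]:
    """Parse a model-ID equation into signed stoichiometry.

    Exchange and biomass pseudo-reactions may have an empty right-hand
    side; the left side is then drained by positive flux (export-positive
    convention for exchanges, consumption of biomass precursors for the
    growth pseudo-reaction).
    """
    sep = None
    for cand in ("<=>", "↔", "="):
        if cand in text:
            sep = cand
            break
    if sep is None:
        raise HostModelError(f"no separator in model equation {text!r}")
    left, right = (s.strip() for s in text.split(sep, 1))
    if not left:
        raise HostModelError(f"empty substrate side in {text!r}")
    if not right and not (is_exchange or is_biomass):
        raise HostModelError(f"empty product side in non-exchange reaction {text!r}")
    stoich: dict[str, float] = {}

    def add_side(side_text: str, sign: float) -> None:
        if not side_text:
            return
        for term in re.split(r"\s\+\s", side_text):
            term = term.strip()
            head, _, rest = term.partition(" ")
            if re.match(r"^\d+(\.\d+)?$", head) and rest.strip():
                coeff, mid = float(head), rest.strip()
            else:
                coeff, mid = 1.0, term
            stoich[mid] = stoich.get(mid, 0.0) + sign * coeff

    add_side(left, -1.0)
    add_side(right, +1.0)
    return tuple(sorted((m, c) for m, c in stoich.items() if c != 0))


def load_host_model(stoich_path, mapping_path=None) -> HostModel:
    """Load a host model from the two-section TSV dialect.

    ``mapping_path`` optionally supplies/overrides the metabolite→KEGG
    mapping (columns ``model_id``, ``kegg_id``, optional ``manual_flag``);
    rows flagged manual always win over inline values.  Unmapped
    metabolites are retained (kegg_id None) and show up in
    :meth:`HostModel.mapping_report`.
    """
    met_rows: list[list[str]] = []
    rxn_rows: list[list[str]] = []
    section = None
    with open(stoich_path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            low = line.strip().lower()
            if low.startswith("# metabolites"):
                section = "met"
                continue
            if low.startswith("# reactions"):
                section = "rxn"
                continue
            if line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if section == "met":
                met_rows.append(cells)
            elif section == "rxn":
                rxn_rows.append(cells)
            else:
                raise HostModelError(f"content before any section header: {line!r}")

    mapping: dict[str, str] = {}
    manual: set[str] = set()
    if mapping_path is not None:
        mdf = pd.read_csv(mapping_path, sep="\t", dtype=str, keep_default_na=False)
        for row in mdf.itertuples(index=False):
            mid, kegg = row.model_id, row.kegg_id
            flag = str(getattr(row, "manual_flag", "0")) in ("1", "true", "True")
            if mid in mapping and mapping[mid] != kegg:
                raise HostModelError(f"model id {mid!r} maps to two compounds")
            if kegg:
                mapping[mid] = kegg
                if flag:
                    manual.add(mid)

    model = HostModel()
    header_skipped = False
    for cells in met_rows:
        if not header_skipped and cells[0] == "model_id":
            header_skipped = True
            continue
        mid = cells[0]
        compartment = cells[1] if len(cells) > 1 and cells[1] else "c"
        inline = cells[2] if len(cells) > 2 and cells[2] else None
        kegg = mapping.get(mid, inline)
        if mid in manual:
            kegg = mapping[mid]
        model.add_metabolite(HostMetabolite(mid, compartment, kegg))

    header_skipped = False
    for cells in rxn_rows:
        if not header_skipped and cells[0] == "id":
            header_skipped = True
            continue
        if len(cells) < 4:
            raise HostModelError(f"reaction row too short: {cells!r}")
        rid, eqn, lb, ub = cells[0], cells[1], float(cells[2]), float(cells[3])
        is_biomass = len(cells) > 4 and cells[4] in ("1", "true", "True")
        is_exchange = len(cells) > 5 and cells[5] in ("1", "true", "True")
        stoich = _parse_model_equation(eqn, is_exchange, is_biomass)
        model.add_reaction(
            HostReaction(rid, stoich, lb, ub, is_biomass, is_exchange)
        )
    return model


def write_host_model(model: HostModel, path) -> None:
    """Write a model back out in the two-section TSV dialect (debug/export)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# metabolites\nmodel_id\tcompartment\tkegg_id\n")
        for mid in model.metabolites:
            met = model.metabolites[mid]
            fh.write(f"{met.model_id}\t{met.compartment}\t{met.kegg_id or ''}\n")
        fh.write("# reactions\nid\tequation\tlb\tub\tis_biomass\tis_exchange\n")
        for rid in model.reactions:
            rxn = model.reactions[rid]
            subs = [(m, -c) for m, c in rxn.stoichiometry if c < 0]
            prods = [(m, c) for m, c in rxn.stoichiometry if c > 0]
            fmt = lambda side: " + ".join(
                m if c == 1 else f"{c:g} {m}" for m, c in side
            )
            eqn = f"{fmt(subs)} <=> {fmt(prods)}".rstrip()
            fh.write(
                f"{rid}\t{eqn}\t{rxn.lower_bound:g}\t{rxn.upper_bound:g}\t"
                f"{int(rxn.is_biomass)}\t{int(rxn.is_exchange)}\n"
            )


def load_host_model_sbml(path, mapping_path=None) -> HostModel:
    """Import an SBML (level 3 / FBC) model into the HostModel container.

    Requires python-libsbml.  KEGG IDs come from the mapping TSV or, if
    absent, from 'kegg.compound' annotations when present.
    """
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SBML import requires python-libsbml") from exc

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise HostModelError(f"libsbml failed to read {path}")
    sbml_model = doc.getModel()

    mapping: dict[str, str] = {}
    if mapping_path is not None:
        mdf = pd.read_csv(mapping_path, sep="\t", dtype=str, keep_default_na=False)
        mapping = {r.model_id: r.kegg_id for r in mdf.itertuples(index=False) if r.kegg_id}

    model = HostModel()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        model.add_metabolite(
            HostMetabolite(sp.getId(), sp.getCompartment() or "c", mapping.get(sp.getId()))
        )

    fbc = sbml_model.getPlugin("fbc")
    objective_ids: set[str] = set()
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        for j in range(obj.getNumFluxObjectives()):
            objective_ids.add(obj.getFluxObjective(j).getReaction())

    def _param(pid, default):
        p = sbml_model.getParameter(pid) if pid else None
        return p.getValue() if p is not None else default

    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            if ref.getSpecies() in model.metabolites:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            if ref.getSpecies() in model.metabolites:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None:
            lb = _param(rfbc.getLowerFluxBound(), -1000.0)
            ub = _param(rfbc.getUpperFluxBound(), 1000.0)
        else:
            lb, ub = (-1000.0, 1000.0) if rx.getReversible() else (0.0, 1000.0)
        is_biomass = rx.getId() in objective_ids
        model.add_reaction(
            HostReaction(
                rx.getId(),
                tuple(sorted(stoich.items())),
                lb,
                ub,
                is_biomass=is_biomass,
                is_exchange=len(stoich) == 1 and not is_biomass,
            )
        )
    return model


def native_sets(model: HostModel) -> tuple[set[str], set[tuple]]:
    """Native metabolite set M0 and reaction-signature set R0.

    M0 is compartment-collapsed: a KEGG compound is native if any
    compartmental species maps to it.  R0 contains the signatures of native
    non-boundary reactions expressed over KEGG IDs; reactions touching
    unmapped metabolites (and pure transport reactions, whose KEGG-space
    stoichiometry cancels) have no signature and are excluded — they remain
    in the model for flux balance analysis but cannot be compared against
    KEGG-space candidates.
    """
    m0 = {m.kegg_id for m in model.metabolites.values() if m.kegg_id}
    r0: set[tuple] = set()
    for rxn in model.reactions.values():
        if rxn.is_exchange or rxn.is_biomass:
            continue
        kegg_ids = {}
        ok = True
        for mid, _ in rxn.stoichiometry:
            kegg = model.metabolites[mid].kegg_id
            if kegg is None:
                ok = False
                break
            kegg_ids[mid] = kegg
        if not ok:
            continue
        subs: dict[str, float] = {}
        prods: dict[str, float] = {}
        for mid, coeff in rxn.stoichiometry:
            bucket = subs if coeff < 0 else prods
            k = kegg_ids[mid]
            bucket[k] = bucket.get(k, 0.0) + abs(coeff)
        # transport reactions cancel to empty sides in compound space
        for cid in set(subs) & set(prods):
            common = min(subs[cid], prods[cid])
            subs[cid] -= common
            prods[cid] -= common
            if subs[cid] <= 0:
                del subs[cid]
            if prods[cid] <= 0:
                del prods[cid]
        if not subs or not prods:
            continue
        r0.add(
            reaction_signature(
                Reaction(
                    reaction_id=rxn.reaction_id,
                    substrates=tuple(sorted(subs.items())),
                    products=tuple(sorted(prods.items())),
                )
            )
        )
    return m0, r0
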