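"""Iterative network expansion and heterologous pathway backtracing.

The host network, represented by its native compound set M0 and native
reaction-signature set R0, is expanded in synchronous rounds.  At round i,
every candidate database reaction is tried in both directions (all
candidates are treated as reversible).  A direction *fires* when its
substrate requirement is met by the compounds accumulated so far:

* ``all_substrates`` (default): every substrate of that direction must be
  available — the stoichiometrically meaningful rule;
* ``any_substrate``: one available substrate suffices — a permissive
  reachability variant, kept as a documented option.

A fired reaction is admitted to the layer set Ri iff its signature is new
(not in R0 nor in any earlier layer) and it produces at least one compound
not yet connected; those compounds form Mi.  Rounds repeat until no further
reaction is connectable.  Because a reaction whose one direction has fired
has both of its sides fully connected, admitting each reaction at most once
loses no reachability.

For any connected target the producer map — which reaction, fired in which
direction, first produced each compound — is walked backwards to extract a
heterologous pathway: the producer of the target, plus recursively the
producers of every nonnative substrate consumed along the way.  The result
is one deterministic pathway, minimal in connection depth; it is not
guaranteed to be minimum-cardinality over all conceivable reaction subsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .reaction_db import Reaction, ReactionDatabase, reaction_signature

__all__ = [
    "ExpansionLayer",
    "ExpansionResult",
    "HeterologousPathway",
    "NOT_CONNECTED",
    "NATIVE",
    "expand",
    "connection_iteration",
    "backtrace",
    "iteration_curve",
    "replay_pathway",
    "write_pathway_table",
]

FIRING_RULES = ("all_substrates", "any_substrate")

#: Sentinel returned for targets never reached by the expansion.
NOT_CONNECTED = "not_connected"
#: Sentinel returned for targets already native to the host.
NATIVE = "native"


@dataclass(frozen=True)
class ExpansionLayer:
    """One expansion round: reactions admitted (Ri) and compounds first
    produced (Mi) at iteration ``index`` (1-based)."""

    index: int
    reaction_ids: frozenset[str]
    compounds: frozenset[str]
    directions: dict[str, str] = field(default_factory=dict, compare=False)


@dataclass
class ExpansionResult:
    """Layered expansion output plus the per-compound producer map.

    ``producer_map`` assigns each connected nonnative compound the
    ``(reaction_id, direction, iteration)`` that first produced it (ties
    broken by lexicographically smallest reaction id).
    """

    m0: frozenset[str]
    layers: list[ExpansionLayer]
    producer_map: dict[str, tuple[str, str, int]]
    firing_rule: str
    terminated: bool
    db: ReactionDatabase | None = None

    @property
    def connected_compounds(self) -> set[str]:
        out: set[str] = set()
        for layer in self.layers:
            out |= layer.compounds
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "firing_rule": self.firing_rule,
            "terminated": self.terminated,
            "layers": [
                {
                    "index": l.index,
                    "reactions": sorted(l.reaction_ids),
                    "compounds": sorted(l.compounds),
                }
                for l in self.layers
            ],
            "producer_map": {
                c: {"reaction": r, "direction": d, "iteration": i}
                for c, (r, d, i) in sorted(self.producer_map.items())
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class HeterologousPathway:
    """An ordered heterologous reaction set sufficient to reach ``target``."""

    target: str
    reactions: list[tuple[str, str]]  # (reaction_id, direction), dependency order
    connection_iteration: int | str

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)


def _fires(substrates, known: set[str], rule: str) -> bool:
    ids = [c for c, _ in substrates]
    if rule == "all_substrates":
        return all(c in known for c in ids)
    return any(c in known for c in ids)


def expand(
    m0,
    r0,
    db: ReactionDatabase,
    firing_rule: str = "all_substrates",
) -> ExpansionResult:
    """Expand the host network to termination.

    Parameters
    ----------
    m0 : iterable of compound IDs native to the host.
    r0 : set of native reaction signatures (see
        :func:`heteropath.host_model.native_sets`).
    db : deduplicated candidate reaction database.
    firing_rule : 'all_substrates' (default) or 'any_substrate'.
    """
    if firing_rule not in FIRING_RULES:
        raise ValueError(f"unknown firing rule {firing_rule!r}")
    m0 = frozenset(m0)
    known = set(m0)
    used_signatures = set(r0)

    # candidates whose signature already exists in the host are never
    # heterologous additions
    remaining: dict[str, Reaction] = {}
    for rid in sorted(db.reactions):
        if reaction_signature(db.reactions[rid]) not in used_signatures:
            remaining[rid] = db.reactions[rid]

    layers: list[ExpansionLayer] = []
    producer_map: dict[str, tuple[str, str, int]] = {}
    admitted_ids: set[str] = set()
    iteration = 0
    while True:
        iteration += 1
        admitted: dict[str, str] = {}  # rid newly admitted -> firing direction
        new_compounds: dict[str, tuple[str, str]] = {}  # cid -> (rid, direction)
        for rid in sorted(remaining):
            rxn = remaining[rid]
            for direction in ("forward", "reverse"):
                subs, prods = rxn.side(direction)
                if not _fires(subs, known, firing_rule):
                    continue
                produced_new = [c for c, _ in prods if c not in known]
                if not produced_new:
                    continue
                # under any_substrate an earlier-admitted reaction may fire
                # a newly enabled direction; its products still connect, but
                # the reaction itself belongs to its first layer only
                if rid not in admitted_ids:
                    admitted.setdefault(rid, direction)
                for cid in produced_new:
                    new_compounds.setdefault(cid, (rid, direction))
        if not new_compounds:
            break
        layer = ExpansionLayer(
            index=iteration,
            reaction_ids=frozenset(admitted),
            compounds=frozenset(new_compounds),
            directions=dict(admitted),
        )
        layers.append(layer)
        for cid, (rid, direction) in new_compounds.items():
            producer_map[cid] = (rid, direction, iteration)
        known |= set(new_compounds)
        for rid in admitted:
            used_signatures.add(reaction_signature(remaining[rid]))
            admitted_ids.add(rid)

    return ExpansionResult(
        m0=m0,
        layers=layers,
        producer_map=producer_map,
        firing_rule=firing_rule,
        terminated=True,
        db=db,
    )


def connection_iteration(result: ExpansionResult, target: str):
    """Layer index at which ``target`` was connected.

    Returns the 1-based iteration, the string ``'native'`` for compounds in
    M0, or ``'not_connected'`` for compounds the expansion never reached.
    """
    if target in result.m0:
        return NATIVE
    if target in result.producer_map:
        return result.producer_map[target][2]
    return NOT_CONNECTED


def backtrace(result: ExpansionResult, target: str) -> HeterologousPathway:
    """Extract the heterologous reaction set that produces ``target``.

    Starting from the target's producer, the producer of every nonnative
    substrate (of the firing direction) of every included reaction is
    pulled in recursively.  The returned list is deduplicated and ordered
    by (iteration, reaction id) — a valid replay order from M0.
    """
    status = connection_iteration(result, target)
    if status == NATIVE:
        return HeterologousPathway(target=target, reactions=[], connection_iteration=NATIVE)
    if status == NOT_CONNECTED:
        raise KeyError(f"target {target!r} is not connected to the host network")
    if result.db is None:
        raise ValueError("expansion result carries no reaction database")

    included: dict[str, tuple[str, int]] = {}  # rid -> (direction, iteration)
    stack = [target]
    seen_compounds: set[str] = set()
    while stack:
        cid = stack.pop()
        if cid in seen_compounds or cid in result.m0:
            continue
        seen_compounds.add(cid)
        rid, direction, it = result.producer_map[cid]
        if rid not in included:
            included[rid] = (direction, it)
            subs, _ = result.db.reactions[rid].side(direction)
            for sub_id, _ in subs:
                stack.append(sub_id)

    ordered = sorted(included.items(), key=lambda kv: (kv[1][1], kv[0]))
    return HeterologousPathway(
        target=target,
        reactions=[(rid, direction) for rid, (direction, _) in ordered],
        connection_iteration=status,
    )


def replay_pathway(
    pathway: HeterologousPathway,
    m0,
    db: ReactionDatabase,
    firing_rule: str = "all_substrates",
) -> bool:
    """Check sufficiency: firing the pathway's reactions (in any feasible
    order) from M0 produces the target."""
    known = set(m0)
    pending = list(pathway.reactions)
    progress = True
    while pending and progress:
        progress = False
        for item in list(pending):
            rid, direction = item
            subs, prods = db.reactions[rid].side(direction)
            if _fires(subs, known, firing_rule):
                known |= {c for c, _ in prods}
                pending.remove(item)
                progress = True
    return pathway.target in known


def iteration_curve(result: ExpansionResult) -> list[tuple[int, int, int]]:
    """Per-iteration connected-compound counts and their running total.

    Returns ``[(iteration, |Mi|, cumulative), ...]``; the final cumulative
    value equals the total number of connected nonnative compounds.
    """
    curve = []
    total = 0
    for layer in result.layers:
        total += len(layer.compounds)
        curve.append((layer.index, len(layer.compounds), total))
    return curve


def write_pathway_table(pathways, db: ReactionDatabase, path) -> None:
    """Export pathways as a TSV: one row per target with its heterologous
    reactions, firing directions, EC numbers, gene sources and minimum-Km
    organism annotation."""
    import pandas as pd

    rows = []
    for pw in pathways:
        rids = [r for r, _ in pw.reactions]
        dirs = [d for _, d in pw.reactions]
        ecs, genes, km_orgs = [], [], []
        for rid in rids:
            rxn = db.reactions[rid]
            ecs.extend(rxn.ec_numbers)
            genes.extend(g for g, _ in rxn.sources)
            if rxn.km_annotation:
                km_orgs.append(f"{rxn.km_annotation.organism} ({rxn.km_annotation.km_value:g} mM)")
        rows.append(
            {
                "target": pw.target,
                "n_reactions": pw.n_reactions,
                "iteration": pw.connection_iteration,
                "reactions": ";".join(rids),
                "directions": ";".join(dirs),
                "ec": ";".join(dict.fromkeys(ecs)),
                "genes": ";".join(dict.fromkeys(genes)),
                "min_km_organism": ";".join(dict.fromkeys(km_orgs)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
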