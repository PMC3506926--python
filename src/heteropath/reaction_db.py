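"""Candidate heterologous reaction databases.

Reactions are stoichiometric equations over KEGG-style compound identifiers,
parsed from a tabular (TSV) dump in the KEGG-ligand equation dialect.  All
reactions are treated as reversible unless stated otherwise: for most
database reactions directionality is poorly annotated, and assuming
reversibility avoids discarding pathways on a wrong irreversibility call.
Plausibility of the predicted direction is left to downstream inspection.

Key primitives:

* :func:`parse_equation` — equation string -> (substrates, products)
* :func:`reaction_signature` — canonical, direction- and order-invariant
  stoichiometric signature used for deduplication and for testing whether a
  candidate reaction already exists in the host network
* :func:`load_reaction_table` — TSV -> :class:`ReactionDatabase` with a skip
  report for unusable rows (symbolic coefficients etc.)
* :func:`attach_km` — annotate reactions with the minimum Michaelis constant
  among orthologous enzymes and its source organism
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "CompoundRef",
    "Reaction",
    "KmAnnotation",
    "ReactionDatabase",
    "EquationParseError",
    "UnusableReactionError",
    "ReactionTableError",
    "parse_equation",
    "serialize_equation",
    "reaction_signature",
    "load_reaction_table",
    "attach_km",
    "resolve_compound_token",
    "synthetic_compound_id",
]

#: Separator tokens accepted between the two sides of an equation.
SEPARATORS = ("<=>", "↔", "=")

#: KEGG-style compound identifier: letter(s) followed by digits.
_ID_PATTERN = re.compile(r"^[A-Za-z]+\d+$")

#: Reserved namespace prefix for compounds named in prose with no known ID.
SYNTHETIC_NAMESPACE = "X__"

#: Symbolic (polymer) coefficient tokens that make a row unusable for FBA.
_SYMBOLIC_COEFF = re.compile(r"^\(?[nmx](\s*[+-]\s*\d+)?\)?$", re.IGNORECASE)

_NUMERIC = re.compile(r"^\d+(\.\d+)?$")


class EquationParseError(ValueError):
    """Equation string violates the accepted grammar."""


class UnusableReactionError(ValueError):
    """Equation parses but has no defined stoichiometry (e.g. 'n C00001')."""


class ReactionTableError(ValueError):
    """Structural problem in a reaction table file."""


@dataclass(frozen=True)
class CompoundRef:
    """A compound identity: KEGG-style ID plus optional free-text name."""

    compound_id: str
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")


@dataclass(frozen=True)
class KmAnnotation:
    """Minimum Michaelis constant among orthologs and its source organism.

    ``km_value`` is in mM; the minimum-Km organism is expected to host the
    highest-affinity enzyme for the reaction's substrate.
    """

    km_value: float
    organism: str

    def __post_init__(self) -> None:
        if not self.km_value > 0:
            raise ValueError("km_value must be positive")


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction over compound IDs.

    ``substrates`` and ``products`` are tuples of ``(compound_id, coeff)``
    with strictly positive coefficients.  ``reversible`` defaults to True
    (the screening assumption for database reactions).
    """

    reaction_id: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    reversible: bool = True
    ec_numbers: tuple[str, ...] = ()
    sources: tuple[tuple[str, str], ...] = ()
    km_annotation: KmAnnotation | None = None

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(
                f"{self.reaction_id}: substrates and products must be non-empty"
            )
        for side in (self.substrates, self.products):
            for cid, coeff in side:
                if not (coeff > 0 and coeff == coeff and coeff != float("inf")):
                    raise ValueError(
                        f"{self.reaction_id}: coefficient for {cid} must be "
                        f"finite and positive, got {coeff!r}"
                    )

    @property
    def compounds(self) -> set[str]:
        return {c for c, _ in self.substrates} | {c for c, _ in self.products}

    def side(self, direction: str) -> tuple[tuple[tuple[str, float], ...], tuple[tuple[str, float], ...]]:
        """Return (substrates, products) for a firing ``direction``."""
        if direction == "forward":
            return self.substrates, self.products
        if direction == "reverse":
            return self.products, self.substrates
        raise ValueError(f"unknown direction {direction!r}")


def synthetic_compound_id(name: str) -> str:
    """Deterministic reserved-namespace ID for a compound named in prose."""
    slug = re.sub(r"[^A-Za-z0-9]+", "_", name.strip()).strip("_").lower()
    return SYNTHETIC_NAMESPACE + slug


def resolve_compound_token(token: str, compound_table: dict[str, str] | None = None) -> str:
    """Map an equation term's compound token to a compound ID.

    Lookup order: explicit name table (case-insensitive), KEGG-style ID
    pattern, then the reserved synthetic namespace.
    """
    token = token.strip()
    if compound_table:
        if token in compound_table:
            return compound_table[token]
        lowered = {k.lower(): v for k, v in compound_table.items()}
        if token.lower() in lowered:
            return lowered[token.lower()]
    if _ID_PATTERN.match(token):
        return token
    return synthetic_compound_id(token)


def _parse_term(term: str, compound_table: dict[str, str] | None) -> tuple[str, float]:
    term = term.strip()
    if not term:
        raise EquationParseError("empty term in equation")
    head, _, rest = term.partition(" ")
    if _NUMERIC.match(head) and rest.strip():
        return resolve_compound_token(rest, compound_table), float(head)
    if _SYMBOLIC_COEFF.match(head) and rest.strip():
        raise UnusableReactionError(f"symbolic coefficient {head!r} in term {term!r}")
    return resolve_compound_token(term, compound_table), 1.0


def parse_equation(
    text: str, compound_table: dict[str, str] | None = None
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Parse an equation string into (substrates, products) stoich lists.

    Accepts ``<=>``, ``↔`` and ``=`` as the side separator and ``+`` (with
    surrounding whitespace) as the term joiner; each term is an optional
    numeric coefficient followed by a compound token.  Term order is
    preserved.  Compound names (possibly containing spaces, hyphens or
    commas) are resolved through ``compound_table`` or the synthetic
    namespace.
    """
    sep = None
    for cand in SEPARATORS:
        if cand in text:
            sep = cand
            break
    if sep is None:
        raise EquationParseError(f"no side separator in equation: {text!r}")
    left, right = text.split(sep, 1)
    for other in SEPARATORS:
        if other != sep and other in right:
            raise EquationParseError(f"multiple separators in equation: {text!r}")
    if not left.strip() or not right.strip():
        raise EquationParseError(f"empty side in equation: {text!r}")
    subs = [_parse_term(t, compound_table) for t in re.split(r"\s\+\s", left.strip())]
    prods = [_parse_term(t, compound_table) for t in re.split(r"\s\+\s", right.strip())]
    return subs, prods


def _fmt_coeff(coeff: float) -> str:
    return f"{coeff:g}"


def serialize_equation(
    substrates: list[tuple[str, float]] | tuple[tuple[str, float], ...],
    products: list[tuple[str, float]] | tuple[tuple[str, float], ...],
) -> str:
    """Canonical textual form: unit coefficients omitted, '<=>' separator."""

    def side(terms):
        out = []
        for cid, coeff in terms:
            out.append(cid if coeff == 1 else f"{_fmt_coeff(coeff)} {cid}")
        return " + ".join(out)

    return f"{side(substrates)} <=> {side(products)}"


def _canonical_sides(reaction: Reaction) -> tuple[tuple, tuple]:
    # Merge repeated terms per side, then cancel any compound appearing on
    # both sides (the common part is removed; an equal split drops it).
    sides = []
    for terms in (reaction.substrates, reaction.products):
        acc: dict[str, float] = {}
        for cid, coeff in terms:
            acc[cid] = acc.get(cid, 0.0) + coeff
        sides.append(acc)
    left, right = sides
    for cid in set(left) & set(right):
        common = min(left[cid], right[cid])
        left[cid] -= common
        right[cid] -= common
        if left[cid] <= 0:
            del left[cid]
        if right[cid] <= 0:
            del right[cid]
    canon = lambda d: tuple(sorted((c, round(k, 9)) for c, k in d.items()))
    return canon(left), canon(right)


def reaction_signature(reaction: Reaction) -> tuple:
    """Canonical stoichiometric signature of a reaction.

    Invariant under term reordering within a side and under swapping the two
    sides (reactions are treated as reversible, so direction carries no
    identity).  Two reactions share a signature iff they have the same net
    stoichiometry over the same compound IDs.
    """
    left, right = _canonical_sides(reaction)
    return tuple(sorted((left, right)))


@dataclass
class ReactionDatabase:
    """A deduplicated collection of candidate heterologous reactions.

    ``skip_report`` records rows that could not be turned into usable
    reactions, as ``(reaction_id, reason)``; ``merged`` maps collapsed
    duplicate reaction IDs to their retained representative.
    """

    reactions: dict[str, Reaction] = field(default_factory=dict)
    skip_report: list[tuple[str, str]] = field(default_factory=list)
    merged: dict[str, str] = field(default_factory=dict)

    @property
    def compounds(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            out |= r.compounds
        return out

    def __len__(self) -> int:
        return len(self.reactions)

    def signatures(self) -> set[tuple]:
        return {reaction_signature(r) for r in self.reactions.values()}

    def write_skip_report(self, path) -> None:
        pd.DataFrame(self.skip_report, columns=["reaction_id", "reason"]).to_csv(
            path, sep="\t", index=False
        )


def _split_list(cell) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    return tuple(s.strip() for s in str(cell).split(";") if s.strip())


def load_reaction_table(
    path,
    compound_table: dict[str, str] | None = None,
    deduplicate: bool = True,
) -> ReactionDatabase:
    """Load a reaction TSV into a :class:`ReactionDatabase`.

    Required columns: ``reaction_id``, ``equation``.  Optional: ``ec``,
    ``genes``, ``organisms`` (semicolon-separated; genes and organisms are
    zipped into (gene, organism) source pairs).  Rows whose equations cannot
    be parsed or have symbolic coefficients are recorded in the skip report
    rather than dropped silently.  With ``deduplicate`` (default), reactions
    with identical signatures are collapsed to the lexicographically
    smallest reaction ID, keeping the union of annotations.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("reaction_id", "equation"):
        if col not in df.columns:
            raise ReactionTableError(f"missing required column {col!r} in {path}")
    if df["reaction_id"].duplicated().any():
        dups = sorted(df.loc[df["reaction_id"].duplicated(), "reaction_id"])
        raise ReactionTableError(f"duplicate reaction_id(s) in {path}: {dups}")

    db = ReactionDatabase()
    for row in df.itertuples(index=False):
        rid = row.reaction_id
        try:
            subs, prods = parse_equation(row.equation, compound_table)
            genes = _split_list(getattr(row, "genes", ""))
            organisms = _split_list(getattr(row, "organisms", ""))
            if len(organisms) == 1 and len(genes) > 1:
                organisms = organisms * len(genes)
            sources = tuple(zip(genes, organisms)) if organisms else tuple(
                (g, "") for g in genes
            )
            rxn = Reaction(
                reaction_id=rid,
                substrates=tuple(subs),
                products=tuple(prods),
                ec_numbers=_split_list(getattr(row, "ec", "")),
                sources=sources,
            )
        except (EquationParseError, UnusableReactionError, ValueError) as exc:
            db.skip_report.append((rid, str(exc)))
            continue
        db.reactions[rid] = rxn

    if deduplicate:
        by_sig: dict[tuple, str] = {}
        for rid in sorted(db.reactions):
            sig = reaction_signature(db.reactions[rid])
            if sig in by_sig:
                keeper_id = by_sig[sig]
                keeper = db.reactions[keeper_id]
                dup = db.reactions.pop(rid)
                db.reactions[keeper_id] = replace(
                    keeper,
                    ec_numbers=tuple(dict.fromkeys(keeper.ec_numbers + dup.ec_numbers)),
                    sources=tuple(dict.fromkeys(keeper.sources + dup.sources)),
                )
                db.merged[rid] = keeper_id
            else:
                by_sig[sig] = rid
    return db


def _ec_matches(rxn_ec: str, table_ec: str) -> bool:
    # Prefix match on defined digits: '1.3.99.-' matches '1.3.99.7'.
    a = [p for p in rxn_ec.split(".")]
    b = [p for p in table_ec.split(".")]
    for pa, pb in zip(a, b):
        if pa in ("-", "") or pb in ("-", ""):
            return True
        if pa != pb:
            return False
    return True


def attach_km(db: ReactionDatabase, km_table) -> ReactionDatabase:
    """Annotate each reaction with the minimum-Km matching row.

    ``km_table`` is a path or DataFrame with columns ``ec``, ``organism``,
    ``km_mM``.  For each reaction, rows matching any of its EC numbers
    (wildcards match by prefix on the defined digits) are collected and the
    minimum km taken, ties broken alphabetically by organism.  Reactions
    without matches stay unannotated.  Returns a new database.
    """
    if not isinstance(km_table, pd.DataFrame):
        km_table = pd.read_csv(km_table, sep="\t", dtype={"ec": str, "organism": str})
    out = ReactionDatabase(skip_report=list(db.skip_report), merged=dict(db.merged))
    rows = [
        (str(r.ec), str(r.organism), float(r.km_mM))
        for r in km_table.itertuples(index=False)
    ]
    for rid, rxn in db.reactions.items():
        matches = [
            (km, org)
            for ec, org, km in rows
            if any(_ec_matches(rec, ec) for rec in rxn.ec_numbers)
        ]
        if matches:
            km, org = min(matches, key=lambda t: (t[0], t[1]))
            rxn = replace(rxn, km_annotation=KmAnnotation(km_value=km, organism=org))
        out.reactions[rid] = rxn
    return out
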