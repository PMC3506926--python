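"""Flux balance analysis on an expanded host network.

A :class:`FluxModel` is the host stoichiometric matrix augmented with the
heterologous reactions of a pathway (placed in the cytosol, reversible with
bounds ±V) and a demand column exporting the target.  Under the pseudo
steady-state constraint S·v = 0 and flux bounds, a chosen objective column
is maximized by linear programming (scipy's HiGHS backend).

Producibility of a nonnative target means a strictly positive maximum
demand flux.  Because the biomass-optimal flux distribution is often
degenerate, growth-coupled production is quantified lexicographically:
maximize biomass first, then re-maximize the target demand with biomass
fixed at its optimum, which yields a unique, reproducible production flux
at maximal growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .expansion import HeterologousPathway
from .host_model import HostModel
from .reaction_db import ReactionDatabase

__all__ = [
    "MediumSpec",
    "FluxModel",
    "FBAResult",
    "build_flux_model",
    "maximize",
    "producibility",
    "biomass_coupled_production",
    "yield_percent",
    "DEFAULT_FREE_EXCHANGES",
]

#: Compounds allowed free transport by default: CO2, H2O, sulfate, sulfite,
#: ammonia, proton, orthophosphate.
DEFAULT_FREE_EXCHANGES = frozenset(
    {"C00011", "C00001", "C00059", "C00094", "C00014", "C00080", "C00009"}
)

#: Default magnitude bound on heterologous reaction fluxes (mmol/gDW/h).
HETEROLOGOUS_BOUND = 1000.0

#: Fluxes below this magnitude are treated as zero.
ZERO_FLUX_TOL = 1e-6

#: Relative tolerance used when fixing the biomass optimum in stage 2.
BIOMASS_FIX_RTOL = 1e-6


@dataclass(frozen=True)
class MediumSpec:
    """Growth medium as exchange-bound policy.

    ``carbon_source`` is the sole carbon source (KEGG compound ID) with
    uptake capped at ``carbon_uptake_max``; ``oxygen_uptake_max``
    implements the aeration level (0 = anaerobic, small positive =
    micro-aerobic); compounds in ``free_exchanges`` may cross the membrane
    freely.  Uptake of every other exchanged compound is closed; secretion
    stays open.  Units: mmol/gDW/h.
    """

    carbon_source: str = "C00031"  # D-glucose
    carbon_uptake_max: float = 10.0
    oxygen_uptake_max: float = 2.0
    free_exchanges: frozenset[str] = DEFAULT_FREE_EXCHANGES
    oxygen_id: str = "C00007"

    def __post_init__(self) -> None:
        if not self.carbon_uptake_max > 0:
            raise ValueError("carbon source uptake bound must be positive")
        if self.oxygen_uptake_max < 0:
            raise ValueError("oxygen uptake bound must be nonnegative")


@dataclass
class FluxModel:
    """Sparse LP data: S·v = 0, lb ≤ v ≤ ub, with named rows/columns."""

    row_ids: list[str]
    col_ids: list[str]
    S: sparse.csr_matrix
    lower: np.ndarray
    upper: np.ndarray
    biomass_col: str | None
    demand_col: str | None
    carbon_exchange_col: str | None
    col_kind: dict[str, str] = field(default_factory=dict)
    row_kegg: dict[str, str] = field(default_factory=dict)

    def col_index(self, col_id: str) -> int:
        return self.col_ids.index(col_id)

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.col_ids)


@dataclass
class FBAResult:
    """LP outcome: solver status, objective value, and the flux vector."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: pd.Series | None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _cytosol_representative(host: HostModel, kegg_id: str) -> str | None:
    """Model metabolite standing for ``kegg_id`` in the cytosol.

    Prefers a species tagged compartment 'c'; falls back to the
    lexicographically smallest matching species for determinism.
    """
    matches = sorted(
        m.model_id for m in host.metabolites.values() if m.kegg_id == kegg_id
    )
    if not matches:
        return None
    cyto = [m for m in matches if host.metabolites[m].compartment == "c"]
    return cyto[0] if cyto else matches[0]


def build_flux_model(
    host: HostModel,
    pathway: HeterologousPathway,
    db: ReactionDatabase,
    medium: MediumSpec,
    target: str,
    heterologous_bound: float = HETEROLOGOUS_BOUND,
) -> FluxModel:
    """Assemble the LP for a host augmented with a heterologous pathway.

    Heterologous reactions are wired to the host's cytosolic species
    through the KEGG mapping; compounds unknown to the host get fresh rows.
    A demand column exporting ``target`` is appended, and the medium policy
    is applied to the host's exchange bounds.
    """
    row_ids = list(host.metabolites)
    row_index = {m: i for i, m in enumerate(row_ids)}
    kegg_rows: dict[str, str] = {}
    for kegg in {m.kegg_id for m in host.metabolites.values() if m.kegg_id}:
        kegg_rows[kegg] = _cytosol_representative(host, kegg)

    col_ids: list[str] = []
    col_kind: dict[str, str] = {}
    lower: list[float] = []
    upper: list[float] = []
    data, rows, cols = [], [], []

    def add_col(cid, stoich, lb, ub, kind):
        j = len(col_ids)
        col_ids.append(cid)
        col_kind[cid] = kind
        lower.append(lb)
        upper.append(ub)
        for mid, coeff in stoich:
            rows.append(row_index[mid])
            cols.append(j)
            data.append(coeff)

    carbon_col = None
    for rid, rxn in host.reactions.items():
        lb, ub = rxn.lower_bound, rxn.upper_bound
        kind = "exchange" if rxn.is_exchange else "native"
        if rxn.is_exchange:
            mids = [m for m, _ in rxn.stoichiometry]
            kegg = host.metabolites[mids[0]].kegg_id if len(mids) == 1 else None
            # export-positive convention: negative flux = uptake
            if kegg == medium.carbon_source:
                lb = -medium.carbon_uptake_max
                carbon_col = rid
            elif kegg == medium.oxygen_id:
                lb = -medium.oxygen_uptake_max
            elif kegg in medium.free_exchanges:
                lb = -HETEROLOGOUS_BOUND
            else:
                lb = max(lb, 0.0)  # close uptake of everything else
        add_col(rid, rxn.stoichiometry, lb, ub, kind)

    def row_for(kegg_id: str) -> str:
        rep = kegg_rows.get(kegg_id)
        if rep is not None:
            return rep
        new_id = f"het:{kegg_id}"
        if new_id not in row_index:
            row_index[new_id] = len(row_ids)
            row_ids.append(new_id)
        kegg_rows[kegg_id] = new_id
        return new_id

    for rid, _direction in pathway.reactions:
        rxn = db.reactions[rid]
        stoich: dict[str, float] = {}
        for cid, coeff in rxn.substrates:
            mid = row_for(cid)
            stoich[mid] = stoich.get(mid, 0.0) - coeff
        for cid, coeff in rxn.products:
            mid = row_for(cid)
            stoich[mid] = stoich.get(mid, 0.0) + coeff
        add_col(
            f"HET_{rid}",
            tuple(sorted(stoich.items())),
            -heterologous_bound,
            heterologous_bound,
            "heterologous",
        )

    if target not in kegg_rows:
        native_rep = _cytosol_representative(host, target)
        if native_rep is None:
            raise KeyError(
                f"target {target!r} absent from both host and pathway compounds"
            )
        kegg_rows[target] = native_rep
    demand_col = f"DM_{target}"
    add_col(demand_col, ((kegg_rows[target], -1.0),), 0.0, heterologous_bound, "demand")

    row_kegg: dict[str, str] = {}
    for mid in row_ids:
        if mid.startswith("het:"):
            row_kegg[mid] = mid[4:]
        elif mid in host.metabolites and host.metabolites[mid].kegg_id:
            row_kegg[mid] = host.metabolites[mid].kegg_id

    S = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(row_ids), len(col_ids))
    )
    return FluxModel(
        row_ids=row_ids,
        col_ids=col_ids,
        S=S,
        lower=np.asarray(lower, dtype=float),
        upper=np.asarray(upper, dtype=float),
        biomass_col=host.biomass_reaction_id,
        demand_col=demand_col,
        carbon_exchange_col=carbon_col,
        col_kind=col_kind,
        row_kegg=row_kegg,
    )


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def maximize(fm: FluxModel, objective_column: str) -> FBAResult:
    """Maximize one flux column subject to S·v = 0 and the bounds."""
    j = fm.col_index(objective_column)
    c = np.zeros(fm.n_cols)
    c[j] = -1.0  # linprog minimizes
    res = linprog(
        c,
        A_eq=fm.S,
        b_eq=np.zeros(fm.n_rows),
        bounds=list(zip(fm.lower, fm.upper)),
        method="highs",
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FBAResult(status=status, objective_value=None, fluxes=None)
    fluxes = pd.Series(res.x, index=fm.col_ids)
    return FBAResult(status="optimal", objective_value=float(fluxes.iloc[j]), fluxes=fluxes)


def producibility(fm: FluxModel, zero_tol: float = ZERO_FLUX_TOL) -> tuple[bool, float]:
    """Maximum target demand flux, thresholded into a producible flag.

    A nonnative metabolite is non-producible under the medium when its
    maximum production flux is (numerically) zero.
    """
    res = maximize(fm, fm.demand_col)
    if not res.optimal:
        return False, 0.0
    return res.objective_value > zero_tol, res.objective_value


def biomass_coupled_production(
    fm: FluxModel, fix_rtol: float = BIOMASS_FIX_RTOL
) -> tuple[FBAResult, FBAResult]:
    """Lexicographic biomass-then-target optimization.

    Stage 1 maximizes the biomass column; stage 2 fixes the biomass flux at
    its optimum (within relative tolerance ``fix_rtol``) and maximizes the
    target demand, resolving degenerate growth optima into a unique
    production flux.  Returns (stage1, stage2) results; a non-optimal
    stage 1 is propagated with stage 2 untouched.
    """
    if fm.biomass_col is None:
        raise ValueError("flux model has no biomass column")
    stage1 = maximize(fm, fm.biomass_col)
    if not stage1.optimal:
        return stage1, FBAResult(status=stage1.status, objective_value=None, fluxes=None)
    j = fm.col_index(fm.biomass_col)
    mu = stage1.objective_value
    fixed = replace(fm, lower=fm.lower.copy(), upper=fm.upper.copy())
    # pin the biomass flux exactly; fall back to a tiny relative band only
    # if the solver rejects the degenerate equality
    fixed.lower[j] = fixed.upper[j] = mu
    stage2 = maximize(fixed, fm.demand_col)
    if not stage2.optimal:
        slack = abs(mu) * fix_rtol
        fixed.lower[j] = mu - slack
        fixed.upper[j] = mu + slack
        stage2 = maximize(fixed, fm.demand_col)
    return stage1, stage2


def yield_percent(
    result: FBAResult, fm: FluxModel, threshold: float = 1.0
) -> tuple[float, bool]:
    """Molar production yield on the carbon source, as a percentage.

    yield = 100 × (target demand flux) / (carbon source uptake flux),
    mol/mol.  A target counts as *produced* when the yield reaches the
    threshold (default 1 %).  Zero uptake with positive demand is flagged
    inconsistent.
    """
    if not result.optimal:
        return 0.0, False
    demand = float(result.fluxes[fm.demand_col])
    uptake = -float(result.fluxes[fm.carbon_exchange_col])
    if uptake <= ZERO_FLUX_TOL:
        if demand > ZERO_FLUX_TOL:
            raise ValueError(
                "positive target demand with zero carbon uptake: inconsistent flux state"
            )
        return 0.0, False
    pct = 100.0 * demand / uptake
    if abs(pct) < 1e-9:
        pct = 0.0
    return pct, pct >= threshold


def steady_state_residual(fm: FluxModel, fluxes: pd.Series) -> float:
    """‖S·v‖∞ for a flux vector — the steady-state feasibility residual."""
    v = fluxes.reindex(fm.col_ids).to_numpy()
    return float(np.max(np.abs(fm.S @ v))) if fm.n_rows else 0.0
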