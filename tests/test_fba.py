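"""Flux balance analysis: closed-form toys, LP oracle agreement, and the
lexicographic biomass-then-target contract."""

import numpy as np
import pytest

from heteropath.expansion import backtrace, expand
from heteropath.fba import (
    MediumSpec,
    biomass_coupled_production,
    build_flux_model,
    maximize,
    producibility,
    steady_state_residual,
    yield_percent,
)
from heteropath.host_model import load_host_model, native_sets
from helpers import empty_pathway, vertex_enumeration_max


def _toy_fm(case):
    return build_flux_model(
        case.host, empty_pathway(case.target), case.db, case.medium, case.target
    )


class TestAnalyticToys:
    def test_linear_chain_demand_equals_uptake(self, fba_toys):
        fm = _toy_fm(fba_toys["chain"])
        res = maximize(fm, fm.demand_col)
        assert res.optimal
        assert res.objective_value == pytest.approx(10.0, abs=1e-8)
        pct, produced = yield_percent(res, fm)
        assert pct == pytest.approx(100.0, abs=1e-8) and produced

    def test_branch_demand_is_half_uptake(self, fba_toys):
        fm = _toy_fm(fba_toys["branch"])
        res = maximize(fm, fm.demand_col)
        assert res.objective_value == pytest.approx(5.0, abs=1e-8)
        pct, _ = yield_percent(res, fm)
        assert pct == pytest.approx(50.0, abs=1e-8)

    def test_closed_model_optimum_is_zero(self, fba_toys):
        fm = _toy_fm(fba_toys["chain"])
        j = fm.col_index("EX_A")
        fm.lower[j] = fm.upper[j] = 0.0
        res = maximize(fm, fm.demand_col)
        assert res.optimal
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("name", ["chain", "branch", "competition"])
    def test_agreement_with_vertex_enumeration_oracle(self, fba_toys, name):
        fm = _toy_fm(fba_toys[name])
        res = maximize(fm, fm.demand_col)
        assert res.objective_value == pytest.approx(
            vertex_enumeration_max(fm, fm.demand_col), abs=1e-8
        )

    def test_steady_state_residual_within_tolerance(self, fba_toys, table2_cases):
        for case in list(fba_toys.values()):
            fm = _toy_fm(case)
            res = maximize(fm, fm.demand_col)
            assert steady_state_residual(fm, res.fluxes) <= 1e-6
        for case in table2_cases.values():
            m0, r0 = native_sets(case.host)
            pw = backtrace(expand(m0, r0, case.db), case.target)
            fm = build_flux_model(case.host, pw, case.db, case.medium, case.target)
            res = maximize(fm, fm.demand_col)
            assert steady_state_residual(fm, res.fluxes) <= 1e-6
            assert np.all(res.fluxes.to_numpy() >= fm.lower - 1e-6)
            assert np.all(res.fluxes.to_numpy() <= fm.upper + 1e-6)


class TestLexicographic:
    def test_stage2_biomass_fixed_at_stage1_optimum(self, fba_toys, table2_cases):
        cases = [c for c in fba_toys.values() if c.host.biomass_reaction_id]
        cases += list(table2_cases.values())
        for case in cases:
            m0, r0 = native_sets(case.host)
            res = expand(m0, r0, case.db)
            pw = (
                backtrace(res, case.target)
                if case.target in res.producer_map
                else empty_pathway(case.target)
            )
            fm = build_flux_model(case.host, pw, case.db, case.medium, case.target)
            s1, s2 = biomass_coupled_production(fm)
            assert s1.optimal and s2.optimal
            b2 = float(s2.fluxes[fm.biomass_col])
            assert b2 == pytest.approx(s1.objective_value, rel=1e-6, abs=1e-9)

    def test_competition_toy_gives_zero_target_at_biomass_opt(self, fba_toys):
        fm = _toy_fm(fba_toys["competition"])
        s1, s2 = biomass_coupled_production(fm)
        assert s1.objective_value == pytest.approx(10.0, abs=1e-8)
        assert s2.objective_value == pytest.approx(0.0, abs=1e-8)

    def test_nadh_coupling_toy_gives_positive_target_at_biomass_opt(self, fba_toys):
        fm = _toy_fm(fba_toys["nadh_coupling"])
        s1, s2 = biomass_coupled_production(fm)
        assert s1.objective_value == pytest.approx(4.0, abs=1e-8)
        assert s2.objective_value == pytest.approx(16.0, abs=1e-8)
        assert s2.objective_value > 0


class TestProducibility:
    def test_disconnected_target_not_producible(self, tmp_path):
        p = tmp_path / "disc.tsv"
        p.write_text(
            "# metabolites\nmodel_id\tcompartment\tkegg_id\n"
            "A_e\te\tC90001\nA_c\tc\tC90001\nB_c\tc\tC90002\nT_c\tc\tC90011\n"
            "# reactions\nid\tequation\tlb\tub\tis_biomass\tis_exchange\n"
            "EX_A\tA_e <=>\t-10\t1000\t0\t1\n"
            "T_A\tA_e <=> A_c\t-1000\t1000\t0\t0\n"
            "SYN\tB_c <=> T_c\t-1000\t1000\t0\t0\n",
            encoding="utf-8",
        )
        host = load_host_model(p)
        from heteropath.reaction_db import ReactionDatabase

        medium = MediumSpec(carbon_source="C90001", oxygen_uptake_max=0.0)
        fm = build_flux_model(host, empty_pathway("C90011"), ReactionDatabase(), medium, "C90011")
        producible, flux = producibility(fm)
        assert not producible and flux == pytest.approx(0.0, abs=1e-8)
        # closing the carbon source keeps it non-producible (monotonicity)
        closed = build_flux_model(
            host, empty_pathway("C90011"), ReactionDatabase(),
            MediumSpec(carbon_source="C90001", carbon_uptake_max=1e-9, oxygen_uptake_max=0.0),
            "C90011",
        )
        assert not producibility(closed)[0]

    def test_table2_targets_producible_under_glucose(self, table2_cases):
        for case in table2_cases.values():
            m0, r0 = native_sets(case.host)
            pw = backtrace(expand(m0, r0, case.db), case.target)
            fm = build_flux_model(case.host, pw, case.db, case.medium, case.target)
            producible, flux = producibility(fm)
            assert producible and flux > 0

    def test_added_reaction_never_decreases_max_demand(self, table2_cases):
        case = table2_cases["pentanedione_cglut"]
        m0, r0 = native_sets(case.host)
        res = expand(m0, r0, case.db)
        # methylglyoxal is reachable with the dehydratase alone; adding the
        # dione-cleaving reaction must not reduce its maximum demand flux
        partial = backtrace(res, "C00546")
        full_pw = backtrace(res, case.target)
        fm_partial = build_flux_model(case.host, partial, case.db, case.medium, "C00546")
        fm_full = build_flux_model(case.host, full_pw, case.db, case.medium, "C00546")
        assert len(full_pw.reactions) > len(partial.reactions)
        v_partial = maximize(fm_partial, fm_partial.demand_col).objective_value
        v_full = maximize(fm_full, fm_full.demand_col).objective_value
        assert v_full >= v_partial - 1e-8


class TestStructure:
    def test_column_and_row_counts(self, table2_cases):
        for case in table2_cases.values():
            m0, r0 = native_sets(case.host)
            res = expand(m0, r0, case.db)
            pw = backtrace(res, case.target)
            fm = build_flux_model(case.host, pw, case.db, case.medium, case.target)
            assert fm.n_cols == len(case.host.reactions) + pw.n_reactions + 1
            n_new_compounds = len([r for r in fm.row_ids if r.startswith("het:")])
            assert fm.n_rows == len(case.host.metabolites) + n_new_compounds

    def test_empty_pathway_adds_only_demand(self, fba_toys):
        case = fba_toys["chain"]
        fm = _toy_fm(case)
        assert fm.n_cols == len(case.host.reactions) + 1
        assert fm.col_kind[fm.demand_col] == "demand"

    def test_single_heterologous_reaction_single_added_column(self, table2_cases):
        case = table2_cases["pentanedione_ecoli"]
        m0, r0 = native_sets(case.host)
        pw = backtrace(expand(m0, r0, case.db), case.target)
        fm = build_flux_model(case.host, pw, case.db, case.medium, case.target)
        het = [c for c, k in fm.col_kind.items() if k == "heterologous"]
        assert het == ["HET_PD1"]

    def test_target_absent_everywhere_raises(self, fba_toys):
        case = fba_toys["chain"]
        with pytest.raises(KeyError):
            build_flux_model(
                case.host, empty_pathway("C99999"), case.db, case.medium, "C99999"
            )


class TestYield:
    def test_yield_arithmetic(self, fba_toys):
        fm = _toy_fm(fba_toys["chain"])
        res = maximize(fm, fm.demand_col)
        fluxes = res.fluxes.copy()
        fluxes[fm.demand_col] = 0.05
        fluxes[fm.carbon_exchange_col] = -10.0
        from heteropath.fba import FBAResult

        pct, produced = yield_percent(FBAResult("optimal", 0.05, fluxes), fm)
        assert pct == pytest.approx(0.5) and not produced
        fluxes[fm.demand_col] = 10.0
        pct, produced = yield_percent(FBAResult("optimal", 10.0, fluxes), fm)
        assert pct == pytest.approx(100.0) and produced

    def test_zero_uptake_with_demand_is_flagged(self, fba_toys):
        fm = _toy_fm(fba_toys["chain"])
        res = maximize(fm, fm.demand_col)
        fluxes = res.fluxes.copy()
        fluxes[fm.carbon_exchange_col] = 0.0
        from heteropath.fba import FBAResult

        with pytest.raises(ValueError, match="inconsistent"):
            yield_percent(FBAResult("optimal", 10.0, fluxes), fm)


def test_cobra_cross_check_on_chain_toy(fba_toys):
    """Independent FBA route: the same chain LP built in cobrapy gives the
    same maximum demand flux."""
    cobra = pytest.importorskip("cobra")
    model = cobra.Model("chain")
    A = cobra.Metabolite("A_c")
    B = cobra.Metabolite("B_c")
    ex_a = cobra.Reaction("EX_A", lower_bound=-10, upper_bound=1000)
    ex_a.add_metabolites({A: -1})
    conv = cobra.Reaction("CONV", lower_bound=-1000, upper_bound=1000)
    conv.add_metabolites({A: -1, B: 1})
    dm = cobra.Reaction("DM_B", lower_bound=0, upper_bound=1000)
    dm.add_metabolites({B: -1})
    model.add_reactions([ex_a, conv, dm])
    model.objective = "DM_B"
    sol = model.optimize()
    fm = _toy_fm(fba_toys["chain"])
    ours = maximize(fm, fm.demand_col).objective_value
    assert ours == pytest.approx(sol.objective_value, abs=1e-8)
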