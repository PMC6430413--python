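import numpy as np
import pytest

from acetome.coupling_solve import (
    Affine,
    CouplingParams,
    MESolveError,
    assemble,
    feasible,
    instantiate,
    maximize_growth,
    me_problem_from_json,
    me_problem_to_json,
    protein_activity,
)
from acetome.netcore import solve_fba
from acetome.toyme import ToyConfig, build_toy_acetogen, set_uptake

from conftest import solve_me


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CouplingParams(unmodeled_fraction=1.0)
        with pytest.raises(ValueError):
            CouplingParams(keff_default=0.0)
        with pytest.raises(ValueError):
            CouplingParams(mu_min=1.0, mu_max=0.5)
        with pytest.raises(ValueError):
            CouplingParams(mu_tol=0.0)


class TestAffine:
    def test_evaluation_and_arithmetic(self):
        a = Affine(1.0, 2.0)
        assert a(0.0) == 1.0
        assert a(0.5) == 2.0
        assert (a + Affine(0.0, 1.0))(1.0) == 4.0
        assert a.scaled(2.0)(1.0) == 6.0
        assert Affine(3.0).is_constant


class TestAssemble:
    def test_dimensions_derived_from_inputs(self, toy_bundle, toy_params):
        net, annex = toy_bundle
        prob = assemble(net, annex, toy_params)
        n_split = sum(1 for r in net.reactions if min(r.lower_bound, 0.0) < 0)
        expected_vars = (
            len(net.reactions)
            + n_split
            + len(prob.expression_reactions)
            + len(annex.species)
        )
        assert prob.n_vars == expected_vars
        n_deg = sum(1 for e in prob.expression_reactions if e.kind == "degradation")
        n_cap = sum(1 for r in prob.rows if r.id.startswith("cap_"))
        expected_rows = (
            len(net.metabolites)
            + len(annex.species)
            + n_deg
            + n_cap
            + 4  # biomass dilution, protein mass, RNA mass, unmodeled ratio
            + 1  # membrane
        )
        assert len(prob.rows) == expected_rows

    def test_every_variable_constrained(self, toy_bundle, toy_params):
        net, annex = toy_bundle
        prob = assemble(net, annex, toy_params)
        seen = set()
        for row in prob.rows:
            seen.update(row.coeffs)
        assert {v.id for v in prob.variables} <= seen

    def test_all_coefficients_affine(self, toy_bundle, toy_params):
        net, annex = toy_bundle
        prob = assemble(net, annex, toy_params)
        for row in prob.rows:
            for aff in row.coeffs.values():
                assert isinstance(aff, Affine)

    def test_no_metal_columns_without_modifications(self, toy_params):
        cfg = ToyConfig(substrates=("fructose",), include_nickel=False)
        net, annex = build_toy_acetogen(cfg)
        for cx in annex.complexes:
            cx.modifications = []
        params = toy_params.with_overrides(unmodeled_fraction=0.0)
        prob = assemble(net, annex, params)
        metal_cols = [
            e.id
            for e in prob.expression_reactions
            if any(m in e.met_stoich for m in ("ni2_c", "fe2_c", "cobalt2_c", "mg2_c"))
        ]
        assert metal_cols == []

    def test_unresolved_complex_raises(self, toy_bundle, toy_params):
        net, annex = toy_bundle
        net = net.copy()
        net.reaction("CODH4").enzyme_complex_id = "cplx_ghost"
        from acetome.netcore import ValidationError

        with pytest.raises(ValidationError, match="cplx_ghost"):
            assemble(net, annex, toy_params)

    def test_huge_keff_drives_coupling_to_zero(self, toy_bundle, toy_params):
        net, annex = toy_bundle
        net = net.copy()
        for rxn in net.reactions:
            rxn.keff = 1e9
        prob = assemble(net, annex, toy_params)
        for row in prob.rows:
            if row.id == "cap_cplx_codh4":
                usages = [
                    aff.a for vid, aff in row.coeffs.items()
                    if not vid.startswith("conc_")
                ]
                assert max(abs(u) for u in usages) < 1e-11


class TestInstantiate:
    def test_mu_zero_drops_dilution(self, toy_bundle, toy_params):
        net, annex = toy_bundle
        prob = assemble(net, annex, toy_params)
        Aeq, beq, *_ = instantiate(prob, 0.0)
        # species balance rows lose their -mu*c dilution term at mu = 0
        eq_rows = [r for r in prob.rows if r.sense == "E"]
        i = next(i for i, r in enumerate(eq_rows) if r.id.startswith("spbal_"))
        row = Aeq[i].toarray().ravel()
        sid = eq_rows[i].id[len("spbal_"):]
        assert row[prob.conc_vars[sid]] == 0.0

    def test_reinstantiation_is_bit_identical(self, toy_bundle, toy_params):
        net, annex = toy_bundle
        prob = assemble(net, annex, toy_params)
        A1, b1, U1, u1, lo1, hi1 = instantiate(prob, 0.2)
        A2, b2, U2, u2, lo2, hi2 = instantiate(prob, 0.2)
        assert (A1 != A2).nnz == 0
        assert np.array_equal(b1, b2)
        assert np.array_equal(lo1, lo2) and np.array_equal(hi1, hi2)

    def test_negative_mu_rejected(self, toy_bundle, toy_params):
        net, annex = toy_bundle
        prob = assemble(net, annex, toy_params)
        with pytest.raises(ValueError):
            instantiate(prob, -0.1)


class TestFeasible:
    def test_open_substrate_feasible_at_zero(self, co20_solution):
        *_, prob = co20_solution
        assert feasible(prob, 0.0)

    def test_infeasible_beyond_any_supported_growth(self, co20_solution):
        *_, prob = co20_solution
        assert not feasible(prob, 1.9)

    def test_closed_exchanges_infeasible(self, toy_bundle, toy_params):
        net, annex = toy_bundle
        net = net.copy()
        for rxn in net.exchange_reactions():
            rxn.lower_bound = 0.0
        prob = assemble(net, annex, toy_params)
        assert not feasible(prob, 0.01)


class TestMaximizeGrowth:
    def test_bisection_matches_grid_scan(self, co20_solution):
        sol, *_, prob = co20_solution
        tol = prob.params.mu_tol
        # local fine-grid scan around mu*: feasible below, infeasible above
        assert feasible(prob, sol.mu_star - tol)
        assert not feasible(prob, sol.mu_star + 10 * tol)
        # coarse global scan confirms nothing above is feasible
        for mu in np.linspace(sol.mu_star + 0.01, prob.params.mu_max, 8):
            assert not feasible(prob, mu)

    def test_mu_max_too_small_raises(self, toy_bundle):
        net, annex = toy_bundle
        net = net.copy()
        set_uptake(net, "EX_co_e", 20)
        params = CouplingParams(mu_max=0.01)
        prob = assemble(net, annex, params)
        with pytest.raises(MESolveError, match="mu_max"):
            maximize_growth(prob, params)

    def test_m_model_limit_recovers_fba(self):
        cfg = ToyConfig(substrates=("co",))
        params = cfg.params.expression_free()
        cfg = ToyConfig(substrates=("co",), params=params)
        net, annex = build_toy_acetogen(cfg)
        set_uptake(net, "EX_co_e", 20)
        fba = solve_fba(net)
        prob = assemble(net, annex, params)
        sol = maximize_growth(prob, params)
        assert sol.mu_star == pytest.approx(fba.objective_value, rel=0.01)

    def test_carbon_closes_at_optimum(self, co20_solution):
        sol, net, _, prob = co20_solution
        carbon_in = -sum(
            sol.secretion[rid]
            * sum(
                net.metabolite(m).formula.get("C", 0)
                for m in net.reaction(rid).stoichiometry
            )
            for rid in sol.secretion
            if sol.secretion[rid] < 0
        )
        carbon_out = sum(
            sol.secretion[rid]
            * sum(
                net.metabolite(m).formula.get("C", 0)
                for m in net.reaction(rid).stoichiometry
            )
            for rid in sol.secretion
            if sol.secretion[rid] > 0
        )
        # growth stores carbon in biomass, so efflux must be below influx
        assert carbon_out <= carbon_in + 1e-6
        assert carbon_in > 0

    def test_metal_conservation(self, co20_solution):
        sol, net, annex, prob = co20_solution
        # nickel uptake equals nickel loaded into complexes (dilution sink)
        ni_uptake = -sol.secretion["EX_ni2_e"]
        assert ni_uptake > 0
        ni_demand = 0.0
        for cx in annex.complexes:
            for mod in cx.modifications:
                if mod.delivery == "hyp_nickel":
                    ni_demand += (
                        mod.count * sol.mu_star * sol.concentrations.get(cx.id, 0.0)
                    )
        assert ni_uptake == pytest.approx(ni_demand, rel=1e-4, abs=1e-10)


class TestProteomeFractions:
    def test_sum_to_one_and_unmodeled_at_f(self, co20_solution):
        sol, *_ = co20_solution
        total = sum(sol.proteome_fractions.values())
        assert total == pytest.approx(1.0, abs=1e-6)
        assert sol.proteome_fractions["protein_g_unmod"] == pytest.approx(
            0.35, abs=1e-3
        )

    def test_unmodeled_zero_at_f_zero(self, toy_bundle):
        params = CouplingParams(unmodeled_fraction=0.0)
        sol, *_ = solve_me(("co",), "EX_co_e", 20, params=params)
        assert sol.proteome_fractions.get("protein_g_unmod", 0.0) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_wlp_fraction_higher_on_co_than_fructose(
        self, co20_solution, fru8_solution
    ):
        wlp_genes = ["g_codh4", "g_fdh", "g_fthfl", "g_mthfr5", "g_metr", "g_acs"]
        co_sol, *_ = co20_solution
        fru_sol, *_ = fru8_solution
        co_frac = sum(co_sol.proteome_fractions.get(f"protein_{g}", 0) for g in wlp_genes)
        fru_frac = sum(
            fru_sol.proteome_fractions.get(f"protein_{g}", 0) for g in wlp_genes
        )
        assert co_frac > fru_frac


class TestProteinActivity:
    def test_identical_solutions_give_one(self, co20_solution):
        sol, *_ = co20_solution
        assert protein_activity(sol, sol, "CODH4") == pytest.approx(1.0)

    def test_zero_reference_zero_limited_gives_zero(self, co20_solution):
        sol, *_ = co20_solution
        assert protein_activity(sol, sol, "HYD2") == 0.0  # no flux on CO

    def test_mismatched_problems_rejected(self, co20_solution):
        sol, *_ = co20_solution
        import copy

        other = copy.deepcopy(sol)
        other.fluxes.pop("CODH4")
        with pytest.raises(MESolveError):
            protein_activity(other, sol, "PTA_ACK")


class TestSerialization:
    def test_round_trip_solves_identically(self, co20_solution):
        sol, *_, prob = co20_solution
        prob2 = me_problem_from_json(me_problem_to_json(prob))
        sol2 = maximize_growth(prob2)
        assert sol2.mu_star == pytest.approx(sol.mu_star, abs=1e-9)
        assert sol2.secretion["EX_ac_e"] == pytest.approx(
            sol.secretion["EX_ac_e"], abs=1e-6
        )

    def test_serialization_deterministic(self, co20_solution):
        *_, prob = co20_solution
        assert me_problem_to_json(prob) == me_problem_to_json(prob)


@pytest.mark.parametrize("seed", range(5))
def test_feasibility_monotone_in_mu(seed):
    from acetome.toyme import build_toy_acetogen

    rng = np.random.default_rng(seed)
    params = CouplingParams(
        keff_default=float(rng.uniform(5, 50)),
        k_rib=float(rng.uniform(6, 20)),
        k_rnap=float(rng.uniform(20, 80)),
        unmodeled_fraction=float(rng.uniform(0.0, 0.6)),
        gam=float(rng.uniform(20, 60)),
    )
    sub = ("co", "fructose")[int(rng.integers(0, 2))]
    cfg = ToyConfig(substrates=(sub,), params=params)
    net, annex = build_toy_acetogen(cfg)
    set_uptake(net, "EX_co_e" if sub == "co" else "EX_fru_e",
               float(rng.uniform(5, 25)))
    prob = assemble(net, annex, params)
    mus = sorted(rng.uniform(0.0, 1.0, size=5))
    states = [feasible(prob, mu) for mu in mus]
    # down-closed: once infeasible, never feasible again at higher mu
    seen_infeasible = False
    for state in states:
        if not state:
            seen_infeasible = True
        else:
            assert not seen_infeasible


class TestConditionalExpression:
    def test_thioredoxin_silent_when_sulfide_is_free(self, co20_solution):
        # nothing reduces thioredoxin when H2S can be imported directly
        sol, *_ = co20_solution
        assert abs(sol.fluxes["TRDR"]) < 1e-9
        assert sol.expression_fluxes.get("g_trx", 0.0) < 1e-9

    def test_thioredoxin_expressed_when_sulfate_is_only_sulfur(self):
        def sulfate_medium(net):
            net.reaction("EX_h2s_e").lower_bound = 0.0
            net.reaction("EX_so4_e").lower_bound = -1000.0

        sol, *_ = solve_me(("co",), "EX_co_e", 20, tweak=sulfate_medium)
        assert sol.status == "optimal"
        assert sol.fluxes["SO4R"] > 1e-9
        assert sol.expression_fluxes["g_trx"] > 1e-12


class TestMembraneConstraint:
    def test_toggle_removes_row(self, toy_bundle):
        net, annex = toy_bundle
        params = CouplingParams(membrane_constraint=False)
        prob = assemble(net, annex, params)
        assert not any(r.id == "membrane" for r in prob.rows)
        prob_on = assemble(net, annex, CouplingParams())
        assert any(r.id == "membrane" for r in prob_on.rows)

    def test_tight_gamma_restricts_growth(self, co20_solution):
        sol_ref, *_ = co20_solution
        params = CouplingParams(membrane_gamma=0.02)
        sol, *_ = solve_me(("co",), "EX_co_e", 20, params=params)
        assert sol.mu_star < sol_ref.mu_star - 1e-4
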