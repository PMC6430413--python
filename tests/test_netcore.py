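import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acetome.netcore import (
    FormatError,
    Metabolite,
    MetabolicReaction,
    Network,
    ValidationError,
    check_balances,
    format_formula,
    parse_formula,
    read_network,
    solve_fba,
    write_network,
)
from acetome.toyme import REACTION_TABLE, ToyConfig, build_toy_acetogen, set_uptake


def simple_network():
    net = Network()
    for mid, comp in (("A_e", "e"), ("A_c", "c"), ("B_c", "c"), ("B_e", "e")):
        net.add_metabolite(
            Metabolite(id=mid, formula={"C": 1}, charge=0, compartment=comp)
        )
    net.add_reaction(MetabolicReaction("EX_A_e", {"A_e": -1}, -10, 0))
    net.add_reaction(MetabolicReaction("At", {"A_e": -1, "A_c": 1}, 0, 1000))
    net.add_reaction(MetabolicReaction("conv", {"A_c": -1, "B_c": 1}, 0, 1000))
    net.add_reaction(MetabolicReaction("Bt", {"B_c": -1, "B_e": 1}, 0, 1000))
    net.add_reaction(MetabolicReaction("EX_B_e", {"B_e": -1}, 0, 1000))
    net.objective_id = "EX_B_e"
    return net


class TestModelInvariants:
    def test_compartment_suffix_enforced(self):
        met = Metabolite(id="x_c", compartment="e")
        with pytest.raises(ValidationError):
            met.validate()

    def test_negative_formula_count_rejected(self):
        met = Metabolite(id="x_c", formula={"C": -1})
        with pytest.raises(ValidationError):
            met.validate()

    def test_bounds_ordering(self):
        rxn = MetabolicReaction("r", {"x_c": -1}, lower_bound=1, upper_bound=-1)
        with pytest.raises(ValidationError):
            rxn.validate()

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ValidationError):
            MetabolicReaction("r", {}).validate()

    def test_keff_positive_when_enzyme_set(self):
        rxn = MetabolicReaction("r", {"x_c": -1}, enzyme_complex_id="cplx", keff=0)
        with pytest.raises(ValidationError):
            rxn.validate()

    def test_dangling_metabolite_reported_by_name(self):
        net = Network()
        net.add_metabolite(Metabolite(id="a_c"))
        net.add_reaction(MetabolicReaction("r", {"a_c": -1, "x_c": 1}))
        with pytest.raises(ValidationError, match="x_c"):
            net.validate()

    def test_exchange_touching_cytosol_rejected(self):
        net = Network()
        net.add_metabolite(Metabolite(id="a_c"))
        net.add_reaction(MetabolicReaction("EX_a_c", {"a_c": -1}))
        with pytest.raises(ValidationError, match="EX_a_c"):
            net.validate()


class TestFormulaRoundTrip:
    @pytest.mark.parametrize(
        "text", ["CO2", "C21H32N7O16P3S", "Fd", "TrxH2", "CfeCH3", ""]
    )
    def test_round_trip(self, text):
        assert format_formula(parse_formula(text)) == format_formula(
            parse_formula(format_formula(parse_formula(text)))
        )

    def test_bad_formula_raises(self):
        with pytest.raises(FormatError):
            parse_formula("2CO")


class TestIO:
    def test_minimal_round_trip(self, tmp_path):
        net = Network()
        net.add_metabolite(Metabolite("a_c", formula={"C": 1}, charge=0))
        net.add_metabolite(Metabolite("b_c", formula={"C": 1}, charge=0))
        net.add_reaction(MetabolicReaction("r", {"a_c": -1, "b_c": 1}, -5, 5))
        net.objective_id = "r"
        path = tmp_path / "m.json"
        write_network(net, path)
        back = read_network(path)
        assert len(back.metabolites) == 2
        assert len(back.reactions) == 1
        assert back.reaction("r").lower_bound == -5
        assert back.objective_id == "r"

    def test_toy_round_trip_field_by_field(self, tmp_path, toy_bundle):
        net, _ = toy_bundle
        path = tmp_path / "toy.json"
        write_network(net, path)
        back = read_network(path)
        assert [m.id for m in back.metabolites] == [m.id for m in net.metabolites]
        for r1 in net.reactions:
            r2 = back.reaction(r1.id)
            assert r2.stoichiometry == r1.stoichiometry
            assert r2.lower_bound == r1.lower_bound
            assert r2.upper_bound == r1.upper_bound
            assert r2.enzyme_complex_id == r1.enzyme_complex_id
            assert r2.keff == r1.keff
            assert r2.spontaneous == r1.spontaneous
        assert back.objective_id == net.objective_id

    def test_write_is_byte_deterministic(self, tmp_path, toy_bundle):
        net, _ = toy_bundle
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_network(net, p1)
        write_network(net, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip_bit_identical(self, tmp_path, toy_bundle):
        net, _ = toy_bundle
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_network(net, p1)
        write_network(read_network(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_toy_reaction_count_matches_table(self, toy_bundle):
        net, _ = toy_bundle
        n_exchanges = sum(1 for r in net.reactions if r.id.startswith("EX_"))
        n_demand = sum(1 for r in net.reactions if r.id.startswith("DM_"))
        expected = len(REACTION_TABLE) + n_exchanges + n_demand + 1  # + biomass
        assert len(net.reactions) == expected

    def test_empty_network_write_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_network(Network(), tmp_path / "x.json")

    def test_unknown_metabolite_reference_named(self, tmp_path):
        payload = {
            "id": "m",
            "metabolites": [{"id": "a_c", "compartment": "c"}],
            "reactions": [
                {
                    "id": "r",
                    "metabolites": {"a_c": -1, "x_c": 1},
                    "lower_bound": 0,
                    "upper_bound": 1,
                }
            ],
            "genes": [],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ValidationError, match="x_c"):
            read_network(path)

    def test_parse_error_names_location(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(FormatError, match="line"):
            read_network(path)

    def test_sbml_subset_read(self, tmp_path, toy_bundle):
        cobra = pytest.importorskip("cobra")
        from acetome.netcore.io import format_formula as ff

        net, _ = toy_bundle
        cmodel = cobra.Model("toy")
        for m in net.metabolites:
            cm = cobra.Metabolite(
                m.id, formula=ff(m.formula) or None, charge=m.charge,
                compartment=m.compartment,
            )
            cmodel.add_metabolites([cm])
        for r in net.reactions:
            cr = cobra.Reaction(r.id)
            cr.lower_bound, cr.upper_bound = r.lower_bound, r.upper_bound
            cmodel.add_reactions([cr])
            cr.add_metabolites(
                {cmodel.metabolites.get_by_id(k): v for k, v in r.stoichiometry.items()}
            )
        cmodel.objective = "BIOMASS"
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(cmodel, str(path))
        back = read_network(path, format="sbml-subset")
        assert len(back.reactions) == len(net.reactions)
        assert back.objective_id == "BIOMASS"
        net = net.copy()
        net.reaction("EX_co_e").lower_bound = -20.0
        back.reaction("EX_co_e").lower_bound = -20.0
        sol_a = solve_fba(net)
        sol_b = solve_fba(back)
        assert sol_a.objective_value == pytest.approx(sol_b.objective_value, rel=1e-6)


class TestCheckBalances:
    def _net(self, reactions, mets):
        net = Network()
        for mid, formula, charge in mets:
            net.add_metabolite(
                Metabolite(mid, formula=parse_formula(formula), charge=charge)
            )
        for rid, stoich in reactions:
            net.add_reaction(MetabolicReaction(rid, stoich, -10, 10))
        return net

    def test_balanced_water_gas_shift(self):
        # co + h2o -> co2 + h2 conserves C1 O2 H2 exactly
        net = self._net(
            [("shift", {"co_c": -1, "h2o_c": -1, "co2_c": 1, "h2_c": 1})],
            [("co_c", "CO", 0), ("h2o_c", "H2O", 0), ("co2_c", "CO2", 0),
             ("h2_c", "H2", 0)],
        )
        assert check_balances(net) == []

    def test_oxygen_imbalance_reported(self):
        net = self._net(
            [("bad", {"co_c": -1, "co2_c": 1})],
            [("co_c", "CO", 0), ("co2_c", "CO2", 0)],
        )
        assert check_balances(net) == [("bad", "O", 1.0)]

    def test_empty_network(self):
        assert check_balances(Network()) == []

    def test_missing_formula_is_explicit(self):
        net = self._net(
            [("r", {"a_c": -1, "b_c": 1})],
            [("a_c", "C", 0), ("b_c", "", 0)],
        )
        report = check_balances(net)
        assert len(report) == 1
        assert report[0][1] == "unbalanceable:b_c"

    def test_toy_model_fully_balanced(self, toy_bundle):
        net, _ = toy_bundle
        assert check_balances(net) == []


class TestSolveFBA:
    def test_linear_chain(self):
        sol = solve_fba(simple_network())
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_toy_co_acetate_yield(self):
        # overall 4 co + 2 h2o -> ac + 2 co2 fixes the maximum acetate
        # yield at 0.25 per CO
        cfg = ToyConfig(substrates=("co",))
        net, _ = build_toy_acetogen(cfg)
        set_uptake(net, "EX_co_e", 20)
        net.reaction("BIOMASS").upper_bound = 0.0
        sol = solve_fba(net, objective_id="EX_ac_e")
        assert sol.objective_value == pytest.approx(5.0, abs=1e-6)

    def test_all_exchanges_closed_gives_zero_growth(self, toy_bundle):
        net, _ = toy_bundle
        net = net.copy()
        for rxn in net.exchange_reactions():
            rxn.lower_bound = 0.0
        net.reaction("ATPM").lower_bound = 0.0  # no maintenance when starved
        sol = solve_fba(net)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_extra_bounds_must_lie_within_declared(self, toy_bundle):
        net, _ = toy_bundle
        with pytest.raises(ValidationError):
            solve_fba(net, extra_bounds={"EX_co_e": (-2000, 0)})

    def test_mass_balance_at_optimum(self, toy_bundle):
        net, _ = toy_bundle
        net = net.copy()
        net.reaction("EX_co_e").lower_bound = -20.0
        sol = solve_fba(net)
        balance = {m.id: 0.0 for m in net.metabolites}
        for rxn in net.reactions:
            v = sol.fluxes[rxn.id]
            for met, coef in rxn.stoichiometry.items():
                balance[met] += coef * v
        internal = [
            b for mid, b in balance.items()
            if not any(
                net.reaction(r.id).is_exchange and mid in r.stoichiometry
                for r in net.exchange_reactions()
            )
        ]
        assert max(abs(b) for b in internal) < 1e-8


# ---------------------------------------------------------------------------
def random_small_network(rng):
    """A random <=6-reaction network amenable to vertex enumeration."""
    n_mets = rng.integers(2, 4)
    mets = [f"m{i}_c" for i in range(n_mets)]
    net = Network()
    for mid in mets:
        net.add_metabolite(Metabolite(mid, formula={"C": 1}))
    net.add_metabolite(Metabolite("s_e", formula={"C": 1}, compartment="e"))
    net.add_reaction(
        MetabolicReaction("EX_s_e", {"s_e": -1}, -float(rng.integers(1, 10)), 0)
    )
    net.add_reaction(MetabolicReaction("upt", {"s_e": -1, mets[0]: 1}, 0, 1000))
    for i in range(int(rng.integers(1, 4))):
        a, b = rng.choice(len(mets), size=2, replace=False)
        net.add_reaction(
            MetabolicReaction(
                f"r{i}",
                {mets[a]: -1, mets[b]: 1},
                float(rng.choice([-1000.0, 0.0])),
                1000.0,
            )
        )
    sink = mets[int(rng.integers(0, n_mets))]
    net.add_reaction(MetabolicReaction("DM_sink_c", {sink: -1}, 0, 1000))
    net.objective_id = "DM_sink_c"
    return net


def vertex_enumeration_optimum(net):
    """Brute-force LP oracle: try every pattern of variables pinned at a
    bound (lo/hi/free), solving the remaining equality system exactly."""
    from acetome.netcore.fba import build_stoichiometric_matrix

    S, met_ids, rxn_ids = build_stoichiometric_matrix(net)
    S = S.toarray()
    n = len(rxn_ids)
    lo = np.array([r.lower_bound for r in net.reactions])
    hi = np.array([r.upper_bound for r in net.reactions])
    obj = np.zeros(n)
    obj[rxn_ids.index(net.objective_id)] = 1.0
    best = None
    for pattern in itertools.product((0, 1, 2), repeat=n):
        fixed = {}
        free = []
        for j, p in enumerate(pattern):
            if p == 0:
                fixed[j] = lo[j]
            elif p == 1:
                fixed[j] = hi[j]
            else:
                free.append(j)
        if any(not np.isfinite(v) for v in fixed.values()):
            continue
        if free:
            A = S[:, free]
            b = np.zeros(S.shape[0])
            for j, v in fixed.items():
                b -= S[:, j] * v
            x_free, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.linalg.norm(A @ x_free - b) > 1e-7:
                continue
        else:
            x_free = np.array([])
            if np.linalg.norm(sum(S[:, j] * v for j, v in fixed.items())) > 1e-7:
                continue
        x = np.zeros(n)
        for j, v in fixed.items():
            x[j] = v
        for k, j in enumerate(free):
            x[j] = x_free[k]
        if np.any(x < lo - 1e-7) or np.any(x > hi + 1e-7):
            continue
        val = obj @ x
        if best is None or val > best:
            best = val
    return best


@pytest.mark.parametrize("seed", range(12))
def test_fba_matches_vertex_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    net = random_small_network(rng)
    sol = solve_fba(net)
    oracle = vertex_enumeration_optimum(net)
    if sol.status == "optimal" and oracle is not None:
        assert sol.objective_value == pytest.approx(oracle, abs=1e-7)


@given(scale=st.floats(min_value=0.1, max_value=10.0))
@settings(max_examples=15, deadline=None)
def test_fba_scaling_invariance(scale):
    net = simple_network()
    base = solve_fba(net).objective_value
    for rxn in net.reactions:
        rxn.lower_bound *= scale
        rxn.upper_bound *= scale
    scaled = solve_fba(net).objective_value
    assert scaled == pytest.approx(base * scale, rel=1e-7)
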