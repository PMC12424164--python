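"""LP correctness against a brute-force vertex oracle, feasibility logic,
and grid scans."""

import numpy as np
import pytest

from commgem import CommunityCondition, ToyConfig, make_toy_triculture
from commgem.fba import check_feasibility, ratio_lattice, scan_feasibility, solve_fba
from commgem.model import MetabolicModel, Metabolite, Reaction
from commgem.scenarios import catabolic_mode, make_feed_bounds

from oracles import brute_force_fba


def chain_model():
    """A_in -> A -> B -> B_out, all bounds [0, 10]."""
    m = MetabolicModel(id="chain", compartments={"c": "cytosol", "e": "extra"})
    for mid, comp in [("A", "c"), ("B", "c")]:
        m.add_metabolite(Metabolite(id=mid, compartment=comp))
    m.add_reaction(Reaction(id="A_in", stoichiometry={"A": 1.0}, lower_bound=0, upper_bound=10))
    m.add_reaction(Reaction(id="AB", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0, upper_bound=10))
    m.add_reaction(Reaction(id="B_out", stoichiometry={"B": -1.0}, lower_bound=0, upper_bound=10))
    return m


def branched_model():
    """Diamond network with a branch split and asymmetric capacities."""
    m = MetabolicModel(id="branch", compartments={"c": "cytosol"})
    for mid in ("A", "B", "C"):
        m.add_metabolite(Metabolite(id=mid, compartment="c"))
    m.add_reaction(Reaction(id="in", stoichiometry={"A": 1.0}, lower_bound=0, upper_bound=8))
    m.add_reaction(Reaction(id="b1", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0, upper_bound=5))
    m.add_reaction(Reaction(id="b2", stoichiometry={"A": -1.0, "C": 1.0}, lower_bound=0, upper_bound=4))
    m.add_reaction(Reaction(id="mix", stoichiometry={"B": -1.0, "C": -1.0}, lower_bound=0, upper_bound=6))
    m.add_reaction(Reaction(id="out_c", stoichiometry={"C": -1.0}, lower_bound=-2, upper_bound=3))
    return m


def reversible_model():
    """Reversible internal conversion with negative lower bounds."""
    m = MetabolicModel(id="rev", compartments={"c": "cytosol"})
    for mid in ("A", "B"):
        m.add_metabolite(Metabolite(id=mid, compartment="c"))
    m.add_reaction(Reaction(id="inA", stoichiometry={"A": 1.0}, lower_bound=-3, upper_bound=7))
    m.add_reaction(Reaction(id="AB", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=-6, upper_bound=6))
    m.add_reaction(Reaction(id="outB", stoichiometry={"B": -1.0}, lower_bound=-4, upper_bound=5))
    return m


SMALL_FIXTURES = [
    (chain_model, "B_out", "max"),
    (chain_model, "A_in", "min"),
    (branched_model, "mix", "max"),
    (branched_model, "out_c", "min"),
    (reversible_model, "outB", "max"),
    (reversible_model, "inA", "min"),
]


class TestOracleEquivalence:
    @pytest.mark.parametrize("maker,objective,direction", SMALL_FIXTURES)
    def test_lp_matches_vertex_enumeration(self, maker, objective, direction):
        model = maker()
        S, _, rxn_ids = model.stoichiometric_matrix()
        lb, ub = model.bounds_arrays()
        c = np.zeros(len(rxn_ids))
        c[rxn_ids.index(objective)] = 1.0
        expected = brute_force_fba(S.toarray(), lb, ub, c, direction=direction)
        sol = solve_fba(model, objective_id=objective, direction=direction)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(expected, abs=1e-8)

    def test_chain_optimum_is_ten(self):
        sol = solve_fba(chain_model(), objective_id="B_out", direction="max")
        assert sol.objective_value == pytest.approx(10.0, abs=1e-8)
        assert sol.fluxes["A_in"] == pytest.approx(10.0, abs=1e-8)


def test_solution_satisfies_steady_state(triculture):
    cond = CommunityCondition(
        0.02, 0.32, {"aw": 0.5, "an": 0.3, "ck": 0.2},
        make_feed_bounds(triculture.model, co=(-3.5, -1.0)),
    )
    from commgem.community import apply_condition

    constrained = apply_condition(triculture, cond).model
    sol = solve_fba(constrained)
    assert sol.optimal
    S, _, rxn_ids = constrained.stoichiometric_matrix()
    v = np.array([sol.fluxes[r] for r in rxn_ids])
    assert np.abs(S @ v).max() < 1e-6
    lb, ub = constrained.bounds_arrays()
    assert np.all(v >= lb - 1e-6) and np.all(v <= ub + 1e-6)


def test_forced_infeasibility_reported():
    m = chain_model()
    m.reactions["A_in"].upper_bound = 1.0
    m.reactions["B_out"].lower_bound = 5.0  # demand above supply
    sol = solve_fba(m, objective_id="B_out")
    assert sol.status == "infeasible"
    assert sol.objective_value is None


def test_unbounded_reported():
    m = MetabolicModel(id="ub", compartments={"c": "cytosol"})
    m.add_metabolite(Metabolite(id="A", compartment="c"))
    m.add_reaction(Reaction(id="src", stoichiometry={"A": 1.0}, lower_bound=0,
                            upper_bound=np.inf))
    m.add_reaction(Reaction(id="sink", stoichiometry={"A": -1.0}, lower_bound=0,
                            upper_bound=np.inf))
    sol = solve_fba(m, objective_id="sink", direction="max")
    assert sol.status == "unbounded"


class TestZeroCO2Limit:
    """With CO and H2 uptake fixed at -3 and -6 mmol/h (CO/H2 = 0.5) and no
    maintenance, the electron balance admits only ethanol as product: 1.5
    mmol/h ethanol, zero CO2, zero acetate."""

    @pytest.fixture()
    def constrained(self, acetogen):
        model = catabolic_mode(acetogen)
        bounds = make_feed_bounds(model, co=(-3.0, -3.0), h2=(-6.0, -6.0))
        for rid, (lo, hi) in bounds.items():
            model.reactions[rid].lower_bound = lo
            model.reactions[rid].upper_bound = hi
        return model

    @pytest.mark.parametrize("direction", ["max", "min"])
    @pytest.mark.parametrize(
        "exchange,expected",
        [("EX_co2_e", 0.0), ("EX_ac_e", 0.0), ("EX_etoh_e", 1.5)],
    )
    def test_forced_fluxes(self, constrained, exchange, expected, direction):
        sol = solve_fba(constrained, objective_id=exchange, direction=direction)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)


def test_co_only_acetogenesis(acetogen):
    """4 CO + 2 H2O -> acetate + 2 CO2 when the ethanol branch is blocked."""
    model = catabolic_mode(acetogen)
    bounds = make_feed_bounds(model, co=(-4.0, -4.0))
    for rid, (lo, hi) in bounds.items():
        model.reactions[rid].lower_bound = lo
        model.reactions[rid].upper_bound = hi
    model.reactions["ETB"].upper_bound = 0.0
    for acid in ("ac", "prop", "but", "val", "cap"):
        model.reactions[f"RED_{acid}"].upper_bound = 0.0
    sol = solve_fba(model, objective_id="EX_ac_e", direction="max")
    assert sol.fluxes["EX_ac_e"] == pytest.approx(1.0, abs=1e-6)
    assert sol.fluxes["EX_co2_e"] == pytest.approx(2.0, abs=1e-6)


class TestFeasibility:
    FR = {"aw": 0.5, "an": 0.3, "ck": 0.2}

    def test_zero_growth_zero_ngam_always_feasible(self):
        cfg = ToyConfig(ngam_rate=0.0)
        cm = make_toy_triculture(cfg, self.FR)
        cond = CommunityCondition(
            0.0, 0.32, self.FR, make_feed_bounds(cm.model, co=(-3.5, 0.0))
        )
        assert check_feasibility(cm, cond)

    def test_carbon_limited_growth_infeasible(self, triculture):
        cond = CommunityCondition(
            0.2, 0.32, self.FR, make_feed_bounds(triculture.model, co=(-1.0, 0.0))
        )
        assert not check_feasibility(triculture, cond)

    def test_single_cell_grid_equals_check(self, triculture):
        feed = make_feed_bounds(triculture.model, co=(-3.5, -1.0))
        grid = scan_feasibility(triculture, [self.FR], [0.02], 0.32, feed)
        assert grid.feasible.shape == (1, 1)
        cond = CommunityCondition(0.02, 0.32, self.FR, feed)
        assert grid.feasible[0, 0] == check_feasibility(triculture, cond)

    def test_all_infeasible_configuration(self, triculture):
        # no carbon at all, but NGAM > 0: nothing can pay maintenance
        feed = make_feed_bounds(triculture.model, co=(0.0, 0.0))
        grid = scan_feasibility(triculture, [self.FR], [0.0, 0.02], 0.32, feed)
        assert not grid.feasible.any()

    def test_feasible_mu_set_is_interval(self, triculture):
        """Constraints are affine in mu, so the feasible growth-rate set per
        ratio row must be contiguous on any grid."""
        feed = make_feed_bounds(triculture.model, co=(-3.5, -1.0))
        mu_grid = [0.005, 0.01, 0.02, 0.03, 0.04, 0.06, 0.08]
        ratios = [
            {"aw": 0.8, "an": 0.1, "ck": 0.1},
            {"aw": 0.5, "an": 0.3, "ck": 0.2},
            {"aw": 0.3, "an": 0.4, "ck": 0.3},
        ]
        grid = scan_feasibility(triculture, ratios, mu_grid, 0.32, feed)
        for row in grid.feasible:
            idx = np.flatnonzero(row)
            if idx.size:
                assert np.array_equal(idx, np.arange(idx[0], idx[-1] + 1))
        # the scan found structure, not a degenerate all-true/all-false grid
        assert grid.feasible.any() and not grid.feasible.all()

    def test_grid_frame_shape(self, triculture):
        feed = make_feed_bounds(triculture.model, co=(-3.5, -1.0))
        ratios = ratio_lattice(["aw", "an", "ck"], step=0.2, min_fraction=0.2)
        grid = scan_feasibility(triculture, ratios, [0.01, 0.02], 0.32, feed)
        frame = grid.to_frame()
        assert len(frame) == len(ratios) * 2
        assert set(frame.columns) >= {"fraction_aw", "growth_rate", "feasible"}


def test_homogeneity_in_total_biomass(triculture):
    """Scaling X and all feed bounds by k scales the whole LP, hence every
    optimal flux, by k."""
    from commgem.community import apply_condition

    FR = {"aw": 0.5, "an": 0.3, "ck": 0.2}
    k = 2.0
    feed1 = make_feed_bounds(triculture.model, co=(-3.5, -1.0))
    feed2 = {
        rid: (lo * k if abs(lo) < 999 else lo, hi * k if abs(hi) < 999 else hi)
        for rid, (lo, hi) in feed1.items()
    }
    sol1 = solve_fba(apply_condition(triculture, CommunityCondition(0.02, 0.32, FR, feed1)).model)
    sol2 = solve_fba(apply_condition(triculture, CommunityCondition(0.02, 0.64, FR, feed2)).model)
    assert sol1.optimal and sol2.optimal
    assert sol2.objective_value == pytest.approx(k * sol1.objective_value, rel=1e-6)


def test_fba_optimum_matches_cobra(acetogen, tmp_path):
    """Independent cross-check: the same growth LP, exported via SBML and
    solved by cobra with its own (GLPK) backend, reaches the same optimum."""
    import cobra

    from commgem.sbml_io import write_sbml

    path = tmp_path / "acetogen.xml"
    write_sbml(acetogen, path)
    ref = cobra.io.read_sbml_model(str(path))
    ref.objective = "Biomass"
    for ex in ref.exchanges:
        ex.lower_bound = 0.0
    ref.reactions.EX_co_e.lower_bound = -10.0
    ref.reactions.EX_h2o_e.lower_bound = -1000.0
    ref.reactions.EX_nh3_e.lower_bound = -1000.0
    expected = ref.optimize().objective_value

    ours = acetogen.copy()
    for rid in ours.exchange_ids():
        ours.reactions[rid].lower_bound = 0.0
    ours.reactions["EX_co_e"].lower_bound = -10.0
    ours.reactions["EX_h2o_e"].lower_bound = -1000.0
    ours.reactions["EX_nh3_e"].lower_bound = -1000.0
    sol = solve_fba(ours, objective_id="Biomass")
    assert sol.objective_value == pytest.approx(expected, abs=1e-6)


def test_ratio_lattice_sums_to_one():
    combos = ratio_lattice(["a", "b", "c"], step=0.1)
    assert combos, "lattice must be nonempty"
    for combo in combos:
        assert sum(combo.values()) == pytest.approx(1.0)
        assert all(f >= 0.1 - 1e-12 for f in combo.values())
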