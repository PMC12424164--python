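"""Stoichiometric correctness of the synthetic species and the triculture."""

import numpy as np
import pytest

from commgem import (
    CommunityCondition,
    ToyConfig,
    make_toy_acetogen,
    make_toy_chain_elongator,
    make_toy_propionigen,
    make_toy_triculture,
    simulate_chemostat_observations,
)
from commgem.bioprocess import degree_of_reduction, steady_state_rate
from commgem.community import apply_condition
from commgem.fba import check_feasibility, solve_fba
from commgem.model import check_elemental_balance
from commgem.sampling import sample_fluxes
from commgem.scenarios import make_feed_bounds, phenotype_screen

CATABOLIC_EXCLUDE = ("Biomass", "DM_biomass", "NGAM")


class TestElementAndElectronClosure:
    @pytest.mark.parametrize("maker", [make_toy_acetogen, make_toy_propionigen,
                                       make_toy_chain_elongator])
    def test_all_reactions_element_balanced(self, maker):
        model = maker()
        report = check_elemental_balance(model)
        assert report.ok, report.imbalanced
        assert set(report.unchecked) <= {"DM_biomass"}

    def test_triculture_element_balanced(self, triculture):
        report = check_elemental_balance(triculture.model)
        assert report.ok, report.imbalanced

    @pytest.mark.parametrize("maker", [make_toy_acetogen, make_toy_propionigen,
                                       make_toy_chain_elongator])
    def test_degree_of_reduction_closure(self, maker):
        """Catabolic lumps conserve available electrons:
        sum over metabolites of gamma * coefficient = 0."""
        model = maker()
        for rid, rxn in model.reactions.items():
            if model.is_exchange(rid) or any(rid.startswith(p) for p in CATABOLIC_EXCLUDE):
                continue
            total = sum(
                degree_of_reduction(model.metabolites[met].formula) * coef
                for met, coef in rxn.stoichiometry.items()
            )
            assert total == pytest.approx(0.0, abs=1e-9), rid

    def test_elongation_gamma_arithmetic(self):
        # ethanol 12 + acetate 8 = butyrate 20; + propionate 14 = valerate 26
        assert degree_of_reduction({"C": 2, "H": 6, "O": 1}) == 12
        assert degree_of_reduction({"C": 4, "H": 8, "O": 2}) == 20
        assert degree_of_reduction({"C": 5, "H": 10, "O": 2}) == 26
        assert degree_of_reduction({"C": 7, "H": 14, "O": 2}) == 38


class TestGeneratorDeterminism:
    def test_same_config_identical_models(self):
        cfg = ToyConfig()
        assert make_toy_acetogen(cfg).equal_to(make_toy_acetogen(cfg))
        assert make_toy_triculture(cfg).model.equal_to(make_toy_triculture(cfg).model)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ToyConfig(ngam_rate=-1.0).validate()
        with pytest.raises(ValueError):
            ToyConfig(biomass_formula={"H": 2}).validate()

    def test_biomass_molar_mass(self):
        assert ToyConfig().biomass_molar_mass == pytest.approx(24.6, abs=0.1)


class TestPropionigen:
    def test_pure_acrylate_ratio_two_to_one(self, propionigen):
        """Acrylate lump alone: propionate:acetate = 2:1."""
        m = propionigen.copy()
        m.reactions["Biomass"].upper_bound = 0.0
        m.reactions["NGAM"].lower_bound = 0.0
        m.reactions["OXE"].upper_bound = 0.0
        for rid, (lo, hi) in make_feed_bounds(m).items():
            m.reactions[rid].lower_bound, m.reactions[rid].upper_bound = lo, hi
        m.reactions["EX_etoh_e"].lower_bound = -3.0
        m.reactions["EX_etoh_e"].upper_bound = -3.0
        m.reactions["EX_co2_e"].lower_bound = -10.0
        sol = solve_fba(m, objective_id="EX_prop_e", direction="max")
        assert sol.fluxes["EX_prop_e"] == pytest.approx(2.0, abs=1e-6)
        assert sol.fluxes["EX_ac_e"] == pytest.approx(1.0, abs=1e-6)

    def test_ratio_tunable_down_to_1p2(self, propionigen):
        """Mixing in ethanol oxidation lowers propionate:acetate; the 1.2:1
        operating point (ACR = 1, OXE = 2/3) is feasible."""
        m = propionigen.copy()
        m.reactions["Biomass"].upper_bound = 0.0
        m.reactions["NGAM"].lower_bound = 0.0
        for rid, (lo, hi) in make_feed_bounds(m).items():
            m.reactions[rid].lower_bound, m.reactions[rid].upper_bound = lo, hi
        m.reactions["EX_co2_e"].lower_bound = -10.0
        m.reactions["EX_etoh_e"].lower_bound = -20.0
        m.reactions["EX_prop_e"].lower_bound = 2.0
        m.reactions["EX_prop_e"].upper_bound = 2.0
        m.reactions["EX_ac_e"].lower_bound = 2.0 / 1.2
        m.reactions["EX_ac_e"].upper_bound = 2.0 / 1.2
        sol = solve_fba(m, objective_id="EX_etoh_e", direction="max")
        assert sol.optimal
        assert sol.fluxes["ACR"] == pytest.approx(1.0, abs=1e-6)
        assert sol.fluxes["OXE"] == pytest.approx(2.0 / 3.0, abs=1e-6)

    def test_no_ethanol_no_growth(self, propionigen):
        flags = phenotype_screen(propionigen, {"ethanol": "EX_etoh_e", "none": []})
        # CO2 alone cannot support it either: the screen closes all carbon
        assert flags["none"] is False


class TestChainElongator:
    def test_no_propionate_no_odd_chains(self, elongator):
        m = elongator.copy()
        for rid, (lo, hi) in make_feed_bounds(m).items():
            m.reactions[rid].lower_bound, m.reactions[rid].upper_bound = lo, hi
        m.reactions["EX_etoh_e"].lower_bound = -10.0
        m.reactions["EX_ac_e"].lower_bound = -10.0
        # propionate stays export-only (no uptake)
        for product in ("EX_val_e", "EX_hep_e"):
            sol = solve_fba(m, objective_id=product, direction="max")
            assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_butyrate_one_to_one_stoichiometry(self, elongator):
        m = elongator.copy()
        m.reactions["Biomass"].upper_bound = 0.0
        m.reactions["NGAM"].lower_bound = 0.0
        m.reactions["OXE"].upper_bound = 0.0
        for rid, (lo, hi) in make_feed_bounds(m).items():
            m.reactions[rid].lower_bound, m.reactions[rid].upper_bound = lo, hi
        m.reactions["EX_etoh_e"].lower_bound = -5.0
        m.reactions["EX_ac_e"].lower_bound = -5.0
        sol = solve_fba(m, objective_id="EX_but_e", direction="max")
        assert sol.fluxes["EX_but_e"] == pytest.approx(5.0, abs=1e-6)
        assert sol.fluxes["EX_etoh_e"] == pytest.approx(-5.0, abs=1e-6)
        assert sol.fluxes["EX_ac_e"] == pytest.approx(-5.0, abs=1e-6)

    def test_needs_ethanol_for_growth(self, elongator):
        flags = phenotype_screen(
            elongator,
            {"ethanol+acetate": ["EX_etoh_e", "EX_ac_e"], "acetate": "EX_ac_e"},
        )
        assert flags["ethanol+acetate"] is True
        assert flags["acetate"] is False


class TestTriculture:
    FR = {"aw": 0.5, "an": 0.3, "ck": 0.2}

    def test_constructive_invariants(self, triculture):
        assert set(triculture.species) == {"aw", "an", "ck"}
        triculture.model.validate()
        ex = triculture.model.reactions["EX_Biomass_e"]
        assert set(ex.stoichiometry) == {"biomass_aw", "biomass_an", "biomass_ck"}

    def test_feasible_on_co_feed(self, triculture):
        cond = CommunityCondition(
            0.02, 0.32, self.FR, make_feed_bounds(triculture.model, co=(-3.5, -1.0))
        )
        assert check_feasibility(triculture, cond)

    def test_valerate_reachable_with_all_species(self, triculture):
        cond = CommunityCondition(
            0.02, 0.32, self.FR, make_feed_bounds(triculture.model, co=(-3.5, -1.0))
        )
        constrained = apply_condition(triculture, cond).model
        sol = solve_fba(constrained, objective_id="EX_val_e", direction="max")
        assert sol.optimal and sol.objective_value > 0.01
        # and sampled solutions actually use the odd-chain route
        sr = sample_fluxes(constrained, n=200, seed=13, thinning=10)
        assert sr.column("EX_val_e").mean() > 0.0


class TestChemostatSimulator:
    def test_zero_noise_exact_recovery(self):
        records = simulate_chemostat_observations(
            {"acetate": 0.51}, dilution_rate=1 / 48, volume=0.4, noise_sd=0.0,
            seed=1, n_obs=3,
        )
        for rec in records:
            assert steady_state_rate(rec, "acetate") == pytest.approx(0.51, abs=1e-12)

    def test_expected_concentration_level(self):
        # 0.51 mmol/h at D = 1/48 h^-1, V = 0.4 L -> ~61 mM steady state
        records = simulate_chemostat_observations(
            {"acetate": 0.51}, 1 / 48, 0.4, noise_sd=0.0, n_obs=1
        )
        assert records[0].concentrations["acetate"] == pytest.approx(61.2, abs=0.1)

    def test_noisy_recovery_within_3_se(self):
        n = 20
        sd = 0.05
        records = simulate_chemostat_observations(
            {"acetate": 0.51}, 1 / 48, 0.4, noise_sd=sd, seed=123, n_obs=n
        )
        rates = np.array([steady_state_rate(r, "acetate") for r in records])
        se = 0.51 * sd / np.sqrt(n)
        assert abs(rates.mean() - 0.51) < 3 * se

    def test_seed_determinism(self):
        a = simulate_chemostat_observations({"x": 1.0}, 0.02, 0.4, 0.1, seed=7)
        b = simulate_chemostat_observations({"x": 1.0}, 0.02, 0.4, 0.1, seed=7)
        assert all(
            ra.concentrations == rb.concentrations for ra, rb in zip(a, b)
        )
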