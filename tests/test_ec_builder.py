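"""Enzyme-constraint construction: costs, splitting, pool behavior, calibration."""

import numpy as np
import pandas as pd
import pytest
from cobra import Metabolite, Model, Reaction

from hydrogem import synthetic_data
from hydrogem.ec_builder import (
    EcConfig,
    EnzymeEntry,
    EnzymeTable,
    ParameterizationError,
    build_ec_model,
    calibrate_kcat,
    enzyme_fraction_f,
    reaction_enzyme_cost,
    split_reversible,
)
from hydrogem.fba_engine import set_uptake


class TestSplitReversible:
    def test_reversible_becomes_two_halves(self, core_model):
        split = split_reversible(core_model)
        assert "PGI_fwd" in split.reactions and "PGI_rev" in split.reactions
        fwd = split.reactions.get_by_id("PGI_fwd")
        rev = split.reactions.get_by_id("PGI_rev")
        assert fwd.bounds == (0.0, 1000.0)
        assert rev.bounds == (0.0, 1000.0)
        stoich_f = {m.id: c for m, c in fwd.metabolites.items()}
        stoich_r = {m.id: c for m, c in rev.metabolites.items()}
        assert stoich_r == {k: -v for k, v in stoich_f.items()}
        assert split.notes["reversible_split"]["PGI_fwd"] == "PGI"

    def test_exchanges_exempt(self, core_model):
        split = split_reversible(core_model)
        assert "EX_glc__D_e" in split.reactions
        assert "EX_glc__D_e_fwd" not in split.reactions

    def test_irreversible_model_unchanged(self, chain_model):
        split = split_reversible(chain_model)
        assert {r.id for r in split.reactions} == {
            r.id for r in chain_model.reactions
        }

    def test_lp_equivalence(self, core_model):
        split = split_reversible(core_model)
        assert split.slim_optimize() == pytest.approx(
            core_model.slim_optimize(), abs=1e-9
        )


class TestReactionEnzymeCost:
    def test_single_gene_arithmetic(self):
        entries = {"a": EnzymeEntry("a", mw=40.0, kcat=100.0)}
        cost = reaction_enzyme_cost(None, "a", entries)
        assert cost == pytest.approx(40.0 / (100.0 * 3600.0))

    def test_complex_sums_mass_slowest_kcat(self):
        entries = {
            "a": EnzymeEntry("a", mw=30.0, subunit_count=2, kcat=80.0),
            "b": EnzymeEntry("b", mw=50.0, subunit_count=1, kcat=50.0),
        }
        cost = reaction_enzyme_cost(None, "a and b", entries)
        assert cost == pytest.approx((2 * 30.0 + 50.0) / (50.0 * 3600.0))

    def test_isozymes_take_cheapest_branch(self):
        entries = {
            "a": EnzymeEntry("a", mw=36.0, kcat=100.0),   # 1e-4
            "b": EnzymeEntry("b", mw=18.0, kcat=100.0),   # 5e-5
        }
        assert reaction_enzyme_cost(None, "a or b", entries) == pytest.approx(5e-5)

    def test_no_gpr_costs_nothing(self):
        assert reaction_enzyme_cost(None, "", {}) == 0.0

    def test_missing_kcat_names_gene(self):
        entries = {"a": EnzymeEntry("a", mw=40.0, kcat=None)}
        with pytest.raises(ParameterizationError, match="a"):
            reaction_enzyme_cost(None, "a", entries)


class TestEnzymeFraction:
    def test_all_genes_in_model(self):
        assert enzyme_fraction_f({"a": 2.0, "b": 3.0}, ["a", "b"]) == 1.0

    def test_half_weight(self):
        assert enzyme_fraction_f(
            {"a": 1.0, "ghost": 1.0}, ["a"]
        ) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_two_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        weights = {g: float(rng.uniform(0, 5)) for g in genes}
        model_genes = genes[:12]
        expected = sum(weights[g] for g in model_genes) / sum(weights.values())
        assert enzyme_fraction_f(weights, model_genes) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            enzyme_fraction_f({"a": 0.0}, ["a"])


def single_reaction_ec(pool: float, cost_kcat: float, mw: float):
    """One costed source->sink conversion; analytic max flux = pool / cost."""
    m = Model("one")
    a = Metabolite("a_c", formula="C", charge=0, compartment="c")
    b_e = Metabolite("b_e", formula="C", charge=0, compartment="e")
    src = Reaction("SRC", lower_bound=-1000.0, upper_bound=0.0)
    src.add_metabolites({a: -1})
    r = Reaction("R", lower_bound=0.0, upper_bound=1000.0)
    r.add_metabolites({a: -1, b_e: 1})
    r.gene_reaction_rule = "g1"
    ex = Reaction("EX_b_e", lower_bound=0.0, upper_bound=1000.0)
    ex.add_metabolites({b_e: -1})
    m.add_reactions([src, r, ex])
    m.objective = "EX_b_e"
    table = EnzymeTable(pd.DataFrame([
        {"gene_id": "g1", "reaction_id": "R", "direction": "fwd",
         "kcat_s": cost_kcat, "mw_kda": mw, "subunits": 1,
         "expression_weight": 1.0},
    ]))
    config = EcConfig(ptot=pool, f=1.0, sigma=1.0)
    return build_ec_model(m, table, config)


class TestBuildEcModel:
    def test_single_costed_reaction_analytic_bound(self):
        ec = single_reaction_ec(pool=0.2, cost_kcat=10.0, mw=72.0)
        cost = 72.0 / (10.0 * 3600.0)
        assert ec.enzyme_cost["R"] == pytest.approx(cost)
        assert ec.model.slim_optimize() == pytest.approx(0.2 / cost, rel=1e-6)

    def test_pool_to_infinity_recovers_gem(self, core_model, reference_ec):
        relaxed = reference_ec.copy()
        relaxed.model.reactions.PROT_POOL_supply.upper_bound = 1e7
        set_uptake(relaxed, 10.0)
        set_uptake(core_model, 10.0)
        assert relaxed.model.slim_optimize() == pytest.approx(
            core_model.slim_optimize(), rel=1e-6
        )

    @pytest.mark.parametrize("seed", [0, 3])
    def test_ec_growth_never_exceeds_gem(self, core_model, seed):
        table, config = synthetic_data.synth_enzyme_tables(core_model, seed)
        ec = build_ec_model(core_model, table, config)
        for uptake in (2.0, 10.0, 25.0):
            set_uptake(ec, uptake)
            set_uptake(core_model, uptake)
            mu_ec = ec.model.slim_optimize(error_value=0.0)
            mu_gem = core_model.slim_optimize(error_value=0.0)
            assert mu_ec <= mu_gem + 1e-6
        set_uptake(core_model, 10.0)

    def test_pool_constraint_active_at_saturating_optimum(self, reference_ec):
        ec = reference_ec.copy()
        set_uptake(ec, 30.0)  # deep in the saturated regime
        solution = ec.model.optimize()
        usage = sum(ec.enzyme_usage(solution.fluxes).values())
        assert usage == pytest.approx(ec.pool, abs=1e-6)

    def test_unit_audit(self):
        """(g/mmol)/(1/h) cost times (mmol/gDW/h) flux gives g/gDW."""
        entry = EnzymeEntry("g", mw=36.0, kcat=10.0)
        cost = reaction_enzyme_cost(None, "g", {"g": entry})  # g.h/mmol
        flux = 7.0  # mmol/gDW/h
        assert cost * flux == pytest.approx(36.0 / 36000.0 * 7.0)

    def test_growth_vs_uptake_saturates_while_gem_is_linear(
        self, core_model, reference_ec
    ):
        uptakes = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 14.0, 20.0, 28.0])
        mu_ec, mu_gem = [], []
        ec = reference_ec.copy()
        gem = core_model.copy()
        for u in uptakes:
            set_uptake(ec, u)
            set_uptake(gem, u)
            mu_ec.append(ec.model.slim_optimize())
            mu_gem.append(gem.slim_optimize())
        slopes_ec = np.diff(mu_ec) / np.diff(uptakes)
        slopes_gem = np.diff(mu_gem) / np.diff(uptakes)
        assert np.all(np.diff(slopes_ec) <= 1e-6)          # concave
        assert slopes_ec[-1] < 0.01 * slopes_ec[0]         # saturated
        assert np.allclose(slopes_gem, slopes_gem[0], atol=1e-6)  # linear


class TestCalibrateKcat:
    def test_matching_model_needs_no_adjustment(self, reference_ec):
        ec = reference_ec.copy()
        set_uptake(ec, 10.0)
        mu = ec.model.slim_optimize()
        calibrated = calibrate_kcat(ec, mu, 10.0)
        adjustments = [e for e in calibrated.calibration_log
                       if e["reaction_id"] is not None]
        assert adjustments == []

    def test_understated_bottleneck_recovered(self, core_model):
        table, config = synthetic_data.reference_enzyme_table(core_model)
        ec_ref = build_ec_model(core_model, table, config)
        set_uptake(ec_ref, 10.0)
        target = ec_ref.model.slim_optimize()
        # understate the growth-machinery kcat 10x: it dominates pool usage
        bad = table.with_kcat("BIOMASS", "fwd", None, 0.1)
        ec_bad = build_ec_model(core_model, bad, config)
        set_uptake(ec_bad, 10.0)
        assert ec_bad.model.slim_optimize() < 0.95 * target
        calibrated = calibrate_kcat(ec_bad, target, 10.0)
        adjusted = {e["reaction_id"] for e in calibrated.calibration_log
                    if e["reaction_id"]}
        assert "BIOMASS" in adjusted
        final = calibrated.model.slim_optimize()
        assert final >= 0.95 * target

    def test_adjustments_never_decrease_growth(self, core_model):
        table, config = synthetic_data.reference_enzyme_table(core_model)
        bad = table.with_kcat("BIOMASS", "fwd", None, 0.05)
        ec = build_ec_model(core_model, bad, config)
        set_uptake(ec, 10.0)
        calibrated = calibrate_kcat(ec, 1.0, 10.0, max_rounds=8)
        growths = [e["growth"] for e in calibrated.calibration_log
                   if e["reaction_id"] is not None]
        assert all(b >= a - 1e-9 for a, b in zip(growths, growths[1:]))
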