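"""Dilution selection and worklist planning."""

from itertools import chain, combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import plateplan as pp
from plateplan.planner import Constraints, InfeasibleSourceError, Stock, StockSet


class TestRequiredVolume:
    def test_dilution_arithmetic(self):
        assert pp.required_volume(0.4, 22.5, 200) == pytest.approx(3.5556, abs=1e-4)

    def test_undiluted_fill(self):
        assert pp.required_volume(5.0, 5.0, 200) == pytest.approx(200.0)

    def test_below_vmin_volume_is_still_computed(self):
        # feasibility filtering happens in feasible_sources, not here
        assert pp.required_volume(0.01, 4.0, 200) == pytest.approx(0.5)

    def test_infeasible_source(self):
        with pytest.raises(InfeasibleSourceError):
            pp.required_volume(10.0, 5.0, 200)

    @given(
        c_target=st.floats(0.01, 10),
        c_hi=st.floats(10, 1000),
        c_lo=st.floats(10, 1000),
    )
    def test_monotone_in_source_concentration(self, c_target, c_hi, c_lo):
        lo, hi = sorted((c_lo, c_hi))
        assert pp.required_volume(c_target, lo, 200) >= pp.required_volume(
            c_target, hi, 200
        )


class TestFeasibleSources:
    CONSTRAINTS = Constraints(v_min=1.0, v_max_frac=0.2)  # v_max = 40 uL at 200 uL
    LIGAND = Stock("L", 100.0, (50.0, 25.0, 11.5))

    def test_all_candidates_feasible(self):
        got = pp.feasible_sources(1.0, self.LIGAND, 200, self.CONSTRAINTS)
        assert got == [100.0, 50.0, 25.0, 11.5]

    def test_only_lowest_feasible(self):
        assert pp.feasible_sources(0.1, self.LIGAND, 200, self.CONSTRAINTS) == [11.5]

    def test_target_above_stock_infeasible(self):
        assert pp.feasible_sources(500.0, self.LIGAND, 200, self.CONSTRAINTS) == []

    def test_vmax_exemption_for_monomer(self):
        # 60 mM from 100 mM stock needs 120 uL > 40 uL cap; exempt passes
        assert pp.feasible_sources(60.0, self.LIGAND, 200, self.CONSTRAINTS) == []
        assert pp.feasible_sources(
            60.0, self.LIGAND, 200, self.CONSTRAINTS, exempt_vmax=True
        ) == [100.0]


def _ligand_recipes(targets_mM, reagents):
    """One recipe per ligand target; c_initiator is 5 mM so ratio = target/5."""
    return [
        pp.RecipeSpec(
            pp.MonomerComposition.equimolar([reagents["HEA"]]),
            reagents["MBiB"],
            {"Me6TREN": c / 5.0},
            dp=200,
            m_final=1.0,
            label=f"r{i}",
        )
        for i, c in enumerate(targets_mM)
    ]


def _support_stocks(ligand_stock):
    return StockSet(
        {
            "HEA": Stock("HEA", 8700.0),
            "MBiB": Stock("MBiB", 100.0),
            "Me6TREN": ligand_stock,
        }
    )


class TestSelectDilutions:
    CONSTRAINTS = Constraints(v_min=1.0, v_max_frac=0.2)

    def test_single_dilution_covers_three_targets(self, reagents):
        recipes = _ligand_recipes([1.0, 0.25, 0.1], reagents)
        stocks = _support_stocks(Stock("Me6TREN", 100.0, (50.0, 25.0, 11.5)))
        plan = pp.select_dilutions(recipes, stocks, self.CONSTRAINTS)
        assert plan.reagents["Me6TREN"].prepared == (11.5,)
        assert not plan.infeasible

    def test_stock_feasible_needs_no_dilution(self, reagents):
        recipes = _ligand_recipes([1.0], reagents)
        stocks = _support_stocks(Stock("Me6TREN", 100.0, (50.0, 25.0, 11.5)))
        plan = pp.select_dilutions(recipes, stocks, self.CONSTRAINTS)
        assert plan.reagents["Me6TREN"].prepared == ()
        assert plan.reagents["Me6TREN"].assignment["r0"] == 100.0

    def test_infeasible_target_reported_not_fatal(self, reagents):
        recipes = _ligand_recipes([0.05, 1.0], reagents)
        stocks = _support_stocks(Stock("Me6TREN", 100.0, (50.0, 25.0, 11.5)))
        plan = pp.select_dilutions(recipes, stocks, self.CONSTRAINTS)
        assert {inf.label for inf in plan.infeasible} == {"r0"}
        inf = plan.infeasible[0]
        assert inf.reagent == "Me6TREN" and inf.target_mM == pytest.approx(0.05)
        assert "v_min" in inf.reason
        assert plan.reagents["Me6TREN"].assignment["r1"] == 100.0

    def test_assignment_prefers_highest_feasible_conc(self, reagents):
        recipes = _ligand_recipes([1.0, 0.1], reagents)
        stocks = _support_stocks(Stock("Me6TREN", 100.0, (50.0, 25.0, 11.5)))
        plan = pp.select_dilutions(recipes, stocks, self.CONSTRAINTS)
        # 11.5 must be prepared for the 0.1 target; the 1.0 target still draws stock
        assert plan.reagents["Me6TREN"].assignment["r0"] == 100.0
        assert plan.reagents["Me6TREN"].assignment["r1"] == 11.5


def _brute_force_min_cover(targets, stock, v_total, constraints):
    """Independent oracle: powerset enumeration over allowed dilutions."""
    def feasible(c_t, c_s):
        if c_s < c_t:
            return False
        v = c_t * v_total / c_s
        return constraints.v_min <= v <= constraints.v_max_frac * v_total

    covered = [c for c in targets if any(feasible(c, s) for s in stock.candidates)]
    need = [c for c in covered if not feasible(c, stock.conc)]
    dil = stock.allowed_dilutions
    best = None
    for subset in chain.from_iterable(combinations(dil, k) for k in range(len(dil) + 1)):
        if all(any(feasible(c, s) for s in subset) for c in need):
            if best is None or len(subset) < len(best):
                best = subset
    return len(best) if best is not None else None


class TestCoverOptimality:
    def test_matches_powerset_enumeration_on_random_instances(self, reagents):
        rng = np.random.default_rng(2024)
        constraints = Constraints(v_min=1.0, v_max_frac=0.25)
        for _ in range(60):
            stock_conc = float(rng.uniform(20, 500))
            n_dil = int(rng.integers(0, 5))
            dilutions = tuple(float(stock_conc * rng.uniform(0.01, 0.9)) for _ in range(n_dil))
            stock = Stock("Me6TREN", stock_conc, dilutions)
            n_rec = int(rng.integers(1, 13))
            targets = [float(rng.uniform(0.01, stock_conc * 0.3)) for _ in range(n_rec)]
            recipes = _ligand_recipes(targets, reagents)
            plan = pp.select_dilutions(recipes, _support_stocks(stock), constraints)
            expected = _brute_force_min_cover(targets, stock, 200.0, constraints)
            got = len(plan.reagents["Me6TREN"].prepared) if "Me6TREN" in plan.reagents else 0
            assert got == expected or (expected is None and got == 0)


class TestDilutionPrep:
    def test_prep_ratio_arithmetic(self, reagents, bench_stocks):
        recipes = _ligand_recipes([0.1], reagents)
        stocks = _support_stocks(Stock("Me6TREN", 100.0, (11.5,)))
        plan = pp.select_dilutions(recipes, stocks, Constraints())
        steps = pp.dilution_prep_steps(
            plan, stocks, {("Me6TREN", 11.5): 885.0}, Constraints(), dead_volume=115.0
        )
        # 1000 uL of 11.5 mM from 100 mM: 115 stock + 885 solvent
        vols = {s.source_name: s.volume_uL for s in steps}
        assert vols["Me6TREN"] == pytest.approx(115.0)
        assert vols["DMSO"] == pytest.approx(885.0)

    def test_no_prep_when_stock_suffices(self, reagents):
        recipes = _ligand_recipes([1.0], reagents)
        stocks = _support_stocks(Stock("Me6TREN", 100.0, (50.0,)))
        plan = pp.select_dilutions(recipes, stocks, Constraints())
        assert pp.dilution_prep_steps(plan, stocks, {}) == []

    def test_prep_volume_covers_demand_plus_dead_volume(self, reagents):
        recipes = _ligand_recipes([1.0, 0.1], reagents)
        stocks = _support_stocks(Stock("Me6TREN", 100.0, (11.5,)))
        plan = pp.select_dilutions(recipes, stocks, Constraints(v_max_frac=0.2))
        demand = {("Me6TREN", 11.5): 17.4 + 1.74}
        steps = pp.dilution_prep_steps(plan, stocks, demand, dead_volume=50.0)
        total = sum(s.volume_uL for s in steps)
        assert total == pytest.approx(69.14, abs=0.01)


class TestPlanBatch:
    def test_standard_recipe_volumes(self, standard_recipe, bench_stocks):
        wl = pp.plan_batch([standard_recipe], bench_stocks)
        by_source = {
            s.source_name: s for s in wl.well_steps if s.step_type == "well_transfer"
        }
        assert by_source["CuBr2"].volume_uL == pytest.approx(3.56)
        assert by_source["Me6TREN"].volume_uL == pytest.approx(1.0)
        assert by_source["ZnTPP"].volume_uL == pytest.approx(2.0)
        assert by_source["ZnTPP"].source_conc_mM == 1.0  # from the prepared dilution
        assert not wl.diagnostics

    def test_volume_conservation_exact(self, standard_recipe, bench_stocks):
        wl = pp.plan_batch([standard_recipe], bench_stocks)
        assert wl.well_volumes() == {"A1": 200.0}

    def test_empty_batch(self, bench_stocks):
        wl = pp.plan_batch([], bench_stocks)
        assert wl.steps == [] and wl.plate == {}

    def test_deterministic_reruns(self, standard_recipe, bench_stocks):
        a = pp.plan_batch([standard_recipe], bench_stocks).to_frame()
        b = pp.plan_batch([standard_recipe], bench_stocks).to_frame()
        assert a.equals(b)

    def test_over_volume_reported(self, reagents, bench_stocks):
        # [M]_f = 5.5 M: monomer + initiator + reagents exceed the 200 uL well
        recipe = pp.RecipeSpec(
            pp.MonomerComposition.equimolar([reagents["HEA"]]),
            reagents["MBiB"],
            {"CuBr2": 0.05, "Me6TREN": 0.3, "EosinY": 0.005},
            dp=200,
            m_final=5.5,
            label="too_concentrated",
        )
        wl = pp.plan_batch([recipe], bench_stocks)
        assert "too_concentrated" in wl.infeasible_labels()
        assert wl.plate == {}

    def test_feasible_wells_proceed_alongside_infeasible(
        self, standard_recipe, reagents, bench_stocks
    ):
        bad = pp.RecipeSpec(
            standard_recipe.composition,
            reagents["MBiB"],
            {"CuBr2": 0.08, "Me6TREN": 0.2, "ZnTPP": 0.00001},
            dp=200,
            m_final=1.0,
            label="pc_too_dilute",
        )
        wl = pp.plan_batch([standard_recipe, bad], bench_stocks)
        assert wl.plate == {"A1": "acrylate_standard"}
        assert "pc_too_dilute" in wl.infeasible_labels()

    def test_mole_delivery_accuracy(self, standard_recipe, bench_stocks):
        """Delivered moles match targets within the rounding-quantum bound."""
        constraints = Constraints()
        wl = pp.plan_batch([standard_recipe], bench_stocks, constraints)
        targets = pp.target_concentrations(standard_recipe)
        for s in wl.well_steps:
            if s.step_type != "well_transfer":
                continue
            delivered = s.source_conc_mM * s.volume_uL / standard_recipe.v_total
            bound = constraints.quantum / standard_recipe.v_total * s.source_conc_mM
            assert abs(delivered - targets[s.source_name]) <= bound + 1e-12

    def test_plate_capacity_enforced(self, standard_recipe, bench_stocks):
        recipes = [
            pp.RecipeSpec(
                standard_recipe.composition,
                standard_recipe.initiator,
                standard_recipe.ratios,
                dp=200,
                m_final=1.0,
                label=f"r{i}",
            )
            for i in range(97)
        ]
        with pytest.raises(pp.PlanningError):
            pp.plan_batch(recipes, bench_stocks)

    def test_row_major_well_assignment(self, standard_recipe, bench_stocks):
        recipes = [
            pp.RecipeSpec(
                standard_recipe.composition,
                standard_recipe.initiator,
                standard_recipe.ratios,
                dp=200,
                m_final=1.0,
                label=f"r{i}",
            )
            for i in range(14)
        ]
        wl = pp.plan_batch(recipes, bench_stocks)
        wells = list(wl.plate)
        assert wells[:3] == ["A1", "A2", "A3"]
        assert wells[11:14] == ["A12", "B1", "B2"]


class TestStockValidation:
    def test_dilution_above_stock_rejected(self):
        with pytest.raises(pp.ValidationError):
            Stock("L", 100.0, (150.0,))

    def test_dilutions_sorted_descending(self):
        assert Stock("L", 100.0, (11.5, 50.0, 25.0)).allowed_dilutions == (50.0, 25.0, 11.5)
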