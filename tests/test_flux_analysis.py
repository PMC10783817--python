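"""FBA, FVA comparison protocol and the saturation statistic."""

import pytest

from ecflux import (
    InfeasibleError,
    UnboundedError,
    average_saturation,
    fba,
    fva,
    make_toy_ec_model,
)


class TestFba:
    def test_plain_toy_optimum(self, toy):
        assert fba(toy).objective_value == pytest.approx(20.0)

    def test_enzyme_bound_lowers_the_optimum(self, toy_p1):
        assert fba(toy_p1).objective_value == pytest.approx(12.0)

    def test_closed_exchanges_give_zero_optimum(self, toy):
        for rid in ("EX_A", "EX_B"):
            toy.model.reactions.get_by_id(rid).upper_bound = 0.0
        assert fba(toy).objective_value == pytest.approx(0.0)

    def test_infeasible_signaled_distinctly(self, toy):
        toy.model.reactions.EX_D.bounds = (50, 50)
        with pytest.raises(InfeasibleError):
            fba(toy)

    def test_unbounded_signaled_distinctly(self, toy):
        # two unbounded exchanges of A form an infinite-flux cycle
        inf = float("inf")
        ex = toy.model.reactions.EX_A
        ex.bounds = (-inf, inf)
        import cobra

        back = cobra.Reaction("EX_A_back")
        back.bounds = (-inf, inf)
        toy.model.add_reactions([back])
        back.add_metabolites({toy.model.metabolites.get_by_id("A"): 1})
        toy.model.objective = {ex: 1.0}
        with pytest.raises((UnboundedError, InfeasibleError)):
            fba(toy)

    def test_shadow_price_signals_the_binding_enzyme(self, toy_p1):
        sol = fba(toy_p1)
        # relaxing P1 by one unit raises D export by 4*kcat/... = 40
        assert sol.protein_reduced_costs["P1"] == pytest.approx(40.0)
        assert sol.protein_reduced_costs["P2"] == pytest.approx(0.0)

    def test_tightening_a_priced_enzyme_lowers_the_optimum(self, toy_p1):
        sol = fba(toy_p1)
        assert sol.protein_reduced_costs["P1"] > 0
        toy_p1.set_protein_bound("P1", 0.2)
        assert fba(toy_p1).objective_value < sol.objective_value


class TestFva:
    def test_fully_determined_fluxes_have_zero_intervals(self, toy_p1):
        res = fva(toy_p1)
        widths = res["maximum"] - res["minimum"]
        assert (widths.abs() < 1e-6).all()

    def test_objective_maximum_equals_the_fba_optimum(self, toy_p1):
        res = fva(toy_p1, ["EX_D"])
        assert res.loc["EX_D", "maximum"] == pytest.approx(12.0, abs=1e-6)

    def test_enzyme_bounds_nest_the_intervals(self):
        # same objective floor (D export >= 6) on both models: the EC
        # feasible set is a subset of the plain one, so intervals nest
        plain = make_toy_ec_model()
        plain.model.reactions.EX_D.lower_bound = 6.0
        tight_model = make_toy_ec_model(p1_concentration=0.3)
        tight_model.model.reactions.EX_D.lower_bound = 6.0
        free = fva(plain, objective_fraction=0.0)
        tight = fva(tight_model, objective_fraction=0.0)
        for rid in ("R1", "R2", "EX_A", "EX_B", "EX_D"):
            assert tight.loc[rid, "minimum"] >= free.loc[rid, "minimum"] - 1e-7
            assert tight.loc[rid, "maximum"] <= free.loc[rid, "maximum"] + 1e-7

    def test_blocked_reaction_interval_is_zero(self, toy):
        toy.model.reactions.R1.bounds = (0.0, 0.0)
        res = fva(toy, ["R1"])
        assert res.loc["R1", "minimum"] == pytest.approx(0.0)
        assert res.loc["R1", "maximum"] == pytest.approx(0.0)

    def test_fix_uptake_pins_the_exchange_at_minimal_consumption(self):
        # make the A supply an uptake-style exchange (negative flux)
        ec = make_toy_ec_model()
        import cobra

        a = ec.model.metabolites.get_by_id("A")
        ec.model.reactions.EX_A.bounds = (0, 0)
        up = cobra.Reaction("EX_A_up")
        up.bounds = (-10, 0)
        ec.model.add_reactions([up])
        up.add_metabolites({a: -1})
        res = fva(ec, ["EX_A_up"], fix_uptake="EX_A_up")
        assert res.loc["EX_A_up", "minimum"] == pytest.approx(-10.0)
        assert res.loc["EX_A_up", "maximum"] == pytest.approx(-10.0)

    def test_block_opposite_split_removes_spurious_two_way_flux(self):
        # an uncatalyzed split pair A <-> B with both halves open shows
        # spurious variability unless the counterpart is blocked
        import cobra

        m = cobra.Model("split")
        a = cobra.Metabolite("A", compartment="c")
        b = cobra.Metabolite("B", compartment="c")

        def add(rid, stoich, lb, ub):
            r = cobra.Reaction(rid)
            r.bounds = (lb, ub)
            m.add_reactions([r])
            r.add_metabolites(stoich)
            return r

        add("EX_A", {a: 1}, 0, 10)
        add("T1", {a: -1, b: 1}, 0, 1000)
        add("T1_REV", {b: -1, a: 1}, 0, 1000)
        add("EX_B", {b: -1}, 0, 1000)
        m.objective = "EX_B"
        from ecflux.ec_model import ECModel

        ec = ECModel(m)
        loose = fva(ec, ["T1"], objective_fraction=1.0)
        strict = fva(
            ec, ["T1"], objective_fraction=1.0, block_opposite_split=True
        )
        assert loose.loc["T1", "maximum"] > strict.loc["T1", "maximum"] + 1
        assert strict.loc["T1", "maximum"] == pytest.approx(10.0, abs=1e-6)

    def test_warm_started_scan_matches_a_fresh_model_per_reaction(self, toy_p1):
        # determinism: scanning twice gives identical tables
        first = fva(toy_p1)
        second = fva(toy_p1)
        assert (first == second).all().all()


class TestSaturation:
    def test_fully_used_enzyme_saturates_at_one(self, toy_p1):
        rep = average_saturation(toy_p1)
        assert rep.overall == pytest.approx(1.0)
        assert rep.active_only == pytest.approx(1.0)
        assert rep.n_bounded == 1

    def test_unused_enzyme_halves_the_overall_mean(self):
        # P2 measured but idle: bound D export low so R2 runs below P2's cap
        ec = make_toy_ec_model(p1_concentration=0.3, p2_concentration=0.15)
        sol = fba(ec)
        rep = average_saturation(ec, sol)
        # P1 fully used (ratio 1), P2 at supply 0.15 -> also at its bound
        assert rep.n_bounded == 2
        assert 0 < rep.overall <= 1

    def test_active_only_excludes_idle_enzymes(self):
        ec = make_toy_ec_model(p1_concentration=0.3, p2_concentration=0.15)
        # close R2 so P2 cannot be used at all
        ec.model.reactions.R2.bounds = (0, 0)
        ec.model.objective = "EX_B"  # some objective that still solves
        ec.model.reactions.EX_B.bounds = (-1000, 20)
        sol = fba(ec)
        rep = average_saturation(ec, sol)
        assert rep.n_active < rep.n_bounded
        assert rep.active_only >= rep.overall

    def test_no_bounded_enzyme_is_an_error(self, toy):
        with pytest.raises(ValueError, match="non-zero"):
            average_saturation(toy)
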