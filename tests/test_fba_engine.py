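"""LP engine: FBA correctness, FVA oracle agreement, envelopes, yields."""

import numpy as np
import pytest

from methyloflux import (
    PRODUCTS,
    build_core_model,
    compute_yield,
    flux_variability,
    production_envelope,
    solve_fba,
)
from methyloflux.fba import (
    InfeasibleModelError,
    UndefinedYieldError,
    steady_state_residual,
)
from methyloflux.model import FluxSolution


class TestSolveFba:
    def test_optimum_satisfies_steady_state_and_bounds(self, core_model):
        sol = solve_fba(core_model, objective="EX_mal_e", direction="maximize")
        assert sol.optimal
        assert steady_state_residual(core_model, sol) < 1e-6
        for rxn in core_model.reactions:
            v = sol.flux(rxn.id)
            assert rxn.lower_bound - 1e-9 <= v <= rxn.upper_bound + 1e-9

    def test_agreement_with_cobrapy_oracle(self, core_model):
        """Independent solver cross-check on the same LP."""
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("core")
        mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment[0])
                for m in core_model.metabolites}
        for rxn in core_model.reactions:
            cr = cobra.Reaction(rxn.id)
            cr.lower_bound, cr.upper_bound = rxn.lower_bound, rxn.upper_bound
            cm.add_reactions([cr])
            cr.add_metabolites({mets[mid]: c for mid, c in rxn.stoich.items()})
        cm.objective = "EX_mal_e"
        ours = solve_fba(core_model, objective="EX_mal_e",
                         direction="maximize", minimize_total_flux=False)
        theirs = cm.optimize()
        assert theirs.status == "optimal"
        assert ours.objective_value == pytest.approx(theirs.objective_value,
                                                     abs=1e-6)

    def test_all_exchanges_closed_gives_zero_vector(self, core_model):
        m = core_model.copy()
        for rxn in m.exchanges():
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
        sol = solve_fba(m, objective="EX_mal_e", direction="maximize")
        assert sol.optimal
        assert max(abs(v) for v in sol.fluxes.values()) < 1e-9

    def test_unattainable_forced_bound_is_infeasible(self, core_model):
        m = core_model.copy()
        # malate export can never exceed 2.5 at uptake 10
        m.reaction("MALt").lower_bound = 5.0
        sol = solve_fba(m, objective="EX_mal_e", direction="maximize")
        assert sol.status == "infeasible"
        assert sol.fluxes is None

    def test_unknown_objective_raises(self, core_model):
        with pytest.raises(KeyError):
            solve_fba(core_model, objective="NOT_A_REACTION")

    def test_representative_flux_vector_is_deterministic(self, core_model):
        a = solve_fba(core_model, objective="EX_mal_e", direction="maximize")
        b = solve_fba(core_model.copy(), objective="EX_mal_e",
                      direction="maximize")
        assert a.fluxes == b.fluxes

    def test_total_flux_minimization_preserves_objective(self, core_model):
        plain = solve_fba(core_model, objective="EX_mal_e",
                          direction="maximize", minimize_total_flux=False)
        pfba = solve_fba(core_model, objective="EX_mal_e",
                         direction="maximize", minimize_total_flux=True)
        assert pfba.objective_value == pytest.approx(plain.objective_value,
                                                     rel=1e-6)
        total = lambda s: sum(abs(v) for v in s.fluxes.values())
        assert total(pfba) <= total(plain) + 1e-6


class TestComputeYield:
    def test_yield_arithmetic(self):
        sol = FluxSolution(status="optimal", objective_value=2.5,
                           fluxes={"EX_p": 2.5, "EX_s": -10.0})
        assert compute_yield(sol, "EX_p", "EX_s") == pytest.approx(0.25)
        sol.fluxes.update({"EX_p": 1.0, "EX_s": -8.0})
        assert compute_yield(sol, "EX_p", "EX_s") == pytest.approx(0.125)
        sol.fluxes.update({"EX_p": 0.0})
        assert compute_yield(sol, "EX_p", "EX_s") == 0.0

    def test_zero_substrate_uptake_is_undefined(self):
        sol = FluxSolution(status="optimal", objective_value=0.0,
                           fluxes={"EX_p": 0.0, "EX_s": 0.0})
        with pytest.raises(UndefinedYieldError):
            compute_yield(sol, "EX_p", "EX_s")

    def test_yield_invariant_under_common_bound_scaling(self):
        for scale in (0.5, 1.0, 3.0):
            m = build_core_model(uptake=10 * scale)
            sol = solve_fba(m, objective="EX_mal_e", direction="maximize",
                            minimize_total_flux=False)
            y = compute_yield(sol, "EX_mal_e", "EX_meoh_e")
            assert y == pytest.approx(0.25, abs=1e-6)


class TestFluxVariability:
    @pytest.mark.parametrize("rid", ["AKGDH", "ICL", "MDHm", "EX_co2_e"])
    def test_agreement_with_two_solve_oracle(self, core_model, rid):
        lo, hi = flux_variability(core_model, rid)
        oracle_lo = solve_fba(core_model, objective=rid, direction="minimize",
                              minimize_total_flux=False).objective_value
        oracle_hi = solve_fba(core_model, objective=rid, direction="maximize",
                              minimize_total_flux=False).objective_value
        assert lo == pytest.approx(oracle_lo, abs=1e-7)
        assert hi == pytest.approx(oracle_hi, abs=1e-7)
        assert lo <= hi

    def test_dead_metabolite_exchange_pins_to_zero(self, core_model):
        m = core_model.copy()
        # cut the only producer of formaldehyde: its consumers must be silent
        m.reaction("AOX").upper_bound = 0.0
        lo, hi = flux_variability(m, "DAS")
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(0.0, abs=1e-9)

    def test_objective_fixing_narrows_range(self, core_model):
        m = core_model.copy()
        m.objective = ("EX_mal_e", "maximize")
        free_lo, free_hi = flux_variability(m, "FDH")
        fixed_lo, fixed_hi = flux_variability(m, "FDH",
                                              fix_objective_fraction=1.0)
        assert free_lo - 1e-7 <= fixed_lo and fixed_hi <= free_hi + 1e-7

    def test_strong_duality_refix(self, core_model):
        """Re-solving with the objective pinned at its optimum stays feasible."""
        sol = solve_fba(core_model, objective="EX_mal_e", direction="maximize")
        m = core_model.copy()
        rxn = m.reaction("EX_mal_e")
        rxn.lower_bound = sol.objective_value - 1e-9
        again = solve_fba(m, objective="EX_mal_e", direction="maximize",
                          minimize_total_flux=False)
        assert again.optimal


@pytest.fixture(scope="module")
def envelopes(core_model):
    return {name: production_envelope(core_model, name, n_points=11)
            for name in sorted(PRODUCTS)}


class TestProductionEnvelope:
    def test_zero_growth_point_is_unconstrained_maximum(self, envelopes):
        assert envelopes["malate"][0].max_yield == pytest.approx(0.25, abs=1e-6)

    @pytest.mark.parametrize("name", sorted(PRODUCTS))
    def test_full_growth_point_is_zero(self, envelopes, name):
        assert envelopes[name][-1].max_yield == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("name", sorted(PRODUCTS))
    def test_yields_non_increasing_in_growth(self, envelopes, name):
        ys = [p.max_yield for p in envelopes[name]]
        assert all(b <= a + 1e-7 for a, b in zip(ys, ys[1:]))

    def test_growth_fractions_cover_unit_interval(self, envelopes):
        fs = [p.growth_fraction for p in envelopes["malate"]]
        assert fs[0] == 0.0 and fs[-1] == 1.0
        assert np.all(np.diff(fs) > 0)

    def test_malate_envelope_steepest_in_yield_per_growth_rate(self, envelopes):
        def slope(points):
            return points[0].max_yield / points[-1].growth_rate

        assert slope(envelopes["malate"]) > slope(envelopes["acetone"]) \
            > slope(envelopes["isoprene"])

    def test_zero_growth_capacity_raises(self, core_model):
        m = core_model.copy()
        m.reaction("BIOMASS").upper_bound = 0.0
        with pytest.raises(InfeasibleModelError, match="envelope undefined"):
            production_envelope(m, "malate", n_points=3)
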