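"""Free energies, potentials, thresholds, windows, ladders and curves."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from syntherm import (
    Basis,
    ConditionSet,
    Reaction,
    Species,
    SyntrophyWindow,
    aom_h2_ceiling,
    couple_reactions,
    delta_g_prime,
    energy_ladder,
    h2_threshold,
    henry_convert,
    profile_curve,
    redox_potential,
    syntrophy_window,
)
from syntherm.constants import HENRY_H2, R_KJ
from syntherm.synthetic import GeneratorConfig, random_scenarios

from conftest import analytic_h2_threshold_standard, bisect_h2


class TestDeltaGPrime:
    def test_standard_state_returns_dg0_exactly(self, bundle, standard):
        for rid in ("sulfate_reduction", "aom", "pce_dechlorination"):
            rxn = bundle.reaction(rid)
            res = delta_g_prime(rxn, standard)
            assert res.dg_prime_reaction == rxn.dg0_prime_reaction

    @pytest.mark.parametrize(
        "rid, expected",
        [("aom_sulfate", -5.0), ("aom_pce", -574.0)],
    )
    def test_environmental_free_energies_match_print(
        self, bundle, table3_env, rid, expected
    ):
        res = delta_g_prime(bundle.reaction(rid), table3_env)
        assert round(res.dg_prime_per_reference, 1) == expected

    def test_normalisation_bases_are_consistent(self, bundle, table3_env, standard):
        for rid, rxn in bundle.reactions.items():
            conds = table3_env if rid.startswith("aom_") else standard
            res = delta_g_prime(rxn, conds)
            n = float(rxn.n_electrons)
            assert res.dg_prime_per_electron * n == pytest.approx(
                res.dg_prime_reaction, rel=1e-12
            )
            if rxn.electron_acceptor is not None:
                nu = abs(float(rxn.coefficient(rxn.electron_acceptor)))
                assert res.dg_prime_per_acceptor * nu == pytest.approx(
                    res.dg_prime_reaction, rel=1e-12
                )

    def test_reversal_antisymmetry(self, bundle, table3_env):
        for rid in ("aom_sulfate", "aom_pce", "aom_dca"):
            rxn = bundle.reaction(rid)
            fwd = delta_g_prime(rxn, table3_env).dg_prime_reaction
            rev = delta_g_prime(rxn.reverse(), table3_env).dg_prime_reaction
            assert rev == pytest.approx(-fwd, rel=1e-12)
            assert redox_potential(rxn.reverse()) == pytest.approx(
                -redox_potential(rxn), rel=1e-12
            )

    def test_coupling_additivity(self, bundle, table3_env):
        env = table3_env.with_activity("H2", 1e-6)
        aom = bundle.reaction("aom")
        half = bundle.reaction("half_tce")
        coupled = couple_reactions(aom, 1, half, 4)
        assert delta_g_prime(coupled, env).dg_prime_reaction == pytest.approx(
            delta_g_prime(aom, env).dg_prime_reaction
            + 4 * delta_g_prime(half, env).dg_prime_reaction,
            rel=1e-9,
        )


class TestRedoxPotential:
    @pytest.mark.parametrize(
        "rid, volts",
        [
            ("nitrate_reduction", 0.82),
            ("pce_dechlorination", 0.90),
            ("aom", -0.18),
        ],
    )
    def test_standard_potentials_match_print(self, bundle, rid, volts):
        assert round(redox_potential(bundle.reaction(rid)), 2) == volts

    def test_zero_free_energy_gives_zero_volts(self):
        a = Species("A", "aq")
        b = Species("B", "aq")
        rxn = Reaction("null", {a: Fraction(-1), b: Fraction(1)},
                       dg0_prime=0.0, reference_species="A", n_electrons=2)
        assert redox_potential(rxn) == 0.0

    def test_missing_electron_count_rejected(self):
        a = Species("A", "aq")
        rxn = Reaction("no_n", {a: Fraction(-1)}, dg0_prime=-5.0,
                       reference_species="A")
        with pytest.raises(ValueError, match="n_electrons"):
            redox_potential(rxn)


class TestHenryConversion:
    H2 = Species("H2", "g", henry_constant=HENRY_H2)

    def test_one_atmosphere_of_hydrogen(self):
        molar = henry_convert(self.H2, 1.0, "atm_to_M")
        assert molar == pytest.approx(7.90e-4, rel=1e-3)

    def test_zero_maps_to_zero(self):
        assert henry_convert(self.H2, 0.0, "atm_to_M") == 0.0
        assert henry_convert(self.H2, 0.0, "M_to_atm") == 0.0

    def test_roundtrip(self):
        x = 0.123
        back = henry_convert(
            self.H2, henry_convert(self.H2, x, "atm_to_M"), "M_to_atm"
        )
        assert back == pytest.approx(x, rel=1e-12)

    def test_species_without_constant_rejected(self):
        with pytest.raises(ValueError, match="Henry"):
            henry_convert(Species("H2S", "aq"), 1.0, "atm_to_M")


class TestH2Threshold:
    def test_balanced_synthetic_reaction_thresholds_at_one_atmosphere(self):
        a = Species("A", "aq")
        b = Species("B", "aq")
        h2 = Species("H2", "g", henry_constant=HENRY_H2)
        rxn = Reaction("unit", {a: Fraction(-1), h2: Fraction(-1), b: Fraction(1)},
                       dg0_prime=-10.0, reference_species="H2",
                       electron_donor="H2", n_electrons=2)
        conds = ConditionSet(activities={"A": 1.0, "B": 1.0})
        res = h2_threshold(rxn, conds, dg_min=-10.0, basis=Basis.H2)
        assert res.h2_atm == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("rid", ["methanogenesis", "sulfate_reduction"])
    def test_standard_thresholds_match_bisection_oracle(
        self, bundle, standard, rid
    ):
        rxn = bundle.reaction(rid)
        res = h2_threshold(rxn, standard, dg_min=-10.0, basis=Basis.H2)
        oracle = bisect_h2(rxn, standard, dg_min=-10.0, basis=Basis.H2)
        assert res.h2_atm == pytest.approx(oracle, rel=1e-9)
        analytic = analytic_h2_threshold_standard(
            rxn.dg0_prime_reaction / abs(float(rxn.coefficient("H2"))), -10.0
        )
        assert res.h2_atm == pytest.approx(analytic, rel=1e-12)

    def test_methanogenesis_threshold_magnitudes(self, bundle, standard):
        res = h2_threshold(bundle.reaction("methanogenesis"), standard)
        assert res.h2_atm == pytest.approx(6.6e-5, rel=0.02)
        assert res.h2_molar == pytest.approx(5.2e-8, rel=0.02)

    def test_threshold_satisfies_its_own_contract(self, bundle, fig2_env):
        # evaluating dG' at the threshold recovers dg_min on the basis
        for rid in ("sulfate_reduction", "nitrate_reduction", "iron_reduction"):
            rxn = bundle.reaction(rid)
            for basis in (Basis.H2, Basis.REACTION, Basis.ACCEPTOR):
                res = h2_threshold(rxn, fig2_env, dg_min=-10.0, basis=basis)
                at = delta_g_prime(
                    rxn, fig2_env.with_activity("H2", res.h2_atm)
                )
                value = {
                    Basis.H2: at.dg_prime_reaction
                    / abs(float(rxn.coefficient("H2"))),
                    Basis.REACTION: at.dg_prime_reaction,
                    Basis.ACCEPTOR: at.dg_prime_per_acceptor,
                }[basis]
                assert abs(value - (-10.0)) < 1e-9

    def test_molar_value_is_henry_conversion_of_pressure(self, bundle, standard):
        res = h2_threshold(bundle.reaction("sulfate_reduction"), standard)
        h2 = bundle.registry["H2"]
        assert res.h2_molar == henry_convert(h2, res.h2_atm, "atm_to_M")

    def test_reaction_without_hydrogen_rejected(self, bundle, table3_env):
        with pytest.raises(ValueError, match="H2"):
            h2_threshold(bundle.reaction("aom_sulfate"), table3_env)

    def test_hydrogen_producer_rejected(self, bundle, standard):
        with pytest.raises(ValueError, match="produces"):
            h2_threshold(bundle.reaction("aom"), standard)


class TestAomCeiling:
    def test_degenerate_ceiling_is_one_atmosphere(self):
        conds = ConditionSet(activities={"CH4": 0.5, "HCO3-": 0.5})
        res = aom_h2_ceiling(conds, dg_min=135.4)
        assert res.h2_atm == pytest.approx(1.0, rel=1e-12)

    def test_environmental_ceiling_matches_bisection_oracle(self, bundle):
        conds = ConditionSet(activities={"CH4": 2.14, "HCO3-": 2.02e-2})
        res = aom_h2_ceiling(conds, dg_min=-10.0)
        oracle = bisect_h2(bundle.reaction("aom"), conds, dg_min=-10.0,
                           basis=Basis.REFERENCE)
        assert res.h2_atm == pytest.approx(oracle, rel=1e-9)

    def test_ceiling_increases_with_methane(self):
        base = {"HCO3-": 2.02e-2}
        ceilings = [
            aom_h2_ceiling(
                ConditionSet(activities={"CH4": a, **base}), dg_min=-10.0
            ).h2_atm
            for a in (0.1, 1.0, 2.14, 10.0)
        ]
        assert ceilings == sorted(ceilings)

    def test_missing_methane_activity_rejected(self):
        with pytest.raises(ValueError, match="CH4"):
            aom_h2_ceiling(ConditionSet(activities={"HCO3-": 1e-2}))


class TestSyntrophyWindow:
    def test_dechlorination_partner_is_feasible(self, bundle, fig2_env):
        win = syntrophy_window(
            bundle.reaction("pce_dechlorination"), fig2_env, dg_min=-10.0
        )
        assert win.feasible
        # dechlorination keeps H2 many orders below the methane ceiling
        assert win.floor_h2 < win.ceiling_h2 * 1e-10

    def test_endergonic_consumer_is_infeasible(self, bundle, fig2_env):
        rxn = bundle.reaction("pce_dechlorination")
        endergonic = Reaction(
            id="uphill", stoichiometry=rxn.stoichiometry, dg0_prime=+100.0,
            reference_species=rxn.reference_species, electron_donor="H2",
            electron_acceptor=rxn.electron_acceptor, n_electrons=rxn.n_electrons,
        )
        win = syntrophy_window(endergonic, fig2_env, dg_min=-10.0)
        assert not win.feasible

    def test_zero_width_window_is_feasible(self):
        win = SyntrophyWindow(floor_h2=1e-9, ceiling_h2=1e-9, dg_min=-10.0)
        assert win.feasible


class TestEnergyLadder:
    def test_per_electron_ladder_under_standard_conditions(self, bundle, standard):
        ids = [
            "acetogenesis", "methanogenesis", "sulfate_reduction",
            "iron_reduction", "nitrate_reduction", "pce_dechlorination",
        ]
        ladder = energy_ladder(
            [bundle.reaction(r) for r in ids], standard, basis=Basis.ELECTRON
        )
        assert [rid for rid, _ in ladder] == [
            "pce_dechlorination", "nitrate_reduction", "iron_reduction",
            "sulfate_reduction", "methanogenesis", "acetogenesis",
        ]
        printed = [-86.7, -79.0, -22.3, -19.0, -16.9, -13.0]
        assert [round(v, 1) for _, v in ladder] == printed

    def test_singleton_ladder(self, bundle, standard):
        ladder = energy_ladder([bundle.reaction("aom")], standard,
                               basis=Basis.ELECTRON)
        assert len(ladder) == 1 and ladder[0][0] == "aom"

    def test_ties_break_by_identifier(self, bundle, standard):
        rxn = bundle.reaction("sulfate_reduction")
        twin = Reaction(id="a_twin", stoichiometry=rxn.stoichiometry,
                        dg0_prime=rxn.dg0_prime,
                        reference_species=rxn.reference_species,
                        electron_acceptor=rxn.electron_acceptor,
                        n_electrons=rxn.n_electrons)
        ladder = energy_ladder([rxn, twin], standard, basis=Basis.ELECTRON)
        assert [rid for rid, _ in ladder] == ["a_twin", "sulfate_reduction"]

    def test_empty_reactions_are_excluded(self, bundle, standard):
        empty = couple_reactions(bundle.reaction("aom"), 1,
                                 bundle.reaction("methanogenesis"), 1)
        ladder = energy_ladder([bundle.reaction("aom"), empty], standard,
                               basis=Basis.REFERENCE)
        assert [rid for rid, _ in ladder] == ["aom"]


class TestProfileCurve:
    def test_consumer_curve_crosses_threshold_at_closed_form(
        self, bundle, fig2_env
    ):
        rxn = bundle.reaction("sulfate_reduction")
        thr = h2_threshold(rxn, fig2_env, dg_min=-10.0, basis=Basis.ACCEPTOR)
        grid = np.logspace(
            math.log10(thr.h2_molar) - 1, math.log10(thr.h2_molar) + 1, 201
        )
        curve = profile_curve(rxn, fig2_env, grid, basis=Basis.ACCEPTOR)
        # interpolate the -10 kJ crossing; must sit within one grid step
        crossing = np.interp(-10.0, curve["dg_prime"][::-1],
                             curve["h2_molar"][::-1])
        step = grid[1] / grid[0]
        assert thr.h2_molar / step <= crossing <= thr.h2_molar * step

    def test_single_point_equals_direct_evaluation(self, bundle, fig2_env):
        rxn = bundle.reaction("nitrate_reduction")
        curve = profile_curve(rxn, fig2_env, [1e-8], basis=Basis.ACCEPTOR)
        direct = delta_g_prime(rxn, fig2_env.with_activity(
            "H2", float(curve["h2_atm"].iloc[0])))
        assert curve["dg_prime"].iloc[0] == direct.dg_prime_per_acceptor

    def test_consumer_decreasing_and_producer_increasing(self, bundle, fig2_env):
        grid = np.logspace(-10, -4, 20)
        consumer = profile_curve(bundle.reaction("sulfate_reduction"),
                                 fig2_env, grid, basis=Basis.ACCEPTOR)
        producer = profile_curve(bundle.reaction("aom"), fig2_env, grid,
                                 basis=Basis.REFERENCE)
        assert consumer["dg_prime"].is_monotonic_decreasing
        assert producer["dg_prime"].is_monotonic_increasing

    def test_reversing_the_reaction_negates_the_curve(self, bundle, fig2_env):
        grid = np.logspace(-9, -5, 10)
        rxn = bundle.reaction("methanogenesis")
        fwd = profile_curve(rxn, fig2_env, grid, basis=Basis.REACTION)
        rev = profile_curve(rxn.reverse(), fig2_env, grid, basis=Basis.REACTION)
        assert np.allclose(rev["dg_prime"], -fwd["dg_prime"], rtol=1e-12)

    @pytest.mark.parametrize("grid", [[0.0, 1e-6], [1e-6, 1e-7], [-1e-6]])
    def test_bad_grids_rejected(self, bundle, fig2_env, grid):
        with pytest.raises(ValueError):
            profile_curve(bundle.reaction("sulfate_reduction"), fig2_env, grid)


class TestOracleEquivalence:
    def test_closed_form_matches_bisection_on_random_scenarios(self):
        config = GeneratorConfig(seed=20260925)
        for reaction, conditions in random_scenarios(config, 200):
            closed = h2_threshold(reaction, conditions, dg_min=-10.0,
                                  basis=Basis.H2)
            oracle = bisect_h2(reaction, conditions, dg_min=-10.0,
                               basis=Basis.H2, lo=-250.0, hi=120.0)
            assert closed.h2_atm == pytest.approx(oracle, rel=1e-9)
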