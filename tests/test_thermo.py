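"""Gibbs-energy evaluation: conventions, additivity, ATP driving forces."""

import math

import numpy as np
import pytest

from ncrfit import thermo
from ncrfit.routes import RouteBasis
from ncrfit.thermo import (
    MissingConstantError,
    ThermoContext,
    atp_driving_force,
    catabolic_gibbs_energy,
    reaction_energy,
    reference_atp_reactions,
    respiratory_partition,
)


class TestContext:
    def test_decade_shift_is_rt_ln10(self, ctx):
        assert ctx.decade_shift() == pytest.approx(5.708, abs=5e-4)

    def test_positive_parameters_enforced(self):
        with pytest.raises(ValueError):
            ThermoContext(temperature=-1)
        with pytest.raises(ValueError):
            ThermoContext(concentration=0.0)


class TestReactionEnergy:
    def test_null_reaction_is_zero(self, ctx, constants):
        assert reaction_energy({}, ctx, constants).value == 0.0

    def test_net_one_solute_at_1mM(self, registry, ctx, constants):
        """A net +1 solute reaction gains RT ln(1e-3) = -17.12 kJ/mol."""
        # glucose -> 2 lactate: net +1 solute
        stoich = {
            registry.species("glucose"): -1.0,
            registry.species("lactate"): 2.0,
        }
        result = reaction_energy(stoich, ctx, constants)
        assert result.value - result.standard == pytest.approx(
            ctx.RT * math.log(1e-3), abs=1e-9
        )

    def test_water_carries_no_concentration_term(self, registry, ctx, constants):
        stoich = {  # combustion: net solutes -1, water +6 excluded
            registry.species("glucose"): -1.0,
            registry.species("O2"): -6.0,
            registry.species("CO2"): 6.0,
            registry.species("H2O"): 6.0,
        }
        result = reaction_energy(stoich, ctx, constants)
        assert result.value - result.standard == pytest.approx(
            -ctx.RT * math.log(1e-3), abs=1e-9
        )

    def test_unbalanced_input_rejected(self, registry, ctx, constants):
        with pytest.raises(ValueError, match="balanced"):
            reaction_energy(
                {registry.species("glucose"): -1.0, registry.species("CO2"): 6.0},
                ctx, constants,
            )

    def test_missing_constant_names_species(self, ctx, constants):
        from ncrfit.stoichiometry import ElementalComposition, Species

        comp = ElementalComposition.from_formula("C8H10N4O2")
        x = Species("caffeine", comp)
        y = Species("caffeine_isomer", comp)
        with pytest.raises(MissingConstantError, match="caffeine"):
            reaction_energy({x: -1.0, y: 1.0}, ctx, constants)

    def test_biomass_rejected(self, registry, ctx, constants):
        bio = registry.biomass_species("CH2O")
        with pytest.raises(ValueError, match="biomass"):
            reaction_energy({bio: 1.0, registry.species("glucose"): -1 / 6}, ctx, constants)

    def test_temperature_note_flagged(self, registry, constants):
        ctx_hot = ThermoContext(temperature=310.15)
        stoich = {
            registry.species("glucose"): -1.0,
            registry.species("lactate"): 2.0,
        }
        result = reaction_energy(stoich, ctx_hot, constants)
        assert any("298.15" in note for note in result.notes)


class TestCatabolicGibbsEnergy:
    def test_linearity_in_stoichiometry(self, registry, ctx, constants):
        route = registry.respiration_route("glucose")
        one = catabolic_gibbs_energy(route.stoich, ctx, constants).value
        double = catabolic_gibbs_energy(route.scaled(2.0), ctx, constants).value
        assert double == pytest.approx(2 * one, rel=1e-12)

    def test_scaled_respiration_ncr(self, registry, ctx, constants):
        route = registry.respiration_route("glucose")
        scaled = catabolic_gibbs_energy(route.scaled(0.95), ctx, constants).value
        per_cmol = catabolic_gibbs_energy(route.stoich, ctx, constants).value
        assert scaled == pytest.approx(0.95 * per_cmol, rel=1e-12)
        # complete oxidation of glucose dissipates roughly 490 kJ per C-mol
        assert per_cmol == pytest.approx(-485.6, abs=5.0)


class TestRespiratoryPartition:
    def _basis(self, registry):
        return RouteBasis([
            registry.anabolic_route("glucose", "CH1.8O0.5N0.2"),
            registry.respiration_route("glucose"),
            registry.build_product_route("glucose", "ethanol"),
        ])

    def test_hess_additivity(self, registry, ctx, constants):
        basis = self._basis(registry)
        alpha = {"anabolic": 1.0, "glucose_respiration": 0.7,
                 "glucose_to_ethanol": 2.0}
        total, resp, non_resp = respiratory_partition(alpha, basis, ctx, constants)
        assert resp + non_resp == pytest.approx(total, abs=1e-9)
        e_resp = reaction_energy(
            registry.respiration_route("glucose").to_moles(), ctx, constants
        ).value
        assert resp == pytest.approx(0.7 * e_resp, rel=1e-12)

    def test_respiration_only_fit(self, registry, ctx, constants):
        basis = RouteBasis([
            registry.anabolic_route("glucose", "CH1.8O0.5N0.2"),
            registry.respiration_route("glucose"),
        ])
        total, resp, non_resp = respiratory_partition(
            {"anabolic": 1.0, "glucose_respiration": 0.7}, basis, ctx, constants
        )
        assert resp == pytest.approx(total)
        assert non_resp == pytest.approx(0.0, abs=1e-12)

    def test_anaerobic_fit_zero_respiratory(self, registry, ctx, constants):
        basis = RouteBasis([
            registry.anabolic_route("glucose", "CH1.8O0.5N0.2", aerobic=False),
            registry.build_product_route("glucose", "ethanol"),
        ])
        total, resp, non_resp = respiratory_partition(
            {"anabolic": 1.0, "glucose_to_ethanol": 5.0}, basis, ctx, constants
        )
        assert resp == 0.0
        assert non_resp == pytest.approx(total)


class TestAtpDrivingForce:
    def test_reference_reactions_against_printed_values(self, registry, ctx, constants):
        """Six classical lumped pathways at 1 mM biochemical standard state."""
        expected = {
            "L. lactis mixed-acid fermentation": -43.8,
            "L. lactis homolactic fermentation": -59.4,
            "S. cerevisiae respiration (36 ATP)": -38.2,
            "S. cerevisiae ethanol fermentation": -93.9,
            "E. coli respiration (28 ATP)": -61.6,
            "E. coli acetate overflow": -198.7,
        }
        for rec in reference_atp_reactions(registry):
            value = atp_driving_force(rec["stoichiometry"], ctx, constants)
            assert value == pytest.approx(expected[rec["name"]], abs=3.0), rec["name"]

    def test_intensive_under_scaling(self, registry, ctx, constants):
        rec = reference_atp_reactions(registry)[0]
        doubled = {sp: 2 * c for sp, c in rec["stoichiometry"].items()}
        assert atp_driving_force(doubled, ctx, constants) == pytest.approx(
            atp_driving_force(rec["stoichiometry"], ctx, constants), rel=1e-12
        )

    def test_zero_atp_rejected(self, registry, ctx, constants):
        stoich = {
            registry.species("glucose"): -1.0,
            registry.species("lactate"): 2.0,
        }
        with pytest.raises(ValueError, match="ATP"):
            atp_driving_force(stoich, ctx, constants)


class TestParseReaction:
    def test_combustion_string(self, registry, ctx, constants):
        stoich = thermo.parse_reaction(
            "glucose + 6 O2 -> 6 CO2 + 6 H2O", registry
        )
        result = reaction_energy(stoich, ctx, constants)
        assert result.standard == pytest.approx(-2930.5, abs=1e-6)

    def test_fractional_coefficients(self, registry):
        stoich = thermo.parse_reaction("0.5 glucose -> 1 lactate", registry)
        assert stoich[registry.species("glucose")] == -0.5

    def test_missing_arrow_rejected(self, registry):
        with pytest.raises(ValueError, match="->"):
            thermo.parse_reaction("glucose + O2", registry)
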