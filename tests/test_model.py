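"""Growth-equation fitting: NNLS, macrochemical equation, NCR, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncrfit.model import (
    ExchangeDataset,
    GrowthEquationModel,
    carbon_recovery,
    normalize_dataset,
)
from ncrfit.routes import RouteBasis
from ncrfit.stoichiometry import electron_balance, is_balanced
from ncrfit.routes import cmol_to_moles


def make_dataset(registry, alpha, routes=None, measured=None, substrate="glucose",
                 aerobic=True, **kwargs):
    """Exact exchange vector for a route combination (alpha_0 first)."""
    if routes is None:
        routes = [
            registry.anabolic_route(substrate, "CH1.8O0.5N0.2", aerobic=aerobic),
            registry.respiration_route(substrate),
            registry.build_product_route(substrate, "ethanol"),
        ][: len(alpha)]
    basis = RouteBasis(routes)
    if measured is None:
        names = ["biomass", substrate, "O2", "CO2"]
        for r in basis.catabolic:
            for sp in r.stoich:
                if sp.name not in names and sp.phase_role == "solute":
                    names.append(sp.name)
        measured = [n for n in names
                    if any(r.coefficient(n) for r in basis) or n == "biomass"]
    alpha = np.asarray(alpha, dtype=float)
    e = basis.projection_matrix(measured) @ (alpha / alpha[0])
    data = ExchangeDataset(
        species=measured, values=e, dilution_rate=0.1, substrate=substrate,
        aerobic=aerobic, **kwargs,
    )
    return data, basis


class TestNormalizeDataset:
    def test_volumetric_conversion(self, registry):
        """10 mmol/L/h glucose uptake, 0.05 C-mol/L biomass, D=0.2 -> -6.0."""
        data = normalize_dataset(
            {"glucose": -0.010, "O2": -0.008},
            dilution_rate=0.2,
            biomass_cmol_per_L=0.05,
            registry=registry,
            substrate="glucose",
        )
        assert data.value("glucose") == pytest.approx(-6.0)
        # O2 is carbon-free: handled in mol, no carbon-count factor
        assert data.value("O2") == pytest.approx(-0.008 / 0.01)
        assert data.values[0] == 1.0

    def test_missing_biomass_rejected(self, registry):
        with pytest.raises(ValueError, match="biomass concentration"):
            normalize_dataset({"glucose": -1}, 0.1, 0.0, registry, substrate="glucose")

    def test_dataset_invariants(self):
        with pytest.raises(ValueError, match="substrate"):
            ExchangeDataset(
                species=["biomass", "glucose"], values=[1.0, +2.0],
                dilution_rate=0.1, substrate="glucose",
            )


class TestFit:
    def test_exact_interpolation(self, registry):
        # e constructed exactly from a 60:40 anabolic/respiration split
        # (per-biomass normalization rescales alpha_0 to 1)
        data, basis = make_dataset(registry, [1.0, 0.4 / 0.6])
        fit = GrowthEquationModel(data, basis, registry).fit()
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert fit.params["anabolic"] == pytest.approx(1.0, abs=1e-9)
        assert fit.params["glucose_respiration"] == pytest.approx(0.4 / 0.6, abs=1e-9)

    def test_unexplained_product_gives_orthogonal_residual(self, registry):
        data, basis = make_dataset(registry, [1.0, 0.5])
        # append a measured product that no route touches
        species = data.species + ["succinate"]
        values = np.append(data.values, 0.25)
        data2 = ExchangeDataset(
            species=species, values=values, dilution_rate=0.1, substrate="glucose",
        )
        fit = GrowthEquationModel(data2, basis, registry).fit()
        assert fit.rss == pytest.approx(0.25**2, abs=1e-12)

    def test_permutation_invariance(self, registry):
        data, basis = make_dataset(registry, [1.0, 0.7, 2.0])
        order = list(range(len(data.species)))
        order[1:] = order[:0:-1]  # reverse all non-biomass axes
        fit1 = GrowthEquationModel(data, basis, registry).fit()
        data2 = ExchangeDataset(
            species=[data.species[i] for i in order],
            values=data.values[order],
            dilution_rate=0.1, substrate="glucose",
        )
        fit2 = GrowthEquationModel(data2, basis, registry).fit()
        np.testing.assert_allclose(fit1.alpha, fit2.alpha, atol=1e-12)

    def test_adding_route_never_increases_residual(self, registry):
        data, _ = make_dataset(registry, [1.0, 0.7, 2.0])
        noisy = data.values.copy()
        noisy[2:] *= 1.03  # perturb so the residual is nonzero
        data = ExchangeDataset(
            species=data.species, values=noisy, dilution_rate=0.1,
            substrate="glucose",
        )
        small = RouteBasis([
            registry.anabolic_route("glucose", "CH1.8O0.5N0.2"),
            registry.respiration_route("glucose"),
        ])
        big = RouteBasis(small.routes + [registry.build_product_route("glucose", "ethanol")])
        rss_small = GrowthEquationModel(data, small, registry).fit().rss
        rss_big = GrowthEquationModel(data, big, registry).fit().rss
        assert rss_big <= rss_small + 1e-12

    @given(
        a0=st.floats(0.2, 3.0),
        a1=st.floats(0.0, 3.0),
        a2=st.floats(0.0, 5.0),
    )
    @settings(derandomize=True, max_examples=40)
    def test_noise_free_recovery_is_exact(self, registry, a0, a1, a2):
        """Any non-negative alpha is recovered exactly from noise-free data."""
        data, basis = make_dataset(registry, [a0, a1, a2])
        fit = GrowthEquationModel(data, basis, registry).fit()
        assert fit.rss < 1e-12
        np.testing.assert_allclose(
            fit.alpha * a0, [a0, a1, a2], atol=1e-8
        )

    def test_grid_search_oracle_agreement(self, registry):
        """NNLS matches an exhaustive grid search on a noisy 3-route instance."""
        rng = np.random.default_rng(7)
        data, basis = make_dataset(registry, [1.0, 0.7, 2.0])
        noisy = data.values * (1 + 0.02 * rng.standard_normal(data.values.size))
        noisy[0] = 1.0
        data = ExchangeDataset(
            species=data.species, values=noisy, dilution_rate=0.1,
            substrate="glucose",
        )
        fit = GrowthEquationModel(data, basis, registry).fit()
        V = basis.projection_matrix(data.species)

        def rss(alphas):
            resid = data.values[:, None] - V @ alphas
            return np.einsum("ij,ij->j", resid, resid)

        # coarse pass then 1e-3 refinement around the coarse optimum
        axes = [np.arange(0.0, 3.0, 0.05)] * 3
        grids = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1)
        best = grids[:, np.argmin(rss(grids))]
        axes = [np.arange(max(0.0, b - 0.06), b + 0.06, 1e-3) for b in best]
        grids = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1)
        idx = np.argmin(rss(grids))
        best, best_rss = grids[:, idx], rss(grids[:, [idx]])[0]
        assert fit.rss <= best_rss + 1e-12
        np.testing.assert_allclose(fit.alpha, best, atol=2e-3)

    def test_degenerate_basis_names_routes(self, registry):
        data, basis = make_dataset(registry, [1.0, 0.7, 2.0])
        data2 = ExchangeDataset(
            species=data.species[:2], values=data.values[:2],
            dilution_rate=0.1, substrate="glucose",
        )
        with pytest.raises(ValueError, match="glucose_respiration"):
            GrowthEquationModel(data2, basis, registry).fit()


class TestDerivedQuantities:
    def test_macrochemical_equation_normalized(self, registry):
        data, basis = make_dataset(registry, [1.0, 0.95])
        fit = GrowthEquationModel(data, basis, registry).fit()
        m = {sp.name: c for sp, c in fit.macrochemical_equation.items()}
        assert m["biomass"] == pytest.approx(1.0, abs=1e-12)
        # anabolic consumes 1.05, catabolic 0.95 -> 2.0 C-mol glucose total
        assert m["glucose"] == pytest.approx(-2.0, abs=1e-9)

    def test_single_route_equation_is_the_anabolic_route(self, registry):
        data, basis = make_dataset(registry, [1.0, 0.0])
        fit = GrowthEquationModel(data, basis, registry).fit()
        m = fit.macrochemical_equation
        assert m == pytest.approx(dict(basis.anabolic.stoich))

    def test_ncr_is_biomass_free_and_balanced(self, registry):
        data, basis = make_dataset(registry, [1.0, 0.7, 2.0])
        fit = GrowthEquationModel(data, basis, registry).fit()
        ncr = fit.ncr
        assert all(sp.phase_role != "biomass" for sp in ncr)
        moles = cmol_to_moles(ncr)
        assert is_balanced(moles)
        assert electron_balance(moles) == pytest.approx(0.0, abs=1e-9)

    def test_pure_anabolic_limit_empty_ncr(self, registry):
        data, basis = make_dataset(registry, [1.0, 0.0])
        fit = GrowthEquationModel(data, basis, registry).fit()
        assert fit.ncr == {}
        assert fit.gibbs_energy().value == 0.0

    def test_acetate_only_ncr_proportional_to_route(self, registry):
        route = registry.build_product_route("glucose", "acetate")
        data, basis = make_dataset(
            registry, [1.0, 1.3],
            routes=[registry.anabolic_route("glucose", "CH1.8O0.5N0.2"), route],
        )
        fit = GrowthEquationModel(data, basis, registry).fit()
        for sp, coeff in fit.ncr.items():
            assert coeff == pytest.approx(1.3 * route.stoich.get(sp, 0.0), abs=1e-9)


class TestCarbonRecovery:
    def test_perfect_synthetic_vector(self, registry):
        data, _ = make_dataset(registry, [1.0, 0.7, 2.0])
        assert carbon_recovery(data, registry) == pytest.approx(1.0, abs=1e-12)

    def test_inflated_uptake(self, registry):
        data, _ = make_dataset(registry, [1.0, 0.7])
        values = data.values.copy()
        values[data.species.index("glucose")] *= 1.05
        data = ExchangeDataset(
            species=data.species, values=values, dilution_rate=0.1,
            substrate="glucose",
        )
        assert carbon_recovery(data, registry) == pytest.approx(1 / 1.05)

    def test_dropped_product_row(self, registry):
        data, _ = make_dataset(registry, [1.0, 0.7])
        keep = [i for i, s in enumerate(data.species) if s != "CO2"]
        data2 = ExchangeDataset(
            species=[data.species[i] for i in keep], values=data.values[keep],
            dilution_rate=0.1, substrate="glucose",
        )
        co2_share = data.value("CO2")
        expected = (carbon_recovery(data, registry) * (-data.value("glucose"))
                    - co2_share) / (-data.value("glucose"))
        assert carbon_recovery(data2, registry) == pytest.approx(expected)


class TestSummary:
    def test_summary_mentions_key_quantities(self, registry):
        data, basis = make_dataset(registry, [1.0, 0.7])
        fit = GrowthEquationModel(data, basis, registry).fit()
        text = fit.summary()
        assert "carbon recovery" in text
        assert "dG_X/S" in text
        assert "anabolic" in text

    def test_report_round_trips_to_json(self, registry):
        import json

        data, basis = make_dataset(registry, [1.0, 0.7])
        fit = GrowthEquationModel(data, basis, registry).fit()
        text = json.dumps(fit.report())
        assert "delta_g_x_s" in text
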