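"""Synthetic chemostat exchange data with known ground truth.

The generator emulates the statistical structure of steady-state chemostat
exchange measurements: a biomass production flux plus a small set of
catabolic route fluxes (respiration and/or overflow products), multiplicative
Gaussian measurement noise on every measured flux, and a carbon-recovery
distortion factor applied to the substrate row (recovery mismatch in real
datasets manifests as a substrate uptake that the balanced fit cannot
reproduce).  Everything is seeded and reproducible.

``preset_suite`` ships yeast-like and bacterium-like scenarios under
aerobic/anaerobic carbon, nitrogen, phosphorus, sulfur and potassium
limitations.  The true route coefficients were chosen once so that the
carbon-limited scenarios dissipate roughly 330-370 kJ per C-mol biomass and
every anabolic (non-carbon) limitation dissipates strictly more, spanning
approximately -330 to -1550 kJ per C-mol biomass overall — the qualitative
pattern of published chemostat compilations (energy-limited growth is cheap;
anabolic nutrient limitation is thermodynamically expensive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np

from . import thermo
from .model import ExchangeDataset, default_registry
from .routes import BIOMASS_NAME, RouteBasis, RouteRegistry, RouteVector

__all__ = ["ScenarioSpec", "generate", "scenario_basis", "preset", "preset_suite"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth description of a synthetic chemostat experiment.

    ``alpha_true`` maps route names to the true non-negative coefficients;
    the key ``"anabolic"`` (alpha_0, biomass production) must be positive.
    ``sigma`` is the relative standard deviation of the multiplicative
    Gaussian measurement noise; ``distortion`` multiplies the substrate row
    only (1.0 = perfect carbon recovery).
    """

    name: str
    substrate: str = "glucose"
    biomass_formula: str = "CH1.8O0.5N0.2"
    nitrogen_source: str = "ammonia"
    aerobic: bool = True
    alpha_true: Mapping[str, float] = field(default_factory=dict)
    sigma: float = 0.02
    distortion: float = 1.0
    dilution_rate: float = 0.1
    seed: int = 0
    limitation: str = "carbon"
    organism: str = "generic"

    def __post_init__(self) -> None:
        if self.alpha_true.get("anabolic", 0.0) <= 0:
            raise ValueError("alpha_true['anabolic'] must be positive")
        if any(a < 0 for a in self.alpha_true.values()):
            raise ValueError("route coefficients must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.distortion <= 0:
            raise ValueError("distortion must be positive")
        object.__setattr__(self, "alpha_true", dict(self.alpha_true))


def scenario_basis(spec: ScenarioSpec, registry: RouteRegistry | None = None) -> RouteBasis:
    """Route basis matching the scenario's true coefficients.

    The anabolic route comes first; catabolic routes follow in the order of
    ``alpha_true`` (the respiration route name is ``<substrate>_respiration``).
    """
    reg = registry or default_registry()
    routes: List[RouteVector] = [
        reg.anabolic_route(
            spec.substrate, spec.biomass_formula, spec.nitrogen_source, spec.aerobic
        )
    ]
    for name in spec.alpha_true:
        if name == "anabolic":
            continue
        if name.endswith("_respiration"):
            routes.append(reg.respiration_route(spec.substrate, spec.nitrogen_source))
        else:
            routes.append(reg.route(name))
    return RouteBasis(routes)


def _measured_species(spec: ScenarioSpec, basis: RouteBasis) -> List[str]:
    """Biomass, substrate, gases and products appearing in the active routes."""
    measured = [BIOMASS_NAME, spec.substrate]
    rest = []
    for route in basis:
        for sp in route.stoich:
            if sp.phase_role in ("water", "biomass"):
                continue
            if sp.name in measured or sp.name in rest:
                continue
            rest.append(sp.name)
    # gases first, then products, in stable alphabetical order
    gases = [n for n in ("O2", "CO2") if n in rest]
    products = sorted(n for n in rest if n not in ("O2", "CO2"))
    return measured + gases + products


def generate(
    spec: ScenarioSpec,
    registry: RouteRegistry | None = None,
    basis: RouteBasis | None = None,
    seed: int | None = None,
) -> Tuple[ExchangeDataset, dict]:
    """Generate one synthetic exchange dataset plus its truth record.

    The noise-free exchange vector is the exact route combination
    ``e = sum_i alpha*_i v_i`` projected on the measured axes and divided by
    alpha_0 (per-biomass normalization keeps the biomass row exactly +1;
    measurement error therefore lives in the other rows).  Each non-biomass
    row gets independent multiplicative Gaussian noise ``(1 + sigma * z)``
    and the substrate row is multiplied by the distortion factor.

    Returns ``(dataset, truth)`` where the truth record carries the true
    coefficients, the true macrochemical equation/NCR and the true dG_X/S.
    """
    reg = registry or default_registry()
    if basis is None:
        basis = scenario_basis(spec, reg)
    alpha = np.array([spec.alpha_true.get(r.name, 0.0) for r in basis.routes])
    if abs(alpha[0]) <= 0:
        raise ValueError("anabolic coefficient missing from alpha_true")
    measured = _measured_species(spec, basis)
    design = basis.projection_matrix(measured)
    e = design @ (alpha / alpha[0])

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    noise = 1.0 + spec.sigma * rng.standard_normal(e.size)
    noise[0] = 1.0  # biomass row is the normalization reference
    e_noisy = e * noise
    sub_idx = measured.index(spec.substrate)
    e_noisy[sub_idx] *= spec.distortion

    dataset = ExchangeDataset(
        species=measured,
        values=e_noisy,
        dilution_rate=spec.dilution_rate,
        substrate=spec.substrate,
        biomass_formula=spec.biomass_formula,
        nitrogen_source=spec.nitrogen_source,
        aerobic=spec.aerobic,
        limitation=spec.limitation,
        name=spec.name,
    )

    alpha_norm = alpha / alpha[0]
    ncr_true: Dict = {}
    for a, route in zip(alpha_norm[1:], basis.catabolic):
        for sp, coeff in route.stoich.items():
            ncr_true[sp] = ncr_true.get(sp, 0.0) + a * coeff
    truth = {
        "name": spec.name,
        "alpha_true": {r.name: float(a) for r, a in zip(basis.routes, alpha)},
        "ncr_true": {sp.name: c for sp, c in ncr_true.items() if abs(c) > 1e-15},
        "delta_g_true": thermo.catabolic_gibbs_energy(ncr_true).value,
        "sigma": spec.sigma,
        "distortion": spec.distortion,
        "seed": spec.seed if seed is None else seed,
        "limitation": spec.limitation,
        "organism": spec.organism,
        "aerobic": spec.aerobic,
    }
    return dataset, truth


def preset_suite() -> List[ScenarioSpec]:
    """Bundled scenario presets (yeast-like and bacterium-like chemostats).

    Twelve scenarios: aerobic and anaerobic yeast under C/N/P/S limitation
    and an aerobic bacterium under C/N/P/K limitation.  Yeast overflow is
    ethanol, bacterial overflow is acetate; anaerobic scenarios ferment only.
    Dilution rates and coefficient magnitudes echo classic chemostat studies.
    """
    resp = "glucose_respiration"
    eth = "glucose_to_ethanol"
    ace = "glucose_to_acetate"
    presets = [
        # -- aerobic yeast-like (Crabtree-negative at low D; overflow under
        #    anabolic limitation) --
        ScenarioSpec(
            name="yeast_aerobic_Clim", organism="yeast", aerobic=True,
            limitation="carbon", dilution_rate=0.10, seed=101,
            alpha_true={"anabolic": 1.0, resp: 0.70},
        ),
        ScenarioSpec(
            name="yeast_aerobic_Nlim", organism="yeast", aerobic=True,
            limitation="nitrogen", dilution_rate=0.10, seed=102,
            alpha_true={"anabolic": 1.0, resp: 0.79, eth: 4.8},
        ),
        ScenarioSpec(
            name="yeast_aerobic_Plim", organism="yeast", aerobic=True,
            limitation="phosphorus", dilution_rate=0.10, seed=103,
            alpha_true={"anabolic": 1.0, resp: 1.15, eth: 5.0},
        ),
        ScenarioSpec(
            name="yeast_aerobic_Slim", organism="yeast", aerobic=True,
            limitation="sulfur", dilution_rate=0.10, seed=104,
            alpha_true={"anabolic": 1.0, resp: 0.77, eth: 2.7},
        ),
        # -- anaerobic yeast-like (fermentation only) --
        ScenarioSpec(
            name="yeast_anaerobic_Clim", organism="yeast", aerobic=False,
            limitation="carbon", dilution_rate=0.10, seed=111,
            alpha_true={"anabolic": 1.0, eth: 7.27},
        ),
        ScenarioSpec(
            name="yeast_anaerobic_Nlim", organism="yeast", aerobic=False,
            limitation="nitrogen", dilution_rate=0.10, seed=112,
            alpha_true={"anabolic": 1.0, eth: 10.5},
        ),
        ScenarioSpec(
            name="yeast_anaerobic_Plim", organism="yeast", aerobic=False,
            limitation="phosphorus", dilution_rate=0.10, seed=113,
            alpha_true={"anabolic": 1.0, eth: 11.2},
        ),
        ScenarioSpec(
            name="yeast_anaerobic_Slim", organism="yeast", aerobic=False,
            limitation="sulfur", dilution_rate=0.10, seed=114,
            alpha_true={"anabolic": 1.0, eth: 9.65},
        ),
        # -- aerobic bacterium-like (acetate overflow; potassium limitation
        #    is the thermodynamically most expensive condition) --
        ScenarioSpec(
            name="bacterium_aerobic_Clim", organism="bacterium", aerobic=True,
            limitation="carbon", dilution_rate=0.30, seed=121,
            alpha_true={"anabolic": 1.0, resp: 0.75},
        ),
        ScenarioSpec(
            name="bacterium_aerobic_Nlim", organism="bacterium", aerobic=True,
            limitation="nitrogen", dilution_rate=0.30, seed=122,
            alpha_true={"anabolic": 1.0, resp: 0.80, ace: 1.4},
        ),
        ScenarioSpec(
            name="bacterium_aerobic_Plim", organism="bacterium", aerobic=True,
            limitation="phosphorus", dilution_rate=0.30, seed=123,
            alpha_true={"anabolic": 1.0, resp: 1.20, ace: 1.8},
        ),
        ScenarioSpec(
            name="bacterium_aerobic_Klim", organism="bacterium", aerobic=True,
            limitation="potassium", dilution_rate=0.30, seed=124,
            alpha_true={"anabolic": 1.0, resp: 2.20, ace: 2.3},
        ),
    ]
    return presets


def preset(name: str) -> ScenarioSpec:
    """Look up one bundled preset by name."""
    for spec in preset_suite():
        if spec.name == name:
            return spec
    raise KeyError(
        f"unknown preset {name!r}; available: {[s.name for s in preset_suite()]}"
    )
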