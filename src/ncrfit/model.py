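"""Growth-equation model: non-negative least-squares fit of route coefficients.

The measured exchange fluxes of a chemostat experiment form a vector
``e = (e_0, ..., e_n)`` per carbon-mole of biomass (index 0 = biomass, always
+1; consumed compounds negative; carbon species in C-mol, carbon-free species
such as O2 in mol).  Given a route basis ``[v_0 (anabolic), v_1..v_k
(catabolic)]``, the model finds non-negative coefficients

    min_{alpha >= 0}  sum_j ( e_j - sum_i alpha_i v_{i,j} )^2

over the measured axes only.  The fitted linear combination defines the
balanced macrochemical growth equation ``m`` (normalized so the biomass
coefficient is exactly 1) and the net catabolic reaction

    v_NCR = sum_{i>=1} alpha_i v_i / alpha_0,

the fully mass-balanced conversion whose reaction Gibbs energy is the
catabolic energy requirement dG_X/S per C-mol biomass.

The problem is a convex NNLS; `scipy.optimize.nnls` (active-set) returns its
global minimum deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import thermo
from .routes import (
    BIOMASS_NAME,
    RouteBasis,
    RouteRegistry,
    RouteVector,
    UnknownRouteError,
)
from .stoichiometry import Species
from .thermo import ConstantsTable, EnergyResult, ThermoContext

__all__ = [
    "ExchangeDataset",
    "GrowthEquationModel",
    "GrowthFitResults",
    "normalize_dataset",
    "carbon_recovery",
]

_DEFAULT_REGISTRY: RouteRegistry | None = None


def default_registry() -> RouteRegistry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = RouteRegistry()
    return _DEFAULT_REGISTRY


@dataclass
class ExchangeDataset:
    """Measured exchange fluxes of one chemostat experiment.

    ``species`` lists measured species names with biomass at index 0;
    ``values`` holds the exchange coefficients in C-mol (C-mol biomass)^-1
    (mol for carbon-free compounds), consumption negative, biomass exactly
    +1.  Conditions carry the experimental context used for route building
    and Gibbs-energy evaluation.
    """

    species: List[str]
    values: np.ndarray
    dilution_rate: float
    substrate: str
    biomass_formula: str = "CH1.8O0.5N0.2"
    temperature: float = 298.15
    pH: float = 7.0
    nitrogen_source: str = "ammonia"
    aerobic: bool = True
    limitation: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.species) != self.values.size:
            raise ValueError("species and values lengths differ")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate measured species")
        if self.species[0] != BIOMASS_NAME:
            raise ValueError(f"index 0 must be {BIOMASS_NAME!r}, got {self.species[0]!r}")
        if abs(self.values[0] - 1.0) > 1e-9:
            raise ValueError("biomass entry must be +1 after per-biomass normalization")
        if self.dilution_rate <= 0:
            raise ValueError("dilution rate must be positive")
        if self.substrate not in self.species:
            raise ValueError(f"substrate {self.substrate!r} not among measured species")
        if self.values[self.species.index(self.substrate)] >= 0:
            raise ValueError("substrate must be consumed (negative exchange value)")

    def value(self, species_name: str) -> float:
        return float(self.values[self.species.index(species_name)])

    @property
    def has_gas_exchange(self) -> bool:
        """True when O2 or CO2 exchange was measured (needed for the error bracket)."""
        return "O2" in self.species or "CO2" in self.species

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species": self.species, "value": self.values})


def normalize_dataset(
    rates_mol_per_L_h: Mapping[str, float],
    dilution_rate: float,
    biomass_cmol_per_L: float,
    registry: RouteRegistry | None = None,
    **conditions,
) -> ExchangeDataset:
    """Convert volumetric rates (mol/L/h, consumption negative) to an
    :class:`ExchangeDataset`.

    Each rate is divided by (biomass C-mol concentration x dilution rate);
    carbon-containing compounds are additionally converted mol -> C-mol by
    multiplying with their carbon count.  The biomass row is +1 by
    construction.
    """
    if biomass_cmol_per_L <= 0:
        raise ValueError("biomass concentration must be positive")
    if dilution_rate <= 0:
        raise ValueError("dilution rate must be positive")
    reg = registry or default_registry()
    species = [BIOMASS_NAME]
    values = [1.0]
    denom = biomass_cmol_per_L * dilution_rate
    for name, rate in rates_mol_per_L_h.items():
        carbons = reg.species(name).carbon
        factor = carbons if carbons > 0 else 1.0
        species.append(name)
        values.append(rate * factor / denom)
    return ExchangeDataset(
        species=species, values=np.array(values), dilution_rate=dilution_rate,
        **conditions,
    )


def carbon_recovery(data: ExchangeDataset, registry: RouteRegistry | None = None) -> float:
    """C-mol leaving (biomass + CO2 + products) over C-mol entering.

    Exchange values of carbon species are already in C-mol, so recovery is
    the ratio of positive to negative carbon entries (biomass included at
    +1); 1.0 means perfectly balanced data.
    """
    reg = registry or default_registry()
    c_in = 0.0
    c_out = 1.0  # biomass row
    for name, value in zip(data.species[1:], data.values[1:]):
        if reg.has_species(name) and reg.species(name).carbon > 0:
            if value >= 0:
                c_out += value
            else:
                c_in -= value
    if c_in <= 0:
        raise ValueError("no carbon uptake in dataset")
    return c_out / c_in


class GrowthEquationModel:
    """Fit a balanced macrochemical growth equation to exchange-flux data.

    Parameters
    ----------
    dataset
        The measured exchange vector and experimental conditions.
    basis
        Route basis ``[anabolic, catabolic...]``.  When omitted, a default
        basis is assembled from the registry: the idealized anabolic route,
        the respiration route (aerobic datasets), and one canonical route per
        measured product with a registry entry.
    registry
        Species/route registry (bundled one by default).
    weights
        Optional per-measurement weights (1/sigma); the default is the
        unweighted objective.
    """

    def __init__(
        self,
        dataset: ExchangeDataset,
        basis: RouteBasis | None = None,
        registry: RouteRegistry | None = None,
        weights: Sequence[float] | None = None,
    ) -> None:
        self.registry = registry or default_registry()
        self.data = dataset
        self.basis = basis if basis is not None else self.default_basis()
        if self.basis.anabolic.substrate.name != dataset.substrate:
            raise ValueError(
                "basis anabolic route substrate "
                f"{self.basis.anabolic.substrate.name!r} does not match dataset "
                f"substrate {dataset.substrate!r}"
            )
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        if self.weights is not None and self.weights.size != dataset.values.size:
            raise ValueError("weights length must match measured species")

    @classmethod
    def from_csv(cls, path, registry: RouteRegistry | None = None, **kwargs):
        from .io import read_dataset_csv

        dataset = read_dataset_csv(path, registry=registry)
        return cls(dataset, registry=registry, **kwargs)

    def default_basis(self) -> RouteBasis:
        data = self.data
        routes: List[RouteVector] = [
            self.registry.anabolic_route(
                data.substrate,
                data.biomass_formula,
                data.nitrogen_source,
                data.aerobic,
            )
        ]
        if data.aerobic:
            routes.append(self.registry.respiration_route(data.substrate, data.nitrogen_source))
        seen = {r.name for r in routes}
        for name, value in zip(data.species[1:], data.values[1:]):
            if name in (data.substrate, "O2", "CO2", "H2O"):
                continue
            if value <= 0:
                continue
            try:
                route = self.registry.build_product_route(data.substrate, name)
            except UnknownRouteError:
                continue
            if route.name not in seen:
                routes.append(route)
                seen.add(route.name)
        return RouteBasis(routes)

    def fit(self) -> "GrowthFitResults":
        """Solve the non-negative least-squares problem (global minimum)."""
        measured = self.data.species
        self.basis.check_independence(measured)
        design = self.basis.projection_matrix(measured)
        e = self.data.values
        if self.weights is not None:
            w = self.weights
            alpha, _ = nnls(design * w[:, None], e * w)
        else:
            alpha, _ = nnls(design, e)
        fitted = design @ alpha
        residuals = e - fitted
        rss = float(residuals @ residuals)
        return GrowthFitResults(self, alpha, fitted, residuals, rss)


class GrowthFitResults:
    """Fitted macrochemical growth equation and derived quantities.

    Exposes the non-negative route coefficients (``params``), the residual
    sum of squares in squared C-mol units (``rss``), the normalized
    macrochemical equation ``m`` (biomass coefficient exactly 1), the net
    catabolic reaction, and methods that evaluate dG_X/S, its respiratory
    partition and the carbon-recovery error bracket.
    """

    def __init__(self, model, alpha, fitted, residuals, rss) -> None:
        self.model = model
        self.data = model.data
        self.basis = model.basis
        self.alpha = np.asarray(alpha, dtype=float)
        self.fittedvalues = fitted
        self.resid = residuals
        self.rss = rss

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.alpha, index=self.basis.names, name="alpha")

    @property
    def alpha_0(self) -> float:
        return float(self.alpha[0])

    @property
    def carbon_recovery(self) -> float:
        """Carbon recovery of the raw data (before fitting)."""
        return carbon_recovery(self.data, self.model.registry)

    # -- stoichiometric outputs -----------------------------------------
    def _combination(self, include_anabolic: bool) -> Dict[Species, float]:
        if self.alpha_0 <= 0:
            raise ValueError(
                "fit assigns zero biomass production (alpha_0 = 0); the "
                "macrochemical equation cannot be normalized"
            )
        total: Dict[Species, float] = {}
        routes = self.basis.routes if include_anabolic else self.basis.catabolic
        offset = 0 if include_anabolic else 1
        for i, route in enumerate(routes):
            a = float(self.alpha[i + offset])
            if a == 0.0:
                continue
            for sp, coeff in route.stoich.items():
                total[sp] = total.get(sp, 0.0) + a * coeff / self.alpha_0
        return {sp: c for sp, c in total.items() if abs(c) > 1e-15}

    @property
    def macrochemical_equation(self) -> Dict[Species, float]:
        """Full fitted stoichiometry per C-mol biomass (m_0 = 1 exactly)."""
        return self._combination(include_anabolic=True)

    @property
    def ncr(self) -> Dict[Species, float]:
        """Net catabolic reaction per C-mol biomass (biomass-free, balanced)."""
        return self._combination(include_anabolic=False)

    def fitted_substrate_uptake(self) -> float:
        """Substrate coefficient of m (negative, C-mol per C-mol biomass)."""
        for sp, coeff in self.macrochemical_equation.items():
            if sp.name == self.data.substrate:
                return coeff
        return 0.0

    # -- thermodynamic outputs ------------------------------------------
    def thermo_context(self, context: ThermoContext | None = None) -> ThermoContext:
        if context is not None:
            return context
        return ThermoContext(temperature=self.data.temperature, pH=self.data.pH)

    def gibbs_energy(
        self,
        context: ThermoContext | None = None,
        constants: ConstantsTable | None = None,
    ) -> EnergyResult:
        """dG_X/S of the fitted NCR in kJ per C-mol biomass."""
        return thermo.catabolic_gibbs_energy(
            self.ncr, self.thermo_context(context), constants
        )

    def respiratory_partition(
        self,
        context: ThermoContext | None = None,
        constants: ConstantsTable | None = None,
    ):
        """(total, respiratory, non-respiratory) split of dG_X/S."""
        return thermo.respiratory_partition(
            dict(self.params), self.basis, self.thermo_context(context), constants
        )

    def error_bracket(
        self,
        context: ThermoContext | None = None,
        constants: ConstantsTable | None = None,
    ):
        """Two-extreme carbon-recovery error bracket on dG_X/S."""
        from .uncertainty import error_bracket

        return error_bracket(self, self.thermo_context(context), constants)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        data = self.data
        lines = []
        title = "Growth equation fit (net catabolic reaction analysis)"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"dataset:         {data.name or '<unnamed>'}")
        lines.append(
            f"substrate:       {data.substrate}   biomass: {data.biomass_formula}"
        )
        lines.append(
            f"dilution rate:   {data.dilution_rate:g} 1/h   "
            f"{'aerobic' if data.aerobic else 'anaerobic'}, "
            f"N source: {data.nitrogen_source}"
        )
        lines.append(f"carbon recovery: {self.carbon_recovery:.4f}")
        lines.append(f"residual SS:     {self.rss:.3e} (C-mol/C-mol biomass)^2")
        lines.append("")
        lines.append("route coefficients alpha (>= 0):")
        for name, a in self.params.items():
            lines.append(f"  {name:<28s} {a:12.6f}")
        lines.append("")
        lines.append("macrochemical equation (per C-mol biomass):")
        lines.append("  " + format_equation(self.macrochemical_equation))
        lines.append("net catabolic reaction:")
        lines.append("  " + format_equation(self.ncr))
        try:
            energy = self.gibbs_energy()
            total, resp, non_resp = self.respiratory_partition()
            lines.append("")
            lines.append(
                f"dG_X/S:          {energy.value:10.1f} kJ / C-mol biomass"
            )
            lines.append(
                f"  respiratory:   {resp:10.1f}   non-respiratory: {non_resp:10.1f}"
            )
            bracket = self.error_bracket()
            if bracket.available:
                lines.append(
                    f"  recovery bracket: [{bracket.lower:.1f}, {bracket.upper:.1f}]"
                )
            else:
                lines.append("  recovery bracket: unavailable (no gas exchange data)")
            for note in energy.notes:
                lines.append(f"  note: {note}")
        except thermo.MissingConstantError as exc:
            lines.append(f"dG_X/S: unavailable ({exc})")
        return "\n".join(lines)

    def report(self) -> dict:
        """Machine-parseable per-run report (JSON-serializable)."""
        data = self.data
        rec: dict = {
            "name": data.name,
            "substrate": data.substrate,
            "dilution_rate": data.dilution_rate,
            "aerobic": data.aerobic,
            "limitation": data.limitation,
            "nitrogen_source": data.nitrogen_source,
            "biomass_formula": data.biomass_formula,
            "temperature_K": data.temperature,
            "pH": data.pH,
            "alpha": {k: float(v) for k, v in self.params.items()},
            "rss": self.rss,
            "rss_note": (
                "residual sum of squares on the per-biomass exchange axes, "
                "(C-mol per C-mol biomass)^2"
            ),
            "carbon_recovery": self.carbon_recovery,
            "macrochemical_equation": {
                sp.name: c for sp, c in self.macrochemical_equation.items()
            },
            "ncr": {sp.name: c for sp, c in self.ncr.items()},
            "gamma_excludes_SP": True,
        }
        energy = self.gibbs_energy()
        total, resp, non_resp = self.respiratory_partition()
        rec["delta_g_x_s"] = energy.value
        rec["delta_g_standard"] = energy.standard
        rec["delta_g_respiratory"] = resp
        rec["delta_g_non_respiratory"] = non_resp
        rec["thermo_notes"] = list(energy.notes)
        bracket = self.error_bracket()
        rec["bracket"] = bracket.as_dict()
        return rec


def format_equation(stoich: Mapping[Species, float], digits: int = 4) -> str:
    """Human-readable `a A + b B -> c C` form of a stoichiometry map."""
    left = []
    right = []
    for sp, coeff in sorted(stoich.items(), key=lambda x: x[0].name):
        part = f"{abs(coeff):.{digits}g} {sp.name}"
        (left if coeff < 0 else right).append(part)
    if not left and not right:
        return "(empty)"
    return " + ".join(left) + " -> " + " + ".join(right)
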