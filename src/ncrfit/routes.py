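"""Candidate conversion routes for the macrochemical growth equation.

The growth equation is decomposed onto a convex basis of chemically explicit
*routes*, each normalized so that it composes directly with carbon-mole
exchange vectors:

* **catabolic routes** convert exactly one carbon-mole of substrate into one
  observed product (plus CO2/H2O/O2 as redox bookkeeping demands);
* the **respiration route** oxidizes one C-mol of substrate completely to CO2
  using gamma_S / 4 mol O2;
* the **idealized anabolic route** converts substrate carbon into biomass at
  the maximal theoretical carbon yield min(1, gamma_S/gamma_X).  If biomass is
  more reduced than the substrate, the deficit electrons come from oxidizing
  extra substrate carbon to CO2; if biomass is more oxidized, O2 serves as the
  electron acceptor (which presumes aerobic growth).

Catabolic routes are fully elementally balanced; the anabolic route is carbon
and redox balanced only (it deliberately ignores N/P/S balances, which is why
it cannot pass a full element balance when biomass contains nitrogen).

Coefficient units throughout: C-mol for carbon-containing species, mol for
carbon-free species (O2, H2O).  Consumption is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np

from .stoichiometry import (
    BALANCE_TOL,
    ElementalComposition,
    Species,
    degree_of_reduction,
    element_balance,
    electron_balance,
)

__all__ = [
    "RouteVector",
    "RouteBasis",
    "RouteRegistry",
    "respiration_route",
    "anabolic_route",
    "cmol_to_moles",
    "UnknownRouteError",
    "UnbalancedRouteError",
]

BIOMASS_NAME = "biomass"


class UnknownRouteError(KeyError):
    """No canonical route is registered for a (substrate, product) pair."""


class UnbalancedRouteError(ValueError):
    """A route stoichiometry fails elemental or redox balance."""


def cmol_to_moles(stoich: Mapping[Species, float]) -> Dict[Species, float]:
    """Convert mixed-unit coefficients (C-mol for carbon species) to moles."""
    return {
        sp: (coeff / sp.carbon if sp.carbon > 0 else coeff)
        for sp, coeff in stoich.items()
    }


def _check_catabolic(stoich: Mapping[Species, float], n_ref: str) -> None:
    moles = cmol_to_moles(stoich)
    net = element_balance(moles)
    bad = {el: v for el, v in net.items() if abs(v) > BALANCE_TOL}
    if bad:
        raise UnbalancedRouteError(f"route not elementally balanced: residuals {bad}")
    electrons = electron_balance(moles, n_ref)
    if abs(electrons) > 1e-6:
        raise UnbalancedRouteError(f"route not redox balanced: {electrons} e-")


@dataclass(frozen=True)
class RouteVector:
    """One carbon- and redox-balanced chemical conversion.

    ``stoich`` maps species to coefficients per C-mol of substrate (catabolic)
    or per C-mol of biomass formed (anabolic); carbon species in C-mol,
    others in mol.
    """

    name: str
    stoich: Mapping[Species, float]
    kind: str  # "catabolic" | "anabolic"
    substrate: Species
    is_respiratory: bool = False
    nitrogen_reference: str = "ammonia"

    def __post_init__(self) -> None:
        if self.kind not in ("catabolic", "anabolic"):
            raise ValueError(f"unknown route kind {self.kind!r}")
        stoich = {sp: float(c) for sp, c in self.stoich.items() if c != 0.0}
        object.__setattr__(self, "stoich", stoich)
        if self.kind == "catabolic":
            sub = stoich.get(self.substrate, 0.0)
            if abs(sub + 1.0) > 1e-9:
                raise UnbalancedRouteError(
                    f"catabolic route {self.name}: substrate coefficient {sub} "
                    "(must be exactly -1 C-mol)"
                )
            if any(sp.phase_role == "biomass" for sp in stoich):
                raise UnbalancedRouteError(
                    f"catabolic route {self.name} must not contain biomass"
                )
            _check_catabolic(stoich, self.nitrogen_reference)
        else:
            bio = [sp for sp in stoich if sp.phase_role == "biomass"]
            if len(bio) != 1 or abs(stoich[bio[0]] - 1.0) > 1e-9:
                raise UnbalancedRouteError(
                    f"anabolic route {self.name}: biomass coefficient must be +1"
                )
            moles = cmol_to_moles(stoich)
            carbon = element_balance(moles).get("C", 0.0)
            if abs(carbon) > BALANCE_TOL:
                raise UnbalancedRouteError(
                    f"anabolic route {self.name}: carbon residual {carbon}"
                )
            electrons = electron_balance(moles, self.nitrogen_reference)
            if abs(electrons) > 1e-6:
                raise UnbalancedRouteError(
                    f"anabolic route {self.name}: redox residual {electrons} e-"
                )

    def to_moles(self) -> Dict[Species, float]:
        return cmol_to_moles(self.stoich)

    def coefficient(self, species_name: str) -> float:
        for sp, coeff in self.stoich.items():
            if sp.name == species_name:
                return coeff
        return 0.0

    def projection(self, measured: Sequence[str]) -> np.ndarray:
        """Coefficients on the measured-species axes (0 where absent)."""
        return np.array([self.coefficient(name) for name in measured])

    def scaled(self, factor: float) -> Dict[Species, float]:
        return {sp: factor * c for sp, c in self.stoich.items()}

    def __repr__(self) -> str:
        terms = ", ".join(
            f"{sp.name}:{c:+.4g}" for sp, c in sorted(self.stoich.items(), key=lambda x: x[0].name)
        )
        return f"RouteVector({self.name}: {terms})"


def respiration_route(
    substrate: Species, nitrogen_reference: str = "ammonia"
) -> RouteVector:
    """Complete oxidation of one C-mol of substrate to CO2.

    Per C-mol: -1 substrate, -gamma_S/4 mol O2, +1 CO2, +(H - 3N)/(2C) mol
    H2O, +N/C ammonia (nitrogen in the substrate, if any, is released as the
    nitrogen reference compound).
    """
    comp = substrate.composition
    gamma = degree_of_reduction(comp, nitrogen_reference)  # raises if C == 0
    if gamma <= 0:
        raise UnbalancedRouteError(
            f"{substrate.name} has degree of reduction {gamma}; nothing to oxidize"
        )
    c = comp.carbon
    stoich: Dict[Species, float] = {
        substrate: -1.0,
        _O2: -gamma / 4.0,
        _CO2: +1.0,
    }
    n = comp["N"]
    water = (comp["H"] - 3.0 * n) / (2.0 * c)
    if abs(water) > 0:
        stoich[_H2O] = water
    if n > 0:
        stoich[_NH3] = n / c
    return RouteVector(
        name=f"{substrate.name}_respiration",
        stoich=stoich,
        kind="catabolic",
        substrate=substrate,
        is_respiratory=True,
        nitrogen_reference=nitrogen_reference,
    )


def anabolic_route(
    substrate: Species,
    biomass: Species,
    nitrogen_reference: str = "ammonia",
    aerobic: bool = True,
) -> RouteVector:
    """Idealized anabolic conversion of substrate into one C-mol of biomass.

    With gamma_X > gamma_S the missing electrons come from oxidizing extra
    substrate carbon:  (gX/gS) S -> X + (gX/gS - 1) CO2.  With gamma_X <
    gamma_S the surplus electrons go to oxygen:  S + (gS - gX)/4 O2 -> X,
    which presumes an aerobic context (anaerobic growth on a substrate more
    reduced than biomass is outside the model).  The equation is carbon and
    redox balanced but intentionally ignores N/P/S balances.
    """
    gamma_s = degree_of_reduction(substrate.composition, nitrogen_reference)
    gamma_x = degree_of_reduction(biomass.composition, nitrogen_reference)
    if gamma_s <= 0:
        raise UnbalancedRouteError(
            f"substrate {substrate.name} has non-positive degree of reduction"
        )
    stoich: Dict[Species, float] = {biomass: +1.0}
    ratio = gamma_x / gamma_s
    if ratio > 1.0 + 1e-12:
        stoich[substrate] = -ratio
        stoich[_CO2] = ratio - 1.0
    elif ratio < 1.0 - 1e-12:
        if not aerobic:
            raise UnbalancedRouteError(
                "anaerobic growth with biomass more oxidized than the substrate "
                "is outside the idealized anabolic model (no electron acceptor)"
            )
        stoich[substrate] = -1.0
        stoich[_O2] = -(gamma_s - gamma_x) / 4.0
    else:
        stoich[substrate] = -1.0
    return RouteVector(
        name="anabolic",
        stoich=stoich,
        kind="anabolic",
        substrate=substrate,
        nitrogen_reference=nitrogen_reference,
    )


def theoretical_carbon_yield(gamma_s: float, gamma_x: float) -> float:
    """Maximal carbon yield of the idealized anabolic process, min(1, gS/gX)."""
    return min(1.0, gamma_s / gamma_x)


@dataclass
class RouteBasis:
    """Ordered route basis [v_0 (anabolic), v_1 ... v_k (catabolic)]."""

    routes: List[RouteVector]

    def __post_init__(self) -> None:
        if not self.routes or self.routes[0].kind != "anabolic":
            raise ValueError("basis must start with the anabolic route")
        if any(r.kind != "catabolic" for r in self.routes[1:]):
            raise ValueError("all routes after the first must be catabolic")
        names = [r.name for r in self.routes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate route names in basis: {names}")

    @property
    def anabolic(self) -> RouteVector:
        return self.routes[0]

    @property
    def catabolic(self) -> List[RouteVector]:
        return self.routes[1:]

    @property
    def names(self) -> List[str]:
        return [r.name for r in self.routes]

    def __len__(self) -> int:
        return len(self.routes)

    def __iter__(self):
        return iter(self.routes)

    def respiratory_index(self) -> int | None:
        idx = [i for i, r in enumerate(self.routes) if r.is_respiratory]
        if len(idx) > 1:
            raise ValueError("basis flags more than one respiratory route")
        return idx[0] if idx else None

    def projection_matrix(self, measured: Sequence[str]) -> np.ndarray:
        """(n_measured x n_routes) matrix of route projections."""
        return np.column_stack([r.projection(measured) for r in self.routes])

    def check_independence(self, measured: Sequence[str], tol: float = 1e-9) -> None:
        """Reject bases whose projections on the measured axes are parallel.

        Routes that differ only in unmeasured species (e.g. H2O) would let
        the fit split coefficients arbitrarily between them.
        """
        mat = self.projection_matrix(measured)
        norms = np.linalg.norm(mat, axis=0)
        for i in range(mat.shape[1]):
            if norms[i] <= tol:
                raise ValueError(
                    f"route {self.routes[i].name} has no projection on the "
                    f"measured species {list(measured)}"
                )
            for j in range(i + 1, mat.shape[1]):
                cross = abs(
                    float(np.dot(mat[:, i], mat[:, j]))
                ) / (norms[i] * norms[j])
                if abs(cross - 1.0) <= tol:
                    raise ValueError(
                        "degenerate basis: routes "
                        f"{self.routes[i].name} and {self.routes[j].name} have "
                        "parallel projections on the measured axes"
                    )


class RouteRegistry:
    """Species table plus the canonical (substrate, product) route registry.

    Both ship as editable TSV data files; every registry route is validated
    (elemental and redox balance) when loaded.  User routes can be added with
    :meth:`add_route`.
    """

    def __init__(
        self,
        species: Mapping[str, Species] | None = None,
        route_records: Iterable[tuple] | None = None,
    ) -> None:
        if species is None:
            species = _load_species_table()
        self._species: Dict[str, Species] = dict(species)
        self._routes: Dict[str, RouteVector] = {}
        self._by_pair: Dict[tuple, str] = {}
        if route_records is None:
            route_records = _load_route_table(self._species)
        for name, substrate, products, stoich_mol in route_records:
            self._register(name, substrate, products, stoich_mol)

    # -- species ---------------------------------------------------------
    def species(self, name: str) -> Species:
        try:
            return self._species[name]
        except KeyError:
            raise KeyError(
                f"unknown species {name!r}; known: {sorted(self._species)}"
            ) from None

    def has_species(self, name: str) -> bool:
        return name in self._species

    @property
    def species_names(self) -> List[str]:
        return sorted(self._species)

    def biomass_species(self, formula: str) -> Species:
        """Biomass species with a per-C-mol composition from a formula string."""
        comp = ElementalComposition.from_formula(formula).per_carbon()
        return Species(name=BIOMASS_NAME, composition=comp, phase_role="biomass")

    # -- routes ----------------------------------------------------------
    def _register(
        self,
        name: str,
        substrate_name: str,
        product_names: Sequence[str],
        stoich_mol: Mapping[str, float],
    ) -> None:
        substrate = self.species(substrate_name)
        sub_cmol = -stoich_mol[substrate_name] * substrate.carbon
        if sub_cmol <= 0:
            raise UnbalancedRouteError(
                f"route {name}: substrate {substrate_name} must be consumed"
            )
        stoich: Dict[Species, float] = {}
        for sp_name, coeff in stoich_mol.items():
            sp = self.species(sp_name)
            value = coeff * (sp.carbon if sp.carbon > 0 else 1.0)
            stoich[sp] = value / sub_cmol
        route = RouteVector(
            name=name, stoich=stoich, kind="catabolic", substrate=substrate
        )
        self._routes[name] = route
        key = (substrate_name, product_names[0])
        self._by_pair.setdefault(key, name)

    def add_route(
        self,
        name: str,
        substrate: str,
        products: Sequence[str],
        stoichiometry_mol: Mapping[str, float],
    ) -> RouteVector:
        """Register a user-supplied route (stoichiometry in moles)."""
        self._register(name, substrate, products, stoichiometry_mol)
        return self._routes[name]

    def route(self, name: str) -> RouteVector:
        try:
            return self._routes[name]
        except KeyError:
            raise UnknownRouteError(
                f"unknown route {name!r}; known: {sorted(self._routes)}"
            ) from None

    @property
    def route_names(self) -> List[str]:
        return sorted(self._routes)

    def known_products(self, substrate: str) -> List[str]:
        return sorted(p for (s, p) in self._by_pair if s == substrate)

    def build_product_route(self, substrate: str, product: str) -> RouteVector:
        """Canonical catabolic route producing ``product`` from ``substrate``.

        The CO2 "product" maps to the respiration route.  Raises
        :class:`UnknownRouteError` (listing the known products) when no
        canonical route exists for the pair.
        """
        if product == "CO2":
            return self.respiration_route(substrate)
        key = (substrate, product)
        if key not in self._by_pair:
            raise UnknownRouteError(
                f"no canonical route from {substrate!r} to {product!r}; known "
                f"products for {substrate!r}: {self.known_products(substrate) + ['CO2']}"
            )
        return self._routes[self._by_pair[key]]

    def respiration_route(
        self, substrate: str, nitrogen_reference: str = "ammonia"
    ) -> RouteVector:
        return respiration_route(self.species(substrate), nitrogen_reference)

    def anabolic_route(
        self,
        substrate: str,
        biomass_formula: str,
        nitrogen_reference: str = "ammonia",
        aerobic: bool = True,
    ) -> RouteVector:
        return anabolic_route(
            self.species(substrate),
            self.biomass_species(biomass_formula),
            nitrogen_reference,
            aerobic,
        )


def _load_species_table() -> Dict[str, Species]:
    table: Dict[str, Species] = {}
    text = resources.files("ncrfit.data").joinpath("species.tsv").read_text()
    header: List[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        rec = dict(zip(header, fields))
        table[rec["name"]] = Species(
            name=rec["name"],
            composition=ElementalComposition.from_formula(
                rec["formula"], charge=int(rec["charge"])
            ),
            phase_role=rec["phase_role"],
        )
    return table


def _load_route_table(species: Mapping[str, Species]):
    text = resources.files("ncrfit.data").joinpath("routes.tsv").read_text()
    header: List[str] | None = None
    records = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        rec = dict(zip(header, fields))
        stoich = {}
        for term in rec["stoichiometry"].split(";"):
            sp_name, coeff = term.split(":")
            stoich[sp_name.strip()] = float(coeff)
        records.append(
            (rec["name"], rec["substrate"], rec["products"].split(","), stoich)
        )
    return records


# Module-level carbon-free helper species shared by route constructors.
_REGISTRY_SPECIES = _load_species_table()
_O2 = _REGISTRY_SPECIES["O2"]
_CO2 = _REGISTRY_SPECIES["CO2"]
_H2O = _REGISTRY_SPECIES["H2O"]
_NH3 = _REGISTRY_SPECIES["ammonia"]
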