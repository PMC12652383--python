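"""Elemental compositions, degree-of-reduction arithmetic and balance checks.

All black-box growth bookkeeping in this package rests on two primitives:

* the elemental composition of a chemical species (possibly fractional, as in
  biomass formulas such as ``CH1.8O0.5N0.2``), and
* the *degree of reduction* gamma — the number of electrons per carbon-mole
  that a compound can donate relative to the reference set CO2, H2O and the
  nitrogen source of growth.

Gamma is computed with the classical valence bookkeeping of bioprocess
stoichiometry (Roels-style): C = +4, H = +1, O = -2, and a nitrogen weight
that depends on the nitrogen reference (-3 for ammonia, +5 for nitrate, 0 for
dinitrogen), so that CO2, H2O and the nitrogen source itself all have gamma
exactly 0.  Sulfur and phosphorus are excluded from gamma by default; biomass
S/P contents are small and the convention for them is not standardized (see
:data:`GAMMA_EXCLUDED_ELEMENTS`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

__all__ = [
    "ElementalComposition",
    "Species",
    "parse_formula",
    "degree_of_reduction",
    "element_balance",
    "is_balanced",
    "electron_balance",
    "NITROGEN_WEIGHTS",
    "BALANCE_TOL",
]

#: Absolute tolerance on net elemental counts for a reaction to count as
#: balanced.  Stoichiometries are exact rationals of measured reals, so the
#: tolerance only has to absorb floating-point round-off.
BALANCE_TOL = 1e-9

#: Valence weight of nitrogen for each admissible nitrogen reference
#: (the reference compound itself must come out at gamma = 0).
NITROGEN_WEIGHTS = {"ammonia": -3.0, "nitrate": +5.0, "dinitrogen": 0.0}

#: Elements that do not enter the degree of reduction under the default
#: convention.  Their presence is flagged in fit reports.
GAMMA_EXCLUDED_ELEMENTS = frozenset({"S", "P"})

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+\.?\d*|\.\d+)?")


def parse_formula(formula: str) -> Dict[str, float]:
    """Parse a Hill-notation formula string into an element -> count map.

    Fractional subscripts are accepted (``CH1.8O0.5N0.2``).  Raises
    ``ValueError`` on anything that is not a plain element/subscript string.
    """
    formula = formula.strip()
    if not formula:
        raise ValueError("empty formula string")
    pos = 0
    counts: Dict[str, float] = {}
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        element, number = match.groups()
        counts[element] = counts.get(element, 0.0) + (float(number) if number else 1.0)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


@dataclass(frozen=True)
class ElementalComposition:
    """Element -> count map per mole of compound, plus an optional charge.

    Counts may be fractional but must be non-negative, and at least one
    element must be present.  Compositions are always stored *per mole*;
    per-carbon-mole views are computed on demand (never stored) so a
    composition cannot be normalized twice.
    """

    counts: Mapping[str, float]
    charge: int = 0

    def __post_init__(self) -> None:
        cleaned = {el: float(n) for el, n in self.counts.items() if n != 0}
        if not cleaned:
            raise ValueError("composition must contain at least one element")
        for el, n in cleaned.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
        object.__setattr__(self, "counts", cleaned)

    @classmethod
    def from_formula(cls, formula: str, charge: int = 0) -> "ElementalComposition":
        return cls(parse_formula(formula), charge=charge)

    def __getitem__(self, element: str) -> float:
        return self.counts.get(element, 0.0)

    @property
    def carbon(self) -> float:
        return self["C"]

    @property
    def elements(self) -> Iterable[str]:
        return self.counts.keys()

    def per_carbon(self) -> "ElementalComposition":
        """Composition normalized to one carbon-mole (requires C > 0)."""
        if self.carbon <= 0:
            raise ValueError("per-carbon normalization requires C > 0")
        return ElementalComposition(
            {el: n / self.carbon for el, n in self.counts.items()},
            charge=self.charge,
        )

    def formula(self) -> str:
        """Hill-ish formula string (C, H first, then alphabetical)."""

        def fmt(n: float) -> str:
            if abs(n - round(n)) < 1e-12:
                n = int(round(n))
                return "" if n == 1 else str(n)
            return f"{n:g}"

        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{el}{fmt(self.counts[el])}" for el in order)


@dataclass(frozen=True, eq=False)
class Species:
    """A named chemical species taking part in growth stoichiometry.

    ``phase_role`` distinguishes dissolved solutes (which carry concentration
    terms in Gibbs-energy evaluation), water (activity 1) and biomass (no
    formation energy; removed before any energy evaluation).  ``composition``
    is per mole; biomass species are conventionally defined with a
    one-carbon formula so that mole and C-mol coincide.

    Species are identified by name (hash/equality), so stoichiometry maps can
    be keyed by Species objects.
    """

    name: str
    composition: ElementalComposition
    phase_role: str = "solute"  # solute | water | biomass
    formation_key: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.phase_role not in ("solute", "water", "biomass"):
            raise ValueError(f"unknown phase role {self.phase_role!r}")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Species) and self.name == other.name

    def __hash__(self) -> int:
        return hash(self.name)

    @property
    def carbon(self) -> float:
        return self.composition.carbon

    def __repr__(self) -> str:  # keep reprs short in error messages
        return f"Species({self.name})"


def degree_of_reduction(
    comp: ElementalComposition, nitrogen_reference: str = "ammonia"
) -> float:
    """Electrons available per carbon-mole, relative to CO2/H2O/N-source.

    Parameters
    ----------
    comp
        Elemental composition (per mole or per C-mol; the result is
        intensive).  Must contain carbon.
    nitrogen_reference
        Reference redox state of nitrogen: ``"ammonia"`` (weight -3),
        ``"nitrate"`` (+5) or ``"dinitrogen"`` (0).

    Returns
    -------
    float
        gamma = (4*C + 1*H - 2*O + w_N*N) / C.  S and P are excluded.
    """
    if comp.carbon <= 0:
        raise ValueError("degree of reduction requires a carbon-containing compound")
    try:
        w_n = NITROGEN_WEIGHTS[nitrogen_reference]
    except KeyError:
        raise ValueError(
            f"unknown nitrogen reference {nitrogen_reference!r}; "
            f"expected one of {sorted(NITROGEN_WEIGHTS)}"
        ) from None
    electrons = 4.0 * comp["C"] + 1.0 * comp["H"] - 2.0 * comp["O"] + w_n * comp["N"]
    return electrons / comp.carbon


def element_balance(reaction: Mapping[Species, float]) -> Dict[str, float]:
    """Net elemental counts of a reaction given as species -> mole coefficient.

    A balanced reaction returns all-zero entries (within round-off);
    production is positive, consumption negative, matching the sign
    convention of the coefficients.
    """
    net: Dict[str, float] = {}
    for species, coeff in reaction.items():
        for el, n in species.composition.counts.items():
            net[el] = net.get(el, 0.0) + coeff * n
    return net


def is_balanced(
    reaction: Mapping[Species, float],
    tol: float = BALANCE_TOL,
    elements: Iterable[str] | None = None,
) -> bool:
    """True if the net count of every (or each named) element is within tol."""
    net = element_balance(reaction)
    if elements is None:
        return all(abs(v) <= tol for v in net.values())
    return all(abs(net.get(el, 0.0)) <= tol for el in elements)


def electron_balance(
    reaction: Mapping[Species, float], nitrogen_reference: str = "ammonia"
) -> float:
    """Net degree-of-reduction electrons of a reaction (0 when redox balanced).

    Carbon species contribute gamma * (C-mol flux); O2 accepts 4 electrons
    per mole, so with the consumption-negative sign convention it contributes
    ``-4 * coefficient``, which cancels the electrons donated by the oxidized
    carbon.  Coefficients are per mole.
    """
    net = 0.0
    for species, coeff in reaction.items():
        comp = species.composition
        if comp.carbon > 0:
            gamma = degree_of_reduction(comp, nitrogen_reference)
            net += gamma * comp.carbon * coeff
        elif comp["O"] == 2 and len(comp.counts) == 1:  # O2
            net -= 4.0 * coeff
    return net
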