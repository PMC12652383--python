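"""Reaction Gibbs energies under biochemical standard conventions.

Energies are evaluated from a bundled table of standard transformed formation
energies (pH 7.0, ionic strength 0.25 mol/L, Mg2+ 1 mM, 298.15 K).  For a
mole-based stoichiometry {species: nu}:

    drG'0 = sum nu * dfG'0
    drG   = drG'0 + R T sum_{solutes} nu * ln(c / 1 M)

with water at activity 1 and dissolved gases (O2, CO2) treated as solutes at
the same default concentration (1 mM unless overridden), so that one decade
of concentration change of a single species shifts drG by R T ln 10 = 5.708
kJ/mol at 298.15 K.

The catabolic Gibbs energy of growth, dG_X/S, is the reaction energy of the
net catabolic reaction normalized to one C-mol of biomass; favorable
catabolism is negative.  Only elementally balanced stoichiometries are
accepted, so dG_X/S is only ever reported for fully mass-balanced NCRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Mapping, Tuple

from .routes import RouteBasis, cmol_to_moles
from .stoichiometry import BALANCE_TOL, Species, element_balance

__all__ = [
    "R_KJ_PER_MOL_K",
    "ThermoContext",
    "ConstantsTable",
    "EnergyResult",
    "reaction_energy",
    "catabolic_gibbs_energy",
    "respiratory_partition",
    "atp_driving_force",
    "reference_atp_reactions",
    "MissingConstantError",
]

#: Gas constant in kJ mol^-1 K^-1.
R_KJ_PER_MOL_K = 8.314462618e-3


class MissingConstantError(KeyError):
    """A species in the reaction has no bundled formation energy."""


@dataclass(frozen=True)
class ThermoContext:
    """Evaluation conventions for reaction Gibbs energies.

    temperature : K (default 298.15; the reference state of the constants)
    pH, ionic_strength, magnesium : recorded conventions of the constants
        table (pH 7, 0.25 mol/L, 1 mM); they are provenance metadata, not
        recomputation knobs — no Legendre re-transform is attempted.
    concentration : default solute concentration in mol/L (1 mM).
    """

    temperature: float = 298.15
    pH: float = 7.0
    ionic_strength: float = 0.25
    magnesium: float = 1e-3
    concentration: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("temperature", "ionic_strength", "magnesium", "concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def RT(self) -> float:
        return R_KJ_PER_MOL_K * self.temperature

    def decade_shift(self) -> float:
        """Gibbs-energy shift per decade of one species' concentration (kJ/mol)."""
        return self.RT * math.log(10.0)


class ConstantsTable:
    """Standard transformed formation energies dfG'0 (kJ/mol) per species.

    Shipped as a versioned TSV fixture with per-entry provenance so the
    package evaluates energies offline; see ``data/formation_energies.tsv``
    for the reference conditions and anchor reactions.
    """

    REFERENCE = ThermoContext()

    def __init__(self, values: Mapping[str, float], provenance: Mapping[str, str] | None = None):
        self._values = dict(values)
        self.provenance = dict(provenance or {})

    @classmethod
    def bundled(cls) -> "ConstantsTable":
        text = resources.files("ncrfit.data").joinpath("formation_energies.tsv").read_text()
        values: Dict[str, float] = {}
        prov: Dict[str, str] = {}
        header = None
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            rec = dict(zip(header, fields))
            values[rec["species"]] = float(rec["dfG_prime_kJ_mol"])
            prov[rec["species"]] = rec.get("provenance", "")
        return cls(values, prov)

    def __contains__(self, key: str) -> bool:
        return key in self._values

    def __getitem__(self, key: str) -> float:
        try:
            return self._values[key]
        except KeyError:
            raise MissingConstantError(
                f"no standard formation energy for species {key!r}"
            ) from None

    def formation_energy(self, species: Species) -> float:
        return self[species.formation_key or species.name]


@dataclass(frozen=True)
class EnergyResult:
    """A reaction Gibbs energy under a stated convention.

    ``standard`` is drG'0 at the table's reference state; ``value`` adds the
    R T ln(c) concentration terms of the context.  For growth fits, ``value``
    is dG_X/S in kJ per C-mol biomass.  ``notes`` records convention caveats
    (e.g. evaluation at a temperature away from the constants' reference).
    """

    standard: float
    value: float
    context: ThermoContext
    notes: Tuple[str, ...] = ()

    def __float__(self) -> float:
        return self.value


def reaction_energy(
    stoichiometry_mol: Mapping[Species, float],
    context: ThermoContext | None = None,
    constants: ConstantsTable | None = None,
) -> EnergyResult:
    """Gibbs energy of a mole-based, elementally balanced reaction.

    Raises :class:`MissingConstantError` for species without constants and
    ``ValueError`` for unbalanced stoichiometries.  The empty reaction has
    energy exactly 0.
    """
    ctx = context or ThermoContext()
    table = constants or _BUNDLED
    stoich = {sp: c for sp, c in stoichiometry_mol.items() if c != 0.0}
    if not stoich:
        return EnergyResult(standard=0.0, value=0.0, context=ctx)
    net = element_balance(stoich)
    bad = {el: v for el, v in net.items() if abs(v) > max(BALANCE_TOL, 1e-9)}
    if bad:
        raise ValueError(
            f"reaction is not elementally balanced (residuals {bad}); "
            "Gibbs energies are only reported for mass-balanced conversions"
        )
    standard = 0.0
    log_term = 0.0
    for sp, coeff in stoich.items():
        if sp.phase_role == "biomass":
            raise ValueError(
                "biomass has no formation energy; subtract the anabolic route first"
            )
        standard += coeff * table.formation_energy(sp)
        if sp.phase_role == "solute":
            log_term += coeff * math.log(ctx.concentration)
    value = standard + ctx.RT * log_term
    notes: List[str] = []
    if abs(ctx.temperature - table.REFERENCE.temperature) > 1e-9:
        notes.append(
            f"RT terms use T = {ctx.temperature} K but formation energies are "
            f"tabulated at {table.REFERENCE.temperature} K (no dfG'0 re-transform)"
        )
    return EnergyResult(standard=standard, value=value, context=ctx, notes=tuple(notes))


def catabolic_gibbs_energy(
    ncr_cmol: Mapping[Species, float],
    context: ThermoContext | None = None,
    constants: ConstantsTable | None = None,
) -> EnergyResult:
    """dG_X/S: reaction energy of the per-C-mol-biomass NCR (kJ / C-mol X).

    ``ncr_cmol`` uses C-mol coefficients for carbon species (mol otherwise),
    as produced by the growth-equation fit; it is converted to moles before
    evaluation.  Favorable catabolism gives a negative value.
    """
    return reaction_energy(cmol_to_moles(ncr_cmol), context, constants)


def respiratory_partition(
    alpha: Mapping[str, float],
    basis: RouteBasis,
    context: ThermoContext | None = None,
    constants: ConstantsTable | None = None,
) -> Tuple[float, float, float]:
    """Split dG_X/S into (total, respiratory, non-respiratory) components.

    Each catabolic route i contributes alpha_i * E(v_i) / alpha_0 per C-mol
    biomass; the respiratory component is the complete-oxidation route's
    share (0, with all of dG_X/S non-respiratory, if the basis has none).
    By Hess's law the two components sum exactly to the total.
    """
    alpha_0 = alpha[basis.anabolic.name]
    if alpha_0 <= 0:
        raise ValueError("no biomass production in fit (alpha_0 <= 0)")
    total = 0.0
    respiratory = 0.0
    for route in basis.catabolic:
        a = alpha[route.name]
        if a == 0.0:
            continue
        energy = reaction_energy(route.to_moles(), context, constants).value
        contribution = a * energy / alpha_0
        total += contribution
        if route.is_respiratory:
            respiratory += contribution
    return total, respiratory, total - respiratory


def atp_driving_force(
    stoichiometry_mol: Mapping[Species, float],
    context: ThermoContext | None = None,
    constants: ConstantsTable | None = None,
) -> float:
    """Reaction Gibbs energy per mole of ATP formed (kJ/mol ATP).

    The reaction must produce net ATP; the result is intensive (invariant
    under scaling the whole reaction).
    """
    n_atp = 0.0
    for sp, coeff in stoichiometry_mol.items():
        if sp.name == "ATP":
            n_atp += coeff
    if n_atp <= 0:
        raise ValueError("reaction does not produce net ATP")
    energy = reaction_energy(stoichiometry_mol, context, constants)
    return energy.value / n_atp


# ---------------------------------------------------------------------------
# Demonstration catabolic pathways with explicit ATP stoichiometry.
# These are the classical textbook lumped reactions for slow (respiratory)
# versus fast (fermentative / overflow) growth of three model organisms;
# per-ATP driving forces computed from them illustrate how pathway choice
# trades Gibbs energy per ATP against ATP yield per glucose.
_ATP_PATHWAYS = [
    ("L. lactis mixed-acid fermentation", "slow",
     {"glucose": -1, "ADP": -3, "phosphate": -3,
      "acetate": 1, "ethanol": 1, "formate": 2, "ATP": 3, "H2O": 2}),
    ("L. lactis homolactic fermentation", "fast",
     {"glucose": -1, "ADP": -2, "phosphate": -2,
      "lactate": 2, "ATP": 2, "H2O": 2}),
    # Water coefficients are the balanced ones (combustion water plus one
    # H2O per ATP formed); water has activity 1 so this only restores the
    # elemental balance, it does not change any concentration term.
    ("S. cerevisiae respiration (36 ATP)", "slow",
     {"glucose": -1, "ADP": -36, "phosphate": -36, "O2": -6,
      "CO2": 6, "ATP": 36, "H2O": 42}),
    ("S. cerevisiae ethanol fermentation", "fast",
     {"glucose": -1, "ADP": -2, "phosphate": -2,
      "ethanol": 2, "CO2": 2, "ATP": 2, "H2O": 2}),
    ("E. coli respiration (28 ATP)", "slow",
     {"glucose": -1, "ADP": -28, "phosphate": -28, "O2": -6,
      "CO2": 6, "ATP": 28, "H2O": 34}),
    ("E. coli acetate overflow", "fast",
     {"glucose": -1, "ADP": -5, "phosphate": -5, "O2": -2,
      "acetate": 2, "CO2": 2, "ATP": 5, "H2O": 7}),
]


def reference_atp_reactions(registry) -> List[dict]:
    """The bundled demonstration ATP-pathway reactions, moles-based.

    Returns a list of dicts with keys ``name``, ``growth`` (slow/fast),
    ``stoichiometry`` ({Species: mol coefficient}) and ``n_atp``.
    """
    out = []
    for name, growth, stoich_names in _ATP_PATHWAYS:
        stoich = {registry.species(k): float(v) for k, v in stoich_names.items()}
        out.append(
            {
                "name": name,
                "growth": growth,
                "stoichiometry": stoich,
                "n_atp": float(stoich_names["ATP"]),
            }
        )
    return out


def parse_reaction(text: str, registry) -> Dict[Species, float]:
    """Parse a reaction string like ``glucose + 6 O2 -> 6 CO2 + 6 H2O``.

    Species are registry names; ``->`` or ``=`` separates sides; optional
    numeric (possibly fractional) prefactors.  Returns a moles-based map.
    """
    for sep in ("->", "=", "→"):
        if sep in text:
            lhs, rhs = text.split(sep, 1)
            break
    else:
        raise ValueError("reaction string needs '->' or '=' between sides")
    stoich: Dict[Species, float] = {}

    def add_side(side: str, sign: float) -> None:
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ValueError(f"empty term in reaction string {text!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, name = 1.0, parts[0]
            elif len(parts) == 2:
                coeff, name = float(parts[0]), parts[1]
            else:
                raise ValueError(f"cannot parse term {term!r}")
            sp = registry.species(name)
            stoich[sp] = stoich.get(sp, 0.0) + sign * coeff

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    return stoich


_BUNDLED = ConstantsTable.bundled()


def bundled_constants() -> ConstantsTable:
    """The package's bundled formation-energy table."""
    return _BUNDLED
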