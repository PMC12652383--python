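"""Two-extreme error bracket for carbon-recovery mismatch.

Chemostat datasets rarely close their carbon balance exactly; the fitted
(mass-balanced) growth equation therefore consumes a slightly different
amount of substrate than was measured.  The mismatch

    delta = |measured uptake| - |fitted uptake|   (C-mol per C-mol biomass)

is 'corrected' under two extreme assumptions, giving a bracket on dG_X/S:

* **to biomass** — the missing carbon was converted into biomass through the
  idealized anabolic route.  The NCR is unchanged but is now normalized to a
  larger biomass production, so |dG_X/S| shrinks.
* **to respiration** — the missing carbon was completely respired to CO2; the
  respiration conversion is added to the NCR, so |dG_X/S| grows.

When the fitted uptake exceeds the measured one the same construction runs in
reverse (delta < 0 removes biomass or respiration).  Both adjusted equations
stay fully mass balanced, and the bracket collapses to the point estimate as
carbon recovery approaches 100%.  Without measured gas exchange the recovery
mismatch is not interpretable and the bracket is reported unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from . import thermo
from .thermo import ConstantsTable, ThermoContext

__all__ = ["ErrorBracket", "error_bracket"]


@dataclass(frozen=True)
class ErrorBracket:
    """dG_X/S point estimate with recovery-mismatch extremes (kJ / C-mol X).

    ``to_biomass`` and ``to_respiration`` are the two extreme corrections;
    ``lower``/``upper`` are the same two values in numerical order, so
    ``lower <= point <= upper`` whenever the bracket is available.
    """

    point: float
    to_biomass: Optional[float] = None
    to_respiration: Optional[float] = None
    delta: Optional[float] = None
    available: bool = True
    reason: str | None = None

    @property
    def lower(self) -> float:
        return min(self.to_biomass, self.to_respiration)

    @property
    def upper(self) -> float:
        return max(self.to_biomass, self.to_respiration)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def __contains__(self, value: float) -> bool:
        return self.available and self.lower <= value <= self.upper

    def as_dict(self) -> dict:
        if not self.available:
            return {"available": False, "reason": self.reason, "point": self.point}

        def finite(x):  # JSON has no Infinity; None marks an unbounded extreme
            return x if math.isfinite(x) else None

        return {
            "available": True,
            "point": self.point,
            "lower": finite(self.lower),
            "upper": finite(self.upper),
            "to_biomass": finite(self.to_biomass),
            "to_respiration": finite(self.to_respiration),
            "delta_cmol": self.delta,
        }


def error_bracket(
    fit,
    context: ThermoContext | None = None,
    constants: ConstantsTable | None = None,
) -> ErrorBracket:
    """Compute the recovery-mismatch bracket for a growth-equation fit.

    Parameters
    ----------
    fit : GrowthFitResults
        A fitted growth equation (provides the NCR, the anabolic route and
        the measured/fitted substrate uptake).
    """
    ctx = fit.thermo_context(context)
    point = thermo.catabolic_gibbs_energy(fit.ncr, ctx, constants).value
    data = fit.data
    if not data.has_gas_exchange:
        return ErrorBracket(
            point=point,
            available=False,
            reason=(
                "gas exchange was not measured; the carbon recovery mismatch "
                "cannot be attributed and the bracket is omitted"
            ),
        )
    measured = data.value(data.substrate)  # negative
    fitted = fit.fitted_substrate_uptake()  # negative
    delta = abs(measured) - abs(fitted)
    if delta == 0.0:
        return ErrorBracket(
            point=point, to_biomass=point, to_respiration=point, delta=0.0
        )

    # Extreme 1: missing carbon -> biomass via the idealized anabolic route.
    # Adding lam * v_0 consumes lam * |v0_substrate| C-mol substrate, so the
    # biomass total becomes (1 + lam) and the unchanged NCR is renormalized.
    v0_sub = abs(fit.basis.anabolic.coefficient(data.substrate))
    lam = delta / v0_sub
    if 1.0 + lam <= 0:
        # The fitted uptake exceeds the measured one by more than the entire
        # anabolic consumption: no positive biomass amount can absorb the
        # mismatch, so the biomass-side extreme diverges (|dG| -> inf as the
        # corrected biomass -> 0) and is reported unbounded.
        g_biomass = math.copysign(math.inf, point) if point != 0 else 0.0
    else:
        g_biomass = point / (1.0 + lam)

    # Extreme 2: missing carbon -> completely respired to CO2; delta C-mol of
    # the respiration route is added to (or removed from) the NCR.
    resp = fit.model.registry.respiration_route(data.substrate, data.nitrogen_source)
    e_resp = thermo.reaction_energy(resp.to_moles(), ctx, constants).value
    g_respired = point + delta * e_resp

    return ErrorBracket(
        point=point,
        to_biomass=g_biomass,
        to_respiration=g_respired,
        delta=delta,
    )
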