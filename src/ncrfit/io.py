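"""Dataset CSV reader/writer and the multi-dataset analysis pipeline.

Exchange-dataset CSV layout (one file per experiment): a metadata block of
``key,value`` rows, a blank line, then the species table with header
``species,role,value,unit``.  Roles are biomass | substrate | product | gas.
Values are exchange coefficients in C-mol per C-mol biomass (mol for gases);
alternatively, rows may carry volumetric rates (unit ``mol/L/h``) together
with a ``biomass_concentration`` metadata entry (C-mol/L), in which case the
reader normalizes them per C-mol of biomass.

The writer is deterministic: rerunning on the same inputs produces identical
bytes (timestamps are confined to logging).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    ExchangeDataset,
    GrowthEquationModel,
    default_registry,
    normalize_dataset,
)
from .routes import BIOMASS_NAME, RouteRegistry
from .thermo import ConstantsTable, ThermoContext

__all__ = [
    "read_dataset_csv",
    "write_dataset_csv",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("ncrfit")

_META_BOOL = {"true": True, "false": False, "1": True, "0": False,
              "yes": True, "no": False}


def _fmt(x: float) -> str:
    return repr(float(x))  # shortest exact round-trip representation


def write_dataset_csv(dataset: ExchangeDataset, path, registry: RouteRegistry | None = None) -> None:
    """Write an :class:`ExchangeDataset` in the package CSV schema."""
    reg = registry or default_registry()
    lines = ["# ncrfit exchange dataset v1", "key,value"]
    meta = {
        "name": dataset.name or "",
        "dilution_rate": _fmt(dataset.dilution_rate),
        "temperature": _fmt(dataset.temperature),
        "pH": _fmt(dataset.pH),
        "nitrogen_source": dataset.nitrogen_source,
        "aerobic": "true" if dataset.aerobic else "false",
        "biomass_formula": dataset.biomass_formula,
        "substrate": dataset.substrate,
        "limitation": dataset.limitation or "",
    }
    lines += [f"{k},{v}" for k, v in meta.items()]
    lines.append("")
    lines.append("species,role,value,unit")
    for name, value in zip(dataset.species, dataset.values):
        if name == BIOMASS_NAME:
            role, unit = "biomass", "Cmol/Cmol"
        elif name == dataset.substrate:
            role, unit = "substrate", "Cmol/Cmol"
        elif reg.has_species(name) and reg.species(name).carbon == 0:
            role, unit = "gas", "mol/Cmol"
        elif name in ("O2", "CO2"):
            role, unit = "gas", "Cmol/Cmol"
        else:
            role, unit = "product", "Cmol/Cmol"
        lines.append(f"{name},{role},{_fmt(value)},{unit}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_dataset_csv(path, registry: RouteRegistry | None = None) -> ExchangeDataset:
    """Read an exchange dataset from the package CSV schema.

    Accepts either per-biomass exchange values or volumetric rates
    (``mol/L/h`` units plus a ``biomass_concentration`` metadata entry).
    """
    reg = registry or default_registry()
    text = Path(path).read_text()
    meta: Dict[str, str] = {}
    rows: List[dict] = []
    section = "meta"
    header: List[str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("#"):
            continue
        if not line:
            if meta:
                section = "table"
            continue
        if section == "meta":
            if line.lower().startswith("key,"):
                continue
            key, _, value = line.partition(",")
            meta[key.strip()] = value.strip()
        else:
            if header is None:
                header = [h.strip() for h in line.split(",")]
                continue
            rows.append(dict(zip(header, (f.strip() for f in line.split(",")))))
    if not rows:
        raise ValueError(f"{path}: no species table found")
    required = ("dilution_rate", "substrate", "biomass_formula")
    missing = [k for k in required if not meta.get(k)]
    if missing:
        raise ValueError(f"{path}: missing metadata entries {missing}")

    conditions = dict(
        substrate=meta["substrate"],
        biomass_formula=meta["biomass_formula"],
        temperature=float(meta.get("temperature", 298.15)),
        pH=float(meta.get("pH", 7.0)),
        nitrogen_source=meta.get("nitrogen_source", "ammonia"),
        aerobic=_META_BOOL[meta.get("aerobic", "true").lower()],
        limitation=meta.get("limitation") or None,
        name=meta.get("name") or None,
    )
    dilution = float(meta["dilution_rate"])

    volumetric = any(r["unit"] == "mol/L/h" for r in rows)
    if volumetric:
        if "biomass_concentration" not in meta:
            raise ValueError(
                f"{path}: volumetric rates need a biomass_concentration "
                "metadata entry (C-mol/L)"
            )
        rates = {
            r["species"]: float(r["value"])
            for r in rows
            if r["role"] != "biomass"
        }
        return normalize_dataset(
            rates,
            dilution,
            float(meta["biomass_concentration"]),
            registry=reg,
            **conditions,
        )

    species = [r["species"] for r in rows]
    values = np.array([float(r["value"]) for r in rows])
    if BIOMASS_NAME in species and species[0] != BIOMASS_NAME:
        idx = species.index(BIOMASS_NAME)
        order = [idx] + [i for i in range(len(species)) if i != idx]
        species = [species[i] for i in order]
        values = values[order]
    return ExchangeDataset(
        species=species, values=values, dilution_rate=dilution, **conditions
    )


def write_truth_json(truth: Mapping, path) -> None:
    Path(path).write_text(json.dumps(dict(truth), indent=2, sort_keys=True) + "\n")


@dataclass
class RunConfig:
    """Configuration of a multi-dataset pipeline run.

    CLI flags override config values; all effective settings are echoed into
    each report for provenance.
    """

    dataset_paths: Sequence[str]
    output_dir: str | None = None
    context: ThermoContext | None = None
    constants: ConstantsTable | None = None
    registry: RouteRegistry | None = None
    extra_routes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    verbosity: int = 0

    def __post_init__(self) -> None:
        missing = [p for p in self.dataset_paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"dataset files not found: {missing}")


def run_pipeline(config: RunConfig):
    """Run normalize -> basis -> fit -> NCR -> dG_X/S -> bracket per dataset.

    Returns ``(reports, table, failures)``: per-dataset report dicts, a
    combined DataFrame (one row per dataset, suitable for a dG_X/S versus
    dilution-rate plot colored by limitation), and a list of (path, error)
    pairs for datasets that failed (failures are isolated, not fatal).
    """
    registry = config.registry or default_registry()
    for name, stoich in config.extra_routes.items():
        parts = dict(stoich)
        substrate = parts.pop("__substrate__")
        products = parts.pop("__products__").split(",")
        registry.add_route(name, substrate, products, {k: float(v) for k, v in parts.items()})
    reports: List[dict] = []
    failures: List[tuple] = []
    for path in config.dataset_paths:
        try:
            dataset = read_dataset_csv(path, registry=registry)
            model = GrowthEquationModel(dataset, registry=registry)
            fit = model.fit()
            log.info(
                "%s: carbon recovery %.4f, basis %s, rss %.3e",
                path, fit.carbon_recovery, model.basis.names, fit.rss,
            )
            report = fit.report()
            if config.context is not None or config.constants is not None:
                energy = fit.gibbs_energy(config.context, config.constants)
                total, resp, non_resp = fit.respiratory_partition(
                    config.context, config.constants
                )
                bracket = fit.error_bracket(config.context, config.constants)
                report.update(
                    delta_g_x_s=energy.value,
                    delta_g_standard=energy.standard,
                    delta_g_respiratory=resp,
                    delta_g_non_respiratory=non_resp,
                    thermo_notes=list(energy.notes),
                    bracket=bracket.as_dict(),
                )
            report["source"] = str(path)
            reports.append(report)
        except Exception as exc:  # per-dataset isolation
            log.error("%s: %s", path, exc)
            failures.append((str(path), str(exc)))
    table = combined_table(reports)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for report in reports:
            stem = report.get("name") or Path(report["source"]).stem
            (out / f"{stem}.report.json").write_text(
                json.dumps(report, indent=2, sort_keys=True) + "\n"
            )
        table.to_csv(out / "combined.tsv", sep="\t", index=False)
    return reports, table, failures


def combined_table(reports: Sequence[Mapping]) -> pd.DataFrame:
    """One-row-per-dataset summary table of a pipeline run."""
    rows = []
    for rep in reports:
        bracket = rep.get("bracket", {})
        rows.append(
            {
                "name": rep.get("name"),
                "substrate": rep.get("substrate"),
                "dilution_rate": rep.get("dilution_rate"),
                "limitation": rep.get("limitation"),
                "aerobic": rep.get("aerobic"),
                "carbon_recovery": rep.get("carbon_recovery"),
                "rss": rep.get("rss"),
                "delta_g_x_s": rep.get("delta_g_x_s"),
                "delta_g_respiratory": rep.get("delta_g_respiratory"),
                "bracket_lower": bracket.get("lower"),
                "bracket_upper": bracket.get("upper"),
                "bracket_available": bracket.get("available"),
            }
        )
    return pd.DataFrame(rows)
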