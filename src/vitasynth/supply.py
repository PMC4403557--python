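"""Microbiota-to-host B-vitamin supply model.

Converts heterogeneous literature measurements of intracellular vitamin
content to a common mmol/gDW basis and estimates, per vitamin, the maximal
percentage of the human dietary reference intake (DRI) that colonic
bacteria could supply:

    %DRI = conc * biomass * M * r / DRI * 100

where ``conc`` is the intracellular concentration (mmol/gDW), ``biomass``
the lysing colonic biomass in gDW (cell count x per-cell dry mass x dead
fraction), ``M`` the molar mass (g/mol, so mmol*g/mol is numerically mg),
``r`` the predicted fraction of gut-microbiome producers, and DRI in
mg/day.  The estimate is an upper bound: it assumes the entire intracellular
pool of every dead producer cell reaches the host.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .annotations import VITAMINS, ValidationError

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214e23

UNITS = (
    "molar",
    "mass_per_volume",
    "molecules_per_cell",
    "mass_per_gDW",
    "production_rate_per_mgDW",
)

#: Units whose conversion needs a molar mass.
MASS_BASED_UNITS = ("mass_per_volume", "mass_per_gDW")


@dataclass(frozen=True)
class CellModel:
    """The colonic bacterial biomass model.

    Defaults: 10^14 cells in the colonic space, E. coli reference dry mass
    (4.89e-13 gDW/cell) and volume (1.1 um^3 = 1.1e-15 L), 31.7% dead
    (lysed, vitamin-releasing) cells as measured in fecal matter, and an
    anaerobic E. coli growth rate of 0.26 h^-1 for integrating production
    rates.
    """

    n_cells: float = 1e14
    cell_dry_mass: float = 4.89e-13  # gDW per cell
    dead_fraction: float = 0.317  # unitless, in (0, 1]
    cell_volume: float = 1.1e-15  # L per cell
    growth_rate: float = 0.26  # 1/h

    def __post_init__(self) -> None:
        for name in ("n_cells", "cell_dry_mass", "cell_volume", "growth_rate"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not (0 < self.dead_fraction <= 1):
            raise ValidationError("dead_fraction must lie in (0, 1]")

    @property
    def available_biomass_g(self) -> float:
        """gDW of lysing (vitamin-releasing) cells in the colon."""
        return self.n_cells * self.cell_dry_mass * self.dead_fraction


@dataclass(frozen=True)
class ConcentrationMeasurement:
    """One literature measurement of intracellular vitamin content."""

    vitamin: str
    value: float
    unit: str
    organism: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError("measurement value must be strictly positive")
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")


@dataclass(frozen=True)
class SupplyEntry:
    """Per-vitamin parameters of the supply model."""

    vitamin: str
    conc_mmol_per_gdw: float
    dri_mg_per_day: float
    hgm_producer_ratio: float
    molar_mass_g_per_mol: float
    molar_mass_form: str = ""

    def __post_init__(self) -> None:
        if self.conc_mmol_per_gdw <= 0 or self.molar_mass_g_per_mol <= 0:
            raise ValidationError("concentration and molar mass must be positive")
        if self.dri_mg_per_day <= 0:
            raise ValidationError("DRI must be strictly positive")
        if not (0 <= self.hgm_producer_ratio <= 1):
            raise ValidationError("producer ratio must lie in [0, 1]")


class SupplyParameters:
    """Supply-model entries for the eight vitamins, in canonical order."""

    def __init__(self, entries: dict[str, SupplyEntry]) -> None:
        self.entries = {v: entries[v] for v in VITAMINS if v in entries}
        extra = set(entries) - set(VITAMINS)
        if extra:
            raise ValidationError(f"unknown vitamin(s) in supply parameters: {sorted(extra)}")

    def __getitem__(self, vitamin: str) -> SupplyEntry:
        return self.entries[vitamin]

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


def to_mmol_per_gdw(
    m: ConcentrationMeasurement,
    cell: CellModel,
    molar_mass: float | None = None,
) -> float:
    """Convert a measurement to mmol per gDW.

    Conversions by unit (all results in mmol/gDW):

    - ``molar`` (mol/L of cell volume): value * cell_volume / cell_dry_mass
    - ``mass_per_volume`` (g/L): (value / M) * cell_volume / cell_dry_mass
    - ``molecules_per_cell``: value / (N_A * cell_dry_mass)
    - ``mass_per_gDW`` (g/gDW): value / M
    - ``production_rate_per_mgDW`` (mol h^-1 mgDW^-1): value / growth_rate,
      rescaled mgDW -> gDW (the steady-state content of a culture growing
      exponentially at the given rate)
    """
    if m.unit in MASS_BASED_UNITS:
        if molar_mass is None:
            raise ValidationError(f"molar mass required for unit {m.unit!r}")
        if molar_mass <= 0:
            raise ValidationError("molar mass must be strictly positive")
    per_gdw_L = cell.cell_volume / cell.cell_dry_mass  # L of cell volume per gDW
    if m.unit == "molar":
        mol_per_gdw = m.value * per_gdw_L
    elif m.unit == "mass_per_volume":
        mol_per_gdw = (m.value / molar_mass) * per_gdw_L
    elif m.unit == "molecules_per_cell":
        mol_per_gdw = m.value / (AVOGADRO * cell.cell_dry_mass)
    elif m.unit == "mass_per_gDW":
        mol_per_gdw = m.value / molar_mass
    else:  # production_rate_per_mgDW
        mol_per_gdw = m.value / cell.growth_rate * 1e3  # mgDW -> gDW
    return mol_per_gdw * 1e3  # mol -> mmol


def percent_dri(entry: SupplyEntry, cell: CellModel) -> float:
    """Percent of the daily reference intake suppliable by the microbiota.

    vitamin_mg = conc (mmol/gDW) * available biomass (gDW) * M (g/mol);
    %DRI = vitamin_mg * producer_ratio / DRI * 100.
    """
    vitamin_mg = (
        entry.conc_mmol_per_gdw * cell.available_biomass_g * entry.molar_mass_g_per_mol
    )
    return vitamin_mg * entry.hgm_producer_ratio / entry.dri_mg_per_day * 100.0


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention for tables)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _load_config() -> dict:
    text = resources.files("vitasynth.data").joinpath("supply.yaml").read_text()
    return yaml.safe_load(text)


def default_cell_model() -> CellModel:
    cfg = _load_config()["cell"]
    return CellModel(**cfg)


def default_supply_parameters() -> SupplyParameters:
    cfg = _load_config()["vitamins"]
    return SupplyParameters(
        {v: SupplyEntry(vitamin=v, **spec) for v, spec in cfg.items()}
    )


def default_measurements() -> dict[str, ConcentrationMeasurement]:
    cfg = _load_config()["measurements"]
    return {
        v: ConcentrationMeasurement(vitamin=v, **spec) for v, spec in cfg.items()
    }


def load_supply_config(path) -> tuple[SupplyParameters, CellModel, dict]:
    """Load a user constants file with the same layout as the packaged one."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cell = CellModel(**cfg.get("cell", {}))
    params = SupplyParameters(
        {v: SupplyEntry(vitamin=v, **spec) for v, spec in cfg["vitamins"].items()}
    )
    measurements = {
        v: ConcentrationMeasurement(vitamin=v, **spec)
        for v, spec in (cfg.get("measurements") or {}).items()
    }
    return params, cell, measurements


def convert_measurements(
    measurements: dict[str, ConcentrationMeasurement],
    cell: CellModel,
    params: SupplyParameters,
) -> dict[str, float]:
    """Convert all measurements to mmol/gDW using each vitamin's molar mass."""
    return {
        v: to_mmol_per_gdw(m, cell, params[v].molar_mass_g_per_mol)
        for v, m in measurements.items()
    }


def audit_conversions(
    measurements: dict[str, ConcentrationMeasurement],
    params: SupplyParameters,
    cell: CellModel,
) -> pd.DataFrame:
    """Compare converted measurements against the canonical concentrations.

    The canonical column is what the %DRI computation uses; conversions
    that disagree beyond 1 unit in the second significant figure are
    flagged and logged rather than forced (two are known literature-side
    inconsistencies: the biotin measurement converts 100-fold above the
    canonical value, and the niacin molecules-per-cell measurement converts
    ~15% above it).
    """
    converted = convert_measurements(measurements, cell, params)
    rows = []
    for v in VITAMINS:
        if v not in converted:
            continue
        canonical = params[v].conc_mmol_per_gdw
        got = converted[v]
        # agreement within one unit of the 2nd significant figure
        ulp = 10 ** (math.floor(math.log10(abs(canonical))) - 1)
        agrees = abs(got - canonical) <= ulp + 1e-12 * canonical
        if not agrees:
            logger.warning(
                "%s: converted concentration %.3g mmol/gDW disagrees with the "
                "canonical %.3g mmol/gDW (ratio %.3g); canonical value retained",
                v,
                got,
                canonical,
                got / canonical,
            )
        rows.append(
            {
                "vitamin": v,
                "converted_mmol_per_gdw": got,
                "canonical_mmol_per_gdw": canonical,
                "ratio": got / canonical,
                "agrees_2sf": agrees,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "vitamin",
            "converted_mmol_per_gdw",
            "canonical_mmol_per_gdw",
            "ratio",
            "agrees_2sf",
        ],
    )


def build_supply_table(
    params: SupplyParameters,
    cell: CellModel,
    measurements: dict[str, ConcentrationMeasurement] | None = None,
) -> pd.DataFrame:
    """The per-vitamin supply table: concentration, DRI, producer ratio, %DRI.

    When raw measurements are supplied, a converted-concentration column and
    an agreement flag are appended (see :func:`audit_conversions`).
    """
    rows = []
    for entry in params:
        rows.append(
            {
                "vitamin": entry.vitamin,
                "conc_mmol_per_gdw": entry.conc_mmol_per_gdw,
                "dri_mg_per_day": entry.dri_mg_per_day,
                "hgm_producer_ratio": entry.hgm_producer_ratio,
                "molar_mass_g_per_mol": entry.molar_mass_g_per_mol,
                "percent_dri": percent_dri(entry, cell),
            }
        )
    table = pd.DataFrame(rows).set_index("vitamin")
    if measurements is not None:
        audit = audit_conversions(measurements, params, cell).set_index("vitamin")
        table["converted_mmol_per_gdw"] = audit["converted_mmol_per_gdw"]
        table["conversion_agrees_2sf"] = audit["agrees_2sf"]
    return table
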