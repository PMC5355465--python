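"""Unit conventions and conversions for IgG quantities.

All internal computation uses µmol for amounts, days for time and
µmol day⁻¹ for rates.  Serum measurements arrive as concentrations in
g l⁻¹ (protein electrophoresis) or per-kg synthesis rates; these helpers
convert at the boundary using a small set of physiological constants:
the molar mass of IgG (0.15 g µmol⁻¹, i.e. 150 kDa), an average adult
plasma volume of 3 l, and an average body weight of 70 kg.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "UnitConstants",
    "DEFAULT_CONSTANTS",
    "conc_to_quantity",
    "quantity_to_conc",
    "mass_to_amount",
    "per_kg_rate_to_absolute",
]


@dataclass(frozen=True)
class UnitConstants:
    """Physiological constants used in unit conversions.

    Parameters
    ----------
    molar_mass : float
        Molar mass of IgG in g µmol⁻¹ (default 0.15).
    plasma_volume_v1 : float
        Average plasma volume in litres (default 3).
    body_weight_w : float
        Average body weight in kg (default 70).
    """

    molar_mass: float = 0.15
    plasma_volume_v1: float = 3.0
    body_weight_w: float = 70.0

    def __post_init__(self) -> None:
        for name in ("molar_mass", "plasma_volume_v1", "body_weight_w"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def from_config(cls, config: dict) -> "UnitConstants":
        """Build from flat config keys (molar_mass_g_per_umol,
        plasma_volume_l, body_weight_kg); missing keys take defaults."""
        return cls(
            molar_mass=float(config.get("molar_mass_g_per_umol", 0.15)),
            plasma_volume_v1=float(config.get("plasma_volume_l", 3.0)),
            body_weight_w=float(config.get("body_weight_kg", 70.0)),
        )


DEFAULT_CONSTANTS = UnitConstants()


def _require_nonnegative(value: float, name: str) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


def conc_to_quantity(concentration: float, constants: UnitConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a plasma concentration (g l⁻¹) to a plasma quantity (µmol).

    Divides by the molar mass and multiplies by the plasma volume.
    """
    _require_nonnegative(concentration, "concentration")
    return concentration / constants.molar_mass * constants.plasma_volume_v1


def quantity_to_conc(quantity: float, constants: UnitConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a plasma quantity (µmol) to a concentration (g l⁻¹).

    Exact inverse of :func:`conc_to_quantity`.
    """
    _require_nonnegative(quantity, "quantity")
    return quantity * constants.molar_mass / constants.plasma_volume_v1


def mass_to_amount(mass_mg: float, constants: UnitConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a mass in mg (e.g. a tracer dose) to an amount in µmol."""
    _require_nonnegative(mass_mg, "mass")
    return mass_mg / 1000.0 / constants.molar_mass


def per_kg_rate_to_absolute(rate_mg_per_day_per_kg: float,
                            constants: UnitConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a per-kg synthesis/recycling rate (mg day⁻¹ kg⁻¹) to an
    absolute whole-body rate (µmol day⁻¹) for the reference body weight."""
    _require_nonnegative(rate_mg_per_day_per_kg, "rate")
    return rate_mg_per_day_per_kg * constants.body_weight_w / 1000.0 / constants.molar_mass
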