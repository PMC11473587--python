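"""Acid-number stoichiometry for metal carboxylate salts.

A titration acid number (mg KOH per g of acid mixture) fixes the molar
acid content per gram; metal:acid stoichiometry (1:2 for divalent metals)
then gives the metal molar demand, and the metal's atomic weight converts
that to a metal weight fraction of the salt.  The default salt-mass model
takes the salt mass per gram of acid as ``1 g + metal mass``; the variant
that subtracts the displaced acidic protons is available behind a flag.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .rounding import round_sig

__all__ = [
    "KOH_MOLAR_MASS",
    "HYDROGEN_ATOMIC_WEIGHT",
    "MetalSpec",
    "AcidNumberRange",
    "CompositionResult",
    "koh_mmol_per_g",
    "metal_mmol_per_g",
    "metal_weight_fraction",
    "composition_range",
    "load_metal_registry",
    "get_metal",
    "REFINED_ACID_NUMBER_RANGE",
]

#: Molar mass of potassium hydroxide, g/mol.
KOH_MOLAR_MASS = 56.106

#: Conventional atomic weight of hydrogen, g/mol (proton-correction variant).
HYDROGEN_ATOMIC_WEIGHT = 1.008

#: Characteristic acid-number interval for refined naphthenic acids
#: (mg KOH per g of acid).
REFINED_ACID_NUMBER_RANGE = (225.0, 270.0)


@dataclass(frozen=True)
class MetalSpec:
    symbol: str
    atomic_weight: float
    oxidation_state: int = 2
    name: str = ""
    mrl: float | None = None
    mrl_duration: str = ""
    mrl_basis: str = ""

    def __post_init__(self):
        if self.atomic_weight <= 0:
            raise ValueError("atomic_weight must be positive")
        if self.oxidation_state < 1:
            raise ValueError("oxidation_state must be >= 1")
        if self.mrl is not None and self.mrl <= 0:
            raise ValueError("mrl must be positive when present")


@dataclass(frozen=True)
class AcidNumberRange:
    """Acid-number interval in mg KOH per g of acid mixture."""

    lower: float
    upper: float

    def __post_init__(self):
        if not (0 < self.lower <= self.upper):
            raise ValueError(f"invalid acid-number range {self.lower}..{self.upper}")


@dataclass(frozen=True)
class CompositionResult:
    """Weight-fraction bounds for metal and organic components of a salt.

    ``metal_fraction`` is ordered (at lower AN, at upper AN); the
    naphthenate fractions are the complements, so the upper metal bound
    pairs with the lower naphthenate bound.
    """

    metal: MetalSpec
    acid_numbers: AcidNumberRange
    metal_fraction: tuple[float, float]
    naphthenate_fraction: tuple[float, float]
    assumes_complete_reaction: bool = True
    correct_displaced_protons: bool = False

    def metal_percent(self, decimals: int = 1) -> tuple[float, float]:
        return tuple(round(100 * f, decimals) for f in self.metal_fraction)

    def naphthenate_percent(self, decimals: int = 1) -> tuple[float, float]:
        return tuple(round(100 * f, decimals) for f in self.naphthenate_fraction)


def koh_mmol_per_g(acid_number: float) -> float:
    """mmol of KOH needed to neutralize 1 g of the acid mixture."""
    if acid_number <= 0:
        raise ValueError(f"acid number must be positive, got {acid_number}")
    return acid_number / KOH_MOLAR_MASS


def metal_mmol_per_g(acid_mmol: float, oxidation_state: int) -> float:
    """Metal molar demand per gram of acid under 1:n metal:acid stoichiometry."""
    if acid_mmol <= 0:
        raise ValueError(f"acid mmol must be positive, got {acid_mmol}")
    if oxidation_state < 1:
        raise ValueError(f"oxidation state must be >= 1, got {oxidation_state}")
    return acid_mmol / oxidation_state


def metal_weight_fraction(
    acid_number: float,
    metal: MetalSpec,
    correct_displaced_protons: bool = False,
) -> float:
    """Metal weight fraction of the salt formed from 1 g of acid.

    The metal mass per gram of acid is ``mmol_metal * atomic_weight / 1000``;
    the default salt mass is ``1 g + metal mass``.  With
    ``correct_displaced_protons=True`` the mass of the acidic hydrogens
    displaced on salt formation is subtracted from the salt mass.
    """
    acid_mmol = koh_mmol_per_g(acid_number)
    m_metal = metal_mmol_per_g(acid_mmol, metal.oxidation_state) * metal.atomic_weight / 1000.0
    salt_mass = 1.0 + m_metal
    if correct_displaced_protons:
        salt_mass -= acid_mmol * HYDROGEN_ATOMIC_WEIGHT / 1000.0
    return m_metal / salt_mass


def composition_range(
    an_range: AcidNumberRange,
    metal: MetalSpec,
    correct_displaced_protons: bool = False,
) -> CompositionResult:
    """Metal/organic weight-fraction bounds over an acid-number interval."""
    f_lo = metal_weight_fraction(an_range.lower, metal, correct_displaced_protons)
    f_hi = metal_weight_fraction(an_range.upper, metal, correct_displaced_protons)
    return CompositionResult(
        metal=metal,
        acid_numbers=an_range,
        metal_fraction=(f_lo, f_hi),
        naphthenate_fraction=(1.0 - f_lo, 1.0 - f_hi),
        correct_displaced_protons=correct_displaced_protons,
    )


# ---------------------------------------------------------------------------
# registry

def load_metal_registry(path: str | Path | None = None) -> dict[str, MetalSpec]:
    """Load the metal registry (packaged Cu/Zn/Co registry by default)."""
    if path is None:
        text = importlib.resources.files("uvcbkit.data").joinpath("metals.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "metals" not in raw:
        raise ConfigurationError("metal registry must contain a 'metals' list")
    registry = {}
    for entry in raw["metals"]:
        spec = MetalSpec(**entry)
        registry[spec.symbol] = spec
    return registry


def get_metal(symbol: str, path: str | Path | None = None) -> MetalSpec:
    registry = load_metal_registry(path)
    if symbol not in registry:
        raise ConfigurationError(
            f"metal {symbol!r} not in registry (have {sorted(registry)})"
        )
    return registry[symbol]
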