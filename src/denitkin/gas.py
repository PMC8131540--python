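"""Gas-liquid partitioning of headspace gases in sealed culture bottles.

Sealed serum bottles hold a liquid culture phase in equilibrium with a He
headspace.  CO2, N2O and N2 partition between the two phases according to a
dimensionless Henry constant H = C_aq / C_g (solubility convention: H grows
with solubility, so CO2 > N2O > N2).  H is computed from a tabulated solubility
Hcp at 298.15 K with a van't Hoff temperature correction,

    Hcp(T) = Hcp_ref * exp(d * (1/T - 1/298.15)),   H = Hcp(T) * R * T,

optionally reduced for ionic strength by a Sechenov/Schumpe salting-out term.

The default parameter set (literature solubility compilation values) yields
H = 0.726 (CO2), 0.528 (N2O) and 0.015 (N2) at 30 degC and zero ionic strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

R_L_ATM = 0.082057  # gas constant, L atm mol-1 K-1
T_REF = 298.15  # K, reference temperature of the solubility tabulation


class GasConfigurationError(KeyError):
    """Unknown species or missing coefficient in the gas parameter tables."""


@dataclass(frozen=True)
class GasSpeciesSpec:
    """Physical constants of one gas.

    hcp_ref
        Solubility Hcp at 298.15 K, mol L-1 atm-1.
    vant_hoff_d
        d(ln Hcp)/d(1/T), K.  Positive for gases whose solubility falls
        with warming (all three gases here).
    sechenov_gas
        Gas-specific contribution h_G to the Schumpe salting-out model,
        L mol-1.
    """

    name: str
    hcp_ref: float
    vant_hoff_d: float
    sechenov_gas: float = 0.0

    def __post_init__(self) -> None:
        if self.hcp_ref <= 0:
            raise ValueError(f"hcp_ref must be positive, got {self.hcp_ref}")
        if self.vant_hoff_d < 0:
            raise ValueError("vant_hoff_d must be >= 0 for these gases")


# Default literature solubility parameters (overridable via a gas table file).
# Schumpe gas-specific coefficients h_G at 298.15 K, L mol-1.
DEFAULT_SPECIES: dict[str, GasSpeciesSpec] = {
    "CO2": GasSpeciesSpec("CO2", hcp_ref=0.0334, vant_hoff_d=2400.0, sechenov_gas=-0.0172),
    "N2O": GasSpeciesSpec("N2O", hcp_ref=0.0245, vant_hoff_d=2600.0, sechenov_gas=-0.0085),
    "N2": GasSpeciesSpec("N2", hcp_ref=6.4e-4, vant_hoff_d=1300.0, sechenov_gas=-0.0010),
}


@dataclass(frozen=True)
class HenryConstant:
    """Dimensionless Henry constant, solubility convention C_aq/C_g."""

    species: str
    value: float
    temperature: float
    ionic_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("Henry constant must be positive")


@dataclass(frozen=True)
class Ion:
    name: str
    conc: float  # mol L-1
    sechenov: float  # Schumpe ion coefficient h_i, L mol-1
    charge: int

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError(f"negative concentration for ion {self.name}")


@dataclass(frozen=True)
class IonComposition:
    """Ionic composition of a medium for salting-out and charge-balance checks."""

    ions: tuple[Ion, ...] = ()

    @classmethod
    def from_list(cls, items: Sequence[tuple[str, float, float, int]]) -> "IonComposition":
        return cls(tuple(Ion(*item) for item in items))

    @property
    def ionic_strength(self) -> float:
        return 0.5 * sum(ion.conc * ion.charge**2 for ion in self.ions)

    def charge_imbalance(self) -> float:
        """Net charge, eq L-1; should be ~0 for a complete medium description."""
        return sum(ion.conc * ion.charge for ion in self.ions)

    def require_balanced(self, tol: float = 1e-6) -> None:
        imbalance = self.charge_imbalance()
        if abs(imbalance) > tol:
            raise ValueError(f"medium not charge balanced: net {imbalance:+.3g} eq/L")


# CSBK-like minimal medium approximated by its dominant ions with Schumpe
# coefficients (L mol-1).  Concentrations in mol L-1.
DEFAULT_MEDIUM = IonComposition.from_list(
    [
        ("Na+", 0.035, 0.1143, 1),
        ("K+", 0.002, 0.0922, 1),
        ("NH4+", 0.002, 0.0556, 1),
        ("Mg2+", 0.0005, 0.1694, 2),
        ("Ca2+", 0.0005, 0.1762, 2),
        ("Cl-", 0.0105, 0.0318, -1),
        ("HCO3-", 0.0025, 0.0967, -1),
        ("SO42-", 0.001, 0.1117, -2),
        ("HPO42-", 0.013, 0.1499, -2),
    ]
)


@dataclass(frozen=True)
class BottleConfig:
    """Geometry and conditions of one sealed serum bottle.

    Defaults mirror the batch design: 120 mL bottle with 50 mL liquid and
    ~70 mL He headspace at 0.9 atm and 30 degC; aqueous detection limit
    0.001 mmol L-1; gas quantitation range 0.002-20 mmol L-1.
    """

    liquid_volume: float = 0.050  # L
    headspace_volume: float = 0.070  # L
    temperature: float = 303.15  # K
    pressure: float = 0.9  # atm
    medium: IonComposition = field(default_factory=lambda: DEFAULT_MEDIUM)
    detection_limit: float = 0.001  # mmol L-1, aqueous species
    gas_quantitation_range: tuple[float, float] = (0.002, 20.0)  # mmol L-1

    def __post_init__(self) -> None:
        if self.liquid_volume <= 0 or self.headspace_volume <= 0:
            raise ValueError("bottle volumes must be positive")
        if self.pressure <= 0:
            raise ValueError("pressure must be positive")
        if self.liquid_volume + self.headspace_volume > 0.1201:
            raise ValueError("liquid + headspace exceed the 120 mL bottle volume")


def get_species(name: str, table: dict[str, GasSpeciesSpec] | None = None) -> GasSpeciesSpec:
    table = DEFAULT_SPECIES if table is None else table
    try:
        return table[name]
    except KeyError:
        raise GasConfigurationError(
            f"unknown gas species {name!r}; known: {sorted(table)}"
        ) from None


def dimensionless_henry(species: GasSpeciesSpec, temperature: float) -> HenryConstant:
    """Dimensionless Henry constant C_aq/C_g at `temperature` (K), zero ionic strength.

    H = Hcp_ref * exp(d * (1/T - 1/T_ref)) * R * T.
    """
    if not 273.0 < temperature < 373.0:
        raise ValueError(f"temperature {temperature} K outside liquid-water range (273, 373)")
    hcp = species.hcp_ref * math.exp(species.vant_hoff_d * (1.0 / temperature - 1.0 / T_REF))
    return HenryConstant(species.name, hcp * R_L_ATM * temperature, temperature, 0.0)


def headspace_to_aqueous(c_gas: float, h: HenryConstant) -> float:
    """Aqueous concentration in equilibrium with a headspace concentration."""
    if c_gas < 0:
        raise ValueError(f"negative gas concentration {c_gas}")
    return c_gas * h.value


def aqueous_to_headspace(c_aq: float, h: HenryConstant) -> float:
    """Inverse of :func:`headspace_to_aqueous`."""
    if c_aq < 0:
        raise ValueError(f"negative aqueous concentration {c_aq}")
    return c_aq / h.value


def salting_out(
    h0: HenryConstant, medium: IonComposition, species: GasSpeciesSpec
) -> HenryConstant:
    """Reduce a zero-ionic-strength Henry constant for medium salt content.

    Schumpe model: log10(H0/H) = sum_i (h_i + h_G) * c_i over all ions.
    """
    exponent = sum((ion.sechenov + species.sechenov_gas) * ion.conc for ion in medium.ions)
    return HenryConstant(
        h0.species,
        h0.value / 10.0**exponent,
        h0.temperature,
        medium.ionic_strength,
    )


def total_species_moles(c_aq: float, c_gas: float, cfg: BottleConfig) -> float:
    """Whole-bottle inventory in mmol from phase concentrations in mmol L-1."""
    if c_aq < 0 or c_gas < 0:
        raise ValueError("concentrations must be >= 0")
    return c_aq * cfg.liquid_volume + c_gas * cfg.headspace_volume


def partition_total(total_per_liquid_l: float, h: HenryConstant, cfg: BottleConfig) -> tuple[float, float]:
    """Split a whole-bottle pool (expressed as mmol per L of liquid) into
    equilibrium (c_aq, c_gas) phase concentrations, both mmol L-1."""
    if total_per_liquid_l < 0:
        raise ValueError("total must be >= 0")
    c_gas = total_per_liquid_l * cfg.liquid_volume / (
        h.value * cfg.liquid_volume + cfg.headspace_volume
    )
    return h.value * c_gas, c_gas


def vented_overpressure_moles(extra_volume_ml: float, cfg: BottleConfig) -> float:
    """Ideal-gas mmol vented when excess pressure is released to barometric.

    The syringe-piston displacement (mL) recorded before each sampling is the
    headspace volume in excess of the bottle at cfg.pressure; the moles it held
    are added back when accumulating cumulative gas production.
    """
    if extra_volume_ml < 0:
        raise ValueError("vented volume must be >= 0")
    volume_l = extra_volume_ml / 1000.0
    return 1000.0 * cfg.pressure * volume_l / (R_L_ATM * cfg.temperature)


def replace_species(spec: GasSpeciesSpec, **kwargs) -> GasSpeciesSpec:
    """Convenience for overriding default parameters."""
    return replace(spec, **kwargs)
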