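"""Closed-bottle carbonate system: pH, DIC and alkalinity, coupled to
denitrification stoichiometry.

In a sealed, anoxic culture bottle the CO2 produced by acetate oxidation stays
in solution (the headspace fraction is negligible above pH ~8), so complete
denitrification shifts both the dissolved inorganic carbon (DIC) and the total
alkalinity (TA) and hence the pH.  The balanced catabolic reaction is

    0.625 CH3COO- + NO3- + 0.375 H+  ->  0.5 N2 + 1.25 HCO3- + 0.5 H2O

so each mmol of NO3- fully reduced to N2 adds 1.25 mmol DIC and
1.25 + 0.375 = 1.625 meq TA per litre.  With TA and DIC known, pH follows from
carbonate speciation:

    TA = DIC * (a1 + 2 a2) + [OH-] - [H+]        (carbonate alkalinity, meq/L)

where a1, a2 are the HCO3-/CO3 2- ionization fractions.  Starting from the
measured pH 7.50 / TA 2.51 meq/L and ~0.88 mmol/L NO3- reduced, the model
predicts a final pH near 8.9, bracketing the measured 8.82 +/- 0.08.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .gas import BottleConfig, HenryConstant


@dataclass(frozen=True)
class CarbonateConstants:
    """Carbonic acid / water dissociation constants at working conditions."""

    pk1: float
    pk2: float
    pkw: float
    temperature: float = 303.15
    ionic_strength: float = 0.0
    activity_model: str = "none"

    def __post_init__(self) -> None:
        if not self.pk1 < self.pk2:
            raise ValueError("pK1 must be < pK2")
        for pk in (self.pk1, self.pk2, self.pkw):
            if not 0.0 < pk < 20.0:
                raise ValueError(f"pK value {pk} outside (0, 20)")

    @property
    def k1(self) -> float:
        return 10.0**-self.pk1

    @property
    def k2(self) -> float:
        return 10.0**-self.pk2

    @property
    def kw(self) -> float:
        return 10.0**-self.pkw


def _davies_log_gamma(z: int, ionic_strength: float) -> float:
    """Davies activity model, log10 gamma at 25-30 degC (A ~ 0.51)."""
    if ionic_strength <= 0:
        return 0.0
    sqrt_i = math.sqrt(ionic_strength)
    return -0.51 * z * z * (sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength)


def equilibrium_constants(
    temperature: float = 303.15,
    ionic_strength: float = 0.0,
    activity_model: str = "none",
) -> CarbonateConstants:
    """Freshwater carbonate pK values at `temperature` (K).

    Standard polynomial temperature fits for zero ionic strength:
    pK1 ~ 6.35, pK2 ~ 10.33, pKw ~ 14.00 at 25 degC and
    pK1 ~ 6.33, pK2 ~ 10.29, pKw ~ 13.83 at 30 degC.  An optional Davies
    correction converts them to apparent (concentration-scale) constants.
    """
    if not 273.0 < temperature < 373.0:
        raise ValueError(f"temperature {temperature} K outside (273, 373)")
    if activity_model not in ("none", "davies"):
        raise ValueError(f"unknown activity model {activity_model!r}")
    t = temperature
    pk1 = 3404.71 / t + 0.032786 * t - 14.8435
    pk2 = 2902.39 / t + 0.02379 * t - 6.4980
    pkw = 4470.99 / t + 0.017060 * t - 6.0875
    if activity_model == "davies" and ionic_strength > 0:
        lg1 = _davies_log_gamma(1, ionic_strength)
        lg2 = _davies_log_gamma(2, ionic_strength)
        # Apparent constants: K1' = K1 / (g_H g_HCO3 / g_CO2) etc.; neutral
        # species activity taken as 1.
        pk1 = pk1 + 2.0 * lg1
        pk2 = pk2 + lg2  # gamma_H * gamma_CO3 / gamma_HCO3 -> lg1 + lg2 - lg1
        pkw = pkw + 2.0 * lg1
    return CarbonateConstants(pk1, pk2, pkw, temperature, ionic_strength, activity_model)


def ionization_fractions(ph: float, k: CarbonateConstants) -> tuple[float, float, float]:
    """(a0, a1, a2) for CO2(aq), HCO3- and CO3 2- at the given pH; sum to 1."""
    h = 10.0**-ph
    denom = h * h + h * k.k1 + k.k1 * k.k2
    return h * h / denom, h * k.k1 / denom, k.k1 * k.k2 / denom


@dataclass(frozen=True)
class CarbonateState:
    """DIC (mmol/L), carbonate alkalinity TA (meq/L) and pH of one bottle."""

    dic: float
    ta: float
    ph: float

    def __post_init__(self) -> None:
        if self.dic < 0:
            raise ValueError("DIC must be >= 0")


def alkalinity_from_ph_dic(ph: float, dic: float, k: CarbonateConstants) -> float:
    """Carbonate alkalinity (meq/L) from pH and DIC (mmol/L).

    TA = dic*(a1 + 2 a2) + 1000*([OH-] - [H+]); the 1000 converts the mol/L
    proton terms to meq/L.
    """
    if dic < 0:
        raise ValueError("DIC must be >= 0")
    _, a1, a2 = ionization_fractions(ph, k)
    h = 10.0**-ph
    return dic * (a1 + 2.0 * a2) + 1000.0 * (k.kw / h - h)


def ph_from_ta_dic(ta: float, dic: float, k: CarbonateConstants) -> float:
    """Invert :func:`alkalinity_from_ph_dic` by bracketed root finding.

    TA is strictly increasing in pH for dic >= 0, so the root on [2, 13] is
    unique when it exists; residual tolerance 1e-9 meq/L.
    """
    lo, hi = 2.0, 13.0
    f_lo = alkalinity_from_ph_dic(lo, dic, k) - ta
    f_hi = alkalinity_from_ph_dic(hi, dic, k) - ta
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"alkalinity {ta} meq/L not attainable for DIC {dic} mmol/L: "
            f"TA(pH 2) = {f_lo + ta:.4g}, TA(pH 13) = {f_hi + ta:.4g}"
        )
    return brentq(
        lambda p: alkalinity_from_ph_dic(p, dic, k) - ta, lo, hi, xtol=1e-12, rtol=1e-15
    )


def dic_from_ph_ta(ph: float, ta: float, k: CarbonateConstants) -> float:
    """DIC (mmol/L) consistent with a measured pH and TA (meq/L)."""
    _, a1, a2 = ionization_fractions(ph, k)
    h = 10.0**-ph
    dic = (ta - 1000.0 * (k.kw / h - h)) / (a1 + 2.0 * a2)
    if dic < 0:
        raise ValueError(f"negative DIC implied by pH {ph}, TA {ta}")
    return dic


@dataclass(frozen=True)
class StoichiometryCoefficients:
    """Coefficients of acetate-driven denitrification, per mol of N oxide.

    Electron balance (8 e- donated per acetate): NO3- -> N2 takes 5 e-/N so
    acetate_per_no3 = 5/8 = 0.625; NO2- -> N2 takes 3 e-/N (0.375); N2O -> N2
    takes 1 e-/N i.e. 2 e- per N2O (0.25).  TA rises by 1.25 eq (HCO3-) plus
    0.375 eq (H+ consumed) = 1.625 eq per mol NO3- fully reduced.
    """

    acetate_per_no3: float = 0.625
    hco3_per_no3: float = 1.25
    h_consumed_per_no3: float = 0.375
    n2_per_no3: float = 0.5
    ta_change_per_no3: float = 1.625
    acetate_per_no2: float = 0.375
    acetate_per_n2o: float = 0.25
    assimilated_fraction: float = 0.25

    def __post_init__(self) -> None:
        # electron balance must close exactly
        for lhs, rhs in (
            (8.0 * self.acetate_per_no3, 5.0),
            (8.0 * self.acetate_per_no2, 3.0),
            (8.0 * self.acetate_per_n2o, 2.0),
        ):
            if abs(lhs - rhs) > 1e-12:
                raise ValueError(f"electron balance violated: {lhs} != {rhs}")
        if not 0.0 <= self.assimilated_fraction < 1.0:
            raise ValueError("assimilated_fraction must be in [0, 1)")


def apply_denitrification_stoichiometry(
    state: CarbonateState,
    no3_reduced_to_n2: float,
    s: StoichiometryCoefficients | None = None,
    k: CarbonateConstants | None = None,
) -> CarbonateState:
    """Advance the carbonate state after `no3_reduced_to_n2` mmol/L NO3- -> N2.

    DIC gains 1.25 and TA gains 1.625 per mmol NO3-; pH is re-solved and can
    only rise (TA grows faster than DIC in alkalinity units).
    """
    if no3_reduced_to_n2 < 0:
        raise ValueError("no3_reduced_to_n2 must be >= 0")
    s = s or StoichiometryCoefficients()
    k = k or equilibrium_constants()
    dic = state.dic + s.hco3_per_no3 * no3_reduced_to_n2
    ta = state.ta + s.ta_change_per_no3 * no3_reduced_to_n2
    return CarbonateState(dic, ta, ph_from_ta_dic(ta, dic, k))


def stoichiometric_acetate_demand(
    no3_reduced: float, s: StoichiometryCoefficients | None = None
) -> float:
    """Catabolic acetate (mmol/L) oxidized to reduce `no3_reduced` NO3- to N2.

    0.625 mol acetate per mol NO3-; biomass assimilation is accounted
    separately (assimilated_fraction of total consumption).
    """
    if no3_reduced < 0:
        raise ValueError("no3_reduced must be >= 0")
    s = s or StoichiometryCoefficients()
    return s.acetate_per_no3 * no3_reduced


def co2_headspace_fraction(
    state: CarbonateState, cfg: BottleConfig, h_co2: HenryConstant
) -> float:
    """Fraction of total inorganic carbon residing in the headspace as CO2(g).

    CO2(aq) = DIC * a0 at the state's pH; the gas phase holds CO2(aq)/H per
    litre of headspace.  Above pH ~8.5 a0 is tiny and the fraction is < 5%,
    consistent with non-detection of headspace CO2 in alkaline cultures.
    """
    if state.dic == 0:
        return 0.0
    k = equilibrium_constants(cfg.temperature)
    a0, _, _ = ionization_fractions(state.ph, k)
    c_aq = state.dic * a0
    c_gas = c_aq / h_co2.value
    gas_mmol = c_gas * cfg.headspace_volume
    total_mmol = state.dic * cfg.liquid_volume + gas_mmol
    return gas_mmol / total_mmol


ACETATE_PKA = 4.76


def titration_alkalinity(
    ph: float,
    dic: float,
    acetate: float,
    k: CarbonateConstants,
    endpoint_ph: float = 3.5,
) -> float:
    """Alkalinity as measured by acid titration to `endpoint_ph` (meq/L).

    Adds the acetate contribution: the fraction of acetate protonated at the
    endpoint (~0.95 at pH 3.5 against pKa 4.76) consumes titrant on top of the
    carbonate alkalinity.  Flag-controlled alternative to the carbonate-only
    definition; the bottle measurements used a pH 3.5 endpoint.
    """
    frac_protonated = 1.0 / (1.0 + 10.0 ** (endpoint_ph - ACETATE_PKA))
    return alkalinity_from_ph_dic(ph, dic, k) + frac_protonated * acetate
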