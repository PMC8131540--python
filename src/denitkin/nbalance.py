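"""Nitrogen-atom bookkeeping and summary statistics for batch denitrification.

The headline statistic is the percentage of consumed NO3-N recovered as N2,

    % recovered = 100 * 2 * [N2] / ([NO3]initial - [NO3]final - [NO2]final),

where the factor 2 converts mol N2 to mol N and residual NO2- (but not N2O)
is subtracted from the denominator; this is the form that reproduces the
printed per-strain recovery tables.  Fold changes of N2 production between an
optimum-pH reference and a treatment are reported on a signed scale: ratios
below one are expressed as a negative "fold decrease" (-1/ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gas import BottleConfig, dimensionless_henry, get_species, total_species_moles


@dataclass(frozen=True)
class NSpeciesSnapshot:
    """All N pools of one bottle at one time, mmol L-1 in their phases."""

    no3: float = 0.0
    no2: float = 0.0
    n2o_aq: float = 0.0
    n2o_gas: float = 0.0
    n2_aq: float = 0.0
    n2_gas: float = 0.0
    below_detection: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in ("no3", "no2", "n2o_aq", "n2o_gas", "n2_aq", "n2_gas"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        for name in self.below_detection:
            if getattr(self, name, 0.0) != 0.0:
                raise ValueError(f"below-detection species {name} must carry value 0")


@dataclass(frozen=True)
class RecoveryResult:
    percent_recovered_as_n2: float
    n_atoms_in: float  # mmol N, whole bottle
    n_atoms_out_by_species: dict[str, float]
    closure: float  # sum(out) / in


def percent_recovered_as_n2(
    no3_initial: float,
    no3_final: float,
    no2_final: float,
    n2_final: float,
    *,
    literal_printed_form: bool = False,
) -> float:
    """% of consumed NO3-N recovered as N2 (all inputs mmol L-1).

    With `literal_printed_form` the uncorrected ratio
    100*[N2]/([NO3]i - [NO3]f) is returned instead (no factor 2, no NO2-
    subtraction) for comparison with the formula as typeset.
    """
    if min(no3_initial, no3_final, no2_final, n2_final) < 0:
        raise ValueError("concentrations must be >= 0")
    if literal_printed_form:
        denom = no3_initial - no3_final
        if denom <= 0:
            raise ValueError("no NO3- consumed: denominator <= 0")
        return 100.0 * n2_final / denom
    denom = no3_initial - no3_final - no2_final
    if denom <= 0:
        raise ValueError(
            f"denominator NO3i - NO3f - NO2f = {denom:.4g} must be positive"
        )
    return 100.0 * 2.0 * n2_final / denom


def percent_n2o_remaining(n2o: float, n2: float) -> float:
    """100 * [N2O] / ([N2O] + [N2]); undefined when both pools are zero."""
    if n2o < 0 or n2 < 0:
        raise ValueError("concentrations must be >= 0")
    if n2o + n2 == 0:
        raise ValueError("%N2O remaining undefined: no N2O or N2 present")
    return 100.0 * n2o / (n2o + n2)


def percent_no2_reduction(no2_initial: float, no2_final: float) -> float:
    """Percent of the initial NO2- pool reduced by the end of incubation."""
    if no2_initial <= 0:
        raise ValueError("initial NO2- must be positive")
    return 100.0 * (no2_initial - no2_final) / no2_initial


def fold_change(n2_reference: float, n2_treatment: float) -> float:
    """Signed fold change of N2 production relative to a reference condition.

    Ratios >= 1 are reported as-is; ratios < 1 as the negative reciprocal
    ("fold decrease"), so 0.5 -> -2.0.
    """
    if n2_reference <= 0:
        raise ValueError("reference N2 must be positive")
    if n2_treatment < 0:
        raise ValueError("treatment N2 must be >= 0")
    r = n2_treatment / n2_reference
    return r if r >= 1.0 else -1.0 / r


def _atoms(snapshot: NSpeciesSnapshot, cfg: BottleConfig) -> dict[str, float]:
    """mmol N per species, whole bottle (aqueous + gas phases)."""
    return {
        "no3": snapshot.no3 * cfg.liquid_volume,
        "no2": snapshot.no2 * cfg.liquid_volume,
        "n2o": 2.0 * total_species_moles(snapshot.n2o_aq, snapshot.n2o_gas, cfg),
        "n2": 2.0 * total_species_moles(snapshot.n2_aq, snapshot.n2_gas, cfg),
    }


def nitrogen_closure(
    initial: NSpeciesSnapshot, final: NSpeciesSnapshot, cfg: BottleConfig
) -> RecoveryResult:
    """Whole-bottle N-atom conservation audit between two snapshots."""
    atoms_in = sum(_atoms(initial, cfg).values())
    out_by_species = _atoms(final, cfg)
    atoms_out = sum(out_by_species.values())
    if atoms_in <= 0:
        raise ValueError("initial snapshot holds no nitrogen")
    no3_consumed = (initial.no3 - final.no3 - final.no2) * cfg.liquid_volume
    if no3_consumed > 0:
        n2_produced_total = (
            total_species_moles(final.n2_aq, final.n2_gas, cfg)
            - total_species_moles(initial.n2_aq, initial.n2_gas, cfg)
        )
        percent = 100.0 * 2.0 * n2_produced_total / no3_consumed
    else:
        percent = float("nan")
    return RecoveryResult(percent, atoms_in, out_by_species, atoms_out / atoms_in)


def snapshot_from_totals(
    no3: float, no2: float, n2o_total: float, n2_total: float, cfg: BottleConfig
) -> NSpeciesSnapshot:
    """Build a snapshot from whole-bottle N2O/N2 pools (mmol per L liquid),
    partitioning them into phases at Henry equilibrium."""
    from .gas import partition_total

    h_n2o = dimensionless_henry(get_species("N2O"), cfg.temperature)
    h_n2 = dimensionless_henry(get_species("N2"), cfg.temperature)
    n2o_aq, n2o_gas = partition_total(n2o_total, h_n2o, cfg)
    n2_aq, n2_gas = partition_total(n2_total, h_n2, cfg)
    return NSpeciesSnapshot(no3, no2, n2o_aq, n2o_gas, n2_aq, n2_gas)
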