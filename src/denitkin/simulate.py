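"""Seeded ODE simulator of sequential denitrification in sealed bottles.

The latent state is the set of whole-bottle pools (expressed per litre of
liquid): NO3-, NO2-, N2O, N2.  Three Monod steps run in series,

    r1: NO3- -> NO2-     r2: NO2- -> 1/2 N2O     r3: N2O-N -> 1/2 N2

    r_i = vmax_i * X * S_i/(ks_i + S_i) * g_pH(pH) * g_ind,i(t)

with a logistic pH inhibition g_pH = 1/(1 + exp((pH - ph50)/ph_width)) and a
step-up induction gate at a per-step delay (progressive-onset strains delay
steps 2-3; rapid-complete-onset strains have no delays).  Initial NO2- extends
every delay by no2/ki, emulating nitrite toxicity as lag extension.

Everything downstream of the N states is algebraic in the reaction extents:
the electron flow E = 2*s1 + 2*s2 + s3 (mmol e- equivalents per L) fixes
catabolic acetate (E/8), total acetate drain (E/8/(1-f) with assimilated
fraction f), biomass (OD = OD0 + Y_b * f/(1-f) * E/8), DIC (+E/4) and
alkalinity (+0.325*E), from which pH is re-solved continuously.  N2O and N2
partition between liquid and headspace by Henry equilibrium at output times.

Sampled observations get multiplicative log-normal noise (default CV 5%) and
detection-limit censoring; runs are bitwise reproducible per seed.

K_s defaults (0.05 mmol/L) are order-of-magnitude conventions, not measured
values.  Strain presets are calibrated so that noiseless runs at ~0.9 mmol/L
NO3- reproduce the observed completion times (2 d for K172/TK001, 13 d for
NS1) and intermediate phenotypes (transient NO2- peak ~0.74 mmol/L for NS1,
none for the others).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import carbonate as carb
from .gas import BottleConfig, dimensionless_henry, get_species, partition_total
from .qpcr import QpcrMeasurement

STEP_NAMES = ("no3_to_no2", "no2_to_n2o", "n2o_to_n2")


@dataclass(frozen=True)
class KineticParams:
    """Strain phenotype: per-step Monod parameters plus regulatory gates.

    vmax units are mmol (L d OD)-1 (biomass-specific, scaled by OD600);
    ks in mmol L-1; induction delays in days.  phenotype is "RCO" (rapid
    complete onset, all delays zero) or "PO" (progressive onset).
    """

    vmax: tuple[float, float, float]
    ks: tuple[float, float, float] = (0.05, 0.05, 0.05)
    induction_delay: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ph50: float = 9.3
    ph_width: float = 0.3
    no2_inhibition_ki: float = 2.0  # mmol L-1 of initial NO2- per extra day of lag
    biomass_yield: float = 0.5  # OD600 per mmol acetate assimilated
    assimilated_fraction: float = 0.25
    phenotype: str = "RCO"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.vmax + self.ks + self.induction_delay):
            raise ValueError("rates, ks and delays must be >= 0")
        if self.phenotype not in ("RCO", "PO"):
            raise ValueError("phenotype must be RCO or PO")
        if self.phenotype == "RCO" and any(d > 0 for d in self.induction_delay):
            raise ValueError("RCO phenotype requires zero induction delays")


# Presets calibrated against the observed batch phenotypes at ~0.9 mmol/L NO3-.
PRESETS: dict[str, KineticParams] = {
    "K172": KineticParams(
        vmax=(20.0, 120.0, 120.0), biomass_yield=0.61, phenotype="RCO"
    ),
    "NS1": KineticParams(
        vmax=(29.0, 1.8, 8.0),
        induction_delay=(0.0, 0.7, 1.6),
        biomass_yield=0.48,
        phenotype="PO",
    ),
    "TK001": KineticParams(
        vmax=(40.0, 120.0, 120.0), biomass_yield=0.20, phenotype="RCO"
    ),
}


def preset(name: str, **overrides) -> KineticParams:
    """Named strain parameter set; "custom" requires explicit overrides."""
    if name == "custom":
        if not overrides:
            raise ValueError("preset('custom') requires explicit parameter overrides")
        if "vmax" not in overrides:
            raise ValueError("custom preset needs at least vmax")
        return KineticParams(**overrides)
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)} or 'custom'"
        ) from None
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class SimulationResult:
    """Dense latent trajectory plus the noisy, censored sampled series."""

    trajectory: pd.DataFrame  # noise-free latent states at dense times
    observations: pd.DataFrame  # tidy sampled table (io schema)
    params: KineticParams
    config: BottleConfig
    seed: int | None
    strain: str = "custom"


TA_SLOPE_PER_E = 0.325  # eq alkalinity per mmol e- (= 1.625/5)
DIC_SLOPE_PER_E = 0.25  # mmol DIC per mmol e- (= 1.25/5)


class _BottleModel:
    """Right-hand side and algebraic closures for one bottle run."""

    def __init__(
        self,
        params: KineticParams,
        cfg: BottleConfig,
        y0: np.ndarray,
        acetate0: float,
        od0: float,
        dic0: float,
        ta0: float,
    ) -> None:
        self.p = params
        self.cfg = cfg
        self.y0 = y0
        self.acetate0 = acetate0
        self.od0 = od0
        self.dic0 = dic0
        self.ta0 = ta0
        self.k = carb.equilibrium_constants(cfg.temperature)
        no2_init = y0[1]
        extra = no2_init / params.no2_inhibition_ki if params.no2_inhibition_ki > 0 else 0.0
        self.delays = tuple(d + extra if (d > 0 or no2_init > 0) else 0.0
                            for d in params.induction_delay)
        self._ph_cache: tuple[float, float] | None = None

    def extents(self, y: np.ndarray) -> tuple[float, float, float]:
        no3, no2, n2o, n2 = y
        s1 = max(self.y0[0] - no3, 0.0)
        s2 = max(self.y0[1] + s1 - no2, 0.0)
        s3 = max(2.0 * (n2 - self.y0[3]), 0.0)
        return s1, s2, s3

    def electron_flow(self, y: np.ndarray) -> float:
        s1, s2, s3 = self.extents(y)
        return 2.0 * s1 + 2.0 * s2 + s3

    def chemistry(self, y: np.ndarray) -> tuple[float, float, float, float, float]:
        """(dic, ta, ph, acetate, od) at state y."""
        e = self.electron_flow(y)
        dic = self.dic0 + DIC_SLOPE_PER_E * e
        ta = self.ta0 + TA_SLOPE_PER_E * e
        ph = carb.ph_from_ta_dic(ta, dic, self.k)
        f = self.p.assimilated_fraction
        acetate = max(self.acetate0 - e / 8.0 / (1.0 - f), 0.0)
        od = self.od0 + self.p.biomass_yield * (f / (1.0 - f)) * e / 8.0
        return dic, ta, ph, acetate, od

    def _gate(self, t: float, step: int) -> float:
        tau = self.delays[step]
        if tau <= 0.0:
            return 1.0
        # smooth step-up, 0.02 d transition width, keeps the ODE non-stiff
        z = (t - tau) / 0.02
        if z > 40:
            return 1.0
        if z < -40:
            return 0.0
        return 1.0 / (1.0 + math.exp(-z))

    def rates(self, t: float, y: np.ndarray) -> np.ndarray:
        no3, no2, n2o, _ = np.maximum(y, 0.0)
        _, _, ph, _, od = self.chemistry(y)
        if math.isfinite(self.p.ph50):
            z = (ph - self.p.ph50) / self.p.ph_width
            g_ph = 1.0 / (1.0 + math.exp(min(z, 40.0)))
        else:
            g_ph = 1.0
        subs = (no3, no2, n2o)
        r = np.empty(3)
        for i in range(3):
            monod = subs[i] / (self.p.ks[i] + subs[i]) if subs[i] > 0 else 0.0
            r[i] = self.p.vmax[i] * od * monod * g_ph * self._gate(t, i)
        return r

    def rhs(self, t: float, y: np.ndarray) -> list[float]:
        r1, r2, r3 = self.rates(t, y)
        return [-r1, r1 - r2, (r2 - r3) / 2.0, r3 / 2.0]


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative log-normal factors with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def simulate_bottle(
    params: KineticParams,
    cfg: BottleConfig | None = None,
    initial: Mapping[str, float] | None = None,
    t_end: float = 14.0,
    sample_times: Sequence[float] | None = None,
    seed: int | None = None,
    noise_cv: float = 0.05,
    strain: str = "custom",
    replicate: str = "r1",
) -> SimulationResult:
    """Integrate one sealed-bottle run and sample it like a bench experiment.

    `initial` names exactly one electron acceptor ("no3", "no2" or "n2o",
    mmol/L) plus optional "acetate" (default equimolar), "ph" (default 7.50),
    "ta" (default 2.51 meq/L) and "od" (default 0.005).  When only "ph" is
    overridden, the initial DIC is held at the default-medium value and TA is
    recomputed to be consistent with the requested pH.
    """
    cfg = cfg or BottleConfig()
    initial = dict(initial or {"no3": 0.9})
    acceptors = {k: v for k, v in initial.items() if k in ("no3", "no2", "n2o") and v > 0}
    if len(acceptors) != 1:
        raise ValueError(f"exactly one initial electron acceptor required, got {acceptors}")
    (acceptor, amount), = acceptors.items()
    acetate0 = initial.get("acetate", amount)
    if acetate0 <= 0:
        raise ValueError("initial acetate must be positive")
    od0 = initial.get("od", 0.005)

    k = carb.equilibrium_constants(cfg.temperature)
    default_dic = carb.dic_from_ph_ta(7.50, 2.51, k)
    if "ta" in initial and "ph" in initial:
        ta0, ph0 = initial["ta"], initial["ph"]
        dic0 = carb.dic_from_ph_ta(ph0, ta0, k)
    elif "ph" in initial:
        ph0 = initial["ph"]
        dic0 = default_dic
        ta0 = carb.alkalinity_from_ph_dic(ph0, dic0, k)
    else:
        ph0, ta0 = 7.50, initial.get("ta", 2.51)
        dic0 = carb.dic_from_ph_ta(ph0, ta0, k)

    y0 = np.zeros(4)
    index = {"no3": 0, "no2": 1, "n2o": 2}[acceptor]
    y0[index] = amount

    model = _BottleModel(params, cfg, y0.copy(), acetate0, od0, dic0, ta0)
    if sample_times is None:
        sample_times = np.arange(0.0, t_end + 1e-9, 1.0)
    sample_times = np.asarray(sample_times, dtype=float)
    dense_times = np.union1d(np.linspace(0.0, t_end, 561), sample_times)

    sol = solve_ivp(
        model.rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=dense_times,
        rtol=1e-8,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(
            f"bottle integration failed: {sol.message}; final state {sol.y[:, -1]}"
        )

    states = np.maximum(sol.y, 0.0)
    chem = np.array([model.chemistry(states[:, j]) for j in range(states.shape[1])])
    h_n2o = dimensionless_henry(get_species("N2O"), cfg.temperature)
    h_n2 = dimensionless_henry(get_species("N2"), cfg.temperature)
    h_co2 = dimensionless_henry(get_species("CO2"), cfg.temperature)

    n2o_phases = np.array([partition_total(v, h_n2o, cfg) for v in states[2]])
    n2_phases = np.array([partition_total(v, h_n2, cfg) for v in states[3]])
    a0 = np.array([carb.ionization_fractions(p, model.k)[0] for p in chem[:, 2]])
    co2_gas = chem[:, 0] * a0 / h_co2.value

    trajectory = pd.DataFrame(
        {
            "time_d": sol.t,
            "no3_mM": states[0],
            "no2_mM": states[1],
            "n2o_total_mM": states[2],
            "n2_total_mM": states[3],
            "n2o_aq_mM": n2o_phases[:, 0],
            "n2o_gas_mM": n2o_phases[:, 1],
            "n2_aq_mM": n2_phases[:, 0],
            "n2_gas_mM": n2_phases[:, 1],
            "dic_mM": chem[:, 0],
            "ta_meqL": chem[:, 1],
            "ph": chem[:, 2],
            "acetate_mM": chem[:, 3],
            "od600": chem[:, 4],
            "co2_gas_mM": co2_gas,
        }
    )

    # sample like the bench: noisy observation of the latent state, censored
    rng = np.random.default_rng(seed)
    sampled = trajectory[trajectory["time_d"].isin(sample_times)].reset_index(drop=True)
    n = len(sampled)
    obs = pd.DataFrame({"time_d": sampled["time_d"], "strain": strain, "replicate": replicate})
    for col in ("acetate_mM", "no3_mM", "no2_mM", "od600", "ta_meqL",
                "co2_gas_mM", "n2o_gas_mM", "n2_gas_mM"):
        obs[col] = sampled[col].to_numpy() * _noise_factors(rng, noise_cv, n)
    obs["ph"] = sampled["ph"].to_numpy() + (
        rng.normal(0.0, 0.02, n) if noise_cv > 0 else 0.0
    )
    for col in ("no3_mM", "no2_mM", "acetate_mM"):
        obs.loc[obs[col] < cfg.detection_limit, col] = 0.0
    gas_lo = cfg.gas_quantitation_range[0]
    for col in ("co2_gas_mM", "n2o_gas_mM", "n2_gas_mM"):
        obs.loc[obs[col] < gas_lo, col] = 0.0
    obs = obs[
        ["time_d", "strain", "replicate", "acetate_mM", "no3_mM", "no2_mM",
         "od600", "ph", "ta_meqL", "co2_gas_mM", "n2o_gas_mM", "n2_gas_mM"]
    ]
    return SimulationResult(trajectory, obs, params, cfg, seed, strain)


# Factorial designs of the five batch-test sets: (acceptor, levels, extra)
EXPERIMENT_SETS: dict[int, dict] = {
    1: {"acceptor": "no3", "levels": [0.9], "t_end": 14.0},
    2: {"acceptor": "no3", "levels": [2.0, 3.0, 4.0, 5.0], "t_end": 90.0},
    3: {"acceptor": "no2", "levels": [1.0, 2.0, 3.0, 4.0, 5.0], "t_end": 30.0},
    4: {
        "acceptor": "n2o",
        "levels": [0.1, 0.4, 0.7, 1.0],
        "ph_levels": [8.1, 9.0, 9.4, 9.8],
        "acetate": 0.5,
        "t_end": 15.0,
    },
    5: {"acceptor": "no3", "levels": [0.9], "ph_levels": [7.5, 8.1, 8.6, 9.0, 9.4, 9.8],
        "t_end": 14.0},
}


def simulate_experiment_set(
    set_id: int,
    strains: Sequence[str] = ("K172", "NS1", "TK001"),
    replicates: int = 3,
    seed: int | None = 0,
    noise_cv: float = 0.05,
    cfg: BottleConfig | None = None,
    sample_times: Sequence[float] | None = None,
) -> list[SimulationResult]:
    """Simulate one of the five factorial batch-test designs.

    Set 1: ~1 mmol/L NO3-, 14 d.  Set 2: NO3- at 2-5 mmol/L, 90 d.
    Set 3: NO2- at 1-5 mmol/L, 30 d.  Set 4: N2O 0.1-1.0 mmol/L crossed with
    initial pH 8.1-9.8, 15 d.  Set 5: ~1 mmol/L NO3- at initial pH 7.5-10.
    """
    if set_id not in EXPERIMENT_SETS:
        raise ValueError(f"unknown experiment set {set_id}; valid: 1-5")
    design = EXPERIMENT_SETS[set_id]
    ph_levels = design.get("ph_levels", [None])
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(strains) * len(design["levels"]) * len(ph_levels) * replicates))
    results = []
    for strain in strains:
        params = preset(strain)
        for level in design["levels"]:
            for ph0 in ph_levels:
                for rep in range(1, replicates + 1):
                    initial = {design["acceptor"]: level}
                    if "acetate" in design:
                        initial["acetate"] = design["acetate"]
                    if ph0 is not None:
                        initial["ph"] = ph0
                    child_seed = int(next(children).generate_state(1)[0] % (2**31))
                    results.append(
                        simulate_bottle(
                            params,
                            cfg=cfg,
                            initial=initial,
                            t_end=design["t_end"],
                            sample_times=sample_times,
                            seed=child_seed,
                            noise_cv=noise_cv,
                            strain=strain,
                            replicate=f"r{rep}",
                        )
                    )
    return results


def generate_qpcr_dataset(
    expression_model: Mapping[tuple[str, str], float],
    noise_sd: float = 0.2,
    seed: int | None = 0,
    replicates: int = 3,
    reference_gene: str = "16S",
    reference_ct: float = 15.0,
    target_base_ct: float = 22.0,
) -> list[QpcrMeasurement]:
    """Synthetic CT table whose ddCT analysis recovers the given folds.

    `expression_model` maps (target gene, treatment condition) to the intended
    relative expression (fold) against a "control" condition.  CTs are built
    so that dCT_control = target_base_ct - reference_ct and dCT_treatment is
    shifted by -log2(fold), then jittered with Gaussian noise of `noise_sd`
    cycles.
    """
    if any(fold <= 0 for fold in expression_model.values()):
        raise ValueError("all folds must be positive")
    rng = np.random.default_rng(seed)
    conditions = sorted({cond for _, cond in expression_model})
    genes = sorted({gene for gene, _ in expression_model})
    measurements: list[QpcrMeasurement] = []

    def emit(condition: str, gene: str, role: str, ct: float) -> None:
        for r in range(1, replicates + 1):
            jitter = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            measurements.append(
                QpcrMeasurement(
                    sample=f"{condition}-{gene}", condition=condition, gene=gene,
                    role=role, ct=ct + jitter, replicate=f"r{r}",
                )
            )

    for condition in ["control"] + conditions:
        emit(condition, reference_gene, "reference", reference_ct)
        for gene in genes:
            if condition == "control":
                emit(condition, gene, "target", target_base_ct)
            else:
                fold = expression_model.get((gene, condition))
                if fold is None:
                    continue
                emit(condition, gene, "target", target_base_ct - math.log2(fold))
    return measurements
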