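"""Per-bottle report assembly: recovery statistics and kinetic summaries from
tidy observation tables."""

from __future__ import annotations

import pandas as pd

from .gas import BottleConfig, dimensionless_henry, get_species, headspace_to_aqueous
from .kinetics import summarize_bottle
from .nbalance import percent_recovered_as_n2


def _total_per_liquid_l(c_gas: float, h_value: float, cfg: BottleConfig) -> float:
    """Whole-bottle pool (mmol per L liquid) from a headspace concentration."""
    return c_gas * (h_value * cfg.liquid_volume + cfg.headspace_volume) / cfg.liquid_volume


def bottle_totals(df: pd.DataFrame, cfg: BottleConfig | None = None) -> pd.DataFrame:
    """Augment a tidy table with whole-bottle N2O/N2 pools (mmol per L liquid),
    reconstructed from headspace concentrations via Henry equilibrium."""
    cfg = cfg or BottleConfig()
    h_n2o = dimensionless_henry(get_species("N2O"), cfg.temperature)
    h_n2 = dimensionless_henry(get_species("N2"), cfg.temperature)
    out = df.copy()
    out["n2o_total_mM"] = [
        _total_per_liquid_l(c, h_n2o.value, cfg) for c in out["n2o_gas_mM"]
    ]
    out["n2_total_mM"] = [
        _total_per_liquid_l(c, h_n2.value, cfg) for c in out["n2_gas_mM"]
    ]
    out["n2o_aq_mM"] = [headspace_to_aqueous(c, h_n2o) for c in out["n2o_gas_mM"]]
    return out


def recovery_report(df: pd.DataFrame, cfg: BottleConfig | None = None) -> pd.DataFrame:
    """One row per (strain, replicate): the % recovered-as-N2 family of
    statistics computed from first and last sampling points."""
    cfg = cfg or BottleConfig()
    df = bottle_totals(df, cfg)
    rows = []
    for (strain, rep), g in df.groupby(["strain", "replicate"], sort=False):
        g = g.sort_values("time_d")
        first, last = g.iloc[0], g.iloc[-1]
        n2_produced = last["n2_total_mM"] - first["n2_total_mM"]
        try:
            pct = percent_recovered_as_n2(
                first["no3_mM"], last["no3_mM"], last["no2_mM"], n2_produced
            )
        except ValueError:
            pct = float("nan")
        rows.append(
            {
                "strain": strain,
                "replicate": rep,
                "no3_initial_mM": first["no3_mM"],
                "no3_final_mM": last["no3_mM"],
                "no2_final_mM": last["no2_mM"],
                "n2o_final_total_mM": last["n2o_total_mM"],
                "n2_produced_total_mM": n2_produced,
                "percent_recovered_as_n2": pct,
            }
        )
    return pd.DataFrame(rows)


def kinetics_report(df: pd.DataFrame, cfg: BottleConfig | None = None) -> pd.DataFrame:
    """One row per (strain, replicate) of rate/completion/lag/growth summaries."""
    cfg = cfg or BottleConfig()
    df = bottle_totals(df, cfg)
    rows = []
    for (strain, rep), g in df.groupby(["strain", "replicate"], sort=False):
        g = g.sort_values("time_d")
        s = summarize_bottle(
            g["time_d"].to_numpy(),
            g["no3_mM"].to_numpy(),
            g["no2_mM"].to_numpy(),
            g["n2o_total_mM"].to_numpy(),
            g["n2_total_mM"].to_numpy(),
            od=g["od600"].to_numpy(),
            detection_limit=cfg.detection_limit,
        )
        rows.append(
            {
                "strain": strain,
                "replicate": rep,
                "denitrification_rate_mM_d": s.denitrification_rate,
                "completion_time_d": s.completion_time,
                "lag_time_d": s.lag_time,
                "mu_per_d": s.mu,
                "max_od600": s.max_od,
                "yield": s.yield_value,
                "yield_definition": s.yield_definition,
            }
        )
    return pd.DataFrame(rows)


def merged_report(df: pd.DataFrame, cfg: BottleConfig | None = None) -> pd.DataFrame:
    """Recovery and kinetics joined on (strain, replicate)."""
    return recovery_report(df, cfg).merge(
        kinetics_report(df, cfg), on=["strain", "replicate"]
    )
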