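"""Relative gene expression by the 2^(-ddCT) method, with standard-curve QC.

Target-gene CTs (nirS, nosZ) are normalized against a reference gene
(16S rRNA) within each condition, then compared between a treatment and its
control:

    dCT  = mean CT_target - mean CT_reference      (per condition)
    ddCT = dCT_treatment - dCT_control
    relative expression = 2^(-ddCT)

Amplification efficiency from a standard curve CT = slope*log10(input) + b is
(10^(-1/slope) - 1)*100; a perfect doubling per cycle (slope -3.3219) gives
100%.  Efficiency correction (Pfaffl) is deliberately not offered: the assay
efficiencies this layer is designed around sit at 96.8-102.6%, where pure
2^(-ddCT) is standard practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import linregress

REPLICATE_SD_FLAG = 0.5  # cycles; replicate scatter above this is flagged


@dataclass(frozen=True)
class QpcrMeasurement:
    sample: str
    condition: str  # "control" or a treatment label
    gene: str
    role: str  # "reference" | "target"
    ct: float
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if not 0.0 < self.ct < 45.0:
            raise ValueError(f"CT {self.ct} outside plausible cycle range (0, 45)")
        if self.role not in ("reference", "target"):
            raise ValueError(f"role must be reference|target, got {self.role!r}")


@dataclass(frozen=True)
class StandardCurve:
    log10_amounts: tuple[float, ...]
    cts: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float
    efficiency: float  # percent


def standard_curve(log10_amounts: Sequence[float], cts: Sequence[float]) -> StandardCurve:
    """Fit CT = slope*log10(amount) + intercept and report % efficiency."""
    x = np.asarray(log10_amounts, dtype=float)
    y = np.asarray(cts, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct input amounts for a standard curve")
    fit = linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"standard-curve slope {fit.slope:.3f} is non-negative; curve unusable"
        )
    efficiency = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    return StandardCurve(
        tuple(x), tuple(y), float(fit.slope), float(fit.intercept),
        float(fit.rvalue**2), float(efficiency),
    )


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    condition: str
    ddct: float
    relative_expression: float  # 2^(-ddct)
    signed_fold: float
    flags: tuple[str, ...] = ()


def _mean_ct(
    measurements: Iterable[QpcrMeasurement], condition: str, role: str, gene: str | None = None
) -> tuple[float, list[str]]:
    cts = [
        m.ct
        for m in measurements
        if m.condition == condition and m.role == role and (gene is None or m.gene == gene)
    ]
    if not cts:
        what = gene or role
        raise ValueError(f"no CT values for {what!r} in condition {condition!r}")
    flags = []
    if len(cts) > 1 and stdev(cts) > REPLICATE_SD_FLAG:
        flags.append(f"replicate sd {stdev(cts):.2f} > {REPLICATE_SD_FLAG} cycles")
    return mean(cts), flags


def ddct_relative_expression(
    measurements: Sequence[QpcrMeasurement],
    control_condition: str = "control",
) -> list[ExpressionResult]:
    """2^(-ddCT) per (target gene, treatment condition) against the control.

    Replicate CTs are arithmetic-mean-averaged on the CT scale before
    differencing.  Adding a constant to every CT (a plate offset) leaves the
    result unchanged.
    """
    conditions = sorted({m.condition for m in measurements})
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent from data")
    targets = sorted({m.gene for m in measurements if m.role == "target"})
    if not targets:
        raise ValueError("no target-gene measurements present")
    results = []
    for gene in targets:
        ct_t_ctrl, f1 = _mean_ct(measurements, control_condition, "target", gene)
        ct_r_ctrl, f2 = _mean_ct(measurements, control_condition, "reference")
        dct_control = ct_t_ctrl - ct_r_ctrl
        for condition in conditions:
            if condition == control_condition:
                continue
            # sparse designs are fine: skip genes not assayed in a condition
            if not any(
                m.condition == condition and m.role == "target" and m.gene == gene
                for m in measurements
            ):
                continue
            ct_t, f3 = _mean_ct(measurements, condition, "target", gene)
            ct_r, f4 = _mean_ct(measurements, condition, "reference")
            ddct = (ct_t - ct_r) - dct_control
            rel = 2.0**-ddct
            results.append(
                ExpressionResult(
                    gene, condition, float(ddct), float(rel),
                    expression_fold_report(rel), tuple(f1 + f2 + f3 + f4),
                )
            )
    return results


def expression_fold_report(rel_expr: float) -> float:
    """Signed fold convention: >= 1 reported as-is, < 1 as -1/value."""
    if rel_expr <= 0:
        raise ValueError("relative expression must be positive")
    return rel_expr if rel_expr >= 1.0 else -1.0 / rel_expr
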