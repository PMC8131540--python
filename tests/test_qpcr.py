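"""Standard-curve efficiency and 2^(-ddCT) relative expression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from denitkin.qpcr import (
    QpcrMeasurement,
    ddct_relative_expression,
    expression_fold_report,
    standard_curve,
)
from denitkin.simulate import generate_qpcr_dataset


class TestStandardCurve:
    def test_perfect_doubling_slope_gives_100_percent(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0])
        cts = 30.0 - 3.321928 * x
        curve = standard_curve(x, cts)
        assert curve.efficiency == pytest.approx(100.0, abs=1e-3)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_shallower_slope_lower_efficiency(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0])
        curve = standard_curve(x, 30.0 - 3.46 * x)
        assert curve.efficiency == pytest.approx(94.5, abs=0.1)

    def test_efficiency_decreasing_in_slope_magnitude(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0])
        effs = [standard_curve(x, 30.0 - s * x).efficiency for s in (3.1, 3.3219, 3.6)]
        assert effs[0] > effs[1] > effs[2]

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            standard_curve([0, 1, 2], [20, 21, 22])

    def test_too_few_amounts_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            standard_curve([0, 0, 1], [20, 20, 17])


def _measurement_set(ct_target_treat, ct_ref_treat, ct_target_ctrl, ct_ref_ctrl):
    return [
        QpcrMeasurement("s1", "control", "nirS", "target", ct_target_ctrl),
        QpcrMeasurement("s1", "control", "16S", "reference", ct_ref_ctrl),
        QpcrMeasurement("s2", "treatment", "nirS", "target", ct_target_treat),
        QpcrMeasurement("s2", "treatment", "16S", "reference", ct_ref_treat),
    ]


class TestDdct:
    def test_equal_cts_give_unity(self):
        results = ddct_relative_expression(_measurement_set(20, 20, 20, 20))
        assert results[0].relative_expression == 1.0

    def test_forced_three_cycle_shift(self):
        results = ddct_relative_expression(_measurement_set(25, 20, 22, 20))
        assert results[0].ddct == pytest.approx(3.0)
        assert results[0].relative_expression == pytest.approx(0.125)
        assert results[0].signed_fold == pytest.approx(-8.0)

    @given(offset=st.floats(-5, 5))
    @settings(deadline=None)
    def test_plate_offset_invariance(self, offset):
        base = _measurement_set(25, 20, 22, 20)
        shifted = [
            QpcrMeasurement(m.sample, m.condition, m.gene, m.role, m.ct + offset)
            for m in base
        ]
        a = ddct_relative_expression(base)[0].relative_expression
        b = ddct_relative_expression(shifted)[0].relative_expression
        assert a == pytest.approx(b, rel=1e-9)

    def test_missing_condition_named_in_error(self):
        with pytest.raises(ValueError, match="reference"):
            ddct_relative_expression(
                [
                    QpcrMeasurement("s", "control", "nirS", "target", 20),
                    QpcrMeasurement("s", "control", "16S", "reference", 18),
                    QpcrMeasurement("s", "treatment", "nirS", "target", 21),
                ]
            )

    def test_replicate_scatter_flagged(self):
        noisy = [
            QpcrMeasurement("s", "control", "nirS", "target", 20.0, "r1"),
            QpcrMeasurement("s", "control", "nirS", "target", 21.5, "r2"),
            QpcrMeasurement("s", "control", "16S", "reference", 18.0),
            QpcrMeasurement("s", "t", "nirS", "target", 20.0),
            QpcrMeasurement("s", "t", "16S", "reference", 18.0),
        ]
        results = ddct_relative_expression(noisy)
        assert any("replicate sd" in f for f in results[0].flags)

    def test_monte_carlo_interval_around_forced_value(self):
        """CT replicates drawn with sd 0.2 cycles around means forcing
        2^(-3) = 0.125: the recovered fold lies in [0.09, 0.17] for at least
        95% of 1000 seeds."""
        hits = 0
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            ms = []
            for cond, gene_ct, ref_ct in (("control", 22, 20), ("treatment", 25, 20)):
                for rep in range(3):
                    ms.append(
                        QpcrMeasurement(
                            "s", cond, "nirS", "target",
                            gene_ct + rng.normal(0, 0.2), f"r{rep}",
                        )
                    )
                    ms.append(
                        QpcrMeasurement(
                            "s", cond, "16S", "reference",
                            ref_ct + rng.normal(0, 0.2), f"r{rep}",
                        )
                    )
            rel = ddct_relative_expression(ms)[0].relative_expression
            hits += 0.09 <= rel <= 0.17
        assert hits >= 950


class TestFoldReport:
    @pytest.mark.parametrize(
        "rel,expected", [(1.0, 1.0), (0.140, -7.14), (2.44, 2.44), (0.5, -2.0)]
    )
    def test_signed_convention(self, rel, expected):
        assert expression_fold_report(rel) == pytest.approx(expected, abs=0.01)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            expression_fold_report(0.0)


class TestSyntheticCtGenerator:
    def test_noiseless_generator_is_exact_inverse(self):
        model = {("nirS", "highpH"): 0.125, ("nosZ", "highpH"): 1.0}
        ms = generate_qpcr_dataset(model, noise_sd=0.0, seed=0)
        results = {(r.gene, r.condition): r.relative_expression
                   for r in ddct_relative_expression(ms)}
        assert results[("nirS", "highpH")] == pytest.approx(0.125, rel=1e-12)
        assert results[("nosZ", "highpH")] == pytest.approx(1.0, rel=1e-12)

    def test_noisy_generator_unbiased(self):
        """Mean recovered fold over 1000 seeds within 5% of the planted 0.42."""
        folds = []
        for seed in range(1000):
            ms = generate_qpcr_dataset({("nirS", "t"): 0.42}, noise_sd=0.2, seed=seed)
            folds.append(ddct_relative_expression(ms)[0].relative_expression)
        assert np.mean(folds) == pytest.approx(0.42, rel=0.05)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            generate_qpcr_dataset({("nirS", "t"): 0.0})
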