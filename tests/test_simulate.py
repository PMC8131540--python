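"""Bottle simulator: phenotypes, conservation, determinism and parameter
recovery."""

import math

import numpy as np
import pytest

from denitkin.kinetics import completion_time, denitrification_rate, lag_time
from denitkin.nbalance import percent_recovered_as_n2
from denitkin.simulate import (
    EXPERIMENT_SETS,
    KineticParams,
    preset,
    simulate_bottle,
    simulate_experiment_set,
)


def _noiseless(name, no3=0.9, t_end=15.0, **kw):
    return simulate_bottle(preset(name), initial={"no3": no3}, t_end=t_end,
                           noise_cv=0.0, **kw)


def _sampled_completion(result, detection=0.001):
    obs = result.trajectory[result.trajectory.time_d.isin(np.arange(0.0, 100.0))]
    return completion_time(
        obs.time_d.to_numpy(), obs.no3_mM, obs.no2_mM, obs.n2o_total_mM, detection
    )


class TestPresets:
    def test_phenotype_labels(self):
        assert preset("K172").phenotype == "RCO"
        assert preset("TK001").phenotype == "RCO"
        assert preset("NS1").phenotype == "PO"

    def test_rco_presets_have_no_delays(self):
        assert preset("K172").induction_delay == (0.0, 0.0, 0.0)

    def test_custom_without_overrides_rejected(self):
        with pytest.raises(ValueError, match="custom"):
            preset("custom")

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="K172"):
            preset("X999")

    def test_rco_with_delays_rejected(self):
        with pytest.raises(ValueError, match="RCO"):
            KineticParams(vmax=(1, 1, 1), induction_delay=(1, 0, 0), phenotype="RCO")


class TestPhenotypeReproduction:
    def test_rapid_onset_strains_no_intermediate_and_fast_completion(self):
        for name in ("K172", "TK001"):
            r = _noiseless(name)
            assert r.trajectory.no2_mM.max() < 0.05, name
            done = _sampled_completion(r)
            assert done is not None and done <= 3.0, name

    def test_progressive_onset_nitrite_peak_and_slow_completion(self):
        r = _noiseless("NS1")
        tr = r.trajectory
        peak = tr.no2_mM.max()
        t_peak = tr.loc[tr.no2_mM.idxmax(), "time_d"]
        assert 0.6 <= peak <= 0.9
        assert 1.0 <= t_peak <= 3.0
        done = _sampled_completion(r)
        assert done is not None and done <= 14.0

    def test_published_rates_recovered_from_simulated_bottles(self):
        """Noiseless runs at the measured initial NO3- loads reproduce the
        published overall rates 0.431 / 0.071 / 0.429 mmol/(L d)."""
        for name, no3, expected in (
            ("K172", 0.862, 0.431), ("NS1", 0.918, 0.071), ("TK001", 0.859, 0.429)
        ):
            r = _noiseless(name, no3=no3)
            rate = denitrification_rate(no3, _sampled_completion(r))
            assert rate == pytest.approx(expected, rel=0.02), name


class TestConservation:
    @pytest.mark.parametrize("name", ["K172", "NS1", "TK001"])
    def test_whole_bottle_nitrogen_conserved(self, name):
        tr = _noiseless(name).trajectory
        atoms = tr.no3_mM + tr.no2_mM + 2 * tr.n2o_total_mM + 2 * tr.n2_total_mM
        assert np.max(np.abs(atoms / atoms.iloc[0] - 1.0)) < 1e-6

    def test_electron_balance_with_acetate(self):
        """8 x catabolic acetate equals the summed per-step electron flow."""
        tr = _noiseless("NS1").trajectory
        p = preset("NS1")
        s1 = 0.9 - tr.no3_mM
        s2 = s1 - tr.no2_mM
        s3 = 2 * tr.n2_total_mM
        e = 2 * s1 + 2 * s2 + s3
        acetate_total = (0.9 - tr.acetate_mM)
        catabolic = acetate_total * (1 - p.assimilated_fraction)
        assert np.allclose(8 * catabolic, e, atol=1e-8)

    def test_uninhibited_complete_run_recovers_100_percent(self):
        p = preset("K172", ph50=math.inf)
        tr = simulate_bottle(p, initial={"no3": 0.9}, t_end=30, noise_cv=0.0).trajectory
        last = tr.iloc[-1]
        pct = percent_recovered_as_n2(0.9, last.no3_mM, last.no2_mM, last.n2_total_mM)
        assert pct == pytest.approx(100.0, abs=0.1)

    def test_ph_nondecreasing_during_active_denitrification(self):
        tr = _noiseless("NS1").trajectory
        active = tr[tr.no3_mM + tr.no2_mM + tr.n2o_total_mM > 0.001]
        assert np.all(np.diff(active.ph) > -1e-9)


class TestDeterminismAndNoise:
    def test_same_seed_bitwise_identical(self):
        a = simulate_bottle(preset("K172"), initial={"no3": 0.9}, seed=7)
        b = simulate_bottle(preset("K172"), initial={"no3": 0.9}, seed=7)
        assert a.observations.equals(b.observations)

    def test_different_seeds_differ(self):
        a = simulate_bottle(preset("K172"), initial={"no3": 0.9}, seed=7)
        b = simulate_bottle(preset("K172"), initial={"no3": 0.9}, seed=8)
        assert not a.observations.equals(b.observations)

    def test_censoring_below_detection(self, cfg):
        obs = simulate_bottle(preset("K172"), initial={"no3": 0.9}, seed=0).observations
        late = obs[obs.time_d >= 4]
        assert (late.no3_mM == 0.0).all()

    def test_noise_is_multiplicative_and_unbiased(self):
        """Observed/latent ratio at t=0 across seeds averages to ~1."""
        ratios = []
        for seed in range(200):
            r = simulate_bottle(preset("K172"), initial={"no3": 0.9},
                                sample_times=[0.0], seed=seed)
            ratios.append(r.observations.no3_mM.iloc[0] / 0.9)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)
        assert np.std(ratios) == pytest.approx(0.05, abs=0.02)


class TestParameterRecovery:
    def test_zero_order_rate_recovered_noiseless(self):
        """With constant biomass and tiny K_s the planted rate
        k = vmax1 * OD is recovered within 5%."""
        k_true, od0 = 0.45, 0.05
        p = KineticParams(vmax=(k_true / od0, 200.0, 200.0), ks=(0.001,) * 3,
                          biomass_yield=0.0, ph50=math.inf)
        st = np.arange(0, 3.0001, 0.05)
        r = simulate_bottle(p, initial={"no3": 0.9, "od": od0}, t_end=3.0,
                            sample_times=st, noise_cv=0.0)
        o = r.observations
        done = completion_time(o.time_d.to_numpy(), o.no3_mM, o.no2_mM, o.n2o_gas_mM)
        assert denitrification_rate(0.9, done) == pytest.approx(k_true, rel=0.05)

    def test_zero_order_rate_recovered_under_noise(self):
        """Same design with 5% observation noise: within 15% for 100 seeds."""
        k_true, od0 = 0.45, 0.05
        p = KineticParams(vmax=(k_true / od0, 200.0, 200.0), ks=(0.001,) * 3,
                          biomass_yield=0.0, ph50=math.inf)
        st = np.arange(0, 3.0001, 0.05)
        for seed in range(100):
            o = simulate_bottle(p, initial={"no3": 0.9, "od": od0}, t_end=3.0,
                                sample_times=st, seed=seed, noise_cv=0.05).observations
            done = completion_time(o.time_d.to_numpy(), o.no3_mM, o.no2_mM, o.n2o_gas_mM)
            assert denitrification_rate(0.9, done) == pytest.approx(k_true, rel=0.15)

    def test_induction_delay_recovered_as_lag(self):
        """A planted 5-day induction delay on every step shows up as a ~5-day
        NO3- lag in the trajectory."""
        p = KineticParams(vmax=(10.0, 50.0, 50.0), induction_delay=(5.0, 5.0, 5.0),
                          phenotype="PO")
        tr = simulate_bottle(p, initial={"no3": 0.9}, t_end=10, noise_cv=0.0).trajectory
        lag = lag_time(tr.time_d.to_numpy(), tr.no3_mM.to_numpy())
        assert lag == pytest.approx(5.0, abs=0.3)

    def test_initial_nitrite_extends_lag(self):
        """Nitrite toxicity: 5 mmol/L initial NO2- lengthens the onset lag
        relative to 1 mmol/L, mirroring the observed 0.5-3 -> 0.7-5 d shift."""
        lags = []
        for no2 in (1.0, 5.0):
            p = KineticParams(vmax=(0.1, 10.0, 30.0), induction_delay=(0, 0.5, 0.5),
                              no2_inhibition_ki=2.0, phenotype="PO")
            tr = simulate_bottle(p, initial={"no2": no2}, t_end=12, noise_cv=0.0).trajectory
            lags.append(lag_time(tr.time_d.to_numpy(), tr.no2_mM.to_numpy()))
        assert lags[1] > lags[0] + 1.0


class TestStressDirections:
    def test_higher_no3_never_increases_recovery(self):
        pcts = []
        for lvl in (2.0, 3.0, 4.0, 5.0):
            tr = simulate_bottle(preset("NS1"), initial={"no3": lvl}, t_end=90,
                                 noise_cv=0.0, sample_times=[0, 90]).trajectory
            last = tr.iloc[-1]
            pcts.append(percent_recovered_as_n2(lvl, last.no3_mM, last.no2_mM,
                                                last.n2_total_mM))
        assert all(b <= a + 1e-6 for a, b in zip(pcts, pcts[1:]))

    def test_higher_initial_ph_never_increases_final_n2(self):
        n2 = []
        for ph0 in (7.5, 8.1, 8.6, 9.0, 9.4, 9.8):
            tr = simulate_bottle(preset("NS1"), initial={"no3": 0.9, "ph": ph0},
                                 t_end=14, noise_cv=0.0, sample_times=[0, 14]).trajectory
            n2.append(tr.n2_total_mM.iloc[-1])
        assert all(b <= a + 1e-9 for a, b in zip(n2, n2[1:]))

    def test_completion_time_monotone_in_initial_no3(self):
        times = []
        for lvl in (0.5, 1.0, 2.0):
            r = simulate_bottle(preset("K172"), initial={"no3": lvl}, t_end=30,
                                noise_cv=0.0)
            times.append(_sampled_completion(r))
        assert all(t is not None for t in times)
        assert all(a <= b for a, b in zip(times, times[1:]))


class TestExperimentSets:
    def test_invalid_set_rejected(self):
        with pytest.raises(ValueError, match="1-5"):
            simulate_experiment_set(9)

    def test_set4_is_a_16_condition_grid(self):
        res = simulate_experiment_set(4, strains=["NS1"], replicates=1, seed=1,
                                      noise_cv=0.0, sample_times=[0, 15])
        assert len(res) == 16

    def test_set5_spans_the_ph_range(self):
        design = EXPERIMENT_SETS[5]
        assert min(design["ph_levels"]) == 7.5
        assert max(design["ph_levels"]) >= 9.8

    def test_set1_strain_by_replicate_layout(self):
        res = simulate_experiment_set(1, replicates=2, seed=0, noise_cv=0.0,
                                      sample_times=[0, 14])
        assert len(res) == 6
        assert {r.strain for r in res} == {"K172", "NS1", "TK001"}


class TestInputValidation:
    def test_exactly_one_acceptor_required(self):
        with pytest.raises(ValueError, match="electron acceptor"):
            simulate_bottle(preset("K172"), initial={"no3": 0.9, "no2": 0.5})

    def test_acetate_must_be_positive(self):
        with pytest.raises(ValueError, match="acetate"):
            simulate_bottle(preset("K172"), initial={"no3": 0.9, "acetate": 0.0})
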