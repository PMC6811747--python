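"""Generator contracts: phenotype structure, drug thinning, rendering."""

import numpy as np
import pytest
from scipy import stats

from neuroculture.containers import SpikeTrain
from neuroculture.synthdata import (
    CalciumSimConfig,
    DrugProtocol,
    MEARenderConfig,
    NetworkSimConfig,
    PatchSimConfig,
    apply_drug_protocol,
    render_mea,
    simulate_calcium,
    simulate_patch_family,
    simulate_spike_trains,
)


class TestSimulateSpikeTrains:
    def test_burster_gaps_within_ibi_range(self, burster_truth):
        ibis = burster_truth.inter_burst_intervals()
        assert ibis.size > 3
        assert np.all(ibis >= 2.0) and np.all(ibis <= 10.0)

    def test_burster_spikes_confined_to_windows(self, burster_truth):
        windows = burster_truth.burst_windows
        for times in burster_truth.unit_times:
            inside = np.zeros(times.size, dtype=bool)
            for s, e in windows:
                inside |= (times >= s) & (times <= e)
            assert inside.all()

    def test_zero_duration_is_empty(self):
        truth = simulate_spike_trains(NetworkSimConfig(duration=0.0, seed=0))
        assert truth.pooled_times().size == 0
        assert truth.burst_windows == []

    def test_tonic_total_count_in_poisson_interval(self):
        # 10 units x 2 Hz x 60 s => Poisson(1200); central 99% interval
        truth = simulate_spike_trains(
            NetworkSimConfig(phenotype="tonic", n_units=10, duration=60.0,
                             tonic_rate=2.0, seed=4)
        )
        lo, hi = stats.poisson.ppf([0.005, 0.995], 1200)
        assert lo <= truth.pooled_times().size <= hi

    def test_spike_times_within_duration(self, coculture_truth):
        pooled = coculture_truth.pooled_times()
        assert pooled[0] >= 0 and pooled[-1] <= coculture_truth.duration

    def test_burst_windows_sorted_disjoint(self, burster_truth):
        w = burster_truth.burst_windows
        for (s1, e1), (s2, e2) in zip(w, w[1:]):
            assert e1 > s1 and s2 > e1

    def test_deterministic_under_seed(self):
        cfg = NetworkSimConfig(n_units=5, duration=30.0, seed=77)
        a = simulate_spike_trains(cfg)
        b = simulate_spike_trains(cfg)
        for ta, tb in zip(a.unit_times, b.unit_times):
            np.testing.assert_array_equal(ta, tb)
        assert a.burst_windows == b.burst_windows

    def test_mixture_ratio_5_to_2(self):
        truth = simulate_spike_trains(
            NetworkSimConfig(phenotype="mixture", n_units=21, seed=3)
        )
        # 21 units at tonic:burster 5:2 => 15 tonic, 6 burster
        assert truth.phenotypes.count("tonic") == 15
        assert truth.phenotypes.count("burster") == 6

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            simulate_spike_trains(NetworkSimConfig(burst_participation=1.5))


class TestApplyDrugProtocol:
    def test_null_efficacy_identity(self, tonic_truth):
        prot = DrugProtocol(efficacy=0.0, baseline_s=30.0, ramp_s=30.0,
                            steady_s=60.0, target="tonic_rate")
        out = apply_drug_protocol(tonic_truth, prot)
        for a, b in zip(tonic_truth.unit_times, out.unit_times):
            np.testing.assert_array_equal(a, b)

    def test_baseline_counts_unchanged(self):
        truth = simulate_spike_trains(
            NetworkSimConfig(phenotype="tonic", duration=480.0, tonic_rate=5.0, seed=5)
        )
        prot = DrugProtocol(efficacy=0.9, ec50=0.1, target="tonic_rate")
        out = apply_drug_protocol(truth, prot, seed=6)
        for a, b in zip(truth.unit_times, out.unit_times):
            assert np.sum(a < 120.0) == np.sum(b < 120.0)

    def test_steady_state_thinning_matches_survival(self):
        # efficacy 0.6 at saturating dose => survival ~0.4; binomial 99% CI
        truth = simulate_spike_trains(
            NetworkSimConfig(phenotype="tonic", n_units=20, duration=480.0,
                             tonic_rate=5.0, seed=7)
        )
        prot = DrugProtocol(final_dose=20.0, efficacy=0.6, ec50=1e-6,
                            target="tonic_rate")
        out = apply_drug_protocol(truth, prot, seed=8)
        pooled_in = truth.pooled_times()
        pooled_out = out.pooled_times()
        n_steady = int(np.sum((pooled_in >= 240.0)))
        k_kept = int(np.sum(pooled_out >= 240.0))
        lo, hi = stats.binom.ppf([0.005, 0.995], n_steady, 0.4)
        assert lo <= k_kept <= hi

    def test_invalid_efficacy_rejected(self, tonic_truth):
        with pytest.raises(ValueError):
            apply_drug_protocol(tonic_truth, DrugProtocol(efficacy=1.5))

    def test_timeline_coverage_required(self):
        short = simulate_spike_trains(NetworkSimConfig(duration=60.0, seed=1))
        with pytest.raises(ValueError):
            apply_drug_protocol(short, DrugProtocol())

    def test_dose_timeline_shape(self):
        prot = DrugProtocol(final_dose=20.0)
        assert prot.dose(0.0) == 0.0
        assert prot.dose(120.0) == 0.0
        assert prot.dose(180.0) == pytest.approx(10.0)
        assert prot.dose(240.0) == pytest.approx(20.0)
        assert prot.dose(400.0) == pytest.approx(20.0)


class TestRenderMEA:
    def test_pure_noise_sd(self):
        truth = simulate_spike_trains(NetworkSimConfig(n_units=0, duration=5.0, seed=0))
        rec = render_mea(truth, MEARenderConfig(n_electrodes=3, noise_sd=4.0, seed=9))
        sds = rec.samples.std(axis=1)
        assert np.all(np.abs(sds - 4.0) / 4.0 < 0.05)

    def test_default_sampling_rate_20khz(self, small_render):
        _, rec = small_render
        assert rec.sampling_rate == 20_000.0

    def test_deterministic_under_seed(self):
        truth = simulate_spike_trains(NetworkSimConfig(n_units=2, duration=2.0, seed=1))
        cfg = MEARenderConfig(n_electrodes=2, seed=42)
        a = render_mea(truth, cfg)
        b = render_mea(truth, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_spike_beyond_duration_rejected(self):
        truth = simulate_spike_trains(NetworkSimConfig(n_units=1, duration=2.0, seed=1))
        truth.unit_times[0] = np.array([1.0, 5.0])
        with pytest.raises(ValueError):
            render_mea(truth, MEARenderConfig(n_electrodes=1))


class TestSimulateCalcium:
    def test_bleach_only_monotone_decreasing(self):
        truth = simulate_spike_trains(NetworkSimConfig(n_units=1, duration=30.0, seed=1))
        truth.unit_times[0] = np.empty(0)
        truth.joined_bursts[0] = set()
        cfg = CalciumSimConfig(noise_sd=0.0, bleach_drift=0.3)
        tr = simulate_calcium(truth, cfg)[0]
        assert np.all(np.diff(tr.raw) < 0)

    def test_single_spike_single_transient(self):
        truth = simulate_spike_trains(
            NetworkSimConfig(n_units=1, phenotype="tonic", duration=30.0, seed=1)
        )
        truth.unit_times[0] = np.array([10.0])
        cfg = CalciumSimConfig(noise_sd=0.0, bleach_drift=0.0, amplitude=2.5)
        tr = simulate_calcium(truth, cfg)[0]
        resid = tr.raw - cfg.baseline
        t = tr.times()
        expected = np.where(t >= 10.0, 2.5 * np.exp(-(t - 10.0) / cfg.decay_s), 0.0)
        np.testing.assert_allclose(resid, expected, atol=1e-9)

    def test_burster_transients_coincide_within_one_frame(self, burster_truth):
        cfg = CalciumSimConfig(noise_sd=0.0)
        traces = simulate_calcium(burster_truth, cfg)
        # for each burst, participating cells' event times within one frame
        for b, (s, e) in enumerate(burster_truth.burst_windows):
            times = [
                tr.true_transient_times[
                    (tr.true_transient_times >= s) & (tr.true_transient_times <= e)
                ]
                for u, tr in enumerate(traces)
                if b in burster_truth.joined_bursts[u]
            ]
            times = [t[0] for t in times if t.size]
            if len(times) >= 2:
                assert np.ptp(times) <= 5 * cfg.frame_interval

    def test_identity_channels_follow_phenotype(self, coculture_truth):
        cfg = CalciumSimConfig()
        traces = simulate_calcium(coculture_truth, cfg)
        for tr, role in zip(traces, coculture_truth.phenotypes):
            if role == "burster":
                assert tr.cfp_value == cfg.cfp_high
                assert tr.gfp_value == cfg.gfp_high  # crosstalk
            elif role == "tonic":
                assert tr.cfp_value == cfg.channel_background
                assert tr.gfp_value == cfg.gfp_high


class TestSimulatePatchFamily:
    def test_zero_transient_pure_leak(self):
        cfg = PatchSimConfig(peak_amplitude_pA=0.0)
        fam = simulate_patch_family(cfg, "voltage_clamp")
        for v, tr in zip(fam.levels, fam.traces):
            step = tr[int(fam.onset * fam.sampling_rate) + 5 :
                      int(fam.offset * fam.sampling_rate) - 5]
            leak = cfg.leak_pA_per_mV * (v - cfg.holding_mV)
            np.testing.assert_allclose(step, leak, atol=1e-9)

    def test_rheobase_controls_spiking(self):
        from neuroculture.patch import APCriterion, _detect_aps

        cfg = PatchSimConfig(rheobase_pA=30.0)
        fam = simulate_patch_family(cfg, "current_clamp")
        crit = APCriterion()
        for level, tr in zip(fam.levels, fam.traces):
            has = _detect_aps(tr, fam.sampling_rate, crit).size > 0
            assert has == (level >= 30.0)

    def test_transient_minimum_equals_peak_plus_leak(self):
        cfg = PatchSimConfig()
        fam = simulate_patch_family(cfg, "voltage_clamp")
        fs = fam.sampling_rate
        i0 = int(round(fam.onset * fs))
        i30 = int(round((fam.onset + 0.030) * fs))
        for v, tr in zip(fam.levels, fam.traces):
            leak = cfg.leak_pA_per_mV * (v - cfg.holding_mV)
            expected = cfg.transient_peak_pA(v) + leak
            if cfg.transient_peak_pA(v) < -1.0:
                assert np.min(tr[i0:i30]) == pytest.approx(expected, abs=1e-6)
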