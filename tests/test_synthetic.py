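"""Generators: closed forms, determinism, and ground-truth consistency."""

import numpy as np
import pytest

from patchkit.exceptions import ParameterError
from patchkit.synthetic import (
    APWaveformSpec,
    PassiveCircuitSpec,
    PSCTrainSpec,
    PAPER_ISIS_MS,
    make_evoked_pair,
    make_membrane_test,
    make_phenotype_preset,
    make_psc_trace,
    make_step_protocol_sweeps,
)


class TestStepProtocol:
    def test_default_protocol_is_16_steps_of_40_pA(self, step_protocol):
        ss, truth = step_protocol
        amps = [s.stimulus.amplitude for s in ss]
        assert amps == list(range(-120, 481, 40))
        assert len(ss) == 16

    def test_spike_counts_follow_gain_rule(self, step_protocol):
        _, truth = step_protocol
        # rheobase 160, gain 1: counts 1 at 160 pA, +1 per 40 pA above
        expected = [0] * 7 + list(range(1, 10))
        assert truth.spike_counts == expected
        assert truth.params["rheobase_pA"] == 160.0

    def test_same_seed_is_bit_identical(self, default_ap, default_circuit):
        kw = dict(rheobase_pA=160.0, gain_spikes_per_40pA=1.0, seed=9)
        a, _ = make_step_protocol_sweeps(
            default_ap, PassiveCircuitSpec(noise_sd=0.5), **kw)
        b, _ = make_step_protocol_sweeps(
            default_ap, PassiveCircuitSpec(noise_sd=0.5), **kw)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.samples, sb.samples)

    def test_subthreshold_sweeps_follow_rc_closed_form(self, default_ap):
        circ = PassiveCircuitSpec(Rm=100.0, Cm=100.0, V_rest=-65.0)
        ss, _ = make_step_protocol_sweeps(default_ap, circ, rheobase_pA=1e9)
        sweep = ss[0]  # -120 pA
        t = sweep.times
        stim = sweep.stimulus
        tau = circ.Rm * circ.Cm / 1e6  # MOhm * pF = us -> s
        on = (t >= stim.onset_time) & (t < stim.offset_time)
        expect = circ.V_rest + (-120 * circ.Rm / 1000.0) * (
            1 - np.exp(-(t[on] - stim.onset_time) / tau)
        )
        np.testing.assert_allclose(sweep.samples[on], expect, rtol=1e-9)

    def test_unfittable_spike_count_raises(self, default_circuit):
        wide = APWaveformSpec(half_width=40.0, depol_rate=30.0)
        with pytest.raises(ParameterError):
            make_step_protocol_sweeps(wide, default_circuit, rheobase_pA=-120.0,
                                      gain_spikes_per_40pA=10.0)


class TestMembraneTest:
    def test_closed_form_peak_and_steady_state(self):
        circ = PassiveCircuitSpec(Ra=10.0, Rm=100.0, Cm=100.0)
        ss, truth = make_membrane_test(circ)
        assert truth.params["I_peak_pA"] == pytest.approx(1000.0)
        assert truth.params["I_ss_pA"] == pytest.approx(10.0 / 110.0 * 1000.0)
        assert truth.params["tau_ms"] == pytest.approx(100 * (10 * 100 / 110) / 1000)
        # first on-sample carries the full peak above holding
        sweep = ss[0]
        i_on = sweep.sample_index(sweep.stimulus.onset_time)
        hold = truth.params["holding_pA"]
        assert sweep.samples[i_on] - hold == pytest.approx(1000.0, rel=1e-9)

    def test_noise_is_reproducible(self):
        circ = PassiveCircuitSpec(noise_sd=5.0)
        a, _ = make_membrane_test(circ, seed=3)
        b, _ = make_membrane_test(circ, seed=3)
        np.testing.assert_array_equal(a[0].samples, b[0].samples)

    def test_invalid_circuit_raises(self):
        with pytest.raises(ParameterError):
            PassiveCircuitSpec(Ra=-1.0)


class TestPSCTrace:
    def test_zero_rate_gives_flat_noise(self):
        sweep, truth = make_psc_trace(PSCTrainSpec(rate=0.0, noise_sd=1.0,
                                                   duration=10.0, seed=1))
        assert truth.event_times == []
        assert abs(np.mean(sweep.samples)) < 0.1

    def test_poisson_count_near_expectation(self):
        spec = PSCTrainSpec(rate=2.0, duration=300.0, seed=5)
        _, truth = make_psc_trace(spec)
        assert abs(len(truth.event_times) - 600) <= 3 * np.sqrt(600)

    def test_kernel_peak_equals_drawn_amplitude(self):
        spec = PSCTrainSpec(rate=0.1, amp_mean=20.0, amp_sd=0.0, noise_sd=0.0,
                            duration=60.0, seed=2)
        sweep, truth = make_psc_trace(spec)
        rate = sweep.sampling_rate
        for t0, a in zip(truth.event_times, truth.event_amplitudes):
            i0 = int(round(t0 * rate))
            seg = sweep.samples[i0 : i0 + int(0.01 * rate)]
            if seg.size:
                # sampling the kernel just off its true peak costs a little
                assert -seg.min() == pytest.approx(a, rel=2e-3)

    def test_invalid_taus_raise(self):
        with pytest.raises(ParameterError):
            PSCTrainSpec(tau_rise=5.0, tau_decay=1.0)


class TestEvokedPair:
    def test_ground_truth_weighted_tau(self):
        _, truth = make_evoked_pair([(2.0, 10.0), (1.0, 40.0)], isi_ms=50.0)
        assert truth.params["weighted_tau_ms"] == pytest.approx(20.0)

    def test_six_isi_batch(self):
        sets = [make_evoked_pair([(100.0, 15.0)], isi_ms=isi)[0]
                for isi in PAPER_ISIS_MS]
        assert [s.metadata["isi_ms"] for s in sets] == list(PAPER_ISIS_MS)

    def test_second_peak_equals_ppr_times_first(self):
        ss, truth = make_evoked_pair([(100.0, 15.0)], isi_ms=358.0, ppr=1.0)
        x = -ss[0].samples
        rate = ss.sampling_rate
        t1, t2 = ss.metadata["stim_times_s"]
        p1 = x[int(t1 * rate) : int(t2 * rate)].max()
        p2 = x[int(t2 * rate) :].max()
        assert p2 == pytest.approx(p1, rel=1e-6)

    def test_invalid_ppr_raises(self):
        with pytest.raises(ParameterError):
            make_evoked_pair([(100.0, 15.0)], ppr=0.0)


class TestPhenotypePresets:
    def test_p18_ko_rheobase_parameter_below_wt(self):
        wt = make_phenotype_preset("P18", "WT", 30, seed=1)
        ko = make_phenotype_preset("P18", "KO", 30, seed=2)
        assert np.mean([c.rheobase_pA for c in ko]) < np.mean(
            [c.rheobase_pA for c in wt])

    def test_p70_ko_psc_rate_parameter_above_wt(self):
        wt = make_phenotype_preset("P70", "WT", 30, seed=1)
        ko = make_phenotype_preset("P70", "KO", 30, seed=2)
        assert np.mean([c.psc.rate for c in ko]) > np.mean(
            [c.psc.rate for c in wt])

    def test_same_seed_identical_draws(self):
        a = make_phenotype_preset("P18", "KO", 5, seed=7)
        b = make_phenotype_preset("P18", "KO", 5, seed=7)
        assert a == b

    def test_unknown_labels_raise(self):
        with pytest.raises(ParameterError):
            make_phenotype_preset("P30", "WT", 5)
        with pytest.raises(ParameterError):
            make_phenotype_preset("P18", "HET", 5)
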