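"""Multi-exponential decay fits, weighted tau, 100->37% time, paired pulses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchkit.evoked import (
    PAPER_ISIS_MS,
    decay_time_100_37,
    fit_decay,
    paired_pulse,
    weighted_tau,
)
from patchkit.synthetic import make_evoked_pair


def _decay_trace(components, C=0.0, dur_ms=300.0, rate=5000.0, noise_sd=0.0,
                 seed=0):
    t = np.arange(int(dur_ms / 1000.0 * rate)) / rate * 1000.0  # ms
    y = C + sum(a * np.exp(-t / tau) for a, tau in components)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return -y  # inward


class TestWeightedTau:
    def test_single_term_collapses_to_tau1(self):
        assert weighted_tau([(50.0, 20.0)]) == 20.0

    def test_printed_two_component_example(self):
        # A=(2,1), tau=(10,40): (2*10 + 1*40)/3 = 20
        assert weighted_tau([(2.0, 10.0), (1.0, 40.0)]) == pytest.approx(20.0)

    @settings(derandomize=True, max_examples=50)
    @given(scale=st.floats(0.01, 100.0),
           a1=st.floats(1.0, 50.0), a2=st.floats(1.0, 50.0))
    def test_scale_free_in_amplitudes(self, scale, a1, a2):
        comps = [(a1, 5.0), (a2, 30.0)]
        scaled = [(a * scale, tau) for a, tau in comps]
        assert weighted_tau(scaled) == pytest.approx(weighted_tau(comps),
                                                     rel=1e-9)
        lo, hi = 5.0, 30.0
        assert lo <= weighted_tau(comps) <= hi


class TestFitDecay:
    def test_single_exponential_recovered_exactly(self):
        fit = fit_decay(_decay_trace([(50.0, 20.0)]), 5000.0)
        assert fit.n_terms == 1
        assert fit.components[0][1] == pytest.approx(20.0, rel=0.01)
        assert fit.weighted_tau == pytest.approx(fit.components[0][1])

    def test_two_component_weighted_tau_noise_free(self):
        fit = fit_decay(_decay_trace([(100.0, 10.0), (50.0, 40.0)]), 5000.0)
        assert fit.n_terms == 2
        assert fit.weighted_tau == pytest.approx(20.0, rel=0.02)

    def test_two_component_with_noise_selects_two_terms(self):
        trace = _decay_trace([(100.0, 10.0), (50.0, 40.0)], noise_sd=2.0, seed=1)
        fit = fit_decay(trace, 5000.0)
        assert fit.n_terms == 2
        assert fit.weighted_tau == pytest.approx(20.0, rel=0.10)

    @pytest.mark.parametrize("tau1", [5.0, 10.0, 15.0])
    def test_tau_pair_recovery_at_snr_25(self, tau1):
        tau2 = 3.5 * tau1
        amp = 100.0
        trace = _decay_trace([(amp, tau1), (amp / 2, tau2)], dur_ms=12 * tau2,
                             noise_sd=amp / 25.0, seed=int(tau1))
        fit = fit_decay(trace, 5000.0)
        taus = sorted(tau for _, tau in fit.components)[:2]
        assert taus[0] == pytest.approx(tau1, rel=0.15)
        assert taus[-1] == pytest.approx(tau2, rel=0.15)


class TestDecayTime:
    def test_pure_exponential_tau_20(self):
        d = decay_time_100_37(_decay_trace([(100.0, 20.0)]), 5000.0, amp1=100.0)
        # exact crossing is 20*ln(1/0.37) = 19.89 ms; one 5-kHz sample slack
        assert d == pytest.approx(20.0, abs=0.2)

    def test_two_component_matches_direct_evaluation(self):
        comps = [(100.0, 10.0), (50.0, 40.0)]
        trace = _decay_trace(comps, dur_ms=400.0)
        d = decay_time_100_37(trace, 5000.0, amp1=150.0)
        t = np.arange(trace.size) / 5.0  # ms
        f = sum(a * np.exp(-t / tau) for a, tau in comps)
        expected = t[np.nonzero(f < 0.37 * 150.0)[0][0]]
        assert d == pytest.approx(expected, abs=0.2)

    def test_truncated_segment_flagged_undefined(self):
        trace = _decay_trace([(100.0, 50.0)], dur_ms=10.0)
        assert decay_time_100_37(trace, 5000.0, amp1=100.0) is None


class TestPairedPulse:
    def test_no_overlap_unity_ppr(self):
        ss, _ = make_evoked_pair([(100.0, 20.0)], isi_ms=358.0, ppr=1.0)
        r = paired_pulse(ss)
        assert r.ppr == pytest.approx(1.0, abs=0.02)

    def test_overlapping_facilitation_recovered_after_tail_subtraction(self):
        ss, _ = make_evoked_pair([(100.0, 10.0), (50.0, 40.0)], isi_ms=50.0,
                                 ppr=1.8)
        r = paired_pulse(ss)
        assert r.ppr == pytest.approx(1.8, rel=0.05)
        assert r.fit is not None

    def test_batch_over_printed_isis(self):
        results = []
        for isi in PAPER_ISIS_MS:
            ss, _ = make_evoked_pair([(100.0, 15.0)], isi_ms=isi, ppr=1.3)
            results.append(paired_pulse(ss))
        assert [r.isi for r in results] == list(PAPER_ISIS_MS)
        for r in results:
            assert r.ppr == pytest.approx(1.3, rel=0.05)

    def test_amp1_measured_against_baseline(self):
        ss, truth = make_evoked_pair([(80.0, 15.0)], isi_ms=100.0, ppr=1.0)
        r = paired_pulse(ss)
        assert r.amp1 == pytest.approx(truth.event_amplitudes[0], rel=0.02)
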