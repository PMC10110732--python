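"""AP detection gates, threshold/half-width geometry, intrinsic profile."""

import numpy as np
import pytest

from patchkit.exceptions import InputError
from patchkit.spikes import DetectionConfig, detect_aps, intrinsic_profile
from patchkit.synthetic import (
    APWaveformSpec,
    PassiveCircuitSpec,
    _render_ap,
    make_step_protocol_sweeps,
)
from patchkit.trace_io import StimulusEpoch, Sweep, SweepSet


def _sweep_with_template_aps(ap, peak_times, v_base=-70.0, rate=5000.0,
                             duration=1.0):
    v = np.full(int(duration * rate), v_base)
    for t in peak_times:
        _render_ap(v, rate, t, ap, baseline_at=v_base)
    return Sweep(v, rate, "voltage", "current_clamp")


class TestDetection:
    def test_flat_trace_has_no_events(self):
        sweep = Sweep(np.full(5000, -70.0), 5000.0, "voltage", "current_clamp")
        assert detect_aps(sweep) == []

    def test_template_spikes_found_at_ground_truth_times(self):
        ap = APWaveformSpec(threshold_v=-40, peak_v=25, half_width=1.5,
                            depol_rate=150)
        times = [0.2, 0.5, 0.8]
        sweep = _sweep_with_template_aps(ap, times)
        events = detect_aps(sweep)
        assert len(events) == 3
        for ev, t in zip(events, times):
            assert abs(ev.peak_time - t) <= 1.0 / sweep.sampling_rate

    def test_low_spike_rejected_by_height_gate(self):
        # threshold-to-peak 15 mV < the 20-mV approval minimum
        ap = APWaveformSpec(threshold_v=-40, peak_v=-25, half_width=1.5,
                            depol_rate=60, ahp_v=-50)
        sweep = _sweep_with_template_aps(ap, [0.5])
        assert detect_aps(sweep) == []

    def test_wide_spike_rejected_in_mature_mode_only(self):
        ap = APWaveformSpec(threshold_v=-40, peak_v=25, half_width=5.0,
                            depol_rate=150)
        sweep = _sweep_with_template_aps(ap, [0.5])
        assert detect_aps(sweep, DetectionConfig.for_age_mode("mature")) == []
        immature = detect_aps(sweep, DetectionConfig.for_age_mode("immature"))
        assert len(immature) == 1
        assert immature[0].half_width == pytest.approx(5.0, abs=0.25)

    def test_offset_invariance(self):
        ap = APWaveformSpec()
        sweep = _sweep_with_template_aps(ap, [0.3, 0.7])
        shifted = Sweep(sweep.samples + 13.0, sweep.sampling_rate,
                        "voltage", "current_clamp")
        a, b = detect_aps(sweep), detect_aps(shifted)
        assert len(a) == len(b) == 2
        for ea, eb in zip(a, b):
            assert eb.threshold_v - ea.threshold_v == pytest.approx(13.0, abs=1e-9)
            assert eb.height == pytest.approx(ea.height, abs=1e-9)
            assert eb.half_width == pytest.approx(ea.half_width, abs=1e-9)


class TestThresholdAndWidth:
    def test_threshold_matches_template_within_half_mv(self):
        ap = APWaveformSpec(threshold_v=-42.0)
        events = detect_aps(_sweep_with_template_aps(ap, [0.5]))
        assert events[0].threshold_v == pytest.approx(-42.0, abs=0.5)

    def test_five_percent_rule_is_scale_invariant(self):
        # doubling max dV/dt moves the absolute 5% level but not the
        # relative crossing point on the waveform
        slow = APWaveformSpec(depol_rate=100.0)
        fast = APWaveformSpec(depol_rate=200.0)
        ev_s = detect_aps(_sweep_with_template_aps(slow, [0.5]))[0]
        ev_f = detect_aps(_sweep_with_template_aps(fast, [0.5]))[0]
        assert ev_f.threshold_v == pytest.approx(ev_s.threshold_v, abs=0.5)

    def test_two_identical_aps_identical_threshold(self):
        ap = APWaveformSpec()
        events = detect_aps(_sweep_with_template_aps(ap, [0.3, 0.7]))
        assert events[0].threshold_v == pytest.approx(events[1].threshold_v,
                                                      abs=1e-6)

    def test_triangular_spike_half_width(self):
        # isoceles triangle 0 -> 40 mV over 2 ms and back: half-width 2 ms
        rate = 5000.0
        v = np.zeros(5000)
        i0 = 2500
        up = np.linspace(0, 40, int(0.002 * rate) + 1)
        v[i0 : i0 + up.size] = up
        v[i0 + up.size - 1 : i0 + 2 * up.size - 1] = up[::-1]
        events = detect_aps(Sweep(v, rate, "voltage", "current_clamp"))
        assert len(events) == 1
        assert events[0].half_width == pytest.approx(2.0, abs=0.25)

    def test_template_half_width_recovered_within_one_sample(self):
        ap = APWaveformSpec(half_width=1.2)
        events = detect_aps(_sweep_with_template_aps(ap, [0.5]))
        assert events[0].half_width == pytest.approx(1.2, abs=0.2)

    def test_doubling_sampling_rate_changes_width_less_than_one_sample(self):
        ap = APWaveformSpec(half_width=1.3)
        w5 = detect_aps(_sweep_with_template_aps(ap, [0.5], rate=5000.0))[0].half_width
        w10 = detect_aps(_sweep_with_template_aps(ap, [0.5], rate=10000.0))[0].half_width
        assert abs(w10 - w5) < 0.2  # one 5-kHz sample interval in ms


class TestIntrinsicProfile:
    def test_rheobase_and_counts_match_ground_truth(self, step_protocol):
        ss, truth = step_protocol
        prof = intrinsic_profile(ss)
        assert prof.rheobase == truth.params["rheobase_pA"] == 160.0
        assert [prof.fi_curve[a] for a in sorted(prof.fi_curve)] == truth.spike_counts

    def test_fi_curve_reports_every_amplitude_including_zero(self, step_protocol):
        ss, _ = step_protocol
        prof = intrinsic_profile(ss)
        assert sorted(prof.fi_curve) == [s.stimulus.amplitude for s in ss]
        assert prof.fi_curve[-120.0] == 0

    def test_silent_cell_has_undefined_rheobase(self, default_ap):
        ss, _ = make_step_protocol_sweeps(default_ap, PassiveCircuitSpec(),
                                          rheobase_pA=1e9)
        prof = intrinsic_profile(ss)
        assert prof.rheobase is None
        assert all(c == 0 for c in prof.fi_curve.values())

    def test_first_isi_from_known_spike_times(self):
        ap = APWaveformSpec()
        sweep = _sweep_with_template_aps(ap, [0.10, 0.15], duration=1.2)
        sweep = Sweep(sweep.samples, sweep.sampling_rate, "voltage",
                      "current_clamp", StimulusEpoch(0.05, 1.0, 200.0))
        prof = intrinsic_profile(SweepSet([sweep]))
        assert prof.first_isi == pytest.approx(50.0, abs=0.4)

    def test_unordered_sweeps_raise(self, step_protocol):
        ss, _ = step_protocol
        shuffled = SweepSet(list(reversed(ss.sweeps)), metadata=ss.metadata)
        with pytest.raises(InputError):
            intrinsic_profile(shuffled)
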