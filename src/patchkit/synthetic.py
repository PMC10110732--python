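"""Synthetic patch-clamp traces with exact ground truth.

Every generator is a pure function of its parameters and a seed, and returns
both the traces and a :class:`GroundTruth` record sufficient to score any
downstream detector or estimator: event times, amplitudes, per-sweep spike
counts, and the generating parameters echoed back.

What is emulated
----------------
* 1-s current-step protocols (default 16 steps, -120 to +480 pA in 40-pA
  increments) whose sub-rheobase sweeps follow the passive RC response and
  whose supra-rheobase sweeps carry parametric action-potential templates.
* Voltage-clamp membrane tests: the current transient of an Ra-Rm-Cm
  one-compartment circuit to a 10-mV step.
* Long voltage-clamp traces with Poisson-timed biexponential synaptic
  events (spontaneous/miniature PSC recordings; events are inward, i.e.
  negative, as for cells held at -70 mV with a K-gluconate internal).
* Paired-pulse evoked responses built from a known multi-exponential decay.

The action potential is a piecewise raised-cosine template parameterized
directly by threshold, peak, half-width and maximal upstroke slope, so every
feature the extractor reports has a closed-form ground truth. It is a
waveform model, not a conductance model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError
from .trace_io import (
    CURRENT,
    CURRENT_CLAMP,
    VOLTAGE,
    VOLTAGE_CLAMP,
    StimulusEpoch,
    Sweep,
    SweepSet,
)

DEFAULT_RATE = 5_000.0  # Hz; matches the acquisition rate the pipeline assumes
MEMBRANE_TEST_RATE = 50_000.0  # Hz; the fast Ra transient needs finer sampling
STEP_PROTOCOL_PA = tuple(range(-120, 481, 40))  # 16 steps, 40-pA increments


@dataclass(frozen=True)
class APWaveformSpec:
    """Shape parameters of the action-potential template."""

    threshold_v: float = -40.0  # mV
    peak_v: float = 25.0  # mV
    half_width: float = 1.5  # ms, at half the threshold-to-peak amplitude
    depol_rate: float = 150.0  # mV/ms, maximal upstroke dV/dt
    ahp_v: float = -55.0  # mV, trough after the spike

    def __post_init__(self):
        if self.peak_v <= self.threshold_v:
            raise ParameterError("peak_v must exceed threshold_v")
        if self.half_width <= 0 or self.depol_rate <= 0:
            raise ParameterError("half_width and depol_rate must be > 0")
        if self.ahp_v >= self.threshold_v:
            raise ParameterError("ahp_v must lie below threshold_v")

    @property
    def height(self) -> float:
        return self.peak_v - self.threshold_v


@dataclass(frozen=True)
class PassiveCircuitSpec:
    """One-compartment whole-cell circuit."""

    Ra: float = 10.0  # MOhm, access (series) resistance
    Rm: float = 150.0  # MOhm, membrane resistance
    Cm: float = 100.0  # pF, membrane capacitance
    V_rest: float = -65.0  # mV
    noise_sd: float = 0.0  # pA (voltage clamp) or mV (current clamp)

    def __post_init__(self):
        if min(self.Ra, self.Rm, self.Cm) <= 0:
            raise ParameterError("Ra, Rm and Cm must all be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def tau_m_ms(self) -> float:
        """Membrane time constant Rm*Cm (current clamp), in ms."""
        return self.Rm * self.Cm / 1000.0

    @property
    def tau_test_ms(self) -> float:
        """Membrane-test transient time constant Cm*(Ra*Rm)/(Ra+Rm), in ms."""
        return self.Cm * self.Ra * self.Rm / (self.Ra + self.Rm) / 1000.0


@dataclass(frozen=True)
class PSCTrainSpec:
    """Poisson train of biexponential postsynaptic currents."""

    rate: float = 2.0  # Hz
    amp_mean: float = 20.0  # pA, lognormal mean of event magnitudes
    amp_sd: float = 5.0  # pA, lognormal sd
    tau_rise: float = 0.5  # ms
    tau_decay: float = 5.0  # ms
    duration: float = 300.0  # s (5-min recording)
    noise_sd: float = 2.0  # pA
    baseline_pA: float = 0.0  # holding-current offset
    seed: int = 0

    def __post_init__(self):
        if self.rate < 0:
            raise ParameterError("rate must be >= 0")
        if not (self.tau_decay > self.tau_rise > 0):
            raise ParameterError("need tau_decay > tau_rise > 0")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if self.amp_mean <= 0 or self.amp_sd < 0 or self.noise_sd < 0:
            raise ParameterError("amplitudes/noise must be positive")


@dataclass
class GroundTruth:
    """Everything needed to score a detector against a generated input."""

    event_times: list = field(default_factory=list)  # s; per sweep, or flat
    event_amplitudes: list = field(default_factory=list)  # pA or mV magnitudes
    spike_counts: list = field(default_factory=list)  # per sweep
    params: dict = field(default_factory=dict)  # generating parameters echoed back


# ---------------------------------------------------------------------------
# AP template geometry


def _ap_template_times(ap: APWaveformSpec, lead_from: float, lead_slope: float = 2.5):
    """Segment durations (ms) of the raised-cosine template.

    Returns (T_lead, T_up, T_down, T_rec). The lead ramp climbs from the
    local baseline ``lead_from`` to threshold with a peak slope of
    ``lead_slope`` mV/ms — slow enough never to trip dV/dt-based detection.
    """
    H = ap.height
    T_up = H * math.pi / (2.0 * ap.depol_rate)
    if ap.half_width <= T_up / 2.0:
        raise ParameterError(
            f"half_width {ap.half_width} ms is unreachable: the upstroke alone "
            f"takes {T_up:.3f} ms at depol_rate {ap.depol_rate} mV/ms"
        )
    # width at half height = second half of the upstroke + part of downstroke
    half_level = ap.threshold_v + H / 2.0
    q = 2.0 * (half_level - ap.ahp_v) / (ap.peak_v - ap.ahp_v) - 1.0
    T_down = math.pi * (ap.half_width - T_up / 2.0) / math.acos(q)
    climb = max(ap.threshold_v - lead_from, 0.5)
    T_lead = max(2.0, climb * math.pi / (2.0 * lead_slope))
    T_rec = 10.0
    return T_lead, T_up, T_down, T_rec


def _raised_cos(v0: float, v1: float, frac: np.ndarray) -> np.ndarray:
    """Smooth monotone segment from v0 to v1; frac in [0, 1]."""
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * frac))


def _render_ap(v: np.ndarray, rate: float, peak_time: float, ap: APWaveformSpec,
               baseline_at: float) -> None:
    """Overwrite ``v`` in place with one AP template peaking at ``peak_time``."""
    T_lead, T_up, T_down, T_rec = (x / 1000.0 for x in _ap_template_times(ap, baseline_at))
    t0 = peak_time - T_lead - T_up
    segs = [
        (t0, T_lead, baseline_at, ap.threshold_v),
        (t0 + T_lead, T_up, ap.threshold_v, ap.peak_v),
        (t0 + T_lead + T_up, T_down, ap.peak_v, ap.ahp_v),
        (t0 + T_lead + T_up + T_down, T_rec, ap.ahp_v, baseline_at),
    ]
    for start, dur, v0, v1 in segs:
        i0 = max(0, int(math.ceil(start * rate)))
        i1 = min(v.size - 1, int(math.floor((start + dur) * rate)))
        if i1 < i0:
            continue
        t = np.arange(i0, i1 + 1) / rate
        v[i0 : i1 + 1] = _raised_cos(v0, v1, (t - start) / dur)


def ap_template_extent_ms(ap: APWaveformSpec, baseline_at: float) -> float:
    """Total template duration in ms (used to check spikes fit the step)."""
    return sum(_ap_template_times(ap, baseline_at))


# ---------------------------------------------------------------------------
# step protocol


def make_step_protocol_sweeps(
    ap: APWaveformSpec,
    circuit: PassiveCircuitSpec,
    rheobase_pA: float = 200.0,
    gain_spikes_per_40pA: float = 1.0,
    seed: int = 0,
    amplitudes_pA: tuple = STEP_PROTOCOL_PA,
    sampling_rate: float = DEFAULT_RATE,
    stim_onset: float = 0.1,
    stim_duration: float = 1.0,
) -> tuple[SweepSet, GroundTruth]:
    """Current-clamp step protocol with template APs at known times.

    Sub-rheobase sweeps follow V = V_rest + (I*Rm/1000)*(1 - exp(-t/tau_m)).
    Sweeps at or above ``rheobase_pA`` carry
    ``k = gain*(I - rheobase)/40 + 1`` action potentials (rounded, min 1)
    evenly spaced inside the stimulus epoch. The passive depolarization on
    spiking sweeps is capped 5 mV below threshold — passively crossing
    threshold would be unphysical — and spikes are rendered as absolute
    raised-cosine templates realizing the waveform spec exactly.

    Ground truth lists every spike peak time and per-sweep counts; the
    grid-snapped rheobase (first protocol amplitude >= rheobase_pA) is
    echoed in ``params['rheobase_pA']``.
    """
    if sampling_rate < 1000:
        raise ParameterError("sampling_rate must be >= 1 kHz")
    rng = np.random.default_rng(seed)
    rate = sampling_rate
    n = int(round((stim_onset + stim_duration + 0.15) * rate))
    tau_s = circuit.tau_m_ms / 1000.0
    t = np.arange(n) / rate

    sweeps, times_per_sweep, counts = [], [], []
    grid_rheo = next((a for a in amplitudes_pA if a >= rheobase_pA), None)
    for amp in amplitudes_pA:
        spiking = grid_rheo is not None and amp >= grid_rheo
        dv_inf = amp * circuit.Rm / 1000.0  # mV
        if spiking:
            cap = ap.threshold_v - 5.0 - circuit.V_rest
            dv_inf = min(dv_inf, cap)
        v = np.full(n, circuit.V_rest)
        on, off = t >= stim_onset, t >= stim_onset + stim_duration
        v[on] = circuit.V_rest + dv_inf * (1 - np.exp(-(t[on] - stim_onset) / tau_s))
        v_end = v[np.searchsorted(t, stim_onset + stim_duration) - 1]
        v[off] = circuit.V_rest + (v_end - circuit.V_rest) * np.exp(
            -(t[off] - stim_onset - stim_duration) / tau_s
        )

        spike_times = np.array([])
        if spiking:
            k = int(round(gain_spikes_per_40pA * (amp - grid_rheo) / 40.0)) + 1
            lead, span_lo, span_hi = 0.05, 0.05, stim_duration - 0.03
            base_v = circuit.V_rest + dv_inf * (1 - math.exp(-lead / tau_s))
            extent = ap_template_extent_ms(ap, base_v) / 1000.0
            spacing = (span_hi - span_lo) / k
            if extent > spacing or extent > span_hi - span_lo:
                raise ParameterError(
                    f"{k} spikes of ~{extent*1e3:.1f} ms templates cannot fit "
                    f"in the {stim_duration}-s step"
                )
            spike_times = stim_onset + span_lo + spacing * (0.5 + np.arange(k))
            for st in spike_times:
                i_pre = int(st * rate)
                _render_ap(v, rate, st, ap, baseline_at=v[i_pre])
        if circuit.noise_sd > 0:
            v = v + rng.normal(0.0, circuit.noise_sd, size=n)
        sweeps.append(
            Sweep(
                samples=v,
                sampling_rate=rate,
                channel_kind=VOLTAGE,
                clamp_mode=CURRENT_CLAMP,
                stimulus=StimulusEpoch(stim_onset, stim_duration, float(amp)),
            )
        )
        times_per_sweep.append(spike_times)
        counts.append(int(spike_times.size))

    truth = GroundTruth(
        event_times=times_per_sweep,
        spike_counts=counts,
        params={
            "rheobase_pA": grid_rheo,
            "threshold_v": ap.threshold_v,
            "peak_v": ap.peak_v,
            "half_width_ms": ap.half_width,
            "depol_rate": ap.depol_rate,
            "amplitudes_pA": list(amplitudes_pA),
            "circuit": circuit,
            "ap": ap,
        },
    )
    return SweepSet(sweeps=sweeps, metadata={"protocol": "current_steps"}), truth


# ---------------------------------------------------------------------------
# membrane test


def make_membrane_test(
    circuit: PassiveCircuitSpec,
    step_mV: float = 10.0,
    n_reps: int = 1,
    seed: int = 0,
    sampling_rate: float = MEMBRANE_TEST_RATE,
    holding_mV: float = -70.0,
    step_onset: float = 0.010,
    step_duration: float = 0.025,
) -> tuple[SweepSet, GroundTruth]:
    """Voltage-clamp membrane test: current response to a +step_mV step.

    Closed form (t measured from step onset):
    I(t) = I_hold + I_ss + (I_peak - I_ss) * exp(-t/tau) with
    I_peak = dV/Ra, I_ss = dV/(Ra+Rm), tau = Cm*Ra*Rm/(Ra+Rm); units are
    consistent (mV/MOhm -> nA, scaled to pA; MOhm*pF -> microseconds). The
    default sampling is finer than protocol sweeps because the access
    transient of a healthy cell decays in well under a millisecond.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rate = sampling_rate
    n = int(round((step_onset + step_duration + 0.01) * rate))
    t = np.arange(n) / rate

    i_hold = (holding_mV - circuit.V_rest) / (circuit.Ra + circuit.Rm) * 1000.0  # pA
    i_peak = step_mV / circuit.Ra * 1000.0  # pA, relative to holding
    i_ss = step_mV / (circuit.Ra + circuit.Rm) * 1000.0
    tau_s = circuit.tau_test_ms / 1000.0

    base = np.full(n, i_hold)
    on = t >= step_onset
    off = t >= step_onset + step_duration
    base[on] += i_ss + (i_peak - i_ss) * np.exp(-(t[on] - step_onset) / tau_s)
    # Off transient: just before step end the deviation from holding is
    # dev_end; stepping the command back drops the series-resistance current
    # by I_peak, and the remainder relaxes to holding with the same tau.
    dev_end = i_ss + (i_peak - i_ss) * np.exp(-step_duration / tau_s)
    base[off] = i_hold + (dev_end - i_peak) * np.exp(
        -(t[off] - step_onset - step_duration) / tau_s
    )

    sweeps = []
    for _ in range(n_reps):
        cur = base.copy()
        if circuit.noise_sd > 0:
            cur += rng.normal(0.0, circuit.noise_sd, size=n)
        sweeps.append(
            Sweep(
                samples=cur,
                sampling_rate=rate,
                channel_kind=CURRENT,
                clamp_mode=VOLTAGE_CLAMP,
                stimulus=StimulusEpoch(step_onset, step_duration, step_mV),
            )
        )
    truth = GroundTruth(
        params={
            "Ra": circuit.Ra,
            "Rm": circuit.Rm,
            "Cm": circuit.Cm,
            "tau_ms": circuit.tau_test_ms,
            "I_peak_pA": i_peak,
            "I_ss_pA": i_ss,
            "holding_pA": i_hold,
            "step_mV": step_mV,
        }
    )
    return SweepSet(sweeps=sweeps, metadata={"protocol": "membrane_test"}), truth


# ---------------------------------------------------------------------------
# PSC trains


def _biexp_kernel(tau_rise_ms: float, tau_decay_ms: float, rate: float) -> np.ndarray:
    """Unit-peak biexponential kernel exp(-t/tau_d) - exp(-t/tau_r), peak 1."""
    tr, td = tau_rise_ms / 1000.0, tau_decay_ms / 1000.0
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    t_end = t_peak + 8.0 * td
    t = np.arange(int(math.ceil(t_end * rate)) + 1) / rate
    g = np.exp(-t / td) - np.exp(-t / tr)
    return g / (math.exp(-t_peak / td) - math.exp(-t_peak / tr))


def make_psc_trace(
    spec: PSCTrainSpec, sampling_rate: float = DEFAULT_RATE
) -> tuple[Sweep, GroundTruth]:
    """Voltage-clamp trace with Poisson-timed inward biexponential events.

    Each event subtracts a kernel normalized so its peak equals the drawn
    amplitude; overlapping events sum linearly. Ground truth carries kernel
    onset times (sorted) and the drawn positive magnitudes.
    """
    rng = np.random.default_rng(spec.seed)
    rate = sampling_rate
    n = int(round(spec.duration * rate))
    n_events = rng.poisson(spec.rate * spec.duration)
    times = np.sort(rng.uniform(0.0, spec.duration, size=n_events))
    if spec.amp_sd > 0:
        sigma2 = math.log(1.0 + (spec.amp_sd / spec.amp_mean) ** 2)
        mu = math.log(spec.amp_mean) - sigma2 / 2.0
        amps = rng.lognormal(mu, math.sqrt(sigma2), size=n_events)
    else:
        amps = np.full(n_events, spec.amp_mean)

    trace = np.full(n, spec.baseline_pA)
    kernel = _biexp_kernel(spec.tau_rise, spec.tau_decay, rate)
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * rate))
        seg = min(kernel.size, n - i0)
        if seg > 0:
            trace[i0 : i0 + seg] -= a * kernel[:seg]
    if spec.noise_sd > 0:
        trace += rng.normal(0.0, spec.noise_sd, size=n)

    sweep = Sweep(
        samples=trace,
        sampling_rate=rate,
        channel_kind=CURRENT,
        clamp_mode=VOLTAGE_CLAMP,
    )
    truth = GroundTruth(
        event_times=times.tolist(),
        event_amplitudes=amps.tolist(),
        params={"spec": spec},
    )
    return sweep, truth


# ---------------------------------------------------------------------------
# evoked paired pulses

PAPER_ISIS_MS = (20.0, 50.0, 100.0, 136.0, 191.0, 358.0)


def make_evoked_pair(
    components: list[tuple[float, float]],
    C: float = 0.0,
    isi_ms: float = 50.0,
    ppr: float = 1.0,
    seed: int = 0,
    n_reps: int = 1,
    noise_sd: float = 0.0,
    sampling_rate: float = DEFAULT_RATE,
    rise_ms: float = 3.0,
    stim1_s: float = 0.1,
) -> tuple[SweepSet, GroundTruth]:
    """Paired evoked PSCs with a known multi-exponential decay.

    ``components`` is a list of (A_i pA, tau_i ms); the first response rises
    over ``rise_ms`` to a peak of magnitude C + sum(A_i) and decays as
    C + sum A_i exp(-t/tau_i) (inward, negative). The second response is the
    same kernel scaled by ``ppr``, superposed on the first response's tail.
    Stimulus times are stored in the SweepSet metadata.
    """
    if ppr <= 0:
        raise ParameterError("ppr must be > 0")
    if not components or any(a <= 0 or tau <= 0 for a, tau in components):
        raise ParameterError("components must be non-empty with positive A and tau")
    rng = np.random.default_rng(seed)
    rate = sampling_rate
    taus = [tau for _, tau in components]
    dur = stim1_s + isi_ms / 1000.0 + 6.0 * max(taus) / 1000.0 + 0.05
    n = int(round(dur * rate))
    t = np.arange(n) / rate

    def kernel(t0: float) -> np.ndarray:
        out = np.zeros(n)
        rise = (t >= t0) & (t < t0 + rise_ms / 1000.0)
        peak_mag = C + sum(a for a, _ in components)
        out[rise] = -_raised_cos(0.0, peak_mag, (t[rise] - t0) / (rise_ms / 1000.0))
        dec = t >= t0 + rise_ms / 1000.0
        td = t[dec] - (t0 + rise_ms / 1000.0)
        out[dec] = -(C + sum(a * np.exp(-td / (tau / 1000.0)) for a, tau in components))
        return out

    stim2_s = stim1_s + isi_ms / 1000.0
    base = kernel(stim1_s) + ppr * kernel(stim2_s)
    sweeps = []
    for _ in range(n_reps):
        cur = base.copy()
        if noise_sd > 0:
            cur += rng.normal(0.0, noise_sd, size=n)
        sweeps.append(
            Sweep(samples=cur, sampling_rate=rate, channel_kind=CURRENT,
                  clamp_mode=VOLTAGE_CLAMP)
        )
    amp1 = C + sum(a for a, _ in components)
    wtau = sum(a * tau for a, tau in components) / sum(a for a, _ in components)
    sweepset = SweepSet(
        sweeps=sweeps,
        metadata={"protocol": "paired_pulse", "stim_times_s": [stim1_s, stim2_s],
                  "isi_ms": isi_ms},
    )
    truth = GroundTruth(
        event_times=[stim1_s, stim2_s],
        event_amplitudes=[amp1, ppr * amp1],
        params={"components": list(components), "C": C, "ppr": ppr,
                "isi_ms": isi_ms, "weighted_tau_ms": wtau, "rise_ms": rise_ms},
    )
    return sweepset, truth


# ---------------------------------------------------------------------------
# cohort presets

AGES = ("P8", "P18", "P70")
GENOTYPES = ("WT", "KO")

# Illustrative per-cell parameter distributions, (mean, sd) per age x genotype.
# The knockout-vs-wildtype offsets realize the qualitative signed phenotype
# pattern (juvenile hyperexcitability: lower rheobase, narrower spikes,
# steeper FI, higher Rm; adult synaptic shift: higher PSC rate, lower PSC
# amplitude, lower Rm). The numeric values are fabricated presets for
# simulation only — they are not measured quantities.
_PRESETS = {
    ("P8", "WT"): dict(rheobase=(80, 25), gain=(0.3, 0.1), Rm=(400, 60), Cm=(40, 8),
                       half_width=(4.5, 0.5), depol=(60, 10), thr=(-38, 2),
                       peak=(10, 4), vrest=(-60, 2), psc_rate=(0.5, 0.15),
                       psc_amp=(12, 2)),
    ("P8", "KO"): dict(rheobase=(75, 25), gain=(0.4, 0.1), Rm=(400, 60), Cm=(40, 8),
                       half_width=(4.5, 0.5), depol=(60, 10), thr=(-38, 2),
                       peak=(10, 4), vrest=(-60, 2), psc_rate=(0.5, 0.15),
                       psc_amp=(12, 2)),
    ("P18", "WT"): dict(rheobase=(240, 40), gain=(0.8, 0.3), Rm=(150, 30), Cm=(80, 12),
                        half_width=(1.6, 0.15), depol=(150, 20), thr=(-40, 2),
                        peak=(25, 4), vrest=(-65, 2), psc_rate=(1.5, 0.4),
                        psc_amp=(18, 3)),
    ("P18", "KO"): dict(rheobase=(150, 40), gain=(1.6, 0.3), Rm=(200, 30), Cm=(80, 12),
                        half_width=(1.2, 0.15), depol=(150, 20), thr=(-40, 2),
                        peak=(25, 4), vrest=(-65, 2), psc_rate=(1.5, 0.4),
                        psc_amp=(18, 3)),
    ("P70", "WT"): dict(rheobase=(280, 40), gain=(1.0, 0.3), Rm=(120, 15), Cm=(100, 15),
                        half_width=(1.0, 0.1), depol=(200, 25), thr=(-36, 2),
                        peak=(30, 4), vrest=(-68, 2), psc_rate=(2.0, 0.4),
                        psc_amp=(25, 3)),
    ("P70", "KO"): dict(rheobase=(280, 40), gain=(1.0, 0.3), Rm=(90, 15), Cm=(100, 15),
                        half_width=(1.0, 0.1), depol=(200, 25), thr=(-36, 2),
                        peak=(30, 4), vrest=(-68, 2), psc_rate=(4.0, 0.8),
                        psc_amp=(17, 3)),
}


@dataclass(frozen=True)
class CellDraw:
    """Per-cell parameter draw from a phenotype preset."""

    cell_id: str
    age: str
    genotype: str
    circuit: PassiveCircuitSpec
    ap: APWaveformSpec
    psc: PSCTrainSpec
    rheobase_pA: float
    gain_spikes_per_40pA: float


def make_phenotype_preset(
    age: str, genotype: str, n_cells: int, seed: int = 0
) -> list[CellDraw]:
    """Draw per-cell simulation parameters for one age x genotype group.

    The presets are illustrative distributions whose WT/KO offsets carry the
    signed phenotype pattern; see the module docstring. Draws are truncated
    to physically valid ranges.
    """
    if (age, genotype) not in _PRESETS:
        raise ParameterError(f"unknown age/genotype ({age!r}, {genotype!r})")
    if n_cells < 3:
        raise ParameterError("n_cells must be >= 3")
    p = _PRESETS[(age, genotype)]
    rng = np.random.default_rng(seed)

    def draw(key, lo=None):
        mean, sd = p[key]
        x = rng.normal(mean, sd)
        return x if lo is None else max(x, lo)

    cells = []
    for i in range(n_cells):
        thr = draw("thr")
        peak = max(draw("peak"), thr + 20.0 + 5.0)  # keep spikes above the height gate
        circuit = PassiveCircuitSpec(
            Ra=max(rng.normal(11, 2), 4.0),
            Rm=draw("Rm", lo=30.0),
            Cm=draw("Cm", lo=15.0),
            V_rest=draw("vrest"),
            noise_sd=0.3,
        )
        ap = APWaveformSpec(
            threshold_v=thr,
            peak_v=peak,
            half_width=draw("half_width", lo=0.5),
            depol_rate=draw("depol", lo=30.0),
            ahp_v=thr - 12.0,
        )
        psc = PSCTrainSpec(
            rate=draw("psc_rate", lo=0.1),
            amp_mean=draw("psc_amp", lo=7.0),
            amp_sd=4.0,
            duration=300.0,
            noise_sd=2.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cells.append(
            CellDraw(
                cell_id=f"{age}-{genotype}-{i:02d}",
                age=age,
                genotype=genotype,
                circuit=circuit,
                ap=ap,
                psc=psc,
                rheobase_pA=draw("rheobase", lo=40.0),
                gain_spikes_per_40pA=draw("gain", lo=0.1),
            )
        )
    return cells


def make_resting_sweep(
    v_rest: float = -65.0,
    noise_sd: float = 0.3,
    duration: float = 5.0,
    seed: int = 0,
    sampling_rate: float = DEFAULT_RATE,
) -> Sweep:
    """Current-clamp I=0 sweep for resting-potential estimation."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    v = np.full(n, v_rest)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    return Sweep(samples=v, sampling_rate=sampling_rate, channel_kind=VOLTAGE,
                 clamp_mode=CURRENT_CLAMP)
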