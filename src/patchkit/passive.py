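"""Passive membrane properties: resting potential and the membrane test.

The membrane test models the whole-cell recording as a one-compartment
Ra-Rm-Cm circuit. A command step of dV from holding draws an instantaneous
access current I_peak = dV/Ra that relaxes with tau = Cm*Ra*Rm/(Ra+Rm) to a
steady state I_ss = dV/(Ra+Rm). Because the true peak falls between samples
at ordinary sampling rates, the peak is taken from the fitted transient
extrapolated to step onset rather than from the raw maximum.

No junction-potential correction is applied anywhere by default; recordings
analysed here are assumed uncompensated, and correction is an explicit
opt-in (see :mod:`patchkit.ljp`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import EstimationError, InputError
from .trace_io import CURRENT_CLAMP, VOLTAGE, VOLTAGE_CLAMP, Sweep, SweepSet

QC_ACCESS_RESISTANCE_MOHM = 25.0  # cells with Ra at or above this are excluded


@dataclass
class MembraneTestResult:
    Ra: float  # MOhm
    Rm: float  # MOhm
    Cm: float  # pF
    tau: float  # ms
    holding_current: float  # pA
    fit_rmse: float  # pA
    flags: list = field(default_factory=list)


def resting_potential(sweep: Sweep, skip_initial_s: float = 0.1) -> float:
    """Resting membrane potential from a current-clamp sweep at I = 0.

    Mean membrane voltage over the sweep excluding the first
    ``skip_initial_s`` seconds (settle time after switching to I = 0).
    """
    if sweep.clamp_mode != CURRENT_CLAMP or sweep.channel_kind != VOLTAGE:
        raise InputError("resting potential needs a current-clamp voltage sweep")
    if sweep.stimulus is not None and sweep.stimulus.amplitude != 0:
        raise InputError("resting potential requires I = 0 (no stimulus step)")
    i0 = min(sweep.sample_index(skip_initial_s), sweep.samples.size - 1)
    if sweep.duration <= skip_initial_s:
        i0 = 0
    return float(np.mean(sweep.samples[i0:]))


def membrane_test(
    sweepset: SweepSet,
    baseline_margin_s: float = 0.0005,
    steady_fraction: float = 0.25,
) -> MembraneTestResult:
    """Estimate (Ra, Rm, Cm, tau) from voltage-clamp step repetitions.

    Repetitions are averaged first. The transient from the first post-onset
    sample to the end of the step is fit with a single exponential
    I(t) = I_inf + a*exp(-(t - t_on)/tau); the peak current is the fit
    evaluated at onset, I_peak = I_inf + a. Then, relative to the pre-step
    holding current: Ra = dV/I_peak, Rm = dV/I_ss - Ra,
    Cm = tau*(Ra+Rm)/(Ra*Rm) (ms*MOhm -> nF scaled to pF).

    If the transient is not resolvable (amplitude indistinguishable from
    zero), the access resistance is reported as 0 with Rm = dV/I_ss and an
    ``unresolved_transient`` flag; Cm is NaN in that case.
    """
    if sweepset.clamp_mode != VOLTAGE_CLAMP:
        raise InputError("membrane test needs voltage-clamp sweeps")
    stim = sweepset[0].stimulus
    if stim is None:
        raise InputError("membrane test sweeps must carry their step stimulus")
    rate = sweepset.sampling_rate
    dt = 1.0 / rate
    avg = np.mean([s.samples for s in sweepset], axis=0)
    t = np.arange(avg.size) * dt

    dv = stim.amplitude  # mV
    i_on = int(np.ceil(stim.onset_time * rate - 1e-9))
    i_off = int(np.floor(stim.offset_time * rate + 1e-9))
    base_end = max(1, int((stim.onset_time - baseline_margin_s) * rate))
    holding = float(np.mean(avg[:base_end]))

    n_step = i_off - i_on
    ss_start = i_off - max(2, int(steady_fraction * n_step))
    i_ss_total = float(np.mean(avg[ss_start:i_off]))
    i_ss = i_ss_total - holding
    if i_ss == 0:
        raise EstimationError("no steady-state current deflection in the step")

    seg_t = t[i_on:i_off] - stim.onset_time
    seg_i = avg[i_on:i_off]

    # initial guesses: log-linear regression on the early decaying part
    dev = seg_i - i_ss_total
    sign = np.sign(dev[0]) if dev[0] != 0 else 1.0
    pos = np.nonzero(sign * dev > 0.05 * abs(sign * dev[0]))[0]
    if pos.size >= 3:
        k = pos[: max(3, pos.size // 2)]
        slope, intercept = np.polyfit(seg_t[k], np.log(np.abs(dev[k])), 1)
        tau0 = -1.0 / slope if slope < 0 else 5 * dt
        a0 = sign * np.exp(intercept)
    else:
        tau0, a0 = 5 * dt, dev[0]

    def model(tt, i_inf, a, tau):
        return i_inf + a * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model, seg_t, seg_i,
            p0=[i_ss_total, a0, max(tau0, dt / 10)],
            bounds=([-np.inf, -np.inf, dt / 1000.0], [np.inf, np.inf, seg_t[-1] * 10]),
            maxfev=10000,
        )
    except RuntimeError as e:
        raise EstimationError(
            "membrane-test transient fit did not converge",
            diagnostics={"tau0": tau0, "a0": a0, "n_points": seg_t.size},
        ) from e
    i_inf, a, tau_s = popt
    rmse = float(np.sqrt(np.mean((model(seg_t, *popt) - seg_i) ** 2)))

    flags: list[str] = []
    i_peak = (i_inf + a) - holding  # extrapolated to step onset, pA
    i_ss_fit = i_inf - holding
    if abs(a) < 0.02 * abs(i_ss_fit) or tau_s < dt / 4:
        flags.append("unresolved_transient")
        Ra = 0.0
        Rm = dv / i_ss_fit * 1000.0
        Cm = float("nan")
        tau_ms = tau_s * 1000.0
    else:
        Ra = dv / i_peak * 1000.0  # mV/pA = GOhm -> MOhm
        Rm = dv / i_ss_fit * 1000.0 - Ra
        tau_ms = tau_s * 1000.0
        Cm = tau_ms * 1000.0 * (Ra + Rm) / (Ra * Rm)  # us/MOhm -> pF
        if Ra <= 0 or Rm <= 0:
            raise EstimationError(
                "membrane-test produced non-physical resistances",
                diagnostics={"Ra": Ra, "Rm": Rm, "i_peak": i_peak, "i_ss": i_ss_fit},
            )
    return MembraneTestResult(
        Ra=Ra, Rm=Rm, Cm=Cm, tau=tau_ms, holding_current=holding,
        fit_rmse=rmse, flags=flags,
    )


def qc_access_resistance(
    result: MembraneTestResult, limit: float = QC_ACCESS_RESISTANCE_MOHM
) -> bool:
    """Inclusion rule: access resistance strictly below the limit passes."""
    return result.Ra < limit
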