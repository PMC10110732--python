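"""Evoked paired-pulse PSC analysis.

The decaying phase of an evoked PSC is modelled as

    f(t) = C + sum_i A_i * exp(-t / tau_i),        i = 1..n,  n <= 3,

fit to the magnitude of the response from its peak onward. The number of
terms is chosen by the small-sample-corrected Akaike criterion (AICc) over
n in {1, 2, 3}, ties resolved toward fewer terms. The amplitude-weighted
time constant is

    weighted_tau = sum_i A_i tau_i / sum_j A_j,

which is invariant to a common rescaling of the amplitudes and collapses to
tau_1 for a single term. A second, model-free decay measure is the time for
the response to fall from 100% to 37% of its peak amplitude.

Paired-pulse analysis measures the first-response amplitude against the
pre-stimulus baseline and the second against the extrapolated fitted tail of
the first response — necessary at short interstimulus intervals where the
responses overlap; if the fit is unusable it falls back to a 2-ms local
baseline before the second stimulus and flags the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import EstimationError, InputError
from .trace_io import Sweep, SweepSet

PAPER_ISIS_MS = (20.0, 50.0, 100.0, 136.0, 191.0, 358.0)
DECAY_FRACTION = 0.37  # 100% -> 37% decay-time landmark


@dataclass
class ExpFit:
    n_terms: int
    C: float  # pA, offset of the magnitude decay
    components: list  # [(A_i pA, tau_i ms)], sorted by tau
    weighted_tau: float  # ms
    fit_rmse: float  # pA
    scores: dict = field(default_factory=dict)  # n -> AICc


@dataclass
class PairedPulseResult:
    isi: float  # ms
    amp1: float  # pA
    amp2: float  # pA, tail-subtracted
    ppr: float
    decay_tau_100_37: float | None  # ms
    fit: ExpFit | None = None
    flags: tuple = ()


def weighted_tau(components: list[tuple[float, float]]) -> float:
    """Amplitude-weighted mean time constant, sum A_i tau_i / sum A_j."""
    total = sum(a for a, _ in components)
    if total == 0:
        raise InputError("weighted tau undefined for zero total amplitude")
    return sum(a * tau for a, tau in components) / total


def _multiexp(t, C, *params):
    out = np.full_like(t, C, dtype=float)
    for i in range(0, len(params), 2):
        out += params[i] * np.exp(-t / params[i + 1])
    return out


def _aicc(rss: float, n_obs: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n_obs * math.log(rss / n_obs) + 2 * k
    if n_obs - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n_obs - k - 1)
    return aic


def fit_decay(
    segment: np.ndarray,
    sampling_rate: float,
    max_terms: int = 3,
    polarity: int = -1,
) -> ExpFit:
    """Fit the decaying phase of an evoked PSC with 1..max_terms exponentials.

    ``segment`` starts at the response peak (pA, baseline-subtracted). The
    fit is performed on the positive magnitude ``polarity``-rectified trace
    with positivity bounds on every A_i and tau_i. If the residual of some n
    is already at numerical zero, larger n are not tried (they cannot be
    preferred and their AICc is numerically meaningless).
    """
    # events carry the sign of `polarity`, so this is the positive magnitude
    mag = polarity * np.asarray(segment, dtype=float)
    t = np.arange(mag.size) / sampling_rate * 1000.0  # ms
    if mag.size < 10:
        raise InputError("decay segment too short to fit")
    peak = mag[0]
    span = t[-1]

    best = None
    scores: dict[int, float] = {}
    for n in range(1, max_terms + 1):
        k = 2 * n + 1
        if mag.size <= k + 2:
            break
        c0 = float(min(mag.min(), 0.0))
        a_tot = peak - c0
        taus0 = np.geomspace(max(span / 30.0, 1e-3), max(span / 1.5, 2e-3), n)
        p0 = [c0] + [x for tau in taus0 for x in (a_tot / n, tau)]
        lo = [-np.inf] + [0.0, 1e-6] * n
        hi = [np.inf] + [np.inf, np.inf] * n
        try:
            popt, _ = curve_fit(_multiexp, t, mag, p0=p0, bounds=(lo, hi), maxfev=20000)
        except RuntimeError:
            continue
        resid = _multiexp(t, *popt) - mag
        rss = float(np.dot(resid, resid))
        scores[n] = _aicc(rss, mag.size, k)
        if best is None or scores[n] < best[0] - 1e-9:
            best = (scores[n], n, popt, math.sqrt(rss / mag.size))
        if rss / mag.size < (1e-10 * max(peak, 1.0)) ** 2:
            break  # exact fit; more terms cannot help
    if best is None:
        raise EstimationError(
            "multi-exponential decay fit failed for all term counts",
            diagnostics={"n_points": mag.size, "peak": peak},
        )
    _, n, popt, rmse = best
    comps = sorted(
        [(popt[i], popt[i + 1]) for i in range(1, 2 * n + 1, 2)], key=lambda c: c[1]
    )
    return ExpFit(
        n_terms=n,
        C=float(popt[0]),
        components=[(float(a), float(tau)) for a, tau in comps],
        weighted_tau=weighted_tau(comps),
        fit_rmse=rmse,
        scores=scores,
    )


def decay_time_100_37(
    segment: np.ndarray,
    sampling_rate: float,
    amp1: float,
    polarity: int = -1,
) -> float | None:
    """Time (ms) for the response to fall from its peak to 37% of amp1.

    ``segment`` starts at the peak and is baseline-subtracted; returns None
    when the level is never reached within the segment (truncated decay).
    """
    mag = polarity * np.asarray(segment, dtype=float)
    level = DECAY_FRACTION * amp1
    belows = np.nonzero(mag < level)[0]
    if belows.size == 0:
        return None
    j = int(belows[0])
    if j == 0:
        return 0.0
    dt_ms = 1000.0 / sampling_rate
    t = (j - 1 + (mag[j - 1] - level) / (mag[j - 1] - mag[j])) * dt_ms
    return float(t)


def paired_pulse(
    sweepset: SweepSet,
    blank_ms: float = 2.0,
    baseline_ms: float = 50.0,
    polarity: int = -1,
    max_terms: int = 3,
) -> PairedPulseResult:
    """Paired-pulse ratio from evoked pairs at one interstimulus interval.

    Repetitions are averaged before measurement. Stimulus times are read
    from the SweepSet metadata (``stim_times_s``); amplitude 1 is measured
    against the pre-stimulus baseline and amplitude 2 against the fitted,
    extrapolated tail of response 1.
    """
    meta = sweepset.metadata
    if "stim_times_s" not in meta or len(meta["stim_times_s"]) != 2:
        raise InputError("paired-pulse sweeps need two stim_times_s in metadata")
    t1, t2 = (float(x) for x in meta["stim_times_s"])
    isi_ms = meta.get("isi_ms", (t2 - t1) * 1000.0)
    rate = sweepset.sampling_rate
    avg = np.mean([s.samples for s in sweepset], axis=0)
    n = avg.size
    dt = 1.0 / rate

    i1, i2 = int(round(t1 * rate)), int(round(t2 * rate))
    blank = int(round(blank_ms / 1000.0 * rate))
    base_start = max(0, i1 - int(round(baseline_ms / 1000.0 * rate)))
    baseline = float(np.mean(avg[base_start : max(base_start + 1, i1 - 2)]))
    x = polarity * (avg - baseline)  # positive-magnitude trace

    p1 = int(np.argmax(x[i1 + blank : i2])) + i1 + blank
    amp1 = float(x[p1])
    if amp1 <= 0:
        raise EstimationError("no first evoked response found")

    flags: tuple = ()
    fit = None
    seg1 = avg[p1:i2] - baseline
    try:
        fit = fit_decay(seg1, rate, max_terms=max_terms, polarity=polarity)
    except (EstimationError, InputError):
        flags += ("tail_fit_failed",)

    p2_end = min(n, i2 + blank + int(round(0.03 * rate)))
    p2 = int(np.argmax(x[i2 + blank : p2_end])) + i2 + blank
    if fit is not None:
        t_rel = (p2 - p1) * dt * 1000.0  # ms since first peak
        tail = _multiexp(
            np.array([t_rel]), fit.C,
            *[v for a, tau in fit.components for v in (a, tau)],
        )[0]
    else:
        tail_win = avg[max(0, i2 - int(0.002 * rate)) : i2]
        tail = polarity * (float(np.mean(tail_win)) - baseline)
        flags += ("local_baseline_fallback",)
    amp2 = float(x[p2] - tail)

    d37 = decay_time_100_37(seg1, rate, amp1, polarity=polarity)
    if d37 is None:
        flags += ("decay_37_undefined",)
    return PairedPulseResult(
        isi=float(isi_ms),
        amp1=amp1,
        amp2=amp2,
        ppr=amp2 / amp1,
        decay_tau_100_37=d37,
        fit=fit,
        flags=flags,
    )
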