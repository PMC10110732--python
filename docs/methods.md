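# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would want to know.

## Units and conventions

One internal unit system everywhere: time s, voltage mV, current pA,
resistance MΩ, capacitance pF, frequency Hz. Convenient identities follow:
mV/MΩ = nA (×1000 → pA) and MΩ·pF = µs. Sample 0 of a sweep is t = 0; all
event times are sweep-relative seconds. Synaptic currents are inward
(negative) for cells held at −70 mV with a K-gluconate internal; amplitudes
are reported as positive magnitudes. No junction-potential correction is
ever applied implicitly — the `ljp` module computes the correction, and
applying it is the caller's explicit decision.

## Membrane test

Model: one-compartment circuit with access resistance Ra in series with the
membrane (Rm ∥ Cm). For a command step ΔV from holding,

    I(t) = I_hold + I_ss + (I_peak − I_ss)·e^(−t/τ),
    I_peak = ΔV/Ra,  I_ss = ΔV/(Ra+Rm),  τ = Cm·RaRm/(Ra+Rm).

Estimation averages repetitions, measures holding from the pre-step
baseline and the steady state from the last quarter of the step, fits the
single exponential from the first post-onset sample, and evaluates the fit
at step onset for the peak. Extrapolating the peak removes the
sampling-rate bias of taking the raw maximum (at ordinary rates the true
peak falls between samples). With healthy-cell parameters τ can reach
~0.1 ms, so the membrane-test generator defaults to 50 kHz sampling while
protocol sweeps stay at 5 kHz; the estimator works at any rate that
resolves the transient. A transient whose fitted amplitude is
indistinguishable from zero (< 2% of the steady deflection, or τ below a
quarter sample) is flagged `unresolved_transient`: Ra is reported as 0, the
full resistance goes to Rm, and Cm is NaN — the physically honest reading
of a trace with no visible charging current. Multi-compartment transients
are out of scope.

QC: cells pass only with Ra strictly below 25 MΩ.

## Action-potential template and detection

The simulator's spike is a piecewise raised-cosine waveform parameterized
directly by threshold voltage, peak voltage, half-width and maximal
upstroke slope: a slow lead-in ramp (≤ 2.5 mV/ms, below any detection
threshold) from the local baseline to threshold, a raised-cosine upstroke
whose duration realizes the requested max dV/dt, a raised-cosine
downstroke whose duration realizes the requested width at half height, an
afterhyperpolarization trough and a 10-ms recovery. Because every landmark
is closed-form, feature recovery is analytically checkable; the tradeoff is
that the template is a waveform model, not a conductance model (no
depolarization block, no spike-height adaptation).

Detection: central-difference dV/dt (no smoothing by default, since none is
assumed of the input; optional Savitzky–Golay behind a config flag);
candidate onsets at upward crossings of the threshold; the peak is the
voltage maximum before dV/dt returns below zero. The default threshold is
20 mV/ms. Analysis protocols for such recordings sometimes quote
"20 mV/s", but that value sits below the noise floor of any physiological
trace (0.3 mV RMS noise at 5 kHz produces dV/dt noise of ~1 mV/ms), and
the conventional unit of the widely used feature extractors is mV/ms; the
literal mV/s value remains available through the config.

Approval gates: threshold-to-peak height ≥ 20 mV and half-height width
≤ 3 ms (mature) or ≤ 10 ms (immature neurons, whose spikes are broad).
The same half-height width serves as both the approval gate and the
reported half-width — one definition, one implementation. The firing
threshold is the last point, walking back from the peak, where dV/dt sat
below 5% of that spike's maximum; all crossings are refined by linear
interpolation between bracketing samples, so estimates improve smoothly
with sampling rate. The interspike interval is measured between threshold
crossings — the only per-spike "baseline" landmark with an operational
definition — and the firing threshold of a cell is taken from the first
spike of the rheobase sweep (a convention; config-exposed).

## PSC detection

The event detector is deliberately simple and fully parameterized (see the
`psc` module docstring for the step-by-step algorithm): rolling-median
baseline over 200 ms, MAD-scaled candidate threshold (k = 3), a 5-pA
amplitude criterion, 2-ms merging. Two smoothing scales are used on
purpose — a heavier Gaussian (σ 0.8 ms) for candidate detection and peak
location, a light one (σ 0.2 ms) for amplitude readout — so that detection
is robust while amplitudes stay within ~2% of the underlying event.
Events riding the decay of a predecessor get their local baseline from an
exponential extrapolation of that tail, flagged `tail_baseline`.

Operating characteristics (measured on 300-s synthetic trains, 20-pA mean
amplitude): with noise SD 2 pA, recall and precision ≥ 0.95 and frequency
and mean amplitude within 5% of ground truth across 0.5–5 Hz; on pure
2-pA noise the false-event rate is ≈ 0. With noise SD at 4 pA the 5-pA
inclusion criterion sits at 1.25 noise SD and false positives through the
amplitude gate become irreducible for this family of threshold detectors —
recordings that noisy need a template-matching detector (out of scope) or
a higher criterion. Miniature (TTX) and spontaneous recordings are
analysed identically; the pharmacology changes the biology, not the
algorithm.

## Evoked paired pulses

The decay model, term selection (AICc over n ∈ {1,2,3}, ties to fewer
terms, with an early stop once a fit reaches numerical zero residual —
additional terms cannot be preferred and their AICc is meaningless), and
the amplitude-weighted τ are described in the `evoked` module. Fits start
at the response peak, not the stimulus, and a 2-ms artifact blank follows
each stimulus. The second-pulse amplitude is measured against the fitted,
extrapolated tail of the first response; this matters at the short
interstimulus intervals (20–50 ms) where responses overlap, and falls back
to a 2-ms local baseline (flagged) if the fit is unusable. Repetitions are
averaged before measurement. The generator's response rises over 3 ms
(raised cosine), placing the peak outside the artifact blank as in real
evoked responses, and its paired-pulse ratio scales the whole kernel, so
the tail-subtracted ground truth is exact.

## Junction potential

Henderson (linear-profile) approximation rather than full numerical
electrodiffusion: it is the standard desk calculation and agrees with
numerical Nernst–Planck solvers to well under the mobility-table
uncertainty for solutions of this class. Mobilities are limiting molar
ionic conductivities at 25 °C — inorganic ions from standard tabulations,
organic anions (gluconate 24.3, HEPES⁻ 22.05, ATP²⁻/GTP²⁻ ≈ 47,
EGTA²⁻ ≈ 48 S·cm²/mol) from the values junction-potential calculators
conventionally use; these organic values vary across sources and dominate
the ~±1 mV uncertainty, so the table is user-overridable. Speciation:
HEPES is 1/(1+10^(pKa−pH)) anionic at the working pH (pKa 7.48, pH 7.3
→ 39.8%), assumed titrated with KOH; EGTA is counted as its divalent
anion with two K⁺; Mg-ATP dissociates to Mg²⁺ + ATP²⁻; Na-GTP is treated
as the disodium salt; glucose, sucrose and myo-inositol are neutral and
ignored (recorded in the solution's `ignored` list). Electroneutrality is
checked and imbalances over 5% warn. Sign convention: pipette minus bath —
positive values are the amount by which uncorrected potentials
overestimate the true membrane potential (+14.8 mV for the K-gluconate
internal against ACSF).

## Group statistics

The decision tree is a pure function of (data, α): Shapiro–Wilk per group
(per-group rather than on residuals; config-switchable) gates parametric
vs. nonparametric branches as described in the `stats` module; every
branch lands in the report's trace. Standard tests are delegated to
scipy/pingouin — the bespoke content is the gate, the correction logic and
the reporting. Within-cell designs support one between factor (mixed
ANOVA); the Greenhouse–Geisser correction is applied to within-factor
degrees of freedom when Mauchly's test rejects sphericity. Outlier
screening is an iterative two-sided Grubbs test, chosen over
regression-based methods for determinism and a closed-form critical value;
removed values are always reported. Under null simulations (two equal
normal groups, n = 12, 500 replicates) the gated procedure's empirical
type-I error stays within [0.03, 0.08] at α = 0.05.

## Synthetic cohorts and the phenotype demo

The phenotype presets are illustrative per-cell parameter distributions,
not measurements: their wildtype-vs-knockout offsets carry a signed
pattern — juvenile knockouts hyperexcitable (lower rheobase, steeper FI,
narrower spikes, higher Rm), adult knockouts with more frequent but
smaller spontaneous PSCs and lower Rm — with effect sizes of roughly 1.5–2
within-group SDs so that 12-cell groups have power to resolve them. The
demo runs the full chain (simulate → detect → summarize → gated test) and
asserts each effect's sign and significance. Spontaneous-PSC traces in the
demo are 60 s per cell (rather than full 5-min recordings) purely as a
problem-size choice; at the preset rates this still yields 100–250 events
per cell. What passing the demo shows is that the pipeline preserves group
differences it is fed; it says nothing about effect sizes in real tissue,
where spike shapes adapt, baselines drift, and event kernels vary
event-to-event — none of which the generators emulate.

## File formats

The portable interchange format is the sweep bundle (one `time_s,value`
CSV per sweep plus a JSON sidecar); write→read is the identity. The ABF
reader covers the episodic, single-channel ABF v1 subset at fixed header
offsets, converting to mV/pA from the header's unit string (files with
unrecognizable units are rejected, never guessed) and reconstructing step
stimuli from the DAC-A epoch table; the companion writer produces the same
subset so fixtures can be generated on the fly. ABF v2, multi-channel
files, and NWB/HEKA/Igor formats are out of scope.
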