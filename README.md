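# patchkit

Analysis toolkit for whole-cell patch-clamp recordings from cortical
neurons: intrinsic membrane properties, action-potential features,
spontaneous/miniature/evoked postsynaptic currents, liquid junction
potentials, and the normality-gated group statistics used to compare
genotype × age cohorts (e.g. wildtype vs. knockout animals across
development). It is written for electrophysiologists who want a scriptable,
deterministic replacement for point-and-click analysis chains, and ships a
synthetic-trace generator with exact ground truth so every stage of the
pipeline is testable without any recordings.

## What it computes

**Passive properties.** The voltage-clamp membrane test models the
recording as an Ra–Rm–Cm one-compartment circuit. A 10-mV command step
draws `I_peak = ΔV/Ra` through the access resistance, relaxing with
`τ = Cm·RaRm/(Ra+Rm)` to `I_ss = ΔV/(Ra+Rm)`. Fitting the transient (and
extrapolating the peak back to step onset, since the true peak falls
between samples) yields Ra, Rm and Cm; cells with Ra ≥ 25 MΩ fail the
inclusion QC.

**Spikes.** Action potentials are located at upward crossings of a dV/dt
threshold (default 20 mV/ms) and approved by height (≥ 20 mV from firing
threshold to peak) and width at half height (≤ 3 ms, or ≤ 10 ms in
immature mode). The firing threshold is the point where dV/dt last sat
below 5% of the spike's maximal dV/dt. Per-cell measures: rheobase (first
suprathreshold step of a −120→+480 pA, 40-pA-increment protocol), firing
threshold, first interspike interval, and the FI curve (spikes per 1-s
step).

**Synaptic currents.** Spontaneous/miniature PSCs are detected by a
documented, deterministic pipeline (rolling-median baseline, MAD-scaled
threshold, 5-pA amplitude criterion) and summarized as frequency, mean
amplitude and amplitude CDFs. Evoked paired-pulse responses are measured
as `PPR = amp₂/amp₁` with the second amplitude taken against the
extrapolated fitted tail of the first response; decays are fit with

    f(t) = C + Σᵢ Aᵢ·exp(−t/τᵢ),   weighted τ = Σᵢ Aᵢτᵢ / Σⱼ Aⱼ,

the number of terms chosen by AICc, plus the model-free 100%→37% decay
time.

**Junction potential.** The Henderson (stationary Nernst–Planck)
approximation computes the liquid junction potential between the pipette
and bath solutions from tabulated limiting ionic mobilities, with a
documented salt dissociation map (pipette-minus-bath sign convention).

**Statistics.** Group comparisons follow a Shapiro–Wilk gate: parametric
(t test with Levene gating, ANOVA, or repeated-measures/mixed ANOVA with
Mauchly's test and Greenhouse–Geisser correction) when every group looks
normal, otherwise Mann–Whitney/Kruskal–Wallis, with Bonferroni-adjusted
post hocs and an auditable trace of every branch taken. Outlier screening
is an explicit iterative Grubbs test.

## Worked example

Simulate a current-step protocol for a neuron with a 160-pA rheobase, then
extract its intrinsic profile:

```
$ patchkit simulate steps --seed 1 --rheobase 160 --out demo_steps
$ patchkit spikes demo_steps --out demo
$ cat demo_cell.csv
rheobase_pA,threshold_mV,first_isi_ms,fi_-120pA,...,fi_480pA
160.0,-40.003,460.0,0,0,0,0,0,0,0,1,2,3,4,5,6,7,8,9
```

The detected rheobase is exactly the generator's 160-pA ground truth; the
firing threshold (−40.003 mV) recovers the template's −40 mV to within
3 µV, and the FI curve counts one extra spike per 40 pA above rheobase.
A membrane test with 2-pA noise, averaged over 5 repetitions:

```
$ patchkit simulate mtest --noise 2 --reps 5 --out demo_mt
$ patchkit passive demo_mt
cell_id,Ra_MOhm,Rm_MOhm,Cm_pF,tau_ms,holding_pA,qc_pass
,9.995,150.007,99.960,0.937,-31.234,True
```

recovering the simulated circuit (Ra 10 MΩ, Rm 150 MΩ, Cm 100 pF) to a
fraction of a percent; `qc_pass` applies the strict Ra < 25 MΩ rule. The
junction potential of the K-gluconate internal against ACSF:

```
$ patchkit ljp
+14.81 mV
```

meaning uncorrected voltage readings overestimate the true membrane
potential by about 15 mV with these solutions.

## Layout

- `src/patchkit/trace_io.py`, `abf.py` — sweep containers, portable CSV+JSON
  sweep bundles, minimal ABF v1 reader/writer
- `src/patchkit/synthetic.py` — generators with exact ground truth
- `src/patchkit/passive.py`, `spikes.py`, `psc.py`, `evoked.py` — analysis
- `src/patchkit/ljp.py` — Henderson junction potential
- `src/patchkit/stats.py`, `cohort.py`, `pipeline.py`, `cli.py` — statistics,
  cohort demos, orchestration, CLI

See `docs/methods.md` for models, parameter defaults, numerical choices
and known limitations.
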