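"""Sweep containers and portable sweep-bundle I/O.

The whole pipeline speaks one internal unit system: time in seconds, voltage
in mV, current in pA, resistance in MOhm, capacitance in pF, frequency in Hz.
Readers and writers are the only places unit conversions may happen.

A *sweep bundle* is the portable on-disk form: a directory with one
two-column CSV per sweep (``time_s,value``) plus a ``bundle.json`` sidecar
holding sampling rate, units, clamp mode, stimulus epochs and free-form
metadata. ``write_bundle`` followed by ``read_bundle`` is the identity on a
SweepSet up to float round-trip.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConsistencyError, FormatError, InputError

log = logging.getLogger(__name__)

VOLTAGE = "voltage"
CURRENT = "current"
CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"


@dataclass(frozen=True)
class StimulusEpoch:
    """A rectangular stimulus step.

    Amplitude is in pA for current-clamp sweeps and mV for voltage-clamp
    sweeps, always relative to the holding level.
    """

    onset_time: float  # s, sweep-relative (sample 0 is t = 0)
    duration: float  # s
    amplitude: float  # pA (current step) or mV (voltage step)

    def __post_init__(self):
        if self.onset_time < 0:
            raise InputError(f"stimulus onset must be >= 0, got {self.onset_time}")
        if self.duration <= 0:
            raise InputError(f"stimulus duration must be > 0, got {self.duration}")

    @property
    def offset_time(self) -> float:
        return self.onset_time + self.duration


@dataclass
class Sweep:
    """One uniformly sampled trace (voltage in mV or current in pA)."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    channel_kind: str  # "voltage" | "current"
    clamp_mode: str  # "current_clamp" | "voltage_clamp"
    stimulus: StimulusEpoch | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise InputError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InputError("a sweep needs a 1-D array of at least 2 samples")
        if self.channel_kind not in (VOLTAGE, CURRENT):
            raise InputError(f"unknown channel_kind {self.channel_kind!r}")
        if self.clamp_mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise InputError(f"unknown clamp_mode {self.clamp_mode!r}")
        if self.stimulus is not None and self.stimulus.offset_time > self.duration + 1e-12:
            raise InputError("stimulus epoch extends past the end of the sweep")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def sample_index(self, t: float) -> int:
        """Nearest sample index for a sweep-relative time."""
        return int(round(t * self.sampling_rate))


@dataclass
class SweepSet:
    """An ordered collection of sweeps from one cell/protocol.

    All sweeps must share sampling rate and clamp mode. Metadata is free-form
    (cell id, genotype label such as WT/KO, age-group label such as
    P8/P18/P70, condition, ...) and is preserved verbatim by bundle I/O.
    """

    sweeps: list[Sweep]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.sweeps:
            raise InputError("SweepSet needs at least one sweep")
        r0, m0 = self.sweeps[0].sampling_rate, self.sweeps[0].clamp_mode
        for s in self.sweeps:
            if s.sampling_rate != r0:
                raise InputError("all sweeps in a SweepSet must share sampling_rate")
            if s.clamp_mode != m0:
                raise InputError("all sweeps in a SweepSet must share clamp_mode")

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    def __getitem__(self, i) -> Sweep:
        return self.sweeps[i]

    @property
    def sampling_rate(self) -> float:
        return self.sweeps[0].sampling_rate

    @property
    def clamp_mode(self) -> str:
        return self.sweeps[0].clamp_mode

    def stimulus_amplitudes(self) -> list[float | None]:
        return [s.stimulus.amplitude if s.stimulus else None for s in self.sweeps]


# ---------------------------------------------------------------------------
# sweep-bundle reader/writer


def _stim_to_json(stim: StimulusEpoch | None):
    if stim is None:
        return None
    return {
        "onset_time_s": stim.onset_time,
        "duration_s": stim.duration,
        "amplitude": stim.amplitude,
    }


def _stim_from_json(obj) -> StimulusEpoch | None:
    if obj is None:
        return None
    return StimulusEpoch(
        onset_time=float(obj["onset_time_s"]),
        duration=float(obj["duration_s"]),
        amplitude=float(obj["amplitude"]),
    )


def write_bundle(sweepset: SweepSet, path: str | Path) -> Path:
    """Write a SweepSet as a bundle directory (CSV per sweep + JSON sidecar)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, sweep in enumerate(sweepset):
        fname = f"sweep_{i:03d}.csv"
        with open(path / fname, "w") as fh:
            np.savetxt(
                fh,
                np.column_stack([sweep.times, sweep.samples]),
                delimiter=",", fmt="%.17g", header="time_s,value", comments="",
            )
        entries.append(
            {
                "file": fname,
                "n_samples": int(sweep.samples.size),
                "channel_kind": sweep.channel_kind,
                "units": "mV" if sweep.channel_kind == VOLTAGE else "pA",
                "stimulus": _stim_to_json(sweep.stimulus),
            }
        )
    sidecar = {
        "format": "patchkit-sweep-bundle",
        "version": 1,
        "sampling_rate_hz": sweepset.sampling_rate,
        "clamp_mode": sweepset.clamp_mode,
        "sweeps": entries,
        "metadata": sweepset.metadata,
    }
    with open(path / "bundle.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def read_bundle(path: str | Path) -> SweepSet:
    """Read a bundle directory written by :func:`write_bundle`."""
    path = Path(path)
    sidecar_path = path / "bundle.json"
    if not sidecar_path.exists():
        raise FormatError(f"no bundle.json sidecar in {path}")
    try:
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
    except json.JSONDecodeError as e:
        raise FormatError(f"unparseable sidecar {sidecar_path}: {e}") from e
    if sidecar.get("format") != "patchkit-sweep-bundle":
        raise FormatError(f"{sidecar_path} is not a patchkit sweep bundle")

    rate = float(sidecar["sampling_rate_hz"])
    clamp_mode = sidecar["clamp_mode"]
    sweeps = []
    for entry in sidecar["sweeps"]:
        csv_path = path / entry["file"]
        values = np.loadtxt(csv_path, delimiter=",", skiprows=1, usecols=1, ndmin=1)
        if values.size != entry["n_samples"]:
            raise ConsistencyError(
                f"{csv_path.name}: sidecar says {entry['n_samples']} samples, "
                f"CSV has {values.size}"
            )
        sweeps.append(
            Sweep(
                samples=values,
                sampling_rate=rate,
                channel_kind=entry["channel_kind"],
                clamp_mode=clamp_mode,
                stimulus=_stim_from_json(entry.get("stimulus")),
            )
        )
    return SweepSet(sweeps=sweeps, metadata=dict(sidecar.get("metadata", {})))
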