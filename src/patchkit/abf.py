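"""Minimal Axon ABF v1 support.

Implements the episodic, single-channel subset of the ABF v1 binary layout
that patch-clamp step protocols produce: a 2048-byte little-endian header at
fixed offsets, float32 or int16 sample data starting at the data-section
block, and the DAC-A epoch table for rectangular step stimuli. ABF v2 and
multi-channel files are out of scope; NWB/HEKA/Igor formats are not handled.

The reader converts to the package unit system (mV / pA) using the header's
channel unit string; a file without a recognizable unit string is rejected
rather than silently guessed. ``write_abf`` exists so that fixtures can be
produced from any :class:`~patchkit.trace_io.SweepSet` — it writes the same
subset the reader consumes.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np

from .exceptions import FormatError
from .trace_io import (
    CURRENT,
    CURRENT_CLAMP,
    VOLTAGE,
    VOLTAGE_CLAMP,
    StimulusEpoch,
    Sweep,
    SweepSet,
)

log = logging.getLogger(__name__)

_HEADER_BYTES = 2048
_BLOCK = 512

# (name, struct format, byte offset) — ABF v1 header subset
_FIELDS = [
    ("fFileSignature", "4s", 0),
    ("fFileVersionNumber", "f", 4),
    ("nOperationMode", "h", 8),
    ("lActualAcqLength", "i", 10),
    ("lActualEpisodes", "i", 16),
    ("lDataSectionPtr", "i", 40),
    ("nDataFormat", "h", 100),
    ("nADCNumChannels", "h", 120),
    ("fADCSampleInterval", "f", 122),
    ("lNumSamplesPerEpisode", "i", 138),
    ("fADCRange", "f", 244),
    ("lADCResolution", "i", 252),
    ("sADCUnits", "8s", 602),  # channel 0 only
    ("fInstrumentScaleFactor", "f", 922),
    ("fInstrumentOffset", "f", 986),
    ("nWaveformEnable", "h", 1436),
    ("nEpochType", "10h", 1448),  # DAC A epochs
    ("fEpochInitLevel", "10f", 1488),
    ("fEpochLevelInc", "10f", 1568),
    ("lEpochInitDuration", "10i", 1648),
    ("lEpochDurationInc", "10i", 1728),
]

_EPOCH_STEP = 1  # nEpochType code for a rectangular step


def _read_header(buf: bytes) -> dict:
    header = {}
    for name, fmt, offset in _FIELDS:
        values = struct.unpack_from("<" + fmt, buf, offset)
        header[name] = values[0] if len(values) == 1 else list(values)
    return header


def _units_to_kinds(unit_str: str) -> tuple[str, str]:
    """Map a channel unit string to (channel_kind, clamp_mode)."""
    u = unit_str.strip().strip("\x00").lower()
    if u == "mv":
        return VOLTAGE, CURRENT_CLAMP
    if u == "pa":
        return CURRENT, VOLTAGE_CLAMP
    if u == "na":
        # acquisition systems often record current in nA; convert downstream
        return CURRENT, VOLTAGE_CLAMP
    raise FormatError(
        f"unknown units {unit_str!r} in ABF header; cannot infer channel kind"
    )


def read_abf(path: str | Path) -> SweepSet:
    """Read an episodic single-channel ABF v1 file into a SweepSet.

    Samples are converted to mV (voltage channel) or pA (current channel).
    Step stimuli are reconstructed from the DAC-A epoch table when the
    waveform is enabled; otherwise sweeps carry no stimulus and a warning is
    logged.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_BYTES:
        raise FormatError(f"{path}: too short to hold an ABF v1 header")
    h = _read_header(raw)
    if h["fFileSignature"] != b"ABF ":
        raise FormatError(f"{path}: missing 'ABF ' signature (ABF v2 or not an ABF)")
    if h["nOperationMode"] != 5:
        raise FormatError(
            f"{path}: only episodic (mode 5) files supported, got mode {h['nOperationMode']}"
        )
    if h["nADCNumChannels"] != 1:
        raise FormatError(f"{path}: only single-channel files supported")

    unit_str = h["sADCUnits"].decode("ascii", errors="replace")
    channel_kind, clamp_mode = _units_to_kinds(unit_str)
    unit_scale = 1000.0 if unit_str.strip().strip("\x00").lower() == "na" else 1.0

    rate = 1e6 / h["fADCSampleInterval"]
    n_per_episode = h["lNumSamplesPerEpisode"]
    n_episodes = h["lActualEpisodes"]
    n_total = h["lActualAcqLength"]
    if n_total != n_per_episode * n_episodes:
        raise FormatError(
            f"{path}: acquisition length {n_total} does not equal "
            f"{n_episodes} episodes x {n_per_episode} samples"
        )

    data_start = h["lDataSectionPtr"] * _BLOCK
    if h["nDataFormat"] == 1:
        data = np.frombuffer(raw, dtype="<f4", count=n_total, offset=data_start)
        data = data.astype(float)
    elif h["nDataFormat"] == 0:
        ints = np.frombuffer(raw, dtype="<i2", count=n_total, offset=data_start)
        data = ints.astype(float) * (h["fADCRange"] / h["lADCResolution"])
    else:
        raise FormatError(f"{path}: unsupported data format {h['nDataFormat']}")
    data = data * h["fInstrumentScaleFactor"] + h["fInstrumentOffset"]
    data = data * unit_scale

    stimuli = _stimuli_from_epochs(h, rate, n_per_episode, n_episodes)
    if stimuli is None:
        log.warning("%s: no stimulus waveform table; sweeps carry no stimulus", path)
        stimuli = [None] * n_episodes

    sweeps = [
        Sweep(
            samples=data[i * n_per_episode : (i + 1) * n_per_episode],
            sampling_rate=rate,
            channel_kind=channel_kind,
            clamp_mode=clamp_mode,
            stimulus=stimuli[i],
        )
        for i in range(n_episodes)
    ]
    return SweepSet(sweeps=sweeps, metadata={"source": str(path)})


def _stimuli_from_epochs(h, rate, n_per_episode, n_episodes):
    if not h["nWaveformEnable"]:
        return None
    # ABF v1 holds the output at the holding level for 1/64 of the episode
    # before the first epoch starts.
    pre_hold = n_per_episode // 64
    t = pre_hold
    step = None
    for k in range(10):
        if h["nEpochType"][k] != _EPOCH_STEP:
            continue
        dur = h["lEpochInitDuration"][k]
        level, inc = h["fEpochInitLevel"][k], h["fEpochLevelInc"][k]
        if level != 0.0 or inc != 0.0:
            if step is not None:
                raise FormatError("multiple non-zero stimulus epochs not supported")
            step = (t, dur, level, inc)
        t += dur
    if step is None:
        return None
    onset, dur, level, inc = step
    return [
        StimulusEpoch(
            onset_time=onset / rate,
            duration=dur / rate,
            amplitude=level + i * inc,
        )
        for i in range(n_episodes)
    ]


def write_abf(sweepset: SweepSet, path: str | Path) -> Path:
    """Write a SweepSet as an episodic single-channel float32 ABF v1 file.

    All sweeps must share length. If every sweep carries a step stimulus
    with a common onset/duration, the DAC-A epoch table encodes it (a
    constant per-sweep amplitude increment is required, as in ABF episodic
    protocols); otherwise the waveform table is left disabled.
    """
    path = Path(path)
    n_per_episode = sweepset[0].samples.size
    if any(s.samples.size != n_per_episode for s in sweepset):
        raise FormatError("ABF episodic files need equal-length sweeps")
    rate = sweepset.sampling_rate
    n_episodes = len(sweepset)

    header = bytearray(_HEADER_BYTES)
    values = {
        "fFileSignature": b"ABF ",
        "fFileVersionNumber": 1.3,
        "nOperationMode": 5,
        "lActualAcqLength": n_per_episode * n_episodes,
        "lActualEpisodes": n_episodes,
        "lDataSectionPtr": _HEADER_BYTES // _BLOCK,
        "nDataFormat": 1,
        "nADCNumChannels": 1,
        "fADCSampleInterval": 1e6 / rate,
        "lNumSamplesPerEpisode": n_per_episode,
        "fADCRange": 10.0,
        "lADCResolution": 32768,
        "sADCUnits": (b"mV" if sweepset[0].channel_kind == VOLTAGE else b"pA").ljust(8),
        "fInstrumentScaleFactor": 1.0,
        "fInstrumentOffset": 0.0,
        "nWaveformEnable": 0,
        "nEpochType": [0] * 10,
        "fEpochInitLevel": [0.0] * 10,
        "fEpochLevelInc": [0.0] * 10,
        "lEpochInitDuration": [0] * 10,
        "lEpochDurationInc": [0] * 10,
    }

    stim = _encode_epochs(sweepset, rate, n_per_episode)
    if stim is not None:
        pre_dur, step_dur, level, inc = stim
        values["nWaveformEnable"] = 1
        values["nEpochType"] = [_EPOCH_STEP, _EPOCH_STEP] + [0] * 8
        values["fEpochInitLevel"] = [0.0, level] + [0.0] * 8
        values["fEpochLevelInc"] = [0.0, inc] + [0.0] * 8
        values["lEpochInitDuration"] = [pre_dur, step_dur] + [0] * 8
        values["lEpochDurationInc"] = [0] * 10

    for name, fmt, offset in _FIELDS:
        v = values[name]
        struct.pack_into("<" + fmt, header, offset, *(v if isinstance(v, list) else [v]))

    data = np.concatenate([s.samples for s in sweepset]).astype("<f4")
    path.write_bytes(bytes(header) + data.tobytes())
    return path


def _encode_epochs(sweepset, rate, n_per_episode):
    stims = [s.stimulus for s in sweepset]
    if any(st is None for st in stims):
        return None
    onset0, dur0 = stims[0].onset_time, stims[0].duration
    if any(abs(st.onset_time - onset0) > 1e-9 or abs(st.duration - dur0) > 1e-9 for st in stims):
        return None
    amps = [st.amplitude for st in stims]
    inc = amps[1] - amps[0] if len(amps) > 1 else 0.0
    if any(abs(amps[i] - (amps[0] + i * inc)) > 1e-6 for i in range(len(amps))):
        return None
    pre_hold = n_per_episode // 64
    onset_samples = int(round(onset0 * rate))
    pre_dur = onset_samples - pre_hold
    if pre_dur < 0:
        return None  # onset earlier than the ABF pre-episode hold allows
    step_dur = int(round(dur0 * rate))
    return pre_dur, step_dur, amps[0], inc
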