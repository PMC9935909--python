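"""Audio and label I/O for breathing-sound recordings.

Recordings are handled as mono waveforms in [-1, 1].  Whole-night audio is
nominally captured at 44.1 kHz and analysed at 11.025 kHz; :func:`downsample`
performs the anti-aliased rate reduction.  :func:`equalize_amplitude`
implements the optional amplitude-contrast reduction that keeps faint
breathing epochs comparable to loud ones.

Ground-truth / result cycle labels travel as CSV with columns
``start_s, end_s, state, snore, event``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d
from scipy.signal import firwin, resample_poly

__all__ = [
    "AudioSignal",
    "CycleRecord",
    "read_wav",
    "write_wav",
    "downsample",
    "equalize_amplitude",
    "read_labels",
    "write_labels",
    "smoothed_envelope",
]

ANALYSIS_FS = 11025.0

VALID_STATES = ("normal", "abnormal")
VALID_EVENTS = ("none", "hypopnea", "apnea")

# 16-bit PCM scaling: divide by 32768 so that -32768 maps to exactly -1.0
# (full-scale positive is then 32767/32768 = 0.999969...).
_PCM16_SCALE = 32768.0


@dataclass
class AudioSignal:
    """A sampled mono waveform.

    Parameters
    ----------
    samples
        Sample values, nominally within [-1, 1].
    fs
        Sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal expects a 1-D sample array")
        if len(self.samples) < 1:
            raise ValueError("AudioSignal must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioSignal samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.fs = float(self.fs)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class CycleRecord:
    """One manually- or machine-labelled breathing cycle."""

    start_s: float
    end_s: float
    state: str = "normal"
    snore: bool = False
    event: str = "none"

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"cycle end ({self.end_s}) must exceed start ({self.start_s})"
            )
        if self.state not in VALID_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.event not in VALID_EVENTS:
            raise ValueError(f"unknown event {self.event!r}")


def read_wav(path: str | os.PathLike) -> AudioSignal:
    """Read a PCM/float WAV file; multi-channel input keeps the first channel.

    Integer samples are scaled by the full-scale negative value (1/32768 for
    16-bit), so -full-scale maps to exactly -1.0.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        fs, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"{path} is not a readable WAV file: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"{path} contains no audio samples")
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data / _PCM16_SCALE
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32 / float64 WAV
        samples = data.astype(np.float64)
    return AudioSignal(samples, float(fs))


def write_wav(path: str | os.PathLike, signal: AudioSignal) -> None:
    """Write 16-bit PCM.  Samples are clipped to [-1, 1] before quantization."""
    x = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.clip(np.round(x * _PCM16_SCALE), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(round(signal.fs)), pcm)


def downsample(signal: AudioSignal, target_fs: float = ANALYSIS_FS) -> AudioSignal:
    """Anti-alias filter and decimate to ``target_fs``.

    The source rate must be an integer multiple of the target (44100 -> 11025
    is factor 4).  A linear-phase (delay-compensated) Kaiser FIR low-pass with
    its transition band just below the new Nyquist removes content that would
    alias, while tones up to ~0.91 x Nyquist pass essentially unattenuated.
    Decimation is polyphase, so cost stays linear in the input length.
    Output length is ``ceil(len/factor)``.
    """
    ratio = signal.fs / target_fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"sampling rate {signal.fs} Hz is not an integer multiple of "
            f"{target_fs} Hz; resample the recording first"
        )
    if factor == 1:
        return AudioSignal(signal.samples.copy(), target_fs)
    new_nyq = target_fs / 2.0
    numtaps = 100 * factor + 1
    h = firwin(numtaps, 0.95 * new_nyq, fs=signal.fs, window=("kaiser", 6.0))
    out = resample_poly(signal.samples, up=1, down=factor, window=h)
    return AudioSignal(out, target_fs)


def equalize_amplitude(
    signal: AudioSignal,
    window_s: float = 2.0,
    target_rms: float = 0.1,
    floor: float = 1e-4,
) -> AudioSignal:
    """Sliding-window RMS gain normalization ("amplitude contrast diminution").

    Each sample is scaled by ``target_rms / local_rms`` where the local RMS is
    measured over a centred window of ``window_s`` seconds.  Regions whose
    local RMS falls below ``floor`` are considered silent and left at unit
    gain, so pauses are not amplified into noise.  Output is hard-limited to
    [-1, 1].
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    w = max(1, int(round(window_s * signal.fs)))
    local_ms = uniform_filter1d(signal.samples**2, size=w, mode="nearest")
    local_rms = np.sqrt(np.maximum(local_ms, 0.0))
    gain = np.ones_like(local_rms)
    active = local_rms >= floor
    gain[active] = target_rms / local_rms[active]
    out = np.clip(signal.samples * gain, -1.0, 1.0)
    return AudioSignal(out, signal.fs)


def smoothed_envelope(signal: AudioSignal, smooth_s: float = 0.05) -> np.ndarray:
    """Rectified, moving-average-smoothed amplitude envelope."""
    w = max(1, int(round(smooth_s * signal.fs)))
    return uniform_filter1d(np.abs(signal.samples), size=w, mode="nearest")


def _records_to_frame(records: Sequence[CycleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [r.start_s for r in records],
            "end_s": [r.end_s for r in records],
            "state": [r.state for r in records],
            "snore": [int(r.snore) for r in records],
            "event": [r.event for r in records],
        }
    )


def write_labels(records: Sequence[CycleRecord], path: str | os.PathLike) -> None:
    """Write per-cycle labels as CSV (schema: start_s, end_s, state, snore, event)."""
    _validate_records(records)
    # %.17g keeps float round-trips exact
    _records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_labels(path: str | os.PathLike) -> list[CycleRecord]:
    """Read a per-cycle label CSV written by :func:`write_labels`."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such label file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"start_s", "end_s", "state", "snore", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label CSV missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            snore = int(row["snore"])
            if snore not in (0, 1):
                raise ValueError(f"snore flag must be 0/1, got {row['snore']}")
            records.append(
                CycleRecord(
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                    state=str(row["state"]),
                    snore=bool(snore),
                    event=str(row["event"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed label row {i}: {exc}") from exc
    _validate_records(records)
    return records


def _validate_records(records: Sequence[CycleRecord]) -> None:
    for prev, cur in zip(records, records[1:]):
        if cur.start_s < prev.end_s:
            raise ValueError(
                f"overlapping label intervals: [{prev.start_s}, {prev.end_s}) "
                f"and [{cur.start_s}, {cur.end_s})"
            )
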