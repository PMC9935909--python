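"""Synthetic whole-night breathing audio with ground-truth labels.

The generator emulates the acoustic structure the detection rules assume:

* quasi-periodic breathing cycles (~4 s period) whose inspiration and
  expiration are band-limited noise bursts with dominant energy in
  500-1500 Hz (the normal-breathing band);
* snoring as an inspiratory low-frequency component: a harmonic series at
  50-120 Hz plus sub-500 Hz noise (>= 70 % of power below 500 Hz);
* abnormal (obstructed) breathing as added sub-500 Hz plus 3500-5000 Hz
  noise across the whole active phase (>= 60 % of power outside
  500-3500 Hz);
* breathing stops: hypopnea gaps of 6-10 s, apnea gaps of 10-25 s, each
  preceded by an abnormal cycle;
* stationary white background noise at a configured breath-band SNR.

Component levels are fixed design choices (snoring is markedly louder than
quiet breathing; obstructed breathing louder still), chosen so truth labels
and audio stay mutually consistent at the default 20 dB SNR.  It does not
model room reverberation, body-movement artifacts, or physiological airflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfilt
from scipy.signal.windows import tukey

from .audio_io import AudioSignal, CycleRecord

__all__ = [
    "SyntheticConfig",
    "LabeledRecording",
    "gen_breath_burst",
    "gen_snore_component",
    "gen_abnormal_component",
    "gen_night",
]


@dataclass
class SyntheticConfig:
    """Study conditions of one simulated night."""

    fs: float = 11025.0
    n_cycles: int = 100
    cycle_s: float = 4.0          # mean full cycle length
    active_s: float = 2.5         # mean inspiration+expiration span
    intra_pause_s: float = 0.3    # short stop between inspiration and expiration
    jitter: float = 0.1           # CV of all timing draws
    snr_db: float = 20.0          # breath-band level over background
    p_snore: float = 0.2
    p_abnormal: float = 0.3
    p_apnea: float = 0.05
    p_hypopnea: float = 0.05
    seed: int = 0
    # amplitude design: RMS of each component while present
    breath_level: float = 0.05
    snore_level: float = 0.15
    abnormal_level: float = 0.12
    #: abnormal cycles also snore with this probability
    p_snore_given_abnormal: float = 0.8

    def __post_init__(self) -> None:
        for name in ("p_snore", "p_abnormal", "p_apnea", "p_hypopnea"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fs <= 0 or self.n_cycles <= 0:
            raise ValueError("fs and n_cycles must be positive")
        if self.cycle_s - self.active_s - self.intra_pause_s <= 0:
            raise ValueError(
                "infeasible timing: cycle_s must exceed active_s + intra_pause_s"
            )
        if self.p_apnea + self.p_hypopnea > 1:
            raise ValueError("p_apnea + p_hypopnea must not exceed 1")


@dataclass
class LabeledRecording:
    audio: AudioSignal
    truth: list[CycleRecord]


def _rms_scale(x: np.ndarray, level: float) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2)) if len(x) else 0.0
    return x * (level / rms) if rms > 0 else x


def gen_breath_burst(
    duration_s: float,
    band: tuple[float, float] = (500.0, 1500.0),
    level: float = 0.05,
    rng: np.random.Generator | None = None,
    fs: float = 11025.0,
) -> np.ndarray:
    """Band-pass Gaussian noise under a raised-cosine (Tukey) envelope,
    scaled to RMS ``level``; >= 80 % of spectral power stays in ``band``."""
    lo, hi = band
    if not 0 < lo < hi <= fs / 2:
        raise ValueError(f"invalid band {band} for fs={fs}")
    rng = rng or np.random.default_rng()
    n = int(round(duration_s * fs))
    if n == 0:
        return np.zeros(0)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfilt(sos, rng.standard_normal(n))
    x = x * tukey(n, alpha=0.25)
    return _rms_scale(x, level)


def gen_snore_component(
    duration_s: float,
    f0_hz: float = 90.0,
    level: float = 0.15,
    rng: np.random.Generator | None = None,
    fs: float = 11025.0,
) -> np.ndarray:
    """Low-frequency snore: harmonic series at ``f0_hz`` (1/h amplitude
    roll-off, harmonics up to 450 Hz) plus sub-500 Hz noise; >= 70 % of
    power below 500 Hz."""
    if not f0_hz < 250:
        raise ValueError("snore fundamental must be below 250 Hz")
    rng = rng or np.random.default_rng()
    n = int(round(duration_s * fs))
    if n == 0 or level == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    harm = np.zeros(n)
    h = 1
    while h * f0_hz <= 450.0:
        harm += (1.0 / h) * np.cos(2 * np.pi * h * f0_hz * t + rng.uniform(0, 2 * np.pi))
        h += 1
    sos = butter(4, 450.0, btype="lowpass", fs=fs, output="sos")
    noise = sosfilt(sos, rng.standard_normal(n))
    # ~80 % of component power in the harmonic train, 20 % in shaped noise
    x = _rms_scale(harm, np.sqrt(0.8)) + _rms_scale(noise, np.sqrt(0.2))
    x = x * tukey(n, alpha=0.25)
    return _rms_scale(x, level)


def gen_abnormal_component(
    duration_s: float,
    level: float = 0.12,
    rng: np.random.Generator | None = None,
    fs: float = 11025.0,
) -> np.ndarray:
    """Obstructed-breathing noise: sub-500 Hz plus 3500-5000 Hz bands;
    >= 60 % of power outside the 500-3500 Hz mid range."""
    if fs / 2 <= 3500:
        raise ValueError("sampling rate too low for the high abnormal band")
    rng = rng or np.random.default_rng()
    n = int(round(duration_s * fs))
    if n == 0:
        return np.zeros(0)
    sos_lo = butter(4, 450.0, btype="lowpass", fs=fs, output="sos")
    sos_hi = butter(4, [3500.0, 5000.0], btype="bandpass", fs=fs, output="sos")
    low = sosfilt(sos_lo, rng.standard_normal(n))
    high = sosfilt(sos_hi, rng.standard_normal(n))
    # high-band dominant: obstruction turbulence carries most of the energy
    x = _rms_scale(high, np.sqrt(0.75)) + _rms_scale(low, np.sqrt(0.25))
    x = x * tukey(n, alpha=0.25)
    return _rms_scale(x, level)


def _jittered(rng: np.random.Generator, mean: float, cv: float, lo: float) -> float:
    return max(lo, mean * (1.0 + cv * rng.standard_normal()))


def gen_night(config: SyntheticConfig | None = None) -> LabeledRecording:
    """Assemble a labelled night of breathing audio.

    Cycle layout: inspiration burst, short intra-cycle stop, expiration
    burst, then the inter-cycle gap.  With probability ``p_apnea`` /
    ``p_hypopnea`` the gap becomes an apnea (uniform 10-25 s) or hypopnea
    (uniform 6-10 s) breathing stop and the preceding cycle turns abnormal.
    Identical seeds produce bit-identical output.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    normal_gap_mean = cfg.cycle_s - cfg.active_s - cfg.intra_pause_s

    pieces: list[np.ndarray] = [np.zeros(int(round(1.0 * fs)))]  # lead-in
    truth: list[CycleRecord] = []
    t_cursor = pieces[0].size / fs

    for _ in range(cfg.n_cycles):
        insp_s = _jittered(rng, cfg.active_s / 2, cfg.jitter, 0.5)
        exp_s = _jittered(rng, cfg.active_s / 2, cfg.jitter, 0.5)
        intra_s = _jittered(rng, cfg.intra_pause_s, cfg.jitter, 0.1)

        u = rng.uniform()
        if u < cfg.p_apnea:
            event, gap_s = "apnea", rng.uniform(10.0, 25.0)
        elif u < cfg.p_apnea + cfg.p_hypopnea:
            event, gap_s = "hypopnea", rng.uniform(6.0, 10.0)
        else:
            event, gap_s = "none", _jittered(rng, normal_gap_mean, cfg.jitter, 0.6)

        abnormal = event != "none" or rng.uniform() < cfg.p_abnormal
        if abnormal:
            snore = rng.uniform() < cfg.p_snore_given_abnormal
        else:
            snore = rng.uniform() < cfg.p_snore

        insp = gen_breath_burst(insp_s, level=cfg.breath_level, rng=rng, fs=fs)
        exp = gen_breath_burst(exp_s, level=cfg.breath_level, rng=rng, fs=fs)
        intra = np.zeros(int(round(intra_s * fs)))
        if snore:
            f0 = rng.uniform(50.0, 120.0)
            insp = insp + gen_snore_component(
                len(insp) / fs, f0_hz=f0, level=cfg.snore_level, rng=rng, fs=fs
            )
        active = np.concatenate([insp, intra, exp])
        if abnormal:
            active = active + gen_abnormal_component(
                len(active) / fs, level=cfg.abnormal_level, rng=rng, fs=fs
            )

        start_s = t_cursor
        end_s = start_s + len(active) / fs
        truth.append(
            CycleRecord(
                start_s=start_s,
                end_s=end_s,
                state="abnormal" if abnormal else "normal",
                snore=snore,
                event=event,
            )
        )
        gap = np.zeros(int(round(gap_s * fs)))
        pieces.extend([active, gap])
        t_cursor = end_s + len(gap) / fs

    audio = np.concatenate(pieces)
    bg_rms = cfg.breath_level * 10.0 ** (-cfg.snr_db / 20.0)
    audio = audio + bg_rms * rng.standard_normal(len(audio))
    audio = np.clip(audio, -1.0, 1.0)
    return LabeledRecording(AudioSignal(audio, fs), truth)
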