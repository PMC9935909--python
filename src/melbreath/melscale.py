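"""Mel-scale spectral-occupancy features for breathing cycles.

Per segmented cycle the pipeline is: rectangular 1024-sample frames with 50 %
overlap -> order-32 Yule-Walker autoregressive power spectral density ->
20-filter triangular Mel bank -> log10 band energies ``f[i, j]`` -> per-frame
argmax label (the *Mel-scale label*, MsL) -> per-label frame counts
(``N_MsL``), the cycle's spectral-occupancy histogram.

The Mel map is anchored so Mel(1000 Hz) = 1000 mel::

    Mel(f) = 1000 * log10(1 + f/700) / log10(1 + 1000/700)

AR spectra (rather than raw periodogram energies) keep per-frame band
energies smooth at the short 93 ms frame length, which stabilises the argmax
label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "FrameGrid",
    "PsdFrame",
    "MelFilterBank",
    "MelFeatureMatrix",
    "MslSequence",
    "MslHistogram",
    "MelConfig",
    "hz_to_mel",
    "mel_to_hz",
    "frame_signal",
    "yule_walker",
    "ar_psd",
    "build_filterbank",
    "mel_features",
    "extract_msl",
    "msl_histogram",
]

_MEL_DENOM = np.log10(1.0 + 1000.0 / 700.0)


def hz_to_mel(f):
    """Mel(f) = 1000 * lg(1 + f/700) / lg(1 + 1000/700); Mel(1000) = 1000."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    out = 1000.0 * np.log10(1.0 + f / 700.0) / _MEL_DENOM
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m):
    """Exact inverse of :func:`hz_to_mel`."""
    m = np.asarray(m, dtype=np.float64)
    if np.any(m < 0):
        raise ValueError("mel value must be nonnegative")
    out = 700.0 * (np.power(10.0, m * _MEL_DENOM / 1000.0) - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FrameGrid:
    """Rectangular analysis frames: ``hop`` is half the window (50 % overlap)."""

    win_len: int = 1024
    hop: int = 512
    n_frames: int = 1

    def __post_init__(self) -> None:
        if self.hop * 2 != self.win_len:
            raise ValueError("hop must be half the window length")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


@dataclass
class PsdFrame:
    """One-sided power spectral density on a uniform [0, fs/2] grid."""

    freqs: np.ndarray
    psd: np.ndarray


@dataclass
class MelFilterBank:
    """Triangular filters with edges uniform on the Mel scale.

    ``edges`` has ``n_filters + 2`` entries (Hz, snapped to the analysis
    grid); filter ``m`` (1-based) rises from ``edges[m-1]`` to peak 1 at
    ``edges[m]`` and falls to ``edges[m+1]`` — so each filter's peak is the
    left edge (the "starting") of the next one.
    """

    n_filters: int
    edges: np.ndarray
    weights: np.ndarray
    freqs: np.ndarray

    def peak_freqs(self) -> np.ndarray:
        return self.edges[1:-1]


@dataclass
class MelFeatureMatrix:
    """log10 Mel-band energies, shape (n_filters, n_frames)."""

    values: np.ndarray
    grid: FrameGrid


@dataclass
class MslSequence:
    """Per-frame argmax filter labels, 1-based."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) and (self.labels.min() < 1):
            raise ValueError("MsL labels are 1-based")


@dataclass
class MslHistogram:
    """Frame counts per Mel-scale label; ``counts[i-1]`` is N_MsL for label i."""

    counts: np.ndarray
    total: int

    def count(self, label: int) -> int:
        return int(self.counts[label - 1])


@dataclass
class MelConfig:
    """Tunable parameters of the feature extractor."""

    win_len: int = 1024
    hop: int = 512
    order: int = 32
    n_filters: int = 20
    f_low: float = 0.0
    f_high: float | None = None  # defaults to fs/2
    n_freq: int = 513
    eps: float = 1e-12

    @classmethod
    def from_yaml(cls, path) -> "MelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw.get("mel", raw))


def frame_signal(cycle_samples: np.ndarray, win_len: int = 1024, hop: int | None = None) -> np.ndarray:
    """Split into rectangular (untapered) frames, 50 % overlap by default.

    Returns an array of shape (n_frames, win_len) with
    ``n_frames = floor((len - win_len)/hop) + 1``; the trailing remainder
    (< hop samples) is dropped.
    """
    x = np.asarray(cycle_samples, dtype=np.float64)
    if hop is None:
        hop = win_len // 2
    if len(x) < win_len:
        raise ValueError(
            f"cycle of {len(x)} samples is shorter than one analysis window "
            f"({win_len}); zero-pad the cycle if analysis is still wanted"
        )
    n_frames = (len(x) - win_len) // hop + 1
    view = np.lib.stride_tricks.sliding_window_view(x, win_len)[::hop]
    return np.ascontiguousarray(view[:n_frames])


def _biased_autocorr(frames: np.ndarray, order: int) -> np.ndarray:
    """Biased (1/n) autocorrelation lags 0..order for each row."""
    n = frames.shape[-1]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frames, nfft, axis=-1)
    acov = np.fft.irfft(spec * np.conj(spec), nfft, axis=-1)[..., : order + 1]
    return acov.real / n


def _levinson(r: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Levinson-Durbin recursion on autocorrelation lags ``r[0..p]``.

    Returns AR polynomial coefficients ``a[1..p]`` (denominator
    ``1 + sum a_k z^-k``), the prediction-error variance, and the
    reflection-coefficient sequence.
    """
    p = len(r) - 1
    a = np.zeros(p)
    ks = np.zeros(p)
    err = r[0]
    for m in range(p):
        acc = r[m + 1] + np.dot(a[:m], r[m:0:-1])
        k = -acc / err
        ks[m] = k
        a[: m + 1] = np.concatenate((a[:m], [0.0])) + k * np.concatenate(
            (a[:m][::-1], [1.0])
        )
        err *= 1.0 - k * k
        if err <= 0:
            err = np.finfo(float).tiny
    return a, float(err), ks


def yule_walker(frame: np.ndarray, order: int = 32) -> tuple[np.ndarray, float, np.ndarray]:
    """AR model fit by the Yule-Walker normal equations.

    Uses the biased autocorrelation estimate (divides lag sums by the frame
    length), which guarantees a stable all-pole model.  Returns
    ``(a, sigma2, reflection)`` with the denominator convention
    ``A(z) = 1 + sum_k a_k z^-k``.
    """
    x = np.asarray(frame, dtype=np.float64)
    if len(x) <= order:
        raise ValueError(f"frame length {len(x)} must exceed AR order {order}")
    r = _biased_autocorr(x[None, :], order)[0]
    if r[0] <= 0 or not np.isfinite(r[0]):
        raise ZeroDivisionError("frame has no energy; no AR model exists")
    return _levinson(r)


def _ar_transfer_matrix(freqs: np.ndarray, order: int, fs: float) -> np.ndarray:
    k = np.arange(1, order + 1)
    return np.exp(-2j * np.pi * np.outer(freqs, k) / fs)


def ar_psd(
    frame: np.ndarray,
    order: int = 32,
    n_freq: int = 513,
    fs: float = 11025.0,
) -> PsdFrame:
    """One-sided Yule-Walker AR power spectral density.

    ``psd(f) = sigma2 / fs / |1 + sum_k a_k exp(-2 pi i f k / fs)|^2`` on
    ``n_freq`` uniform frequencies spanning [0, fs/2].  An all-zero frame has
    no AR model; it yields a flat epsilon-level PSD with a warning.
    """
    freqs = np.linspace(0.0, fs / 2.0, n_freq)
    try:
        a, sigma2, _ = yule_walker(frame, order)
    except ZeroDivisionError:
        warnings.warn("zero-energy frame: returning flat epsilon PSD", stacklevel=2)
        return PsdFrame(freqs, np.full(n_freq, 1e-20))
    denom = np.abs(1.0 + _ar_transfer_matrix(freqs, order, fs) @ a) ** 2
    return PsdFrame(freqs, sigma2 / fs / denom)


def build_filterbank(
    n_filters: int = 20,
    f_low: float = 0.0,
    f_high: float = 5512.5,
    freqs: np.ndarray | None = None,
) -> MelFilterBank:
    """Triangular Mel bank with edges uniform on the Mel scale.

    Edge frequencies are snapped to the supplied analysis grid so each
    triangle attains its peak value of exactly 1 at a grid point.  A grid too
    coarse to separate adjacent edges raises.
    """
    if not (0 <= f_low < f_high):
        raise ValueError("need 0 <= f_low < f_high")
    if n_filters < 1:
        raise ValueError("need at least one filter")
    if freqs is None:
        freqs = np.linspace(f_low, f_high, 513)
    freqs = np.asarray(freqs, dtype=np.float64)
    mel_edges = np.linspace(hz_to_mel(f_low), hz_to_mel(f_high), n_filters + 2)
    hz_edges = mel_to_hz(mel_edges)
    idx = np.clip(np.searchsorted(freqs, hz_edges), 0, len(freqs) - 1)
    for j in range(len(idx)):  # snap to the nearer neighbour
        i = idx[j]
        if i > 0 and abs(freqs[i - 1] - hz_edges[j]) < abs(freqs[i] - hz_edges[j]):
            idx[j] = i - 1
    if np.any(np.diff(idx) < 1):
        raise ValueError(
            "frequency grid too coarse to resolve the narrowest Mel filter"
        )
    edges = freqs[idx]
    weights = np.zeros((n_filters, len(freqs)))
    for m in range(n_filters):
        lo, mid, hi = edges[m], edges[m + 1], edges[m + 2]
        rise = (freqs >= lo) & (freqs <= mid)
        fall = (freqs > mid) & (freqs <= hi)
        weights[m, rise] = (freqs[rise] - lo) / (mid - lo)
        weights[m, fall] = (hi - freqs[fall]) / (hi - mid)
    return MelFilterBank(n_filters, edges, weights, freqs)


def mel_features(
    cycle_samples: np.ndarray,
    fs: float,
    config: MelConfig | None = None,
    bank: MelFilterBank | None = None,
) -> MelFeatureMatrix:
    """log10 Mel-band energy matrix ``f[i, j]`` for one breathing cycle.

    Per frame: AR PSD -> bank-weighted band energies
    ``E_i = sum_k w[i, k] psd[k]`` -> ``log10(max(E_i, eps))``.
    """
    cfg = config or MelConfig()
    f_high = cfg.f_high if cfg.f_high is not None else fs / 2.0
    freqs = np.linspace(0.0, fs / 2.0, cfg.n_freq)
    if bank is None:
        bank = build_filterbank(cfg.n_filters, cfg.f_low, f_high, freqs)
    frames = frame_signal(cycle_samples, cfg.win_len, cfg.hop)
    n_frames = frames.shape[0]

    acov = _biased_autocorr(frames, cfg.order)
    tf = _ar_transfer_matrix(freqs, cfg.order, fs)
    psds = np.empty((n_frames, cfg.n_freq))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(n_frames):
            r = acov[j]
            if r[0] <= 0 or not np.isfinite(r[0]):
                psds[j] = 1e-20
                continue
            a, sigma2, _ = _levinson(r)
            psds[j] = sigma2 / fs / (np.abs(1.0 + tf @ a) ** 2)
    energies = bank.weights @ psds.T  # (n_filters, n_frames)
    values = np.log10(np.maximum(energies, cfg.eps))
    grid = FrameGrid(cfg.win_len, cfg.hop, n_frames)
    return MelFeatureMatrix(values, grid)


def extract_msl(features: MelFeatureMatrix) -> MslSequence:
    """Per-frame argmax label (1-based); ties break to the lowest label."""
    return MslSequence(np.argmax(features.values, axis=0) + 1)


def msl_histogram(seq: MslSequence, n_labels: int = 20) -> MslHistogram:
    """Count how many frames carry each label (the N_MsL histogram)."""
    if len(seq.labels) == 0:
        raise ValueError("cannot histogram an empty label sequence")
    counts = np.bincount(seq.labels, minlength=n_labels + 1)[1:]
    if len(counts) > n_labels:
        raise ValueError("label outside 1..n_labels")
    return MslHistogram(counts, int(len(seq.labels)))
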