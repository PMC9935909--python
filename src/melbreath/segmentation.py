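"""Breathing-cycle segmentation by characteristic-moment-waveform analysis.

Two waveforms drive the segmentation:

* **TCW** ``c(t, delta)`` — the sliding-window variance of the audio over a
  short window of half-width ``delta`` (~0.1 s, about a tenth of one
  inspiration/expiration phase).  It is large inside breath bursts and near
  zero in pauses.

* **CMW** ``I(t, delta, l)`` — the second spatial moment of the TCW over a
  longer window of half-width ``l`` (~half a breathing cycle, 1.5-3 s):
  ``I(t) = integral_{t-l}^{t+l} (tau - t)^2 c(tau) dtau``.
  Because the quadratic weight suppresses mass near the centre, the CMW is
  *minimal* when ``t`` sits on a breath burst and *maximal* mid-pause, which
  makes its local maxima natural cycle-boundary candidates.

Boundaries are then snapped to the nearest TCW valley between adjacent TCW
peaks, and spuriously segmented near-silent "cycles" are merged back into
their surrounding pause using an amplitude threshold.

For recordings longer than ten minutes the waveforms are evaluated on a
10 ms-hop grid instead of every sample; the discrete sums are exact at the
evaluated points for the TCW and Riemann-approximated for the CMW.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, find_peaks

from .audio_io import AudioSignal, smoothed_envelope

__all__ = [
    "MomentWaveforms",
    "BreathingCycle",
    "SegmentationResult",
    "compute_tcw",
    "compute_cmw",
    "moment_waveforms",
    "find_cycle_boundaries",
    "merge_weak_pauses",
    "refine_active_phases",
    "segment",
]

#: default short-window half-width (s): ~1/10 of one breath phase
DEFAULT_DELTA_S = 0.1
#: default moment-window half-width (s): about half a breathing cycle
DEFAULT_L_S = 2.0
#: shortest plausible breathing cycle (s); minimum extrema separation
DEFAULT_MIN_CYCLE_S = 1.5
#: recordings longer than this are processed on a decimated grid
MAX_FULL_RATE_S = 600.0
#: hop of the decimated evaluation grid (s)
GRID_HOP_S = 0.01


@dataclass
class MomentWaveforms:
    """TCW and CMW evaluated on a common time grid.

    ``fs`` is the rate of the *grid* (equal to the signal rate when computed
    per sample); ``tcw``/``cmw`` are nonnegative by construction.
    """

    tcw: np.ndarray
    cmw: np.ndarray
    delta_s: float
    l_s: float
    fs: float


@dataclass(frozen=True)
class BreathingCycle:
    """Half-open sample-index interval [start_idx, end_idx) at rate ``fs``."""

    start_idx: int
    end_idx: int
    fs: float

    def __post_init__(self) -> None:
        if not self.end_idx > self.start_idx:
            raise ValueError("cycle end must exceed start")

    @property
    def start_s(self) -> float:
        return self.start_idx / self.fs

    @property
    def end_s(self) -> float:
        return self.end_idx / self.fs

    @property
    def duration_s(self) -> float:
        return (self.end_idx - self.start_idx) / self.fs


@dataclass
class SegmentationResult:
    """Cycles, their active phases, and the pauses between active phases.

    ``active_phases[i]`` is the (start_idx, end_idx) span of detectable
    breathing inside ``cycles[i]``; ``pauses`` are the gaps between
    consecutive active phases plus the recording edges.  ``extrema`` keeps
    the C_min / T_max / boundary index sequences for diagnostics.  All
    indices refer to the grid at rate ``fs``.
    """

    cycles: list[BreathingCycle]
    pauses: list[tuple[int, int]]
    active_phases: list[tuple[int, int]]
    extrema: dict
    fs: float
    n_samples: int

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def pause_after(self, i: int) -> tuple[int, int] | None:
        """The pause that starts at cycle i's active-phase end, if any."""
        end = self.active_phases[i][1]
        for p in self.pauses:
            if p[0] == end:
                return p
        return None


def _tcw_at(y: np.ndarray, fs: float, d: int, idx: np.ndarray) -> np.ndarray:
    """Windowed-variance TCW at sample indices ``idx`` via cumulative sums.

    The window integral uses the exact (possibly edge-truncated) window
    duration W = n/fs in place of the nominal 2*delta, so a constant signal
    yields exactly zero.
    """
    cs1 = np.concatenate(([0.0], np.cumsum(y)))
    cs2 = np.concatenate(([0.0], np.cumsum(y * y)))
    a = np.maximum(idx - d, 0)
    b = np.minimum(idx + d, len(y) - 1)
    cnt = b - a + 1
    s1 = cs1[b + 1] - cs1[a]
    s2 = cs2[b + 1] - cs2[a]
    dt = 1.0 / fs
    w = cnt * dt
    ybar = s1 / cnt
    return np.maximum(s2 * dt - w * ybar * ybar, 0.0)


def compute_tcw(signal: AudioSignal, delta_s: float = DEFAULT_DELTA_S) -> np.ndarray:
    """Time characteristic waveform: sliding variance over +-``delta_s``.

    Edge windows are truncated.  O(N) via running sums.
    """
    d = int(round(delta_s * signal.fs))
    if 2 * d + 1 > len(signal):
        raise ValueError(
            f"delta window ({2 * d + 1} samples) exceeds signal length {len(signal)}"
        )
    return _tcw_at(signal.samples, signal.fs, d, np.arange(len(signal)))


def compute_cmw(tcw: np.ndarray, l_s: float, fs: float) -> np.ndarray:
    """Characteristic moment waveform: quadratic moment of the TCW.

    ``I[t] = sum_{|k| <= L} (k/fs)^2 * tcw[t+k] / fs`` with L = round(l_s*fs),
    edge windows truncated.  Computed as an FFT convolution with the
    quadratic kernel, which is algebraically identical to running-moment
    sums but free of the large-moment cancellation they suffer at late t.
    """
    tcw = np.asarray(tcw, dtype=np.float64)
    L = int(round(l_s * fs))
    if 2 * L + 1 > len(tcw):
        raise ValueError(
            f"moment window ({2 * L + 1} samples) exceeds TCW length {len(tcw)}"
        )
    dt = 1.0 / fs
    k = np.arange(-L, L + 1, dtype=np.float64)
    kernel = (k * dt) ** 2 * dt
    out = fftconvolve(tcw, kernel, mode="same")
    return np.maximum(out, 0.0)


def moment_waveforms(
    signal: AudioSignal,
    delta_s: float = DEFAULT_DELTA_S,
    l_s: float = DEFAULT_L_S,
    max_full_rate_s: float = MAX_FULL_RATE_S,
    grid_hop_s: float = GRID_HOP_S,
) -> MomentWaveforms:
    """Compute TCW and CMW, decimating the evaluation grid for long inputs."""
    if signal.duration_s <= max_full_rate_s:
        tcw = compute_tcw(signal, delta_s)
        cmw = compute_cmw(tcw, l_s, signal.fs)
        return MomentWaveforms(tcw, cmw, delta_s, l_s, signal.fs)
    hop = max(1, int(round(grid_hop_s * signal.fs)))
    grid_fs = signal.fs / hop
    idx = np.arange(0, len(signal), hop)
    d = int(round(delta_s * signal.fs))
    tcw = _tcw_at(signal.samples, signal.fs, d, idx)
    cmw = compute_cmw(tcw, l_s, grid_fs)
    return MomentWaveforms(tcw, cmw, delta_s, l_s, grid_fs)


def _active_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as half-open (start, end)."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _pauses_from_actives(
    actives: list[tuple[int, int]], n: int
) -> list[tuple[int, int]]:
    pauses: list[tuple[int, int]] = []
    prev_end = 0
    for a, b in actives:
        if a > prev_end:
            pauses.append((prev_end, a))
        prev_end = b
    if prev_end < n:
        pauses.append((prev_end, n))
    return pauses


def find_cycle_boundaries(
    mw: MomentWaveforms,
    min_cycle_s: float = DEFAULT_MIN_CYCLE_S,
    active_tcw_frac: float = 0.05,
) -> SegmentationResult:
    """Segment the grid into breathing cycles from CMW/TCW extrema.

    1. local minima of the CMW (minimum separation ``min_cycle_s``) give the
       breath-centred sequence C_min;
    2. the TCW maximum inside a +-``l_s`` window around each C_min point
       gives the breath-peak sequence T_max;
    3. CMW local maxima are boundary candidates, each shifted into the TCW
       valley between the adjacent T_max points: the midpoint of the longest
       below-threshold TCW run there (the true inter-breath gap), or the
       literal argmin when the TCW never drops below threshold.

    Active phases are the TCW runs above ``active_tcw_frac`` times the median
    T_max peak value (later refined against the raw envelope by
    :func:`refine_active_phases`).
    """
    n = len(mw.cmw)
    dist = max(1, int(round(min_cycle_s * mw.fs)))
    l_n = max(1, int(round(mw.l_s * mw.fs)))

    c_min, _ = find_peaks(-mw.cmw, distance=dist)
    t_max_set: set[int] = set()
    for c in c_min:
        a = max(0, c - l_n)
        b = min(n, c + l_n + 1)
        t_max_set.add(a + int(np.argmax(mw.tcw[a:b])))
    t_max = np.array(sorted(t_max_set), dtype=int)

    candidates, _ = find_peaks(mw.cmw, distance=dist)

    # reference breath-peak level and the silence threshold derived from it
    if len(t_max):
        peak_ref = float(np.median(mw.tcw[t_max]))
    else:
        peak_ref = float(np.max(mw.tcw)) if n else 0.0
    theta = active_tcw_frac * peak_ref

    def _valley(lo: int, hi: int) -> int:
        low_runs = _active_runs(mw.tcw[lo : hi + 1] < theta)
        if low_runs:
            a, b = max(low_runs, key=lambda r: r[1] - r[0])
            return lo + (a + b) // 2
        return lo + int(np.argmin(mw.tcw[lo : hi + 1]))

    boundaries: set[int] = set()
    for cand in candidates:
        j = np.searchsorted(t_max, cand)
        if 0 < j < len(t_max):
            lo, hi = t_max[j - 1], t_max[j]
        elif j == 0 and len(t_max):
            lo, hi = 0, t_max[0]
        elif len(t_max):
            lo, hi = t_max[-1], n - 1
        else:
            lo, hi = max(0, cand - l_n), min(n - 1, cand + l_n)
        boundaries.add(_valley(lo, hi) if hi > lo else cand)
    bnd = np.array(sorted(boundaries), dtype=int)

    if len(bnd) < 2:
        warnings.warn(
            "fewer than 2 cycle boundaries found; returning a single cycle",
            stacklevel=2,
        )
        cycles = [BreathingCycle(0, n, mw.fs)]
    else:
        edges = [0, *bnd.tolist(), n]
        # drop edges closer than min_cycle_s to keep every cycle long enough
        kept = [edges[0]]
        for e in edges[1:]:
            if e - kept[-1] >= dist:
                kept.append(e)
        if kept[-1] != n:
            if n - kept[-1] < dist and len(kept) > 1:
                kept[-1] = n
            else:
                kept.append(n)
        cycles = [
            BreathingCycle(a, b, mw.fs) for a, b in zip(kept, kept[1:]) if b > a
        ]

    # provisional active phases from the TCW level
    actives_all = _active_runs(mw.tcw > theta)
    active_phases = []
    for cyc in cycles:
        inside = [
            (max(a, cyc.start_idx), min(b, cyc.end_idx))
            for a, b in actives_all
            if a < cyc.end_idx and b > cyc.start_idx
        ]
        if inside:
            active_phases.append((inside[0][0], inside[-1][1]))
        else:
            active_phases.append((cyc.start_idx, cyc.end_idx))

    pauses = _pauses_from_actives(active_phases, n)
    return SegmentationResult(
        cycles=cycles,
        pauses=pauses,
        active_phases=active_phases,
        extrema={"c_min": c_min, "t_max": t_max, "boundaries": bnd},
        fs=mw.fs,
        n_samples=n,
    )


def _cycle_peak_envelopes(
    result: SegmentationResult, signal: AudioSignal, smooth_s: float = 0.05
) -> np.ndarray:
    env = smoothed_envelope(signal, smooth_s)
    scale = signal.fs / result.fs
    peaks = []
    for a, b in result.active_phases:
        ia = int(round(a * scale))
        ib = max(ia + 1, int(round(b * scale)))
        peaks.append(float(np.max(env[ia : min(ib, len(env))])))
    return np.asarray(peaks)


def merge_weak_pauses(
    result: SegmentationResult,
    signal: AudioSignal,
    alpha: float = 0.2,
    min_pause_s: float = 0.35,
) -> SegmentationResult:
    """Combine incorrectly segmented pauses back into real cycles.

    Two complementary rules, both driven by the smoothed signal envelope:

    * **amplitude** — a "cycle" whose peak envelope falls below ``alpha``
      times the mean per-cycle peak amplitude is no real breath; it is
      absorbed into the surrounding pause (this removes noise blips inside
      long apnea gaps);
    * **pause length** — adjacent cycles whose separating envelope gap is
      shorter than ``min_pause_s`` were split at the brief stop *within* a
      breath (between inspiration and expiration), not at a true
      inter-cycle pause; they are recombined into one cycle.

    ``alpha = 0`` disables the whole merge stage and returns the input
    unchanged.
    """
    if alpha <= 0 or not result.cycles:
        return result
    # measure active phases against the raw envelope before judging gaps
    result = refine_active_phases(result, signal)
    peaks = _cycle_peak_envelopes(result, signal)
    mean_peak = float(np.mean(peaks))
    keep = peaks >= alpha * mean_peak
    cycles: list[BreathingCycle] = []
    actives: list[tuple[int, int]] = []
    for k, cyc, act in zip(keep, result.cycles, result.active_phases):
        if not k:
            continue
        gap_s = (act[0] - actives[-1][1]) / result.fs if cycles else np.inf
        if gap_s < min_pause_s:
            prev = cycles[-1]
            cycles[-1] = BreathingCycle(prev.start_idx, cyc.end_idx, result.fs)
            actives[-1] = (actives[-1][0], act[1])
        else:
            cycles.append(cyc)
            actives.append(act)
    pauses = _pauses_from_actives(actives, result.n_samples)
    return SegmentationResult(
        cycles=cycles,
        pauses=pauses,
        active_phases=actives,
        extrema=result.extrema,
        fs=result.fs,
        n_samples=result.n_samples,
    )


def refine_active_phases(
    result: SegmentationResult,
    signal: AudioSignal,
    frac: float = 0.1,
    smooth_s: float = 0.05,
) -> SegmentationResult:
    """Re-measure each cycle's active phase against the raw envelope.

    The active span becomes the region of the cycle where the smoothed
    envelope exceeds ``frac`` times *that cycle's own* peak amplitude, so
    faint breaths keep their full phase extent.  This tightens pause
    (breathing-stop) durations to the waveform itself, which matters for
    the 6 s / 10 s hypopnea/apnea boundaries.
    """
    if not result.cycles:
        return result
    env = smoothed_envelope(signal, smooth_s)
    peaks = _cycle_peak_envelopes(result, signal, smooth_s)
    scale = signal.fs / result.fs
    actives = []
    for cyc, peak in zip(result.cycles, peaks):
        theta = frac * peak
        ia = int(round(cyc.start_idx * scale))
        ib = min(int(round(cyc.end_idx * scale)), len(env))
        above = np.flatnonzero(env[ia:ib] > theta)
        if len(above):
            a_sig, b_sig = ia + above[0], ia + above[-1] + 1
            a = max(cyc.start_idx, int(round(a_sig / scale)))
            b = min(cyc.end_idx, max(a + 1, int(round(b_sig / scale))))
            actives.append((a, b))
        else:
            actives.append((cyc.start_idx, cyc.end_idx))
    pauses = _pauses_from_actives(actives, result.n_samples)
    return SegmentationResult(
        cycles=result.cycles,
        pauses=pauses,
        active_phases=actives,
        extrema=result.extrema,
        fs=result.fs,
        n_samples=result.n_samples,
    )


def segment(
    signal: AudioSignal,
    delta_s: float = DEFAULT_DELTA_S,
    l_s: float = DEFAULT_L_S,
    min_cycle_s: float = DEFAULT_MIN_CYCLE_S,
    alpha: float = 0.2,
) -> SegmentationResult:
    """Full segmentation pipeline: waveforms -> boundaries -> merge -> refine."""
    mw = moment_waveforms(signal, delta_s=delta_s, l_s=l_s)
    result = find_cycle_boundaries(mw, min_cycle_s=min_cycle_s)
    result = merge_weak_pauses(result, signal, alpha=alpha)
    return refine_active_phases(result, signal)
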