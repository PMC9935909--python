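"""Rule-based breathing-state detection from Mel-scale label histograms.

Three disjoint label sets partition the spectral axis:

* **FL** (low, default {2}) — snore energy (fundamental + harmonics below
  ~500 Hz);
* **FM** (middle, default {4..7}) — normal breathing energy (~500-1500 Hz);
* **FH** (high, default {15..17}) — abnormal breathing energy.

A set's symbol is 1 when *any* of its labels occupies strictly more frames
than its threshold; thresholds are fractions (40 % for FM/FH, 20 % for FL)
of a reference active-phase frame count of ~50 (one ~2.5 s breath at a
1024/512 frame grid).  A cycle is *abnormal* iff FH fires; it *snores* iff
FL fires.  Breathing stops between active phases longer than 10 s are apnea
events, 6-10 s hypopnea.  The night-level quality index is
``R_Sleep = T_Normal / T_Monitoring``.

The default sets suit the original headset recordings; for other data (or
the synthetic generator) :func:`label_sets_from_bank` derives equivalent
sets from the filter-bank geometry.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .melscale import MelFilterBank, MslHistogram
from .segmentation import SegmentationResult

__all__ = [
    "MslSets",
    "ThresholdConfig",
    "CycleLabel",
    "MonitoringReport",
    "symbolize",
    "classify_cycle",
    "classify_pause",
    "compute_rsleep",
    "summarize",
    "score_against_truth",
    "label_sets_from_bank",
]

APNEA_MIN_S = 10.0
HYPOPNEA_MIN_S = 6.0


@dataclass(frozen=True)
class MslSets:
    """Low/middle/high-frequency Mel-scale label sets (pairwise disjoint)."""

    FL: frozenset = frozenset({2})
    FM: frozenset = frozenset({4, 5, 6, 7})
    FH: frozenset = frozenset({15, 16, 17})

    def __post_init__(self) -> None:
        fl, fm, fh = set(self.FL), set(self.FM), set(self.FH)
        if fl & fm or fl & fh or fm & fh:
            raise ValueError("FL/FM/FH label sets must be pairwise disjoint")
        object.__setattr__(self, "FL", frozenset(fl))
        object.__setattr__(self, "FM", frozenset(fm))
        object.__setattr__(self, "FH", frozenset(fh))


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-label count thresholds as fractions of a reference frame count.

    With the defaults (ref 50 frames for a ~2.5 s active phase) the FM/FH
    threshold is 20 frames and the FL threshold 10 frames.
    """

    frac_FM: float = 0.4
    frac_FH: float = 0.4
    frac_FL: float = 0.2
    ref_frames: int = 50

    @property
    def theta_FM(self) -> float:
        return self.frac_FM * self.ref_frames

    @property
    def theta_FH(self) -> float:
        return self.frac_FH * self.ref_frames

    @property
    def theta_FL(self) -> float:
        return self.frac_FL * self.ref_frames


@dataclass
class CycleLabel:
    """Per-cycle symbols, state and (following-pause) event call."""

    fl_sym: int = 0
    fm_sym: int = 0
    fh_sym: int = 0
    state: str = "normal"
    snore: bool = False
    event: str = "none"


@dataclass
class MonitoringReport:
    """Night-level summary (durations in hours)."""

    T_monitoring: float
    T_normal: float
    T_abnormal: float
    T_snore: float
    R_sleep: float
    cycle_count: int
    apnea_count: int
    hypopnea_count: int
    accuracy_state: float | None = None
    accuracy_snore: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def symbolize(
    hist: MslHistogram,
    sets: MslSets | None = None,
    thr: ThresholdConfig | None = None,
) -> tuple[int, int, int]:
    """(fl, fm, fh) symbols: 1 iff any label in the set strictly exceeds
    its threshold count."""
    sets = sets or MslSets()
    thr = thr or ThresholdConfig()

    def fires(labels, theta) -> int:
        return int(any(hist.count(i) > theta for i in labels))

    return (
        fires(sets.FL, thr.theta_FL),
        fires(sets.FM, thr.theta_FM),
        fires(sets.FH, thr.theta_FH),
    )


def classify_cycle(symbols: tuple[int, int, int]) -> CycleLabel:
    """State from the symbols: abnormal iff FH fired; snore iff FL fired.

    Cycles with no symbol at all default to normal (quiet breathing).
    """
    fl, fm, fh = symbols
    return CycleLabel(
        fl_sym=fl,
        fm_sym=fm,
        fh_sym=fh,
        state="abnormal" if fh else "normal",
        snore=bool(fl),
    )


def classify_pause(gap_s: float) -> str:
    """apnea if the breathing stop exceeds 10 s, hypopnea for 6-10 s
    (closed interval), otherwise none."""
    if gap_s < 0:
        raise ValueError("pause duration cannot be negative")
    if gap_s > APNEA_MIN_S:
        return "apnea"
    if gap_s >= HYPOPNEA_MIN_S:
        return "hypopnea"
    return "none"


def compute_rsleep(t_normal_h: float, t_monitoring_h: float) -> float:
    """R_Sleep = T_Normal / T_Monitoring (fraction of the night breathing
    normally)."""
    if t_monitoring_h <= 0:
        raise ValueError("monitoring time must be positive")
    if not 0 <= t_normal_h <= t_monitoring_h:
        raise ValueError("need 0 <= T_normal <= T_monitoring")
    return t_normal_h / t_monitoring_h


def summarize(
    labels: list[CycleLabel], seg: SegmentationResult
) -> MonitoringReport:
    """Aggregate per-cycle labels into the night report.

    Each cycle's attributed span is its active phase plus the pause that
    follows it; spans are summed per state.  Events are classified from the
    pause durations and written back onto ``labels``.
    """
    if len(labels) != len(seg.cycles):
        raise ValueError(
            f"{len(labels)} labels do not align with {len(seg.cycles)} cycles"
        )
    fs = seg.fs
    t_norm = t_abn = t_snore = 0.0
    apnea = hypopnea = 0
    for i, lab in enumerate(labels):
        a, b = seg.active_phases[i]
        span = (b - a) / fs
        pause = seg.pause_after(i)
        gap_s = (pause[1] - pause[0]) / fs if pause else 0.0
        lab.event = classify_pause(gap_s)
        if lab.event == "apnea":
            apnea += 1
        elif lab.event == "hypopnea":
            hypopnea += 1
        attributed = span + gap_s
        if lab.state == "normal":
            t_norm += attributed
        else:
            t_abn += attributed
        if lab.snore:
            t_snore += span
    t_mon_h = seg.duration_s / 3600.0
    t_norm_h, t_abn_h, t_snore_h = t_norm / 3600.0, t_abn / 3600.0, t_snore / 3600.0
    return MonitoringReport(
        T_monitoring=t_mon_h,
        T_normal=t_norm_h,
        T_abnormal=t_abn_h,
        T_snore=t_snore_h,
        R_sleep=compute_rsleep(t_norm_h, t_mon_h) if t_mon_h > 0 else 0.0,
        cycle_count=len(labels),
        apnea_count=apnea,
        hypopnea_count=hypopnea,
    )


def score_against_truth(
    predicted: list[CycleLabel], truth: list[CycleLabel]
) -> tuple[float, float]:
    """Fractions of aligned cycles with matching state and snore flag."""
    if len(predicted) != len(truth):
        raise ValueError(
            f"cannot score {len(predicted)} predictions against "
            f"{len(truth)} truth labels"
        )
    if not predicted:
        raise ValueError("cannot score an empty label list")
    state_ok = sum(p.state == t.state for p, t in zip(predicted, truth))
    snore_ok = sum(bool(p.snore) == bool(t.snore) for p, t in zip(predicted, truth))
    n = len(predicted)
    return state_ok / n, snore_ok / n


def label_sets_from_bank(
    bank: MelFilterBank,
    low_band: tuple[float, float] = (0.0, 500.0),
    mid_band: tuple[float, float] = (500.0, 1500.0),
    high_band: tuple[float, float] = (3500.0, float("inf")),
) -> MslSets:
    """Derive FL/FM/FH sets from where the filters peak.

    A label joins a set when its triangle's peak frequency falls inside the
    corresponding band; labels peaking in none (or in the transition above
    the high-band floor but whose triangle straddles it) stay unassigned.
    This mirrors the per-individual set selection of the original method:
    the band semantics (snore < 500 Hz, normal 500-1500 Hz, abnormal outside)
    are fixed while the concrete label indices follow the bank geometry.
    """
    peaks = bank.peak_freqs()
    fl, fm, fh = set(), set(), set()
    for i, p in enumerate(peaks, start=1):
        if low_band[0] <= p < low_band[1]:
            fl.add(i)
        elif mid_band[0] <= p < mid_band[1]:
            fm.add(i)
        elif high_band[0] <= p < high_band[1]:
            fh.add(i)
    if not (fl and fm and fh):
        raise ValueError("bank geometry leaves an empty FL/FM/FH set")
    return MslSets(frozenset(fl), frozenset(fm), frozenset(fh))
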