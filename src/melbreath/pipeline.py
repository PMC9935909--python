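"""End-to-end analysis: audio in, per-cycle labels and night report out.

Feature extraction runs on each cycle's *active phase* (the detected
inspiration+expiration span), matching the ~50-frame reference the
thresholds are calibrated to; the pauses between active phases carry the
apnea/hypopnea information and are classified separately by duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio_io import AudioSignal, CycleRecord
from .detection import (
    CycleLabel,
    MonitoringReport,
    MslSets,
    ThresholdConfig,
    classify_cycle,
    score_against_truth,
    summarize,
    symbolize,
)
from .melscale import MelConfig, build_filterbank, extract_msl, mel_features, msl_histogram
from .segmentation import SegmentationResult, segment

__all__ = ["AnalysisResult", "analyze_signal", "align_truth", "match_events", "cycles_frame"]


@dataclass
class AnalysisResult:
    report: MonitoringReport
    segmentation: SegmentationResult
    labels: list[CycleLabel]


def analyze_signal(
    signal: AudioSignal,
    mel_config: MelConfig | None = None,
    sets: MslSets | None = None,
    thr: ThresholdConfig | None = None,
    delta_s: float = 0.1,
    l_s: float = 2.0,
    min_cycle_s: float = 1.5,
    alpha: float = 0.2,
) -> AnalysisResult:
    """Segment, extract Mel-scale labels, classify, and summarize one night."""
    cfg = mel_config or MelConfig()
    sets = sets or MslSets()
    thr = thr or ThresholdConfig()
    seg = segment(signal, delta_s=delta_s, l_s=l_s, min_cycle_s=min_cycle_s, alpha=alpha)
    f_high = cfg.f_high if cfg.f_high is not None else signal.fs / 2.0
    freqs = np.linspace(0.0, signal.fs / 2.0, cfg.n_freq)
    bank = build_filterbank(cfg.n_filters, cfg.f_low, f_high, freqs)

    scale = signal.fs / seg.fs
    labels: list[CycleLabel] = []
    for a, b in seg.active_phases:
        ia, ib = int(round(a * scale)), int(round(b * scale))
        samples = signal.samples[ia : min(ib, len(signal.samples))]
        if len(samples) < cfg.win_len:  # too short to frame: zero-pad
            samples = np.pad(samples, (0, cfg.win_len - len(samples)))
        feats = mel_features(samples, signal.fs, cfg, bank=bank)
        hist = msl_histogram(extract_msl(feats), cfg.n_filters)
        labels.append(classify_cycle(symbolize(hist, sets, thr)))

    report = summarize(labels, seg)
    return AnalysisResult(report=report, segmentation=seg, labels=labels)


def align_truth(
    result: AnalysisResult, truth: list[CycleRecord]
) -> tuple[list[CycleLabel], list[CycleLabel]]:
    """Pair each truth cycle with the predicted cycle of maximal overlap.

    Returns aligned (predicted, truth) label lists of the truth's length;
    truth cycles with no overlapping prediction get a default quiet-normal
    prediction (counted as a miss for abnormal/snoring cycles).
    """
    seg = result.segmentation
    fs = seg.fs
    pred_iv = [(a / fs, b / fs) for a, b in seg.active_phases]
    aligned_pred: list[CycleLabel] = []
    truth_labels: list[CycleLabel] = []
    for rec in truth:
        best, best_ov = None, 0.0
        for j, (a, b) in enumerate(pred_iv):
            ov = min(b, rec.end_s) - max(a, rec.start_s)
            if ov > best_ov:
                best, best_ov = j, ov
        aligned_pred.append(result.labels[best] if best is not None else CycleLabel())
        truth_labels.append(
            CycleLabel(state=rec.state, snore=rec.snore, event=rec.event)
        )
    return aligned_pred, truth_labels


def score_result(
    result: AnalysisResult, truth: list[CycleRecord]
) -> tuple[float, float]:
    """State and snore accuracy of a result against ground-truth records."""
    pred, true = align_truth(result, truth)
    return score_against_truth(pred, true)


def match_events(
    result: AnalysisResult, truth: list[CycleRecord]
) -> list[tuple[str, str]]:
    """(truth_event, predicted_event) for every truth apnea/hypopnea.

    The predicted event is the duration class of the detected pause
    following the truth cycle's matched prediction.
    """
    pred, _ = align_truth(result, truth)
    pairs = []
    for rec, plab in zip(truth, pred):
        if rec.event != "none":
            pairs.append((rec.event, plab.event))
    return pairs


def cycles_frame(result: AnalysisResult) -> pd.DataFrame:
    """Per-cycle table (start_s, end_s, fl, fm, fh, state, snore, event)."""
    seg = result.segmentation
    fs = seg.fs
    rows = []
    for (a, b), lab in zip(seg.active_phases, result.labels):
        rows.append(
            {
                "start_s": a / fs,
                "end_s": b / fs,
                "fl": lab.fl_sym,
                "fm": lab.fm_sym,
                "fh": lab.fh_sym,
                "state": lab.state,
                "snore": int(lab.snore),
                "event": lab.event,
            }
        )
    return pd.DataFrame(rows)
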