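"""Reference monitoring summaries of the eight-tester overnight study.

The detection rules and their default thresholds were calibrated on eight
whole-night recordings (four testers in their twenties, two in their
thirties and two older testers with PSG-diagnosed moderate/severe OSA).
The raw audio is not distributable; this module carries the published
per-night summary figures so that the night-level arithmetic — the
R_Sleep quality index and the cohort-mean detection accuracies — can be
recomputed and checked.

Columns: monitoring / normal / abnormal / snoring durations in hours,
snore-vs-normal detection accuracy (%), normal-breathing ratio (%), and
abnormal-vs-normal detection accuracy (%).
"""

from __future__ import annotations

import pandas as pd

from .detection import compute_rsleep

__all__ = ["REFERENCE_NIGHTS", "rsleep_percent", "mean_accuracies"]

REFERENCE_NIGHTS = pd.DataFrame(
    {
        "tester": [1, 2, 3, 4, 5, 6, 7, 8],
        "age": [20, 21, 21, 20, 31, 34, 58, 60],
        "monitoring_h": [7.7, 7.5, 6.8, 6.0, 7.5, 8.0, 5.0, 6.8],
        "normal_h": [6.0, 5.6, 4.9, 2.4, 5.5, 4.2, 2.8, 2.3],
        "abnormal_h": [1.7, 1.9, 1.9, 3.6, 2.0, 3.8, 2.2, 4.5],
        "snoring_h": [0.5, 0.3, 0.1, 2.2, 1.0, 3.2, 1.8, 3.8],
        "accuracy_sn_pct": [93.5, 96.0, 98.5, 96.4, 90.8, 97.6, 97.5, 98.2],
        "normal_ratio_pct": [77.9, 74.7, 72.1, 40.0, 73.3, 52.5, 56.0, 33.8],
        "accuracy_an_pct": [93.2, 94.4, 91.9, 90.2, 94.9, 92.2, 95.2, 92.7],
    }
).set_index("tester")


def rsleep_percent(tester: int, decimals: int = 1) -> float:
    """R_Sleep for one reference night, recomputed from its durations (%)."""
    row = REFERENCE_NIGHTS.loc[tester]
    r = compute_rsleep(row["normal_h"], row["monitoring_h"])
    return round(100.0 * r, decimals)


def mean_accuracies(decimals: int = 1) -> tuple[float, float]:
    """Cohort means of the abnormal/normal and snore/normal accuracies (%)."""
    an = round(float(REFERENCE_NIGHTS["accuracy_an_pct"].mean()), decimals)
    sn = round(float(REFERENCE_NIGHTS["accuracy_sn_pct"].mean()), decimals)
    return an, sn
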