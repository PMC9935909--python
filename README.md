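# melbreath

Sleep-breathing-state monitoring from whole-night breathing audio.

Sleep-related breathing disorders — obstructive/central apnea, hypopnea,
snoring — degrade sleep quality and raise cardiovascular risk, yet the
clinical gold standard (polysomnography) is costly and cumbersome. A single
microphone near the nose records enough information to screen for them at
home: breathing is quasi-periodic band-limited noise, snoring adds strong
low-frequency harmonics, obstructed breathing shifts energy out of the
normal band, and apnea/hypopnea appear as long silent gaps. `melbreath`
implements a complete rule-based analysis chain for such recordings, plus a
labelled synthetic-night generator so every stage is testable without
clinical data.

## Method

Audio is analysed at 11.025 kHz (44.1 kHz input is downsampled). Four
stages:

**1. Cycle segmentation by moment-waveform analysis.** With
y(t) the recorded signal, the *time characteristic waveform* (TCW) is the
sliding-window variance

&nbsp;&nbsp;&nbsp;&nbsp;c(t, δ) = ∫_{t−δ}^{t+δ} y(τ)² dτ − 2δ·ȳ(t)²,&nbsp;&nbsp;
ȳ(t) = (1/2δ) ∫_{t−δ}^{t+δ} y(τ) dτ,&nbsp;&nbsp;δ ≈ 0.1 s,

and the *characteristic moment waveform* (CMW) is its second spatial moment
over a longer window,

&nbsp;&nbsp;&nbsp;&nbsp;I(t, δ, l) = ∫_{t−l}^{t+l} (τ−t)² c(τ, δ) dτ,&nbsp;&nbsp;l ≈ 2 s
(about half a breathing cycle).

The CMW is minimal on breath bursts and maximal mid-pause; its local maxima,
snapped into the TCW valley between adjacent TCW peaks, are the cycle
boundaries. Spuriously segmented near-silent "cycles" are merged back into
their pauses by an amplitude threshold, both computations run in O(N).

**2. Mel-scale features.** Each cycle's active phase is cut into
1024-sample rectangular frames with 50 % overlap; each frame gets an
order-32 Yule–Walker autoregressive power spectral density, filtered by a
bank of 20 triangular filters uniformly spaced on the Mel scale

&nbsp;&nbsp;&nbsp;&nbsp;Mel(f) = 1000 · lg(1 + f/700) / lg(1 + 1000/700),

and log₁₀-compressed into a 20 × N matrix f_{i,j}. The per-frame argmax
filter index A_j ∈ {1..20} is the **Mel-scale label** (MsL); its per-cycle
occurrence counts **N_MsL** summarise where the cycle's energy lives.

**3. Threshold rules.** Three disjoint label sets — FL (low: snoring),
FM (middle: normal breathing, ≈500–1500 Hz), FH (high: abnormal breathing)
— fire when any of their labels occupies strictly more frames than a
threshold (40 % of a ~50-frame reference for FM/FH, i.e. 20 frames; 20 %
for FL, i.e. 10 frames). A cycle is *abnormal* iff FH fires and *snoring*
iff FL fires. Breathing stops of 6–10 s are hypopnea events, > 10 s apnea.

**4. Night report.** Durations per state, event counts, and the quality
index R_Sleep = T_Normal / T_Monitoring.

## Worked example

Generate a labelled 100-cycle synthetic night (~8 minutes of audio) and
analyse it, scoring against the generator's truth labels:

```bash
melbreath simulate --out night.wav --truth truth.csv --seed 7
# wrote night.wav (496.9 s, 100 cycles)

melbreath analyze night.wav --labels truth.csv --config cfg.yaml --cycles-csv cycles.csv
```

where `cfg.yaml` selects the label sets matching this recording's band
geometry (see `melbreath.detection.label_sets_from_bank`):

```yaml
detection:
  sets: {FL: [1, 2, 3, 4], FM: [6, 7, 8, 9, 10, 11], FH: [18, 19, 20]}
```

Output:

```json
{
  "T_monitoring": 0.13803958175862938,
  "T_normal": 0.07298553791887126,
  "T_abnormal": 0.0647670949861426,
  "T_snore": 0.027738019652305358,
  "R_sleep": 0.5287290571952827,
  "cycle_count": 102,
  "apnea_count": 4,
  "hypopnea_count": 5,
  "accuracy_state": 1.0,
  "accuracy_snore": 1.0
}
```

Reading: of 0.138 h monitored, 0.073 h were normal breathing
(R_Sleep ≈ 53 %, a poor night by the > 70 % norm of healthy sleepers), with
4 apnea and 5 hypopnea events; every cycle's normal/abnormal state and
snore flag matched the generator's truth. The per-cycle table lands in
`cycles.csv`:

```csv
start_s,end_s,fl,fm,fh,state,snore,event
1.033015873015873,3.761360544217687,1,0,0,normal,1,none
5.026757369614512,7.976961451247165,0,0,1,abnormal,0,none
9.14185941043084,11.972698412698414,0,1,0,normal,0,none
```

The same pipeline is available as a library:

```python
from melbreath import SyntheticConfig, gen_night
from melbreath.pipeline import analyze_signal, score_result

rec = gen_night(SyntheticConfig(n_cycles=100, seed=7))
result = analyze_signal(rec.audio)
print(result.report.R_sleep, score_result(result, rec.truth))
```

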