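# Methods

## Signal model and assumptions

The recorded signal is modelled as y(t) = r(t) + n(t): breathing sound
r(t) plus stationary zero-mean background noise n(t). Breathing is
quasi-periodic (cycle length ~4 s, inspiration+expiration span ~2.5 s) with
these spectral signatures at the 11.025 kHz analysis rate:

* normal breath flow: band-limited noise with dominant energy ~500–1500 Hz;
* snoring: a low-frequency harmonic series (fundamental ~50–120 Hz) plus
  shaped noise, most power below 500 Hz, loudest during inspiration;
* obstructed/abnormal breathing: energy displaced out of the mid band,
  below 500 Hz and above 3500 Hz;
* apnea / hypopnea: breathing stops of > 10 s / 6–10 s.

All detection is rule-based; no classifier is trained.

## Cycle segmentation

**Discretization.** The TCW/CMW integrals become Riemann sums with
dt = 1/fs. In the TCW the nominal window length 2δ is replaced by the exact
(possibly edge-truncated) window duration W = n/fs, so a constant signal
yields exactly zero variance; edge windows are truncated, not padded, and
the first/last l seconds are accordingly lower-confidence. The TCW uses
O(N) cumulative sums. The CMW is an FFT convolution of the TCW with the
fixed quadratic kernel ((k/fs)² / fs, |k| ≤ l·fs) — algebraically identical
to running-moment sums (which reach the same O(N) bound) but immune to the
catastrophic cancellation the raw moments S₂ − 2tS₁ + t²S₀ suffer when t
grows to hours. Both are verified against a direct per-window summation
oracle to 1e-9 relative error.

**Defaults.** δ = 0.1 s (about a tenth of one breath phase); l = 2.0 s,
inside the workable (1.5, 3) s range of about half a cycle;
min_cycle_s = 1.5 s (shortest plausible breathing cycle) is the minimum
separation imposed on all extrema and on emitted cycles.

**Boundary detection.** Local CMW minima (separation ≥ min_cycle_s) mark
breath centres; the TCW maximum within ±l of each gives the breath-peak
sequence T_max. CMW maxima are boundary candidates; each is moved into the
TCW valley between the adjacent T_max points. Because the TCW is
essentially flat at noise level throughout a pause, the literal argmin is
arbitrary there; the boundary is instead placed at the midpoint of the
*longest* below-threshold TCW run between the two peaks (the true
inter-breath gap rather than the brief stop inside a breath), falling back
to the argmin when the TCW never drops below threshold. The threshold is
5 % of the median TCW value at the T_max points.

**Merging.** Two rules, both measured on a rectified envelope smoothed
over 50 ms, interpret the "combine incorrectly segmented pauses" step:
(a) a segment whose peak envelope is below α = 0.2 of the mean per-cycle
peak is no breath and is absorbed into the surrounding pause (this clears
noise blips inside long apnea gaps); (b) adjacent segments separated by an
envelope gap shorter than 0.35 s were split at the stop *within* a breath
and are recombined. α = 0 disables the stage. Whether the original
combine-threshold applies to amplitude or pause length is ambiguous;
implementing both proved necessary and sufficient on synthetic nights.

**Active phases and pauses.** Each cycle's active phase is the envelope
run above 10 % of that cycle's own peak (per-cycle reference, so faint
breaths keep their full extent); pauses are the gaps between consecutive
active phases. Measured pause durations carry a small systematic
positive bias (~0.1 s on synthetic data) because the quiet burst tails
fall under the envelope threshold; events whose true gap lies within that
margin of the 6 s / 10 s class boundaries can therefore flip class. This
is inherent to any duration-threshold event rule.

**Long recordings.** Above 10 minutes the waveforms are evaluated on a
10 ms-hop grid (TCW exactly, via the same cumulative sums; CMW with
dt = hop). Exactness tests always run on the per-sample grid.

## Mel-scale features

* Frames: 1024 samples (~93 ms), rectangular, hop 512; a cycle's trailing
  remainder < hop is dropped; a ~2.5 s active phase gives ~52 frames.
* AR spectra: Yule–Walker normal equations on the *biased* autocorrelation
  (guarantees a stable model), solved by Levinson–Durbin; order 32; PSD
  σ²/fs / |A(e^{j2πf/fs})|² on 513 uniform frequencies over [0, fs/2].
  One-sided scaling is fixed arbitrarily — the MsL is an argmax and is
  invariant to any global PSD scale (and to overall recording gain, which
  shifts every log-energy by the same 2·log₁₀ g).
* Filter bank: 22 edges uniform in Mel over [0, fs/2] (band edges are
  otherwise unspecified; full band keeps the map invertible), snapped to
  the PSD grid so each triangle peaks at exactly 1 on a grid point; each
  filter's peak is the left edge of the next. A grid too coarse to separate
  adjacent edges raises.
* log₁₀ with floor ε = 1e-12 on band energies; an all-zero frame yields a
  flat ε-level PSD.
* Argmax ties break to the lowest label (measure-zero on real audio, but
  deterministic).
* Features are computed on the cycle's **active phase**, not the whole
  boundary-to-boundary interval: the ~50-frame threshold reference
  corresponds to the ~2.5 s inspiration+expiration span, and including
  pause frames would let broadband background noise (whose flat spectrum
  the widest, highest filter wins by area) contaminate the histogram.
* No cepstral/DCT step: the features of interest are the post-logarithm
  band energies themselves, not cepstral coefficients.

## Detection rules

* Default sets FL = {2}, FM = {4..7}, FH = {15..17}; thresholds
  θ_FM = θ_FH = 0.4 × 50 = 20 frames, θ_FL = 0.2 × 50 = 10 frames;
  strictly-greater comparison; a set fires when *any* of its labels
  exceeds its threshold (per-label counts are what the rule thresholds).
* State: abnormal ⇔ FH fired; snore ⇔ FL fired; FM is retained as a
  heavy-breathing indicator but defines no further subtype (no operational
  rule exists for one).
* The label sets are an individual-level calibration, not a constant of
  the method: with a 20-filter bank over [0, 5512.5] Hz the filters peaking
  above 3500 Hz are 18–20, not 15–17, so
  `label_sets_from_bank` derives the sets from the bank geometry (a label
  joins FL/FM/FH when its triangle peaks inside the snore / normal /
  abnormal band). Synthetic-night analyses use these geometric sets; the
  defaults are kept for compatibility with recordings labelled under the
  original convention.
* Events: pause > 10 s → apnea; 6 s ≤ pause ≤ 10 s → hypopnea (closed
  interval at both ends).
* Durations: each cycle's attributed time is its active phase plus the
  following pause, summed per state; T_snore sums active spans of snoring
  cycles; R_Sleep = T_Normal / T_Monitoring.

## Synthetic data generator

Defaults: 100 cycles, cycle 4.0 s, active span 2.5 s (split into
inspiration, a 0.3 s intra-breath stop, expiration), timing CV 10 %,
breath-band SNR 20 dB over white background. Per-cycle probabilities:
snore 0.2, abnormal 0.3; per-gap: apnea 0.05 (gap uniform 10–25 s),
hypopnea 0.05 (uniform 6–10 s); cycles preceding an event are abnormal,
and abnormal cycles also snore with probability 0.8 (the two components
co-occur in obstructed breathing). Component RMS levels while present —
breath 0.05, snore 0.15 (snoring is much louder than quiet breathing,
applied to inspiration), abnormal 0.12 (split ~75 % high band / 25 % low,
across the whole active phase) — are fixed design choices keeping every
labelled component detectable at the stated thresholds while the summed
waveform stays inside [-1, 1] (a hard clip guards the tail). Identical
seeds give bit-identical nights.

Not modelled: room reverberation and non-stationary noise, body-movement
artifacts, microphone displacement, physiological airflow shapes,
irregular-breathing-rate as a separate label (cycle-length jitter exists
but is unlabelled), and OSA severity. Passing synthetic tests therefore
demonstrates the pipeline's correctness under the stated spectral/timing
model, not clinical performance on real recordings; the bundled reference
table records what the rule set achieved on the original eight-night
cohort.

## Problem sizes in tests and the acceptance script

Oracle agreement runs 100 random 1 s signals; end-to-end recovery runs ten
100-cycle nights (~8 min audio each) and checks per-night cycle counts
(±5 %), mean state/snore accuracy (≥ 0.90), and event classes. The
acceptance script analyses three seeded 100-cycle nights and recomputes
the reference-table arithmetic; these sizes keep a full run in minutes on
one CPU while leaving the statistics stable.

## Known limitations

* The amplitude-equalization preprocessing (sliding 2 s RMS normalization
  toward a target level, silence left untouched) is one reading of
  "amplitude contrast diminution", for which no formula exists; it is off
  by default and not required by the downstream math.
* Pause durations inherit the ~0.1 s envelope-threshold bias described
  above.
* Threshold defaults assume the ~50-frame active-phase reference; very
  slow or fast breathers would need `ref_frames` (or per-cycle
  normalization) adjusted.
* The 16-bit WAV path quantizes at 1/32768; mp3 or Bluetooth transport
  artifacts of the original acquisition chain are out of scope (transcode
  to WAV first).
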