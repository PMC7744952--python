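# Methods

## Signal model

A synthetic ECG record is a uniformly sampled voltage series
$v(t_i)$, $t_i = i/f_s$, $i = 0 \ldots \mathrm{round}(D f_s) - 1$, for
duration $D$ (default 60 s) and sampling rate $f_s$ (default 250 Hz, the
rate of the congestive-heart-failure recordings the profiles emulate).
Beats are placed at $r_k = (k + \tfrac12)T$, $T = 60/\mathrm{HR}$, so every
beat has a complete cycle around it; each contributes five Gaussian
deflections

$$v_k(t) = \sum_{w \in \{P,Q,R,S,T\}} a_w \exp\!\left(-\frac{(t - r_k - c_w)^2}{2 b_w^2}\right),$$

with amplitude $a_w$ (mV), apex offset $c_w$ (s, relative to R) and width
$b_w$ (s). An elevated ST segment is a plateau of height `st_offset` (mV)
between the S and T waves, shaped by two logistic ramps of 10 ms scale so
the signal stays smooth. Noise is additive white Gaussian
(`noise_sd`, default 0); baseline wander, electrode artefacts and beat-to-
beat morphology variation are deliberately absent. The true R times, Q/S
trough times, QRS width and ST offset are attached to every record.

The generator is specified by its *recoverable ground truth*, not by
physiological realism: the source material characterises its signals only
through their extracted features, so the design constraint is that the
extractor applied to a noise-free synthesis reproduces each class's printed
feature block exactly. Passing tests therefore demonstrate correctness of
the extraction algorithms on clean, known-truth signals — not robustness to
real recordings.

### Class profiles

| class | peaks | QRS (s) | ST elevated | HR (bpm) | excerpt (s) |
|---|---|---|---|---|---|
| sleep_apnea | 6 | 0.06 | yes | 60 | 6 |
| arrhythmia_wide | 5 | 0.5 | no | 50 | 6 |
| arrhythmia_narrow | 7 | 0.047 | yes | 70 | 6 |
| heart_failure | 6 | 0.169 | no | 60 | 6 |
| normal | — | 0.08 | no | 75 | 60 |
| normal_hr110 | 110 | 0.08 | no | 110 | 60 |

The printed peak counts (5–7) are far below what a minute of ECG at any
physiological heart rate contains, so "peaks" is interpreted as the R-peak
count of a short analysed excerpt; the excerpt length (6 s) and heart rate
are chosen jointly so that $\mathrm{peaks} = \mathrm{excerpt} \cdot
\mathrm{HR}/60$ hits the printed count. The 0.5 s QRS of the wide-complex
class is likewise treated as a literal target rather than physiology.
Morphology per class: Q and S troughs at $\mp$ half the target width with
trough widths $\max(w/10, 6\,\mathrm{ms})$, R width $\max(w/8, 9\,\mathrm{ms})$,
amplitudes $(P, Q, R, S, T) = (0.10, -0.35, 1.2, -0.35, 0.25)$ mV, T apex
220 ms past the S trough, and `st_offset` 0.2 mV for the ST-elevated
classes. Keeping the troughs narrow relative to the half-width bounds the
shift induced by the R tail well under one sample at 250 Hz.

Numerics records carry channels named SpO2, HR, ABP/PAP/NBP Sys/Dias,
sampled at a fixed interval (default 1.024 s, the archive's monitor rate),
$\lfloor D/\Delta \rfloor + 1$ samples per channel; the implied frequency
is reported rounded half-up to 6 decimals (1.024 s → 0.976563 Hz).

## Feature extraction

- **Baseline.** The record median. The mean was considered and rejected:
  the R wave and any ST plateau bias it upward by several hundredths of a
  millivolt, which corrupts the ST magnitude; the median tracks the
  isoelectric line and scales correctly under amplitude scaling.
- **Cycle splitting.** Local maxima of the baseline-subtracted signal above
  half its global maximum, at least 200 ms apart (refractory bound), are
  beat anchors; cycle boundaries are midpoints between successive anchors,
  so cycles tile the record. A flat or all-negative record yields no
  cycles. The relative threshold makes segmentation invariant to amplitude
  scaling; the distance scales with $f_s$, so resampling preserves counts.
- **Fiducials.** R is the maximum of the cycle's upper half (ties → earliest
  sample). Q and S are voltage minima in windows of 300 ms before/after R,
  clipped to the cycle. A 120 ms window was considered and rejected because
  the wide-complex class places its troughs 250 ms from R; 300 ms still
  cannot reach into a neighbouring beat at the heart rates used (cycle
  half-length ≥ 270 ms at 110 bpm).
- **ST elevation.** Mean voltage 40–80 ms after the S trough, minus
  baseline; flagged at ≥ 0.1 mV (standard clinical convention; the source
  states no threshold).
- **Record features.** Peak count; median per-cycle QRS width and ST
  magnitude; mean R–R interval with label Regular iff the coefficient of
  variation of R–R intervals is < 0.10 (fewer than two peaks → Regular,
  interval undefined); heart rate = peaks · 60 / duration.

## Vitals summarisation

Each present channel collapses to the arithmetic mean of its valid samples
(finite, non-negative; SpO2 ≤ 100), rounded half-up to an integer to match
the all-integer reference rows. Missing data uses two codes from the source
schema: a channel the monitor never recorded prints `x` (ABSENT); a present
channel whose samples are all invalid prints `0`. The reference vitals
table's numeric cells derive from real archive records and are out of
scope; only the schema, header order and missing-value conventions are
implemented.

## Triage model

The triage mapping is extensional: 580 printed rows of 11 features (SpO2,
high/low pressure, four symptoms, four ECG cells) with an ordered outcome.
No rules are stated, so hand-guessing clinical logic was rejected in favour
of induction with the table as oracle: a scikit-learn decision tree grown
without depth limit (deterministic, `random_state=0`) over the
deduplicated vectors, plus an exact lookup for seen vectors. Unseen vectors
are routed through the tree and flagged as extrapolation; no clinical
validity is claimed for either path. The ECG cells are treated as opaque
categories ("6", "0.06", "normal", "110", ""), matching their role as
printed block signatures.

Duplicate-vector consistency is checked by exhaustive grouping. The source
table contains exactly one contradiction: rows 510 and 551 share the vector
(SpO2 97, BP 12/8, chest pain + breathlessness, at rest, normal ECG) but
are labelled Sick and Cold State. The model resolves to the first
occurrence; the default build configuration carries a positional label
override for row 551 so the emitted table remains cell-identical to the
source, and the conflict is enumerated in every validation report. A
symptom-monotonicity audit (does turning a symptom on ever lower the
level?) is reported but never enforced — the printed table is canonical.

## Dataset builds

The enumeration design is data, not code: a JSON configuration lists, per
table segment, the ECG class, the vitals block and the symptom sequence —
either a named bit-order convention ("chest_pain_msb": chest pain most
significant, at-rest fastest, used by the triage table; "chest_pain_lsb":
chest pain fastest, used by the enumeration table) or an explicit list for
the irregular healthy-ECG blocks. The shipped default reproduces the
source design: 40 segments totalling 580 rows (144 sleep-apnea incl. the
long-term-ST continuation, 144 + 144 arrhythmia, 68 heart-failure with the
printed truncation, 52 normal, 28 fixed-HR), and nine 16-row blocks
truncated to 143 for the enumeration table. Whether the truncations were
intentional is unknowable; they are preserved as printed. The emitted ECG
feature cells are the class profiles' printed targets — the extractor
recovers widths only to ±1/f_s, so re-formatting extracted floats would
break cell-exact reproduction; instead the generation → extraction round
trip runs as a separate verification stage of the same build. Builds are
fully deterministic; two runs produce byte-identical CSV.

Transcription conventions: the printed high/low pressure columns of the
enumeration table are transposed relative to the triage table and are kept
as printed (`bp_high_printed`/`bp_low_printed`); healthy-ECG rows print a
collapsed feature cell transcribed as peaks = "normal" (or the numeric
heart rate "110"), empty QRS/ST, Peak-to-Peak "Regular"; outcome spellings
("risk", "Cold State") are preserved through a canonical ordered level
type.

## Numerical choices and limitations

Ties in argmax/argmin resolve to the earliest sample. QRS-width agreement
is asserted to ±1/f_s (trough times are grid-quantised; off-grid troughs
may round by half a sample on each side). Problem sizes throughout —
6–60 s excerpts at 250 Hz, 100 randomized cycles for the brute-force
fiducial cross-check — keep the full suite and the acceptance run in the
low seconds. The extractor is not a general-purpose QRS detector: it
assumes a positive dominant R deflection, no baseline drift, and noise well
below half the R amplitude; the single-lead Gaussian model has no P/T-wave
pathology, no rhythm variability beyond the regularity label, and the
triage model is valid only over the printed vitals/feature vocabulary.
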