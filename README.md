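# triagesim

Synthetic physiological signals and a fully reproducible emergency-triage
dataset for benchmarking patient-prioritisation systems.

Remote-monitoring and emergency-department research needs labelled patient
cohorts that combine sensor features (ECG morphology, SpO2, blood pressure)
with intake symptoms and an ordered triage outcome. Public waveform archives
provide the raw signals but not the joined, labelled table. `triagesim`
provides that table — a 580-patient dataset built by full-factorial
enumeration of four yes/no symptoms over a grid of vitals blocks and six ECG
classes — together with everything needed to regenerate it from first
principles: a ground-truth-carrying signal generator, the feature
extractors, and an induced triage classifier.

## What it computes

**ECG synthesis.** Each cardiac cycle is a sum of Gaussian deflections
(P, Q, R, S, T), beats placed at $(k+\tfrac12)\,T$ for cycle length
$T = 60/\mathrm{HR}$, with an optional smooth ST-segment plateau and white
noise. The true R times, Q/S trough times and ST offset are attached to
every record, so extractor accuracy is measurable exactly. Low-rate
"numerics" channels (SpO2, HR, arterial/pulmonary/non-invasive pressures)
are sampled every 1.024 s (0.976563 Hz), 59 samples per minute.

**Feature extraction.** The record is re-centred on its baseline (median
voltage), split into cycles around the dominant deflections, and split into
upper/lower halves about the baseline. Per cycle: the R apex is the maximum
of the upper half; Q and S are the windowed minima left and right of R; the
QRS width is $t_S - t_Q$; ST elevation is the mean voltage 40–80 ms after S
relative to baseline, flagged at 0.1 mV. Per record: peak count, median QRS
width, mean R–R interval with a Regular/Irregular label
($\mathrm{CV}(RR) < 0.10 \Rightarrow$ Regular), and heart rate.

**Triage classification.** The triage mapping
(Normal < Cold State < Sick < Urgent < Risk) is specified extensionally by
the packaged 580-row reference table. A decision tree is grown to exact
training fit on the 11-feature vectors; seen vectors resolve through an
exact lookup, unseen vectors fall back to the tree and are flagged as
extrapolation. The one pair of contradictory duplicate rows in the source
(rows 510/551) is detected, reported, and preserved verbatim in the default
build.

## Worked example

```
$ triagesim synth --profile sleep_apnea --out apnea.txt
$ triagesim extract apnea.txt
Record,Peaks,QRS width,Peak to Peak,ST El.,Heart Rate
sleep_apnea,6,0.06,Regular,true,60
```

The sleep-apnea class profile synthesizes a 6 s, 250 Hz excerpt at 60 bpm;
the extractor recovers exactly its printed feature block: 6 R peaks, a
60 ms QRS, regular peak-to-peak intervals, and an elevated ST segment.

```
$ triagesim validate --schema table6
OK: tables identical
conflicting duplicate vectors in the source table:
  row 510: Sick; row 551: Cold State
```

This rebuilds the full 580-row triage dataset from the declarative default
configuration — enumerating every symptom combination per vitals block per
ECG class and classifying each vector with the induced model — and diffs it
cell-by-cell against the packaged reference table: identical, with the one
inherent label conflict enumerated.

```
$ triagesim numerics --channel SpO2=97 --channel HR=70 --out num.csv
$ triagesim vitals num.csv --record-id demo
Record,Spo2 level,Heart Rates (HR),ABP Sys,ABP Dias,PAP Sys,PAP Dias,NBP Sys,NBP Dias
demo,97,70,x,x,x,x,x,x
```

Channels absent from a numerics record print as `x`; a present channel with
no valid sample prints `0`.

## Layout

- `src/triagesim/waveform.py` — ECG/numerics generators, class profiles, signal text I/O
- `src/triagesim/ecg.py` — cycle splitting, R/Q/S location, QRS width, ST elevation, feature vectors
- `src/triagesim/vitals.py` — numerics summarisation with the `x`/`0` missing-value codes
- `src/triagesim/triage.py` — feature vectors, symptom enumeration, consistency check, induced model
- `src/triagesim/builder.py` — declarative dataset builds, fixture validation
- `src/triagesim/data/` — reference tables (CSV) and the default build configuration
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
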