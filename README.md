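# spindlefusion

Fusion sleep-spindle detection and spindle-characteristics analysis for
sleep EEG, with a synthetic annotated-PSG cohort generator for end-to-end
testing.

The fusion detector combines two component detectors and a cluster-level
filter:

1. **Morlet-wavelet detector** — magnitude of a complex Morlet
   convolution of the raw signal, smoothed and thresholded at a multiple
   of the envelope median.
2. **Small-window RMS detector** — 11–16 Hz band-pass, sliding-window
   RMS, thresholded at a percentile of the RMS series.
3. **Overlap resolution** — detections from both detectors that overlap
   in time form an "overlapping" set; the longer event represents each
   overlap group.
4. **k-means cluster rejection** — non-overlapping ("unique") detections
   are clustered on standardized (peak-to-peak amplitude, mean frequency)
   with k-means++ and silhouette-selected k; clusters dominated by
   labelled non-spindles are discarded. Survivors are unioned with the
   overlapping set.

Also included: expert two-of-three consensus ground truth, event-level
and bin-level evaluation metrics (recall, precision, specificity,
accuracy, F1, per-subject variances), spindle characteristics (density,
amplitude, frequency histograms, symmetric-channel counts), and
correlation/group-comparison statistics against PSQI sleep-quality
scores.

## Command-line usage

```bash
# generate a synthetic annotated cohort (EDF + truth/expert CSVs + hypnograms)
spindlefusion simulate --out cohort --seed 42 --n-ds 20 --n-ns 10 --duration-min 20

# run the fusion detector on one recording
spindlefusion detect --edf cohort/DS1.edf --channels C3,C4 \
    --hypnogram cohort/DS1_hypnogram.csv --method fusion \
    --labels cohort/DS1_truth_events.csv --out DS1_fusion.csv

# score predictions against truth (or three expert CSVs via --experts)
spindlefusion evaluate --pred DS1_fusion.csv \
    --truth cohort/DS1_truth_events.csv --window 1200 --out DS1_metrics.csv

# cohort feature + correlation reports
spindlefusion analyze --events-dir cohort --subjects cohort/subjects.csv --out report

# wavelet vs RMS vs fusion comparison over a cohort
spindlefusion compare --cohort-dir cohort --out comparison.csv
```

All detector/fusion/evaluation parameters are exposed through a YAML
config (`--config`); see `spindlefusion.io.RunConfig` for keys and
defaults.

## Layout

- `src/spindlefusion/model.py` — domain types and interval arithmetic
- `src/spindlefusion/edf.py`, `io.py` — EDF/CSV/YAML readers and writers
- `src/spindlefusion/preprocess.py` — band-pass, scoring window, first cycle
- `src/spindlefusion/detectors.py` — Morlet and RMS detectors
- `src/spindlefusion/fusion.py` — overlap partition + k-means rejection
- `src/spindlefusion/evaluation.py` — consensus, matching, metrics, variance
- `src/spindlefusion/features.py` — density, amplitude, frequency, histograms
- `src/spindlefusion/stats.py` — Pearson, Welch's t, cohort summaries
- `src/spindlefusion/synth.py` — synthetic cohort generator
- `src/spindlefusion/cli.py` — command-line interface
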