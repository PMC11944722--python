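# oxiscale

Multi-scale SpO2 feature engineering for sleep-apnea severity screening.

Wearable pulse oximeters record blood-oxygen saturation at far lower
effective resolution than the 1 Hz polysomnography signal that clinical
apnea markers were designed for. `oxiscale` asks, and lets you test, a
concrete question: *which SpO2 features survive coarse temporal resolution?*
It implements

* **coarse-graining** of a 1 Hz saturation series into non-overlapping
  window means over a 29-scale grid (1–600 s);
* **oxygen-desaturation detection** — episodes with a drop ≥ 3 % versus the
  trailing 120 s mean lasting ≥ 10 s — and the classical biomarkers ODI,
  POD, AODmax, AOD100, CA and M;
* a **native bank of non-linear features**: approximate/sample/fuzzy/
  permutation/dispersion/increment/Kolmogorov/conditional/distribution/
  phase/Shannon entropy, ordinal statistical complexity, Lempel–Ziv (LZ76)
  complexity, DFA scaling exponents and PRSA capacity, each verified
  against brute-force references;
* **Spearman screening** of feature relevance against the Apnea–Hypopnea
  Index (AHI) across scales, with classification of each profile into four
  trend groups — A decaying, B coarser-peak, C polarity-shift, D
  constant-high;
* a **repeated severity-classification protocol**: stratified 80/20 splits,
  training-only scaling, grid-searched models (NB, LR, DT, KNN, XGBoost,
  LightGBM, MLP), metrics Acc/Pre/Sen/F1/MCC/AUC from closed-form confusion
  arithmetic, repeated over seeds with mean ± SD reporting;
* a **synthetic oximetry generator** with programmable true AHI, so the
  whole pipeline runs and is tested without access to restricted clinical
  recordings.

Signals are read from EDF (via `mne`) or plain `time_s,spo2_percent` CSV;
AHI labels from delimited tables (NSRR-style column names supported).

## Worked example

```python
from oxiscale import (SimConfig, clean_spo2, coarse_grain,
                      detect_desaturations, extract_all, oximetry_markers)
from oxiscale.synthetic import simulate_record

cfg = SimConfig(duration_h=8.0, true_rate=12.0, seed=7, exact_count=True,
                depth_range=(4.0, 8.0), noise_sd=0.0,
                artifact_rate_per_h=0.0, quantize_step=0.0)
rec = simulate_record(cfg)
series = clean_spo2(rec.series)          # mask readings outside [60, 100] %
events = detect_desaturations(series)
print(len(rec.truth_events), len(events), round(oximetry_markers(series, events).odi, 2))
```

prints

```
96 96 12.0
```

— on a noise-free night the detector recovers all 96 programmed
desaturations, so the oxygen-desaturation index equals the programmed
12 events/h exactly (with the default measurement noise, 1 % quantisation
and depth mix skewed toward the 3 % criterion, some near-criterion dips blur
below the detection threshold — see `examples/01_simulate_and_detect.py`).
Running `python examples/02_multiscale_features.py` then shows the central
phenomenon (true AHI 25.5/h):

```
  tau      n     ODI  SampEn  PermEn     LZ
    1  14400   13.00   0.134   0.232  0.219
    5   2880   13.25   0.296   0.544  0.415
   15    960   11.25   0.578   0.803  0.660
   30    480    3.25   0.985   0.919  0.891
   60    240    0.50   1.639   0.980  1.087
  120    120    0.50   1.741   0.996  1.151
  300     48    0.00   1.717   0.978  0.931
```

ODI tracks the true event rate while windows are shorter than the events,
then collapses once averaging smears the desaturations below the 3 %
criterion — whereas the entropy and complexity features keep responding to
the event-driven structure at scales where a consumer wearable actually
stores data. `examples/03_screen_cohort.py` turns this into cohort-level
Spearman profiles (ODI lands in decaying group A, sample entropy in
constant-high group D), and `examples/04_severity_classification.py` runs
the repeated classification protocol on multi-scale versus native-only
features.

A thin CLI mirrors the pipeline stages and stamps every run with a manifest
(tool version, options, input digests, seed):

```bash
oxiscale simulate --n 50 --rates shhs-mix --seed 7 --out-dir cohort/
oxiscale extract --in cohort/s0000.csv --grid standard --out features.csv
oxiscale screen  --features features.csv --labels cohort/labels.csv --out report.csv
oxiscale classify --features features.csv --labels cohort/labels.csv \
    --tasks cutoff15 --models XGB,LGBM --repeats 50 --base-seed 17 --out clf.csv
```

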