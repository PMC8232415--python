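# eegspect

EEG-based screening for autism spectrum disorder (ASD) via spectrogram
images: a complete, tested re-implementation of the
preprocess → STFT-image → classify pipeline, usable both with real
recordings (EDF or plain numeric matrices) and with a built-in synthetic
EEG cohort simulator that makes every stage verifiable end to end.

**Who it is for.** Researchers and students working on EEG-based
classification who want a small, transparent reference pipeline — every
stage is an importable function with a seeded, deterministic contract —
rather than a black box.

## The method

Raw multi-channel EEG (16 channels, 256 Hz in the reference setting) is
cleaned with common average referencing, an order-4 zero-phase Butterworth
low-pass at 40 Hz, and per-channel normalization to [−1, 1], then cut into
non-overlapping 3.5 s single-channel segments. Each segment becomes an
8-bit grayscale spectrogram image |STFT| (0–50 Hz, peak-referenced dB).
Two classification routes operate on these images:

* **Classical.** tCENTRIST texture features — local ternary pattern (LTP)
  codes with dead band ±t substituted into the CENTRIST census-histogram
  scheme over a 21-block spatial pyramid (512 × 21 = 10 752 features) —
  reduced by PCA (0.95 retained variance) and classified by a bank of six
  classifiers (NB, LDA, RF, kNN k=9, LR, linear SVM) under stratified
  ten-fold cross-validation.
* **Deep.** Three small CNNs (three conv/pool blocks + dense-512; the same
  with dropout 0.2; four conv/pool blocks with dropout 0.25/0.25/0.5 and
  dense-256) trained with Adam and a 70/15/15 split. The CNN engine is a
  compact seeded numpy implementation included in the package.

Performance is reported as sensitivity = TP/(TP+FN)·100,
specificity = TN/(TN+FP)·100, accuracy = (TP+TN)/total·100,
F1 = 2TP/(2TP+FP+FN), and AUC (trapezoidal empirical ROC, midrank ties),
where ASD is the positive class.

## Worked example

```python
import eegspect as es

# a small labeled synthetic cohort: 4+4 subjects, 60 s, 16 ch @ 256 Hz
recs = es.generate_cohort(es.separable_spec(subjects_per_class=4, duration=60, seed=7))

# classical route: images -> tCENTRIST -> PCA -> linear SVM, 10-fold CV
report = es.run_ml_experiment(recs, classifier="svm", k=10, seed=7)
print(f"pooled accuracy {report.accuracy:.2f}%  AUC {report.auc:.3f}")
print(f"sensitivity {report.sensitivity:.2f}%  specificity {report.specificity:.2f}%")
```

prints (exact numbers from this seed):

```
pooled accuracy 91.45%  AUC 0.977
sensitivity 90.44%  specificity 92.46%
```

i.e. on a cohort where the case class has half the alpha power and ~1.5×
the theta power of controls, the texture features recover the planted
spectral difference almost perfectly; on the `null_spec` preset (identical
class parameters) the same pipeline stays at chance under subject-grouped
folds. See `examples/` for one narrative script per capability
(simulation, preprocessing, imaging, features, classical CV, CNN
training) and `docs/methods.md` for modeling choices and caveats.

A thin CLI mirrors the stages:

```bash
eegspect simulate --preset separable --subjects 4 --duration 60 --seed 7 --out cohort/
eegspect preprocess --in cohort/A01.edf --format edf --label ASD --out segs/
eegspect spectrogram --segments segs/ --out imgs/
eegspect extract --images imgs/ --out features.tsv
eegspect ml-cv --features features.tsv --classifier svm --k 10 --seed 7 --out metrics.json
```

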