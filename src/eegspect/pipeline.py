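"""End-to-end experiment helpers tying the stages together in memory:
cohort -> preprocessing -> spectrogram images -> (tCENTRIST features + CV
bank | CNN with 70/15/15 protocol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnn import CNNSpec, TrainConfig, TrainHistory, build_cnn, evaluate_cnn, make_split, prepare_images, train_cnn
from .metrics import MetricsReport
from .ml import LabeledFeatureSet, cross_validate, make_folds
from .preprocess import PreprocessConfig, preprocess_recording
from .recording import ClassLabel, EEGRecording
from .spectrogram import STFTConfig, SpectrogramImage, segment_to_image
from .tcentrist import LTPConfig, extract_tcentrist


def images_from_cohort(
    recordings: list[EEGRecording],
    pre_cfg: PreprocessConfig | None = None,
    stft_cfg: STFTConfig | None = None,
) -> list[SpectrogramImage]:
    """Preprocess every recording and render one image per channel-window."""
    pre_cfg = pre_cfg or PreprocessConfig()
    stft_cfg = stft_cfg or STFTConfig()
    images: list[SpectrogramImage] = []
    for rec in recordings:
        for seg in preprocess_recording(rec, pre_cfg):
            images.append(segment_to_image(seg, stft_cfg))
    return images


def features_from_images(
    images: list[SpectrogramImage], ltp_cfg: LTPConfig | None = None
) -> LabeledFeatureSet:
    """tCENTRIST features for a list of images, labels 1 = ASD."""
    ltp_cfg = ltp_cfg or LTPConfig()
    feats = np.stack([extract_tcentrist(im.pixels, ltp_cfg).values for im in images])
    labels = np.array([1 if im.class_label == ClassLabel.ASD else 0 for im in images])
    subjects = np.array([im.subject_id for im in images], dtype=object)
    item_ids = np.array([im.image_id for im in images], dtype=object)
    return LabeledFeatureSet(features=feats, labels=labels, subject_ids=subjects, item_ids=item_ids)


def run_ml_experiment(
    recordings: list[EEGRecording],
    classifier: str = "svm",
    k: int = 10,
    seed: int = 0,
    pca_target: float = 0.95,
    grouping: str = "image",
    pre_cfg: PreprocessConfig | None = None,
    stft_cfg: STFTConfig | None = None,
    ltp_cfg: LTPConfig | None = None,
) -> MetricsReport:
    """Cohort -> features -> k-fold CV of one classifier."""
    images = images_from_cohort(recordings, pre_cfg, stft_cfg)
    fset = features_from_images(images, ltp_cfg)
    plan = make_folds(fset, k=k, seed=seed, grouping=grouping)
    return cross_validate(fset, classifier, plan=plan, pca_target=pca_target, seed=seed)


@dataclass
class CNNExperimentResult:
    report: MetricsReport
    history: TrainHistory
    n_train: int
    n_val: int
    n_test: int


def run_cnn_experiment(
    recordings: list[EEGRecording],
    model_id: int = 3,
    train_cfg: TrainConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
    stft_cfg: STFTConfig | None = None,
) -> CNNExperimentResult:
    """Cohort -> images -> 70/15/15 split -> train -> held-out metrics."""
    train_cfg = train_cfg or TrainConfig()
    stft_cfg = stft_cfg or STFTConfig()
    images = images_from_cohort(recordings, pre_cfg, stft_cfg)
    x = prepare_images([im.pixels for im in images])
    y = np.array([1 if im.class_label == ClassLabel.ASD else 0 for im in images])
    subjects = np.array([im.subject_id for im in images], dtype=object)
    tr, va, te = make_split(y, subjects, train_cfg)
    spec = CNNSpec(model_id=model_id, input_shape=x.shape[1:])
    model = build_cnn(spec, seed=train_cfg.seed)
    history = train_cnn(model, x[tr], y[tr], x[va], y[va], train_cfg)
    report = evaluate_cnn(model, x[te], y[te])
    return CNNExperimentResult(report=report, history=history,
                               n_train=len(tr), n_val=len(va), n_test=len(te))
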