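"""End-to-end orchestration: profile -> smooth -> words -> reduce -> classify.

Two feature-reduction modes exist.  ``plsi`` trains an aspect model on the
training corpus and represents each protein by its topic distribution
(held-out proteins are folded in).  ``signatures`` additionally ranks topics
by class preference, extracts top gapped-dipeptide signatures and feeds only
those word weights to the SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import classify, features, plsi, profiles, signatures

DEFAULT_SVM_GRID = [
    (2.0**log_c, 2.0**log_g)
    for log_c in range(-3, 12, 2)
    for log_g in range(-11, 2, 2)
]


@dataclass(frozen=True)
class PipelineConfig:
    """Operating point of the full pipeline; defaults are the published ones
    (window 7, max gap 13, 80 topics, five folds, 10 topics and up to 20
    words per class for signature extraction)."""

    window: int = profiles.DEFAULT_WINDOW
    d_max: int = features.DEFAULT_MAX_GAP
    topics: int = 80
    folds: int = 5
    topics_per_class: int = signatures.DEFAULT_TOPICS_PER_CLASS
    words_per_topic: int = signatures.DEFAULT_WORDS_PER_TOPIC
    mode: str = "plsi"  # "plsi" | "signatures"
    seed: int = 0
    plsi_max_iter: int = plsi.DEFAULT_MAX_ITER
    plsi_tol: float = plsi.DEFAULT_TOL
    svm_grid: tuple[tuple[float, float], ...] = tuple(DEFAULT_SVM_GRID)
    svm_folds: int = 3
    pseudo_profile_fallback: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("plsi", "signatures"):
            raise ValueError(f"mode must be 'plsi' or 'signatures', got {self.mode!r}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd positive integer")
        if self.d_max < 0 or self.topics < 1 or self.folds < 2:
            raise ValueError("invalid pipeline configuration")


@dataclass(frozen=True)
class LabeledDataset:
    records: tuple[profiles.ProteinRecord, ...]
    profiles: Mapping[str, profiles.PSSMProfile]
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.id not in self.labels:
                raise ValueError(f"missing label for protein {rec.id!r}")

    def subset(self, ids: Sequence[str]) -> "LabeledDataset":
        keep = set(ids)
        recs = tuple(r for r in self.records if r.id in keep)
        return LabeledDataset(
            recs,
            {r.id: self.profiles[r.id] for r in recs if r.id in self.profiles},
            {r.id: self.labels[r.id] for r in recs},
        )


@dataclass
class FittedPipeline:
    config: PipelineConfig
    model: plsi.PLSIModel
    classifier: classify.TrainedClassifier
    signature_set: signatures.SignatureSet | None = None


def compute_feature_vectors(
    dataset_records: Sequence[profiles.ProteinRecord],
    dataset_profiles: Mapping[str, profiles.PSSMProfile],
    config: PipelineConfig,
) -> list[features.FeatureVector]:
    """Smooth every protein's profile and weight all gapped-dipeptides.

    Proteins without a profile get a substitution-matrix pseudo-profile when
    the fallback is enabled, otherwise they are reported as errors.
    """
    missing = []
    out: list[features.FeatureVector] = []
    sub = profiles.load_blosum62()
    for rec in dataset_records:
        prof = dataset_profiles.get(rec.id)
        if prof is None:
            if not config.pseudo_profile_fallback:
                missing.append(rec.id)
                continue
            prof = profiles.pseudo_profile(rec, sub)
        smoothed = profiles.smooth_profile(prof, config.window)
        out.append(features.build_feature_vector(smoothed, config.d_max))
    if missing:
        raise FileNotFoundError(
            f"no profile for proteins {missing} and pseudo-profile fallback is disabled"
        )
    return out


def fit_pipeline(dataset: LabeledDataset, config: PipelineConfig) -> FittedPipeline:
    """Train PLSI (and, in signatures mode, the signature set) plus the SVM."""
    vectors = compute_feature_vectors(dataset.records, dataset.profiles, config)
    corpus = plsi.Corpus.from_feature_vectors(vectors)
    model = plsi.train_plsi(
        corpus,
        K=config.topics,
        max_iter=config.plsi_max_iter,
        tol=config.plsi_tol,
        seed=config.seed,
    )
    labels = [dataset.labels[fv.protein_id] for fv in vectors]
    sig_set = None
    if config.mode == "signatures":
        prefs = signatures.compute_topic_preferences(model, dataset.labels)
        sig_set = signatures.select_signatures(
            model, prefs, config.topics_per_class, config.words_per_topic
        )
        X = np.vstack([signatures.signature_vector(fv, sig_set) for fv in vectors])
        mode_name = "signatures"
    else:
        X = model.topic_matrix()
        mode_name = "plsi_topics"
    clf = classify.tune_and_train(
        X,
        labels,
        grid=config.svm_grid,
        folds=config.svm_folds,
        seed=config.seed,
        feature_mode=mode_name,
    )
    return FittedPipeline(config, model, clf, sig_set)


def _project(fitted: FittedPipeline, fv: features.FeatureVector) -> tuple[np.ndarray, bool]:
    if fitted.config.mode == "signatures":
        vec = signatures.signature_vector(fv, fitted.signature_set)
        return vec, bool(np.any(vec > 0))
    result = plsi.fold_in(fitted.model, fv.weights)
    return result.distribution, result.in_vocabulary


def predict_pipeline(
    fitted: FittedPipeline,
    records: Sequence[profiles.ProteinRecord],
    profile_map: Mapping[str, profiles.PSSMProfile] | None = None,
) -> dict[str, dict]:
    """Per-protein prediction: class, probability and a low-confidence flag
    for proteins that shared nothing with the trained vocabulary."""
    vectors = compute_feature_vectors(records, profile_map or {}, fitted.config)
    out: dict[str, dict] = {}
    for fv in vectors:
        vec, overlap = _project(fitted, fv)
        cls, prob = classify.predict_localization(fitted.classifier, vec)
        out[fv.protein_id] = {
            "class": cls,
            "probability": prob,
            "low_confidence": not overlap,
        }
    return out
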