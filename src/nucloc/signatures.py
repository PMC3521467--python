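"""Signature mining: localization-preferred topics and their top gapped-dipeptides.

For each topic, the class preference is the mean topic weight ``P(t|d)``
over the documents of that class; a topic prefers the class whose mean is
larger, with confidence equal to the absolute between-class difference.
Per class, the highest-confidence topics are kept and each contributes its
most abundant words (largest ``P(w|t)``), deduplicated on first occurrence.
"""

from __future__ import annotations

import csv
import os
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .features import FeatureVector, GappedDipeptide
from .plsi import PLSIModel

NUCLEAR = "nuclear"
NON_NUCLEAR = "non_nuclear"
CLASSES = (NUCLEAR, NON_NUCLEAR)

DEFAULT_TOPICS_PER_CLASS = 10
DEFAULT_WORDS_PER_TOPIC = 20

#: Physicochemical grouping of the 20 standard letters (a partition).
PHYSICOCHEMICAL_GROUPS = {
    "aromatic": "FYW",
    "charged": "DEHKR",
    "nonpolar": "AIGLMV",
    "polar": "CNPQST",
}

#: Coarser 3-way summary view derived from the same letters.
BASIC_POLAR_HYDROPHOBIC_GROUPS = {
    "basic": "HKR",
    "polar": "CGNQSTY",
    "hydrophobic": "AFILMPVW",
    "acidic": "DE",
}


@dataclass(frozen=True)
class TopicPreference:
    topic: int
    mean_weight_nuclear: float
    mean_weight_non_nuclear: float

    @property
    def confidence(self) -> float:
        return abs(self.mean_weight_nuclear - self.mean_weight_non_nuclear)

    @property
    def preferred_class(self) -> str:
        return NUCLEAR if self.mean_weight_nuclear >= self.mean_weight_non_nuclear else NON_NUCLEAR


@dataclass(frozen=True)
class SignatureEntry:
    word: str
    class_label: str
    topic: int
    rank_in_topic: int
    weight: float  # P(w|t) within the source topic


@dataclass(frozen=True)
class SignatureSet:
    entries: tuple[SignatureEntry, ...]
    #: words that ranked high for both classes; kept under their first class
    cross_class_duplicates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        words = [e.word for e in self.entries]
        if len(set(words)) != len(words):
            dupes = sorted({w for w in words if words.count(w) > 1})
            raise ValueError(f"duplicate signature words: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def words(self) -> list[str]:
        return [e.word for e in self.entries]

    def for_class(self, class_label: str) -> list[SignatureEntry]:
        return [e for e in self.entries if e.class_label == class_label]


def compute_topic_preferences(model: PLSIModel, labels: Mapping[str, str]) -> list[TopicPreference]:
    """Per-topic class means of ``P(t|d)`` over the labelled training documents."""
    masks = {}
    for cls in CLASSES:
        mask = np.array([labels[doc] == cls for doc in model.documents])
        if not mask.any():
            raise ValueError(f"no documents labelled {cls!r}")
        masks[cls] = mask
    ptd = model.topic_given_doc  # (K, D)
    mean_nuc = ptd[:, masks[NUCLEAR]].mean(axis=1)
    mean_non = ptd[:, masks[NON_NUCLEAR]].mean(axis=1)
    return [TopicPreference(t, float(mean_nuc[t]), float(mean_non[t])) for t in range(model.K)]


def select_signatures(
    model: PLSIModel,
    prefs: Sequence[TopicPreference],
    topics_per_class: int = DEFAULT_TOPICS_PER_CLASS,
    words_per_topic: int = DEFAULT_WORDS_PER_TOPIC,
) -> SignatureSet:
    """Top-confidence topics per class, top-``P(w|t)`` words per topic.

    Confidence ties break toward the lower topic index; word ties break
    lexicographically.  A word already selected (for either class) is not
    re-added; cross-class repeats are recorded, not silently dropped.
    """
    if topics_per_class < 1 or words_per_topic < 1:
        raise ValueError("topics_per_class and words_per_topic must be >= 1")
    entries: list[SignatureEntry] = []
    seen: dict[str, str] = {}
    cross: list[str] = []
    vocab = np.array(model.vocabulary)
    for cls in CLASSES:
        candidates = sorted(
            (p for p in prefs if p.preferred_class == cls),
            key=lambda p: (-p.confidence, p.topic),
        )
        if len(candidates) < topics_per_class:
            warnings.warn(
                f"only {len(candidates)} topics prefer class {cls!r} "
                f"(requested {topics_per_class}); taking all"
            )
        for pref in candidates[:topics_per_class]:
            col = model.word_given_topic[:, pref.topic]
            order = sorted(range(len(vocab)), key=lambda j: (-col[j], vocab[j]))
            rank = 0
            for j in order[: max(words_per_topic * 3, words_per_topic)]:
                if rank >= words_per_topic:
                    break
                word = str(vocab[j])
                rank += 1
                if word in seen:
                    if seen[word] != cls:
                        cross.append(word)
                    continue
                seen[word] = cls
                entries.append(SignatureEntry(word, cls, pref.topic, rank, float(col[j])))
    return SignatureSet(tuple(entries), tuple(cross))


def reduce_to_signatures(fv: FeatureVector, sigs: SignatureSet) -> FeatureVector:
    """Project a feature vector onto the signature words (missing words -> 0)."""
    if not sigs.entries:
        raise ValueError("empty signature set")
    weights = {e.word: fv.weights.get(e.word, 0.0) for e in sigs.entries}
    d_max = max(fv.d_max, max(GappedDipeptide.parse(e.word).gap for e in sigs.entries))
    return FeatureVector(fv.protein_id, weights, d_max)


def signature_vector(fv: FeatureVector, sigs: SignatureSet) -> np.ndarray:
    """Dense projection of ``fv`` in signature-set order (stable)."""
    return np.array([fv.weights.get(e.word, 0.0) for e in sigs.entries], dtype=float)


def composition_profile(sigs: SignatureSet, grouping: str = "none") -> dict[str, dict[str, float]]:
    """Letter (or group) frequencies over both letters of each signature word.

    Gap digits are ignored; frequencies sum to 1 per class.  ``grouping``
    is ``"none"`` for raw letters or ``"physicochemical"`` for the 4-way
    aromatic/charged/nonpolar/polar scheme.
    """
    if grouping not in ("none", "physicochemical"):
        raise ValueError(f"unknown grouping {grouping!r}")
    letter_to_group = {}
    if grouping == "physicochemical":
        for group, letters in PHYSICOCHEMICAL_GROUPS.items():
            for letter in letters:
                letter_to_group[letter] = group
    result: dict[str, dict[str, float]] = {}
    for cls in CLASSES:
        counts: dict[str, int] = {}
        total = 0
        for entry in sigs.for_class(cls):
            gd = GappedDipeptide.parse(entry.word)
            for letter in (gd.first, gd.second):
                key = letter_to_group[letter] if letter_to_group else letter
                counts[key] = counts.get(key, 0) + 1
                total += 1
        if total:
            result[cls] = {k: v / total for k, v in sorted(counts.items())}
    return result


def write_signature_tsv(sigs: SignatureSet, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["word", "class", "topic", "rank", "weight"])
        for e in sigs.entries:
            writer.writerow([e.word, e.class_label, e.topic, e.rank_in_topic, repr(e.weight)])


def load_signature_tsv(path: str | os.PathLike) -> SignatureSet:
    """Load a signature list; hand-curated lists may omit topic/rank/weight columns."""
    entries: list[SignatureEntry] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:2] != ["word", "class"]:
            raise ValueError(f"unexpected header {header!r}")
        for row in reader:
            if not row:
                continue
            word, cls = row[0], row[1]
            if cls not in CLASSES:
                raise ValueError(f"unknown class label {cls!r}")
            GappedDipeptide.parse(word)  # validate
            topic = int(row[2]) if len(row) > 2 else -1
            rank = int(row[3]) if len(row) > 3 else len(entries) + 1
            weight = float(row[4]) if len(row) > 4 else 0.0
            entries.append(SignatureEntry(word, cls, topic, rank, weight))
    return SignatureSet(tuple(entries))


def load_reference_signatures() -> SignatureSet:
    """The packaged curated signature list (183 nuclear + 183 non-nuclear words)."""
    ref = resources.files("nucloc.data").joinpath("reference_signatures.tsv")
    with resources.as_file(ref) as path:
        return load_signature_tsv(path)
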