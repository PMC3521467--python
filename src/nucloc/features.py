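"""Gapped-dipeptide features weighted from smoothed profiles.

A gapped-dipeptide ``AdB`` is the pattern "amino acid A, then d intervening
residues, then amino acid B".  Its weight in a protein is the sum, over every
anchored position pair ``(i, i+d+1)``, of the product of the normalized
smoothed-profile entries for A at ``i`` and B at ``i+d+1`` — the sum runs over
all positions, not only those whose sequence letters literally spell A and B.
The per-protein weight vector is finally max-scaled into [0, 1].
"""

from __future__ import annotations

import csv
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .profiles import PSSM_COLUMNS, STANDARD_AA, SmoothedProfile

DEFAULT_MAX_GAP = 13

_WORD_RE = re.compile(r"^([A-Z])(\d{1,3})([A-Z])$")

# permutation taking a PSSM-ordered 20-vector to alphabetical letter order
_TO_ALPHA = np.array([PSSM_COLUMNS.index(a) for a in STANDARD_AA])


@dataclass(frozen=True, order=True)
class GappedDipeptide:
    """Word ``AdB``: letters ``first`` and ``second`` separated by ``gap`` residues."""

    first: str
    gap: int
    second: str

    def __post_init__(self) -> None:
        if self.first not in STANDARD_AA or self.second not in STANDARD_AA:
            raise ValueError(f"non-standard letters in word {self.first}{self.gap}{self.second}")
        if self.gap < 0:
            raise ValueError(f"gap must be >= 0, got {self.gap}")

    def __str__(self) -> str:
        return f"{self.first}{self.gap}{self.second}"

    @classmethod
    def parse(cls, word: str) -> "GappedDipeptide":
        m = _WORD_RE.match(word)
        if not m:
            raise ValueError(f"malformed gapped-dipeptide {word!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3))


def word_order(d_max: int) -> list[str]:
    """Stable dense ordering: first letter A..Y, then gap ascending, then second letter."""
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    return [f"{a}{d}{b}" for a in STANDARD_AA for d in range(d_max + 1) for b in STANDARD_AA]


def feature_dimension(d_max: int) -> int:
    """Dense feature-space size: 20 * 20 * (d_max + 1)."""
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    return 400 * (d_max + 1)


def enumerate_term_positions(n: int, d: int) -> list[tuple[int, int]]:
    """1-based anchored pairs ``(i, i+d+1)`` for i = 1 .. n-(d+1); empty if none fit."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if d < 0:
        raise ValueError("d must be >= 0")
    return [(i, i + d + 1) for i in range(1, n - d)]


@dataclass(frozen=True)
class FeatureVector:
    """Sparse per-protein word weights in [0, 1] over gaps 0..d_max."""

    protein_id: str
    weights: Mapping[str, float]
    d_max: int

    def __post_init__(self) -> None:
        for word, value in self.weights.items():
            gd = GappedDipeptide.parse(word)
            if gd.gap > self.d_max:
                raise ValueError(f"word {word} exceeds d_max={self.d_max}")
            if not (0.0 <= value <= 1.0 + 1e-12):
                raise ValueError(f"weight of {word} outside [0, 1]: {value}")

    @property
    def dimension(self) -> int:
        return feature_dimension(self.d_max)

    def dense(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Dense vector in the given (default: canonical) word order."""
        order = word_order(self.d_max) if order is None else order
        return np.array([self.weights.get(w, 0.0) for w in order], dtype=float)


def weight_gapped_dipeptide(profile: SmoothedProfile, word: GappedDipeptide) -> float:
    """Unnormalized word weight: sum over i of sf(i, A) * sf(i+d+1, B)."""
    d = word.gap
    a = profile.column(word.first)
    b = profile.column(word.second)
    if profile.n <= d + 1:
        return 0.0
    return float(np.dot(a[: profile.n - d - 1], b[d + 1 :]))


def raw_weight_matrix(profile: SmoothedProfile, d_max: int) -> np.ndarray:
    """All unnormalized weights at once, shaped (d_max+1, 20, 20) in alphabetical letter order."""
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    s = profile.normalized[:, _TO_ALPHA]
    n = profile.n
    out = np.zeros((d_max + 1, 20, 20), dtype=float)
    for d in range(d_max + 1):
        if n > d + 1:
            out[d] = s[: n - d - 1].T @ s[d + 1 :]
    return out


def build_feature_vector(profile: SmoothedProfile, d_max: int = DEFAULT_MAX_GAP) -> FeatureVector:
    """Compute every word weight for gaps 0..d_max and max-scale into [0, 1].

    An all-zero weight vector (possible only for n <= 1 proteins) is left
    as-is; zero weights are omitted from the sparse mapping.
    """
    raw = raw_weight_matrix(profile, d_max)
    peak = raw.max()
    if peak > 0:
        raw = raw / peak
    weights: dict[str, float] = {}
    for ai, a in enumerate(STANDARD_AA):
        for d in range(d_max + 1):
            for bi, b in enumerate(STANDARD_AA):
                v = raw[d, ai, bi]
                if v > 0.0:
                    weights[f"{a}{d}{b}"] = float(v)
    return FeatureVector(profile.protein_id, weights, d_max)


def write_sparse_tsv(vectors: Iterable[FeatureVector], path: str | os.PathLike) -> None:
    """Write (protein_id, word, weight) triples, one per line."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "word", "weight"])
        for fv in vectors:
            for word in sorted(fv.weights):
                writer.writerow([fv.protein_id, word, repr(fv.weights[word])])


def read_sparse_tsv(path: str | os.PathLike, d_max: int = DEFAULT_MAX_GAP) -> list[FeatureVector]:
    by_protein: dict[str, dict[str, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["protein_id", "word", "weight"]:
            raise ValueError(f"unexpected header {header!r}")
        for pid, word, weight in reader:
            by_protein.setdefault(pid, {})[word] = float(weight)
    return [FeatureVector(pid, w, d_max) for pid, w in by_protein.items()]


def feature_matrix(vectors: Sequence[FeatureVector], order: Sequence[str] | None = None) -> np.ndarray:
    """Stack dense vectors row-wise; all vectors must share d_max."""
    if not vectors:
        raise ValueError("no feature vectors given")
    d_max = vectors[0].d_max
    if any(fv.d_max != d_max for fv in vectors):
        raise ValueError("feature vectors disagree on d_max")
    order = word_order(d_max) if order is None else list(order)
    index = {w: j for j, w in enumerate(order)}
    mat = np.zeros((len(vectors), len(order)), dtype=float)
    for i, fv in enumerate(vectors):
        for word, value in fv.weights.items():
            j = index.get(word)
            if j is not None:
                mat[i, j] = value
    return mat
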