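"""Deterministic synthetic data: labelled proteins with planted motifs and
aspect-model corpora with known ground truth.

The motif alphabets are test fixtures, not biological claims: "nuclear"
proteins optionally carry a short basic (K/R/H-rich) run, "non-nuclear"
proteins a hydrophobic (L/I/V/F/M) run, both at a uniform random position.
Everything is a pure function of its configuration, seed included.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .features import FeatureVector
from .pipeline import LabeledDataset
from .plsi import Corpus
from .profiles import STANDARD_AA, ProteinRecord, load_blosum62, pseudo_profile
from .signatures import NON_NUCLEAR, NUCLEAR

DEFAULT_MOTIFS = {
    NUCLEAR: {"K": 0.5, "R": 0.35, "H": 0.15},
    NON_NUCLEAR: {"L": 0.4, "I": 0.2, "V": 0.15, "F": 0.15, "M": 0.1},
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_nuclear: int = 100
    n_non_nuclear: int = 100
    length_range: tuple[int, int] = (60, 120)
    signal_strength: float = 1.0  # probability a protein carries its class motif
    motif_length_range: tuple[int, int] = (8, 12)
    motifs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MOTIFS.items()}
    )
    background: Mapping[str, float] | None = None  # None -> uniform over 20 letters
    profile_noise: float = 0.0  # stddev of Gaussian noise added to pseudo-profile rows
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclear < 1 or self.n_non_nuclear < 1:
            raise ValueError("need at least one protein per class")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ValueError("invalid length range")
        if self.motif_length_range[0] > self.motif_length_range[1]:
            raise ValueError("invalid motif length range")
        if self.length_range[0] < self.motif_length_range[1]:
            raise ValueError("minimum protein length is shorter than the longest motif")
        for cls in (NUCLEAR, NON_NUCLEAR):
            if cls not in self.motifs or not self.motifs[cls]:
                raise ValueError(f"missing motif alphabet for class {cls!r}")


def _draw_letters(rng: np.random.Generator, weights: Mapping[str, float], size: int) -> str:
    letters = sorted(weights)
    probs = np.array([weights[a] for a in letters], dtype=float)
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=size, p=probs))


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Labelled proteins with class motifs planted at rate ``signal_strength``,
    plus pseudo-profiles (optionally perturbed by seeded Gaussian noise)."""
    rng = np.random.default_rng(config.seed)
    background = config.background or {a: 1.0 for a in STANDARD_AA}
    sub = load_blosum62()
    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    profile_map = {}
    specs = [(NUCLEAR, i, config.n_nuclear) for i in range(config.n_nuclear)]
    specs += [(NON_NUCLEAR, i, config.n_non_nuclear) for i in range(config.n_non_nuclear)]
    for cls, i, _total in specs:
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = list(_draw_letters(rng, background, length))
        if rng.random() < config.signal_strength:
            m = int(rng.integers(config.motif_length_range[0], config.motif_length_range[1] + 1))
            motif = _draw_letters(rng, config.motifs[cls], m)
            start = int(rng.integers(0, length - m + 1))
            seq[start : start + m] = motif
        pid = f"{'nuc' if cls == NUCLEAR else 'non'}_{i:04d}"
        rec = ProteinRecord(pid, "".join(seq))
        records.append(rec)
        labels[pid] = cls
        prof = pseudo_profile(rec, sub)
        if config.profile_noise > 0:
            noisy = prof.matrix + rng.normal(0.0, config.profile_noise, prof.matrix.shape)
            prof = type(prof)(pid, noisy)
        profile_map[pid] = prof
    return LabeledDataset(tuple(records), profile_map, labels)


def write_dataset(dataset: LabeledDataset, outdir: str | os.PathLike) -> None:
    """Emit the pipeline's input contract: FASTA + labels TSV + profile dir."""
    outdir = str(outdir)
    os.makedirs(os.path.join(outdir, "profiles"), exist_ok=True)
    with open(os.path.join(outdir, "sequences.fasta"), "w") as fh:
        for rec in dataset.records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
    with open(os.path.join(outdir, "labels.tsv"), "w") as fh:
        for rec in dataset.records:
            fh.write(f"{rec.id}\t{dataset.labels[rec.id]}\n")
    header = " ".join(list("ARNDCQEGHILKMFPSTWYV"))
    for rec in dataset.records:
        prof = dataset.profiles[rec.id]
        path = os.path.join(outdir, "profiles", f"{rec.id}.pssm")
        with open(path, "w") as fh:
            fh.write("\nLast position-specific scoring matrix computed\n")
            fh.write(f"    {header}\n")
            for i, letter in enumerate(rec.sequence, start=1):
                row = " ".join(f"{v:.0f}" for v in prof.matrix[i - 1])
                fh.write(f"{i:5d} {letter} {row} 0 0\n")


def generate_aspect_corpus(
    K_true: int,
    n_docs: int,
    vocab_size: int,
    weight_per_doc: float,
    seed: int = 0,
    mode: str = "expected",
    alpha_word: float = 0.1,
    alpha_topic: float = 0.5,
) -> tuple[Corpus, dict]:
    """Corpus drawn from a known aspect model, with the ground truth returned.

    ``expected`` mode emits noise-free expected weights
    ``weight_per_doc * sum_t P(w|t) P(t|d)``; ``sampled`` mode draws integer
    counts multinomially with total ``weight_per_doc`` per document.
    """
    if K_true < 1:
        raise ValueError("K_true must be >= 1")
    if vocab_size < K_true:
        raise ValueError("vocab_size must be >= K_true")
    if n_docs < 1 or weight_per_doc <= 0:
        raise ValueError("need n_docs >= 1 and positive weight_per_doc")
    if mode not in ("expected", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    p_wt = rng.dirichlet(np.full(vocab_size, alpha_word), size=K_true).T  # (W, K)
    p_td = rng.dirichlet(np.full(K_true, alpha_topic), size=n_docs).T  # (K, D)
    p_wd = p_wt @ p_td  # (W, D), columns sum to 1
    if mode == "expected":
        counts = (weight_per_doc * p_wd).T
    else:
        total = int(round(weight_per_doc))
        counts = np.vstack(
            [rng.multinomial(total, p_wd[:, d] / p_wd[:, d].sum()) for d in range(n_docs)]
        ).astype(float)
    docs = [f"doc{d:04d}" for d in range(n_docs)]
    vocab = [f"w{j:04d}" for j in range(vocab_size)]
    corpus = Corpus(docs, vocab, counts)
    truth = {"word_given_topic": p_wt, "topic_given_doc": p_td, "seed": seed}
    return corpus, truth
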