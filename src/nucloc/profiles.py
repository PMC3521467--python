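"""Sequence profiles: FASTA input, PSSM parsing, pseudo-profiles, smoothing.

A protein of ``n`` residues is scored by an ``n x 20`` position-specific
scoring matrix (PSSM) of substitution log-likelihoods.  Profiles are either
parsed from PSI-BLAST ASCII output or, when none is available, synthesised
from a substitution matrix so the whole pipeline runs offline.  Each profile
row is then smoothed by summing the ``w`` surrounding rows (zero-padding at
the termini) and squashed into (0, 1) with a logistic function.

Positions in error messages are 1-based.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

#: Column order of the PSI-BLAST ASCII PSSM log-likelihood block.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"

#: The 20 standard amino-acid letters, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity codes mapped onto a standard residue for profile purposes.
#: Anything else (X, J, O, ...) has no standard equivalent: such positions
#: keep their profile rows but never form gapped-dipeptide letters.
AMBIGUITY_MAP = {"B": "D", "Z": "E", "U": "C"}

#: PSI-BLAST settings recorded for users who compute real profiles themselves;
#: nothing in this package invokes PSI-BLAST.
PSIBLAST_DEFAULTS = {"iterations": 3, "evalue": 1e-3, "database": "nr"}

DEFAULT_WINDOW = 7


class PSSMParseError(ValueError):
    """Raised when PSI-BLAST ASCII PSSM text cannot be parsed."""


class SequenceMismatchError(ValueError):
    """Raised when a profile's residue column disagrees with the expected sequence."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")

    @property
    def n(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PSSMProfile:
    """An ``n x 20`` log-likelihood matrix in :data:`PSSM_COLUMNS` order."""

    protein_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 20:
            raise ValueError(
                f"profile {self.protein_id!r}: expected an n x 20 matrix, got {m.shape}"
            )
        if not np.all(np.isfinite(m)):
            raise ValueError(f"profile {self.protein_id!r}: non-finite entries")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SmoothedProfile:
    """Window-summed and logistic-normalized view of a PSSM.

    ``raw_smoothed[i]`` is the sum of source rows ``i-(w-1)/2 .. i+(w-1)/2``
    with out-of-range rows treated as zero vectors; ``normalized`` is the
    entrywise logistic of ``raw_smoothed`` and lies strictly inside (0, 1).
    """

    protein_id: str
    window: int
    raw_smoothed: np.ndarray
    normalized: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.raw_smoothed.shape[0]

    def column(self, letter: str) -> np.ndarray:
        """Normalized profile column for one amino-acid letter."""
        return self.normalized[:, PSSM_COLUMNS.index(letter)]


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA; ids are the first whitespace token."""
    records = [ProteinRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ids in FASTA: {dupes}")
    return records


def logistic_normalize(x):
    """Map a finite log-likelihood (or array) into (0, 1) via 1/(1+exp(-x))."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("logistic_normalize requires finite input")
    out = 1.0 / (1.0 + np.exp(-arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def parse_pssm(text: str, expected_sequence: str) -> PSSMProfile:
    """Parse the 20-column log-likelihood block of a PSI-BLAST ASCII PSSM.

    The residue letters embedded in the profile must match
    ``expected_sequence`` (ambiguity codes are compared verbatim).
    """
    if not expected_sequence:
        raise ValueError("expected_sequence must be non-empty")
    lines = text.splitlines()
    header_cols: str | None = None
    rows: list[list[float]] = []
    residues: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if header_cols is None and len(tokens) >= 20 and all(
            len(t) == 1 and t.isalpha() for t in tokens[:20]
        ):
            header_cols = "".join(tokens[:20]).upper()
            continue
        if tokens[0].isdigit() and len(tokens) >= 22 and len(tokens[1]) == 1 and tokens[1].isalpha():
            try:
                values = [float(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise PSSMParseError(f"line {lineno}: non-numeric score ({exc})") from None
            expected_index = len(rows) + 1
            if int(tokens[0]) != expected_index:
                raise PSSMParseError(
                    f"line {lineno}: position {tokens[0]} out of order (expected {expected_index})"
                )
            residues.append(tokens[1].upper())
            rows.append(values)
    if not rows:
        raise PSSMParseError("no PSSM rows found in input")
    matrix = np.array(rows, dtype=float)
    if header_cols is not None:
        if sorted(header_cols) != sorted(PSSM_COLUMNS):
            raise PSSMParseError(f"unexpected column alphabet {header_cols!r}")
        if header_cols != PSSM_COLUMNS:
            order = [header_cols.index(a) for a in PSSM_COLUMNS]
            matrix = matrix[:, order]
    profile_seq = "".join(residues)
    if profile_seq != expected_sequence.upper():
        for pos, (a, b) in enumerate(zip(profile_seq, expected_sequence.upper()), start=1):
            if a != b:
                raise SequenceMismatchError(
                    f"profile residue {a!r} != expected {b!r} at position {pos}"
                )
        raise SequenceMismatchError(
            f"profile has {len(profile_seq)} residues, expected {len(expected_sequence)}"
        )
    return PSSMProfile("", matrix)


def load_blosum62() -> np.ndarray:
    """BLOSUM62 scores restricted to the 20 standard letters plus a row lookup."""
    return substitution_matrices.load("BLOSUM62")


def pseudo_profile(record: ProteinRecord, substitution_matrix=None) -> PSSMProfile:
    """Deterministic stand-in for a PSI-BLAST profile.

    Row ``i`` is the substitution-matrix row of residue ``i`` (BLOSUM62 by
    default), after ambiguity mapping.  Raises ``ValueError`` naming the
    1-based position of any residue that has no row in the matrix.
    """
    sub = substitution_matrix if substitution_matrix is not None else load_blosum62()
    alphabet = getattr(sub, "alphabet", None)
    rows = np.empty((record.n, 20), dtype=float)
    for i, letter in enumerate(record.sequence.upper()):
        mapped = AMBIGUITY_MAP.get(letter, letter)
        if alphabet is not None and mapped not in alphabet:
            raise ValueError(
                f"protein {record.id!r}: residue {letter!r} at position {i + 1} "
                "has no substitution-matrix row"
            )
        try:
            rows[i] = [sub[mapped][a] for a in PSSM_COLUMNS]
        except (KeyError, IndexError):
            raise ValueError(
                f"protein {record.id!r}: residue {letter!r} at position {i + 1} "
                "has no substitution-matrix row"
            ) from None
    return PSSMProfile(record.id, rows)


def smooth_profile(pssm: PSSMProfile, w: int = DEFAULT_WINDOW) -> SmoothedProfile:
    """Sum each row with its ``(w-1)/2`` neighbours on both sides, then squash.

    Out-of-range neighbours at the termini contribute zero vectors, so with
    ``w=1`` the raw smoothed matrix equals the source matrix exactly.
    """
    if not isinstance(w, (int, np.integer)) or w < 1 or w % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {w!r}")
    half = (w - 1) // 2
    n = pssm.n
    padded = np.zeros((n + 2 * half, 20), dtype=float)
    padded[half : half + n] = pssm.matrix
    csum = np.vstack([np.zeros((1, 20)), np.cumsum(padded, axis=0)])
    raw = csum[w:] - csum[:-w]  # raw[i] = sum of padded rows i..i+w-1
    return SmoothedProfile(pssm.protein_id, w, raw, logistic_normalize(raw))


def load_profile_directory(
    directory: str | os.PathLike, records: Sequence[ProteinRecord]
) -> dict[str, PSSMProfile]:
    """Load ``<id>.pssm`` files for the given records; missing files are skipped."""
    profiles: dict[str, PSSMProfile] = {}
    for rec in records:
        path = os.path.join(str(directory), f"{rec.id}.pssm")
        if os.path.exists(path):
            with open(path) as fh:
                parsed = parse_pssm(fh.read(), rec.sequence)
            profiles[rec.id] = PSSMProfile(rec.id, parsed.matrix)
    return profiles
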