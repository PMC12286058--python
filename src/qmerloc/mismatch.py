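"""Exact and inexact (mismatch) q-mer profiles over the RNA alphabet.

A q-mer is a length-q window of an RNA sequence S = S1...Sn, Si in
{A, C, G, U}.  The exact q-mer profile counts, for each of the 4^q
possible q-mers, the number of windows of S equal to it (the spectrum
feature map).  The (q, k)-mismatch profile relaxes the match: feature Qi
counts the windows whose Hamming distance to Qi is at most k, so a
window contributes to every q-mer in its Hamming ball.  With k = 0 the
two profiles coincide; for k > 0 the mismatch profile is pointwise >=
the exact one.  Both are normalized by the number of valid (all-ACGU)
windows of the sequence, so exact profiles sum to 1 and mismatch
profiles sum to the Hamming-ball size.

The Hamming ball B(q, k) around any q-mer over a 4-letter alphabet has
size sum_{i=0..k} C(q, i) * 3^i, independent of the center.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache
from math import comb

import numpy as np

ALPHABET = "ACGU"
_CODE = {c: i for i, c in enumerate(ALPHABET)}

# uppercase + DNA->RNA; anything not in ACGU maps to itself (handled as
# an invalid window downstream)
_CANON = str.maketrans("acgtuACGT", "ACGUUACGU")


def canonicalize_sequence(raw: str) -> str:
    """Uppercase a nucleotide string and map T to U.

    Ambiguity symbols (N, R, ...) are preserved; windows containing them
    are skipped during profiling rather than invalidating the sequence.
    """
    if not raw:
        raise ValueError("empty sequence")
    return raw.translate(_CANON)


@dataclass(frozen=True)
class SequenceRecord:
    """One transcript: gene/transcript accessions and its RNA string."""

    gene_id: str
    transcript_id: str
    sequence: str

    def __post_init__(self):
        if not self.gene_id or not self.transcript_id:
            raise ValueError("gene_id and transcript_id must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


def ball_size(q: int, k: int) -> int:
    """Size of the Hamming ball of radius k around a q-mer: sum C(q,i)*3^i."""
    return sum(comb(q, i) * 3**i for i in range(k + 1))


@dataclass(frozen=True)
class QmerSpace:
    """The ordered universe of the 4^q q-mers for a (q, k) model.

    Indexing is lexicographic with A < C < G < U, i.e. a q-mer is read as
    a base-4 number with A=0, C=1, G=2, U=3.  The constraint k <= q//2
    follows the convention that at least half the positions must match;
    pass ``allow_large_k=True`` to lift it.
    """

    q: int
    k: int = 0
    allow_large_k: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.q < 1:
            raise ValueError(f"q must be >= 1, got {self.q}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if self.k > self.q // 2 and not self.allow_large_k:
            raise ValueError(
                f"k={self.k} exceeds floor(q/2)={self.q // 2}; "
                "pass allow_large_k=True to override"
            )

    @property
    def size(self) -> int:
        return 4**self.q

    @property
    def ball(self) -> int:
        return ball_size(self.q, self.k)

    def index(self, qmer: str) -> int:
        if len(qmer) != self.q:
            raise ValueError(f"expected a {self.q}-mer, got {qmer!r}")
        idx = 0
        for c in qmer:
            idx = idx * 4 + _CODE[c]
        return idx

    def qmer(self, index: int) -> str:
        if not 0 <= index < self.size:
            raise IndexError(index)
        out = []
        for _ in range(self.q):
            out.append(ALPHABET[index % 4])
            index //= 4
        return "".join(reversed(out))


def enumerate_qmers(q: int) -> list[str]:
    """All 4^q q-mers in lexicographic order (A < C < G < U)."""
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=q)]


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def hamming_ball(center: str, k: int, allow_large_k: bool = False) -> set[str]:
    """All q-mers within Hamming distance k of ``center`` (inclusive)."""
    q = len(center)
    space = QmerSpace(q, k, allow_large_k=allow_large_k)
    return {space.qmer(i) for i in _ball_indices(space.index(center), q, k)}


@lru_cache(maxsize=65536)
def _ball_indices(code: int, q: int, k: int) -> np.ndarray:
    """Indices of all q-mers within distance k of the q-mer with index ``code``.

    Enumerates each member exactly once by scanning positions left to
    right and either keeping the digit or substituting one of the three
    alternatives while substitution budget remains.
    """
    digits = np.empty(q, dtype=np.int64)
    c = code
    for i in range(q - 1, -1, -1):
        digits[i] = c % 4
        c //= 4
    out: list[int] = []

    def rec(pos: int, remaining: int, acc: int) -> None:
        if pos == q:
            out.append(acc)
            return
        d = int(digits[pos])
        rec(pos + 1, remaining, acc * 4 + d)
        if remaining:
            for s in range(4):
                if s != d:
                    rec(pos + 1, remaining - 1, acc * 4 + s)

    rec(0, k, 0)
    return np.array(sorted(out), dtype=np.int64)


@dataclass
class FeatureProfile:
    """A per-sequence q-mer feature vector FM(S) = {Qi: fi}.

    ``values`` has length 4^q in the lexicographic q-mer order of
    ``space``.  ``total_exact_windows`` is the number of all-ACGU windows
    of the sequence and is the normalization denominator for both exact
    and mismatch kinds.
    """

    space: QmerSpace
    values: np.ndarray
    kind: str  # "exact" | "mismatch"
    normalized: bool = False
    total_exact_windows: int = 0
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (self.space.size,):
            raise ValueError(
                f"values must have length {self.space.size}, got {self.values.shape}"
            )

    @property
    def is_degenerate(self) -> bool:
        """True when the sequence had no valid window (n < q or all ambiguous)."""
        return self.total_exact_windows == 0

    def value_at(self, qmer: str) -> float:
        return float(self.values[self.space.index(qmer)])


def _window_codes(sequence: str, q: int) -> np.ndarray:
    """Base-4 codes of every valid (all-ACGU) q-length window, in order."""
    n = len(sequence)
    if n < q:
        return np.empty(0, dtype=np.int64)
    codes = np.array([_CODE.get(c, -1) for c in sequence], dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, q)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(q - 1, -1, -1, dtype=np.int64)
    return win[valid] @ powers


def _as_sequence(seq) -> tuple[str, str]:
    if isinstance(seq, SequenceRecord):
        return seq.sequence, seq.transcript_id
    return seq, ""


def exact_profile(seq, q: int) -> FeatureProfile:
    """Exact q-mer count profile; windows with non-ACGU symbols are skipped.

    A sequence shorter than q yields an all-zero profile flagged
    degenerate (total_exact_windows = 0) rather than an error.
    """
    s, label = _as_sequence(seq)
    space = QmerSpace(q)
    codes = _window_codes(s, q)
    values = np.bincount(codes, minlength=space.size).astype(np.int64)
    return FeatureProfile(space, values, "exact",
                          total_exact_windows=int(codes.size), label=label)


def mismatch_profile(seq, q: int, k: int, allow_large_k: bool = False) -> FeatureProfile:
    """(q, k)-mismatch profile: feature i counts windows within distance k of q-mer i.

    Computed by enumerating the Hamming ball of each *distinct* window
    once and scattering its exact count into the ball members, i.e.
    O(distinct windows x B(q, k)) instead of the naive O(4^q x windows).
    """
    s, label = _as_sequence(seq)
    space = QmerSpace(q, k, allow_large_k=allow_large_k)
    codes = _window_codes(s, q)
    values = np.zeros(space.size, dtype=np.int64)
    if codes.size:
        uniq, counts = np.unique(codes, return_counts=True)
        for code, count in zip(uniq, counts):
            values[_ball_indices(int(code), q, k)] += count
    return FeatureProfile(space, values, "mismatch",
                          total_exact_windows=int(codes.size), label=label)


def mismatch_profile_oracle(seq, q: int, k: int,
                            allow_large_k: bool = False) -> FeatureProfile:
    """Reference (q, k)-mismatch profile via all pairwise Hamming distances.

    Loops over all 4^q features against all windows (the naive feature-map
    construction); intended as an independent cross-check of
    :func:`mismatch_profile` at small q.
    """
    s, label = _as_sequence(seq)
    space = QmerSpace(q, k, allow_large_k=allow_large_k)
    codes = _window_codes(s, q)
    if codes.size == 0:
        values = np.zeros(space.size, dtype=np.int64)
    else:
        # digit matrices: features (4^q, q) vs windows (W, q)
        idx = np.arange(space.size, dtype=np.int64)
        feat_digits = np.empty((space.size, q), dtype=np.int64)
        rem = idx.copy()
        for pos in range(q - 1, -1, -1):
            feat_digits[:, pos] = rem % 4
            rem //= 4
        win_digits = np.empty((codes.size, q), dtype=np.int64)
        rem = codes.copy()
        for pos in range(q - 1, -1, -1):
            win_digits[:, pos] = rem % 4
            rem //= 4
        dist = (feat_digits[:, None, :] != win_digits[None, :, :]).sum(axis=2)
        values = (dist <= k).sum(axis=1).astype(np.int64)
    return FeatureProfile(space, values, "mismatch",
                          total_exact_windows=int(codes.size), label=label)


def normalize_profile(profile: FeatureProfile) -> FeatureProfile:
    """Divide every value by the sequence's exact-window count.

    The same denominator is used for exact and mismatch profiles, so a
    normalized exact profile sums to 1 and a normalized (q, k)-mismatch
    profile of an all-ACGU sequence sums to the ball size B(q, k).
    """
    if profile.normalized:
        raise ValueError("profile is already normalized")
    if profile.total_exact_windows == 0:
        raise ValueError(
            f"cannot normalize degenerate profile (no valid windows)"
            + (f" for sequence {profile.label!r}" if profile.label else "")
        )
    return replace(profile,
                   values=profile.values / profile.total_exact_windows,
                   normalized=True)
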