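"""Oligonucleotide usage patterns (OUPs) and window-level compositional statistics.

A prokaryotic replicon carries a genome-wide tetranucleotide "signature":
the ranking of all 4-mer words by their frequency is stable along the
chromosome and differs between taxa.  Horizontally acquired segments keep,
for a while, the signature of their donor.  This module provides the
primitives that the rest of the package is built on:

* tetranucleotide counting (optionally summed over both strands),
* the OUP itself — the full word set ordered by frequency,
* a rank-displacement similarity between two OUPs on a 0–100% scale
  (normalised Spearman footrule: 100 for identical orderings, 0 for
  exactly reversed orderings),
* per-window statistics D, RV, GRV and V = GRV/RV used by the island
  scanner: D measures how far a window's OUP sits from the whole-replicon
  OUP (normalised so a typical window scores about 1), RV is the window's
  internally normalised word-count variance, GRV the globally normalised
  one.  In native DNA V stays near 1; inside a foreign insert D and V both
  rise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

K = 4
BASES = "ACGT"

__all__ = [
    "StrandPolicy",
    "WordCounts",
    "OUPattern",
    "WindowStats",
    "GenomeModel",
    "count_tetramers",
    "build_pattern",
    "pattern_similarity",
    "pattern_distance",
    "window_statistics",
    "sequence_pattern",
]


class StrandPolicy(str, Enum):
    """How 4-mers are counted.

    ``DIRECT`` counts the given strand only (256 words).
    ``BOTH_STRANDS_SUMMED`` counts each word together with its reverse
    complement, collapsing the alphabet to 136 strand-symmetric classes
    (120 complementary pairs + 16 palindromes); patterns then do not
    depend on which strand was sequenced.
    """

    DIRECT = "direct"
    BOTH_STRANDS_SUMMED = "both_strands_summed"


# ---------------------------------------------------------------------------
# static word tables
# ---------------------------------------------------------------------------

def _word_of(idx: int) -> str:
    return "".join(BASES[(idx >> (2 * (3 - k))) & 3] for k in range(K))


def _revcomp_index(idx: int) -> int:
    out = 0
    for _ in range(K):
        out = (out << 2) | (3 - (idx & 3))
        idx >>= 2
    return out


_RC = np.array([_revcomp_index(i) for i in range(256)], dtype=np.int64)
_CANON256 = np.minimum(np.arange(256), _RC)
_CANON_IDX = np.unique(_CANON256)                      # 136 canonical word indices
_CLASS_OF = np.searchsorted(_CANON_IDX, _CANON256)     # word index -> class index

WORDS_DIRECT: tuple[str, ...] = tuple(_word_of(i) for i in range(256))
WORDS_COLLAPSED: tuple[str, ...] = tuple(_word_of(i) for i in _CANON_IDX)

# character code table: ACGT(U) -> 0..3, IUPAC ambiguity -> -1, else invalid
_CODE = np.full(256, -2, dtype=np.int64)
for _i, _c in enumerate(BASES):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
_CODE[ord("U")] = _CODE[ord("u")] = 3
for _c in "RYSWKMBDHVN":
    _CODE[ord(_c)] = _CODE[ord(_c.lower())] = -1

# per-word mononucleotide composition, used for zero-order expectations
_DIGITS = np.array(
    [[(i >> (2 * (3 - k))) & 3 for k in range(K)] for i in range(256)],
    dtype=np.int64,
)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WordCounts:
    """Tetranucleotide counts of one sequence under one strand policy.

    ``words`` is the word set in lexicographic order (canonical class
    representatives under the collapsed policy); ``counts`` aligns with it.
    4-mer windows containing an ambiguous base are skipped, not imputed.
    """

    words: tuple[str, ...]
    counts: np.ndarray
    total_words: int
    mono_freqs: np.ndarray          # ACGT frequencies, strand-adjusted
    strand_policy: StrandPolicy
    sequence_length: int

    def as_dict(self) -> dict[str, int]:
        return {w: int(c) for w, c in zip(self.words, self.counts) if c}


def _encode(sequence: str) -> np.ndarray:
    if not sequence:
        raise ValueError("empty input")
    raw = np.frombuffer(sequence.encode("ascii", errors="strict"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == -2).any():
        bad = chr(int(raw[np.argmax(codes == -2)]))
        raise ValueError(f"non-IUPAC character in sequence: {bad!r}")
    return codes


def count_tetramers(
    sequence: str, policy: StrandPolicy = StrandPolicy.DIRECT
) -> WordCounts:
    """Count overlapping 4-mers of ``sequence``.

    Under ``BOTH_STRANDS_SUMMED`` every unambiguous window contributes its
    direct-strand word and the word read on the reverse strand, so the
    total is twice the number of countable windows.
    """
    policy = StrandPolicy(policy)
    codes = _encode(sequence)
    mono_counts = np.bincount(codes[codes >= 0], minlength=4).astype(np.float64)

    if codes.size >= K:
        a, b, c, d = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
        valid = (a >= 0) & (b >= 0) & (c >= 0) & (d >= 0)
        idx = ((a * 4 + b) * 4 + c) * 4 + d
        counts256 = np.bincount(idx[valid], minlength=256).astype(np.int64)
    else:
        counts256 = np.zeros(256, dtype=np.int64)

    if policy is StrandPolicy.DIRECT:
        counts = counts256
        words = WORDS_DIRECT
        mono = mono_counts
    else:
        both = counts256 + counts256[_RC]
        counts = np.zeros(len(_CANON_IDX), dtype=np.int64)
        np.add.at(counts, _CLASS_OF, both)
        words = WORDS_COLLAPSED
        # strand-symmetric mononucleotide composition
        mono = mono_counts + mono_counts[::-1]

    total = mono.sum()
    mono = mono / total if total > 0 else np.full(4, 0.25)
    return WordCounts(
        words=words,
        counts=counts,
        total_words=int(counts.sum()),
        mono_freqs=mono,
        strand_policy=policy,
        sequence_length=len(sequence),
    )


def _zero_order_class_probs(mono: np.ndarray, policy: StrandPolicy) -> np.ndarray:
    """Expected word probabilities from mononucleotide frequencies alone."""
    probs256 = mono[_DIGITS].prod(axis=1)
    if policy is StrandPolicy.DIRECT:
        return probs256
    out = np.zeros(len(_CANON_IDX))
    np.add.at(out, _CLASS_OF, probs256)
    return out


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OUPattern:
    """Full ranking of the word set, most frequent first.

    ``ranks[i]`` is the 0-based rank of ``words[i]``.  Ties are broken
    lexicographically and unobserved words sort last, so the ranking is a
    deterministic total order for any input.
    """

    words: tuple[str, ...]
    ranks: np.ndarray
    strand_policy: StrandPolicy | None = None

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def ordering(self) -> tuple[str, ...]:
        """Words listed from most to least frequent."""
        order = np.argsort(self.ranks)
        return tuple(self.words[i] for i in order)

    @classmethod
    def from_ordering(
        cls, ordered_words, strand_policy: StrandPolicy | None = None
    ) -> "OUPattern":
        ordered = tuple(ordered_words)
        words = tuple(sorted(ordered))
        pos = {w: r for r, w in enumerate(ordered)}
        ranks = np.array([pos[w] for w in words], dtype=np.int64)
        return cls(words=words, ranks=ranks, strand_policy=strand_policy)


def build_pattern(counts: WordCounts) -> OUPattern:
    """Rank the full word set by descending count, ties lexicographic."""
    # words are stored lexicographically, so a stable sort on -count is exact
    order = np.argsort(-counts.counts, kind="stable")
    ranks = np.empty(len(order), dtype=np.int64)
    ranks[order] = np.arange(len(order))
    return OUPattern(words=counts.words, ranks=ranks, strand_policy=counts.strand_policy)


def sequence_pattern(
    sequence: str, policy: StrandPolicy = StrandPolicy.DIRECT
) -> OUPattern:
    """Convenience: pattern of a sequence in one call."""
    return build_pattern(count_tetramers(sequence, policy))


def _check_compatible(a: OUPattern, b: OUPattern) -> None:
    if a.words != b.words:
        raise ValueError("incompatible patterns: word sets differ")


def pattern_similarity(a: OUPattern, b: OUPattern) -> float:
    """Rank-displacement similarity between two OUPs, in percent.

    ``100 * (1 - sum_w |rank_a(w) - rank_b(w)| / floor(n^2 / 2))``.  The
    denominator is the largest achievable displacement sum (attained by the
    reversed ordering), so identical lists score 100 and reversed lists 0.
    Symmetric, and invariant under relabelling of words.
    """
    _check_compatible(a, b)
    n = a.n_words
    rmax = (n * n) // 2
    if rmax == 0:
        return 100.0
    disp = int(np.abs(a.ranks - b.ranks).sum())
    return 100.0 * (1.0 - disp / rmax)


def pattern_distance(a: OUPattern, b: OUPattern) -> float:
    """100 minus the pattern similarity."""
    return 100.0 - pattern_similarity(a, b)


# ---------------------------------------------------------------------------
# window statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowStats:
    """Compositional statistics of one window (0-based half-open interval)."""

    start: int
    end: int
    D: float
    RV: float
    GRV: float
    V: float            # nan when RV == 0 (degenerate near-constant window)

    @property
    def degenerate(self) -> bool:
        return math.isnan(self.V)


@dataclass
class GenomeModel:
    """Whole-replicon reference for window statistics.

    ``median_window_distance`` is the median raw OUP distance of the
    replicon's own sliding windows to the whole-replicon pattern; D is the
    window distance divided by it, so "D >= 1.7" reads as "1.7x the
    genome-typical deviation".
    """

    genome_pattern: OUPattern
    genome_word_freqs: np.ndarray
    mononucleotide_freqs: np.ndarray
    strand_policy: StrandPolicy
    median_window_distance: float | None = None
    length: int = 0

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        policy: StrandPolicy = StrandPolicy.DIRECT,
        window_len: int = 8000,
        window_step: int = 2000,
    ) -> "GenomeModel":
        counts = count_tetramers(sequence, policy)
        if counts.total_words == 0:
            raise ValueError("sequence has no countable 4-mers")
        pattern = build_pattern(counts)
        freqs = counts.counts / counts.total_words
        model = cls(
            genome_pattern=pattern,
            genome_word_freqs=freqs,
            mononucleotide_freqs=counts.mono_freqs,
            strand_policy=policy,
            median_window_distance=None,
            length=len(sequence),
        )
        if len(sequence) >= window_len:
            starts = _window_starts(len(sequence), window_len, window_step)
            dists = [
                pattern_distance(
                    sequence_pattern(sequence[s : s + window_len], policy), pattern
                )
                for s in starts
            ]
            model.median_window_distance = float(np.median(dists))
        return model


def _window_starts(length: int, window_len: int, step: int) -> list[int]:
    """Window start positions; a final window is anchored at the end so the
    tail is always covered and every window has full length."""
    starts = list(range(0, length - window_len + 1, step))
    if not starts:
        return [0]
    if starts[-1] + window_len < length:
        starts.append(length - window_len)
    return starts


def window_statistics(window: str, start: int, model: GenomeModel) -> WindowStats:
    """D, RV, GRV and V for one window against a genome model.

    RV is a chi-square-style normalised variance of observed word counts
    against the window's own zero-order (mononucleotide) expectation; GRV
    uses the genome-wide word frequencies as expectation instead.  Both are
    divided by the word-set size so they are comparable across window
    lengths.  V = GRV / RV; windows sampled from the genome's own model
    give V near 1, foreign inserts push GRV (and D) up.
    """
    wc = count_tetramers(window, model.strand_policy)
    if wc.total_words == 0:
        raise ValueError("window has no countable 4-mer words")
    wp = build_pattern(wc)
    raw_d = pattern_distance(wp, model.genome_pattern)
    if model.median_window_distance is None:
        raise ValueError("genome model lacks window calibration (replicon too short)")
    med = model.median_window_distance
    if med > 0:
        d_stat = raw_d / med
    else:
        d_stat = 0.0 if raw_d == 0 else math.inf

    n = len(wc.words)
    obs = wc.counts.astype(np.float64)

    exp_local = wc.total_words * _zero_order_class_probs(wc.mono_freqs, model.strand_policy)
    mask = exp_local > 0
    rv = float((((obs - exp_local) ** 2)[mask] / exp_local[mask]).sum() / n)

    exp_global = wc.total_words * model.genome_word_freqs
    gmask = exp_global > 0
    grv = float((((obs - exp_global) ** 2)[gmask] / exp_global[gmask]).sum() / n)

    v = grv / rv if rv > 0 else math.nan
    return WindowStats(start=start, end=start + len(window), D=d_stat, RV=rv, GRV=grv, V=v)
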