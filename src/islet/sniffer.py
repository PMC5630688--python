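"""Sliding-window genomic island detection on a single replicon.

The scanner compares 8 kb windows (2 kb step) against the whole-replicon
oligonucleotide usage: a window opens an island candidate when its
normalised pattern distance D and its variance ratio V = GRV/RV both
exceed their thresholds (defaults 1.7 and 1.5).  Candidate borders are
then refined at 0.2 kb resolution, overlapping candidates are merged and
inserts shorter than 5 kb are dropped.

Two screens annotate (never delete) the calls: an rRNA-operon screen
flags candidates that contain a 16S-like segment — ribosomal operons
mimic foreign composition but are not mobile — and a keyword screen
confirms candidates whose annotated products mention mobile-element genes
(integrase, phage, transposase, ...).  From the empirical observation
that only 56% of verified islands carry such keywords, the number of true
positives among unconfirmed calls is extrapolated as
``n_unconfirmed_keypositive * 100 / 56``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .oup import (
    K,
    GenomeModel,
    OUPattern,
    StrandPolicy,
    _window_starts,
    count_tetramers,
    sequence_pattern,
    window_statistics,
)

__all__ = [
    "SnifferParams",
    "GenomicIsland",
    "scan",
    "refine_borders",
    "rrn_screen",
    "keyword_confirm",
    "estimate_true_positives",
    "DEFAULT_KEYWORDS",
]

DEFAULT_KEYWORDS = frozenset(
    {
        "integrase",
        "phage",
        "is-element",
        "transposase",
        "recombinase",
        "conjugation",
        "conjugal",
        "mobile element",
    }
)


@dataclass(frozen=True)
class SnifferParams:
    """Scan parameters; defaults are the tool's standard settings."""

    window_len: int = 8000
    coarse_step: int = 2000
    fine_step: int = 200
    backtrack_windows: int = 3
    d_threshold: float = 1.7
    v_threshold: float = 1.5
    min_island_len: int = 5000
    strand_policy: StrandPolicy = StrandPolicy.DIRECT

    def __post_init__(self):
        if not (0 < self.fine_step < self.coarse_step < self.window_len):
            raise ValueError("need fine_step < coarse_step < window_len, all > 0")
        if self.d_threshold <= 0 or self.v_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_island_len <= 0:
            raise ValueError("min_island_len must be positive")
        if self.backtrack_windows < 0:
            raise ValueError("backtrack_windows must be >= 0")


@dataclass
class GenomicIsland:
    """One called island (0-based half-open coordinates internally)."""

    host_id: str
    start: int
    end: int
    sequence: str
    pattern: OUPattern
    mean_D: float
    mean_V: float
    suspicious_rrn: bool = False
    keyword_confirmed: bool = False
    features: list[tuple[int, int, str, str]] = field(default_factory=list)
    # features: (start, end, strand, product) relative to the replicon

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        # user-facing label, 1-based inclusive
        return f"{self.host_id}:{self.start + 1}-{self.end}"


def _qualifies(st, params: SnifferParams) -> bool:
    return (
        st.D >= params.d_threshold
        and not st.degenerate
        and st.V >= params.v_threshold
    )


def scan(
    replicon,
    params: SnifferParams | None = None,
    host_id: str | None = None,
) -> list[GenomicIsland]:
    """Scan one replicon and return the called islands, sorted by start.

    ``replicon`` is either a plain nucleotide string or a record object
    with ``sequence``/``accession``/``features`` attributes (annotations
    only affect the keyword flag, never the calls).
    """
    params = params or SnifferParams()
    sequence, accession, features = _unpack_replicon(replicon, host_id)
    L = len(sequence)
    if L < params.window_len:
        raise ValueError(
            f"replicon too short: {L} bp < window length {params.window_len} bp"
        )

    model = GenomeModel.from_sequence(
        sequence, params.strand_policy, params.window_len, params.coarse_step
    )

    starts = _window_starts(L, params.window_len, params.coarse_step)
    stats = [
        window_statistics(sequence[s : s + params.window_len], s, model) for s in starts
    ]

    # runs of consecutive qualifying windows open candidates
    candidates: list[tuple[int, int]] = []
    run_start = None
    for st in stats:
        if _qualifies(st, params):
            if run_start is None:
                run_start = st.start
            run_end = st.end
        else:
            if run_start is not None:
                candidates.append((run_start, run_end))
                run_start = None
    if run_start is not None:
        candidates.append((run_start, run_end))

    refined = [refine_borders(sequence, c, model, params) for c in candidates]

    merged: list[list[int]] = []
    for s, e in sorted(refined):
        if merged and s - merged[-1][1] < params.fine_step:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    islands: list[GenomicIsland] = []
    for s, e in merged:
        if e - s < params.min_island_len:
            continue
        inside = [st for st in stats if st.start < e and st.end > s]
        sub = sequence[s:e]
        isl = GenomicIsland(
            host_id=accession,
            start=s,
            end=e,
            sequence=sub,
            pattern=sequence_pattern(sub, params.strand_policy),
            mean_D=float(np.mean([st.D for st in inside])) if inside else 0.0,
            mean_V=float(np.mean([st.V for st in inside])) if inside else 0.0,
            features=[
                (fs, fe, strand, prod)
                for (fs, fe, strand, _type, prod) in features
                if fs < e and fe > s
            ],
        )
        isl.keyword_confirmed = keyword_confirm(isl.features)
        islands.append(isl)
    return islands


def _unpack_replicon(replicon, host_id):
    if isinstance(replicon, str):
        return replicon, host_id or "replicon", []
    sequence = replicon.sequence
    accession = host_id or getattr(replicon, "accession", "replicon")
    feats = []
    for f in getattr(replicon, "features", []) or []:
        if isinstance(f, tuple):
            feats.append(f)
        else:
            feats.append((f.start, f.end, f.strand, f.type, f.product))
    return sequence, accession, feats


def refine_borders(
    sequence: str,
    candidate: tuple[int, int],
    model: GenomeModel,
    params: SnifferParams,
) -> tuple[int, int]:
    """Refine a coarse candidate interval to near-base resolution.

    The scan backtracks ``backtrack_windows`` coarse steps on each side of
    the candidate and re-examines the region position by position: every
    4-mer is scored with the log-likelihood ratio of the candidate's own
    word frequencies against the genome background, and each border is
    placed at the changepoint that maximises the cumulative score of the
    island side (a CUSUM argmax).  Falls back to the coarse interval when
    the region is degenerate; never widens the candidate by more than the
    backtrack distance, nor moves a border inward past one coarse step.
    """
    cs, ce = candidate
    L = len(sequence)
    back = params.backtrack_windows * params.coarse_step
    lo = max(0, cs - back)
    hi = min(L, ce + back)

    core_counts = count_tetramers(sequence[cs:ce], model.strand_policy)
    n = core_counts.counts.size
    p_isl = (core_counts.counts + 0.5) / (core_counts.total_words + 0.5 * n)
    p_core = model.genome_word_freqs
    llr_by_word = np.log(p_isl) - np.log(np.maximum(p_core, 1e-12))

    scores = _position_scores(sequence[lo:hi], llr_by_word, model.strand_policy)
    if scores.size == 0:
        return candidate
    mid = min(max((cs + ce) // 2 - lo, 1), scores.size - 1)

    # left border: argmax over t of sum(scores[t:mid])
    left_suffix = np.concatenate([[0.0], np.cumsum(scores[:mid][::-1])])[::-1]
    s_rel = int(np.argmax(left_suffix))
    # right border: argmax over t of sum(scores[mid:t])
    right_prefix = np.cumsum(scores[mid:])
    e_rel = mid + int(np.argmax(right_prefix)) + K

    s_new = int(lo + s_rel)
    e_new = int(min(hi, lo + e_rel))
    if s_new >= e_new:
        return candidate
    return (s_new, e_new)


def _position_scores(region: str, llr_by_word: np.ndarray, policy) -> np.ndarray:
    """Per-position island-vs-background log-likelihood ratio of each 4-mer."""
    from .oup import _CLASS_OF, _encode  # word tables are module-internal

    codes = _encode(region)
    if codes.size < K:
        return np.empty(0)
    a, b, c, d = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    valid = (a >= 0) & (b >= 0) & (c >= 0) & (d >= 0)
    idx = np.where(valid, ((a * 4 + b) * 4 + c) * 4 + d, 0)
    if policy is not StrandPolicy.DIRECT:
        idx = _CLASS_OF[idx]
    scores = llr_by_word[idx]
    scores[~valid] = 0.0
    return scores


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def rrn_screen(
    island,
    rrna_refs,
    min_identity: float = 0.8,
    min_len: int = 300,
    k: int = 16,
    band: int = 32,
) -> bool:
    """True when the island likely contains an rRNA (16S-like) segment.

    A seed-chain screen: exact shared ``k``-mers between the island and
    each reference are grouped by alignment diagonal; a group spanning at
    least ``min_len`` bp whose k-mer match density implies a per-base
    identity of at least ``min_identity`` (Mash-style ``q**(1/k)``
    estimate) flags the island.  This approximates an ungapped BLASTN hit;
    flagged islands are retained but marked suspicious.
    """
    if not rrna_refs:
        raise ValueError("rRNA screen enabled but no reference sequences given")
    seq = island.sequence if hasattr(island, "sequence") else str(island)
    seq = seq.upper()
    if len(seq) < k:
        return False
    island_kmers: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        island_kmers.setdefault(seq[i : i + k], []).append(i)

    for ref in rrna_refs:
        rseq = (ref.sequence if hasattr(ref, "sequence") else str(ref)).upper()
        diagonals: dict[int, list[int]] = {}
        for j in range(len(rseq) - k + 1):
            for i in island_kmers.get(rseq[j : j + k], ()):
                diagonals.setdefault((i - j) // band, []).append(i)
        merged: dict[int, list[int]] = {}
        for key, pos in diagonals.items():
            merged.setdefault(key, []).extend(pos)
            merged.setdefault(key + 1, []).extend(pos)
        for pos in merged.values():
            if len(pos) < 2:
                continue
            span = max(pos) + k - min(pos)
            if span < min_len:
                continue
            q = min(1.0, len(set(pos)) / (span - k + 1))
            if q > 0 and q ** (1.0 / k) >= min_identity:
                return True
    return False


def keyword_confirm(features, keywords=DEFAULT_KEYWORDS) -> bool:
    """True iff any product annotation contains any keyword (case-insensitive)."""
    for f in features or []:
        product = f[-1] if isinstance(f, tuple) else getattr(f, "product", "")
        if product and any(kw.lower() in product.lower() for kw in keywords):
            return True
    return False


def estimate_true_positives(n_unconfirmed_keypositive: float) -> float:
    """Extrapolate true positives among unconfirmed islands as n * 100 / 56."""
    if n_unconfirmed_keypositive < 0:
        raise ValueError("count must be non-negative")
    return n_unconfirmed_keypositive * 100.0 / 56.0
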