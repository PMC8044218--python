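"""PWM scanning with exact p-value calibration.

A JASPAR-style position frequency matrix is converted to log2-odds
against a background base distribution.  Scores are discretised on a
fixed granularity and the exact null score distribution of a random
background word is obtained by dynamic-programming convolution over
positions, giving an exact tail function Q(s) = P(score >= s).  The score
cutoff for a requested p-value (1e-4 by default) is the smallest
discretised score whose tail falls at or below p.  Sequences are scanned
on the provided strand only (sequences are expected to be extracted
strand-aware, so the scan reads each element 5'->3'); windows containing
N are skipped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from repeat_regprof.binding import consensus_histogram

logger = logging.getLogger(__name__)

DEFAULT_GRANULARITY = 1e-3
# Finite floor for log2-odds of zero-probability letters: a window
# containing such a letter scores at least 30 bits below everything else,
# so only tails below ~2^-30 per position are affected.
LOG_ODDS_FLOOR = -30.0
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    """A position weight matrix with integerised log2-odds scores.

    ``probs`` and ``log_odds`` are 4 x width in A, C, G, T row order;
    ``scores_int`` holds log-odds rounded to units of ``granularity``.
    """

    matrix_id: str
    name: str
    probs: np.ndarray
    background: np.ndarray
    log_odds: np.ndarray
    granularity: float = DEFAULT_GRANULARITY

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise ValueError("probs must be 4 x width with width >= 1")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("each probability column must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("background must sum to 1")
        self.scores_int = np.rint(self.log_odds / self.granularity).astype(np.int64)

    @property
    def width(self) -> int:
        return self.probs.shape[1]


@dataclass
class ScoreDistribution:
    """Exact distribution of the discretised score of a background word."""

    origin: int  # integer score of probs[0]
    probs: np.ndarray
    granularity: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        # tail[i] = P(score_int >= origin + i)
        self._tail = np.cumsum(self.probs[::-1])[::-1]

    @property
    def max_score_int(self) -> int:
        return self.origin + len(self.probs) - 1

    def tail(self, score_int: int) -> float:
        """Q(s) = P(score >= s) at an integer (discretised) score."""
        i = score_int - self.origin
        if i <= 0:
            return 1.0
        if i >= len(self.probs):
            return 0.0
        return float(self._tail[i])


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # 0-based start within the (oriented) sequence
    score: float  # log2-odds
    p_value: float
    matched: str


def load_pwm(counts, pseudocount: float = 0.1, background=None,
             matrix_id: str = "", name: str = "",
             granularity: float = DEFAULT_GRANULARITY) -> PWM:
    """Convert a 4 x width count matrix (A, C, G, T rows) to a PWM.

    probs = (counts + pseudocount) / (column total + 4 pseudocount);
    log_odds = log2(probs / background).  Background defaults to uniform.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("counts must be a 4 x width matrix")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    col_totals = counts.sum(axis=0)
    if np.any(col_totals + 4 * pseudocount <= 0):
        raise ValueError("zero column total with zero pseudocount")
    background = (np.full(4, 0.25) if background is None
                  else np.asarray(background, dtype=float))
    probs = (counts + pseudocount) / (col_totals + 4 * pseudocount)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probs / background[:, None])
    log_odds = np.maximum(log_odds, LOG_ODDS_FLOOR)
    return PWM(matrix_id=matrix_id, name=name, probs=probs,
               background=background, log_odds=log_odds,
               granularity=granularity)


def score_distribution(pwm: PWM) -> ScoreDistribution:
    """Exact null score distribution by convolution across positions.

    The p-value error introduced by discretisation is bounded by
    width x granularity in score units.
    """
    from scipy.signal import convolve

    dist = np.array([1.0])
    origin = 0
    for j in range(pwm.width):
        col_scores = pwm.scores_int[:, j]
        lo, hi = int(col_scores.min()), int(col_scores.max())
        col = np.zeros(hi - lo + 1)
        for b in range(4):
            col[col_scores[b] - lo] += pwm.background[b]
        dist = convolve(dist, col)
        origin += lo
    # FFT round-off can leave tiny negative densities; clip for monotone tails
    np.clip(dist, 0.0, None, out=dist)
    return ScoreDistribution(origin=origin, probs=dist,
                             granularity=pwm.granularity)


def threshold_for_pvalue(dist: ScoreDistribution, p: float) -> int:
    """Smallest discretised score s with Q(s) <= p (hits require
    score >= s), in units of the distribution granularity.

    When even the maximum score is too common, the returned cutoff exceeds
    the maximum attainable score, so no hit can pass (logged).
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    tail = dist._tail
    # tail is non-increasing; find first index with tail <= p
    idx = np.searchsorted(-tail, -p, side="left")
    if idx >= len(tail):
        logger.info("threshold_for_pvalue: p=%g below the smallest attainable "
                    "tail; no word can pass", p)
        return dist.max_score_int + 1
    return dist.origin + int(idx)


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N etc.) -> -1."""
    arr = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.upper().encode(), dtype=np.uint8)
            == ord(base)] = idx
    return arr


def scan_sequences(pwm: PWM, sequences: dict[str, str], cutoff_int: int,
                   dist: ScoreDistribution | None = None) -> list[MotifHit]:
    """Report every window scoring >= cutoff on the provided strand.

    No reverse-complement scan is performed; windows containing N are
    skipped; sequences shorter than the PWM width yield no hits.  When
    ``dist`` is given each hit carries its exact tail p-value.
    """
    hits: list[MotifHit] = []
    w = pwm.width
    for seq_id in sequences:
        seq = sequences[seq_id]
        if len(seq) < w:
            continue
        enc = encode_sequence(seq)
        windows = np.lib.stride_tricks.sliding_window_view(enc, w)
        valid = (windows >= 0).all(axis=1)
        safe = np.where(windows < 0, 0, windows)
        scores = pwm.scores_int[safe, np.arange(w)].sum(axis=1)
        for off in np.nonzero(valid & (scores >= cutoff_int))[0]:
            s_int = int(scores[off])
            hits.append(MotifHit(
                sequence_id=seq_id,
                offset=int(off),
                score=s_int * pwm.granularity,
                p_value=dist.tail(s_int) if dist is not None else float("nan"),
                matched=seq[off:off + w].upper(),
            ))
    return hits


def find_motif_hits(pwm: PWM, sequences: dict[str, str],
                    p: float = 1e-4) -> tuple[list[MotifHit], int]:
    """Convenience wrapper: calibrate the cutoff for ``p`` and scan.

    Returns (hits, cutoff_int).
    """
    dist = score_distribution(pwm)
    cutoff = threshold_for_pvalue(dist, p)
    return scan_sequences(pwm, sequences, cutoff, dist), cutoff


def summarise_hits(hits) -> tuple[dict[str, int], int]:
    """Per-sequence hit counts and the number of sequences with >= 1 hit."""
    per_seq: dict[str, int] = {}
    for h in hits:
        per_seq[h.sequence_id] = per_seq.get(h.sequence_id, 0) + 1
    return per_seq, len(per_seq)


def hits_to_consensus(hits, elements_by_id: dict, width: int,
                      bin_width: int = 5, max_pos: int = 6500,
                      min_peak_count: int = 5):
    """Project motif hits to consensus coordinates and bin them.

    Sequences are oriented 5'->3', so a hit midpoint at sequence offset m
    sits at consensus position consensus_start + m.  Returns
    (histogram counts, n_dropped, logo count matrices per populated bin):
    each logo matrix is 4 x width base counts of the hit subsequences in
    that bin (bins with >= ``min_peak_count`` hits only).
    """
    positions = []
    by_bin: dict[int, list[str]] = {}
    for h in hits:
        el = elements_by_id.get(h.sequence_id)
        if el is None:
            raise KeyError(f"no element with id {h.sequence_id}")
        pos = el.consensus_start + h.offset + width // 2
        positions.append(pos)
        if pos <= max_pos:
            by_bin.setdefault((pos - 1) // bin_width, []).append(h.matched)
    hist, n_dropped = consensus_histogram(positions, bin_width, max_pos)

    logos: dict[int, np.ndarray] = {}
    for bin_idx, words in by_bin.items():
        if len(words) < min_peak_count:
            continue
        counts = np.zeros((4, width), dtype=np.int64)
        for word in words:
            for j, base in enumerate(word):
                if base in _BASE_INDEX:
                    counts[_BASE_INDEX[base], j] += 1
        logos[bin_idx] = counts
    return hist, n_dropped, logos
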