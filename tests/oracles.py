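"""Independent oracles used by the test suite.

These re-derive expected values by routes deliberately different from the
implementation: a per-cell brute-force fitting DP with an explicit
per-breakpoint scan for split realignment (numba-compiled so the exhaustive
scan stays affordable), exact binomial tail inversion for the
Clopper-Pearson interval, and sort+interpolate quantiles for the Tukey
fence.
"""

from __future__ import annotations

import math

import numba
import numpy as np

from meganumt.splitalign import GAP_EXT, GAP_OPEN, MATCH, MISMATCH, revcomp

NEG = -(10**7)


@numba.njit(cache=False)
def _fit_score_cells(piece, ref, match, mismatch, gap_open, gap_ext):
    """Per-cell 3-state fitting DP (whole piece, free reference ends)."""
    m, n = piece.size, ref.size
    m_prev = np.zeros(n + 1, np.int64)
    x_prev = np.full(n + 1, NEG, np.int64)
    y_prev = np.full(n + 1, NEG, np.int64)
    best = NEG
    for i in range(1, m + 1):
        m_row = np.full(n + 1, NEG, np.int64)
        x_row = np.full(n + 1, NEG, np.int64)
        y_row = np.full(n + 1, NEG, np.int64)
        for j in range(n + 1):
            a = m_prev[j] - gap_open
            b = x_prev[j] - gap_ext
            x_row[j] = a if a >= b else b
            if j == 0:
                continue
            s = match if ref[j - 1] == piece[i - 1] else mismatch
            d = m_prev[j - 1]
            if x_prev[j - 1] > d:
                d = x_prev[j - 1]
            if y_prev[j - 1] > d:
                d = y_prev[j - 1]
            m_row[j] = d + s
            a = m_row[j - 1] - gap_open
            b = y_row[j - 1] - gap_ext
            y_row[j] = a if a >= b else b
        if i == m:
            for j in range(n + 1):
                v = m_row[j] if m_row[j] >= x_row[j] else x_row[j]
                if v > best:
                    best = v
        m_prev, x_prev, y_prev = m_row, x_row, y_row
    return best


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def brute_realign(
    read: str,
    nuclear_ref: str | None,
    mt_ref: str,
    min_piece: int = 20,
    min_identity: float = 0.9,
):
    """Exhaustive breakpoint scan with a full per-piece DP at every breakpoint.

    Returns ``None`` (no split) or ``(breakpoint, total_score)``.  Acceptance
    uses the same score-scale thresholds as the contract: a length-L piece
    passes at fitting score >= ``(2*min_identity - 1)*L``, and a read whose
    whole length reaches that bound on a single reference is contiguous, not
    split.
    """
    read = read.upper()
    m = len(read)
    mt_ext = mt_ref + mt_ref[: min(m, len(mt_ref))]
    refs = [_encode(mt_ext), _encode(revcomp(mt_ext))]
    if nuclear_ref is not None:
        refs += [_encode(nuclear_ref), _encode(revcomp(nuclear_ref))]

    def piece_best(piece: str) -> int:
        arr = _encode(piece)
        return max(
            int(_fit_score_cells(arr, ref, MATCH, MISMATCH, GAP_OPEN, GAP_EXT))
            for ref in refs
        )

    def floor(length: int) -> float:
        return (2.0 * min_identity - 1.0) * length

    if piece_best(read) >= floor(m):
        return None
    if m < 2 * min_piece:
        return None
    best_k, best_total, best_pieces = None, NEG, (NEG, NEG)
    for k in range(min_piece, m - min_piece + 1):
        sa = piece_best(read[:k])
        sb = piece_best(read[k:])
        if sa + sb > best_total:
            best_k, best_total, best_pieces = k, sa + sb, (sa, sb)
    if best_pieces[0] < floor(best_k) or best_pieces[1] < floor(m - best_k):
        return None
    return best_k, best_total


def biopython_fit_score(piece: str, ref: str) -> int:
    """Third-party fitting score: Biopython global alignment with free
    reference (target) end gaps and the same match/mismatch/affine scores."""
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXT
    # free end gaps in the target (unaligned reference overhangs)
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return int(aligner.score(ref.upper(), piece.upper()))


def clopper_pearson_oracle(successes: int, trials: int, level: float):
    """Exact CP bounds by bisecting the binomial tail sums (math.comb)."""
    alpha = 1.0 - level

    def upper_tail(p):  # P(X >= successes)
        return sum(
            math.comb(trials, i) * p**i * (1 - p) ** (trials - i)
            for i in range(successes, trials + 1)
        )

    def lower_tail(p):  # P(X <= successes)
        return sum(
            math.comb(trials, i) * p**i * (1 - p) ** (trials - i)
            for i in range(0, successes + 1)
        )

    def bisect(f, target, increasing=True):
        lo, hi = 0.0, 1.0
        for _ in range(100):
            mid = (lo + hi) / 2
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    low = 0.0 if successes == 0 else bisect(upper_tail, alpha / 2)
    high = (
        1.0 if successes == trials else bisect(lower_tail, alpha / 2, increasing=False)
    )
    return low, high


def tukey_fence_oracle(values) -> float:
    """Q3 + 1.5*IQR with hand-rolled linear-interpolation quantiles."""
    xs = sorted(float(v) for v in values)
    n = len(xs)

    def quantile(q):
        h = (n - 1) * q
        lo = math.floor(h)
        hi = math.ceil(h)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    return q3 + 1.5 * (q3 - q1)
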