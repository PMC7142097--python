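"""Two-piece realignment of split reads across NUMT junctions.

A split (soft-clipped) read spanning a junction carries two sub-sequences
from different loci: nuclear + mtDNA-derived (nu-mt) or two mtDNA locations
(mt-mt).  :func:`realign_split` recovers the junction by an exhaustive scan
over every breakpoint of the read: at breakpoint ``k`` the prefix ``read[:k]``
and suffix ``read[k:]`` are each aligned, as whole pieces, against the nuclear
window and the mitochondrial reference on both strands, and the breakpoint
with the highest combined score wins.

Piece alignment is a *fitting* alignment: the entire piece must be consumed,
the reference is free at both ends, and scoring is match +1, mismatch -1,
gap open -2, gap extend -1.  The mitochondrial reference is treated as
circular, so junctions crossing the 16,569/1 origin are recovered in native
coordinates.  Everything is deterministic; ties prefer the smallest
breakpoint and the leftmost reference placement.

The scan exploits the fact that the fitting-DP rows for the full read are
exactly the fitting scores of every read prefix (and, on the reversed
sequences, of every suffix), so one DP pass per reference/strand scores all
breakpoints at once.  Identity and junction coordinates for the winning
breakpoint are then recovered by a small windowed traceback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Side", "SplitAlignment", "realign_split", "revcomp"]

MATCH = 1
MISMATCH = -1
GAP_OPEN = 2  # cost of the first gapped base
GAP_EXT = 1  # cost of each further gapped base

_NEG = -(10**7)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Side:
    """One side of a junction: contig, 1-based position, strand."""

    contig: str
    pos: int
    strand: str


@dataclass(frozen=True)
class SplitAlignment:
    """A read partitioned at ``breakpoint`` into two locally placed pieces.

    ``side_a`` is the junction-adjacent coordinate of the prefix piece (its
    last aligned reference base), ``side_b`` that of the suffix piece (its
    first aligned base).  Identities are matches divided by piece length.
    """

    read_id: str
    breakpoint: int
    score: int
    side_a: Side
    side_b: Side
    identity_a: float
    identity_b: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _fit_row_scores(piece: np.ndarray, ref: np.ndarray):
    """Fitting-alignment DP, returning per-row best scores and end columns.

    Row ``k`` holds the best fitting score of ``piece[:k]`` against any
    window of ``ref`` (whole prefix consumed, reference ends free), together
    with the reference column of the best-scoring cell.  Three affine states:
    aligned pair (M), piece base against a gap (X), reference base against a
    gap (Y; computed with a running-maximum scan since the extend penalty is
    linear in run length).
    """
    m, n = piece.size, ref.size
    jidx = np.arange(n + 1, dtype=np.int64)
    m_prev = np.zeros(n + 1, dtype=np.int64)  # row 0: free reference prefix
    x_prev = np.full(n + 1, _NEG, dtype=np.int64)
    y_prev = np.full(n + 1, _NEG, dtype=np.int64)
    best = np.empty(m + 1, dtype=np.int64)
    endj = np.empty(m + 1, dtype=np.int64)
    best[0] = 0
    endj[0] = 0
    for i in range(1, m + 1):
        s = np.where(ref == piece[i - 1], MATCH, MISMATCH)
        diag = np.maximum(np.maximum(m_prev, x_prev), y_prev)
        m_row = np.empty(n + 1, dtype=np.int64)
        m_row[0] = _NEG
        m_row[1:] = diag[:-1] + s
        x_row = np.maximum(m_prev - GAP_OPEN, x_prev - GAP_EXT)
        # Y[j] = max_{j'<j} M[j'] - GAP_OPEN - (j-j'-1)*GAP_EXT, via prefix max
        acc = np.maximum.accumulate(m_row + jidx * GAP_EXT)
        y_row = np.empty(n + 1, dtype=np.int64)
        y_row[0] = _NEG
        y_row[1:] = acc[:-1] - jidx[1:] * GAP_EXT - (GAP_OPEN - GAP_EXT)
        row_best = np.maximum(m_row, x_row)
        j = int(np.argmax(row_best))
        best[i] = row_best[j]
        endj[i] = j
        m_prev, x_prev, y_prev = m_row, x_row, y_row
    return best, endj


_START, _M, _X, _Y = 0, 1, 2, 3


def _fit_traceback(piece: str, window: str):
    """Full fitting DP of ``piece`` against ``window`` with traceback.

    Returns ``(score, matches, first_j, last_j)`` where ``first_j``/``last_j``
    are the 1-based window coordinates of the outermost aligned (M-state)
    reference bases on the optimal path.  Deterministic tie-breaking: lowest
    end column, M preferred over X.
    """
    m, w = len(piece), len(window)
    M = np.full((m + 1, w + 1), _NEG, dtype=np.int64)
    X = np.full((m + 1, w + 1), _NEG, dtype=np.int64)
    Y = np.full((m + 1, w + 1), _NEG, dtype=np.int64)
    Mp = np.zeros((m + 1, w + 1), dtype=np.uint8)
    Xp = np.zeros((m + 1, w + 1), dtype=np.uint8)
    Yp = np.zeros((m + 1, w + 1), dtype=np.uint8)
    M[0, :] = 0  # free reference prefix before any piece base
    for i in range(1, m + 1):
        pc = piece[i - 1]
        for j in range(w + 1):
            # X: piece base against gap
            a = M[i - 1, j] - GAP_OPEN
            b = X[i - 1, j] - GAP_EXT
            if a >= b:
                X[i, j] = a
                Xp[i, j] = _M if i > 1 else _START
            else:
                X[i, j] = b
                Xp[i, j] = _X
            if j == 0:
                continue
            # M: aligned pair
            s = MATCH if pc == window[j - 1] else MISMATCH
            cands = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            ci = int(np.argmax(cands))
            M[i, j] = cands[ci] + s
            Mp[i, j] = (_M if i > 1 else _START, _X, _Y)[ci]
            # Y: reference base against gap (from this row's M or Y)
            a = M[i, j - 1] - GAP_OPEN
            b = Y[i, j - 1] - GAP_EXT
            if a >= b:
                Y[i, j] = a
                Yp[i, j] = _M
            else:
                Y[i, j] = b
                Yp[i, j] = _Y
    # best end cell in final row
    state, j_end, score = _M, 0, _NEG
    for j in range(w + 1):
        if M[m, j] > score:
            state, j_end, score = _M, j, M[m, j]
        if X[m, j] > score:
            state, j_end, score = _X, j, X[m, j]
    matches = 0
    first_j = last_j = 0
    i, j = m, j_end
    while i > 0:
        if state == _M:
            if piece[i - 1] == window[j - 1]:
                matches += 1
            last_j = max(last_j, j)
            first_j = j if first_j == 0 else min(first_j, j)
            state = Mp[i, j]
            i, j = i - 1, j - 1
        elif state == _X:
            state = Xp[i, j]
            i -= 1
        else:  # _Y
            state = Yp[i, j]
            j -= 1
        if state == _START:
            break
    return int(score), matches, first_j, last_j


@dataclass(frozen=True)
class _Entry:
    contig: str
    strand: str
    seq: str
    kind: str  # "nuclear" | "mt"
    offset: int  # 0-based forward-genome offset of the nuclear window
    mt_len: int  # modular mtDNA length (0 for nuclear entries)

    def to_forward(self, p: int) -> int:
        """Map a 1-based position on this entry's sequence to forward coords."""
        n = len(self.seq)
        if self.strand == "-":
            p = n - p + 1
        if self.kind == "mt":
            return (p - 1) % self.mt_len + 1
        return self.offset + p


def _refine(entry: _Entry, piece: str, endj: int, reverse: bool):
    """Windowed traceback of a piece on an entry; returns identity and the
    junction-side / far-side forward coordinates.

    For ``reverse=True`` the piece and entry are the reversed suffix pair, and
    window coordinates are mapped back through the reversal.
    """
    seq = entry.seq[::-1] if reverse else entry.seq
    n = len(seq)
    end0 = int(endj)
    ws = max(0, end0 - len(piece) - 12)
    we = min(n, end0 + 4)
    window = seq[ws:we]
    _, matches, first_j, last_j = _fit_traceback(piece, window)
    identity = matches / len(piece) if piece else 0.0
    if first_j == 0:  # no aligned base at all
        return identity, None, None
    lo, hi = ws + first_j, ws + last_j  # 1-based on seq
    if reverse:
        lo, hi = n - hi + 1, n - lo + 1
    # junction side: last aligned base for a prefix, first for a suffix
    junction_p = lo if reverse else hi
    far_p = hi if reverse else lo
    return identity, entry.to_forward(junction_p), entry.to_forward(far_p)


def realign_split(
    sequence: str,
    nuclear_ref: str | None,
    mt_ref: str,
    *,
    min_piece: int = 20,
    min_identity: float = 0.9,
    nuclear_contig: str = "chr1",
    nuclear_offset: int = 0,
    mt_contig: str = "MT",
    mt_circular: bool = True,
    read_id: str = "",
) -> SplitAlignment | None:
    """Exhaustive breakpoint scan of a read against nuclear and mtDNA references.

    ``nuclear_ref`` is typically a window of the chromosome around a
    discordant-read cluster; ``nuclear_offset`` is the 0-based forward
    coordinate at which that window starts, so reported positions are in
    chromosome coordinates.  Pass ``nuclear_ref=None`` to search the
    mitochondrial reference only (mt-mt junctions).

    Returns ``None`` when the read aligns contiguously to a single reference
    at >= ``min_identity``, or when no breakpoint yields two pieces of at
    least ``min_piece`` bases each at >= ``min_identity``.  The identity
    thresholds are applied on the score scale — a piece of length L passes
    when its fitting score reaches ``(2*min_identity - 1)*L``, which for
    ungapped alignments is exactly the identity rule and additionally
    penalises gapped patchwork alignments.  Reported identities are
    matches / piece length on the winning alignment.
    """
    sequence = sequence.upper()
    m = len(sequence)
    if len(mt_ref) < min_piece:
        raise ValueError(
            f"mtDNA reference ({len(mt_ref)} bp) shorter than min_piece={min_piece}"
        )
    if nuclear_ref is not None and len(nuclear_ref) < min_piece:
        raise ValueError(
            f"nuclear reference window ({len(nuclear_ref)} bp) shorter than "
            f"min_piece={min_piece}"
        )
    mt_len = len(mt_ref)
    mt_seq = mt_ref + mt_ref[: min(m, mt_len)] if mt_circular else mt_ref
    entries = [
        _Entry(mt_contig, "+", mt_seq.upper(), "mt", 0, mt_len),
        _Entry(mt_contig, "-", revcomp(mt_seq).upper(), "mt", 0, mt_len),
    ]
    if nuclear_ref is not None:
        entries.append(
            _Entry(nuclear_contig, "+", nuclear_ref.upper(), "nuclear", nuclear_offset, 0)
        )
        entries.append(
            _Entry(
                nuclear_contig, "-", revcomp(nuclear_ref).upper(), "nuclear",
                nuclear_offset, 0,
            )
        )

    read_arr = _encode(sequence)
    read_rev = read_arr[::-1].copy()
    pre_best = np.full((len(entries), m + 1), _NEG, dtype=np.int64)
    pre_endj = np.zeros((len(entries), m + 1), dtype=np.int64)
    suf_best = np.full((len(entries), m + 1), _NEG, dtype=np.int64)
    suf_endj = np.zeros((len(entries), m + 1), dtype=np.int64)
    for e, entry in enumerate(entries):
        arr = _encode(entry.seq)
        pre_best[e], pre_endj[e] = _fit_row_scores(read_arr, arr)
        suf_best[e], suf_endj[e] = _fit_row_scores(read_rev, arr[::-1].copy())

    # acceptance thresholds live on the score scale: an ungapped alignment of
    # a length-L piece at identity q scores (2q-1)*L, and gapped paths that
    # chain spurious match runs score well below it
    def floor(length: int) -> float:
        return (2.0 * min_identity - 1.0) * length

    # contiguous single-reference alignment: not a split read
    if pre_best[:, m].max() >= floor(m):
        return None

    if m < 2 * min_piece:
        return None
    pre_max = pre_best.max(axis=0)
    suf_max = suf_best.max(axis=0)
    ks = np.arange(min_piece, m - min_piece + 1)
    totals = pre_max[ks] + suf_max[m - ks]
    k = int(ks[int(np.argmax(totals))])
    score = int(pre_max[k] + suf_max[m - k])
    if pre_max[k] < floor(k) or suf_max[m - k] < floor(m - k):
        return None

    e_a = int(np.argmax(pre_best[:, k]))
    e_b = int(np.argmax(suf_best[:, m - k]))
    prefix, suffix = sequence[:k], sequence[k:]
    id_a, pos_a, _ = _refine(entries[e_a], prefix, pre_endj[e_a, k], False)
    id_b, pos_b, _ = _refine(entries[e_b], suffix[::-1], suf_endj[e_b, m - k], True)
    if pos_a is None or pos_b is None:
        return None
    return SplitAlignment(
        read_id=read_id,
        breakpoint=k,
        score=score,
        side_a=Side(entries[e_a].contig, pos_a, entries[e_a].strand),
        side_b=Side(entries[e_b].contig, pos_b, entries[e_b].strand),
        identity_a=id_a,
        identity_b=id_b,
    )
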