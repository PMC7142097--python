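"""NUMT and breakpoint detection from discordant read pairs and split reads.

The detection strategy works on already-aligned short reads.  Read pairs with
one end on a nuclear chromosome and the mate on the mitochondrial contig
(discordant pairs) are clustered by orientation and nuclear proximity;
clusters supported by at least five pairs mark candidate insertion loci.
Soft-clipped reads near a cluster are then realigned as two-piece splits
(:mod:`meganumt.splitalign`) to define junctions base-precisely: nu-mt
junctions give the nuclear insertion point and the mtDNA breakpoints of the
insert, while mt-mt junctions — two mtDNA-derived sequences joined directly —
betray concatenated (mega-NUMT) structure.  Per-sample calls are finally
grouped across the cohort when both their nuclear and mtDNA footprints agree
within 1 kb, yielding carrier lists and cohort frequencies.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from .splitalign import Side, SplitAlignment, realign_split

__all__ = [
    "AlignedRead",
    "DiscordantCluster",
    "Junction",
    "NumtCall",
    "extract_discordant_pairs",
    "cluster_discordant",
    "find_split_reads",
    "realign_split",
    "call_junctions",
    "detect_numts_sample",
    "group_numts",
    "mt_span",
    "Side",
    "SplitAlignment",
]

log = logging.getLogger(__name__)

MT_CONTIG = "MT"

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class AlignedRead:
    """Simplified SAM-level alignment record (one end of a pair)."""

    read_id: str
    contig: str
    pos: int  # 1-based leftmost aligned position
    strand: str
    mapq: int
    cigar: str
    sequence: str
    mate_contig: str | None = None
    mate_pos: int | None = None
    mate_strand: str | None = None
    is_read1: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"read {self.read_id}: position {self.pos} < 1")
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"read {self.read_id}: mapq {self.mapq} out of range")


def clip_lengths(cigar: str) -> tuple[int, int]:
    """(leading, trailing) soft/hard-clipped base counts of a CIGAR string."""
    ops = _CIGAR_RE.findall(cigar)
    if not ops:
        return (0, 0)
    left = int(ops[0][0]) if ops[0][1] in "SH" else 0
    right = int(ops[-1][0]) if len(ops) > 1 and ops[-1][1] in "SH" else 0
    return (left, right)


def has_clip(read: AlignedRead, min_clip: int = 20) -> bool:
    left, right = clip_lengths(read.cigar)
    return max(left, right) >= min_clip


def extract_discordant_pairs(
    reads, mapq_min: int = 20, mt_contig: str = MT_CONTIG
) -> list[tuple[AlignedRead, AlignedRead]]:
    """Read pairs with exactly one end on a nuclear contig and the mate on the
    mitochondrial contig, both ends at mapping quality >= ``mapq_min``.

    Returned as (nuclear end, mt end).  Read ids without exactly two records
    are skipped (one aggregated warning).
    """
    by_id: dict[str, list[AlignedRead]] = {}
    order: list[str] = []
    for r in reads:
        if r.read_id not in by_id:
            order.append(r.read_id)
        by_id.setdefault(r.read_id, []).append(r)
    pairs: list[tuple[AlignedRead, AlignedRead]] = []
    n_unpaired = 0
    for rid in order:
        group = by_id[rid]
        if len(group) != 2:
            n_unpaired += 1
            continue
        a, b = group
        on_mt = [r.contig == mt_contig for r in (a, b)]
        if sum(on_mt) != 1:
            continue
        if a.mapq < mapq_min or b.mapq < mapq_min:
            continue
        nuclear, mt = (b, a) if on_mt[0] else (a, b)
        pairs.append((nuclear, mt))
    if n_unpaired:
        log.warning("skipped %d read ids without exactly two alignments", n_unpaired)
    return pairs


@dataclass(frozen=True)
class DiscordantCluster:
    """A chained group of same-orientation discordant pairs at one nuclear locus."""

    nuclear_contig: str
    nuclear_interval: tuple[int, int]
    orientation: tuple[str, str]  # (nuclear-end strand, mt-end strand)
    mt_interval: tuple[int, int]
    n_pairs: int
    pairs: tuple = field(repr=False, default=())


def cluster_discordant(
    pairs, gap: int = 500, min_pairs: int = 5
) -> list[DiscordantCluster]:
    """Single-linkage chaining of discordant pairs per (contig, orientation).

    Nuclear-end positions are sorted and joined while consecutive gaps are
    <= ``gap`` bp; chains with fewer than ``min_pairs`` pairs are discarded.
    The cluster's mt interval is the span of the mate positions.
    """
    groups: dict[tuple[str, tuple[str, str]], list] = {}
    for nuc, mt in pairs:
        key = (nuc.contig, (nuc.strand, mt.strand))
        groups.setdefault(key, []).append((nuc, mt))
    clusters: list[DiscordantCluster] = []
    for (contig, orientation), members in sorted(groups.items()):
        members.sort(key=lambda p: p[0].pos)
        chain: list = []
        for pair in members:
            if chain and pair[0].pos - chain[-1][0].pos > gap:
                clusters.extend(
                    _emit_cluster(contig, orientation, chain, min_pairs)
                )
                chain = []
            chain.append(pair)
        clusters.extend(_emit_cluster(contig, orientation, chain, min_pairs))
    clusters.sort(key=lambda c: (c.nuclear_contig, c.nuclear_interval))
    return clusters


def _emit_cluster(contig, orientation, chain, min_pairs):
    if len(chain) < min_pairs:
        return []
    nuc_pos = [p[0].pos for p in chain]
    mt_pos = [p[1].pos for p in chain]
    return [
        DiscordantCluster(
            nuclear_contig=contig,
            nuclear_interval=(min(nuc_pos), max(nuc_pos)),
            orientation=orientation,
            mt_interval=(min(mt_pos), max(mt_pos)),
            n_pairs=len(chain),
            pairs=tuple(chain),
        )
    ]


def find_split_reads(
    reads,
    clusters,
    window: int = 1000,
    min_clip: int = 20,
    mt_contig: str = MT_CONTIG,
) -> list[AlignedRead]:
    """Soft-clipped split-read candidates near discordant clusters.

    Nuclear reads qualify when their position lies within ``window`` bp of a
    cluster's nuclear interval; clipped reads aligned to the mitochondrial
    contig are always candidates (potential mt-mt junctions).
    """
    out: list[AlignedRead] = []
    for r in reads:
        if not has_clip(r, min_clip):
            continue
        if r.contig == mt_contig:
            out.append(r)
            continue
        for c in clusters:
            if c.nuclear_contig != r.contig:
                continue
            lo, hi = c.nuclear_interval
            if lo - window <= r.pos <= hi + window:
                out.append(r)
                break
    return out


@dataclass(frozen=True)
class Junction:
    """A breakpoint defined by concordant split alignments.

    ``nu_mt`` junctions join nuclear and mtDNA-derived sequence; ``mt_mt``
    junctions join two mtDNA-derived fragments (the mega-NUMT signature when
    supported by more than two split reads).
    """

    kind: str  # "nu_mt" | "mt_mt"
    side_a: Side
    side_b: Side
    split_support: int

    def mt_sides(self) -> list[Side]:
        return [s for s in (self.side_a, self.side_b) if s.contig == MT_CONTIG]


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _canonical_sides(split: SplitAlignment, mt_contig: str):
    """Order the two sides deterministically, flipping strands on swap.

    nu-mt: nuclear side first.  mt-mt: smaller position first.  A junction
    read sequenced from the opposite strand yields swapped sides with both
    strands flipped, so canonicalisation makes the two sightings identical.
    """
    a, b = split.side_a, split.side_b
    mt_a, mt_b = a.contig == mt_contig, b.contig == mt_contig
    if mt_a and mt_b:
        kind = "mt_mt"
        swap = (a.pos, a.strand) > (b.pos, b.strand)
    elif mt_a != mt_b:
        kind = "nu_mt"
        swap = mt_a
    else:
        return None  # nuclear-nuclear split: not a NUMT junction
    if swap:
        a, b = (
            Side(b.contig, b.pos, _flip(b.strand)),
            Side(a.contig, a.pos, _flip(a.strand)),
        )
    return kind, a, b


def call_junctions(
    splits, tol: int = 5, mt_contig: str = MT_CONTIG
) -> list[Junction]:
    """Group split alignments whose breakpoints agree within ``tol`` bp on
    both sides into junctions; support = group size."""
    seeds: list[list] = []  # [kind, side_a, side_b, count]
    for split in splits:
        canon = _canonical_sides(split, mt_contig)
        if canon is None:
            continue
        kind, a, b = canon
        for seed in seeds:
            sk, sa, sb, _ = seed
            if (
                sk == kind
                and sa.contig == a.contig
                and sb.contig == b.contig
                and sa.strand == a.strand
                and sb.strand == b.strand
                and abs(sa.pos - a.pos) <= tol
                and abs(sb.pos - b.pos) <= tol
            ):
                seed[3] += 1
                break
        else:
            seeds.append([kind, a, b, 1])
    junctions = [
        Junction(kind=k, side_a=a, side_b=b, split_support=n)
        for k, a, b, n in seeds
    ]
    junctions.sort(key=lambda j: (j.kind, j.side_a.contig, j.side_a.pos, j.side_b.pos))
    return junctions


@dataclass(frozen=True)
class NumtCall:
    """A detected NUMT, per sample or grouped across the cohort."""

    numt_id: str
    nuclear_contig: str
    nuclear_interval: tuple[int, int]
    mt_interval: tuple[int, int]
    junctions: tuple[Junction, ...]
    mt_breakpoints: tuple[Side, ...]
    n_discordant: int
    n_split: int
    carriers: tuple[str, ...]
    cohort_frequency: float | None = None
    mega_evidence: bool = False
    build: str = "GRCh38"


def mt_span(call: NumtCall) -> int:
    """Linear distance between the two outermost mtDNA breakpoints, as printed
    (no circular wrap)."""
    positions = [s.pos for s in call.mt_breakpoints]
    if len(positions) < 2:
        raise ValueError(
            f"NUMT {call.numt_id}: mtDNA span undefined with "
            f"{len(positions)} breakpoint(s)"
        )
    return max(positions) - min(positions)


def detect_numts_sample(
    sample_id: str,
    reads,
    nuclear_refs,
    mt_ref: str,
    *,
    mapq_min: int = 20,
    gap: int = 500,
    min_pairs: int = 5,
    window: int = 1000,
    min_clip: int = 20,
    junction_tol: int = 5,
    min_piece: int = 20,
    min_identity: float = 0.9,
    realign_pad: int = 1500,
    locus_gap: int = 1000,
    mt_contig: str = MT_CONTIG,
    build: str = "GRCh38",
) -> list[NumtCall]:
    """Full per-sample detection: discordant clustering, split-read
    realignment, junction calling, one call per nuclear locus.

    ``nuclear_refs`` maps contig name to its sequence; split reads are
    realigned against a window of ``realign_pad`` bp around the locus.
    """
    reads = list(reads)
    pairs = extract_discordant_pairs(reads, mapq_min, mt_contig)
    clusters = cluster_discordant(pairs, gap, min_pairs)
    if not clusters:
        return []

    # group clusters into nuclear loci (single linkage within locus_gap)
    loci: list[dict] = []
    for c in sorted(clusters, key=lambda c: (c.nuclear_contig, c.nuclear_interval)):
        placed = False
        for locus in loci:
            if locus["contig"] != c.nuclear_contig:
                continue
            lo, hi = locus["interval"]
            if c.nuclear_interval[0] <= hi + locus_gap and c.nuclear_interval[1] >= lo - locus_gap:
                locus["interval"] = (
                    min(lo, c.nuclear_interval[0]),
                    max(hi, c.nuclear_interval[1]),
                )
                locus["clusters"].append(c)
                placed = True
                break
        if not placed:
            loci.append(
                {
                    "contig": c.nuclear_contig,
                    "interval": c.nuclear_interval,
                    "clusters": [c],
                }
            )

    split_candidates = find_split_reads(reads, clusters, window, min_clip, mt_contig)
    locus_splits: dict[int, list[SplitAlignment]] = {i: [] for i in range(len(loci))}
    for read in split_candidates:
        li = _nearest_locus(read, loci, window + realign_pad, mt_contig)
        if li is None:
            continue
        locus = loci[li]
        ref = nuclear_refs.get(locus["contig"])
        if ref is None:
            continue
        lo, hi = locus["interval"]
        ws = max(0, lo - 1 - realign_pad)
        we = min(len(ref), hi + realign_pad)
        split = realign_split(
            read.sequence,
            ref[ws:we],
            mt_ref,
            min_piece=min_piece,
            min_identity=min_identity,
            nuclear_contig=locus["contig"],
            nuclear_offset=ws,
            mt_contig=mt_contig,
            read_id=read.read_id,
        )
        if split is not None:
            locus_splits[li].append(split)

    calls: list[NumtCall] = []
    for li, locus in enumerate(loci):
        junctions = call_junctions(locus_splits[li], junction_tol, mt_contig)
        breakpoints = []
        for j in junctions:
            if j.kind != "nu_mt":
                continue
            for side in j.mt_sides():
                if all(
                    abs(side.pos - b.pos) > junction_tol or side.strand != b.strand
                    for b in breakpoints
                ):
                    breakpoints.append(side)
        mt_positions = [p for c in locus["clusters"] for p in c.mt_interval]
        mt_positions += [s.pos for s in breakpoints]
        mt_positions += [
            s.pos for j in junctions if j.kind == "mt_mt" for s in j.mt_sides()
        ]
        lo, hi = locus["interval"]
        calls.append(
            NumtCall(
                numt_id=f"{sample_id}:{locus['contig']}:{lo}",
                nuclear_contig=locus["contig"],
                nuclear_interval=(lo, hi),
                mt_interval=(min(mt_positions), max(mt_positions)),
                junctions=tuple(junctions),
                mt_breakpoints=tuple(sorted(breakpoints, key=lambda s: s.pos)),
                n_discordant=sum(c.n_pairs for c in locus["clusters"]),
                n_split=sum(j.split_support for j in junctions),
                carriers=(sample_id,),
                mega_evidence=any(
                    j.kind == "mt_mt" and j.split_support > 2 for j in junctions
                ),
                build=build,
            )
        )
    return calls


def _nearest_locus(read, loci, max_dist, mt_contig):
    if read.contig == mt_contig:
        # mt-only split candidate: no nuclear coordinate; attach to the single
        # locus, or to the one whose mt evidence is nearest
        if len(loci) == 1:
            return 0
        best, best_d = None, None
        for i, locus in enumerate(loci):
            for c in locus["clusters"]:
                d = min(
                    abs(read.pos - c.mt_interval[0]), abs(read.pos - c.mt_interval[1])
                )
                if best_d is None or d < best_d:
                    best, best_d = i, d
        return best
    for i, locus in enumerate(loci):
        if locus["contig"] != read.contig:
            continue
        lo, hi = locus["interval"]
        if lo - max_dist <= read.pos <= hi + max_dist:
            return i
    return None


def _interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[0] > b[1]:
        return a[0] - b[1]
    if b[0] > a[1]:
        return b[0] - a[1]
    return 0


def group_numts(
    per_sample_calls,
    cohort_size: int,
    nuclear_gap: int = 1000,
    mt_gap: int = 1000,
    junction_tol: int = 5,
) -> list[NumtCall]:
    """Single-linkage grouping of per-sample calls into cohort-level NUMTs.

    Two calls merge iff they sit on the same contig (and reference build)
    with nuclear intervals within ``nuclear_gap`` bp *and* mt intervals
    within ``mt_gap`` bp.  Carrier lists are unioned and the cohort frequency
    is carriers / ``cohort_size`` (individuals, not trios).
    """
    calls = list(per_sample_calls)
    if not calls:
        return []
    builds = {c.build for c in calls}
    if len(builds) > 1:
        raise ValueError(
            f"cannot group NUMT calls from mixed reference builds: {sorted(builds)}"
        )
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    parent = list(range(len(calls)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            a, b = calls[i], calls[j]
            if a.nuclear_contig != b.nuclear_contig:
                continue
            if _interval_gap(a.nuclear_interval, b.nuclear_interval) > nuclear_gap:
                continue
            if _interval_gap(a.mt_interval, b.mt_interval) > mt_gap:
                continue
            parent[find(i)] = find(j)

    groups: dict[int, list[NumtCall]] = {}
    for i in range(len(calls)):
        groups.setdefault(find(i), []).append(calls[i])

    merged: list[NumtCall] = []
    for members in groups.values():
        members.sort(key=lambda c: (c.nuclear_contig, c.nuclear_interval))
        carriers = tuple(sorted({s for c in members for s in c.carriers}))
        breakpoints: list[Side] = []
        for c in members:
            for side in c.mt_breakpoints:
                if all(
                    abs(side.pos - b.pos) > junction_tol or side.strand != b.strand
                    for b in breakpoints
                ):
                    breakpoints.append(side)
        merged.append(
            NumtCall(
                numt_id="",
                nuclear_contig=members[0].nuclear_contig,
                nuclear_interval=(
                    min(c.nuclear_interval[0] for c in members),
                    max(c.nuclear_interval[1] for c in members),
                ),
                mt_interval=(
                    min(c.mt_interval[0] for c in members),
                    max(c.mt_interval[1] for c in members),
                ),
                junctions=tuple(j for c in members for j in c.junctions),
                mt_breakpoints=tuple(sorted(breakpoints, key=lambda s: s.pos)),
                n_discordant=max(c.n_discordant for c in members),
                n_split=max(c.n_split for c in members),
                carriers=carriers,
                cohort_frequency=len(carriers) / cohort_size,
                mega_evidence=any(c.mega_evidence for c in members),
                build=members[0].build,
            )
        )
    merged.sort(key=lambda c: (c.nuclear_contig, c.nuclear_interval))
    return [
        replace(c, numt_id=f"numt_{i + 1}") for i, c in enumerate(merged)
    ]
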