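"""Discordant-pair extraction, clustering, junction calling and NUMT grouping."""

import itertools

import pytest

from meganumt.numt_detect import (
    AlignedRead,
    NumtCall,
    Side,
    SplitAlignment,
    call_junctions,
    cluster_discordant,
    extract_discordant_pairs,
    find_split_reads,
    group_numts,
    mt_span,
)


def read(rid, contig, pos, strand="+", mapq=60, cigar="150M", mate=None):
    mate_contig, mate_pos, mate_strand = mate or (None, None, None)
    return AlignedRead(
        read_id=rid,
        contig=contig,
        pos=pos,
        strand=strand,
        mapq=mapq,
        cigar=cigar,
        sequence="A" * 150,
        mate_contig=mate_contig,
        mate_pos=mate_pos,
        mate_strand=mate_strand,
    )


def pair(rid, nuc_pos, mt_pos, nuc_mapq=60, mt_mapq=60, nuc_contig="chr13",
         nuc_strand="+", mt_strand="-"):
    return [
        read(rid, nuc_contig, nuc_pos, nuc_strand, nuc_mapq,
             mate=("MT", mt_pos, mt_strand)),
        read(rid, "MT", mt_pos, mt_strand, mt_mapq,
             mate=(nuc_contig, nuc_pos, nuc_strand)),
    ]


def test_extract_discordant_pairs():
    reads = (
        pair("a", 1000, 500)
        + pair("b", 1100, 520, nuc_mapq=19)  # nuclear end below mapq 20
        + [read("c", "chr13", 1000), read("c", "chr13", 1300)]  # concordant
        + [read("d", "chr13", 1000)]  # unpaired
    )
    pairs = extract_discordant_pairs(reads)
    assert [p[0].read_id for p in pairs] == ["a"]
    nuc, mt = pairs[0]
    assert (nuc.contig, mt.contig) == ("chr13", "MT")


def test_cluster_thresholds_and_orientation():
    five = [pair(f"p{i}", 1000 + 60 * i, 500 + i)[0:2] for i in range(5)]
    pairs = [(a, b) for a, b in five]
    clusters = cluster_discordant(pairs)
    assert len(clusters) == 1
    c = clusters[0]
    assert c.n_pairs == 5
    assert c.nuclear_interval == (1000, 1240)
    assert c.mt_interval == (500, 504)
    assert cluster_discordant(pairs[:4]) == []  # below the 5-pair threshold
    # 3+2 split by orientation: neither group reaches five pairs
    mixed = [tuple(pair(f"m{i}", 1000 + 10 * i, 500, nuc_strand="+" if i < 3 else "-"))
             for i in range(5)]
    assert cluster_discordant(mixed) == []


def test_cluster_chaining_matches_brute_force():
    # single-linkage on sorted positions == transitive closure of pairwise <=gap
    positions = [100, 550, 1060, 1580, 4000, 4400, 4900, 9000]
    pairs = [tuple(pair(f"x{i}", p, 500)) for i, p in enumerate(positions)]
    clusters = cluster_discordant(pairs, gap=520, min_pairs=1)
    got = sorted(c.nuclear_interval for c in clusters)

    # brute force: union-find over all pairs within gap
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(positions)), 2):
        if abs(positions[i] - positions[j]) <= 520:
            parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(positions):
        groups.setdefault(find(i), []).append(p)
    expected = sorted((min(g), max(g)) for g in groups.values())
    assert got == expected


def test_each_pair_in_at_most_one_cluster():
    pairs = [tuple(pair(f"p{i}", 1000 + 60 * i, 500)) for i in range(12)]
    clusters = cluster_discordant(pairs, min_pairs=1)
    seen = [p[0].read_id for c in clusters for p in c.pairs]
    assert len(seen) == len(set(seen)) == 12


def test_find_split_reads_window():
    pairs = [tuple(pair(f"p{i}", 2000 + 10 * i, 500)) for i in range(5)]
    clusters = cluster_discordant(pairs)
    near = read("s1", "chr13", 2040 + 800, cigar="75M75S")
    far = read("s2", "chr13", 2040 + 1600, cigar="75M75S")
    unclipped = read("s3", "chr13", 2045, cigar="150M")
    mt_clip = read("s4", "MT", 9000, cigar="80M70S")
    got = find_split_reads([near, far, unclipped, mt_clip], clusters)
    assert [r.read_id for r in got] == ["s1", "s4"]


def split(pos_nu, pos_mt, rid="r", strand_nu="+", strand_mt="+"):
    return SplitAlignment(
        read_id=rid,
        breakpoint=75,
        score=150,
        side_a=Side("chr3", pos_nu, strand_nu),
        side_b=Side("MT", pos_mt, strand_mt),
        identity_a=1.0,
        identity_b=1.0,
    )


def test_call_junctions_grouping_and_support():
    splits = [split(56128996, 11126, rid=f"r{i}") for i in range(3)]
    junctions = call_junctions(splits)
    assert len(junctions) == 1
    j = junctions[0]
    assert j.kind == "nu_mt"
    assert j.split_support == 3
    assert j.side_a == Side("chr3", 56128996, "+")
    assert j.side_b == Side("MT", 11126, "+")
    assert call_junctions([]) == []


def test_call_junctions_tolerance_and_mega_rule():
    mt_splits = [
        SplitAlignment("a", 75, 150, Side("MT", 14977, "+"), Side("MT", 12864, "-"), 1.0, 1.0),
        SplitAlignment("b", 70, 150, Side("MT", 14975, "+"), Side("MT", 12861, "-"), 1.0, 1.0),
        SplitAlignment("c", 70, 150, Side("MT", 14900, "+"), Side("MT", 12861, "-"), 1.0, 1.0),
    ]
    junctions = call_junctions(mt_splits)
    assert sorted(j.split_support for j in junctions) == [1, 2]
    assert all(j.kind == "mt_mt" for j in junctions)
    # two supporting reads is never mega evidence
    assert all(not j.split_support > 2 for j in junctions)


def test_call_junctions_canonicalises_swapped_sides():
    # same junction read from the other orientation: sides swapped, strands flipped
    a = SplitAlignment("a", 75, 150, Side("chr3", 100, "+"), Side("MT", 5000, "+"), 1.0, 1.0)
    b = SplitAlignment("b", 75, 150, Side("MT", 5000, "-"), Side("chr3", 100, "-"), 1.0, 1.0)
    junctions = call_junctions([a, b])
    assert len(junctions) == 1
    assert junctions[0].split_support == 2


def _call(sample, start, mt_lo, mt_hi, build="GRCh38"):
    return NumtCall(
        numt_id=sample,
        nuclear_contig="chr5",
        nuclear_interval=(start, start + 400),
        mt_interval=(mt_lo, mt_hi),
        junctions=(),
        mt_breakpoints=(Side("MT", mt_lo, "+"), Side("MT", mt_hi, "-")),
        n_discordant=8,
        n_split=4,
        carriers=(sample,),
        build=build,
    )


def test_group_numts_both_axes():
    a = _call("s1", 10_000, 3000, 4000)
    b = _call("s2", 10_800, 3100, 4100)  # within 1 kb on both axes
    c = _call("s3", 10_800, 9000, 9800)  # nuclear close, mt 5 kb away
    grouped = group_numts([a, b, c], cohort_size=100)
    carriers = sorted(tuple(g.carriers) for g in grouped)
    assert carriers == [("s1", "s2"), ("s3",)]
    merged = next(g for g in grouped if len(g.carriers) == 2)
    assert merged.cohort_frequency == pytest.approx(2 / 100)


def test_group_numts_partition_and_order_invariance():
    calls = [_call(f"s{i}", 10_000 + 300 * i, 3000, 4000) for i in range(4)]
    calls.append(_call("far", 50_000, 3000, 4000))
    for perm in (calls, calls[::-1]):
        grouped = group_numts(perm, cohort_size=10)
        all_carriers = sorted(s for g in grouped for s in g.carriers)
        assert all_carriers == sorted(c.carriers[0] for c in calls)  # partition
        assert sorted(len(g.carriers) for g in grouped) == [1, 4]


def test_group_numts_frequency_denominator():
    calls = [_call(f"s{i}", 10_000, 3000, 4000) for i in range(6)]
    grouped = group_numts(calls, cohort_size=33_105)
    assert len(grouped) == 1
    assert grouped[0].cohort_frequency == pytest.approx(6 / 33_105)


def test_group_numts_mixed_builds_error():
    with pytest.raises(ValueError, match="builds"):
        group_numts(
            [_call("a", 1000, 100, 900), _call("b", 1000, 100, 900, build="GRCh37")],
            cohort_size=10,
        )


def test_mt_span():
    call = _call("s", 1000, 1641, 13441)
    assert mt_span(call) == 11_800
    assert mt_span(_call("s", 1000, 100, 550)) == 450
    same = NumtCall(
        numt_id="x", nuclear_contig="chr1", nuclear_interval=(1, 2),
        mt_interval=(100, 100), junctions=(),
        mt_breakpoints=(Side("MT", 100, "+"), Side("MT", 100, "-")),
        n_discordant=5, n_split=1, carriers=("s",),
    )
    assert mt_span(same) == 0
    single = NumtCall(
        numt_id="x", nuclear_contig="chr1", nuclear_interval=(1, 2),
        mt_interval=(100, 100), junctions=(),
        mt_breakpoints=(Side("MT", 100, "+"),),
        n_discordant=5, n_split=1, carriers=("s",),
    )
    with pytest.raises(ValueError, match="span"):
        mt_span(single)
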