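"""mtDNA variant records, filter cascade, homoplasmy and detection rules."""

import logging

import pytest
from hypothesis import given
from hypothesis import strategies as st

from meganumt.mt_calls import (
    MT_LENGTH,
    MtVariant,
    SampleCallset,
    filter_variants,
    heteroplasmy_count,
    in_masked_region,
    is_detected,
    is_homoplasmic,
    trio_depth_qc,
)

from conftest import make_callset, make_variant


@pytest.mark.parametrize(
    "position, af, depth, kept",
    [
        (16183, 0.30, 1000, False),  # low-complexity region 16182-16194
        (5000, 0.50, 150, False),  # depth below 200x
        (5000, 0.50, 1000, True),  # passes every rule
        (5000, 0.005, 1000, False),  # AF at/below the 1% floor
        (66, 0.30, 1000, False),  # masked region boundary
        (72, 0.30, 1000, True),  # just outside the masked region
    ],
)
def test_filter_cascade(position, af, depth, kept):
    v = make_variant(position=position, af=af, depth=depth)
    assert (v in filter_variants([v])) is kept


def test_filter_minor_allele_strand_rule():
    # af 0.05, 49/1 strand split for the alt (minor) allele: strand-biased
    v = MtVariant.from_counts(5000, "A", "G", 1000, 49, 1, ref_fwd=475, ref_rev=475)
    assert filter_variants([v]) == []
    balanced = MtVariant.from_counts(5000, "A", "G", 1000, 25, 25, ref_fwd=475, ref_rev=475)
    assert filter_variants([balanced]) == [balanced]


def test_filter_strand_rule_majority_allele_uses_reference_reads():
    # AF 0.7: the minor allele is the reference; its strand split decides
    biased = MtVariant.from_counts(5000, "A", "G", 1000, 350, 350, ref_fwd=299, ref_rev=1)
    assert filter_variants([biased]) == []
    ok = MtVariant.from_counts(5000, "A", "G", 1000, 350, 350, ref_fwd=150, ref_rev=150)
    assert filter_variants([ok]) == [ok]


def test_filter_majority_without_ref_strands_warns_and_uses_alt(caplog):
    v = MtVariant.from_counts(5000, "A", "G", 1000, 350, 350)
    with caplog.at_level(logging.WARNING, logger="meganumt.mt_calls"):
        assert filter_variants([v]) == [v]
    assert any("reference strand counts" in r.message for r in caplog.records)


def test_filter_keeps_homoplasmies_without_minor_allele_reads():
    # a fixed allele (AF 1.0) has no minor allele to strand-check
    v = MtVariant.from_counts(5000, "A", "G", 1000, 500, 500, ref_fwd=0, ref_rev=0)
    assert filter_variants([v]) == [v]


def test_filter_invalid_position_raises():
    v = make_variant(position=1)
    object.__setattr__(v, "position", 20000)
    with pytest.raises(ValueError, match="20000"):
        filter_variants([v])


@given(
    st.lists(
        st.tuples(
            st.integers(min_value=1, max_value=MT_LENGTH),
            st.floats(min_value=0.0, max_value=1.0),
            st.integers(min_value=1, max_value=3000),
        ),
        max_size=30,
    )
)
def test_filter_idempotent_and_subset(raw_specs):
    raw = [
        make_variant(position=pos, af=af, depth=depth)
        for pos, af, depth in raw_specs
    ]
    once = filter_variants(raw)
    assert all(v in raw for v in once)  # subset, nothing invented
    assert filter_variants(once) == once  # idempotent
    # order preserved (compare by object identity: duplicates are allowed)
    ids = [id(v) for v in raw]
    idx = [ids.index(id(v)) for v in once]
    assert idx == sorted(idx)


@pytest.mark.parametrize("af, expected", [(0.96, True), (0.95, False), (0.30, False)])
def test_homoplasmy_strict_threshold(af, expected):
    assert is_homoplasmic(make_variant(af=af)) is expected


@given(st.floats(min_value=0.951, max_value=1.0), st.floats(min_value=0.001, max_value=0.95))
def test_homoplasmic_implies_detected(af, threshold):
    cs = make_callset("s", {5000: af})
    v = cs.variants[(5000, "G")]
    if is_homoplasmic(v):
        assert is_detected(cs, (5000, "G"), threshold)


def test_is_detected_strict_boundary():
    cs = make_callset("s", {100: 0.06, 200: 0.05})
    assert is_detected(cs, (100, "G"), 0.05)
    assert not is_detected(cs, (200, "G"), 0.05)
    assert not is_detected(cs, (300, "G"), 0.05)


@pytest.mark.parametrize(
    "depths, expected",
    [((900, 800, 499), False), ((500, 500, 500), True), ((2000, 2000, 2000), True)],
)
def test_trio_depth_qc(depths, expected):
    f, m, c = (make_callset(s, {100: 0.5}, mean_mt_depth=d) for s, d in zip("fmc", depths))
    assert trio_depth_qc(f, m, c) is expected


def test_variant_invariants_enforced():
    with pytest.raises(ValueError):  # indel rejected at parse time
        MtVariant.from_counts(100, "A", "AT", 1000, 50, 50)
    with pytest.raises(ValueError):  # ref == alt
        MtVariant.from_counts(100, "A", "A", 1000, 50, 50)
    with pytest.raises(ValueError):  # strand counts exceed depth
        MtVariant.from_counts(100, "A", "G", 80, 50, 50)
    with pytest.raises(ValueError):  # af inconsistent with counts
        MtVariant(100, "A", "G", 1000, 50, 50, af=0.5)


def test_callset_rejects_duplicates_and_bad_depth():
    v = make_variant()
    with pytest.raises(ValueError, match="duplicate"):
        SampleCallset.from_variants("s", [v, v], 1000.0)
    with pytest.raises(ValueError, match="depth"):
        SampleCallset.from_variants("s", [v], 0.0)


def test_heteroplasmy_count_bounds():
    cs = make_callset("s", {100: 0.005, 200: 0.02, 300: 0.5, 400: 0.95, 500: 0.96})
    # 1% < af <= 95%: positions 200, 300 and 400
    assert heteroplasmy_count(cs) == 3


def test_masked_regions_inclusive():
    for lo, hi in [(66, 71), (3106, 3107), (16182, 16194)]:
        assert in_masked_region(lo) and in_masked_region(hi)
        assert not in_masked_region(lo - 1) and not in_masked_region(hi + 1)


def test_tsv_roundtrip(tmp_path):
    from meganumt.io import read_callsets_tsv, write_callsets_tsv

    callsets = {
        "s1": [make_variant(100, af=0.2), make_variant(200, af=0.96)],
        "s2": [make_variant(300, af=0.5, ref_strands=False)],
    }
    path = tmp_path / "calls.tsv"
    write_callsets_tsv(callsets, path)
    back = read_callsets_tsv(path)
    assert back == callsets


def test_vcf_reader(tmp_path):
    from meganumt.io import read_callset_vcf

    vcf_text = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=MT,length=16569>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        '##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Fwd depths">\n'
        '##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Rev depths">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "MT\t5000\t.\tA\tG\t.\tPASS\t.\tGT:DP:ADF:ADR\t0/1:1000:400,100:400,100\n"
        "MT\t6000\t.\tC\tCT\t.\tPASS\t.\tGT:DP:ADF:ADR\t0/1:900:400,50:400,50\n"
    )
    path = tmp_path / "s1.vcf"
    path.write_text(vcf_text)
    variants = read_callset_vcf(path)
    assert len(variants) == 1  # the indel record is skipped
    v = variants[0]
    assert (v.position, v.alt_allele, v.depth) == (5000, "G", 1000)
    assert (v.alt_fwd, v.alt_rev, v.ref_fwd, v.ref_rev) == (100, 100, 400, 400)
    assert v.af == pytest.approx(0.2)
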