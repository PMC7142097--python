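"""Trio mixed-haplotype screen, father-led screen and the IQR fence."""

import numpy as np
import pytest

from meganumt.numt_detect import NumtCall, Side
from meganumt.trio_screen import (
    Trio,
    TrioStatus,
    classify_trio,
    find_meganumt_fathers,
    informative_variants,
    iqr_outlier_threshold,
    screen_cohort,
    shared_paternal_variants,
)

from conftest import make_callset
from oracles import tukey_fence_oracle


def make_trio(trio_id, father_afs, mother_afs, child_afs, depth=1000.0):
    return Trio(
        trio_id=trio_id,
        father=make_callset(f"{trio_id}F", father_afs, depth),
        mother=make_callset(f"{trio_id}M", mother_afs, depth),
        child=make_callset(f"{trio_id}C", child_afs, depth),
    )


@pytest.mark.parametrize(
    "father, mother, expected",
    [
        ({100: 0.30}, {}, [(100, "G")]),
        ({100: 0.30}, {100: 0.02}, []),  # shared with mother: non-informative
        ({100: 0.04}, {}, []),  # below the 5% screening threshold
    ],
)
def test_informative_variants(father, mother, expected):
    f = make_callset("f", father)
    m = make_callset("m", mother)
    assert informative_variants(f, m) == expected


@pytest.mark.parametrize(
    "child_afs, expected",
    [({100: 0.15}, [(100, "G")]), ({100: 0.04}, []), ({}, [])],
)
def test_shared_paternal_variants(child_afs, expected):
    trio = make_trio("t", {100: 0.20}, {}, child_afs)
    assert shared_paternal_variants(trio) == expected


def test_classify_excluded_homoplasmy_mismatch():
    # father: 5 homoplasmies, child detects 2; plus one shared low-AF variant
    father = {p: 0.99 for p in (100, 200, 300, 400, 500)}
    father[600] = 0.20
    child = {100: 0.99, 200: 0.99, 600: 0.15}
    c = classify_trio(make_trio("t", father, {}, child))
    assert c.status == TrioStatus.EXCLUDED_HOMOPLASMY_MISMATCH
    assert sorted(p for p, _ in c.missing_homoplasmies) == [300, 400, 500]
    # the low-AF variant and both child-detected homoplasmies are shared
    assert (600, "G") in c.shared_paternal_variants
    assert len(c.shared_paternal_variants) == 3


def test_classify_mixed_haplotype_candidate():
    # shared sub-homoplasmic haplotype, no missing homoplasmies
    father = {p: 0.10 + 0.015 * i for i, p in enumerate(range(100, 1100, 100))}
    child = {p: 0.15 for p in range(100, 1100, 100)}
    c = classify_trio(make_trio("t", father, {}, child))
    assert c.status == TrioStatus.MIXED_HAPLOTYPE_CANDIDATE
    assert len(c.shared_paternal_variants) == 10


def test_classify_two_missing_homoplasmies_is_still_candidate():
    father = {100: 0.99, 200: 0.99, 300: 0.20}
    child = {300: 0.15}
    c = classify_trio(make_trio("t", father, {}, child))
    assert c.status == TrioStatus.MIXED_HAPLOTYPE_CANDIDATE
    assert len(c.missing_homoplasmies) == 2


def test_classify_non_informative_and_informative_only():
    assert (
        classify_trio(make_trio("t", {100: 0.5}, {100: 0.5}, {})).status
        == TrioStatus.NON_INFORMATIVE
    )
    assert (
        classify_trio(make_trio("t", {100: 0.5}, {}, {})).status
        == TrioStatus.INFORMATIVE_ONLY
    )


def test_classify_depth_qc_error():
    trio = make_trio("t", {100: 0.5}, {}, {}, depth=400.0)
    with pytest.raises(ValueError, match="QC"):
        classify_trio(trio)
    assert classify_trio(trio, min_mt_depth=0).status == TrioStatus.INFORMATIVE_ONLY


def test_classify_permutation_invariant():
    father = {p: 0.2 for p in (100, 200, 300)}
    father.update({p: 0.99 for p in (400, 500)})
    trio = make_trio("t", father, {200: 0.3}, {100: 0.1})
    shuffled = Trio(
        trio_id="t",
        father=make_callset("tF", dict(reversed(list(father.items())))),
        mother=trio.mother,
        child=trio.child,
    )
    a, b = classify_trio(trio), classify_trio(shuffled)
    assert a.status == b.status
    assert set(a.informative_variants) == set(b.informative_variants)


def test_sibling_gets_own_classification():
    # proband shares the haplotype, a second sibling does not
    trio = make_trio("t", {100: 0.2}, {}, {100: 0.15})
    sib = make_callset("tS", {})
    assert classify_trio(trio).status == TrioStatus.MIXED_HAPLOTYPE_CANDIDATE
    assert classify_trio(trio, child=sib).status == TrioStatus.INFORMATIVE_ONLY


def test_screen_cohort_counts_and_fraction():
    trios = [make_trio(f"c{i}", {100: 0.2}, {}, {100: 0.15}) for i in range(2)]
    trios += [make_trio(f"n{i}", {}, {}, {}) for i in range(6)]
    screen = screen_cohort(trios)
    assert screen.counts[TrioStatus.MIXED_HAPLOTYPE_CANDIDATE] == 2
    assert screen.counts[TrioStatus.NON_INFORMATIVE] == 6
    assert screen.candidate_fraction_pct == pytest.approx(25.0)
    assert [c.trio_id for c in screen.candidates] == ["c0", "c1"]


def test_screen_empty_cohort():
    screen = screen_cohort([])
    assert screen.n_trios == 0
    assert screen.candidate_fraction_pct == 0.0


def _numt(carriers, span, freq):
    return NumtCall(
        numt_id="n1",
        nuclear_contig="chr1",
        nuclear_interval=(1000, 2000),
        mt_interval=(100, 100 + span),
        junctions=(),
        mt_breakpoints=(Side("MT", 100, "+"), Side("MT", 100 + span, "-")),
        n_discordant=10,
        n_split=5,
        carriers=tuple(carriers),
        cohort_frequency=freq,
    )


@pytest.mark.parametrize(
    "n_het, span, freq, selected",
    [
        (13, 600, 0.0005, True),
        (12, 600, 0.0005, False),  # strictly more than 12
        (20, 400, 0.0005, False),  # breakpoints not >500 bp apart
        (13, 600, 0.002, False),  # too frequent
    ],
)
def test_find_meganumt_fathers(n_het, span, freq, selected):
    father = make_callset("dad", {100 + 10 * i: 0.10 for i in range(n_het)})
    hits = find_meganumt_fathers([father], [_numt(["dad"], span, freq)])
    assert (hits == ["dad"]) is selected


def test_iqr_fence():
    assert iqr_outlier_threshold([3, 3, 3, 3, 3]) == 3.0
    counts = [1, 2, 3, 4, 100]
    assert iqr_outlier_threshold(counts) == pytest.approx(tukey_fence_oracle(counts))
    with pytest.raises(ValueError, match="at least 4"):
        iqr_outlier_threshold([1, 2, 3])


def test_iqr_fence_above_median_poisson():
    rng = np.random.default_rng(0)
    counts = rng.poisson(3, size=10_000)
    assert iqr_outlier_threshold(counts) >= np.median(counts)
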