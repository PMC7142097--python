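"""Synthetic cohort generator: determinism, maternal inheritance, planted
NUMT allele fractions and read evidence."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from meganumt.copy_htf import htf
from meganumt.mt_calls import MT_LENGTH
from meganumt.numt_detect import cluster_discordant, extract_discordant_pairs
from meganumt.splitalign import realign_split
from meganumt.synthetic import (
    PlantedNumt,
    PlantedSpec,
    SimConfig,
    make_references,
    simulate_cohort,
    simulate_numt_reads,
    simulate_trio,
)


def test_make_references_deterministic_and_sized():
    n1, m1 = make_references(3)
    n2, m2 = make_references(3)
    assert (n1, m1) == (n2, m2)
    assert len(m1) == MT_LENGTH == 16_569
    assert len(n1) == 100_000
    gc = (m1.count("G") + m1.count("C")) / len(m1)
    assert 0.3 <= gc <= 0.7
    assert make_references(4)[1] != m1


def test_maternal_inheritance_without_numt():
    trio, truth = simulate_trio(SimConfig(seed=5))
    assert not truth.carrier
    # the child's variant sites are exactly the mother's haplotype sites
    assert set(trio.child.variants) == set(trio.mother.variants)
    for key, v in trio.child.variants.items():
        assert v.af > 0.95
        assert trio.mother.variants[key].af > 0.95


def test_planted_numt_allele_fractions_match_htf():
    # pin depths so the expected AF has a closed form
    cfg = SimConfig(
        seed=6,
        dp_nu_range=(50, 50),
        dp_mt_range=(200, 4500),
        carrier_min_mt_depth=600,
        nmt_copies_range=(20, 20),
        max_carrier_htf=0.95,
    )
    afs, expected = [], []
    for rep in range(60):
        trio, truth = simulate_trio(
            cfg, planted=PlantedSpec(transmit=False, regime="same"), seed=600 + rep
        )
        assert truth.carrier
        numt_keys = [
            k for k, v in trio.father.variants.items() if v.af <= 0.95
        ]
        afs.extend(trio.father.variants[k].af for k in numt_keys)
        expected.extend([truth.htf_father] * len(numt_keys))
    afs, expected = np.array(afs), np.array(expected)
    assert abs(float(np.mean(afs - expected))) < 0.01
    assert np.all(np.abs(afs - expected) < 0.15)


def test_numt_allele_counts_binomial_gof():
    # 1,000 draws of a NUMT allele's alt count fit Binomial(depth, htf)
    rng = np.random.default_rng(9)
    dp_nu, dp_mt, k = 40, 1000, 6
    p = htf(dp_nu, dp_mt, k)
    depth = int(dp_mt + dp_nu / 2 * k)
    draws = rng.binomial(depth, p, size=1000)
    cuts = np.unique(stats.binom.ppf(np.linspace(0.1, 0.9, 9), depth, p))
    edges = np.concatenate([[-0.5], cuts + 0.5, [depth + 0.5]])
    observed, _ = np.histogram(draws, bins=edges)
    probs = np.diff(stats.binom.cdf(edges, depth, p))
    chi2 = stats.chisquare(observed, probs / probs.sum() * 1000)
    assert chi2.pvalue > 0.01


def test_transmission_probability_half():
    cfg = SimConfig(
        n_trios=120, seed=8, planted=tuple(PlantedSpec() for _ in range(120))
    )
    bundle = simulate_cohort(cfg)
    transmitted = sum(t.transmitted for t in bundle.truths.values())
    # binomial 95% band around 0.5 for n=120
    assert 0.37 <= transmitted / 120 <= 0.63


def _planted(mt_ref, fragments, copies):
    return PlantedNumt(
        numt_id="p",
        nuclear_contig="chr1",
        insertion_pos=50_000,
        fragments=fragments,
        copies=copies,
        source_sites=(),
    )


def test_single_fragment_single_copy_has_no_mt_mt_reads():
    nuclear, mt = make_references(10)
    planted = _planted(mt, ((2000, 2600, +1),), 1)
    reads = simulate_numt_reads(planted, 40, 150, 0, nuclear, mt)
    assert not any("mtmt" in r.read_id for r in reads)
    planted2 = _planted(mt, ((2000, 2600, +1),), 2)
    reads2 = simulate_numt_reads(planted2, 40, 150, 0, nuclear, mt)
    assert any("mtmt" in r.read_id for r in reads2)


def test_mt_mt_split_reads_realign_to_fragment_endpoints():
    nuclear, mt = make_references(11)
    fragments = ((3000, 3700, +1), (9000, 8300, -1))  # second fragment reverse
    planted = _planted(mt, fragments, 4)
    reads = simulate_numt_reads(planted, 60, 150, 1, nuclear, mt)
    checked = 0
    for r in reads:
        if "mtmt0" not in r.read_id:
            continue
        s = realign_split(r.sequence, None, mt, read_id=r.read_id)
        assert s is not None
        assert abs(s.side_a.pos - 3700) <= 5 and s.side_a.strand == "+"
        assert abs(s.side_b.pos - 9000) <= 5 and s.side_b.strand == "-"
        checked += 1
    assert checked >= 3


def test_fragment_outside_mt_raises():
    nuclear, mt = make_references(12)
    planted = _planted(mt, ((16_500, 17_200, +1),), 2)
    with pytest.raises(ValueError, match="outside"):
        simulate_numt_reads(planted, 40, 150, 0, nuclear, mt)


def test_discordant_support_at_40x():
    # >=5 discordant pairs per junction side in >=95% of 200 seeded replicates
    nuclear, mt = make_references(13)
    planted = _planted(mt, ((2000, 2900, +1),), 3)
    rng = np.random.default_rng(40)
    ok = 0
    for _ in range(200):
        reads = simulate_numt_reads(planted, 40, 150, rng, nuclear, mt)
        clusters = cluster_discordant(extract_discordant_pairs(reads))
        if len(clusters) == 2 and all(c.n_pairs >= 5 for c in clusters):
            ok += 1
    assert ok / 200 >= 0.95


def test_non_carrier_samples_have_no_discordant_reads():
    cfg = SimConfig(n_trios=4, seed=14, planted=(PlantedSpec(transmit=False),))
    bundle = simulate_cohort(cfg)
    carrier_fathers = {
        p for numt in bundle.planted.values() for p in numt.carrier_ids
    }
    for sid, reads in bundle.reads.items():
        pairs = extract_discordant_pairs(reads)
        if sid in carrier_fathers:
            assert pairs
        else:
            assert pairs == []


def test_truth_labels_match_screen(small_cohort):
    from meganumt.trio_screen import screen_cohort

    bundle = small_cohort
    got = {c.trio_id: c.status for c in screen_cohort(bundle.trios).classifications}
    for tid, truth in bundle.truths.items():
        if truth.expected_status == "excluded_qc":
            continue  # removed by depth QC before screening in the pipeline
        assert got[tid] == truth.expected_status, tid


def test_bundle_write_is_byte_identical(tmp_path):
    cfg = SimConfig(n_trios=3, seed=15, planted=(PlantedSpec(transmit=True, regime="same"),))
    for d in ("a", "b"):
        simulate_cohort(cfg).write(tmp_path / d)
    for name in ["refs.fasta", "callsets.tsv", "pedigree.tsv", "samples.tsv",
                 "truth.json", "config.json"]:
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
    sams_a = sorted((tmp_path / "a" / "reads").glob("*.sam"))
    sams_b = sorted((tmp_path / "b" / "reads").glob("*.sam"))
    assert [p.name for p in sams_a] == [p.name for p in sams_b]
    for pa, pb in zip(sams_a, sams_b):
        assert pa.read_bytes() == pb.read_bytes()


def test_bundle_roundtrip(tmp_path):
    from meganumt.io import load_bundle

    cfg = SimConfig(n_trios=3, seed=16, planted=(PlantedSpec(transmit=True, regime="same"),))
    bundle = simulate_cohort(cfg)
    bundle.write(tmp_path / "c")
    back = load_bundle(tmp_path / "c")
    assert back.config == bundle.config
    assert back.raw_callsets == bundle.raw_callsets
    assert back.pedigree == bundle.pedigree
    assert {k: dataclasses.asdict(v) for k, v in back.truths.items()} == {
        k: dataclasses.asdict(v) for k, v in bundle.truths.items()
    }
    assert back.planted == bundle.planted
    assert set(back.reads) == set(bundle.reads)
    for sid in back.reads:
        assert back.reads[sid] == bundle.reads[sid]


def test_empty_cohort(tmp_path):
    from meganumt.io import load_bundle

    bundle = simulate_cohort(SimConfig(n_trios=0, seed=17))
    bundle.write(tmp_path / "e")
    back = load_bundle(tmp_path / "e")
    assert back.pedigree == [] and back.truths == {}
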