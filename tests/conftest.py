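import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from meganumt.mt_calls import MtVariant, SampleCallset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_variant(
    position=5000,
    af=0.10,
    depth=1000,
    ref="A",
    alt="G",
    ref_strands=True,
) -> MtVariant:
    """A valid variant with the requested AF, strands split evenly."""
    alt_n = int(round(af * depth))
    ref_n = depth - alt_n
    return MtVariant.from_counts(
        position=position,
        ref_allele=ref,
        alt_allele=alt,
        depth=depth,
        alt_fwd=alt_n // 2,
        alt_rev=alt_n - alt_n // 2,
        ref_fwd=ref_n // 2 if ref_strands else None,
        ref_rev=ref_n - ref_n // 2 if ref_strands else None,
    )


def make_callset(sample_id, site_afs, mean_mt_depth=1000.0, depth=1000):
    """Callset from {position: af} or {(position, alt): af}."""
    variants = []
    for key, af in site_afs.items():
        pos, alt = key if isinstance(key, tuple) else (key, "G")
        variants.append(make_variant(position=pos, af=af, depth=depth, alt=alt))
    return SampleCallset.from_variants(sample_id, variants, mean_mt_depth)


@pytest.fixture(scope="session")
def small_cohort():
    """16-trio cohort with three planted mega-NUMT fathers: one transmitting
    within-haplogroup (candidate), one transmitting across haplogroups
    (excluded by homoplasmy mismatch), one non-transmitting."""
    from meganumt.synthetic import PlantedSpec, SimConfig, simulate_cohort

    cfg = SimConfig(
        n_trios=16,
        seed=11,
        planted=(
            PlantedSpec(transmit=True, regime="same"),
            PlantedSpec(transmit=True, regime="different"),
            PlantedSpec(transmit=False, regime="same"),
        ),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_report(small_cohort):
    from meganumt.pipeline import run_full_screen

    # the rarity cut scales with cohort size (0.1% presumes ~33k individuals)
    return run_full_screen(
        small_cohort, seed=1, numt_freq_max=6.5 / small_cohort.n_individuals
    )


@pytest.fixture(scope="session")
def small_refs():
    """Short references for alignment tests: 500 bp nuclear window and a
    700 bp circular mtDNA stand-in."""
    rng = np.random.default_rng(2024)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    nuclear = bases[rng.integers(0, 4, size=500)].tobytes().decode()
    mt = bases[rng.integers(0, 4, size=700)].tobytes().decode()
    return nuclear, mt
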