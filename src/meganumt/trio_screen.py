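"""Trio-level screen for mixed mtDNA haplotypes.

The screen asks, for each mother–father–child trio, whether the child shares
mtDNA variants with the father that the mother does not carry — the signature
that has been read as biparental mtDNA inheritance.  A trio is *informative*
when the father has at least one variant (AF > 5%) absent from the mother's
filtered callset; it becomes a *mixed-haplotype candidate* when the child
shares such a variant; it is *excluded* when the father additionally carries
three or more homoplasmies (AF > 95%) that the child does not show at AF > 5%,
because genuine paternal mtDNA transmission would carry the whole paternal
haplotype, not a subset.

The module also implements the independent father-led screen: fathers with an
outlying number of heteroplasmies (more than 12 at AF > 1%, or a Tukey/IQR
fence computed from the cohort) who carry a rare, large NUMT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mt_calls import (
    SampleCallset,
    heteroplasmy_count,
    is_detected,
    trio_depth_qc,
)
from .numt_detect import NumtCall, mt_span

__all__ = [
    "TrioStatus",
    "Trio",
    "TrioClassification",
    "CohortScreen",
    "informative_variants",
    "shared_paternal_variants",
    "classify_trio",
    "screen_cohort",
    "find_meganumt_fathers",
    "iqr_outlier_threshold",
]


class TrioStatus:
    """Outcome labels of the trio screen."""

    NON_INFORMATIVE = "non_informative"
    INFORMATIVE_ONLY = "informative_only"
    EXCLUDED_HOMOPLASMY_MISMATCH = "excluded_homoplasmy_mismatch"
    MIXED_HAPLOTYPE_CANDIDATE = "mixed_haplotype_candidate"

    ALL = (
        NON_INFORMATIVE,
        INFORMATIVE_ONLY,
        EXCLUDED_HOMOPLASMY_MISMATCH,
        MIXED_HAPLOTYPE_CANDIDATE,
    )


@dataclass
class Trio:
    trio_id: str
    father: SampleCallset
    mother: SampleCallset
    child: SampleCallset
    extra_sibs: tuple[SampleCallset, ...] = ()

    def __post_init__(self) -> None:
        ids = [self.father.sample_id, self.mother.sample_id, self.child.sample_id]
        ids += [s.sample_id for s in self.extra_sibs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids within trio {self.trio_id}: {ids}")


@dataclass
class TrioClassification:
    """Per-trio screen outcome with the variants driving the decision."""

    trio_id: str
    status: str
    informative_variants: dict[tuple[int, str], float]
    shared_paternal_variants: dict[tuple[int, str], tuple[float, float]]
    missing_homoplasmies: list[tuple[int, str]]


def informative_variants(
    father: SampleCallset, mother: SampleCallset, af_threshold: float = 0.05
) -> list[tuple[int, str]]:
    """Father variants at AF strictly above ``af_threshold`` whose key is absent
    from the mother's filtered callset.

    A variant present in the mother at *any* retained AF is non-informative.
    """
    return [
        k
        for k, v in father.variants.items()
        if v.af > af_threshold and k not in mother.variants
    ]


def shared_paternal_variants(
    trio: Trio, af_threshold: float = 0.05
) -> list[tuple[int, str]]:
    """Informative father variants also detected (AF > threshold) in the child."""
    return [
        k
        for k in informative_variants(trio.father, trio.mother, af_threshold)
        if is_detected(trio.child, k, af_threshold)
    ]


def classify_trio(
    trio: Trio,
    af_threshold: float = 0.05,
    homoplasmy_mismatch_min: int = 3,
    *,
    min_mt_depth: float = 500.0,
    child: SampleCallset | None = None,
) -> TrioClassification:
    """Classify one trio under the mixed-haplotype screen.

    ``child`` may substitute a sibling's callset for the trio's proband, so
    extra siblings receive their own father–child classification without
    changing the trio's own status.

    Raises ``ValueError`` when the trio fails the mean mtDNA depth QC (pass
    ``min_mt_depth=0`` for pre-QC'd cohorts).
    """
    kid = trio.child if child is None else child
    if min_mt_depth and not trio_depth_qc(
        trio.father, trio.mother, kid, min_mt_depth
    ):
        raise ValueError(
            f"trio {trio.trio_id} fails mtDNA depth QC (<{min_mt_depth}x); "
            "exclude upstream"
        )
    info = informative_variants(trio.father, trio.mother, af_threshold)
    info_afs = {k: trio.father.variants[k].af for k in info}
    shared = [k for k in info if is_detected(kid, k, af_threshold)]
    shared_afs = {
        k: (trio.father.variants[k].af, kid.variants[k].af) for k in shared
    }
    missing = [
        k
        for k in trio.father.homoplasmies()
        if not is_detected(kid, k, af_threshold)
    ]
    if not info:
        status = TrioStatus.NON_INFORMATIVE
    elif not shared:
        status = TrioStatus.INFORMATIVE_ONLY
    elif len(missing) >= homoplasmy_mismatch_min:
        status = TrioStatus.EXCLUDED_HOMOPLASMY_MISMATCH
    else:
        status = TrioStatus.MIXED_HAPLOTYPE_CANDIDATE
    return TrioClassification(
        trio_id=trio.trio_id,
        status=status,
        informative_variants=info_afs,
        shared_paternal_variants=shared_afs,
        missing_homoplasmies=missing,
    )


@dataclass
class CohortScreen:
    """Tally of trio statuses plus the candidate list."""

    n_trios: int
    counts: dict[str, int]
    classifications: list[TrioClassification] = field(repr=False, default_factory=list)

    @property
    def candidates(self) -> list[TrioClassification]:
        return [
            c
            for c in self.classifications
            if c.status == TrioStatus.MIXED_HAPLOTYPE_CANDIDATE
        ]

    @property
    def candidate_fraction_pct(self) -> float:
        """Candidate trios as a percentage of all screened trios."""
        if self.n_trios == 0:
            return 0.0
        return 100.0 * self.counts[TrioStatus.MIXED_HAPLOTYPE_CANDIDATE] / self.n_trios


def screen_cohort(
    trios,
    af_threshold: float = 0.05,
    homoplasmy_mismatch_min: int = 3,
    *,
    min_mt_depth: float = 0.0,
) -> CohortScreen:
    """Classify every trio and tally the statuses.

    Trios are assumed to have passed QC upstream (``min_mt_depth`` defaults to
    disabled here, unlike :func:`classify_trio`).
    """
    counts = {s: 0 for s in TrioStatus.ALL}
    classifications = []
    n = 0
    for trio in trios:
        n += 1
        c = classify_trio(
            trio,
            af_threshold,
            homoplasmy_mismatch_min,
            min_mt_depth=min_mt_depth,
        )
        counts[c.status] += 1
        classifications.append(c)
    return CohortScreen(n_trios=n, counts=counts, classifications=classifications)


def find_meganumt_fathers(
    fathers,
    numts,
    het_min: int = 12,
    numt_freq_max: float = 0.001,
    mt_span_min: float = 500.0,
) -> list[str]:
    """Father-led mega-NUMT screen.

    Selects fathers carrying strictly more than ``het_min`` heteroplasmies
    (1% < AF <= 95%) *and* at least one NUMT that is rare in the cohort
    (frequency strictly below ``numt_freq_max``) with its two outermost mtDNA
    breakpoints strictly more than ``mt_span_min`` bp apart.
    """
    carrier_numts: dict[str, list[NumtCall]] = {}
    for call in numts:
        for sid in call.carriers:
            carrier_numts.setdefault(sid, []).append(call)

    hits: list[str] = []
    for father in fathers:
        if heteroplasmy_count(father) <= het_min:
            continue
        for call in carrier_numts.get(father.sample_id, []):
            if call.cohort_frequency is None:
                continue
            if call.cohort_frequency >= numt_freq_max:
                continue
            if len(call.mt_breakpoints) < 2:
                continue
            if mt_span(call) > mt_span_min:
                hits.append(father.sample_id)
                break
    return hits


def iqr_outlier_threshold(het_counts) -> float:
    """Tukey upper fence Q3 + 1.5*IQR of per-father heteroplasmy counts.

    Quartiles use linear-interpolation quantiles.  This is the data-driven
    analogue of the fixed ">12 heteroplasmies" cut.  Requires >= 4 values.
    """
    x = np.asarray(list(het_counts), dtype=float)
    if x.size < 4:
        raise ValueError(
            f"need at least 4 heteroplasmy counts for an IQR fence, got {x.size}"
        )
    q1, q3 = np.quantile(x, [0.25, 0.75])
    return float(q3 + 1.5 * (q3 - q1))
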