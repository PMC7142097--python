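"""mtDNA variant records and the variant-level filtering / homoplasmy rules.

A sample's mtDNA callset is a table of single-nucleotide variants on the
16,569 bp circular mitochondrial reference, each with total depth and
per-strand read counts for the alternate allele.  Variants pass through a
fixed filter cascade before any trio-level reasoning:

1. allele fraction (AF) strictly above 1%;
2. single-nucleotide substitutions only (indels are rejected at parse time);
3. site depth >= 200x;
4. at least two reads on each strand supporting the minor allele;
5. site outside six low-complexity regions of the mitochondrial genome.

Homoplasmy is conservatively defined as AF > 95%; everything retained between
1% and 95% counts as a heteroplasmy.  All threshold comparisons are strict in
the printed direction, and boundary behaviour is pinned down by tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = [
    "MT_LENGTH",
    "MASKED_REGIONS",
    "MtVariant",
    "SampleCallset",
    "filter_variants",
    "is_homoplasmic",
    "is_detected",
    "trio_depth_qc",
    "in_masked_region",
    "heteroplasmy_count",
]

log = logging.getLogger(__name__)

#: Length of the revised Cambridge Reference Sequence (rCRS) coordinate system.
MT_LENGTH = 16569

#: Low-complexity mtDNA regions excluded from variant calling (1-based, inclusive).
MASKED_REGIONS = (
    (66, 71),
    (300, 316),
    (513, 525),
    (3106, 3107),
    (12418, 12425),
    (16182, 16194),
)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MtVariant:
    """One mtDNA-aligned SNV call.

    ``af`` is the allele fraction (alt reads / depth); ``alt_fwd``/``alt_rev``
    are the strand-resolved alternate read counts.  Reference strand counts
    are optional and only needed to apply the minor-allele strand rule to
    majority-allele variants (0.5 < AF <= 0.95).
    """

    position: int
    ref_allele: str
    alt_allele: str
    depth: int
    alt_fwd: int
    alt_rev: int
    af: float
    ref_fwd: int | None = None
    ref_rev: int | None = None

    def __post_init__(self) -> None:
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got "
                f"{self.ref_allele!r}>{self.alt_allele!r} at {self.position}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.position}")
        if self.depth <= 0:
            raise ValueError(f"non-positive depth {self.depth} at {self.position}")
        if self.alt_fwd < 0 or self.alt_rev < 0:
            raise ValueError(f"negative strand count at {self.position}")
        if self.alt_fwd + self.alt_rev > self.depth:
            raise ValueError(
                f"alt reads exceed depth at {self.position}: "
                f"{self.alt_fwd}+{self.alt_rev} > {self.depth}"
            )
        expected = (self.alt_fwd + self.alt_rev) / self.depth
        if abs(self.af - expected) > 1e-9:
            raise ValueError(
                f"af {self.af} inconsistent with strand counts at {self.position} "
                f"(expected {expected})"
            )

    @classmethod
    def from_counts(
        cls,
        position: int,
        ref_allele: str,
        alt_allele: str,
        depth: int,
        alt_fwd: int,
        alt_rev: int,
        ref_fwd: int | None = None,
        ref_rev: int | None = None,
    ) -> "MtVariant":
        """Build a variant with AF computed from the read counts."""
        return cls(
            position=position,
            ref_allele=ref_allele,
            alt_allele=alt_allele,
            depth=depth,
            alt_fwd=alt_fwd,
            alt_rev=alt_rev,
            af=(alt_fwd + alt_rev) / depth,
            ref_fwd=ref_fwd,
            ref_rev=ref_rev,
        )

    @property
    def alt_total(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def key(self) -> tuple[int, str]:
        """Variant identity: (position, alt allele).  Multi-allelic sites are
        independent records under this key."""
        return (self.position, self.alt_allele)


def in_masked_region(position: int) -> bool:
    """True if the 1-based mtDNA position falls in a low-complexity region."""
    return any(lo <= position <= hi for lo, hi in MASKED_REGIONS)


def filter_variants(
    raw,
    *,
    af_min: float = 0.01,
    depth_min: int = 200,
    min_strand_reads: int = 2,
    homoplasmy_af: float = 0.95,
) -> list["MtVariant"]:
    """Apply the variant filter cascade, preserving input order.

    The minor-allele strand rule is applied to the alternate allele when
    AF <= 0.5 and to the reference allele when 0.5 < AF <= ``homoplasmy_af``
    (falling back to alt counts, with a warning, when reference strand counts
    were not carried through).  Conservatively homoplasmic calls
    (AF > ``homoplasmy_af``) are exempt: a fixed allele has no minor-allele
    read support whose strand balance could flag an artefact, and dropping
    them would empty every homoplasmy-based downstream rule.

    Raises ``ValueError`` for positions outside 1..16569.
    """
    out: list[MtVariant] = []
    warned = False
    for v in raw:
        if not 1 <= v.position <= MT_LENGTH:
            raise ValueError(
                f"invalid mtDNA position {v.position} (must be 1..{MT_LENGTH}) "
                f"in record {v.ref_allele}>{v.alt_allele}"
            )
        if not v.af > af_min:
            continue
        if v.depth < depth_min:
            continue
        if in_masked_region(v.position):
            continue
        if v.af > homoplasmy_af:
            pass  # no minor allele to assess
        else:
            if v.af > 0.5:
                if v.ref_fwd is not None and v.ref_rev is not None:
                    fwd, rev = v.ref_fwd, v.ref_rev
                else:
                    if not warned:
                        log.warning(
                            "AF > 50%% variant without reference strand counts; "
                            "applying minor-allele strand rule to alt counts"
                        )
                        warned = True
                    fwd, rev = v.alt_fwd, v.alt_rev
            else:
                fwd, rev = v.alt_fwd, v.alt_rev
            if fwd < min_strand_reads or rev < min_strand_reads:
                continue
        out.append(v)
    return out


def is_homoplasmic(v: MtVariant, *, threshold: float = 0.95) -> bool:
    """True iff the allele fraction is strictly above the homoplasmy threshold."""
    return v.af > threshold


@dataclass
class SampleCallset:
    """Filtered (or raw) variant calls for one sample, keyed by (pos, alt)."""

    sample_id: str
    variants: dict[tuple[int, str], MtVariant] = field(default_factory=dict)
    mean_mt_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_mt_depth <= 0:
            raise ValueError(
                f"mean mtDNA depth must be positive for {self.sample_id}"
            )

    @classmethod
    def from_variants(
        cls, sample_id: str, variants, mean_mt_depth: float
    ) -> "SampleCallset":
        d: dict[tuple[int, str], MtVariant] = {}
        for v in variants:
            if v.key in d:
                raise ValueError(
                    f"duplicate variant key {v.key} in sample {sample_id}"
                )
            d[v.key] = v
        return cls(sample_id=sample_id, variants=d, mean_mt_depth=mean_mt_depth)

    def filtered(self, **filter_kwargs) -> "SampleCallset":
        """Return a new callset with :func:`filter_variants` applied."""
        kept = filter_variants(self.variants.values(), **filter_kwargs)
        return SampleCallset.from_variants(
            self.sample_id, kept, self.mean_mt_depth
        )

    def af(self, key: tuple[int, str]) -> float | None:
        v = self.variants.get(key)
        return None if v is None else v.af

    def homoplasmies(self, *, threshold: float = 0.95) -> list[tuple[int, str]]:
        return [k for k, v in self.variants.items() if is_homoplasmic(v, threshold=threshold)]

    def __len__(self) -> int:
        return len(self.variants)


def is_detected(
    callset: SampleCallset, key: tuple[int, str], threshold: float = 0.05
) -> bool:
    """True iff the variant key is present with AF strictly above ``threshold``."""
    v = callset.variants.get(key)
    return v is not None and v.af > threshold


def trio_depth_qc(
    father: SampleCallset,
    mother: SampleCallset,
    child: SampleCallset,
    min_depth: float = 500.0,
) -> bool:
    """True iff no family member's mean mtDNA depth falls below ``min_depth``.

    "Below" is strict: a trio at exactly the threshold passes.
    """
    return all(
        s.mean_mt_depth >= min_depth for s in (father, mother, child)
    )


def heteroplasmy_count(
    callset: SampleCallset, *, af_min: float = 0.01, af_max: float = 0.95
) -> int:
    """Number of heteroplasmic variants: ``af_min < AF <= af_max``."""
    return sum(1 for v in callset.variants.values() if af_min < v.af <= af_max)
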