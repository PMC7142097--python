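"""Seeded synthetic cohorts with planted mega-NUMTs and ground-truth labels.

The generator emulates the data regime of a large trio whole-genome study:

* mtDNA is transmitted maternally — each child's mtDNA haplotype is exactly
  the mother's;
* father and mother mtDNA backgrounds diverge at a regime-dependent number of
  sites (same haplogroup: 1–5; different haplogroups: 20–40), each appearing
  as a near-fixed (homoplasmic) variant against the reference;
* a planted autosomal mega-NUMT — K concatenated mtDNA-derived fragments
  inserted at one nuclear locus — is carried heterozygously by a father and
  transmitted to each child with probability 1/2.  Every NUMT-defining allele
  appears in a carrier's mtDNA callset at an expected allele fraction given
  exactly by the closed-form mixed-haplotype fraction
  ``HTF = (DPnu/2*K)/(DPnu/2*K + DPmt)``, with read counts drawn binomially
  and strands split 50/50;
* read evidence at the insertion is emitted as already-aligned SAM-style
  records: discordant pairs (nuclear end + mtDNA mate) Poisson-sampled around
  each nu-mt junction side, split reads whose sequences are literally
  constructed from the two reference sides of each junction, and concordant
  background pairs covering the flanks.

All randomness flows from the single configuration seed; regenerating a
bundle is bit-reproducible.  Ground-truth labels (carrier, transmitted,
expected trio classification, planted coordinates, copy number) accompany
every trio so downstream stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .copy_htf import htf
from .mt_calls import MASKED_REGIONS, MT_LENGTH, MtVariant, SampleCallset, filter_variants
from .numt_detect import AlignedRead
from .splitalign import revcomp
from .trio_screen import Trio, TrioStatus

__all__ = [
    "SimConfig",
    "PlantedSpec",
    "PlantedNumt",
    "TrioTruth",
    "SampleInfo",
    "CohortBundle",
    "make_references",
    "simulate_trio",
    "simulate_numt_reads",
    "simulate_cohort",
]

_STATUS_EXCLUDED_QC = "excluded_qc"


@dataclass(frozen=True)
class PlantedSpec:
    """Directive for planting one mega-NUMT father in the cohort.

    ``transmit=None`` draws transmission per offspring at the configured
    Mendelian probability; ``regime=None`` draws the father/mother haplogroup
    regime at the configured probability.  Specs sharing ``share_group`` get
    an identical NUMT (geometry, copy number and source haplotype), emulating
    recurrent NUMTs seen across unrelated families.
    """

    transmit: bool | None = None
    regime: str | None = None  # "same" | "different"
    share_group: int | None = None


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Depth ranges follow the study regime (nuclear 30–99x, true mtDNA
    200–4500x).  Carrier trios draw mtDNA depth from at least
    ``carrier_min_mt_depth`` (the analysed cohort is post-QC at >=500x) and
    depths are rejection-sampled until the carrier's expected haplotype
    fraction lies within [``min_carrier_htf``, ``max_carrier_htf``] — the
    observed mixed-haplotype signature band — so ground-truth labels are
    robust to binomial sampling noise.
    """

    n_trios: int = 100
    read_length: int = 150
    dp_nu_range: tuple[int, int] = (30, 99)
    dp_mt_range: tuple[int, int] = (200, 4500)
    p_father_numt: float = 0.0
    nmt_copies_range: tuple[int, int] = (2, 20)
    mt_fragment_min_span: int = 600
    p_transmit: float = 0.5
    same_divergence_range: tuple[int, int] = (1, 5)
    diff_divergence_range: tuple[int, int] = (20, 40)
    p_different_haplogroup: float = 0.5
    n_numt_sites_range: tuple[int, int] = (13, 22)
    n_background_sites_range: tuple[int, int] = (5, 15)
    n_fragments_range: tuple[int, int] = (1, 3)
    fragment_len_range: tuple[int, int] = (400, 1200)
    dcr_rate: float = 0.35  # discordant pairs per junction side per 1x nuclear depth
    spr_rate: float = 0.2  # split reads per unique junction per 1x nuclear depth
    min_carrier_htf: float = 0.07
    max_carrier_htf: float = 0.45
    carrier_min_mt_depth: int = 600
    base_error: float = 0.005
    nuclear_contig: str = "chr1"
    nuclear_len: int = 100_000
    seed: int = 0
    planted: tuple[PlantedSpec, ...] = ()

    def __post_init__(self) -> None:
        for lo, hi in (
            self.dp_nu_range,
            self.dp_mt_range,
            self.nmt_copies_range,
            self.n_fragments_range,
        ):
            if lo > hi:
                raise ValueError(f"empty range ({lo}, {hi})")
        for p in (self.p_father_numt, self.p_transmit, self.p_different_haplogroup):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass(frozen=True)
class PlantedNumt:
    """Ground truth of one planted mega-NUMT."""

    numt_id: str
    nuclear_contig: str
    insertion_pos: int  # insertion between this base and the next
    fragments: tuple[tuple[int, int, int], ...]  # (start, end, strand ±1), printed style
    copies: int
    source_sites: tuple[tuple[int, str], ...]  # NUMT-defining (position, alt)
    carrier_ids: tuple[str, ...] = ()
    transmitted_to: tuple[str, ...] = ()


@dataclass
class TrioTruth:
    trio_id: str
    regime: str
    carrier: bool
    transmitted: bool
    expected_status: str
    numt_id: str | None = None
    copies: int | None = None
    father_private_homoplasmies: int = 0
    htf_father: float | None = None
    htf_child: float | None = None


@dataclass
class SampleInfo:
    sample_id: str
    trio_id: str
    role: str
    dp_nu: int
    dp_mt: int
    depth_x: float
    depth_y: float
    nuclear_het_afs: tuple[float, ...] = ()


def make_references(
    seed: int,
    nuclear_len: int = 100_000,
    mt_length: int = MT_LENGTH,
    nuclear_contig: str = "chr1",
) -> tuple[str, str]:
    """Deterministic pseudo-random nuclear contig and mtDNA reference.

    Bases are uniform over ACGT; the mtDNA sequence has the rCRS length
    (16,569 bp) so coordinates and masked regions line up.  A real rCRS FASTA
    may substitute the mtDNA sequence downstream.
    """
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    nuclear = bases[rng.integers(0, 4, size=nuclear_len)].tobytes().decode()
    mt = bases[rng.integers(0, 4, size=mt_length)].tobytes().decode()
    return nuclear, mt


def _fragment_seq(mt_ref: str, frag: tuple[int, int, int]) -> str:
    start, end, strand = frag
    if strand > 0:
        return mt_ref[start - 1 : end]
    return revcomp(mt_ref[end - 1 : start])


def _fragment_cover(frag: tuple[int, int, int]) -> range:
    start, end, _ = frag
    lo, hi = min(start, end), max(start, end)
    return range(lo, hi + 1)


def _sample_fragments(rng, config: SimConfig) -> tuple[tuple[int, int, int], ...]:
    """Fragment geometry with a >``mt_fragment_min_span`` bp breakpoint span
    and no near-contiguous junctions (which would not be split-detectable)."""
    for _ in range(500):
        n = int(rng.integers(config.n_fragments_range[0], config.n_fragments_range[1] + 1))
        frags = []
        for _ in range(n):
            length = int(
                rng.integers(config.fragment_len_range[0], config.fragment_len_range[1] + 1)
            )
            a = int(rng.integers(200, MT_LENGTH - 200 - length))
            if rng.random() < 0.5:
                frags.append((a, a + length - 1, +1))
            else:
                frags.append((a + length - 1, a, -1))
        entry, exit_ = frags[0][0], frags[-1][1]
        if abs(entry - exit_) <= config.mt_fragment_min_span:
            continue
        ok = True
        order = list(range(len(frags))) + [0]
        for i in range(len(order) - 1):
            prev, nxt = frags[order[i]], frags[order[i + 1]]
            if prev[2] == nxt[2] and abs(nxt[0] - prev[1]) < 50:
                ok = False
                break
        if ok:
            return tuple(frags)
    raise RuntimeError("could not sample a valid fragment geometry")


def _sample_sites(rng, n: int, forbidden: set[int], within: list[int] | None = None):
    """Distinct usable mtDNA positions, outside masked regions and
    ``forbidden``; restricted to ``within`` (a position pool) when given."""
    masked = set()
    for lo, hi in MASKED_REGIONS:
        masked.update(range(lo, hi + 1))
    sites: list[int] = []
    tries = 0
    while len(sites) < n:
        tries += 1
        if tries > 100_000:
            raise RuntimeError("site sampling exhausted")
        if within is not None:
            pos = int(within[int(rng.integers(0, len(within)))])
        else:
            pos = int(rng.integers(1, MT_LENGTH + 1))
        if pos in masked or pos in forbidden or pos in sites:
            continue
        sites.append(pos)
    return sites


_ALT = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _alts_for(rng, mt_ref: str, positions) -> dict[int, str]:
    return {
        p: _ALT[mt_ref[p - 1]][int(rng.integers(0, 3))] for p in positions
    }


def _draw_variant(rng, pos, ref, alt, depth_mean, p) -> MtVariant | None:
    depth = max(1, int(rng.poisson(depth_mean)))
    alt_n = int(rng.binomial(depth, p))
    if alt_n == 0:
        return None
    alt_fwd = int(rng.binomial(alt_n, 0.5))
    ref_n = depth - alt_n
    ref_fwd = int(rng.binomial(ref_n, 0.5)) if ref_n else 0
    return MtVariant.from_counts(
        position=pos,
        ref_allele=ref,
        alt_allele=alt,
        depth=depth,
        alt_fwd=alt_fwd,
        alt_rev=alt_n - alt_fwd,
        ref_fwd=ref_fwd,
        ref_rev=ref_n - ref_fwd,
    )


@dataclass
class CohortBundle:
    """In-memory synthetic cohort: references, callsets, reads and truth."""

    config: SimConfig
    nuclear_ref: str
    mt_ref: str
    raw_callsets: dict[str, list[MtVariant]]
    sample_info: dict[str, SampleInfo]
    pedigree: list[dict]
    truths: dict[str, TrioTruth]
    planted: dict[str, PlantedNumt]
    reads: dict[str, list[AlignedRead]]
    _trios: list[Trio] | None = field(default=None, repr=False)

    @property
    def n_individuals(self) -> int:
        return len(self.sample_info)

    def callset(self, sample_id: str, *, filtered: bool = True) -> SampleCallset:
        variants = self.raw_callsets[sample_id]
        if filtered:
            variants = filter_variants(variants)
        return SampleCallset.from_variants(
            sample_id, variants, float(self.sample_info[sample_id].dp_mt)
        )

    @property
    def trios(self) -> list[Trio]:
        if self._trios is None:
            self._trios = [
                Trio(
                    trio_id=row["trio_id"],
                    father=self.callset(row["father_id"]),
                    mother=self.callset(row["mother_id"]),
                    child=self.callset(row["child_id"]),
                    extra_sibs=tuple(
                        self.callset(s) for s in row["sib_ids"]
                    ),
                )
                for row in self.pedigree
            ]
        return self._trios

    def write(self, out_dir) -> None:
        from . import io as mio

        mio.write_bundle(self, out_dir)


def simulate_numt_reads(
    planted: PlantedNumt,
    dp_nu: int,
    read_length: int,
    seed_or_rng,
    nuclear_ref: str,
    mt_ref: str,
    *,
    sample_id: str = "S",
    dcr_rate: float = 0.35,
    spr_rate: float = 0.2,
    nuclear_contig: str = "chr1",
) -> list[AlignedRead]:
    """Aligned-read evidence for one carrier at one planted mega-NUMT.

    Emits, per nu-mt junction side, a Poisson(``dcr_rate * dp_nu``) number of
    discordant pairs with homogeneous orientation, and per unique junction
    (two nu-mt plus the mt-mt joins between consecutive concatemer fragments,
    including the tandem-repeat wrap join when K >= 2) a
    Poisson(``spr_rate * dp_nu``) number of split reads whose sequences are
    built literally from the two reference sides.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    for start, end, _ in planted.fragments:
        for p in (start, end):
            if not 1 <= p <= len(mt_ref):
                raise ValueError(
                    f"fragment coordinate {p} outside mtDNA 1..{len(mt_ref)}"
                )
    rl = read_length
    ip = planted.insertion_pos
    frag_seqs = [_fragment_seq(mt_ref, f) for f in planted.fragments]
    reads: list[AlignedRead] = []
    counter = [0]

    def rid(tag: str) -> str:
        counter[0] += 1
        return f"{sample_id}:{planted.numt_id}:{tag}:{counter[0]}"

    def add_split(seq: str, contig: str, pos: int, cigar: str, tag: str) -> None:
        reads.append(
            AlignedRead(
                read_id=rid(tag),
                contig=contig,
                pos=max(1, pos),
                strand="+",
                mapq=60,
                cigar=cigar,
                sequence=seq,
            )
        )

    # nu-mt split reads, left junction (nuclear | array head)
    head = frag_seqs[0]
    tail = frag_seqs[-1]
    for _ in range(int(rng.poisson(spr_rate * dp_nu))):
        u = int(rng.integers(30, rl - 29))
        seq = nuclear_ref[ip - u : ip] + head[: rl - u]
        add_split(seq, nuclear_contig, ip - u + 1, f"{u}M{rl - u}S", "numtL")
    # nu-mt split reads, right junction (array tail | nuclear)
    for _ in range(int(rng.poisson(spr_rate * dp_nu))):
        u = int(rng.integers(30, rl - 29))
        seq = tail[-u:] + nuclear_ref[ip : ip + rl - u]
        add_split(seq, nuclear_contig, ip + 1, f"{u}S{rl - u}M", "numtR")
    # mt-mt split reads at each unique concatemer junction
    joins = [(i, i + 1) for i in range(len(frag_seqs) - 1)]
    if planted.copies >= 2:
        joins.append((len(frag_seqs) - 1, 0))
    for a, b in joins:
        prev_frag = planted.fragments[a]
        for _ in range(int(rng.poisson(spr_rate * dp_nu))):
            u = int(rng.integers(30, rl - 29))
            seq = frag_seqs[a][-u:] + frag_seqs[b][: rl - u]
            pos = prev_frag[1] - u + 1 if prev_frag[2] > 0 else prev_frag[1]
            add_split(seq, "MT", pos, f"{u}M{rl - u}S", f"mtmt{a}{b}")
    # discordant pairs, one homogeneous-orientation batch per junction side
    for side, frag, frag_seq in (("L", planted.fragments[0], head), ("R", planted.fragments[-1], tail)):
        for _ in range(int(rng.poisson(dcr_rate * dp_nu))):
            if side == "L":
                p = int(rng.integers(ip - 470, ip - 160 + 1))
                nuc_strand = "+"
                o = int(rng.integers(20, max(21, min(350, len(frag_seq) - rl - 10))))
                mt_pos = frag[0] + o if frag[2] > 0 else frag[0] - o - rl + 1
            else:
                p = int(rng.integers(ip + 10, ip + 320 + 1))
                nuc_strand = "-"
                o = int(rng.integers(20, max(21, min(350, len(frag_seq) - rl - 10))))
                mt_pos = frag[1] - o - rl + 1 if frag[2] > 0 else frag[1] + o
            mt_pos = min(max(1, mt_pos), len(mt_ref) - rl)
            mt_strand = "-" if frag[2] > 0 else "+"
            name = rid(f"dcr{side}")
            reads.append(
                AlignedRead(
                    read_id=name,
                    contig=nuclear_contig,
                    pos=p,
                    strand=nuc_strand,
                    mapq=60,
                    cigar=f"{rl}M",
                    sequence=nuclear_ref[p - 1 : p + rl - 1],
                    mate_contig="MT",
                    mate_pos=mt_pos,
                    mate_strand=mt_strand,
                    is_read1=True,
                )
            )
            reads.append(
                AlignedRead(
                    read_id=name,
                    contig="MT",
                    pos=mt_pos,
                    strand=mt_strand,
                    mapq=60,
                    cigar=f"{rl}M",
                    sequence=mt_ref[mt_pos - 1 : mt_pos + rl - 1],
                    mate_contig=nuclear_contig,
                    mate_pos=p,
                    mate_strand=nuc_strand,
                    is_read1=False,
                )
            )
    return reads


def _background_reads(
    nuclear_ref: str,
    center: int,
    dp_nu: int,
    rl: int,
    rng,
    sample_id: str,
    nuclear_contig: str,
    half_width: int = 2200,
) -> list[AlignedRead]:
    """Concordant pairs covering the flanks at roughly ``dp_nu`` x depth."""
    lo = max(1, center - half_width)
    hi = min(len(nuclear_ref) - 2 * rl - 200, center + half_width)
    n_pairs = int(dp_nu * (hi - lo) / (2 * rl))
    reads: list[AlignedRead] = []
    for i in range(n_pairs):
        s = int(rng.integers(lo, hi))
        name = f"{sample_id}:bg:{i}"
        for pos, strand, first in ((s, "+", True), (s + rl + 30, "-", False)):
            mate_pos = s + rl + 30 if first else s
            reads.append(
                AlignedRead(
                    read_id=name,
                    contig=nuclear_contig,
                    pos=pos,
                    strand=strand,
                    mapq=60,
                    cigar=f"{rl}M",
                    sequence=nuclear_ref[pos - 1 : pos + rl - 1],
                    mate_contig=nuclear_contig,
                    mate_pos=mate_pos,
                    mate_strand="-" if strand == "+" else "+",
                    is_read1=first,
                )
            )
    return reads


def _carrier_depths(rng, config: SimConfig, copies: int) -> tuple[int, int, float]:
    """Rejection-sample (dp_nu, dp_mt) for a carrier until the expected
    haplotype fraction falls in the configured signature band."""
    lo_mt = max(config.dp_mt_range[0], config.carrier_min_mt_depth)
    for _ in range(500):
        dp_nu = int(rng.integers(config.dp_nu_range[0], config.dp_nu_range[1] + 1))
        dp_mt = int(rng.integers(lo_mt, config.dp_mt_range[1] + 1))
        h = htf(dp_nu, dp_mt, copies)
        if config.min_carrier_htf <= h <= config.max_carrier_htf:
            return dp_nu, dp_mt, h
    dp_nu = config.dp_nu_range[1]
    target = 0.15
    dp_mt = int(
        min(
            max(lo_mt, dp_nu / 2 * copies * (1 - target) / target),
            config.dp_mt_range[1],
        )
    )
    return dp_nu, dp_mt, htf(dp_nu, dp_mt, copies)


def simulate_cohort(config: SimConfig, mt_ref: str | None = None) -> CohortBundle:
    """Generate a full synthetic cohort per the configuration.

    Returns an in-memory :class:`CohortBundle`; call ``bundle.write(dir)`` to
    persist it as FASTA / SAM / TSV / JSON files.
    """
    nuclear_ref, generated_mt = make_references(
        config.seed, config.nuclear_len, nuclear_contig=config.nuclear_contig
    )
    mt = mt_ref if mt_ref is not None else generated_mt
    if len(mt) != MT_LENGTH:
        raise ValueError(f"mtDNA reference must be {MT_LENGTH} bp, got {len(mt)}")
    rng = np.random.default_rng([config.seed, 1])

    n = config.n_trios
    specs: dict[int, PlantedSpec] = {}
    if config.planted:
        if len(config.planted) > n:
            raise ValueError("more planted fathers than trios")
        idx = sorted(
            int(i) for i in rng.choice(n, size=len(config.planted), replace=False)
        )
        for i, spec in zip(idx, config.planted):
            specs[i] = spec
    if config.p_father_numt > 0:
        for i in range(n):
            if i not in specs and rng.random() < config.p_father_numt:
                specs[i] = PlantedSpec()

    # one planted NUMT per share group (or per solo spec)
    geometries: dict[object, dict] = {}
    planted_out: dict[str, PlantedNumt] = {}
    for i in sorted(specs):
        spec = specs[i]
        gkey = ("share", spec.share_group) if spec.share_group is not None else ("solo", i)
        if gkey not in geometries:
            frags = _sample_fragments(rng, config)
            copies = int(
                rng.integers(config.nmt_copies_range[0], config.nmt_copies_range[1] + 1)
            )
            cover = set()
            for f in frags:
                cover.update(_fragment_cover(f))
            n_sites = int(
                rng.integers(config.n_numt_sites_range[0], config.n_numt_sites_range[1] + 1)
            )
            site_pool = sorted(cover)
            positions = _sample_sites(rng, n_sites, set(), within=site_pool)
            alts = _alts_for(rng, mt, positions)
            ip = int(rng.integers(10_000, config.nuclear_len - 10_000))
            geometries[gkey] = {
                "numt_id": f"pn{len(geometries) + 1}",
                "insertion_pos": ip,
                "fragments": frags,
                "copies": copies,
                "cover": cover,
                "sites": {p: alts[p] for p in sorted(alts)},
            }

    raw_callsets: dict[str, list[MtVariant]] = {}
    sample_info: dict[str, SampleInfo] = {}
    pedigree: list[dict] = []
    truths: dict[str, TrioTruth] = {}
    reads: dict[str, list[AlignedRead]] = {}
    carriers_by_numt: dict[str, list[str]] = {}
    transmitted_by_numt: dict[str, list[str]] = {}

    for i in range(n):
        trio_id = f"T{i:04d}"
        fid, mid, cid = f"{trio_id}F", f"{trio_id}M", f"{trio_id}C"
        spec = specs.get(i)
        carrier = spec is not None
        geom = None
        if carrier:
            gkey = (
                ("share", spec.share_group)
                if spec.share_group is not None
                else ("solo", i)
            )
            geom = geometries[gkey]

        regime = spec.regime if (spec and spec.regime) else (
            "different" if rng.random() < config.p_different_haplogroup else "same"
        )
        div_range = (
            config.diff_divergence_range
            if regime == "different"
            else config.same_divergence_range
        )
        d = int(rng.integers(div_range[0], div_range[1] + 1))
        if spec is not None and spec.regime == "same":
            f_private_n = int(rng.integers(0, min(2, d) + 1))
        elif spec is not None and spec.regime == "different":
            f_private_n = int(rng.integers(3, d + 1))
        else:
            f_private_n = int(rng.binomial(d, 0.5))
        m_private_n = d - f_private_n

        forbidden = set(geom["cover"]) | set(geom["sites"]) if geom else set()
        n_bg = int(
            rng.integers(
                config.n_background_sites_range[0],
                config.n_background_sites_range[1] + 1,
            )
        )
        all_sites = _sample_sites(rng, n_bg + d, forbidden)
        shared = all_sites[:n_bg]
        f_private = all_sites[n_bg : n_bg + f_private_n]
        m_private = all_sites[n_bg + f_private_n :]
        alts = _alts_for(rng, mt, all_sites)

        # depths
        if carrier:
            dp_nu_f, dp_mt_f, htf_f = _carrier_depths(rng, config, geom["copies"])
        else:
            dp_nu_f = int(rng.integers(*_inc(config.dp_nu_range)))
            dp_mt_f = int(rng.integers(*_inc(config.dp_mt_range)))
            htf_f = None
        if spec is not None and spec.transmit is not None:
            transmitted = bool(spec.transmit)
        elif carrier:
            transmitted = bool(rng.random() < config.p_transmit)
        else:
            transmitted = False
        if carrier and transmitted:
            dp_nu_c, dp_mt_c, htf_c = _carrier_depths(rng, config, geom["copies"])
        else:
            dp_nu_c = int(rng.integers(*_inc(config.dp_nu_range)))
            dp_mt_c = (
                int(rng.integers(max(config.dp_mt_range[0], config.carrier_min_mt_depth), config.dp_mt_range[1] + 1))
                if carrier
                else int(rng.integers(*_inc(config.dp_mt_range)))
            )
            htf_c = None
        dp_nu_m = int(rng.integers(*_inc(config.dp_nu_range)))
        dp_mt_m = (
            int(rng.integers(max(config.dp_mt_range[0], config.carrier_min_mt_depth), config.dp_mt_range[1] + 1))
            if carrier
            else int(rng.integers(*_inc(config.dp_mt_range)))
        )

        hom_p = 1.0 - config.base_error

        def callset_for(sites, dp_mt, numt_htf, numt_depth_extra):
            variants = []
            for pos in sorted(sites):
                v = _draw_variant(rng, pos, mt[pos - 1], alts[pos], dp_mt, hom_p)
                if v is not None:
                    variants.append(v)
            if numt_htf is not None:
                for pos, alt in geom["sites"].items():
                    v = _draw_variant(
                        rng, pos, mt[pos - 1], alt, dp_mt + numt_depth_extra, numt_htf
                    )
                    if v is not None:
                        variants.append(v)
            return variants

        raw_callsets[fid] = callset_for(
            shared + f_private,
            dp_mt_f,
            htf_f if carrier else None,
            (dp_nu_f / 2 * geom["copies"]) if carrier else 0,
        )
        raw_callsets[mid] = callset_for(shared + m_private, dp_mt_m, None, 0)
        raw_callsets[cid] = callset_for(
            shared + m_private,
            dp_mt_c,
            htf_c if (carrier and transmitted) else None,
            (dp_nu_c / 2 * geom["copies"]) if (carrier and transmitted) else 0,
        )

        child_sex = "female" if rng.random() < 0.5 else "male"
        n_het = 30
        for sid, role, dp_nu, dp_mt, sex in (
            (fid, "father", dp_nu_f, dp_mt_f, "male"),
            (mid, "mother", dp_nu_m, dp_mt_m, "female"),
            (cid, "child", dp_nu_c, dp_mt_c, child_sex),
        ):
            het = tuple(
                float(x) / dp_nu for x in rng.binomial(dp_nu, 0.5, size=n_het)
            )
            dx, dy = (
                (float(dp_nu), 0.0) if sex == "female" else (dp_nu / 2.0, dp_nu / 2.0)
            )
            sample_info[sid] = SampleInfo(
                sample_id=sid,
                trio_id=trio_id,
                role=role,
                dp_nu=dp_nu,
                dp_mt=dp_mt,
                depth_x=dx,
                depth_y=dy,
                nuclear_het_afs=het,
            )

        if carrier:
            pn = PlantedNumt(
                numt_id=geom["numt_id"],
                nuclear_contig=config.nuclear_contig,
                insertion_pos=geom["insertion_pos"],
                fragments=geom["fragments"],
                copies=geom["copies"],
                source_sites=tuple(sorted(geom["sites"].items())),
            )
            reads[fid] = simulate_numt_reads(
                pn,
                dp_nu_f,
                config.read_length,
                rng,
                nuclear_ref,
                mt,
                sample_id=fid,
                dcr_rate=config.dcr_rate,
                spr_rate=config.spr_rate,
                nuclear_contig=config.nuclear_contig,
            ) + _background_reads(
                nuclear_ref, geom["insertion_pos"], dp_nu_f, config.read_length,
                rng, fid, config.nuclear_contig,
            )
            if transmitted:
                reads[cid] = simulate_numt_reads(
                    pn,
                    dp_nu_c,
                    config.read_length,
                    rng,
                    nuclear_ref,
                    mt,
                    sample_id=cid,
                    dcr_rate=config.dcr_rate,
                    spr_rate=config.spr_rate,
                    nuclear_contig=config.nuclear_contig,
                ) + _background_reads(
                    nuclear_ref, geom["insertion_pos"], dp_nu_c, config.read_length,
                    rng, cid, config.nuclear_contig,
                )
            else:
                reads[cid] = _background_reads(
                    nuclear_ref, geom["insertion_pos"], dp_nu_c, config.read_length,
                    rng, cid, config.nuclear_contig,
                )
            reads[mid] = _background_reads(
                nuclear_ref, geom["insertion_pos"], dp_nu_m, config.read_length,
                rng, mid, config.nuclear_contig,
            )
            carriers_by_numt.setdefault(geom["numt_id"], []).append(fid)
            if transmitted:
                carriers_by_numt[geom["numt_id"]].append(cid)
                transmitted_by_numt.setdefault(geom["numt_id"], []).append(cid)

        qc_fail = min(dp_mt_f, dp_mt_m, dp_mt_c) < 500
        if qc_fail:
            expected = _STATUS_EXCLUDED_QC
        elif carrier and transmitted and f_private_n < 3:
            expected = TrioStatus.MIXED_HAPLOTYPE_CANDIDATE
        elif carrier and transmitted:
            expected = TrioStatus.EXCLUDED_HOMOPLASMY_MISMATCH
        elif carrier or f_private_n >= 1:
            expected = TrioStatus.INFORMATIVE_ONLY
        else:
            expected = TrioStatus.NON_INFORMATIVE

        pedigree.append(
            {
                "trio_id": trio_id,
                "father_id": fid,
                "mother_id": mid,
                "child_id": cid,
                "sib_ids": [],
            }
        )
        truths[trio_id] = TrioTruth(
            trio_id=trio_id,
            regime=regime,
            carrier=carrier,
            transmitted=transmitted,
            expected_status=expected,
            numt_id=geom["numt_id"] if carrier else None,
            copies=geom["copies"] if carrier else None,
            father_private_homoplasmies=f_private_n,
            htf_father=htf_f,
            htf_child=htf_c,
        )

    for numt_id, pn_carriers in carriers_by_numt.items():
        gkey = next(k for k, g in geometries.items() if g["numt_id"] == numt_id)
        geom = geometries[gkey]
        planted_out[numt_id] = PlantedNumt(
            numt_id=numt_id,
            nuclear_contig=config.nuclear_contig,
            insertion_pos=geom["insertion_pos"],
            fragments=geom["fragments"],
            copies=geom["copies"],
            source_sites=tuple(sorted(geom["sites"].items())),
            carrier_ids=tuple(pn_carriers),
            transmitted_to=tuple(transmitted_by_numt.get(numt_id, [])),
        )

    return CohortBundle(
        config=config,
        nuclear_ref=nuclear_ref,
        mt_ref=mt,
        raw_callsets=raw_callsets,
        sample_info=sample_info,
        pedigree=pedigree,
        truths=truths,
        planted=planted_out,
        reads=reads,
    )


def _inc(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


def simulate_trio(
    config: SimConfig,
    planted: PlantedSpec | None = None,
    seed: int | None = None,
):
    """One trio plus its ground-truth label (convenience over a 1-trio cohort)."""
    from dataclasses import replace as dc_replace

    cfg = dc_replace(
        config,
        n_trios=1,
        planted=(planted,) if planted is not None else (),
        seed=config.seed if seed is None else seed,
    )
    bundle = simulate_cohort(cfg)
    trio = bundle.trios[0]
    return trio, bundle.truths[trio.trio_id]
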