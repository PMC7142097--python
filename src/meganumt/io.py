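"""File formats: FASTA references, SAM reads, TSV tables, VCF callsets,
and persistence of synthetic cohort bundles.

Callset tables use a documented TSV dialect with columns
``sample_id, position, ref, alt, depth, alt_fwd, alt_rev`` plus optional
``ref_fwd, ref_rev`` (reference strand counts, needed to apply the
minor-allele strand rule to majority-allele variants).  VCF input expects
single-sample records with ``DP``, ``ADF`` and ``ADR`` FORMAT fields.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mt_calls import MtVariant
from .numt_detect import AlignedRead, NumtCall

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_sam",
    "write_sam",
    "read_callsets_tsv",
    "write_callsets_tsv",
    "read_callset_vcf",
    "read_pedigree",
    "write_pedigree",
    "numt_calls_frame",
    "write_bundle",
    "load_bundle",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_sam(reads, path, contig_lengths: dict[str, int]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in contig_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.read_id
            seg.query_sequence = r.sequence
            seg.reference_name = r.contig
            seg.reference_start = r.pos - 1
            seg.mapping_quality = r.mapq
            seg.cigarstring = r.cigar
            flag = 0
            if r.strand == "-":
                flag |= 0x10
            if r.mate_contig is not None:
                flag |= 0x1
                flag |= 0x40 if r.is_read1 else 0x80
                if r.mate_strand == "-":
                    flag |= 0x20
                seg.next_reference_name = r.mate_contig
                seg.next_reference_start = (r.mate_pos or 1) - 1
            seg.flag = flag
            out.write(seg)


def read_sam(path) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam.fetch(until_eof=True):
            if seg.is_unmapped or seg.reference_name is None:
                continue
            mate_contig = mate_pos = mate_strand = None
            if seg.is_paired and not seg.mate_is_unmapped and seg.next_reference_name:
                mate_contig = seg.next_reference_name
                mate_pos = seg.next_reference_start + 1
                mate_strand = "-" if seg.mate_is_reverse else "+"
            reads.append(
                AlignedRead(
                    read_id=seg.query_name,
                    contig=seg.reference_name,
                    pos=seg.reference_start + 1,
                    strand="-" if seg.is_reverse else "+",
                    mapq=seg.mapping_quality,
                    cigar=seg.cigarstring or "",
                    sequence=seg.query_sequence or "",
                    mate_contig=mate_contig,
                    mate_pos=mate_pos,
                    mate_strand=mate_strand,
                    is_read1=not seg.is_read2,
                )
            )
    return reads


_CALLSET_COLS = [
    "sample_id", "position", "ref", "alt", "depth", "alt_fwd", "alt_rev",
    "ref_fwd", "ref_rev",
]


def write_callsets_tsv(callsets: dict[str, list[MtVariant]], path) -> None:
    rows = []
    for sample_id, variants in callsets.items():
        for v in variants:
            rows.append(
                (
                    sample_id, v.position, v.ref_allele, v.alt_allele, v.depth,
                    v.alt_fwd, v.alt_rev,
                    "" if v.ref_fwd is None else v.ref_fwd,
                    "" if v.ref_rev is None else v.ref_rev,
                )
            )
    pd.DataFrame(rows, columns=_CALLSET_COLS).to_csv(path, sep="\t", index=False)


def read_callsets_tsv(path) -> dict[str, list[MtVariant]]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    out: dict[str, list[MtVariant]] = {}
    has_ref_strands = "ref_fwd" in df.columns
    for row in df.itertuples(index=False):
        ref_fwd = ref_rev = None
        if has_ref_strands and not _isna(row.ref_fwd) and not _isna(row.ref_rev):
            ref_fwd, ref_rev = int(row.ref_fwd), int(row.ref_rev)
        out.setdefault(str(row.sample_id), []).append(
            MtVariant.from_counts(
                position=int(row.position),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                depth=int(row.depth),
                alt_fwd=int(row.alt_fwd),
                alt_rev=int(row.alt_rev),
                ref_fwd=ref_fwd,
                ref_rev=ref_rev,
            )
        )
    return out


def _isna(x) -> bool:
    try:
        return x is None or (isinstance(x, float) and math.isnan(x)) or x == ""
    except TypeError:
        return False


def read_callset_vcf(path, sample: str | None = None) -> list[MtVariant]:
    """Single-sample VCF with DP/ADF/ADR FORMAT fields (per-allele
    strand-resolved depths, reference allele first).  Indels are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 1 and sample is None:
        raise ValueError(
            f"{path}: expected a single-sample VCF, found {len(vcf.samples)} samples"
        )
    si = 0 if sample is None else vcf.samples.index(sample)
    variants: list[MtVariant] = []
    for rec in vcf:
        adf = rec.format("ADF")
        adr = rec.format("ADR")
        dp = rec.format("DP")
        if adf is None or adr is None or dp is None:
            raise ValueError(f"{path}: ADF/ADR/DP FORMAT fields required")
        for ai, alt in enumerate(rec.ALT, start=1):
            if len(rec.REF) != 1 or len(alt) != 1:
                continue
            variants.append(
                MtVariant.from_counts(
                    position=rec.POS,
                    ref_allele=rec.REF,
                    alt_allele=alt,
                    depth=int(np.asarray(dp[si]).reshape(-1)[0]),
                    alt_fwd=int(adf[si][ai]),
                    alt_rev=int(adr[si][ai]),
                    ref_fwd=int(adf[si][0]),
                    ref_rev=int(adr[si][0]),
                )
            )
    return variants


def write_pedigree(pedigree: list[dict], path) -> None:
    rows = [
        (
            row["trio_id"], row["father_id"], row["mother_id"], row["child_id"],
            ",".join(row.get("sib_ids", [])),
        )
        for row in pedigree
    ]
    pd.DataFrame(
        rows, columns=["trio_id", "father_id", "mother_id", "child_id", "sib_ids"]
    ).to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        {
            "trio_id": row.trio_id,
            "father_id": row.father_id,
            "mother_id": row.mother_id,
            "child_id": row.child_id,
            "sib_ids": [s for s in str(getattr(row, "sib_ids", "")).split(",") if s],
        }
        for row in df.itertuples(index=False)
    ]


def numt_calls_frame(calls: list[NumtCall]) -> pd.DataFrame:
    """BED-like table of NUMT calls (one row per call)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "nuclear_contig": c.nuclear_contig,
                "start": c.nuclear_interval[0],
                "end": c.nuclear_interval[1],
                "numt_id": c.numt_id,
                "n_discordant": c.n_discordant,
                "n_split": c.n_split,
                "mt_breakpoints": ";".join(
                    f"{s.pos}({s.strand})" for s in c.mt_breakpoints
                ),
                "carriers": ",".join(c.carriers),
                "frequency": c.cohort_frequency,
                "mega_evidence": c.mega_evidence,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort bundle persistence


def write_bundle(bundle, out_dir) -> None:
    from .synthetic import CohortBundle  # noqa: F401  (type context)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    write_fasta(
        {cfg.nuclear_contig: bundle.nuclear_ref, "MT": bundle.mt_ref},
        out / "refs.fasta",
    )
    write_callsets_tsv(bundle.raw_callsets, out / "callsets.tsv")
    write_pedigree(bundle.pedigree, out / "pedigree.tsv")
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "trio_id": s.trio_id,
                "role": s.role,
                "dp_nu": s.dp_nu,
                "mean_mt_depth": s.dp_mt,
                "depth_x": s.depth_x,
                "depth_y": s.depth_y,
                "het_afs": ",".join(f"{x:.6f}" for x in s.nuclear_het_afs),
            }
            for s in bundle.sample_info.values()
        ],
        columns=[
            "sample_id", "trio_id", "role", "dp_nu", "mean_mt_depth",
            "depth_x", "depth_y", "het_afs",
        ],
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    contig_lengths = {cfg.nuclear_contig: len(bundle.nuclear_ref), "MT": len(bundle.mt_ref)}
    for sample_id, reads in bundle.reads.items():
        write_sam(reads, reads_dir / f"{sample_id}.sam", contig_lengths)
    truth = {
        "trios": {tid: asdict(t) for tid, t in bundle.truths.items()},
        "planted": {nid: asdict(p) for nid, p in bundle.planted.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    (out / "config.json").write_text(
        json.dumps(asdict(cfg), indent=1, sort_keys=True)
    )


def load_bundle(bundle_dir):
    from .synthetic import (
        CohortBundle,
        PlantedNumt,
        PlantedSpec,
        SampleInfo,
        SimConfig,
        TrioTruth,
    )

    d = Path(bundle_dir)
    raw_cfg = json.loads((d / "config.json").read_text())
    raw_cfg["planted"] = tuple(
        PlantedSpec(**spec) for spec in raw_cfg.get("planted", [])
    )
    for key, val in list(raw_cfg.items()):
        if isinstance(val, list):
            raw_cfg[key] = tuple(val)
    config = SimConfig(**raw_cfg)
    refs = read_fasta(d / "refs.fasta")
    samples_df = pd.read_csv(d / "samples.tsv", sep="\t", dtype={"sample_id": str}).fillna("")
    sample_info = {}
    for row in samples_df.itertuples(index=False):
        sample_info[str(row.sample_id)] = SampleInfo(
            sample_id=str(row.sample_id),
            trio_id=str(row.trio_id),
            role=str(row.role),
            dp_nu=int(row.dp_nu),
            dp_mt=int(row.mean_mt_depth),
            depth_x=float(row.depth_x),
            depth_y=float(row.depth_y),
            nuclear_het_afs=tuple(
                float(x) for x in str(row.het_afs).split(",") if x
            ),
        )
    callsets = read_callsets_tsv(d / "callsets.tsv")
    for sid in sample_info:
        callsets.setdefault(sid, [])
    truth = json.loads((d / "truth.json").read_text())
    truths = {tid: TrioTruth(**t) for tid, t in truth["trios"].items()}
    planted = {}
    for nid, p in truth["planted"].items():
        p["fragments"] = tuple(tuple(f) for f in p["fragments"])
        p["source_sites"] = tuple((int(a), b) for a, b in p["source_sites"])
        p["carrier_ids"] = tuple(p["carrier_ids"])
        p["transmitted_to"] = tuple(p["transmitted_to"])
        planted[nid] = PlantedNumt(**p)
    reads = {}
    reads_dir = d / "reads"
    if reads_dir.is_dir():
        for sam_path in sorted(reads_dir.glob("*.sam")):
            reads[sam_path.stem] = read_sam(sam_path)
    return CohortBundle(
        config=config,
        nuclear_ref=refs[config.nuclear_contig],
        mt_ref=refs["MT"],
        raw_callsets=callsets,
        sample_info=sample_info,
        pedigree=read_pedigree(d / "pedigree.tsv"),
        truths=truths,
        planted=planted,
        reads=reads,
    )
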