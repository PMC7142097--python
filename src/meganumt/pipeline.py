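"""End-to-end analysis: QC, trio screen, NUMT detection, copy/HTF modelling
and transmission statistics, producing a single study-style report.

Two independent discovery routes are always run and cross-tabulated:

1. the child-led trio screen (informative trios → shared paternal variants →
   homoplasmy-mismatch exclusion → mixed-haplotype candidates), and
2. the father-led screen (heteroplasmy-count outliers carrying a rare, large
   NUMT), which can recover transmissions whose haplotype fraction falls
   below the trio screen's 5% threshold.

Trio classification never depends on NUMT calls — the two routes are
independent lines of evidence that a mixed haplotype is nuclear-encoded.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

from . import __version__
from .cohort_stats import (
    count_extreme_heterozygotes,
    determine_sex,
    transmission_summary,
)
from .copy_htf import estimate_nmt, flanking_depth
from .numt_detect import NumtCall, detect_numts_sample, group_numts
from .trio_screen import (
    CohortScreen,
    find_meganumt_fathers,
    informative_variants,
    iqr_outlier_threshold,
    screen_cohort,
)
from .mt_calls import heteroplasmy_count

__all__ = ["RunReport", "run_full_screen", "cross_family_numt_match"]

log = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Everything the full screen computed, with thresholds echoed."""

    n_trios_total: int
    n_trios_qc_excluded: int
    n_trios_screened: int
    n_individuals: int
    qc_exclusions: list[dict]
    screen_counts: dict[str, int]
    candidate_fraction_pct: float
    candidates: list[dict]
    numt_calls: list[dict]
    father_screen: dict
    copy_estimates: list[dict]
    transmission: dict | None
    cross_family: list[dict]
    extreme_het_counts: dict[str, int]
    parameters: dict
    seed: int
    version: str = __version__
    _grouped_calls: list[NumtCall] = field(default_factory=list, repr=False)
    _screen: CohortScreen | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            k: v
            for k, v in self.__dict__.items()
            if not k.startswith("_")
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def _call_row(c: NumtCall) -> dict:
    return {
        "numt_id": c.numt_id,
        "nuclear_contig": c.nuclear_contig,
        "start": c.nuclear_interval[0],
        "end": c.nuclear_interval[1],
        "mt_breakpoints": [f"{s.pos}({s.strand})" for s in c.mt_breakpoints],
        "n_discordant": c.n_discordant,
        "n_split": c.n_split,
        "carriers": list(c.carriers),
        "frequency": c.cohort_frequency,
        "mega_evidence": c.mega_evidence,
    }


def cross_family_numt_match(calls, sample_to_family=None) -> list[dict]:
    """Families sharing one grouped NUMT call, with the shared mt-mt junction
    list (identical mtDNA-derived junctions across unrelated families are the
    hallmark of a recurrent mega-NUMT co-segregating with the haplotype)."""
    groups = []
    for c in calls:
        if sample_to_family is None:
            # generator sample ids end in a role letter (F/M/C)
            families = sorted({re.sub(r"[FMC]$", "", s) for s in c.carriers})
        else:
            families = sorted({sample_to_family[s] for s in c.carriers})
        if len(families) < 2:
            continue
        groups.append(
            {
                "numt_id": c.numt_id,
                "families": families,
                "carriers": list(c.carriers),
                "shared_mt_mt_junctions": [
                    {
                        "side_a": f"{j.side_a.pos}({j.side_a.strand})",
                        "side_b": f"{j.side_b.pos}({j.side_b.strand})",
                        "split_support": j.split_support,
                    }
                    for j in c.junctions
                    if j.kind == "mt_mt"
                ],
            }
        )
    return groups


def run_full_screen(
    bundle,
    *,
    seed: int = 0,
    af_threshold: float = 0.05,
    homoplasmy_mismatch_min: int = 3,
    min_mt_depth: float = 500.0,
    het_min: int = 12,
    numt_freq_max: float = 0.001,
    mt_span_min: float = 500.0,
    min_pairs: int = 5,
    mapq_min: int = 20,
    ci_level: float = 0.95,
) -> RunReport:
    """Run QC, both discovery routes, copy-number estimation and the
    transmission summary over a cohort bundle.

    ``bundle`` is a :class:`~meganumt.synthetic.CohortBundle` (in-memory or
    loaded from disk); the pipeline is deterministic given the bundle and
    parameters.
    """
    info = bundle.sample_info
    sample_to_family = {s.sample_id: s.trio_id for s in info.values()}

    # --- stage 1: sample / trio QC -----------------------------------------
    qc_exclusions: list[dict] = []
    extreme_het: dict[str, int] = {}
    included_rows = []
    for row in bundle.pedigree:
        members = [row["father_id"], row["mother_id"], row["child_id"]] + row["sib_ids"]
        for sid in members:
            extreme_het[sid] = count_extreme_heterozygotes(
                info[sid].nuclear_het_afs
            )
        reasons = []
        if any(info[s].dp_mt < min_mt_depth for s in members[:3]):
            reasons.append("mt_depth_below_500")
        if determine_sex(info[row["father_id"]].depth_x, info[row["father_id"]].depth_y) != "male":
            reasons.append("father_sex_mismatch")
        if determine_sex(info[row["mother_id"]].depth_x, info[row["mother_id"]].depth_y) != "female":
            reasons.append("mother_sex_mismatch")
        if reasons:
            qc_exclusions.append({"trio_id": row["trio_id"], "reasons": reasons})
        else:
            included_rows.append(row)
    log.info("QC: %d/%d trios retained", len(included_rows), len(bundle.pedigree))

    included_ids = {row["trio_id"] for row in included_rows}
    trios = [t for t in bundle.trios if t.trio_id in included_ids]
    trio_by_id = {t.trio_id: t for t in trios}
    row_by_id = {row["trio_id"]: row for row in included_rows}

    # --- stage 2: child-led trio screen ------------------------------------
    screen = screen_cohort(trios, af_threshold, homoplasmy_mismatch_min)
    log.info("screen: %s", screen.counts)

    # --- stage 3: father heteroplasmy outliers -----------------------------
    het_counts = {
        row["father_id"]: heteroplasmy_count(trio_by_id[row["trio_id"]].father)
        for row in included_rows
    }
    iqr_fence = (
        iqr_outlier_threshold(het_counts.values()) if len(het_counts) >= 4 else None
    )
    flagged_fathers = [fid for fid, n in het_counts.items() if n > het_min]

    # --- stage 4: NUMT detection on flagged families -----------------------
    candidate_ids = {c.trio_id for c in screen.candidates}
    target_samples: set[str] = set()
    for row in included_rows:
        fam_flagged = row["father_id"] in flagged_fathers
        if row["trio_id"] in candidate_ids or fam_flagged:
            target_samples.update(
                [row["father_id"], row["mother_id"], row["child_id"]], row["sib_ids"]
            )
    per_sample_calls = []
    nuclear_refs = {bundle.config.nuclear_contig: bundle.nuclear_ref}
    for sid in sorted(target_samples):
        reads = bundle.reads.get(sid)
        if not reads:
            continue
        per_sample_calls.extend(
            detect_numts_sample(
                sid, reads, nuclear_refs, bundle.mt_ref,
                mapq_min=mapq_min, min_pairs=min_pairs,
            )
        )
    grouped = group_numts(per_sample_calls, cohort_size=bundle.n_individuals)
    calls_by_carrier: dict[str, list[NumtCall]] = {}
    for c in grouped:
        for s in c.carriers:
            calls_by_carrier.setdefault(s, []).append(c)

    # --- stage 5: father-led screen ----------------------------------------
    father_callsets = [trio_by_id[sample_to_family[fid]].father for fid in flagged_fathers]
    hits = find_meganumt_fathers(
        father_callsets, grouped, het_min, numt_freq_max, mt_span_min
    )
    father_screen = {
        "het_min": het_min,
        "iqr_fence": iqr_fence,
        "numt_freq_max": numt_freq_max,
        "mt_span_min": mt_span_min,
        "flagged_fathers": sorted(flagged_fathers),
        "hits": sorted(hits),
        "fraction_pct": 100.0 * len(hits) / len(included_rows) if included_rows else 0.0,
    }

    # --- stage 6: candidate co-segregation annotations ---------------------
    candidates = []
    for c in screen.candidates:
        row = row_by_id[c.trio_id]
        father_calls = calls_by_carrier.get(row["father_id"], [])
        call = father_calls[0] if father_calls else None
        candidates.append(
            {
                "trio_id": c.trio_id,
                "n_shared_paternal_variants": len(c.shared_paternal_variants),
                "numt_id": call.numt_id if call else None,
                "numt_detected": call is not None,
                "mega_evidence": call.mega_evidence if call else False,
                "child_carries_numt": bool(call and row["child_id"] in call.carriers),
                "mother_carries_numt": bool(call and row["mother_id"] in call.carriers),
            }
        )

    # --- stage 7: copy-number estimates ------------------------------------
    copy_estimates = []
    for fid in sorted(set(hits) | {row_by_id[c["trio_id"]]["father_id"] for c in candidates}):
        trio = trio_by_id[sample_to_family[fid]]
        row = row_by_id[trio.trio_id]
        for call in calls_by_carrier.get(fid, [])[:1]:
            for sid, callset in (
                (fid, trio.father),
                (row["child_id"], trio.child),
            ):
                if sid not in call.carriers:
                    continue
                keys = [
                    k
                    for k in informative_variants(trio.father, trio.mother, 0.01)
                    if k in callset.variants and callset.variants[k].af <= 0.95
                ]
                variants = [
                    (k, callset.variants[k].depth, callset.variants[k].alt_total)
                    for k in keys
                ]
                if not variants:
                    continue
                dp_adj = flanking_depth(
                    bundle.reads.get(sid, []), call.nuclear_contig, call.nuclear_interval
                )
                if dp_adj <= 0:
                    continue
                est = estimate_nmt(
                    variants, dp_adj, sample_id=sid, numt_id=call.numt_id
                )
                copy_estimates.append(
                    {
                        "sample_id": sid,
                        "numt_id": call.numt_id,
                        "n_variants": len(variants),
                        "dp_adj_numt": round(dp_adj, 2),
                        "summary_nmt": round(est.summary_nmt, 3),
                    }
                )

    # --- stage 8: transmission summary over father-screen hits -------------
    pairs = []
    for fid in sorted(hits):
        row = row_by_id[sample_to_family[fid]]
        father_calls = calls_by_carrier.get(fid, [])
        if not father_calls:
            continue
        call = father_calls[0]
        for child_id in [row["child_id"], *row["sib_ids"]]:
            pairs.append((fid, child_id, child_id in call.carriers))
    transmission = (
        transmission_summary(pairs, ci_level).to_dict() if pairs else None
    )

    report = RunReport(
        n_trios_total=len(bundle.pedigree),
        n_trios_qc_excluded=len(qc_exclusions),
        n_trios_screened=len(included_rows),
        n_individuals=bundle.n_individuals,
        qc_exclusions=qc_exclusions,
        screen_counts=dict(screen.counts),
        candidate_fraction_pct=screen.candidate_fraction_pct,
        candidates=candidates,
        numt_calls=[_call_row(c) for c in grouped],
        father_screen=father_screen,
        copy_estimates=copy_estimates,
        transmission=transmission,
        cross_family=cross_family_numt_match(grouped, sample_to_family),
        extreme_het_counts=extreme_het,
        parameters={
            "af_threshold": af_threshold,
            "homoplasmy_mismatch_min": homoplasmy_mismatch_min,
            "min_mt_depth": min_mt_depth,
            "het_min": het_min,
            "numt_freq_max": numt_freq_max,
            "mt_span_min": mt_span_min,
            "min_pairs": min_pairs,
            "mapq_min": mapq_min,
            "ci_level": ci_level,
        },
        seed=seed,
        _grouped_calls=grouped,
        _screen=screen,
    )
    return report
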