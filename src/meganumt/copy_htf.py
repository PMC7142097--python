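"""Copy-number and haplotype-fraction modelling for mega-NUMTs.

If a NUMT carries ``Nmt`` concatenated copies of an mtDNA-derived fragment on
one autosome, a carrier sequenced at nuclear depth ``DPnu`` contributes
``DPnu/2 * Nmt`` NUMT-derived reads at each discriminating site of the
mtDNA alignment, on top of ``DPmt`` reads from true mtDNA.  Two consequences
drive this module:

* the copy number can be estimated from the alternate-read count of each
  informative variant, ``Nmt = Altmt / (DPadjnumt / 2)``, where ``DPadjnumt``
  is the nuclear depth flanking the insertion and alt counts above 50% AF are
  folded (``Altmt = DPmtvar - Altmt'``);
* the apparent heteroplasmic fraction of the mixed haplotype is
  ``HTF = (DPnu/2 * Nmt) / (DPnu/2 * Nmt + DPmt)``, which *falls* as true
  mtDNA content rises — the opposite of what genuine heteroplasmy would do.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "CopyEstimate",
    "flanking_depth",
    "HtfGridPoint",
    "fold_alt_count",
    "estimate_nmt",
    "htf",
    "htf_grid",
    "af_depth_correlation",
    "plot_htf_grid",
]


@dataclass(frozen=True)
class CopyEstimate:
    """Per-variant and summary copy-number estimates for one carrier."""

    sample_id: str
    numt_id: str
    per_variant: tuple[tuple[tuple[int, str], int, float], ...]  # (key, Altmt, Nmt)
    summary_nmt: float  # median of per-variant Nmt


@dataclass(frozen=True)
class HtfGridPoint:
    dp_nu: float
    dp_mt: float
    nmt: float
    htf: float
    ci_low: float
    ci_high: float


def fold_alt_count(dp_mtvar: int, alt_raw: int) -> int:
    """Fold alt counts above 50% AF: the NUMT-derived allele is the minority,
    so an apparent majority call means the alt reads are true mtDNA."""
    if dp_mtvar <= 0:
        raise ValueError(f"non-positive variant depth {dp_mtvar}")
    if not 0 <= alt_raw <= dp_mtvar:
        raise ValueError(f"alt reads {alt_raw} outside 0..{dp_mtvar}")
    if alt_raw / dp_mtvar > 0.5:
        return dp_mtvar - alt_raw
    return alt_raw


def estimate_nmt(
    informative_variants,
    dp_adj_numt: float,
    *,
    sample_id: str = "",
    numt_id: str = "",
) -> CopyEstimate:
    """Estimate the number of concatenated fragment copies from the mixed
    haplotype's informative variants.

    ``informative_variants`` is an iterable of ``(dp_mtvar, alt_raw)`` or
    ``(key, dp_mtvar, alt_raw)`` tuples; ``dp_adj_numt`` is the mean nuclear
    depth flanking the insertion (both homologous chromosomes).  The summary
    is the median of per-variant estimates, which resists junction-proximal
    outliers.
    """
    if dp_adj_numt <= 0:
        raise ValueError(f"non-positive flanking depth {dp_adj_numt}")
    per_variant = []
    for item in informative_variants:
        if len(item) == 3:
            key, dp, alt = item
        else:
            dp, alt = item
            key = (0, "N")
        alt_mt = fold_alt_count(dp, alt)
        per_variant.append((key, alt_mt, alt_mt / (dp_adj_numt / 2.0)))
    if not per_variant:
        raise ValueError("no informative variants to estimate copy number from")
    return CopyEstimate(
        sample_id=sample_id,
        numt_id=numt_id,
        per_variant=tuple(per_variant),
        summary_nmt=statistics.median(n for _, _, n in per_variant),
    )


def flanking_depth(
    reads,
    contig: str,
    interval: tuple[int, int],
    flank: int = 1000,
    exclude: int = 200,
) -> float:
    """Mean per-base nuclear depth over 1 kb flanks on each side of an
    insertion locus, excluding ``exclude`` bp around the junctions (depth
    there is distorted by clipped reads).

    ``reads`` are aligned records with ``contig``, ``pos`` (1-based) and
    ``sequence``; both homologous chromosomes contribute, so this is the
    DPadjnumt of the copy-number estimator.
    """
    start, end = interval
    regions = [
        (start - exclude - flank, start - exclude - 1),
        (end + exclude + 1, end + exclude + flank),
    ]
    covered = 0
    total = sum(hi - lo + 1 for lo, hi in regions)
    for r in reads:
        if r.contig != contig:
            continue
        r_lo, r_hi = r.pos, r.pos + len(r.sequence) - 1
        for lo, hi in regions:
            covered += max(0, min(hi, r_hi) - max(lo, r_lo) + 1)
    return covered / total


def htf(dp_nu: float, dp_mt: float, nmt: float) -> float:
    """Modelled mixed-haplotype fraction for ``nmt`` fragment copies at
    nuclear depth ``dp_nu`` and true mtDNA depth ``dp_mt``."""
    if dp_nu <= 0 or dp_mt <= 0:
        raise ValueError("depths must be positive")
    if nmt < 0:
        raise ValueError("copy number must be non-negative")
    numt_reads = dp_nu / 2.0 * nmt
    return numt_reads / (numt_reads + dp_mt)


def htf_grid(
    dp_nu_values=(35, 40, 45, 50),
    dp_mt_values=range(200, 4501, 100),
    nmt_values=range(1, 21),
    ci_level: float = 0.95,
) -> list[HtfGridPoint]:
    """HTF over the depth/copy grid with exact binomial confidence bands.

    At each point the alt-read count is modelled as
    ``Binomial(n = round(DPnu/2*Nmt + DPmt), p = HTF)`` and the band is the
    exact binomial quantile interval divided by n (no normal approximation;
    alt counts are small at one copy).
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    alpha = 1.0 - ci_level
    points = []
    for dp_nu in dp_nu_values:
        for nmt in nmt_values:
            for dp_mt in dp_mt_values:
                p = htf(dp_nu, dp_mt, nmt)
                n = int(round(dp_nu / 2.0 * nmt + dp_mt))
                lo = stats.binom.ppf(alpha / 2.0, n, p) / n
                hi = stats.binom.ppf(1.0 - alpha / 2.0, n, p) / n
                points.append(
                    HtfGridPoint(
                        dp_nu=float(dp_nu),
                        dp_mt=float(dp_mt),
                        nmt=float(nmt),
                        htf=p,
                        ci_low=float(lo),
                        ci_high=float(hi),
                    )
                )
    return points


def af_depth_correlation(points) -> dict:
    """Pearson correlation of observed haplotype AF against true mtDNA depth.

    A nuclear-encoded mixed haplotype is diluted by mtDNA content, so the
    expected correlation is negative.  Returns ``{"r", "p_value", "n",
    "statistic"}``; the ``statistic`` key records that this is the Pearson
    product-moment coefficient r (a signed quantity, unlike R^2).
    """
    pts = [(float(d), float(a)) for d, a in points]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 points, got {len(pts)}")
    depths = [d for d, _ in pts]
    afs = [a for _, a in pts]
    if len(set(depths)) == 1 or len(set(afs)) == 1:
        raise ValueError("correlation undefined: zero variance in a coordinate")
    r, p = stats.pearsonr(depths, afs)
    return {"r": float(r), "p_value": float(p), "n": len(pts), "statistic": "pearson_r"}


def plot_htf_grid(points, path, band_nmt=(1, 20)):
    """Render HTF-vs-depth curves (one line per copy number and nuclear depth)
    with confidence bands for the copy numbers in ``band_nmt``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    by_curve: dict[tuple[float, float], list[HtfGridPoint]] = {}
    for p in points:
        by_curve.setdefault((p.dp_nu, p.nmt), []).append(p)
    for (dp_nu, nmt), pts in sorted(by_curve.items()):
        pts.sort(key=lambda p: p.dp_mt)
        x = [p.dp_mt for p in pts]
        ax.plot(x, [p.htf for p in pts], lw=0.8, alpha=0.7)
        if nmt in band_nmt:
            ax.fill_between(
                x, [p.ci_low for p in pts], [p.ci_high for p in pts], alpha=0.15
            )
    ax.set_xlabel("true mtDNA depth (x)")
    ax.set_ylabel("modelled haplotype fraction")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
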