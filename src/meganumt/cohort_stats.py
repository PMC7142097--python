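"""Study-level statistics and sample-QC heuristics.

Transmission of an autosomal insertion from a heterozygous father follows
Mendelian expectation (probability 1/2 per offspring), so the observed
proportion of transmitted NUMTs with an exact (Clopper-Pearson) binomial
confidence interval is the key consistency check against autosomal
inheritance.  The QC heuristics — sex from sex-chromosome depth ratio and a
count of extreme nuclear heterozygotes as a contamination flag — mirror the
checks applied to whole-genome cohorts before trio analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "TransmissionSummary",
    "clopper_pearson_ci",
    "transmission_summary",
    "determine_sex",
    "count_extreme_heterozygotes",
]


def clopper_pearson_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval via beta quantiles.

    Lower bound is 0 when ``successes == 0`` and upper bound 1 when
    ``successes == trials``.
    """
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes {successes} outside 0..{trials}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    if successes == 0:
        low = 0.0
    else:
        low = float(stats.beta.ppf(alpha / 2.0, successes, trials - successes + 1))
    if successes == trials:
        high = 1.0
    else:
        high = float(stats.beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes))
    return (low, high)


@dataclass(frozen=True)
class TransmissionSummary:
    """Father-to-offspring transmission proportion with exact CI (percent)."""

    n_pairs: int
    n_transmitted: int
    proportion: float
    ci_low: float
    ci_high: float
    ci_level: float

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_transmitted": self.n_transmitted,
            "proportion_pct": round(self.proportion, 1),
            "ci_low_pct": round(self.ci_low, 1),
            "ci_high_pct": round(self.ci_high, 1),
            "ci_level": self.ci_level,
        }


def transmission_summary(pairs, level: float = 0.95) -> TransmissionSummary:
    """Summarise father–offspring transmission outcomes.

    ``pairs`` is an iterable of ``(father_id, child_id, transmitted)``
    triples.  Percentages are on the 0–100 scale.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no father-offspring pairs to summarise")
    n = len(pairs)
    k = sum(1 for _, _, t in pairs if t)
    low, high = clopper_pearson_ci(k, n, level)
    return TransmissionSummary(
        n_pairs=n,
        n_transmitted=k,
        proportion=100.0 * k / n,
        ci_low=100.0 * low,
        ci_high=100.0 * high,
        ci_level=level,
    )


def determine_sex(depth_x: float, depth_y: float, ratio: float = 10.0) -> str:
    """Sex from mean sex-chromosome depths: female iff chrX depth is at least
    ``ratio`` times chrY depth (zero chrY depth maps to female)."""
    if depth_x <= 0:
        raise ValueError(f"chrX depth must be positive, got {depth_x}")
    if depth_y < 0:
        raise ValueError(f"chrY depth must be non-negative, got {depth_y}")
    if depth_y == 0 or depth_x >= ratio * depth_y:
        return "female"
    return "male"


def count_extreme_heterozygotes(
    het_afs, low: float = 0.25, high: float = 0.75
) -> int:
    """Number of nuclear heterozygous AFs strictly beyond [``low``, ``high``].

    A contamination heuristic: mixed DNA pushes heterozygote allele fractions
    away from ~50%.  Boundary values count as inside the range.
    """
    n = 0
    for af in het_afs:
        if not 0 <= af <= 1:
            raise ValueError(f"allele fraction {af} outside [0, 1]")
        if af < low or af > high:
            n += 1
    return n
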