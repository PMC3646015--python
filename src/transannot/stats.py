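"""Welch's t-test for length comparisons and assembly summary reporting.

Length distributions of annotation categories (with/without database hits,
coding/non-coding, clade-restricted) have unequal variances, so pairwise
comparisons use Welch's unequal-variance t-test with Welch–Satterthwaite
degrees of freedom. The summary calculator reproduces the standard
read-fate percentage bookkeeping of an assembly report: pass rate over raw
reads, read fates over quality-passing reads, hit rates over isotig /
singleton counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import ClassVar, Mapping, Sequence

from scipy import stats as _scipy_stats

__all__ = [
    "WelchResult",
    "AssemblySummary",
    "welch_t",
    "summarize_assembly",
    "compare_length_tables",
    "significance_code",
]

#: Star coding used in the pairwise comparison matrices.
SIGNIFICANCE_LEVELS: tuple[tuple[float, str], ...] = (
    (0.0001, "***"),
    (0.001, "**"),
    (0.05, "*"),
)


@dataclass(frozen=True)
class WelchResult:
    """Welch's t-test outcome; df may be non-integral.

    Swapping the samples negates t and preserves p.
    """

    t: float
    df: float
    p_two_sided: float
    mean1: float
    mean2: float
    var1: float
    var2: float
    n1: int
    n2: int


def _mean_var(sample: Sequence[float]) -> tuple[float, float]:
    n = len(sample)
    m = sum(sample) / n
    v = sum((x - m) ** 2 for x in sample) / (n - 1)
    return m, v


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided.

    t = (m₁−m₂)/√(s₁²/n₁ + s₂²/n₂); degrees of freedom by
    Welch–Satterthwaite; p from the t survival function. Two samples with
    zero variance and equal means yield t = 0, p = 1.
    """
    n1, n2 = len(sample_a), len(sample_b)
    if n1 < 2 or n2 < 2:
        raise ValueError("welch_t requires n ≥ 2 in both samples")
    m1, v1 = _mean_var(sample_a)
    m2, v2 = _mean_var(sample_b)
    se1, se2 = v1 / n1, v2 / n2
    pooled = se1 + se2
    if pooled == 0:
        if m1 == m2:
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0, m1, m2, v1, v2, n1, n2)
        raise ValueError("zero pooled variance with unequal means")
    t = (m1 - m2) / math.sqrt(pooled)
    df = pooled**2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = 2.0 * float(_scipy_stats.t.sf(abs(t), df))
    return WelchResult(t, df, min(p, 1.0), m1, m2, v1, v2, n1, n2)


def significance_code(p: float) -> str:
    """Star coding: *** p<0.0001, ** p<0.001, * p<0.05, else the number."""
    for threshold, code in SIGNIFICANCE_LEVELS:
        if p < threshold:
            return code
    return format(p, ".4g")


def compare_length_tables(
    category_samples: Mapping[str, Sequence[float]],
) -> dict[tuple[str, str], tuple[WelchResult, str]]:
    """Pairwise Welch comparisons across ≥2 length categories.

    Returns an upper-triangular mapping (label pair in sorted order) of
    (result, significance code). Categories with n < 2 are excluded with a
    warning. No multiple-testing correction is applied.
    """
    usable = {}
    for label, sample in category_samples.items():
        if len(sample) < 2:
            warnings.warn(
                f"category {label!r} has n < 2; excluded from comparisons",
                stacklevel=2,
            )
            continue
        usable[label] = sample
    if len(usable) < 2:
        raise ValueError("need ≥2 categories with n ≥ 2")
    labels = sorted(usable)
    matrix: dict[tuple[str, str], tuple[WelchResult, str]] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            result = welch_t(usable[a], usable[b])
            matrix[(a, b)] = (result, significance_code(result.p_two_sided))
    return matrix


@dataclass
class AssemblySummary:
    """Assembly report counts and their derived percentages.

    Denominators: ``passed_reads`` over ``raw_reads`` for the pass rate;
    read fates (fully/partially assembled, too-short, repeat, outlier,
    singleton reads) over ``passed_reads``; isotig nr-hit counts over
    ``n_isotigs``; singleton nr-hit counts over ``n_singletons``;
    single-isotig isogroups over ``n_isogroups``. Percentages are stored
    unrounded; ``report()`` rounds half-up to two decimals.
    """

    raw_reads: int | None = None
    passed_reads: int | None = None
    fully_assembled: int | None = None
    partially_assembled: int | None = None
    too_short: int | None = None
    repeat_reads: int | None = None
    outliers: int | None = None
    singletons: int | None = None
    n_contigs: int | None = None
    n_isotigs: int | None = None
    n_isogroups: int | None = None
    n_singleton_products: int | None = None
    isotigs_with_hit: int | None = None
    singletons_with_hit: int | None = None
    single_isotig_isogroups: int | None = None

    #: percentage name → (numerator field, denominator field)
    PERCENTAGE_REGISTRY: ClassVar[tuple[tuple[str, str, str], ...]] = (
        ("pct_passed", "passed_reads", "raw_reads"),
        ("pct_fully_assembled", "fully_assembled", "passed_reads"),
        ("pct_partially_assembled", "partially_assembled", "passed_reads"),
        ("pct_too_short", "too_short", "passed_reads"),
        ("pct_repeat", "repeat_reads", "passed_reads"),
        ("pct_outliers", "outliers", "passed_reads"),
        ("pct_singletons", "singletons", "passed_reads"),
        ("pct_isotigs_with_hit", "isotigs_with_hit", "n_isotigs"),
        ("pct_singletons_with_hit", "singletons_with_hit", "n_singleton_products"),
        ("pct_single_isotig_isogroups", "single_isotig_isogroups", "n_isogroups"),
    )

    def percentages(self) -> dict[str, float]:
        """Unrounded percentages for every computable registry entry."""
        out: dict[str, float] = {}
        for name, num_field, den_field in self.PERCENTAGE_REGISTRY:
            num = getattr(self, num_field)
            den = getattr(self, den_field)
            if num is None or den is None:
                continue
            if den <= 0:
                raise ValueError(f"non-positive denominator {den_field}")
            if num > den:
                raise ValueError(
                    f"{num_field} ({num}) exceeds {den_field} ({den})"
                )
            out[name] = 100.0 * num / den
        return out

    def check_read_conservation(self) -> None:
        """Read fates must sum to the passed-read count when all present."""
        parts = [
            self.fully_assembled,
            self.partially_assembled,
            self.too_short,
            self.repeat_reads,
            self.outliers,
            self.singletons,
        ]
        if self.passed_reads is None or any(p is None for p in parts):
            return
        total = sum(parts)  # type: ignore[arg-type]
        if total != self.passed_reads:
            raise ValueError(
                f"read fates sum to {total}, expected {self.passed_reads}"
            )

    def report(self) -> str:
        lines = ["# Assembly summary"]
        for f in fields(self):
            value = getattr(self, f.name)
            if value is not None and isinstance(value, int):
                lines.append(f"{f.name}\t{value:,}")
        for name, pct in self.percentages().items():
            # half-up rounding to 2 decimals for report strings
            shown = math.floor(pct * 100 + 0.5) / 100
            lines.append(f"{name}\t{shown:.2f}%")
        return "\n".join(lines)


def summarize_assembly(**counts: int) -> AssemblySummary:
    """Build an :class:`AssemblySummary` from keyword counts.

    Partial input is allowed; the read-conservation check only runs when
    every read-fate field is supplied. Raises on a numerator exceeding its
    denominator.
    """
    summary = AssemblySummary(**counts)
    summary.check_read_conservation()
    summary.percentages()  # validates numerator/denominator relations
    return summary
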