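"""Gene-discovery saturation analysis over a ladder of subassemblies.

Random read subsets of increasing size are assembled (by an external
assembler hook or the synthetic exact-overlap assembler used for tests)
and each subassembly is scored for unique reference hits, coverage and
N50. A plateau in unique hits indicates sampling completeness; the curve
machinery never enforces monotonicity — unique hits can legitimately drop
near full depth as previously separate contigs merge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from transannot.blasttab import Hsp, count_unique_subjects
from transannot.seqmodel import coverage_stats, n50

__all__ = [
    "SaturationPlan",
    "SaturationPoint",
    "LinearFit",
    "subset_reads",
    "saturation_curve",
]


@dataclass(frozen=True)
class SaturationPlan:
    """Subsampling schedule: fractions of the read pool, RNG seed, and the
    size-rounding convention (half-up ``round`` or ``floor``)."""

    fractions: tuple[float, ...] = tuple(
        round(0.1 * i, 10) for i in range(1, 11)
    )
    seed: int = 0
    rounding: str = "round"

    def __post_init__(self) -> None:
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if list(self.fractions) != sorted(set(self.fractions)):
            raise ValueError("fractions must be strictly increasing")
        if self.rounding not in ("round", "floor"):
            raise ValueError(f"unknown rounding {self.rounding!r}")


@dataclass(frozen=True)
class SaturationPoint:
    fraction: float
    n_reads: int
    unique_hits: int
    coverage_per_bp: float
    n50: int
    pct_singleton_reads: float
    isotig_length_hist: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


def _subset_size(n: int, fraction: float, rounding: str) -> int:
    if rounding == "floor":
        return math.floor(fraction * n)
    # half-up (not banker's) rounding
    return math.floor(fraction * n + 0.5)


def subset_reads(
    read_ids: Sequence[str],
    fraction: float,
    seed: int,
    rounding: str = "round",
) -> list[str]:
    """Uniform sample of read ids without replacement.

    Sampling is performed over the sorted id list, so the result depends
    only on the id *set*, the fraction and the seed — not on input order.
    Size is ``round(fraction × N)`` with half-up rounding (or floor).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    ids = sorted(set(read_ids))
    if fraction == 1.0:
        return ids
    k = _subset_size(len(ids), fraction, rounding)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=k, replace=False)
    return [ids[i] for i in sorted(chosen)]


def _linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    if len(x) < 2:
        raise ValueError("need ≥2 points for the linear fit")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    slope, intercept = np.polyfit(xa, ya, 1)
    residuals = ya - (slope * xa + intercept)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    # constant-response convention: zero total sum of squares → R² = 0
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return LinearFit(slope=float(slope), intercept=float(intercept), r_squared=r2)


def saturation_curve(
    point_inputs: Sequence[Mapping],
) -> tuple[list[SaturationPoint], LinearFit]:
    """Score each subassembly and fit coverage vs read count by OLS.

    Each input bundle carries ``n_reads``, a per-query ``best_hits``
    mapping (query → Hsp), isotig ``lengths``, coverage inputs
    (``aligned_bp``, ``contig_lengths``) and optionally
    ``n_singleton_reads``. Returns the per-point metrics plus the linear
    fit of coverage-per-bp against read count (slope, intercept, R²).
    """
    if len(point_inputs) < 2:
        raise ValueError("need ≥2 subassembly points")
    points: list[SaturationPoint] = []
    for bundle in point_inputs:
        n_reads = int(bundle["n_reads"])
        best: Mapping[str, Hsp] = bundle["best_hits"]
        lengths: Sequence[int] = bundle["lengths"]
        cov = coverage_stats(bundle["aligned_bp"], bundle["contig_lengths"])
        n_singleton = int(bundle.get("n_singleton_reads", 0))
        hist: dict[str, int] = {}
        for length in lengths:
            bin_label = f"{(length // 500) * 500}"
            hist[bin_label] = hist.get(bin_label, 0) + 1
        points.append(
            SaturationPoint(
                fraction=float(bundle.get("fraction", float("nan"))),
                n_reads=n_reads,
                unique_hits=count_unique_subjects(best),
                coverage_per_bp=cov.avg_coverage_per_bp,
                n50=n50(lengths),
                pct_singleton_reads=100.0 * n_singleton / n_reads
                if n_reads
                else 0.0,
                isotig_length_hist=hist,
            )
        )
    fit = _linear_fit(
        [p.n_reads for p in points], [p.coverage_per_bp for p in points]
    )
    return points, fit


def write_curve_tsv(points: Sequence[SaturationPoint], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#fraction\tn_reads\tunique_hits\tcoverage_per_bp\tn50\t"
            "pct_singleton_reads\n"
        )
        for p in points:
            fh.write(
                f"{p.fraction:.2f}\t{p.n_reads}\t{p.unique_hits}\t"
                f"{p.coverage_per_bp:.4f}\t{p.n50}\t"
                f"{p.pct_singleton_reads:.2f}\n"
            )
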