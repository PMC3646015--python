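"""Ortholog hit ratio (OHR): a transcript-completeness proxy.

The OHR of an assembly product is its length divided by the full length of
its putative ortholog's mRNA (cDNA length as the proxy, absent a genome).
A ratio near 1 suggests a near-full-length predicted transcript; ratios can
exceed 1 when UTRs differ between the species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from transannot.rbh_annotator import AnnotationTable

__all__ = ["OhrRecord", "OhrSummary", "compute_ohr", "summarize_ohr"]


@dataclass(frozen=True)
class OhrRecord:
    product_id: str
    product_length: int
    ortholog_id: str
    ortholog_transcript_length: int
    ratio: float


@dataclass(frozen=True)
class OhrSummary:
    """Fraction of products at or above each threshold, plus a histogram.

    Histogram bins cover [0, 1] at ``bin_width`` steps with a final open
    ``>1`` overflow bin; counts sum to n.
    """

    n: int
    frac_ge: dict[float, float]
    histogram: dict[str, int]
    bin_width: float


def compute_ohr(
    annotations: AnnotationTable | Mapping[str, str],
    product_lengths: Mapping[str, int],
    transcript_lengths: Mapping[str, int],
) -> list[OhrRecord]:
    """One OHR record per annotated product; unannotated products omitted.

    ``annotations`` is either an orthology table or a plain
    product→ortholog best-hit mapping. Ratios are not capped at 1. Raises
    ``KeyError``-style errors naming the missing ortholog or product.
    """
    if isinstance(annotations, AnnotationTable):
        pairs = {
            c.transcript_id: c.protein_id for c in annotations.calls
        }
    else:
        pairs = dict(annotations)

    records: list[OhrRecord] = []
    for product_id in sorted(pairs):
        ortholog_id = pairs[product_id]
        if product_id not in product_lengths:
            raise ValueError(f"no length for product {product_id}")
        if ortholog_id not in transcript_lengths:
            raise ValueError(
                f"no reference transcript length for ortholog {ortholog_id}"
            )
        plen = product_lengths[product_id]
        tlen = transcript_lengths[ortholog_id]
        if plen < 1 or tlen < 1:
            raise ValueError(
                f"non-positive length for {product_id}/{ortholog_id}"
            )
        records.append(
            OhrRecord(
                product_id=product_id,
                product_length=plen,
                ortholog_id=ortholog_id,
                ortholog_transcript_length=tlen,
                ratio=plen / tlen,
            )
        )
    return records


def summarize_ohr(
    records: Sequence[OhrRecord] | Iterable[OhrRecord],
    thresholds: Sequence[float] = (0.5, 0.8),
    bin_width: float = 0.1,
) -> OhrSummary:
    """Threshold fractions (inclusive ≥) and a mass-conserving histogram."""
    ratios = [r.ratio for r in records]
    if not ratios:
        raise ValueError("summarize_ohr of an empty record list")
    n = len(ratios)
    frac_ge = {
        t: sum(1 for r in ratios if r >= t) / n for t in thresholds
    }
    n_bins = math.ceil(round(1.0 / bin_width, 9))
    histogram: dict[str, int] = {}
    edges = [round(i * bin_width, 9) for i in range(n_bins + 1)]
    for i in range(n_bins):
        lo, hi = edges[i], min(edges[i + 1], 1.0)
        label = f"[{lo:g},{hi:g})" if i < n_bins - 1 else f"[{lo:g},{hi:g}]"
        histogram[label] = 0
    histogram[">1"] = 0
    labels = list(histogram)
    for r in ratios:
        if r > 1.0:
            histogram[">1"] += 1
            continue
        idx = min(int(r / bin_width), n_bins - 1)
        histogram[labels[idx]] += 1
    return OhrSummary(
        n=n, frac_ge=frac_ge, histogram=histogram, bin_width=bin_width
    )


def write_ohr_tsv(records: Sequence[OhrRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#product_id\tproduct_length\tortholog_id\t"
            "ortholog_transcript_length\tratio\n"
        )
        for r in records:
            fh.write(
                f"{r.product_id}\t{r.product_length}\t{r.ortholog_id}\t"
                f"{r.ortholog_transcript_length}\t{r.ratio:.4f}\n"
            )
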