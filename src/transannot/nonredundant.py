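"""Pre-annotation redundancy filter.

A de novo 454 assembly contains near-identical products created by SNPs,
sequencing error and low-quality reads. Before annotation, any isotig or
singleton whose full span aligns at high identity inside a *longer* product
is dropped, keeping the longer one. The filter consumes an all-vs-all
nucleotide self-comparison in BLAST tabular form; it never aligns sequences
itself.

Semantics are single-pass: removal is judged against the original product
set, so a containment chain a ⊂ b ⊂ c removes a and b and keeps c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from transannot.blasttab import HitTable, Hsp
from transannot.seqmodel import AssemblyCollection

__all__ = ["RedundancyRule", "RemovalRecord", "filter_redundant"]


@dataclass(frozen=True)
class RedundancyRule:
    """Thresholds for calling a product redundant.

    ``min_identity`` is exclusive (identity must exceed it; default 95).
    With ``span="full_query"`` the HSP must cover the query end to end,
    allowing ``end_slack`` unaligned bp at each end (454 homopolymer ends);
    ``span="fractional"`` instead requires query coverage ≥ ``min_cover``.
    """

    min_identity: float = 95.0
    span: str = "full_query"
    end_slack: int = 0
    min_cover: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if self.end_slack < 0:
            raise ValueError("end_slack must be ≥ 0")
        if self.span not in ("full_query", "fractional"):
            raise ValueError(f"unknown span mode {self.span!r}")


@dataclass(frozen=True)
class RemovalRecord:
    removed_id: str
    retained_id: str
    identity: float
    q_cover: float


def _spans_query(hsp: Hsp, q_len: int, rule: RedundancyRule) -> bool:
    lo, hi = hsp.query_interval  # 0-based half-open
    if rule.span == "full_query":
        return lo <= rule.end_slack and hi >= q_len - rule.end_slack
    return (hi - lo) / q_len >= rule.min_cover


def filter_redundant(
    products: AssemblyCollection | Mapping[str, int],
    self_hits: HitTable,
    rule: RedundancyRule = RedundancyRule(),
) -> tuple[set[str], list[RemovalRecord]]:
    """Split products into a kept set and removal records.

    A product q is removed iff some HSP q→s exists with s ≠ q, s longer than
    q (or equal length with the lexicographically smaller id), identity
    strictly above ``rule.min_identity``, and the HSP spanning q per the
    rule. Each removal record names the longest qualifying retainer (ties
    broken by higher bitscore, then smaller id). Self-matches (q→q) in the
    input are tolerated and ignored.

    Raises ``ValueError`` if a hit references an id absent from products.
    """
    if isinstance(products, AssemblyCollection):
        lengths = {pid: p.length for pid, p in products.products.items()}
    else:
        lengths = dict(products)

    best_retainer: dict[str, tuple[tuple[int, float, str], Hsp]] = {}
    for hsp in self_hits:
        q, s = hsp.query_id, hsp.subject_id
        if q not in lengths:
            raise ValueError(f"hit references unknown query id {q}")
        if s not in lengths:
            raise ValueError(f"hit references unknown subject id {s}")
        if q == s:
            continue
        q_len, s_len = lengths[q], lengths[s]
        longer = s_len > q_len or (s_len == q_len and s < q)
        if not longer:
            continue
        if hsp.pct_identity <= rule.min_identity:
            continue
        if not _spans_query(hsp, q_len, rule):
            continue
        # prefer the longest retainer, then highest bitscore, then smallest id
        rank = (-s_len, -hsp.bitscore, s)
        current = best_retainer.get(q)
        if current is None or rank < current[0]:
            best_retainer[q] = (rank, hsp)

    removals: list[RemovalRecord] = []
    for q in sorted(best_retainer):
        _, hsp = best_retainer[q]
        lo, hi = hsp.query_interval
        removals.append(
            RemovalRecord(
                removed_id=q,
                retained_id=hsp.subject_id,
                identity=hsp.pct_identity,
                q_cover=(hi - lo) / lengths[q],
            )
        )
    kept = set(lengths) - set(best_retainer)
    return kept, removals


def write_removals_tsv(removals: list[RemovalRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#removed_id\tretained_id\tidentity\tq_cover\n")
        for r in removals:
            fh.write(
                f"{r.removed_id}\t{r.retained_id}\t"
                f"{r.identity:.2f}\t{r.q_cover:.4f}\n"
            )
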