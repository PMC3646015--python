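"""BLAST tabular (12-column ``-outfmt 6``) parsing and selection primitives.

Every downstream stage consumes :class:`Hsp` records through these
primitives: significance filtering at an E-value cutoff, deterministic
best-hit / top-N selection, and unique-subject counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Hsp",
    "HitTable",
    "parse_blast_tabular",
    "write_blast_tabular",
    "filter_significant",
    "best_hit",
    "hit_sort_key",
    "top_n",
    "count_unique_subjects",
]

COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class Hsp:
    """One high-scoring segment pair, as read from a tabular row.

    Coordinates are 1-based inclusive as BLAST writes them; for minus-strand
    subjects ``s_start > s_end``. ``query_interval``/``subject_interval``
    expose orientation-normalized 0-based half-open intervals.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative evalue for {self.query_id}")
        if self.pct_identity > 100:
            raise ValueError(f"pct_identity > 100 for {self.query_id}")

    @property
    def query_interval(self) -> tuple[int, int]:
        lo, hi = sorted((self.q_start, self.q_end))
        return lo - 1, hi

    @property
    def subject_interval(self) -> tuple[int, int]:
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi

    @property
    def subject_reversed(self) -> bool:
        return self.s_start > self.s_end

    def to_row(self) -> str:
        return "\t".join(
            (
                self.query_id,
                self.subject_id,
                format(self.pct_identity, ".2f"),
                str(self.aln_len),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                format(self.evalue, ".2e"),
                format(self.bitscore, ".1f"),
            )
        )


@dataclass
class HitTable:
    """All HSPs of one BLAST run, grouped by query with file order kept."""

    hsps: list[Hsp] = field(default_factory=list)
    program: str = "blastn"

    def by_query(self) -> dict[str, list[Hsp]]:
        groups: dict[str, list[Hsp]] = {}
        for h in self.hsps:
            groups.setdefault(h.query_id, []).append(h)
        return groups

    def query_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for h in self.hsps:
            seen.setdefault(h.query_id)
        return list(seen)

    def subject_ids(self) -> set[str]:
        return {h.subject_id for h in self.hsps}

    def __len__(self) -> int:
        return len(self.hsps)

    def __iter__(self):
        return iter(self.hsps)


def parse_blast_tabular(path: str | Path, program: str = "blastn") -> HitTable:
    """Parse a 12-column tab-separated BLAST report.

    ``#`` comment lines are skipped. Raises ``ValueError`` with the line
    number on a wrong column count or an unparseable numeric field.
    """
    hsps: list[Hsp] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                hsp = Hsp(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_len=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hsps.append(hsp)
    return HitTable(hsps=hsps, program=program)


def write_blast_tabular(table: HitTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in table.hsps:
            fh.write(h.to_row() + "\n")


def filter_significant(table: HitTable, e_cutoff: float) -> HitTable:
    """Keep exactly the HSPs with evalue ≤ cutoff (inclusive), order kept."""
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    return HitTable(
        hsps=[h for h in table.hsps if h.evalue <= e_cutoff],
        program=table.program,
    )


def hit_sort_key(h: Hsp) -> tuple[float, float, str]:
    # Deterministic "top hit": best evalue, then highest bitscore, then
    # lexicographically smallest subject id.
    return (h.evalue, -h.bitscore, h.subject_id)


def best_hit(hits_for_query: Sequence[Hsp]) -> Hsp:
    """The top hit under (evalue, −bitscore, subject id); ties deterministic."""
    if not hits_for_query:
        raise ValueError("best_hit of an empty hit list")
    return min(hits_for_query, key=hit_sort_key)


def top_n(hits_for_query: Sequence[Hsp], n: int) -> list[Hsp]:
    """First ``n`` hits under the best-hit ordering (fewer if fewer exist)."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    return sorted(hits_for_query, key=hit_sort_key)[:n]


def best_hits_per_query(table: HitTable, e_cutoff: float | None = None) -> dict[str, Hsp]:
    """Convenience: significance-filter then take the best hit per query."""
    if e_cutoff is not None:
        table = filter_significant(table, e_cutoff)
    return {q: best_hit(hits) for q, hits in table.by_query().items()}


def strip_version(accession: str) -> str:
    head, dot, tail = accession.rpartition(".")
    if dot and tail.isdigit():
        return head
    return accession


def count_unique_subjects(
    best_hits: Mapping[str, Hsp] | Iterable[Hsp],
    strip_versions: bool = False,
) -> int:
    """Number of distinct subject accessions among per-query best hits.

    By default subjects are compared as exact accession strings; with
    ``strip_versions`` a trailing ``.N`` version suffix is removed first.
    """
    hsps = best_hits.values() if isinstance(best_hits, Mapping) else best_hits
    subjects = {h.subject_id for h in hsps}
    if strip_versions:
        subjects = {strip_version(s) for s in subjects}
    return len(subjects)
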