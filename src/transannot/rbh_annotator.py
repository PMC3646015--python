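"""Reciprocal-best-hit orthology assignment with isoform/paralog calls.

The predictor consumes two BLAST comparisons against a reference proteome:

* *forward* — proteome → transcriptome (translated, tblastn-style), top-N
  hits per protein; query coordinates are protein residues;
* *reverse* — transcriptome → proteome (blastx-style), best hit per
  transcript.

A transcript T is *confirmed* for protein P when P's forward list contains
T and T's reverse best hit is P. The first confirmed transcript per protein
is its putative ortholog. A later confirmed transcript that overlaps all
previously accepted transcripts by no more than ``max_nonoverlap_aa``
residues on P covers a distinct region of the protein and is also recorded
as an ortholog (a de novo assembly frequently splits one transcript into
non-overlapping products). Otherwise it is an *alternate isoform* when it
is a singleton or shares an isogroup (the assembler's gene proxy) with a
previously accepted transcript, and a *putative paralog* when it does
neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from transannot.blasttab import (
    HitTable,
    Hsp,
    best_hit,
    filter_significant,
    hit_sort_key,
    top_n,
)

__all__ = [
    "PredictorConfig",
    "OrthologyCall",
    "AnnotationTable",
    "reverse_best_index",
    "assign_orthology",
    "evaluate_against_known",
]


@dataclass(frozen=True)
class PredictorConfig:
    """Tunables of the reciprocal-best-hit predictor.

    ``e_cutoff`` — significance cutoff applied to both directions (1e-5);
    ``max_nonoverlap_aa`` — residues of protein-coordinate overlap still
    treated as "non-overlapping" when accepting a second ortholog (14);
    ``top_n_forward`` — forward hits retained per reference protein (50);
    ``merge_hsp_intervals`` — represent a multi-HSP candidate by the union
    envelope of its HSP intervals instead of the best HSP's interval.
    """

    e_cutoff: float = 1e-5
    max_nonoverlap_aa: int = 14
    top_n_forward: int = 50
    merge_hsp_intervals: bool = False

    def __post_init__(self) -> None:
        if self.e_cutoff <= 0:
            raise ValueError("e_cutoff must be positive")
        if self.max_nonoverlap_aa < 0:
            raise ValueError("max_nonoverlap_aa must be ≥ 0")
        if self.top_n_forward < 1:
            raise ValueError("top_n_forward must be ≥ 1")


@dataclass(frozen=True)
class OrthologyCall:
    transcript_id: str
    protein_id: str
    category: str  # {"ortholog", "isoform", "paralog"}
    protein_interval: tuple[int, int]  # 1-based inclusive residues
    evalue: float


@dataclass
class AnnotationTable:
    """Orthology calls with per-protein and per-transcript indices.

    A transcript maps to at most one protein; a protein gains multiple
    transcripts only via the distinct-region rule or isoform/paralog
    categories.
    """

    calls: list[OrthologyCall] = field(default_factory=list)

    def by_protein(self) -> dict[str, list[OrthologyCall]]:
        idx: dict[str, list[OrthologyCall]] = {}
        for c in self.calls:
            idx.setdefault(c.protein_id, []).append(c)
        return idx

    def by_transcript(self) -> dict[str, OrthologyCall]:
        idx: dict[str, OrthologyCall] = {}
        for c in self.calls:
            if c.transcript_id in idx:
                raise ValueError(
                    f"transcript {c.transcript_id} assigned twice"
                )
            idx[c.transcript_id] = c
        return idx

    def __len__(self) -> int:
        return len(self.calls)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "#transcript_id\tprotein_id\tcategory\tp_start\tp_end\tevalue\n"
            )
            for c in self.calls:
                fh.write(
                    f"{c.transcript_id}\t{c.protein_id}\t{c.category}\t"
                    f"{c.protein_interval[0]}\t{c.protein_interval[1]}\t"
                    f"{c.evalue:.2e}\n"
                )


def reverse_best_index(
    reverse_hits: HitTable, cfg: PredictorConfig = PredictorConfig()
) -> dict[str, str]:
    """Best significant proteome hit per transcript.

    Transcripts with no hit at or below ``cfg.e_cutoff`` are absent.
    """
    significant = filter_significant(reverse_hits, cfg.e_cutoff)
    return {
        t: best_hit(hits).subject_id
        for t, hits in significant.by_query().items()
    }


def _overlap_aa(a: tuple[int, int], b: tuple[int, int]) -> int:
    # 1-based inclusive residue intervals
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _candidate_interval(hsps: list[Hsp], cfg: PredictorConfig) -> tuple[int, int, float]:
    """Protein-coordinate interval and evalue representing a candidate.

    For a translated forward search the protein is the query, so the
    interval comes from the HSP's query coordinates.
    """
    best = min(hsps, key=hit_sort_key)
    if cfg.merge_hsp_intervals:
        lo = min(min(h.q_start, h.q_end) for h in hsps)
        hi = max(max(h.q_start, h.q_end) for h in hsps)
    else:
        lo, hi = sorted((best.q_start, best.q_end))
    return lo, hi, best.evalue


def assign_orthology(
    forward_hits: HitTable,
    reverse_index: Mapping[str, str],
    isogroup_map: Mapping[str, str],
    kinds: Mapping[str, str],
    cfg: PredictorConfig = PredictorConfig(),
) -> AnnotationTable:
    """Run the reciprocal-best-hit classifier over all reference proteins.

    Proteins are processed in lexicographic id order; within a protein,
    candidate transcripts in (evalue, −bitscore, subject id) order over the
    significance-filtered forward hits truncated to ``cfg.top_n_forward``.
    A transcript already assigned to another protein is skipped. The output
    is invariant to row permutations within each query group of the input.
    """
    significant = filter_significant(forward_hits, cfg.e_cutoff)
    groups = significant.by_query()

    for hits in groups.values():
        for h in hits:
            if h.subject_id not in kinds:
                raise ValueError(
                    f"forward hit subject {h.subject_id} has no declared kind"
                )

    table = AnnotationTable()
    assigned: set[str] = set()

    for protein_id in sorted(groups):
        candidates = top_n(groups[protein_id], cfg.top_n_forward)
        # group per transcript, visiting transcripts in best-HSP order
        per_transcript: dict[str, list[Hsp]] = {}
        order: list[str] = []
        for h in candidates:
            if h.subject_id not in per_transcript:
                order.append(h.subject_id)
            per_transcript.setdefault(h.subject_id, []).append(h)

        accepted: list[OrthologyCall] = []
        for transcript_id in order:
            if transcript_id in assigned:
                continue
            if reverse_index.get(transcript_id) != protein_id:
                continue  # not reciprocally confirmed; may win elsewhere
            lo, hi, evalue = _candidate_interval(
                per_transcript[transcript_id], cfg
            )
            interval = (lo, hi)
            if not accepted:
                category = "ortholog"
            else:
                max_overlap = max(
                    _overlap_aa(interval, c.protein_interval) for c in accepted
                )
                if max_overlap <= cfg.max_nonoverlap_aa:
                    category = "ortholog"
                elif kinds[transcript_id] == "singleton" or any(
                    isogroup_map.get(transcript_id) is not None
                    and isogroup_map.get(transcript_id)
                    == isogroup_map.get(c.transcript_id)
                    for c in accepted
                ):
                    category = "isoform"
                else:
                    category = "paralog"
            call = OrthologyCall(
                transcript_id=transcript_id,
                protein_id=protein_id,
                category=category,
                protein_interval=interval,
                evalue=evalue,
            )
            accepted.append(call)
            assigned.add(transcript_id)
            table.calls.append(call)

    return table


def evaluate_against_known(
    table: AnnotationTable, known_pairs: Mapping[str, str]
) -> dict[str, float]:
    """Recovery of a known transcript→protein truth set.

    A known pair counts as recovered when the table assigns the transcript
    to that protein under any category.
    """
    if not known_pairs:
        raise ValueError("known_pairs must be non-empty")
    by_transcript = table.by_transcript()
    n_recovered = sum(
        1
        for t, p in known_pairs.items()
        if t in by_transcript and by_transcript[t].protein_id == p
    )
    n_known = len(known_pairs)
    return {
        "n_known": n_known,
        "n_recovered": n_recovered,
        "fraction": n_recovered / n_known,
    }
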