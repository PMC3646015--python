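"""Category partitioning and composition analyses of assembly products.

Products are labeled along independent axes: similarity to a reference
protein database (nr-hit / no-hit); among the no-hit remainder, predicted
protein-coding status (hexanucleotide-model coding calls) and presence of
recognized protein domains; and clade-restricted similarity (hits found
exclusively in one of two related-taxon sequence collections, in both, or
in neither). Domain tallies collapse related accessions into families
("combined" groups such as zinc fingers and DUFs) and report top-k
proportions; proteome-representation counts how much of a reference
proteome has a putative ortholog in the assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from transannot.blasttab import HitTable, filter_significant

__all__ = [
    "CategoryPartition",
    "DomainTally",
    "ProteomeRepresentation",
    "partition_by_nr",
    "clade_partition",
    "coding_and_domain_overlay",
    "tally_domains",
    "proteome_representation",
    "load_family_map",
    "DEFAULT_FAMILY_RULES",
]

#: Prefix rules collapsing related Pfam-style names into combined families.
DEFAULT_FAMILY_RULES: tuple[tuple[str, str], ...] = (
    ("zf", "zinc finger (combined)"),
    ("DUF", "DUF (combined)"),
    ("Myb", "Myb_DNA-binding (combined)"),
    ("Glyco_hydro", "Glyco_hydro (combined)"),
    ("Ribosomal", "Ribosomal (combined)"),
    ("EFG", "EFG domains (combined)"),
    ("GTP_EFTU", "GTP_EFTU domains (combined)"),
)


@dataclass
class CategoryPartition:
    """Per-product label sets along the declared axes."""

    labels: dict[str, set[str]] = field(default_factory=dict)

    def with_label(self, label: str) -> set[str]:
        return {pid for pid, ls in self.labels.items() if label in ls}

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ls in self.labels.values():
            for label in ls:
                out[label] = out.get(label, 0) + 1
        return out

    def merge(self, other: "CategoryPartition") -> "CategoryPartition":
        merged = CategoryPartition(
            labels={pid: set(ls) for pid, ls in self.labels.items()}
        )
        for pid, ls in other.labels.items():
            merged.labels.setdefault(pid, set()).update(ls)
        return merged


@dataclass(frozen=True)
class DomainTally:
    """Family counts after collapsing and per-sequence deduplication."""

    counts: dict[str, int]
    family_map: dict[str, str]
    top: list[tuple[str, int, float]]  # (family, count, proportion of top-k)


@dataclass(frozen=True)
class ProteomeRepresentation:
    proteome_name: str
    n_proteins: int
    n_with_match: int

    @property
    def fraction(self) -> float:
        return self.n_with_match / self.n_proteins if self.n_proteins else 0.0


def partition_by_nr(
    product_ids: Iterable[str], nr_hits: HitTable, e_cutoff: float = 1e-5
) -> CategoryPartition:
    """Label each product ``nr_hit`` (≥1 significant HSP) or ``no_nr_hit``."""
    ids = set(product_ids)
    hit_queries = {
        h.query_id for h in filter_significant(nr_hits, e_cutoff)
    }
    unknown = hit_queries - ids
    if unknown:
        raise ValueError(
            f"hit table references ids outside the product set: "
            f"{sorted(unknown)[:5]}"
        )
    return CategoryPartition(
        labels={
            pid: {"nr_hit"} if pid in hit_queries else {"no_nr_hit"}
            for pid in ids
        }
    )


def clade_partition(
    no_hit_ids: Iterable[str],
    cladeA_hits: HitTable,
    cladeB_hits: HitTable,
    e_cutoff: float = 1e-5,
) -> CategoryPartition:
    """Partition nr-unidentified products by clade-restricted similarity.

    ``excl_cladeA`` — significant only in collection A; ``excl_cladeB`` —
    only in B; ``both_clades`` — in both; ``no_clade`` — in neither. The
    four classes partition the input exactly.
    """
    ids = set(no_hit_ids)
    in_a = {
        h.query_id for h in filter_significant(cladeA_hits, e_cutoff)
    } & ids
    in_b = {
        h.query_id for h in filter_significant(cladeB_hits, e_cutoff)
    } & ids
    labels: dict[str, set[str]] = {}
    for pid in ids:
        if pid in in_a and pid in in_b:
            labels[pid] = {"both_clades"}
        elif pid in in_a:
            labels[pid] = {"excl_cladeA"}
        elif pid in in_b:
            labels[pid] = {"excl_cladeB"}
        else:
            labels[pid] = {"no_clade"}
    return CategoryPartition(labels=labels)


def coding_and_domain_overlay(
    no_hit_ids: Iterable[str],
    coding_calls: Iterable[tuple],
    domain_table: Iterable[tuple],
    relax: bool = False,
) -> CategoryPartition:
    """Overlay coding / domain-bearing labels onto nr-unidentified products.

    ``coding_calls`` rows start with a product id (remaining columns — CDS
    coordinates and strand — are pass-through). ``domain_table`` rows start
    with a product id followed by a domain accession. A product is
    ``coding`` iff it has ≥1 coding call and ``domain_bearing`` iff it is
    coding and has ≥1 domain row; a domain row on a non-coding product
    violates the containment invariant and raises unless ``relax`` is set.
    """
    ids = set(no_hit_ids)
    coding_ids = {row[0] for row in coding_calls if row[0] in ids}
    domain_ids = {row[0] for row in domain_table if row[0] in ids}
    stray = domain_ids - coding_ids
    if stray and not relax:
        raise ValueError(
            f"domain rows on products without coding calls: "
            f"{sorted(stray)[:5]} (use relax=True to keep them non-coding)"
        )
    labels: dict[str, set[str]] = {pid: set() for pid in ids}
    for pid in coding_ids:
        labels[pid].add("coding")
        if pid in domain_ids:
            labels[pid].add("domain_bearing")
    return CategoryPartition(labels=labels)


def load_family_map(path: str | Path) -> dict[str, str]:
    """Load an accession→family TSV (two columns, '#' comments skipped)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            accession, family = line.split("\t")[:2]
            mapping[accession] = family
    return mapping


def _family_of(
    accession: str,
    family_map: Mapping[str, str] | None,
    prefix_rules: Sequence[tuple[str, str]],
) -> str:
    if family_map and accession in family_map:
        return family_map[accession]
    for prefix, family in prefix_rules:
        if accession.startswith(prefix):
            return family
    return accession


def tally_domains(
    domain_table: Iterable[tuple],
    family_map: Mapping[str, str] | None = None,
    sequence_subset: Iterable[str] | None = None,
    top_k: int = 25,
    per_sequence: bool = True,
    prefix_rules: Sequence[tuple[str, str]] = DEFAULT_FAMILY_RULES,
) -> DomainTally:
    """Tally domain families over a sequence subset.

    Rows are (sequence id, accession, ...); unmapped accessions pass
    through as their own family. With ``per_sequence`` (default) a sequence
    contributes at most once per family regardless of how many of its
    accessions collapse into it; ``per_sequence=False`` counts occurrences
    (still deduplicating exact duplicate rows). Proportions are over the
    top-k families' total, ranked descending with lexicographic tie-break.
    """
    subset = set(sequence_subset) if sequence_subset is not None else None
    resolved: dict[str, str] = {}
    incidences: set[tuple[str, str]] = set()
    for row in domain_table:
        seq_id, accession = row[0], row[1]
        if subset is not None and seq_id not in subset:
            continue
        family = _family_of(accession, family_map, prefix_rules)
        resolved[accession] = family
        key = family if per_sequence else f"{family}\x00{accession}"
        incidences.add((seq_id, key))

    counts: dict[str, int] = {}
    for _seq, key in incidences:
        family = key.split("\x00")[0]
        counts[family] = counts.get(family, 0) + 1

    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    top_total = sum(c for _f, c in ranked)
    top = [
        (fam, c, c / top_total if top_total else 0.0) for fam, c in ranked
    ]
    return DomainTally(counts=counts, family_map=resolved, top=top)


def proteome_representation(
    proteome_ids: Iterable[str],
    proteome_vs_assembly_hits: HitTable,
    e_cutoff: float = 1e-5,
    direction: str = "assembly_query",
    proteome_name: str = "proteome",
) -> ProteomeRepresentation:
    """Fraction of a reference proteome with a match in the assembly.

    ``direction`` declares which side of the hit table holds proteome ids:
    ``assembly_query`` (blastx of products against the proteome; proteome
    ids are subjects) or ``proteome_query`` (proteome ids are queries).
    """
    ids = set(proteome_ids)
    significant = filter_significant(proteome_vs_assembly_hits, e_cutoff)
    if direction == "assembly_query":
        matched = significant.subject_ids() & ids
    elif direction == "proteome_query":
        matched = set(significant.by_query()) & ids
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return ProteomeRepresentation(
        proteome_name=proteome_name,
        n_proteins=len(ids),
        n_with_match=len(matched),
    )
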