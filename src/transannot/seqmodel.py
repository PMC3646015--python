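"""Core data model for assembly products, FASTA I/O and basic metrics.

An :class:`AssemblyProduct` is the universal unit flowing through every
downstream stage: a single isotig, singleton or contig with its nucleotide
sequence and (for isotigs) its isogroup linkage. Module-level functions
provide N50, length summaries and per-contig read-depth statistics.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AssemblyProduct",
    "AssemblyCollection",
    "LengthSummary",
    "CoverageStats",
    "read_fasta",
    "write_fasta",
    "load_isogroup_map",
    "n50",
    "length_summary",
    "coverage_stats",
]

# IUPAC nucleotide codes; 454 assemblies contain ambiguity calls beyond ACGTN.
_IUPAC_NT = set("ACGTNRYSWKMBDHV")

#: Default header rule: Newbler names isotigs "isotig#####"; everything else
#: in an assembly FASTA is treated as a singleton read.
DEFAULT_KIND_PATTERNS: tuple[tuple[str, str], ...] = (
    (r"^isotig", "isotig"),
    (r"^contig", "contig"),
)


@dataclass
class AssemblyProduct:
    """One isotig, singleton or contig.

    ``length`` always equals ``len(sequence)``; Ns and other ambiguity codes
    count toward length. Isotigs must carry an ``isogroup_id``; singletons
    must not.
    """

    id: str
    kind: str  # {"isotig", "singleton", "contig"}
    sequence: str
    isogroup_id: str | None = None
    contig_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"product {self.id!r}: empty sequence")
        if self.kind not in ("isotig", "singleton", "contig"):
            raise ValueError(f"product {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "singleton" and self.isogroup_id is not None:
            raise ValueError(f"singleton {self.id!r} must not have an isogroup")
        for pos, base in enumerate(self.sequence):
            if base not in _IUPAC_NT:
                raise ValueError(
                    f"product {self.id!r}: non-IUPAC character {base!r} "
                    f"at position {pos + 1}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyCollection:
    """A keyed set of assembly products plus the isogroup index.

    Every isotig's ``isogroup_id`` appears in ``isogroups`` and vice versa;
    membership lists carry no duplicates.
    """

    products: dict[str, AssemblyProduct] = field(default_factory=dict)
    isogroups: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_products(
        cls, products: Iterable[AssemblyProduct]
    ) -> "AssemblyCollection":
        coll = cls()
        for p in products:
            coll.add(p)
        return coll

    def add(self, product: AssemblyProduct) -> None:
        if product.id in self.products:
            raise ValueError(f"duplicate id {product.id}")
        self.products[product.id] = product
        if product.isogroup_id is not None:
            members = self.isogroups.setdefault(product.isogroup_id, [])
            if product.id in members:
                raise ValueError(
                    f"duplicate isogroup membership for {product.id}"
                )
            members.append(product.id)

    def apply_isogroup_map(self, mapping: Mapping[str, str]) -> None:
        """Attach isogroup ids from an isotig→isogroup mapping."""
        for isotig_id, group in mapping.items():
            if isotig_id not in self.products:
                continue
            p = self.products[isotig_id]
            if p.isogroup_id == group:
                continue
            if p.isogroup_id is not None:
                self.isogroups[p.isogroup_id].remove(isotig_id)
                if not self.isogroups[p.isogroup_id]:
                    del self.isogroups[p.isogroup_id]
            p.isogroup_id = group
            self.isogroups.setdefault(group, []).append(isotig_id)

    def lengths(self, kind: str | None = None) -> list[int]:
        return [
            p.length
            for p in self.products.values()
            if kind is None or p.kind == kind
        ]

    def kinds(self) -> dict[str, str]:
        return {pid: p.kind for pid, p in self.products.items()}

    def validate(self) -> None:
        for gid, members in self.isogroups.items():
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate membership in isogroup {gid}")
            for m in members:
                if self.products[m].isogroup_id != gid:
                    raise ValueError(f"isogroup index out of sync for {m}")
        for p in self.products.values():
            if p.kind == "isotig" and p.isogroup_id is None:
                raise ValueError(f"isotig {p.id} lacks an isogroup")


@dataclass(frozen=True)
class LengthSummary:
    """min / max / median / mean of a length sample.

    The median of an even-sized sample is the midpoint of the two central
    values, hence may be half-integral (e.g. 1,054.5 bp).
    """

    n: int
    min: int
    max: int
    median: float
    mean: float


@dataclass(frozen=True)
class CoverageStats:
    """Assembly-wide and per-contig read depth.

    ``avg_coverage_per_bp`` is total aligned read bp over total assembly bp
    (the length-weighted mean of per-contig depths).
    """

    avg_coverage_per_bp: float
    contig_depths: dict[str, float]
    n_low: int
    n_high: int
    low_threshold: float
    high_threshold: float


def infer_kind(
    header_id: str,
    patterns: Sequence[tuple[str, str]] = DEFAULT_KIND_PATTERNS,
) -> str:
    """Classify a FASTA id as isotig/contig/singleton by header regex."""
    for pattern, kind in patterns:
        if re.search(pattern, header_id):
            return kind
    return "singleton"


def read_fasta(
    path: str | Path,
    kind_patterns: Sequence[tuple[str, str]] = DEFAULT_KIND_PATTERNS,
    isogroup_map: Mapping[str, str] | None = None,
) -> list[AssemblyProduct]:
    """Read assembly products from a FASTA file.

    Kinds are inferred from the header id via ``kind_patterns`` (first match
    wins, default: ids beginning ``isotig``/``contig``, everything else a
    singleton). Sequences are uppercased. Isotigs receive their isogroup id
    from ``isogroup_map`` when given.

    Raises ``ValueError`` on duplicate ids, an empty file, or non-IUPAC
    characters.
    """
    path = Path(path)
    seen: set[str] = set()
    products: list[AssemblyProduct] = []
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate id {record.id}")
        seen.add(record.id)
        kind = infer_kind(record.id, kind_patterns)
        isogroup = None
        if kind == "isotig" and isogroup_map is not None:
            isogroup = isogroup_map.get(record.id)
        products.append(
            AssemblyProduct(
                id=record.id,
                kind=kind,
                sequence=str(record.seq),
                isogroup_id=isogroup,
            )
        )
    if not products:
        raise ValueError(f"empty FASTA file: {path}")
    return products


def write_fasta(
    products: Iterable[AssemblyProduct], path: str | Path, width: int = 60
) -> None:
    """Write products as multi-record FASTA, 60-column wrapped."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in products
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def load_isogroup_map(path: str | Path) -> dict[str, str]:
    """Load a two-column isotig→isogroup TSV (header line optional).

    Raises ``ValueError`` if an isotig is mapped to two different groups.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            isotig_id, group = fields
            if lineno == 1 and isotig_id.lower() in ("isotig", "isotig_id", "id"):
                continue
            if isotig_id in mapping and mapping[isotig_id] != group:
                raise ValueError(
                    f"isotig {isotig_id} mapped to two groups: "
                    f"{mapping[isotig_id]} and {group}"
                )
            mapping[isotig_id] = group
    return mapping


def group_index(mapping: Mapping[str, str]) -> dict[str, list[str]]:
    """Invert an isotig→isogroup mapping to isogroup→member list."""
    index: dict[str, list[str]] = {}
    for isotig_id, group in mapping.items():
        index.setdefault(group, []).append(isotig_id)
    return index


def n50(lengths: Sequence[int]) -> int:
    """Standard N50: the largest length L such that sequences of length ≥ L
    cover at least half of the total assembled bases.

    Computed by sorting descending and accumulating; the first length at
    which the cumulative sum reaches half the total is returned. Order
    invariant.
    """
    if not lengths:
        raise ValueError("n50 of an empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    cumulative = 0
    for length in sorted(lengths, reverse=True):
        cumulative += length
        if 2 * cumulative >= total:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def length_summary(lengths: Sequence[int]) -> LengthSummary:
    """min/max/median/mean of a non-empty length sample.

    Median of even n is the midpoint of the two central values
    (``statistics.median``), so half-integral medians are possible.
    """
    if not lengths:
        raise ValueError("length_summary of an empty sample")
    return LengthSummary(
        n=len(lengths),
        min=min(lengths),
        max=max(lengths),
        median=float(statistics.median(lengths)),
        mean=sum(lengths) / len(lengths),
    )


def coverage_stats(
    aligned_bp_per_contig: Mapping[str, float],
    contig_lengths: Mapping[str, int],
    low_threshold: float = 10.0,
    high_threshold: float = 10_000.0,
) -> CoverageStats:
    """Per-contig read depth and the assembly-wide average coverage.

    Depth of a contig is total aligned read bp divided by contig length; the
    assembly average is total aligned bp over total assembly length. Also
    counts contigs at or below ``low_threshold`` and at or above
    ``high_threshold`` depth.
    """
    if set(aligned_bp_per_contig) != set(contig_lengths):
        raise ValueError("aligned_bp and contig_lengths key sets differ")
    depths: dict[str, float] = {}
    for cid, bp in aligned_bp_per_contig.items():
        clen = contig_lengths[cid]
        if clen <= 0:
            raise ValueError(f"zero-length contig {cid}")
        depths[cid] = bp / clen
    total_bp = sum(aligned_bp_per_contig.values())
    total_len = sum(contig_lengths.values())
    return CoverageStats(
        avg_coverage_per_bp=total_bp / total_len,
        contig_depths=depths,
        n_low=sum(1 for d in depths.values() if d <= low_threshold),
        n_high=sum(1 for d in depths.values() if d >= high_threshold),
        low_threshold=low_threshold,
        high_threshold=high_threshold,
    )
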