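"""Synthetic ground truth for offline testing of every pipeline stage.

The generator plants a reference proteome, a transcriptome with isogroup
structure (splice-isoform pairs share an isogroup, paralogs do not,
region-split products cover disjoint protein intervals), full-span
duplicate products at above-threshold identity together with near-miss
containments below it, clade-restricted similarity, and domain content.
``emulate_hits`` then writes the BLAST tabular rows these relationships
imply: in noise-free mode the tables encode the truth exactly (planted
best hits rank first by E-value); ``drop_rate`` removes true rows and
``decoy_rate`` injects non-reciprocal rows that are strictly worse than
any true row for the same query, so decoys can never displace a true best
hit.

Homology is *declared* by the truth tables, not rediscovered by alignment:
sequences are uniform random nucleotides with planted substrings, which is
sufficient because every consumer reads hit tables, not alignments. The
planted duplicates are real substrings with substitutions, so an
independent alignment-based oracle can verify the redundancy filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from transannot.blasttab import HitTable, Hsp, write_blast_tabular
from transannot.seqmodel import AssemblyProduct, write_fasta

__all__ = ["TranscriptTruth", "TruthSet", "generate_truth", "emulate_hits", "write_bundle"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TranscriptTruth:
    id: str
    source_protein: str
    length_nt: int
    isogroup: str | None
    kind: str  # isotig | singleton
    protein_interval: tuple[int, int]  # 1-based inclusive aa
    category: str  # ortholog | isoform | paralog
    rank: int  # planted acceptance order within the gene (0 = first)


@dataclass
class TruthSet:
    """Everything the generator planted, keyed for direct assertion."""

    proteins: dict[str, int] = field(default_factory=dict)  # aa length
    cdna_lengths: dict[str, int] = field(default_factory=dict)  # nt, per protein
    transcripts: dict[str, TranscriptTruth] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)
    isogroup_map: dict[str, str] = field(default_factory=dict)
    duplicates: list[tuple[str, str, float]] = field(default_factory=list)
    near_misses: list[tuple[str, str, float]] = field(default_factory=list)
    clade_membership: dict[str, set[str]] = field(default_factory=dict)
    domain_truth: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    @property
    def ortholog_pairs(self) -> dict[str, tuple[str, str]]:
        """transcript id → (protein id, planted category)."""
        return {
            t.id: (t.source_protein, t.category)
            for t in self.transcripts.values()
        }

    def kinds(self) -> dict[str, str]:
        kinds = {t.id: t.kind for t in self.transcripts.values()}
        for contained, _container, _ident in self.duplicates + self.near_misses:
            kinds[contained] = "singleton"
        return kinds

    def product_lengths(self) -> dict[str, int]:
        return {pid: len(seq) for pid, seq in self.sequences.items()}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Apply exactly n_sub substitutions at distinct positions."""
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def generate_truth(
    n_genes: int,
    isoform_rate: float = 0.08,
    paralog_rate: float = 0.06,
    dup_rate: float = 0.05,
    region_split_rate: float = 0.04,
    clade_rate: float = 0.10,
    seed: int = 0,
) -> TruthSet:
    """Plant a truth set of ``n_genes`` reference proteins.

    Each gene yields one base transcript (its own isogroup, planted
    category ``ortholog``). Per-gene, at most one extra event fires:
    an *isoform* (same isogroup, or a singleton — both legal isoform
    evidence — overlapping the base by ≥15 aa on the protein), a *paralog*
    (distinct isogroup, ≥15 aa overlap), or a *region split* (a second
    ortholog on a disjoint interval, ≤14 aa overlap — both boundary values
    occur). ``dup_rate`` plants full-span duplicates at 96–100 % identity
    and an equal number of near-miss containments at 90–94 %, bracketing
    the >95 % redundancy threshold. Deterministic for a fixed seed; rates
    must sum below 1.

    Raises ``ValueError`` on invalid rates or ``n_genes < 1``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be ≥ 1")
    rates = (isoform_rate, paralog_rate, dup_rate, region_split_rate)
    if any(not 0 <= r < 1 for r in rates):
        raise ValueError("rates must lie in [0, 1)")
    if isoform_rate + paralog_rate + region_split_rate + dup_rate >= 1:
        raise ValueError("rates must sum to less than 1")

    rng = np.random.default_rng(seed)
    truth = TruthSet(seed=seed)
    counter = 0
    singleton_counter = 0
    domain_pool = (
        "PF00096", "PF00097", "DUF1090", "DUF2340", "PF00240",
        "PF00076", "PF00069", "PF00023",
    )

    def new_isotig() -> str:
        nonlocal counter
        counter += 1
        return f"isotig{counter:05d}"

    def new_singleton() -> str:
        nonlocal singleton_counter
        singleton_counter += 1
        return f"GBS{singleton_counter:05d}"

    def add_transcript(
        protein: str,
        interval: tuple[int, int],
        isogroup: str | None,
        kind: str,
        category: str,
        rank: int,
    ) -> TranscriptTruth:
        tid = new_isotig() if kind == "isotig" else new_singleton()
        nt_len = 3 * (interval[1] - interval[0] + 1)
        t = TranscriptTruth(
            id=tid,
            source_protein=protein,
            length_nt=nt_len,
            isogroup=isogroup,
            kind=kind,
            protein_interval=interval,
            category=category,
            rank=rank,
        )
        truth.transcripts[tid] = t
        truth.sequences[tid] = _random_seq(rng, nt_len)
        if isogroup is not None:
            truth.isogroup_map[tid] = isogroup
        return t

    isoform_singleton_toggle = False
    for g in range(n_genes):
        protein = f"prot{g:05d}"
        aa_len = int(rng.integers(150, 600))
        truth.proteins[protein] = aa_len
        truth.cdna_lengths[protein] = 3 * aa_len + int(rng.integers(100, 500))
        base_group = f"isogroup{g:05d}"

        u = rng.random()
        if u < isoform_rate + paralog_rate + region_split_rate:
            # extra transcript events need room on the protein
            aa_len = max(aa_len, 120)
            truth.proteins[protein] = max(truth.proteins[protein], aa_len)

        if u < isoform_rate:
            base = add_transcript(
                protein, (1, aa_len), base_group, "isotig", "ortholog", 0
            )
            # overlap ≥ 15 aa forces the isoform/paralog branch; alternate
            # between the same-isogroup and the singleton form of evidence
            overlap = int(rng.integers(15, max(16, aa_len // 2)))
            start = aa_len - overlap + 1
            end = min(aa_len, start + int(rng.integers(overlap, aa_len)))
            isoform_singleton_toggle = not isoform_singleton_toggle
            if isoform_singleton_toggle:
                add_transcript(
                    protein, (start, end), base_group, "isotig", "isoform", 1
                )
            else:
                add_transcript(
                    protein, (start, end), None, "singleton", "isoform", 1
                )
        elif u < isoform_rate + paralog_rate:
            base = add_transcript(
                protein, (1, aa_len), base_group, "isotig", "ortholog", 0
            )
            overlap = int(rng.integers(15, max(16, aa_len // 2)))
            start = aa_len - overlap + 1
            end = min(aa_len, start + int(rng.integers(overlap, aa_len)))
            add_transcript(
                protein,
                (start, end),
                f"isogroup{g:05d}p",
                "isotig",
                "paralog",
                1,
            )
        elif u < isoform_rate + paralog_rate + region_split_rate:
            # two orthologs on regions overlapping by at most 14 aa;
            # draw the overlap from [0, 14] so the boundary value occurs
            overlap = int(rng.integers(0, 15))
            split = aa_len // 2
            base = add_transcript(
                protein, (1, split), base_group, "isotig", "ortholog", 0
            )
            add_transcript(
                protein,
                (split - overlap + 1, aa_len),
                f"isogroup{g:05d}r",
                "isotig",
                "ortholog",
                1,
            )
        else:
            # plain 1:1 ortholog covering part or all of the protein
            start = 1
            end = int(rng.integers(max(2, aa_len // 3), aa_len + 1))
            base = add_transcript(
                protein, (start, end), base_group, "isotig", "ortholog", 0
            )

        if rng.random() < dup_rate:
            # full-span duplicate above the >95 % identity threshold …
            container = truth.transcripts[
                sorted(
                    t for t in truth.transcripts
                    if truth.transcripts[t].source_protein == protein
                )[0]
            ]
            seq = truth.sequences[container.id]
            # strictly shorter than the container, so the longer-retainer
            # rule applies without the equal-length lexicographic tie
            dlen = min(len(seq) - 1, max(30, int(rng.integers(len(seq) // 2, len(seq)))))
            offset = int(rng.integers(0, len(seq) - dlen + 1))
            identity = float(rng.integers(96, 101))
            n_sub = int(round(dlen * (100 - identity) / 100))
            identity = 100.0 * (dlen - n_sub) / dlen
            did = new_singleton()
            truth.sequences[did] = _mutate(
                rng, seq[offset : offset + dlen], n_sub
            )
            truth.duplicates.append((did, container.id, identity))
            # … and a near-miss at 90–94 %, below the threshold
            identity2 = float(rng.integers(90, 95))
            n_sub2 = int(round(dlen * (100 - identity2) / 100))
            identity2 = 100.0 * (dlen - n_sub2) / dlen
            nid = new_singleton()
            truth.sequences[nid] = _mutate(
                rng, seq[offset : offset + dlen], n_sub2
            )
            truth.near_misses.append((nid, container.id, identity2))

        if rng.random() < clade_rate:
            which = rng.random()
            membership = (
                {"A"} if which < 0.5 else ({"B"} if which < 0.8 else {"A", "B"})
            )
            truth.clade_membership[base.id] = membership

        if rng.random() < 0.3:
            k = int(rng.integers(1, 4))
            truth.domain_truth[base.id] = [
                domain_pool[int(i)]
                for i in rng.choice(len(domain_pool), size=k, replace=False)
            ]

    return truth


def _true_forward_rows(truth: TruthSet) -> list[Hsp]:
    rows: list[Hsp] = []
    for t in truth.transcripts.values():
        lo, hi = t.protein_interval
        # planted acceptance order is encoded in the E-value ranking
        evalue = 10.0 ** (-60 + 10 * t.rank)
        rows.append(
            Hsp(
                query_id=t.source_protein,
                subject_id=t.id,
                pct_identity=88.0,
                aln_len=hi - lo + 1,
                mismatches=int(0.12 * (hi - lo + 1)),
                gap_opens=0,
                q_start=lo,
                q_end=hi,
                s_start=1,
                s_end=t.length_nt,
                evalue=evalue,
                bitscore=400.0 - 50.0 * t.rank,
            )
        )
    return rows


def _true_reverse_rows(truth: TruthSet) -> list[Hsp]:
    rows: list[Hsp] = []
    for t in truth.transcripts.values():
        lo, hi = t.protein_interval
        rows.append(
            Hsp(
                query_id=t.id,
                subject_id=t.source_protein,
                pct_identity=88.0,
                aln_len=hi - lo + 1,
                mismatches=int(0.12 * (hi - lo + 1)),
                gap_opens=0,
                q_start=1,
                q_end=t.length_nt,
                s_start=lo,
                s_end=hi,
                evalue=1e-60,
                bitscore=400.0,
            )
        )
    return rows


def _true_self_rows(truth: TruthSet) -> list[Hsp]:
    rows: list[Hsp] = []
    for contained, container, identity in truth.duplicates + truth.near_misses:
        q_len = len(truth.sequences[contained])
        rows.append(
            Hsp(
                query_id=contained,
                subject_id=container,
                pct_identity=round(identity, 2),
                aln_len=q_len,
                mismatches=int(round(q_len * (100 - identity) / 100)),
                gap_opens=0,
                q_start=1,
                q_end=q_len,
                s_start=1,
                s_end=q_len,
                evalue=1e-80,
                bitscore=2.0 * q_len,
            )
        )
    return rows


def _true_clade_rows(truth: TruthSet, clade: str) -> list[Hsp]:
    rows: list[Hsp] = []
    prefix = "LK" if clade == "A" else "LM"
    for tid, membership in sorted(truth.clade_membership.items()):
        if clade not in membership:
            continue
        t = truth.transcripts[tid]
        rows.append(
            Hsp(
                query_id=tid,
                subject_id=f"{prefix}_{tid}",
                pct_identity=82.0,
                aln_len=max(30, t.length_nt // 3),
                mismatches=10,
                gap_opens=0,
                q_start=1,
                q_end=max(30, t.length_nt // 3),
                s_start=1,
                s_end=max(30, t.length_nt // 3),
                evalue=1e-20,
                bitscore=120.0,
            )
        )
    return rows


def emulate_hits(
    truth: TruthSet,
    direction: str,
    drop_rate: float = 0.0,
    decoy_rate: float = 0.0,
    seed: int | None = None,
) -> HitTable:
    """Emit the hit table implied by the truth, with optional noise.

    Directions: ``forward`` (proteome→transcriptome, protein residues in
    query coordinates), ``reverse`` (transcriptome→proteome), ``self``
    (all-vs-all nucleotide containments), ``cladeA`` / ``cladeB``.
    ``drop_rate`` deletes each true row independently; ``decoy_rate`` adds,
    per surviving true row, a decoy row with probability given, pointing at
    a wrong partner with an E-value strictly worse than any true row.
    """
    builders = {
        "forward": _true_forward_rows,
        "reverse": _true_reverse_rows,
        "self": _true_self_rows,
        "cladeA": lambda t: _true_clade_rows(t, "A"),
        "cladeB": lambda t: _true_clade_rows(t, "B"),
    }
    if direction not in builders:
        raise ValueError(f"unknown direction {direction!r}")
    rows = builders[direction](truth)
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    if drop_rate > 0:
        rows = [h for h in rows if rng.random() >= drop_rate]
    if decoy_rate > 0 and direction in ("forward", "reverse"):
        proteins = sorted(truth.proteins)
        transcripts = sorted(truth.transcripts)
        decoys: list[Hsp] = []
        for h in rows:
            if rng.random() >= decoy_rate:
                continue
            if direction == "forward":
                wrong = transcripts[int(rng.integers(0, len(transcripts)))]
                if wrong == h.subject_id:
                    continue
                decoys.append(
                    Hsp(
                        h.query_id, wrong, 40.0, 60, 30, 2,
                        1, 60, 1, 180, 1e-6, 45.0,
                    )
                )
            else:
                wrong = proteins[int(rng.integers(0, len(proteins)))]
                if wrong == h.subject_id:
                    continue
                decoys.append(
                    Hsp(
                        h.query_id, wrong, 40.0, 60, 30, 2,
                        1, 180, 1, 60, 1e-6, 45.0,
                    )
                )
        rows = rows + decoys
    program = {
        "forward": "tblastn",
        "reverse": "blastx",
        "self": "blastn",
        "cladeA": "tblastx",
        "cladeB": "tblastx",
    }[direction]
    return HitTable(hsps=rows, program=program)


def truth_products(truth: TruthSet) -> list[AssemblyProduct]:
    kinds = truth.kinds()
    products = []
    for pid in sorted(truth.sequences):
        products.append(
            AssemblyProduct(
                id=pid,
                kind=kinds[pid],
                sequence=truth.sequences[pid],
                isogroup_id=truth.isogroup_map.get(pid),
            )
        )
    return products


def write_bundle(truth: TruthSet, outdir: str | Path) -> dict[str, Path]:
    """Write the FASTA/TSV bundle the pipeline consumes.

    Emits the assembly FASTA, the isotig→isogroup TSV, all four emulated
    hit tables (noise-free), reference cDNA lengths and the planted-truth
    pair table. Returns the path of each artifact by name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["assembly"] = outdir / "assembly.fasta"
    write_fasta(truth_products(truth), paths["assembly"])

    paths["isogroups"] = outdir / "isogroups.tsv"
    with open(paths["isogroups"], "w") as fh:
        for tid in sorted(truth.isogroup_map):
            fh.write(f"{tid}\t{truth.isogroup_map[tid]}\n")

    for name in ("forward", "reverse", "self", "cladeA", "cladeB"):
        paths[name] = outdir / f"{name}.tsv"
        write_blast_tabular(emulate_hits(truth, name), paths[name])

    paths["cdna_lengths"] = outdir / "cdna_lengths.tsv"
    with open(paths["cdna_lengths"], "w") as fh:
        for pid in sorted(truth.cdna_lengths):
            fh.write(f"{pid}\t{truth.cdna_lengths[pid]}\n")

    paths["truth_pairs"] = outdir / "truth_pairs.tsv"
    with open(paths["truth_pairs"], "w") as fh:
        fh.write("#transcript_id\tprotein_id\tcategory\n")
        for tid in sorted(truth.transcripts):
            t = truth.transcripts[tid]
            fh.write(f"{tid}\t{t.source_protein}\t{t.category}\n")

    return paths
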