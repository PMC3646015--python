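import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transannot import seqmodel
from transannot.seqmodel import (
    AssemblyCollection,
    AssemblyProduct,
    coverage_stats,
    length_summary,
    load_isogroup_map,
    n50,
    read_fasta,
    write_fasta,
)


def _write(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


class TestReadFasta:
    def test_kind_inference_and_lengths(self, tmp_path):
        path = tmp_path / "a.fa"
        _write(path, [("isotig00001", "A" * 600), ("GXYZ123", "C" * 250)])
        products = read_fasta(path)
        assert {p.kind for p in products} == {"isotig", "singleton"}
        assert {p.length for p in products} == {600, 250}

    def test_duplicate_header_is_an_error(self, tmp_path):
        path = tmp_path / "dup.fa"
        _write(path, [("s1", "ACGT"), ("s1", "ACGT")])
        with pytest.raises(ValueError, match="duplicate id s1"):
            read_fasta(path)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.fa"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_fasta(path)

    def test_non_iupac_character_reports_position(self, tmp_path):
        path = tmp_path / "bad.fa"
        _write(path, [("s1", "ACXGT")])
        with pytest.raises(ValueError, match="position 3"):
            read_fasta(path)

    def test_sequences_uppercased(self, tmp_path):
        path = tmp_path / "lc.fa"
        _write(path, [("s1", "acgtn")])
        assert read_fasta(path)[0].sequence == "ACGTN"

    def test_roundtrip_is_byte_identical(self, tmp_path):
        rng = random.Random(7)
        products = [
            AssemblyProduct(
                id=f"isotig{i:05d}" if i % 2 else f"GB{i:05d}",
                kind="isotig" if i % 2 else "singleton",
                sequence="".join(
                    rng.choice("ACGTN") for _ in range(rng.randint(1, 400))
                ),
                isogroup_id=f"g{i}" if i % 2 else None,
            )
            for i in range(100)
        ]
        p1 = tmp_path / "one.fa"
        p2 = tmp_path / "two.fa"
        write_fasta(products, p1)
        reread = read_fasta(p1)
        assert [(p.id, p.sequence) for p in reread] == [
            (p.id, p.sequence) for p in products
        ]
        write_fasta(reread, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestIsogroupMap:
    def test_basic_grouping(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("isotig1\tg1\nisotig2\tg1\nisotig3\tg2\n")
        mapping = load_isogroup_map(path)
        groups = seqmodel.group_index(mapping)
        assert len(groups) == 2
        assert sorted(groups["g1"]) == ["isotig1", "isotig2"]

    def test_conflicting_assignment_is_an_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("isotig1\tg1\nisotig1\tg2\n")
        with pytest.raises(ValueError, match="two groups"):
            load_isogroup_map(path)

    def test_synthetic_roundtrip(self, tmp_path):
        rng = random.Random(3)
        truth = {
            f"isotig{i:05d}": f"g{rng.randrange(400):04d}" for i in range(1000)
        }
        path = tmp_path / "many.tsv"
        path.write_text(
            "".join(f"{k}\t{v}\n" for k, v in truth.items())
        )
        assert load_isogroup_map(path) == truth

    def test_member_counts_sum_to_isotig_count(self):
        rng = random.Random(5)
        mapping = {f"i{i}": f"g{rng.randrange(50)}" for i in range(300)}
        groups = seqmodel.group_index(mapping)
        assert sum(len(m) for m in groups.values()) == 300


class TestN50:
    def test_single_sequence(self):
        assert n50([500]) == 500

    def test_hand_accumulation(self):
        # total 20; descending cumulative 6, 11 ≥ 10 at length 5
        assert n50([2, 3, 4, 5, 6]) == 5

    def test_order_invariance(self):
        lengths = [100, 20, 340, 5, 5, 77]
        assert n50(lengths) == n50(sorted(lengths)) == n50(lengths[::-1])

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            n50([])

    def test_against_brute_force_definition(self):
        # N50 = largest L with sum(lengths ≥ L) ≥ total/2, scanned directly
        rng = random.Random(11)
        for _ in range(1000):
            lengths = [rng.randint(1, 500) for _ in range(rng.randint(1, 40))]
            total = sum(lengths)
            oracle = max(
                L
                for L in lengths
                if sum(x for x in lengths if x >= L) * 2 >= total
            )
            assert n50(lengths) == oracle


class TestLengthSummary:
    def test_single_value(self):
        s = length_summary([100])
        assert (s.min, s.max, s.median, s.mean) == (100, 100, 100, 100)

    def test_even_n_midpoint_median(self):
        assert length_summary([100, 200]).median == 150.0

    def test_against_sort_and_index_oracle(self):
        rng = random.Random(13)
        lengths = [rng.randint(1, 100_000) for _ in range(10_001)]
        s = length_summary(lengths)
        srt = sorted(lengths)
        assert s.min == srt[0] and s.max == srt[-1]
        assert s.median == srt[len(srt) // 2]  # odd n
        assert s.mean == pytest.approx(sum(srt) / len(srt))

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_min_le_median_le_max(self, lengths):
        s = length_summary(lengths)
        assert s.min <= s.median <= s.max


class TestCoverageStats:
    def test_single_contig(self):
        c = coverage_stats({"c1": 1000.0}, {"c1": 100})
        assert c.contig_depths["c1"] == 10.0
        assert c.avg_coverage_per_bp == 10.0

    def test_hand_arithmetic_two_contigs(self):
        c = coverage_stats({"a": 300.0, "b": 100.0}, {"a": 100, "b": 100})
        assert c.avg_coverage_per_bp == 2.0
        assert sorted(c.contig_depths.values()) == [1.0, 3.0]

    def test_scaling_linearity(self):
        aligned = {"a": 300.0, "b": 100.0}
        lengths = {"a": 120, "b": 80}
        base = coverage_stats(aligned, lengths).avg_coverage_per_bp
        scaled = coverage_stats(
            {k: 7 * v for k, v in aligned.items()}, lengths
        ).avg_coverage_per_bp
        assert scaled == pytest.approx(7 * base)

    def test_avg_is_length_weighted_mean_of_depths(self):
        rng = np.random.default_rng(2)
        lengths = {f"c{i}": int(rng.integers(50, 5000)) for i in range(200)}
        aligned = {k: float(rng.integers(0, 10**6)) for k in lengths}
        c = coverage_stats(aligned, lengths)
        weighted = sum(
            c.contig_depths[k] * lengths[k] for k in lengths
        ) / sum(lengths.values())
        assert c.avg_coverage_per_bp == pytest.approx(weighted, rel=1e-9)

    def test_depth_threshold_counts(self):
        c = coverage_stats(
            {"lo": 100.0, "mid": 5_000.0, "hi": 10**7},
            {"lo": 100, "mid": 100, "hi": 100},
        )
        assert c.n_low == 1 and c.n_high == 1

    def test_zero_length_contig_is_an_error(self):
        with pytest.raises(ValueError, match="zero-length"):
            coverage_stats({"c": 10.0}, {"c": 0})


class TestAssemblyCollection:
    def test_isotig_requires_isogroup_on_validate(self):
        coll = AssemblyCollection.from_products(
            [AssemblyProduct("isotig1", "isotig", "ACGT")]
        )
        with pytest.raises(ValueError, match="lacks an isogroup"):
            coll.validate()

    def test_singleton_with_isogroup_rejected(self):
        with pytest.raises(ValueError, match="must not have an isogroup"):
            AssemblyProduct("s1", "singleton", "ACGT", isogroup_id="g1")

    def test_apply_isogroup_map_syncs_index(self):
        coll = AssemblyCollection.from_products(
            [AssemblyProduct("isotig1", "isotig", "ACGT")]
        )
        coll.apply_isogroup_map({"isotig1": "g9"})
        coll.validate()
        assert coll.isogroups == {"g9": ["isotig1"]}
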