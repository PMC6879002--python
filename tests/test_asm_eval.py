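"""Assembly decomposition, contiguity metrics, and diploid-window statistics."""

import numpy as np
import pytest

from lrkit.asm_eval import (
    AlignmentBlock,
    AssemblyRecord,
    break_at_misassemblies,
    break_scaffolds,
    chance_overlap,
    classify_windows,
    diploid_length_report,
    nx,
    overlap_chi2,
    parse_haplotype_label,
    parse_paf,
    phase_block_n50,
    read_assembly_fasta,
)
from lrkit.params import EmptyInputError, InvalidParameterError


class TestBreakScaffolds:
    def test_n_run_below_threshold_is_kept(self):
        scaf = AssemblyRecord("s/1", "ACGT" + "N" * 9 + "ACGT")
        (contig,) = break_scaffolds([scaf])
        assert len(contig) == 17
        assert contig.haplotype_label == scaf.haplotype_label

    def test_n_run_at_threshold_splits(self):
        scaf = AssemblyRecord("s/1", "ACGT" + "N" * 10 + "ACGT", haplotype_label=1)
        contigs = break_scaffolds([scaf])
        assert [len(c) for c in contigs] == [4, 4]
        assert [c.offset for c in contigs] == [0, 14]
        assert all(c.origin_scaffold == "s/1" for c in contigs)
        assert all(c.haplotype_label == 1 for c in contigs)

    def test_round_trip_reconstruction(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            parts = []
            for _ in range(rng.integers(1, 6)):
                parts.append(
                    "".join(rng.choice(list("ACGT"), size=rng.integers(1, 60)))
                )
                parts.append("N" * rng.integers(1, 30))
            seq = "".join(parts[:-1])
            scaf = AssemblyRecord("scaf", seq)
            contigs = break_scaffolds([scaf])
            canvas = bytearray(b"N" * len(seq))
            for c in contigs:
                canvas[c.offset : c.offset + len(c)] = c.sequence.encode()
            assert canvas.decode() == seq
            assert not any("N" * 10 in c.sequence for c in contigs)

    def test_leading_trailing_runs_dropped(self):
        scaf = AssemblyRecord("s", "N" * 12 + "ACGTACGT" + "N" * 15)
        (contig,) = break_scaffolds([scaf])
        assert contig.sequence == "ACGTACGT"
        assert contig.offset == 12


def brute_force_nx(lengths, x=50.0):
    total = sum(lengths)
    best = 0
    for candidate in sorted(set(lengths)):
        if sum(l for l in lengths if l >= candidate) >= x / 100 * total:
            best = candidate
    return best


class TestNx:
    def test_examples(self):
        assert nx([7]) == 7
        assert nx([5, 4, 3, 2, 1]) == 4

    def test_monotone_in_x(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            lengths = rng.integers(1, 1000, size=rng.integers(1, 30)).tolist()
            assert nx(lengths, 50) >= nx(lengths, 90)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(29)
        for _ in range(1000):
            lengths = rng.integers(1, 100, size=rng.integers(1, 20)).tolist()
            assert nx(lengths) == brute_force_nx(lengths)

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            nx([])


def _block(q, qs, qe, t="ref", ts=None, te=None, strand="+", qlen=10_000, mapq=60):
    if ts is None:
        ts = qs
    if te is None:
        te = ts + (qe - qs)
    return AlignmentBlock(q, qlen, qs, qe, strand, t, ts, te, aln_len=qe - qs, mapq=mapq)


class TestBreakAtMisassemblies:
    def test_single_block_unbroken(self):
        lengths = break_at_misassemblies([_block("q", 0, 10_000)])
        assert lengths == [10_000.0]

    def test_target_switch_splits_at_midpoint(self):
        blocks = [
            _block("q", 0, 4800, t="refA"),
            _block("q", 5200, 10_000, t="refB"),
        ]
        assert sorted(break_at_misassemblies(blocks)) == [5000.0, 5000.0]

    def test_strand_flip_splits(self):
        blocks = [
            _block("q", 0, 5000, strand="+"),
            _block("q", 5000, 10_000, ts=20_000, strand="-"),
        ]
        assert len(break_at_misassemblies(blocks)) == 2

    def test_consistent_small_gap_no_split(self):
        blocks = [
            _block("q", 0, 4000),
            _block("q", 4100, 10_000, ts=4200),  # 100 vs 200 bp gap: within 1 kb
        ]
        assert break_at_misassemblies(blocks) == [10_000.0]

    def test_large_gap_disagreement_splits(self):
        blocks = [
            _block("q", 0, 4000),
            _block("q", 4100, 10_000, ts=9000),  # 100 vs 5000 bp gap
        ]
        assert len(break_at_misassemblies(blocks)) == 2

    def test_unaligned_query_contributes_full_length(self):
        lengths = break_at_misassemblies([], query_lengths={"orphan": 7000})
        assert lengths == [7000.0]

    def test_short_queries_excluded(self):
        lengths = break_at_misassemblies([], query_lengths={"tiny": 400})
        assert lengths == []

    def test_total_length_preserved_and_na50_bounded(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            qlen = int(rng.integers(2000, 50_000))
            blocks = []
            cursor = 0
            while cursor < qlen - 600:
                size = int(rng.integers(600, 5000))
                end = min(cursor + size, qlen)
                blocks.append(
                    _block(
                        "q",
                        cursor,
                        end,
                        t=rng.choice(["refA", "refB"]),
                        ts=int(rng.integers(0, 100_000)),
                        qlen=qlen,
                    )
                )
                cursor = end + int(rng.integers(0, 500))
            broken = break_at_misassemblies(blocks, query_lengths={"q": qlen})
            assert sum(broken) == pytest.approx(qlen)
            assert nx(broken) <= nx([qlen])


class TestClassifyWindows:
    REF = {"ref": 10_000}

    def test_full_diploid(self):
        blocks = [
            _block("a/1", 0, 10_000),
            _block("b/2", 0, 10_000),
        ]
        frac = classify_windows(blocks, self.REF).fractions()
        assert frac["diploid"] == 1.0
        assert frac["overall"] == 1.0

    def test_single_haplotype_is_haploid(self):
        frac = classify_windows([_block("a/1", 0, 10_000)], self.REF).fractions()
        assert frac == pytest.approx(
            {"uncovered": 0, "haploid": 1.0, "diploid": 0, "excess": 0, "overall": 1.0}
        )

    def test_unlabeled_counts_toward_overall_only(self):
        with pytest.warns(UserWarning):
            frac = classify_windows([_block("noname", 0, 10_000)], self.REF).fractions()
        assert frac["overall"] == 1.0
        assert frac["diploid"] == frac["haploid"] == 0.0

    def test_partial_window_coverage_requires_full_span(self):
        # block covers 3.25 windows fully, the 4th partially
        cls = classify_windows([_block("a/1", 0, 1625)], self.REF)
        assert int((cls.classes["ref"] == 1).sum()) == 3

    def test_block_split_invariance(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            start = int(rng.integers(0, 5000))
            end = int(rng.integers(start + 1000, 10_000))
            whole = [_block("a/1", start, end, ts=start), _block("b/2", 0, 10_000)]
            cut = int(rng.integers(start + 1, end))
            split = [
                _block("a/1", start, cut, ts=start),
                _block("a/1", cut, end, ts=cut),
                _block("b/2", 0, 10_000),
            ]
            assert (
                classify_windows(whole, self.REF).fractions()
                == classify_windows(split, self.REF).fractions()
            )

    def test_contig_order_invariance(self):
        blocks = [
            _block("a/1", 0, 4000),
            _block("b/2", 2000, 9000, ts=2000),
            _block("c/1", 5000, 10_000, ts=5000),
        ]
        assert (
            classify_windows(blocks, self.REF).fractions()
            == classify_windows(blocks[::-1], self.REF).fractions()
        )

    def test_diploid_regions_bed(self):
        blocks = [_block("a/1", 0, 5000), _block("b/2", 0, 5000)]
        regions = classify_windows(blocks, self.REF).diploid_regions()
        assert regions == [("ref", 0, 5000)]


class TestChanceOverlap:
    def test_three_assembly_products(self):
        # chance expectation is the product of per-assembly diploid fractions
        assert 100 * chance_overlap([0.589, 0.733, 0.772]) == pytest.approx(33.3, abs=0.05)
        assert 100 * chance_overlap([0.734, 0.792, 0.781]) == pytest.approx(45.4, abs=0.05)

    def test_degenerate(self):
        assert chance_overlap([1.0, 1.0, 1.0]) == 1.0

    def test_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            chance_overlap([0.5, 1.2])


class TestOverlapChi2:
    def test_exact_expectation_gives_zero(self):
        result = overlap_chi2(300, 1000, 0.3)
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_statistic(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            total = int(rng.integers(10, 10_000))
            observed = int(rng.integers(0, total + 1))
            p = float(rng.uniform(0.01, 0.99))
            expected = [total * p, total * (1 - p)]
            oracle = (observed - expected[0]) ** 2 / expected[0] + (
                total - observed - expected[1]
            ) ** 2 / expected[1]
            assert overlap_chi2(observed, total, p).statistic == pytest.approx(oracle)

    def test_p_value_monotone_in_departure(self):
        previous = 1.0
        for observed in (500, 550, 600, 700, 900):
            p = overlap_chi2(observed, 1000, 0.5).p_value
            assert p <= previous + 1e-12
            previous = p

    def test_low_expected_count_flagged(self):
        assert overlap_chi2(1, 10, 0.05).low_expected_count
        assert not overlap_chi2(300, 1000, 0.3).low_expected_count


class TestDiploidLengthReport:
    def test_megabubble_percentage_arithmetic(self):
        # one labeled and one unlabeled contig with the reported lengths
        contigs = [
            AssemblyRecord("mb/1", "A" * 1000, haplotype_label=1),
            AssemblyRecord("hap", "A" * 1000, haplotype_label="unphased"),
        ]
        report = diploid_length_report(contigs)
        assert report["megabubble_percent"] == pytest.approx(50.0)
        # a reported length pair reproduces its quoted percentage
        assert 100 * 3_758_345_846 / 5_632_483_053 == pytest.approx(66.73, abs=0.005)

    def test_all_labeled_is_100_percent(self):
        contigs = [AssemblyRecord(f"c{i}/1", "A" * 600, 1) for i in range(3)]
        assert diploid_length_report(contigs)["megabubble_percent"] == 100.0

    def test_short_contigs_excluded(self):
        contigs = [
            AssemblyRecord("long/1", "A" * 1000, 1),
            AssemblyRecord("short/2", "A" * 100, 2),
        ]
        report = diploid_length_report(contigs)
        assert report["total_contig_length"] == 1000

    def test_fraction_consistency_with_classification(self):
        blocks = [
            _block("a/1", 0, 6000),
            _block("b/2", 3000, 10_000, ts=3000),
        ]
        cls = classify_windows(blocks, {"ref": 10_000})
        contigs = [
            AssemblyRecord("a/1", "A" * 6000, 1),
            AssemblyRecord("b/2", "A" * 7000, 2),
        ]
        report = diploid_length_report(contigs, cls)
        assert (
            report["diploid_percent"] + report["haploid_percent"]
            <= report["overall_percent"] + 1e-9
        )
        assert report["diploid_percent"] == pytest.approx(30.0)

    def test_designated_region_haploid_fraction(self):
        # hemizygous-region check: only one haplotype aligns there
        blocks = [
            _block("a/1", 0, 10_000),
            _block("b/2", 0, 5000),
        ]
        cls = classify_windows(blocks, {"ref": 10_000})
        contigs = [AssemblyRecord("a/1", "A" * 10_000, 1)]
        report = diploid_length_report(
            contigs, cls, designated_regions=[("ref", 5000, 10_000)]
        )
        assert report["designated_haploid_percent"] == pytest.approx(100.0)


class TestPhaseBlocks:
    def test_single_run(self):
        cls = classify_windows(
            [_block("a/1", 0, 10_000), _block("b/2", 0, 10_000)], {"ref": 10_000}
        )
        assert phase_block_n50(cls) == 10_000

    def test_equals_nx_of_run_lengths(self):
        blocks = [
            _block("a/1", 0, 10_000),
            _block("b/2", 0, 3000),
            _block("b/2", 6000, 10_000, ts=6000),
        ]
        cls = classify_windows(blocks, {"ref": 10_000})
        runs = [e - s for _, s, e in cls.diploid_regions()]
        assert sorted(runs) == [3000, 4000]
        assert phase_block_n50(cls) == nx(runs)

    def test_merging_abutting_runs_never_decreases_n50(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            runs = rng.integers(1, 100, size=rng.integers(2, 10)).tolist()
            merged = [runs[0] + runs[1]] + runs[2:]
            assert nx(merged) >= nx(runs)

    def test_no_diploid_windows_raises(self):
        cls = classify_windows([_block("a/1", 0, 10_000)], {"ref": 10_000})
        with pytest.raises(EmptyInputError):
            phase_block_n50(cls)


class TestIoHelpers:
    def test_parse_haplotype_label(self):
        assert parse_haplotype_label("scaffold_12/1") == 1
        assert parse_haplotype_label("scaffold_12/2") == 2
        assert parse_haplotype_label("scaffold_12/2.3") == 2  # broken-contig suffix
        assert parse_haplotype_label("contig_1_hap2") == 2
        assert parse_haplotype_label("scaffold_12") == "unphased"

    def test_paf_round_trip(self, tmp_path):
        paf = tmp_path / "toy.paf"
        paf.write_text(
            "q1\t10000\t0\t4800\t+\trefA\t50000\t100\t4900\t4700\t4800\t60\n"
            "q1\t10000\t5200\t10000\t-\trefB\t60000\t0\t4800\t4600\t4800\t55\n"
        )
        blocks = parse_paf(paf)
        assert len(blocks) == 2
        assert blocks[0].target == "refA"
        assert blocks[1].strand == "-"
        assert blocks[1].mapq == 55

    def test_assembly_fasta_reader(self, tmp_path):
        fa = tmp_path / "asm.fa"
        fa.write_text(">s1/1 extra words\nACGT\nACGT\n>s2/2\nTTTT\n>s3\nGGGG\n")
        records = read_assembly_fasta(fa)
        assert [(r.name, r.haplotype_label, len(r)) for r in records] == [
            ("s1/1", 1, 8),
            ("s2/2", 2, 4),
            ("s3", "unphased", 4),
        ]

    def test_end_to_end_toy_diploid_fraction(self):
        # design a toy diploid assembly with known coverage gaps and verify
        # the diploid fraction equals the designed covered fraction exactly
        ref_len = 100_000
        gaps = {1: (20_000, 30_000), 2: (60_000, 70_000)}  # per-haplotype gap
        blocks = []
        for hap, (gs, ge) in gaps.items():
            blocks.append(_block(f"asm_a/{hap}", 0, gs, t="ref"))
            blocks.append(_block(f"asm_b/{hap}", ge, ref_len, ts=ge, t="ref"))
        cls = classify_windows(blocks, {"ref": ref_len})
        frac = cls.fractions()
        # diploid wherever neither haplotype has its gap: 80 kb of 100 kb
        assert frac["diploid"] == pytest.approx(0.8)
        assert frac["haploid"] == pytest.approx(0.2)
        assert frac["overall"] == 1.0
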