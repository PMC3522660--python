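import math

import numpy as np
import pytest

import mitopool as mp
from mitopool.mitoseq_io import MitoseqError


class TestMutateHaplotype:
    def test_zero_rate_is_identity(self, ancestor):
        hap, log = mp.mutate_haplotype(ancestor, mp.ErrorModel(mutation_rate=0.0), 1)
        assert hap.seq == ancestor.seq and log == []

    def test_event_count_matches_binomial_expectation(self, ancestor):
        model = mp.ErrorModel(mutation_rate=0.001)
        counts = [
            len(mp.mutate_haplotype(ancestor, model, seed)[1]) for seed in range(200)
        ]
        expected = len(ancestor) * 0.001
        assert np.mean(counts) == pytest.approx(expected, rel=0.10)

    def test_indel_length_geometric_mean(self, ancestor):
        # force many indels; their length should be geometric with mean 1/(1-0.3)
        model = mp.ErrorModel(mutation_rate=0.2, indel_frac=1.0, indel_ext=0.3)
        lengths = []
        seed = 0
        while len(lengths) < 10_000:
            _, log = mp.mutate_haplotype(ancestor, model, seed)
            lengths += [e.length for e in log if e.kind in ("ins", "del")]
            seed += 1
        assert np.mean(lengths) == pytest.approx(1 / 0.7, abs=0.05)

    def test_substitution_indel_split(self, ancestor):
        model = mp.ErrorModel(mutation_rate=0.05, indel_frac=0.1)
        _, log = mp.mutate_haplotype(ancestor, model, 3)
        frac_indel = sum(e.kind != "sub" for e in log) / len(log)
        assert frac_indel == pytest.approx(0.1, abs=0.03)

    def test_deterministic_under_seed(self, ancestor):
        model = mp.ErrorModel()
        h1, l1 = mp.mutate_haplotype(ancestor, model, 9)
        h2, l2 = mp.mutate_haplotype(ancestor, model, 9)
        assert h1.seq == h2.seq and l1 == l2


class TestSimulatePool:
    def test_read_count_formula(self, ancestor):
        rs = mp.simulate_pool(
            [ancestor],
            mp.CoveragePlan.uniform(20),
            read_length=400,
            model=mp.ErrorModel(error_rate=0, mutation_rate=0, random_read_prob=0),
            seed=1,
        )
        assert len(rs) == math.ceil(20 * len(ancestor) / 400)

    def test_ladder_coverages(self):
        plan = mp.CoveragePlan.ladder(10, 2)
        assert plan.coverage_for(1) == 10
        assert [plan.coverage_for(i) for i in (1, 2, 30)] == [10, 12, 68]

    def test_deterministic_byte_identical_output(self, ancestor, tmp_path):
        outs = []
        for run in (1, 2):
            rs = mp.simulate_pool(
                [ancestor], mp.CoveragePlan.uniform(5), 150, seed=77
            )
            fq, tsv = tmp_path / f"r{run}.fastq", tmp_path / f"r{run}.tsv"
            rs.write_fastq(fq)
            rs.write_truth(tsv)
            outs.append((fq.read_bytes(), tsv.read_bytes()))
        assert outs[0] == outs[1]

    def test_error_free_reads_are_substrings_of_doubled_haplotype(self, ancestor):
        rs = mp.simulate_pool(
            [ancestor], mp.CoveragePlan.uniform(3), 150,
            model=mp.ErrorModel(error_rate=0, mutation_rate=0.001, random_read_prob=0),
            seed=5,
        )
        hap = rs.haplotypes[ancestor.id]
        doubled = hap.seq + hap.seq
        for read, truth in zip(rs.reads, rs.truth):
            frag = doubled[truth.start : truth.start + 150]
            expect = mp.reverse_complement(frag) if truth.strand == "-" else frag
            assert read.sequence == expect
            assert truth.wrapped == (truth.start + 150 > len(hap))

    def test_measured_error_rate(self, ancestor):
        rs = mp.simulate_pool(
            [ancestor], mp.CoveragePlan.uniform(40), 150,
            model=mp.ErrorModel(mutation_rate=0, random_read_prob=0), seed=11,
        )
        doubled = ancestor.seq + ancestor.seq
        mm = tot = 0
        for read, truth in zip(rs.reads, rs.truth):
            frag = doubled[truth.start : truth.start + 150]
            if truth.strand == "-":
                frag = mp.reverse_complement(frag)
            mm += sum(a != b for a, b in zip(read.sequence, frag))
            tot += 150
        assert mm / tot == pytest.approx(0.02, abs=0.002)

    def test_random_read_fraction(self, ancestor):
        rs = mp.simulate_pool(
            [ancestor], mp.CoveragePlan.uniform(40), 150, seed=13
        )
        frac = sum(t.origin == "RANDOM" for t in rs.truth) / len(rs)
        assert frac == pytest.approx(0.05, abs=0.02)
        # genome-derived coverage is unaffected by contamination
        n_genome = sum(t.origin == ancestor.id for t in rs.truth)
        realized = n_genome * 150 / len(ancestor)
        assert realized == pytest.approx(40, rel=0.02)

    def test_paired_end_mates(self, ancestor):
        rs = mp.simulate_pool(
            [ancestor], mp.CoveragePlan.uniform(5), 150, paired=True,
            model=mp.ErrorModel(error_rate=0, mutation_rate=0, random_read_prob=0),
            seed=3,
        )
        mates = {}
        for read in rs.reads:
            base = read.read_id.rsplit("/", 1)[0]
            mates.setdefault(base, []).append(read.mate)
        assert all(sorted(v) == [1, 2] for v in mates.values())
        # mates face each other: one + and one - per pair
        truth = rs.truth_by_id()
        for base in mates:
            strands = sorted(truth[f"{base}/{m}"].strand for m in (1, 2))
            assert strands == ["+", "-"]

    def test_paired_insert_shorter_than_read_errors(self, ancestor):
        with pytest.raises(MitoseqError, match="insert"):
            mp.simulate_pool(
                [ancestor], mp.CoveragePlan.uniform(5), 150, paired=True,
                insert_mean=100, seed=1,
            )


class TestExactReads:
    def test_uniform_tiling(self):
        g = mp.AnnotatedMitogenome(id="g", seq="ACGT" * 250)  # 1000 bp
        rs = mp.exact_reads(g, 100, 50)
        assert len(rs) == 20
        cov = np.zeros(1000, dtype=int)
        for t in rs.truth:
            for i in range(100):
                cov[(t.start + i) % 1000] += 1
        assert (cov == 2).all()

    def test_step_equals_length_is_1x(self):
        g = mp.AnnotatedMitogenome(id="g", seq="ACGT" * 250)
        rs = mp.exact_reads(g, 100, 100)
        assert len(rs) == 10 and all(not t.wrapped for t in rs.truth[:-1])

    def test_wrapping_read(self):
        g = mp.AnnotatedMitogenome(id="g", seq="ACGT" * 250)
        rs = mp.exact_reads(g, 100, 50)
        last = rs.reads[-1]
        truth = rs.truth[-1]
        assert truth.start == 950 and truth.wrapped
        assert last.sequence == g.seq[950:] + g.seq[:50]
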