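import numpy as np
import pytest

import mitopool as mp
from mitopool._dna import random_dna
from mitopool.assembly_baseline import count_kmers, _rc_code
from mitopool.mitoseq_io import MitoseqError, reverse_complement


def kmer_multiset(seqs, k):
    """Independent canonical k-mer counting oracle (string based)."""
    out = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if set(km) - set("ACGT"):
                continue
            canon = min(km, reverse_complement(km))
            out[canon] = out.get(canon, 0) + 1
    return out


def decode_code(code, k):
    return "".join("ACGT"[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


class TestBuildGraph:
    def test_hand_enumeration_with_canonicalization(self):
        # ACGTACG, k=3: occurrences ACG,CGT,GTA,TAC,ACG (5); canonical pairs
        # ACG<->CGT and GTA<->TAC collapse to two distinct canonical forms
        codes, counts = count_kmers(["ACGTACG"], 3)
        assert counts.sum() == 5
        assert len(codes) == 2
        assert sorted(decode_code(c, 3) for c in codes) == ["ACG", "GTA"]
        assert len({"ACG", "CGT", "GTA", "TAC"}) == 4  # raw k-mers, pre-canonical

    def test_matches_string_oracle(self, rng):
        seqs = [random_dna(rng, int(rng.integers(40, 120))) for _ in range(20)]
        codes, counts = count_kmers(seqs, 7)
        oracle = kmer_multiset(seqs, 7)
        got = {decode_code(c, 7): int(n) for c, n in zip(codes, counts)}
        assert got == oracle

    def test_exact_reads_recover_genome_kmer_set(self, ancestor):
        rs = mp.exact_reads(ancestor, 160, 4)
        g = mp.build_graph(rs, k=31, min_count=1)
        oracle = kmer_multiset([ancestor.seq + ancestor.seq[:30]], 31)
        assert len(g.counts) == len(oracle)

    def test_n_splits_reads(self):
        codes, counts = count_kmers(["ACGTNACGT"], 3)
        assert counts.sum() == 4  # two segments of 4 bases each, 2 k-mers per segment

    def test_even_k_rejected(self):
        with pytest.raises(MitoseqError, match="odd"):
            mp.build_graph(["ACGTACGT"], k=4)

    def test_min_count_prunes_singletons(self):
        reads = ["ACGTACGTACGT"] * 3 + ["ACGTACTTACGT"]  # one erroneous read
        g1 = mp.build_graph(reads, k=5, min_count=1)
        g2 = mp.build_graph(reads, k=5, min_count=2)
        assert len(g2.counts) < len(g1.counts)
        assert all(c >= 2 for c in g2.counts.values())

    def test_rc_code_roundtrip(self, rng):
        for _ in range(20):
            s = random_dna(rng, 31)
            codes, _ = count_kmers([s], 31)
            rc_codes, _ = count_kmers([reverse_complement(s)], 31)
            assert codes.tolist() == rc_codes.tolist()
            code = int(codes[0])
            assert _rc_code(_rc_code(code, 31), 31) == code


class TestUnitigs:
    def test_single_circular_genome_one_contig(self, rng):
        seq = random_dna(rng, 10_000)
        g = mp.AnnotatedMitogenome(id="g", seq=seq)
        # repeat-free at k=31 verified per fixture
        _, counts = count_kmers([seq + seq[:30]], 31)
        assert counts.max() == 1
        cs = mp.assemble(mp.exact_reads(g, 100, 10))
        assert len(cs) == 1
        c = cs.contigs[0]
        assert c.circular_flag and len(c) >= 10_000
        body = c.sequence[:10_000]
        doubled = seq + seq
        assert body in doubled or reverse_complement(body) in doubled

    def test_two_disjoint_genomes_partition(self, rng):
        a, b = random_dna(rng, 1500), random_dna(rng, 1500)
        ga = mp.AnnotatedMitogenome(id="a", seq=a)
        gb = mp.AnnotatedMitogenome(id="b", seq=b)
        reads = mp.exact_pool([ga, gb], 100, 10)
        cs = mp.assemble(reads)
        for c in cs:
            in_a = c.sequence[: len(a)] in a + a or reverse_complement(
                c.sequence[: len(a)]
            ) in a + a
            in_b = c.sequence[: len(b)] in b + b or reverse_complement(
                c.sequence[: len(b)]
            ) in b + b
            assert in_a != in_b  # each contig belongs to exactly one genome

    def test_empty_graph_empty_set(self):
        cs = mp.unitigs(mp.KmerGraph(k=31, counts={}))
        assert len(cs) == 0

    def test_every_kmer_in_exactly_one_unitig(self, rng):
        seqs = [random_dna(rng, 300) for _ in range(5)]
        graph = mp.build_graph(seqs, k=21, min_count=1)
        cs = mp.unitigs(graph)
        spelled = {}
        for c in cs:
            for i in range(len(c.sequence) - 20):
                km = c.sequence[i : i + 21]
                canon = min(km, reverse_complement(km))
                spelled[canon] = spelled.get(canon, 0) + 1
        assert all(n == 1 for n in spelled.values())
        assert len(spelled) == len(graph.counts)

    def test_deterministic_ordering(self, rng):
        seqs = [random_dna(rng, 500) for _ in range(4)]
        c1 = mp.assemble(seqs, k=21, min_count=1)
        c2 = mp.assemble(list(seqs), k=21, min_count=1)
        assert [(c.contig_id, c.sequence) for c in c1] == [
            (c.contig_id, c.sequence) for c in c2
        ]


class TestAssemble:
    def test_error_reads_recover_large_contig(self, ancestor):
        rs = mp.simulate_pool(
            [ancestor], mp.CoveragePlan.uniform(40), 150,
            model=mp.ErrorModel(mutation_rate=0, random_read_prob=0), seed=2,
        )
        cs = mp.assemble(rs)  # error reads get the error-model abundance floor
        assert cs.params["min_count"] == 4
        assert max(len(c) for c in cs) >= 0.70 * len(ancestor)

    def test_zero_reads_empty(self):
        assert len(mp.assemble([], k=31, min_count=1)) == 0

    def test_params_logged_in_fasta_header(self, tmp_path, rng):
        cs = mp.assemble([random_dna(rng, 200)], k=21, min_count=1)
        path = tmp_path / "contigs.fasta"
        cs.write_fasta(path)
        head = path.read_text().splitlines()[0]
        assert head.startswith(";assembly parameters") and "k=21" in head
        back = mp.ContigSet.from_fasta(path)
        assert [c.sequence for c in back] == [c.sequence for c in cs]

    def test_best_contig_coverage_trend_on_exact_reads(self, rng):
        # pooled disjoint random genomes: contig recovery is not degraded
        # as coverage (tiling density) increases
        genomes = [
            mp.AnnotatedMitogenome(id=f"g{i}", seq=random_dna(rng, 3000))
            for i in range(3)
        ]
        fracs = []
        for step in (50, 25, 10):  # 2x, 4x, 10x
            reads = mp.exact_pool(genomes, 100, step)
            cs = mp.assemble(reads)
            best = max(len(c) for c in cs)
            fracs.append(best / 3000)
        assert fracs[0] <= fracs[-1] + 1e-9
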