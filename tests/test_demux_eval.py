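import numpy as np
import pytest

import mitopool as mp
from mitopool._dna import random_dna
from mitopool.assembly_baseline import Contig
from mitopool.demux_eval import Placement
from mitopool.mitoseq_io import MitoseqError


@pytest.fixture(scope="module")
def refdb(family10):
    genomes, _ = family10
    return mp.ReferenceDB.from_genomes(genomes)


def contig(seq, cid="c1"):
    return Contig(cid, seq, mean_abundance=1.0)


class TestAssignContigs:
    def test_exact_coi_scores_one(self, family10, refdb):
        genomes, _ = family10
        c = contig(genomes[0].gene_seq("COI"))
        rep = mp.assign_contigs([c], refdb)
        (a,) = rep.assignments
        assert a.status == "assigned"
        assert a.best_taxon == genomes[0].id
        assert a.best_score == 1.0
        assert "COI" in a.markers_hit

    def test_reverse_complement_same_assignment(self, family10, refdb):
        genomes, _ = family10
        c = contig(mp.reverse_complement(genomes[0].gene_seq("COI")))
        rep = mp.assign_contigs([c], refdb)
        (a,) = rep.assignments
        assert a.status == "assigned" and a.best_taxon == genomes[0].id
        assert a.best_score == 1.0

    def test_random_contig_unassigned(self, refdb, rng):
        c = contig(random_dna(rng, 1000))
        rep = mp.assign_contigs([c], refdb)
        assert rep.assignments[0].status == "unassigned"
        assert rep.assignments[0].best_taxon is None

    def test_margin_makes_close_call_ambiguous(self):
        db = mp.ReferenceDB(
            [
                mp.demux_eval.ReferenceEntry("tax1", "COI", "ACGTACGTAACCGGTTACGT"),
                mp.demux_eval.ReferenceEntry("tax2", "COI", "ACGTACGTAACCGGTTACGA"),
            ],
            k=5,
        )
        rep = mp.assign_contigs([contig("ACGTACGTAACCGGTTACGT")], db)
        assert rep.assignments[0].status == "ambiguous"

    def test_empty_refdb_errors(self):
        with pytest.raises(MitoseqError, match="empty reference"):
            mp.assign_contigs([contig("ACGT" * 10)], mp.ReferenceDB([]))


class TestMapContigsToTruth:
    def test_origin_spanning_exact_substring(self, family10):
        genomes, _ = family10
        g = genomes[0]
        L = len(g)
        c = contig(mp.slice_circular(g, L - 500, L + 500))
        (p,) = mp.map_contigs_to_truth([c], genomes)
        assert p.genome == g.id
        assert p.identity == 1.0
        assert p.strand == "+"
        assert p.start == L - 500 and p.end == L + 500  # wraps the origin

    def test_chimera_flagged(self, family10):
        genomes, _ = family10
        a, b = genomes[0], genomes[1]
        c = contig(a.seq[:1000] + b.seq[:1000])
        (p,) = mp.map_contigs_to_truth([c], genomes)
        assert p.chimeric

    def test_mutated_haplotype_high_identity(self, family10):
        genomes, _ = family10
        g = genomes[0]
        hap, log = mp.mutate_haplotype(g, mp.ErrorModel(mutation_rate=0.001), 5)
        c = contig(hap.seq[:5000])
        (p,) = mp.map_contigs_to_truth([c], genomes)
        assert p.genome == g.id
        assert p.identity >= 0.99
        assert not p.chimeric

    def test_reverse_strand_placement(self, family10):
        genomes, _ = family10
        g = genomes[0]
        c = contig(mp.reverse_complement(g.seq[2000:4000]))
        (p,) = mp.map_contigs_to_truth([c], genomes)
        assert p.genome == g.id and p.strand == "-" and p.identity == 1.0

    def test_unrelated_contig_unplaced(self, family10, rng):
        genomes, _ = family10
        assert mp.map_contigs_to_truth([contig(random_dna(rng, 800))], genomes) == []


class TestOverlapSummary:
    def test_fixed_denominator_arithmetic(self):
        g = mp.AnnotatedMitogenome(id="g", seq="ACGT" * 4000)  # 16,000 bp
        pl = Placement("c1", "g", 0, 8400, "+", 1.0)
        summ = mp.overlap_summary([pl], [g], denominator_mode="fixed_16400")
        go = summ.per_genome["g"]
        assert go.best_fraction == pytest.approx(8400 / 16_400)
        assert summ.pool_counts[0.5] == 1  # 0.512 > 0.5
        assert summ.pool_counts[0.66] == 0

    def test_no_contigs_zero_fraction(self):
        g = mp.AnnotatedMitogenome(id="g", seq="ACGT" * 1000)
        summ = mp.overlap_summary([], [g])
        assert summ.per_genome["g"].best_fraction == 0.0
        assert summ.per_genome["g"].covered_bp == 0

    def test_full_circle_fraction_one(self):
        g = mp.AnnotatedMitogenome(id="g", seq="ACGT" * 1000)
        pl = Placement("c1", "g", 100, 100 + 4000, "+", 1.0)
        summ = mp.overlap_summary([pl], [g])
        assert summ.per_genome["g"].best_fraction == 1.0
        assert summ.per_genome["g"].covered_bp == 4000

    def test_split_circle_reported_per_contig(self):
        # circularity split into two contigs: each reported alone, no merging
        g = mp.AnnotatedMitogenome(id="g", seq="ACGT" * 1000)
        pls = [
            Placement("c1", "g", 0, 1800, "+", 1.0),
            Placement("c2", "g", 1800, 4000, "+", 1.0),
        ]
        summ = mp.overlap_summary(pls, [g])
        go = summ.per_genome["g"]
        assert go.best_fraction == pytest.approx(2200 / 4000)
        assert go.covered_bp == 4000
        assert go.n_contigs[0.33] == 2 and go.n_contigs[0.5] == 1

    def test_strict_threshold(self):
        g = mp.AnnotatedMitogenome(id="g", seq="ACGT" * 1000)
        pl = Placement("c1", "g", 0, 2000, "+", 1.0)  # exactly 50%
        summ = mp.overlap_summary([pl], [g])
        assert summ.pool_counts[0.5] == 0  # strict ">"

    def test_invalid_threshold_errors(self):
        g = mp.AnnotatedMitogenome(id="g", seq="ACGT" * 100)
        with pytest.raises(MitoseqError):
            mp.overlap_summary([], [g], thresholds=(0.0, 0.5))

    def test_invariant_under_contig_permutation_and_rotation(self, family10):
        genomes, _ = family10
        g = genomes[0]
        contigs = [
            contig(mp.slice_circular(g, 100, 4100), "c1"),
            contig(mp.slice_circular(g, 9000, 12_000), "c2"),
        ]
        def fractions(cs, gen):
            pl = mp.map_contigs_to_truth(cs, [gen])
            s = mp.overlap_summary(pl, [gen])
            return (
                s.per_genome[gen.id].best_fraction,
                s.per_genome[gen.id].covered_bp,
            )

        base = fractions(contigs, g)
        assert fractions(contigs[::-1], g) == base
        assert fractions(contigs, mp.rotate(g, 5000)) == base


class TestTetraProfile:
    def test_homopolymer(self):
        prof = mp.tetra_profile("AAAA")
        assert prof[0] == 1.0 and prof.sum() == 1.0

    def test_enumerated_frequencies(self):
        # ACGTACGT: tetramers ACGT x2, CGTA, GTAC, TACG
        prof = mp.tetra_profile("ACGTACGT")
        def idx(s):
            return sum("ACGT".index(c) * 4 ** (3 - i) for i, c in enumerate(s))
        assert prof[idx("ACGT")] == pytest.approx(0.4)
        for tet in ("CGTA", "GTAC", "TACG"):
            assert prof[idx(tet)] == pytest.approx(0.2)

    def test_sums_to_one(self, rng):
        for _ in range(5):
            prof = mp.tetra_profile(random_dna(rng, int(rng.integers(4, 500))))
            assert prof.sum() == pytest.approx(1.0)
            assert (prof >= 0).all() and prof.shape == (256,)

    def test_too_short_errors(self):
        with pytest.raises(MitoseqError):
            mp.tetra_profile("ACG")
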