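"""Sequence-as-tag demultiplexing and assembly evaluation.

Contigs are attributed to specimens by comparing them with a reference
marker database (COI and/or other mitochondrial markers): the score for
a taxon is the fraction of a marker's canonical 15-mers found in the
contig's 15-mer set, maximised over that taxon's markers.  In a
simulation context, contigs are also mapped back to the truth genomes
(on the doubled sequence, so origin-spanning placements are handled) and
summarised as the fraction of each mitogenome its best contig overlaps
— against the genome's own length or against a fixed 16,400 bp average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from ._dna import encode
from .assembly_baseline import _segment_codes
from .mitoseq_io import MitoseqError, reverse_complement

ASSIGN_K = 15
MARKERS = ("COI", "12S", "16S", "CYTB", "other")
FIXED_DENOMINATOR = 16_400


def kmer_set(seq: str, k: int = ASSIGN_K) -> set[int]:
    """Canonical k-mer codes of a sequence (N-containing windows skipped)."""
    return set().union(
        *(set(c.tolist()) for c in _segment_codes(encode(seq), k)), set()
    )


def kmer_positions(seq: str, k: int = ASSIGN_K) -> dict[int, list[int]]:
    pos: dict[int, list[int]] = {}
    codes = encode(seq)
    pow_desc = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    pow_asc = 4 ** np.arange(k, dtype=np.int64)
    if len(codes) < k:
        return pos
    ok = codes <= 3
    valid = np.lib.stride_tricks.sliding_window_view(ok, k).all(axis=1)
    win = np.lib.stride_tricks.sliding_window_view(
        np.where(ok, codes, 0).astype(np.int64), k
    )
    canon = np.minimum(win @ pow_desc, (3 - win) @ pow_asc)
    for i in np.flatnonzero(valid):
        pos.setdefault(int(canon[i]), []).append(int(i))
    return pos


# ---------------------------------------------------------------------------
# reference database and contig assignment
# ---------------------------------------------------------------------------

@dataclass
class ReferenceEntry:
    taxon: str
    marker: str
    sequence: str


@dataclass
class ReferenceDB:
    entries: list[ReferenceEntry]
    k: int = ASSIGN_K
    _kmers: dict[tuple[str, str], set[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.taxon, e.marker)
            if key in seen:
                raise MitoseqError(f"duplicate reference entry {key}")
            seen.add(key)
            if "-" in e.sequence:
                raise MitoseqError(f"reference {key} contains gaps")
            self._kmers[key] = kmer_set(e.sequence, self.k)

    @classmethod
    def from_fasta(cls, path: str | Path, k: int = ASSIGN_K) -> "ReferenceDB":
        """Headers are ``taxon|marker`` (marker defaults to COI)."""
        from Bio import SeqIO

        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxon, _, marker = rec.id.partition("|")
            entries.append(
                ReferenceEntry(taxon, marker or "COI", str(rec.seq).upper())
            )
        return cls(entries, k=k)

    @classmethod
    def from_genomes(
        cls, genomes, markers=("COI",), k: int = ASSIGN_K
    ) -> "ReferenceDB":
        """Extract annotated marker genes from genomes as reference entries."""
        entries = []
        for g in genomes:
            for m in markers:
                if g.gene(m) is not None:
                    entries.append(ReferenceEntry(g.id, m, g.gene_seq(m)))
        return cls(entries, k=k)

    def taxa(self) -> list[str]:
        return sorted({e.taxon for e in self.entries})


@dataclass
class Assignment:
    contig_id: str
    best_taxon: str | None
    best_score: float
    second_score: float
    status: str  # assigned | ambiguous | unassigned
    markers_hit: list[str] = field(default_factory=list)


@dataclass
class AssignmentReport:
    assignments: list[Assignment]
    min_score: float
    margin: float

    def by_contig(self) -> dict[str, Assignment]:
        return {a.contig_id: a for a in self.assignments}

    def assigned(self) -> list[Assignment]:
        return [a for a in self.assignments if a.status == "assigned"]


def assign_contigs(
    contigs, refdb: ReferenceDB, min_score: float = 0.2, margin: float = 2.0
) -> AssignmentReport:
    """Attribute contigs to taxa by shared-canonical-k-mer containment.

    score(contig, taxon) = max over the taxon's markers of
    |contig k-mers ∩ marker k-mers| / |marker k-mers| — strand-insensitive
    by canonicalisation.  A contig is assigned when the best score clears
    ``min_score`` and exceeds ``margin`` times the runner-up; exact ties
    are ambiguous.
    """
    if not refdb.entries:
        raise MitoseqError("empty reference database")
    out = []
    for contig in contigs:
        ck = kmer_set(contig.sequence, refdb.k)
        per_taxon: dict[str, float] = {}
        hits: dict[str, list[str]] = {}
        for e in refdb.entries:
            mk = refdb._kmers[(e.taxon, e.marker)]
            score = len(ck & mk) / len(mk) if mk else 0.0
            if score > per_taxon.get(e.taxon, -1.0):
                per_taxon[e.taxon] = score
            if score > 0:
                hits.setdefault(e.taxon, []).append(e.marker)
        ranked = sorted(per_taxon.items(), key=lambda kv: (-kv[1], kv[0]))
        best_taxon, best = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else 0.0
        if best < min_score:
            status, best_taxon = "unassigned", None
        elif best == second or best < margin * second:
            status = "ambiguous"
        else:
            status = "assigned"
        out.append(
            Assignment(
                contig.contig_id, best_taxon, best, second, status,
                sorted(hits.get(best_taxon, [])) if best_taxon else [],
            )
        )
    return AssignmentReport(out, min_score, margin)


# ---------------------------------------------------------------------------
# truth mapping
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    contig_id: str
    genome: str
    start: int       # 0-based on the circular truth genome
    end: int         # exclusive; > genome length when the placement wraps
    strand: str
    identity: float
    chimeric: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start


def _longest_covered_run(
    contig_positions, genome_kmers, k: int, gap_tol: int = 50
) -> tuple[int, int] | None:
    """Largest contiguous contig segment covered by shared k-mers.

    Runs are merged across gaps of up to ``gap_tol`` bases; isolated
    homologous k-mers elsewhere on the contig do not stretch the run.
    """
    hit = []
    for code, plist in contig_positions.items():
        if code in genome_kmers:
            hit.extend(plist)
    if not hit:
        return None
    hit.sort()
    cur_start = hit[0]
    best_span = (hit[0], hit[0] + k)
    cur_end = hit[0] + k
    for p in hit[1:]:
        if p <= cur_end + gap_tol:
            cur_end = max(cur_end, p + k)
        else:
            if cur_end - cur_start > best_span[1] - best_span[0]:
                best_span = (cur_start, cur_end)
            cur_start, cur_end = p, p + k
    if cur_end - cur_start > best_span[1] - best_span[0]:
        best_span = (cur_start, cur_end)
    return best_span


def map_contigs_to_truth(
    contigs,
    truth_genomes,
    k: int = ASSIGN_K,
    min_shared: int = 5,
    chimera_min_len: int = 500,
    chimera_identity: float = 0.9,
) -> list[Placement]:
    """Anchor each contig to its best truth genome on the doubled sequence.

    Placement identity comes from an infix edit-distance alignment of the
    contig against the doubled genome (wrap-safe).  A contig carrying
    >= ``chimera_min_len`` bp of >= ``chimera_identity`` matches to two or
    more genomes is flagged chimeric.
    """
    genomes = list(truth_genomes)
    doubled = {g.id: g.seq + g.seq for g in genomes}
    gkmers = {g.id: kmer_set(doubled[g.id], k) for g in genomes}
    lengths = {g.id: len(g) for g in genomes}
    placements: list[Placement] = []
    for contig in contigs:
        cpos = kmer_positions(contig.sequence, k)
        shared = {
            gid: sum(len(cpos[c]) for c in cpos if c in km)
            for gid, km in gkmers.items()
        }
        candidates = [gid for gid, n in shared.items() if n >= min_shared]
        if not candidates:
            continue
        best_gid = max(candidates, key=lambda gid: (shared[gid], gid))
        aln_f = edlib.align(contig.sequence, doubled[best_gid], mode="HW", task="locations")
        rc = reverse_complement(contig.sequence)
        aln_r = edlib.align(rc, doubled[best_gid], mode="HW", task="locations")
        if aln_f["editDistance"] <= aln_r["editDistance"]:
            aln, strand = aln_f, "+"
        else:
            aln, strand = aln_r, "-"
        loc = aln["locations"][0]
        L = lengths[best_gid]
        start, end = loc[0] % L, loc[0] % L + (loc[1] + 1 - loc[0])
        identity = 1.0 - aln["editDistance"] / max(len(contig.sequence), 1)
        # chimera screen: substantial high-identity coverage on >= 2 genomes
        n_chimeric_parents = 0
        for gid in candidates:
            run = _longest_covered_run(cpos, gkmers[gid], k)
            if run is None or run[1] - run[0] < chimera_min_len:
                continue
            seg = contig.sequence[run[0] : run[1]]
            d = min(
                edlib.align(seg, doubled[gid], mode="HW")["editDistance"],
                edlib.align(reverse_complement(seg), doubled[gid], mode="HW")["editDistance"],
            )
            if 1.0 - d / len(seg) >= chimera_identity:
                n_chimeric_parents += 1
        placements.append(
            Placement(
                contig.contig_id, best_gid, start, min(end, start + L), strand,
                identity, chimeric=n_chimeric_parents >= 2,
            )
        )
    return placements


# ---------------------------------------------------------------------------
# overlap summaries
# ---------------------------------------------------------------------------

@dataclass
class GenomeOverlap:
    genome: str
    best_contig: str | None
    best_fraction: float
    covered_bp: int
    covered_fraction: float
    n_contigs: dict[float, int]  # threshold -> contigs exceeding it


@dataclass
class OverlapSummary:
    per_genome: dict[str, GenomeOverlap]
    pool_counts: dict[float, int]  # threshold -> genomes with a contig > threshold
    thresholds: tuple
    denominator_mode: str


def _circular_union(intervals, L: int) -> int:
    """Total bases covered by [start, end) intervals on a circle of length L."""
    segs = []
    for s, e in intervals:
        s %= L
        e = s + min(e - s, L)
        if e <= L:
            segs.append((s, e))
        else:
            segs.append((s, L))
            segs.append((0, e - L))
    if not segs:
        return 0
    segs.sort()
    total = 0
    cur_s, cur_e = segs[0]
    for s, e in segs[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return min(total, L)


def overlap_summary(
    placements,
    truth_genomes,
    thresholds=(0.33, 0.5, 0.66),
    denominator_mode: str = "own_length",
) -> OverlapSummary:
    """Best-contig overlap fractions per truth genome and pool-level counts.

    Fractions use each genome's own length, or the fixed 16,400 bp
    average mitogenome size.  Threshold counts use a strict ``>``.  A
    circular genome split into two contigs is reported per contig — the
    pieces are not merged.
    """
    thresholds = tuple(sorted(thresholds))
    if any(not 0 < t < 1 for t in thresholds):
        raise MitoseqError(f"thresholds must lie in (0,1): {thresholds}")
    if denominator_mode not in ("own_length", "fixed_16400"):
        raise MitoseqError(f"unknown denominator_mode {denominator_mode!r}")
    genomes = list(truth_genomes)
    per_genome: dict[str, GenomeOverlap] = {}
    by_genome: dict[str, list[Placement]] = {g.id: [] for g in genomes}
    for p in placements:
        if p.genome in by_genome:
            by_genome[p.genome].append(p)
    for g in genomes:
        L = len(g)
        denom = L if denominator_mode == "own_length" else FIXED_DENOMINATOR
        plist = by_genome[g.id]
        fractions = [(min(p.span, L) / denom, p.contig_id) for p in plist]
        best_fraction, best_contig = max(fractions, default=(0.0, None))
        covered = _circular_union([(p.start, p.end) for p in plist], L)
        per_genome[g.id] = GenomeOverlap(
            genome=g.id,
            best_contig=best_contig,
            best_fraction=best_fraction,
            covered_bp=covered,
            covered_fraction=covered / denom,
            n_contigs={t: sum(1 for f, _ in fractions if f > t) for t in thresholds},
        )
    pool_counts = {
        t: sum(1 for go in per_genome.values() if go.best_fraction > t)
        for t in thresholds
    }
    return OverlapSummary(per_genome, pool_counts, thresholds, denominator_mode)


# ---------------------------------------------------------------------------
# composition profile
# ---------------------------------------------------------------------------

def tetra_profile(sequence: str) -> np.ndarray:
    """Sliding tetranucleotide frequencies as a 256-vector summing to 1.

    Index order is lexicographic AAAA..TTTT; windows containing N are
    skipped.
    """
    if len(sequence) < 4:
        raise MitoseqError("sequence shorter than 4 bp has no tetranucleotides")
    codes = encode(sequence)
    ok = codes <= 3
    win_ok = np.lib.stride_tricks.sliding_window_view(ok, 4).all(axis=1)
    if not win_ok.any():
        raise MitoseqError("no ACGT-only tetranucleotide window in sequence")
    win = np.lib.stride_tricks.sliding_window_view(
        np.where(ok, codes, 0).astype(np.int64), 4
    )
    idx = win @ np.array([64, 16, 4, 1], dtype=np.int64)
    counts = np.bincount(idx[win_ok], minlength=256).astype(float)
    return counts / counts.sum()
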