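"""Read simulation from pooled circular mitogenomes, with truth tracking.

The error model mirrors short-read simulators of the wgsim family and is
parameterised by a per-base read substitution rate (default 0.02), a
per-site haplotype mutation rate (default 0.001, of which 1/10 are
indels whose length is geometric with extension probability 0.3), and a
probability that a read is random DNA contamination (default 0.05).

Each genome first receives one mutated haplotype per run (the specimen's
true sequence differing from the reference), then reads are drawn
uniformly on the circle — reads may span the origin — with per-base
substitution errors.  Every read carries a truth record (origin genome
or RANDOM, 0-based start, strand, error counts, wrap flag); identical
seeds and inputs give byte-identical FASTQ and truth TSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._dna import decode, encode, random_dna
from .mitoseq_io import AnnotatedMitogenome, MitoseqError, reverse_complement

RANDOM_ORIGIN = "RANDOM"
MAX_QUALITY = 40


@dataclass
class ErrorModel:
    error_rate: float = 0.02        # per-base substitution probability in reads
    mutation_rate: float = 0.001    # per-site haplotype mutation probability
    indel_frac: float = 0.1         # fraction of haplotype mutations that are indels
    indel_ext: float = 0.3          # geometric extension probability of an indel
    random_read_prob: float = 0.05  # probability a read is random DNA
    homopolymer_mode: bool = False  # optional: bias read errors to indels in homopolymers

    def __post_init__(self) -> None:
        for name in ("error_rate", "mutation_rate", "indel_frac", "indel_ext", "random_read_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise MitoseqError(f"ErrorModel.{name} must lie in [0,1], got {v}")

    @property
    def quality(self) -> int:
        if self.error_rate <= 0:
            return MAX_QUALITY
        return min(MAX_QUALITY, round(-10 * math.log10(self.error_rate)))


EXACT_MODEL = ErrorModel(error_rate=0.0, mutation_rate=0.0, random_read_prob=0.0)


@dataclass
class CoveragePlan:
    """Per-genome coverage multipliers: a 10x + 2x ladder or uniform depth."""

    mode: str = "uniform"
    start: float = 10.0
    step: float = 2.0
    depth: float = 40.0

    @classmethod
    def ladder(cls, start: float = 10.0, step: float = 2.0) -> "CoveragePlan":
        return cls(mode="ladder", start=start, step=step)

    @classmethod
    def uniform(cls, depth: float) -> "CoveragePlan":
        return cls(mode="uniform", depth=depth)

    def coverage_for(self, index: int) -> float:
        """Coverage of the (1-based) ``index``-th genome in the pool."""
        cov = (
            self.start + self.step * (index - 1)
            if self.mode == "ladder"
            else self.depth
        )
        if cov <= 0:
            raise MitoseqError(f"coverage must be positive, got {cov}")
        return cov


@dataclass
class TruthRecord:
    read_id: str
    origin: str          # genome id or RANDOM
    start: int           # 0-based on the circular origin haplotype (-1 for RANDOM)
    strand: str          # +/- ('.' for RANDOM)
    n_subs: int          # substitution errors introduced into the read
    n_indels: int        # indel errors introduced into the read
    wrapped: bool        # read spans the origin


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    mate: int = 0        # 0 = unpaired, 1/2 = mate index


@dataclass
class SimulatedReadSet:
    reads: list[SimulatedRead]
    truth: list[TruthRecord]
    quality: int = MAX_QUALITY
    haplotypes: dict[str, AnnotatedMitogenome] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {t.read_id: t for t in self.truth}

    def write_fastq(self, path: str | Path) -> None:
        q = chr(33 + self.quality)
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{q * len(r.sequence)}\n")

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\torigin\tstart\tstrand\tn_subs\tn_indels\twrapped\n")
            for t in self.truth:
                fh.write(
                    f"{t.read_id}\t{t.origin}\t{t.start}\t{t.strand}\t"
                    f"{t.n_subs}\t{t.n_indels}\t{int(t.wrapped)}\n"
                )


# ---------------------------------------------------------------------------
# haplotype mutation
# ---------------------------------------------------------------------------

@dataclass
class MutationEvent:
    kind: str      # sub | ins | del
    position: int  # 0-based on the *reference* genome
    length: int    # 1 for subs, indel length otherwise
    detail: str    # new base for subs, inserted sequence, or deleted sequence


def _geometric_length(rng: np.random.Generator, ext: float, cap: int = 1000) -> int:
    n = 1
    while n < cap and rng.random() < ext:
        n += 1
    return n


def mutate_haplotype(
    genome: AnnotatedMitogenome, model: ErrorModel, seed: int
) -> tuple[AnnotatedMitogenome, list[MutationEvent]]:
    """One mutated haplotype per genome per run, with a full event log.

    Each site mutates with probability ``mutation_rate``; 9/10 of events
    are substitutions (uniform over the 3 alternative bases), 1/10 are
    indels (insertion or deletion, equally likely) with geometric
    length of mean 1/(1 - indel_ext).
    """
    rng = np.random.default_rng(seed)
    if model.mutation_rate == 0:
        return genome, []
    codes = encode(genome.seq)
    L = len(codes)
    sites = np.flatnonzero(rng.random(L) < model.mutation_rate)
    events: list[MutationEvent] = []
    pieces: list[str] = []
    prev = 0
    for pos in sites:
        pos = int(pos)
        pieces.append(genome.seq[prev:pos])
        if rng.random() >= model.indel_frac:  # substitution
            old = int(codes[pos])
            new = (old + int(rng.integers(1, 4))) % 4 if old < 4 else old
            nb = decode(np.array([new])) if old < 4 else genome.seq[pos]
            pieces.append(nb)
            events.append(MutationEvent("sub", pos, 1, nb))
            prev = pos + 1
        elif rng.random() < 0.5:  # insertion before pos
            ln = _geometric_length(rng, model.indel_ext)
            ins = random_dna(rng, ln)
            pieces.append(ins)
            events.append(MutationEvent("ins", pos, ln, ins))
            prev = pos
        else:  # deletion starting at pos
            ln = _geometric_length(rng, model.indel_ext)
            ln = min(ln, L - pos)
            events.append(MutationEvent("del", pos, ln, genome.seq[pos : pos + ln]))
            prev = pos + ln
    pieces.append(genome.seq[prev:])
    seq = "".join(pieces)
    # remap annotations through the cumulative indel offsets
    genes = []
    for g in genome.genes:
        shift_start = sum(
            (e.length if e.kind == "ins" else -min(e.length, max(0, g.start - e.position)))
            for e in events
            if e.kind != "sub" and e.position <= g.start
        )
        new_start = max(0, min(len(seq) - 1, g.start + shift_start))
        genes.append(
            type(g)(name=g.name, start=new_start,
                    end=min(new_start + g.length, new_start + len(seq)),
                    strand=g.strand)
        )
    mutated = AnnotatedMitogenome(
        id=genome.id, seq=seq, circular=genome.circular, genes=genes,
        source=f"{genome.source} (mutated haplotype)",
    )
    return mutated, events


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

def _apply_read_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    codes = encode(seq).astype(np.int64)
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    hit = hit[codes[hit] < 4]
    if hit.size == 0:
        return seq, 0
    codes[hit] = (codes[hit] + rng.integers(1, 4, hit.size)) % 4
    return decode(codes.astype(np.uint8)), int(hit.size)


def _genome_read(
    hap_seq: str, doubled: str, start: int, length: int, strand: str,
    model: ErrorModel, rng: np.random.Generator,
) -> tuple[str, int, bool]:
    L = len(hap_seq)
    frag = doubled[start : start + length]
    if strand == "-":
        frag = reverse_complement(frag)
    seq, n_subs = _apply_read_errors(frag, model.error_rate, rng)
    return seq, n_subs, start + length > L


def simulate_pool(
    genomes,
    coverage_plan: CoveragePlan,
    read_length: int,
    paired: bool = False,
    model: ErrorModel | None = None,
    seed: int = 0,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
) -> SimulatedReadSet:
    """Simulate a pooled sequencing run over several circular genomes.

    Per genome, ceil(coverage x genome_length / read_length) genome-derived
    reads are produced (a pair counts as two); contamination reads are
    additive, occurring with probability ``random_read_prob`` per emitted
    read so genome coverage stays at its nominal value.  All reads from
    all genomes are pooled and shuffled under the seed.
    """
    model = model or ErrorModel()
    genomes = list(genomes)
    if not genomes:
        raise MitoseqError("no genomes to simulate from")
    if read_length > min(len(g) for g in genomes):
        raise MitoseqError("read_length exceeds the shortest genome")
    if paired and insert_mean < read_length:
        raise MitoseqError(
            f"paired reads need insert ({insert_mean}) >= read_length ({read_length})"
        )
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    truth: list[TruthRecord] = []
    haplotypes: dict[str, AnnotatedMitogenome] = {}
    for idx, genome in enumerate(genomes, start=1):
        cov = coverage_plan.coverage_for(idx)
        hap, _events = mutate_haplotype(
            genome, model, seed=int(rng.integers(2**31))
        )
        haplotypes[genome.id] = hap
        L = len(hap)
        doubled = hap.seq + hap.seq
        n_target = math.ceil(cov * L / read_length)
        n_done = 0
        serial = 0
        while n_done < n_target:
            serial += 1
            is_random = rng.random() < model.random_read_prob
            if paired:
                rid = f"{genome.id}_p{serial}"
                if is_random:
                    for mate in (1, 2):
                        reads.append(
                            SimulatedRead(f"{rid}/{mate}", random_dna(rng, read_length), mate)
                        )
                        truth.append(
                            TruthRecord(f"{rid}/{mate}", RANDOM_ORIGIN, -1, ".", 0, 0, False)
                        )
                    continue
                insert = int(round(rng.normal(insert_mean, insert_sd)))
                insert = max(read_length, min(insert, L))
                start = int(rng.integers(0, L))
                strand = "+" if rng.random() < 0.5 else "-"
                s1, e1 = start, start + read_length
                s2 = (start + insert - read_length) % L
                layout = (
                    ((s1, "+"), (s2, "-")) if strand == "+" else ((s2, "-"), (s1, "+"))
                )
                for mate, (s, st) in enumerate(layout, start=1):
                    seq, n_subs, wrapped = _genome_read(
                        hap.seq, doubled, s, read_length, st, model, rng
                    )
                    reads.append(SimulatedRead(f"{rid}/{mate}", seq, mate))
                    truth.append(
                        TruthRecord(f"{rid}/{mate}", genome.id, s, st, n_subs, 0, wrapped)
                    )
                n_done += 2
            else:
                rid = f"{genome.id}_r{serial}"
                if is_random:
                    reads.append(SimulatedRead(rid, random_dna(rng, read_length)))
                    truth.append(TruthRecord(rid, RANDOM_ORIGIN, -1, ".", 0, 0, False))
                    continue
                start = int(rng.integers(0, L))
                strand = "+" if rng.random() < 0.5 else "-"
                seq, n_subs, wrapped = _genome_read(
                    hap.seq, doubled, start, read_length, strand, model, rng
                )
                reads.append(SimulatedRead(rid, seq))
                truth.append(
                    TruthRecord(rid, genome.id, start, strand, n_subs, 0, wrapped)
                )
                n_done += 1
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = [truth[i] for i in order]
    return SimulatedReadSet(
        reads=reads,
        truth=truth,
        quality=model.quality,
        haplotypes=haplotypes,
        params={
            "read_length": read_length,
            "paired": paired,
            "seed": seed,
            "model": model,
            "coverage_plan": coverage_plan,
        },
    )


def exact_reads(
    genome: AnnotatedMitogenome, read_length: int, step: int
) -> SimulatedReadSet:
    """Error-free reads tiling the circle at a fixed step.

    Origin-spanning reads are included; when ``step`` divides the genome
    length every base is covered exactly read_length/step times.
    """
    if read_length > len(genome):
        raise MitoseqError("read_length exceeds genome length")
    if step < 1:
        raise MitoseqError("step must be >= 1")
    L = len(genome)
    doubled = genome.seq + genome.seq
    reads: list[SimulatedRead] = []
    truth: list[TruthRecord] = []
    for i, start in enumerate(range(0, L, step), start=1):
        rid = f"{genome.id}_x{i}"
        reads.append(SimulatedRead(rid, doubled[start : start + read_length]))
        truth.append(
            TruthRecord(rid, genome.id, start, "+", 0, 0, start + read_length > L)
        )
    return SimulatedReadSet(
        reads=reads,
        truth=truth,
        quality=MAX_QUALITY,
        haplotypes={genome.id: genome},
        params={"read_length": read_length, "step": step, "exact": True},
    )


def exact_pool(genomes, read_length: int, step: int, seed: int | None = None) -> SimulatedReadSet:
    """Exact reads for several genomes pooled together (optionally shuffled)."""
    reads: list[SimulatedRead] = []
    truth: list[TruthRecord] = []
    haplotypes = {}
    for g in genomes:
        rs = exact_reads(g, read_length, step)
        reads.extend(rs.reads)
        truth.extend(rs.truth)
        haplotypes[g.id] = g
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(reads))
        reads = [reads[i] for i in order]
        truth = [truth[i] for i in order]
    return SimulatedReadSet(
        reads=reads, truth=truth, quality=MAX_QUALITY, haplotypes=haplotypes,
        params={"read_length": read_length, "step": step, "exact": True},
    )
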