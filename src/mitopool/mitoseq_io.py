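"""Sequence and annotation I/O for circular mitochondrial genomes.

Coordinates are 0-based half-open throughout.  Annotation files in GFF3
(1-based inclusive) are converted on read.  Genomes are circular by
default; features may wrap the origin, in which case ``end`` exceeds the
genome length (never by more than one full revolution).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("mitopool")

DNA_ALPHABET = set("ACGTN")
GAP = "-"


class MitoseqError(Exception):
    """Base error for the toolkit."""


class FastaParseError(MitoseqError):
    """Malformed FASTA content; message names the offending line."""


@dataclass
class GeneAnnotation:
    """A gene interval on a (possibly circular) genome.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``end`` may exceed
    the genome length to denote an origin-spanning feature.
    """

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise MitoseqError(
                f"gene {self.name}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in "+-":
            raise MitoseqError(f"gene {self.name}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedMitogenome:
    """A DNA sequence with gene annotations, circular unless stated otherwise."""

    id: str
    seq: str
    circular: bool = True
    genes: list[GeneAnnotation] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise MitoseqError(f"genome {self.id}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise MitoseqError(
                f"genome {self.id}: characters outside A/C/G/T/N: {sorted(bad)}"
            )
        L = len(self.seq)
        norm = []
        for g in self.genes:
            start = g.start % L
            end = start + g.length
            if g.length > L:
                raise MitoseqError(
                    f"genome {self.id}: gene {g.name} longer than genome"
                )
            norm.append(replace(g, start=start, end=end))
        self.genes = norm
        if sum(1 for g in self.genes if g.name == "COI") > 1:
            raise MitoseqError(f"genome {self.id}: more than one COI annotation")

    def __len__(self) -> int:
        return len(self.seq)

    def gene(self, name: str) -> GeneAnnotation | None:
        for g in self.genes:
            if g.name == name:
                return g
        return None

    @property
    def coi(self) -> GeneAnnotation | None:
        return self.gene("COI")

    def gene_seq(self, name: str) -> str:
        """Sequence of a named gene in reading orientation (revcomp on '-')."""
        g = self.gene(name)
        if g is None:
            raise MitoseqError(f"genome {self.id}: no annotation named {name}")
        s = slice_circular(self, g.start, g.end)
        return reverse_complement(s) if g.strand == "-" else s


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | Path, alignment: bool = False) -> list[AnnotatedMitogenome]:
    """Read FASTA records as (unannotated) genomes.

    Sequences are upper-cased.  Gap characters are stripped unless
    ``alignment`` is set, in which case they are preserved (used when the
    caller is loading pre-aligned pairs; note that gapped records are not
    valid AnnotatedMitogenome sequences and are returned as raw tuples by
    :func:`read_alignment_fasta` instead).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("no FASTA records found in %s", path)
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
        return []
    genomes = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not alignment:
            seq = seq.replace(GAP, "")
        bad = set(seq) - DNA_ALPHABET - {GAP}
        if bad:
            lineno = _find_bad_line(path, bad)
            raise FastaParseError(
                f"{path}, line {lineno}: invalid sequence characters {sorted(bad)}"
            )
        genomes.append(
            AnnotatedMitogenome(id=rec.id, seq=seq, source=str(path))
        )
    return genomes


def read_alignment_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA as (id, gapped row) pairs, validated and upper-cased."""
    path = Path(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        row = str(rec.seq).upper()
        bad = set(row) - DNA_ALPHABET - {GAP}
        if bad:
            lineno = _find_bad_line(path, bad)
            raise FastaParseError(
                f"{path}, line {lineno}: invalid sequence characters {sorted(bad)}"
            )
        out.append((rec.id, row))
    return out


def _find_bad_line(path: Path, bad: set[str]) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return i
    return 0


def write_fasta(genomes, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            gid, seq = (g.id, g.seq) if hasattr(g, "seq") else g
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotations: GFF3 (1-based inclusive) or minimal 5-column TSV
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[str, list[GeneAnnotation]]:
    """Read gene annotations, keyed by genome id.

    Accepts GFF3 (detected by a ``##gff`` pragma or 9 tab-separated
    columns) or a minimal TSV with columns id, name, start, end, strand
    (start/end 1-based inclusive in both formats, converted to 0-based
    half-open).
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    is_gff = any(ln.startswith("##gff") for ln in lines) or (
        lines and not lines[0].startswith("#") and len(lines[0].split("\t")) == 9
    )
    if is_gff:
        return _read_gff3(path)
    out: dict[str, list[GeneAnnotation]] = {}
    for ln in lines:
        if ln.startswith("#"):
            continue
        cols = ln.split("\t")
        if len(cols) != 5:
            raise FastaParseError(f"{path}: expected 5 TSV columns, got {len(cols)}")
        seqid, name, start, end, strand = cols
        out.setdefault(seqid, []).append(
            GeneAnnotation(name=name, start=int(start) - 1, end=int(end), strand=strand)
        )
    return out


def _read_gff3(path: Path) -> dict[str, list[GeneAnnotation]]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FastaParseError(f"{path}: malformed GFF3: {exc}") from exc
    out: dict[str, list[GeneAnnotation]] = {}
    for feat in db.all_features():
        name = feat.attributes.get("Name", feat.attributes.get("gene", [feat.id]))[0]
        out.setdefault(feat.seqid, []).append(
            GeneAnnotation(
                name=name, start=feat.start - 1, end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    return out


def write_annotations(genomes, path: str | Path) -> None:
    """Write the minimal 5-column TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for g in genomes:
            for a in g.genes:
                fh.write(f"{g.id}\t{a.name}\t{a.start + 1}\t{a.end}\t{a.strand}\n")


def attach_annotations(genomes, annotations) -> None:
    """Attach annotations read by :func:`read_annotations`, in place."""
    for g in genomes:
        if g.id in annotations:
            g.genes = annotations[g.id]
            g.__post_init__()


# ---------------------------------------------------------------------------
# circular coordinate handling
# ---------------------------------------------------------------------------

def slice_circular(genome: AnnotatedMitogenome | str, start: int, end: int) -> str:
    """seq[start:end] with wrap-around past the origin.

    ``end - start`` may not exceed one full revolution.
    """
    seq = genome if isinstance(genome, str) else genome.seq
    L = len(seq)
    if not 0 <= start < L:
        raise MitoseqError(f"start {start} outside [0, {L})")
    if end <= start:
        raise MitoseqError("end must exceed start")
    if end - start > L:
        raise MitoseqError("slice cannot exceed one full revolution")
    return (seq + seq)[start:end]


def rotate(genome: AnnotatedMitogenome, offset: int) -> AnnotatedMitogenome:
    """Rotate a circular genome so position ``offset`` becomes position 0."""
    L = len(genome)
    offset %= L
    seq = genome.seq[offset:] + genome.seq[:offset]
    genes = [
        replace(g, start=(g.start - offset) % L, end=(g.start - offset) % L + g.length)
        for g in genome.genes
    ]
    return AnnotatedMitogenome(
        id=genome.id, seq=seq, circular=genome.circular, genes=genes,
        source=genome.source,
    )


def reverse_complement_genome(genome: AnnotatedMitogenome) -> AnnotatedMitogenome:
    L = len(genome)
    seq = reverse_complement(genome.seq)
    genes = []
    for g in genome.genes:
        # feature occupying [start, end) maps to [L - end, L - start) on the
        # reverse strand; origin-spanning features keep their length
        new_start = (L - g.end) % L
        genes.append(
            replace(
                g,
                start=new_start,
                end=new_start + g.length,
                strand="-" if g.strand == "+" else "+",
            )
        )
    return AnnotatedMitogenome(
        id=genome.id, seq=seq, circular=genome.circular, genes=genes,
        source=genome.source,
    )


def linearize_at_coi(genome: AnnotatedMitogenome) -> AnnotatedMitogenome:
    """Rotate (and reorient) a circular genome so COI starts at position 0.

    If COI is annotated on the minus strand the genome is
    reverse-complemented first, so the returned genome carries COI at
    position 0 on the plus strand.  Length is preserved.
    """
    coi = genome.coi
    if coi is None:
        raise MitoseqError(
            f"genome {genome.id}: no COI annotation; rotate manually or annotate COI"
        )
    if not genome.circular:
        raise MitoseqError(f"genome {genome.id}: cannot rotate a linear genome")
    g = reverse_complement_genome(genome) if coi.strand == "-" else genome
    return rotate(g, g.coi.start)
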