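"""Synthetic annotated mitogenome families at controlled divergence.

A random ancestral mitogenome is built from a metazoan-style region
layout (13 protein-coding genes with a 1,545 bp COI first, 2 rRNAs,
22 interleaved tRNAs and a control region, ~15.6 kb in total), then
descendant specimens are drawn on a star phylogeny by placing an exact
per-region number of substitutions — so the realized divergence from
the ancestor is a constant, not an expectation.  Region classes mutate
at different relative rates (control region fastest, rRNAs slowest),
giving the conserved/variable mosaic that sliding-window screening of
real mitogenomes has to contend with.

None of the rate multipliers are biological estimates; they are
configuration reproducing the qualitative conservation ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dna import decode, random_dna
from . import divergence as dv
from .mitoseq_io import AnnotatedMitogenome, GeneAnnotation, MitoseqError

DEFAULT_RATE_MULTIPLIERS = {"PCG": 1.0, "rRNA": 0.3, "tRNA": 0.5, "CR": 2.0}
MAX_TARGET = 0.35
MAX_REGION_P = 0.75


@dataclass
class Region:
    name: str
    length: int
    cls: str  # PCG | rRNA | tRNA | CR

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise MitoseqError(f"region {self.name}: length must be positive")
        if self.cls not in DEFAULT_RATE_MULTIPLIERS:
            raise MitoseqError(f"region {self.name}: unknown class {self.cls}")


def _vertebrate_like_layout() -> list[Region]:
    pcg = {
        "COI": 1545, "COII": 684, "ATP8": 165, "ATP6": 678, "COIII": 783,
        "ND3": 345, "ND4L": 294, "ND4": 1299, "ND5": 1554, "ND6": 519,
        "CYTB": 1137, "ND1": 954, "ND2": 1035,
    }
    trna_names = [
        "S1", "D", "K", "G", "R", "H", "S2", "L1", "E", "T", "P",
        "F", "V", "L2", "I", "Q", "M", "W", "A", "N2", "C", "Y",
    ]
    t = iter(trna_names)

    def trna(n):
        return [Region(f"trn{next(t)}", 68, "tRNA") for _ in range(n)]

    regions = [Region("COI", pcg["COI"], "PCG")]
    regions += trna(2)
    regions += [Region(n, pcg[n], "PCG") for n in ("COII", "ATP8", "ATP6", "COIII")]
    regions += trna(2)
    regions += [Region(n, pcg[n], "PCG") for n in ("ND3", "ND4L", "ND4")]
    regions += trna(3)
    regions += [Region("ND5", pcg["ND5"], "PCG"), Region("ND6", pcg["ND6"], "PCG")]
    regions += trna(2)
    regions += [Region("CYTB", pcg["CYTB"], "PCG")]
    regions += trna(3)
    regions += [Region("CR", 800, "CR")]
    regions += trna(2)
    regions += [Region("12S", 810, "rRNA")]
    regions += trna(1)
    regions += [Region("16S", 1480, "rRNA")]
    regions += trna(2)
    regions += [Region("ND1", pcg["ND1"], "PCG")]
    regions += trna(3)
    regions += [Region("ND2", pcg["ND2"], "PCG")]
    regions += trna(2)
    return regions


@dataclass
class RegionModel:
    layout: list[Region] = field(default_factory=_vertebrate_like_layout)
    rate_multiplier: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RATE_MULTIPLIERS)
    )

    def __post_init__(self) -> None:
        if not any(r.name == "COI" for r in self.layout):
            raise MitoseqError("layout must include a COI region")
        if any(m <= 0 for m in self.rate_multiplier.values()):
            raise MitoseqError("rate multipliers must be positive")

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.layout)

    @property
    def weighted_mean_multiplier(self) -> float:
        return (
            sum(r.length * self.rate_multiplier[r.cls] for r in self.layout)
            / self.total_length
        )

    def offsets(self) -> list[int]:
        off, out = 0, []
        for r in self.layout:
            out.append(off)
            off += r.length
        return out


@dataclass
class FamilySpec:
    n_taxa: int
    target_divergence: float  # genome-wide mean p vs. the ancestor, per taxon
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise MitoseqError("n_taxa must be >= 1")
        if not 0 <= self.target_divergence <= MAX_TARGET:
            raise MitoseqError(
                f"target_divergence must lie in [0, {MAX_TARGET}]"
            )


# ---------------------------------------------------------------------------

def make_ancestor(
    region_model: RegionModel | None = None, seed: int = 0, max_tries: int = 50
) -> AnnotatedMitogenome:
    """Uniform-random annotated circular genome over the region layout.

    Seeds whose genome repeats a 31-mer are rejected and redrawn (with a
    derived sub-seed), so downstream k=31 assembly of a single genome is
    repeat-free by construction.
    """
    from .assembly_baseline import count_kmers

    model = region_model or RegionModel()
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        seq = random_dna(rng, model.total_length)
        _, counts = count_kmers([seq], 31)
        if counts.size and counts.max() == 1:
            genes = [
                GeneAnnotation(r.name, off, off + r.length, "+")
                for r, off in zip(model.layout, model.offsets())
            ]
            return AnnotatedMitogenome(
                id=f"ancestor_s{seed}", seq=seq, circular=True, genes=genes,
                source="synthetic ancestor",
            )
    raise MitoseqError("could not draw a 31-mer-repeat-free ancestor")


def _folmer_span(model: RegionModel) -> tuple[int, int]:
    off = dict(zip((r.name for r in model.layout), model.offsets()))
    coi = off["COI"]
    return coi + dv.FOLMER_START, coi + dv.FOLMER_END


def evolve(
    ancestor: AnnotatedMitogenome,
    target_divergence: float,
    region_model: RegionModel | None = None,
    indel_rate: float = 0.0,
    seed: int = 0,
    taxon_id: str | None = None,
) -> AnnotatedMitogenome:
    """One descendant with an exact per-region substitution count.

    Per region, round(length x target x multiplier / weighted-mean
    multiplier) sites are drawn without replacement and changed to a
    different base, so the realized p-distance to the ancestor is exact
    before indels.  Short indels (1-10 bp, geometric) are then placed at
    ``indel_rate`` per site — never inside the Folmer COI window, so the
    barcode proxy stays well defined.
    """
    model = region_model or RegionModel()
    if model.total_length != len(ancestor):
        raise MitoseqError("region model does not match ancestor length")
    rng = np.random.default_rng(seed)
    wmean = model.weighted_mean_multiplier
    codes = np.array(
        ["ACGT".index(c) for c in ancestor.seq], dtype=np.int64
    )
    for r, off in zip(model.layout, model.offsets()):
        region_p = target_divergence * model.rate_multiplier[r.cls] / wmean
        if region_p > MAX_REGION_P:
            raise MitoseqError(
                f"region {r.name}: implied p {region_p:.2f} exceeds {MAX_REGION_P}"
            )
        n_subs = round(r.length * region_p)
        if n_subs == 0:
            continue
        sites = off + rng.choice(r.length, n_subs, replace=False)
        codes[sites] = (codes[sites] + rng.integers(1, 4, n_subs)) % 4
    seq = decode(codes.astype(np.uint8))
    genes = [
        GeneAnnotation(g.name, g.start, g.end, g.strand) for g in ancestor.genes
    ]
    if indel_rate > 0:
        seq, genes = _apply_indels(seq, genes, model, indel_rate, rng)
    return AnnotatedMitogenome(
        id=taxon_id or f"{ancestor.id}_d{seed}", seq=seq, circular=True,
        genes=genes, source=f"evolved from {ancestor.id} at target {target_divergence}",
    )


def _apply_indels(seq, genes, model, indel_rate, rng):
    L = len(seq)
    f_lo, f_hi = _folmer_span(model)
    n = rng.binomial(L, indel_rate)
    positions = sorted(
        (int(p) for p in rng.integers(0, L, n) if not f_lo <= p < f_hi),
        reverse=True,
    )
    for pos in positions:
        ln = int(min(10, rng.geometric(0.5)))
        if rng.random() < 0.5:  # insertion
            seq = seq[:pos] + random_dna(rng, ln) + seq[pos:]
            delta, cut = ln, 0
        else:  # deletion
            ln = min(ln, len(seq) - pos)
            seq = seq[:pos] + seq[pos + ln:]
            delta, cut = -ln, ln
        out = []
        for g in genes:
            start, end = g.start, g.end
            if pos < start:
                start, end = start + delta, end + delta
            elif pos < end:
                end = max(start + 1, end + delta) if delta < 0 else end + delta
            out.append(GeneAnnotation(g.name, max(0, start), max(1, end), g.strand))
        genes = out
    return seq, genes


def expected_pairwise_p(target: float) -> float:
    """Expected leaf-to-leaf p on a star phylogeny.

    A site differs between two leaves unless neither branch touched it
    ((1-t)^2) or both did and landed on the same base (t^2/3), giving
    p = 2t(1 - 2t/3).
    """
    return 2 * target * (1 - 2 * target / 3)


def make_family(
    spec: FamilySpec, region_model: RegionModel | None = None
) -> tuple[list[AnnotatedMitogenome], pd.DataFrame]:
    """Independent descendants of one ancestor (star phylogeny).

    Returns the genomes and a truth table of measured pairwise Folmer
    proxies alongside the star-doubling expectation.
    """
    model = region_model or RegionModel()
    rng = np.random.default_rng(spec.seed)
    ancestor = make_ancestor(model, seed=int(rng.integers(2**31)))
    genomes = [
        evolve(
            ancestor,
            spec.target_divergence,
            model,
            indel_rate=spec.indel_rate,
            seed=int(rng.integers(2**31)),
            taxon_id=f"taxon{i + 1:02d}",
        )
        for i in range(spec.n_taxa)
    ]
    rows = []
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            rows.append(
                {
                    "idA": genomes[i].id,
                    "idB": genomes[j].id,
                    "folmer_proxy": dv.folmer_proxy(genomes[i], genomes[j]),
                    # COI is a PCG region; its branch divergence is the target
                    # scaled by the PCG multiplier over the weighted mean
                    "expected_pairwise_p": expected_pairwise_p(
                        spec.target_divergence
                        * model.rate_multiplier["PCG"]
                        / model.weighted_mean_multiplier
                    ),
                }
            )
    return genomes, pd.DataFrame(rows)
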