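"""Pairwise p-distances, the Folmer COI proxy and sliding-window profiles.

The p-distance is the fraction of differing sites among comparable
columns (both rows in A/C/G/T — pairwise deletion of gaps and N).  The
Folmer proxy is the p-distance over COI positions 50-700 (1-based
inclusive, i.e. the ~651 bp 5' barcode fragment), used to decide whether
two specimens diverge enough to be pooled without tags.

Full-genome pairs are aligned by chaining unique shared k-mers as
anchors and closing the inter-anchor gaps with an affine-gap global
aligner (match +1, mismatch -1, gap open -4 for the first gapped column,
-1 for each further column).  Externally produced alignments are
accepted anywhere a :class:`PairwiseAlignment` is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .mitoseq_io import AnnotatedMitogenome, MitoseqError

NW_MATCH = 1.0
NW_MISMATCH = -1.0
NW_GAP_OPEN = -4.0   # cost of the first column of a gap run
NW_GAP_EXTEND = -1.0  # cost of each subsequent column
ANCHOR_K = 15
MAX_FILL = 5000

FOLMER_START = 49   # 0-based; paper's position 50, 1-based inclusive
FOLMER_END = 700    # exclusive; paper's position 700 inclusive


class AlignmentError(MitoseqError):
    pass


@dataclass
class PairwiseAlignment:
    idA: str
    idB: str
    rowA: str
    rowB: str
    method: str = "external"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rowA) != len(self.rowB):
            raise AlignmentError(
                f"{self.idA}/{self.idB}: rows differ in length "
                f"({len(self.rowA)} vs {len(self.rowB)})"
            )

    def __len__(self) -> int:
        return len(self.rowA)

    def score(self) -> float:
        """Alignment score under the toolkit's fixed scoring scheme."""
        a = np.frombuffer(self.rowA.encode(), dtype="S1")
        b = np.frombuffer(self.rowB.encode(), dtype="S1")
        gap = b"-"
        ga, gb = a == gap, b == gap
        aligned = ~ga & ~gb
        score = NW_MATCH * int(((a == b) & aligned).sum())
        score += NW_MISMATCH * int(((a != b) & aligned).sum())
        for g in (ga, gb):
            idx = np.flatnonzero(g)
            if idx.size:
                runs = 1 + int((np.diff(idx) > 1).sum())
                score += NW_GAP_OPEN * runs + NW_GAP_EXTEND * (idx.size - runs)
        return score


@dataclass
class DivergenceProfile:
    """Per-window p-distances along one pairwise alignment."""

    idA: str
    idB: str
    window_length: int
    step: int
    window_starts: list[int]
    p: list[float | None]
    comparable: list[int]
    low_info: list[bool]

    def __len__(self) -> int:
        return len(self.window_starts)

    def to_rows(self):
        """(window_start, p, comparable, low_info) tuples for TSV output."""
        return list(zip(self.window_starts, self.p, self.comparable, self.low_info))


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

_ACGT = frozenset(b"ACGT")


def _masks(aln: PairwiseAlignment) -> tuple[np.ndarray, np.ndarray]:
    """(comparable, mismatch-and-comparable) boolean masks per column."""
    a = np.frombuffer(aln.rowA.encode(), dtype=np.uint8)
    b = np.frombuffer(aln.rowB.encode(), dtype=np.uint8)
    ok = np.isin(a, list(_ACGT)) & np.isin(b, list(_ACGT))
    return ok, ok & (a != b)


def p_distance(
    aln: PairwiseAlignment, col_range: tuple[int, int] | None = None
) -> tuple[float | None, int]:
    """(p, comparable) over all columns or a half-open column range.

    ``p`` is None when no column is comparable (pairwise deletion leaves
    nothing to score).
    """
    ok, mm = _masks(aln)
    if col_range is not None:
        lo, hi = col_range
        if not (0 <= lo < hi <= len(aln)):
            raise AlignmentError(f"column range {col_range} outside alignment")
        ok, mm = ok[lo:hi], mm[lo:hi]
    comparable = int(ok.sum())
    if comparable == 0:
        return None, 0
    return int(mm.sum()) / comparable, comparable


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = NW_MATCH
    al.mismatch_score = NW_MISMATCH
    al.open_gap_score = NW_GAP_OPEN
    al.extend_gap_score = NW_GAP_EXTEND
    return al


def align_global(
    seqA: str, seqB: str, idA: str = "A", idB: str = "B"
) -> PairwiseAlignment:
    """Affine-gap Needleman-Wunsch global alignment (no anchoring)."""
    if not seqA or not seqB:
        rowA = seqA or "-" * len(seqB)
        rowB = seqB or "-" * len(seqA)
        return PairwiseAlignment(idA, idB, rowA, rowB, method="global")
    aln = _aligner().align(seqA, seqB)[0]
    return PairwiseAlignment(idA, idB, str(aln[0]), str(aln[1]), method="global")


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _chain_anchors(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain with strictly increasing positions in both sequences."""
    anchors = sorted(anchors)
    if not anchors:
        return []
    posB = [b for _, b in anchors]
    # patience LIS on posB (strictly increasing), O(n log n)
    import bisect

    tails: list[int] = []
    tidx: list[int] = []
    parent = [-1] * len(anchors)
    for i, b in enumerate(posB):
        j = bisect.bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            tidx.append(i)
        else:
            tails[j] = b
            tidx[j] = i
        parent[i] = tidx[j - 1] if j > 0 else -1
    chain = []
    i = tidx[len(tails) - 1]
    while i != -1:
        chain.append(anchors[i])
        i = parent[i]
    return chain[::-1]


def align_anchored(
    seqA: str,
    seqB: str,
    idA: str = "A",
    idB: str = "B",
    k: int = ANCHOR_K,
    max_fill: int = MAX_FILL,
) -> PairwiseAlignment:
    """Global alignment via unique shared k-mer anchors plus NW gap filling.

    Raises :class:`AlignmentError` when fewer than 3 collinear anchors
    exist (sequences too divergent — supply an external alignment) or an
    inter-anchor gap exceeds ``max_fill`` columns.
    """
    ua, ub = _unique_kmer_positions(seqA, k), _unique_kmer_positions(seqB, k)
    shared = set(ua) & set(ub)
    chain = _chain_anchors([(ua[km], ub[km]) for km in shared])
    # drop anchors overlapping their predecessor's k-mer footprint
    filtered: list[tuple[int, int]] = []
    for a, b in chain:
        if filtered and (a < filtered[-1][0] + k or b < filtered[-1][1] + k):
            continue
        filtered.append((a, b))
    if len(filtered) < 3:
        raise AlignmentError(
            f"{idA}/{idB}: fewer than 3 collinear anchors; sequences too "
            "divergent for anchored alignment; supply external alignment"
        )
    rowA_parts: list[str] = []
    rowB_parts: list[str] = []
    prevA = prevB = 0
    for a, b in filtered + [(len(seqA), len(seqB))]:
        fa, fb = seqA[prevA:a], seqB[prevB:b]
        if len(fa) > max_fill or len(fb) > max_fill:
            raise AlignmentError(
                f"{idA}/{idB}: inter-anchor gap of {max(len(fa), len(fb))} "
                f"columns exceeds {max_fill}"
            )
        if fa or fb:
            sub = align_global(fa, fb)
            rowA_parts.append(sub.rowA)
            rowB_parts.append(sub.rowB)
        if (a, b) != (len(seqA), len(seqB)):
            rowA_parts.append(seqA[a : a + k])
            rowB_parts.append(seqB[b : b + k])
            prevA, prevB = a + k, b + k
    return PairwiseAlignment(
        idA,
        idB,
        "".join(rowA_parts),
        "".join(rowB_parts),
        method="anchored",
        params={
            "k": k,
            "match": NW_MATCH,
            "mismatch": NW_MISMATCH,
            "gap_open": NW_GAP_OPEN,
            "gap_extend": NW_GAP_EXTEND,
        },
    )


# ---------------------------------------------------------------------------
# Folmer proxy
# ---------------------------------------------------------------------------

def folmer_fragment(genome: AnnotatedMitogenome) -> str:
    """COI positions 50-700 (1-based inclusive) in reading orientation."""
    coi = genome.coi
    if coi is None:
        raise MitoseqError(f"genome {genome.id}: no COI annotation")
    gene = genome.gene_seq("COI")
    if len(gene) < FOLMER_END:
        warnings.warn(
            f"genome {genome.id}: COI is {len(gene)} bp (<{FOLMER_END}); "
            "using the available overlap of the Folmer fragment",
            stacklevel=2,
        )
    if len(gene) <= FOLMER_START:
        raise MitoseqError(
            f"genome {genome.id}: COI too short ({len(gene)} bp) for the Folmer fragment"
        )
    return gene[FOLMER_START : min(FOLMER_END, len(gene))]


def folmer_proxy(
    genomeA: AnnotatedMitogenome, genomeB: AnnotatedMitogenome
) -> float | None:
    """p-distance between the two genomes' Folmer COI fragments."""
    fa, fb = folmer_fragment(genomeA), folmer_fragment(genomeB)
    aln = align_global(fa, fb, genomeA.id, genomeB.id)
    p, _ = p_distance(aln)
    return p


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def sliding_profile(
    aln: PairwiseAlignment,
    window_length: int,
    step: int,
    min_comparable_frac: float = 0.5,
) -> DivergenceProfile:
    """Per-window p-distances along an alignment.

    A window is flagged ``low_info`` when fewer than
    ``min_comparable_frac x window_length`` of its columns are comparable
    — typically because one row is a long deletion — so a spuriously low
    p in such a window is never mistaken for true similarity.
    """
    L = len(aln)
    if window_length > L:
        raise AlignmentError(
            f"window_length {window_length} exceeds alignment length {L}"
        )
    if step < 1:
        raise AlignmentError("step must be >= 1")
    ok, mm = _masks(aln)
    cs_ok = np.concatenate([[0], np.cumsum(ok)])
    cs_mm = np.concatenate([[0], np.cumsum(mm)])
    n_windows = (L - window_length) // step + 1
    starts = [i * step for i in range(n_windows)]
    ps: list[float | None] = []
    comp: list[int] = []
    low: list[bool] = []
    min_comp = min_comparable_frac * window_length
    for s in starts:
        e = s + window_length
        c = int(cs_ok[e] - cs_ok[s])
        m = int(cs_mm[e] - cs_mm[s])
        flagged = c < min_comp
        low.append(flagged)
        comp.append(c)
        ps.append(None if flagged or c == 0 else m / c)
    return DivergenceProfile(
        aln.idA, aln.idB, window_length, step, starts, ps, comp, low
    )


def min_window_divergence(profile: DivergenceProfile) -> float | None:
    """Minimum window p over informative windows; None if all are flagged."""
    vals = [p for p, flag in zip(profile.p, profile.low_info) if not flag and p is not None]
    return min(vals) if vals else None


def profile_pair(
    genomeA: AnnotatedMitogenome,
    genomeB: AnnotatedMitogenome,
    window_length: int = 450,
    step: int = 45,
    min_comparable_frac: float = 0.5,
) -> DivergenceProfile:
    """Anchored full-genome alignment followed by a sliding-window profile."""
    aln = align_anchored(genomeA.seq, genomeB.seq, genomeA.id, genomeB.id)
    return sliding_profile(aln, window_length, step, min_comparable_frac)
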