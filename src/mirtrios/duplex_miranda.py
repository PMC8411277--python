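"""miRNA:DNA duplex scanning with a miRanda-style scoring scheme.

The miRNA is read 3'->5' against the target DNA read 5'->3' (antiparallel
duplex geometry) and the best local complementarity alignment is found by
dynamic programming.  Watson-Crick pairs score +5, G:U wobbles (read as G:T /
U:G on the DNA) +1, mismatches -3, gaps -9 to open and -4 to extend.  Columns
pairing miRNA positions 2-8 from the 5' end carry a 4x seed weight.  Hits
must reach the score threshold (default 140) and, when the simple stacking
energy model is enabled, an energy at or below the energy threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .sequence_io import (
    EnhancerRegion,
    MatureMiRNA,
    SequenceError,
    reverse_complement,
)
from .seed_needle import DuplexHit

ENERGY_NONE = "none"
ENERGY_SIMPLE_STACK = "simple_stack"

PLUS = "+"
MINUS = "-"


@dataclass(frozen=True)
class DuplexScanParams:
    match_score: float = 5.0
    wobble_score: float = 1.0
    mismatch_score: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_scale: float = 4.0
    seed_start: int = 2   # 1-based miRNA position, inclusive
    seed_end: int = 8     # inclusive
    score_threshold: float = 140.0
    energy_threshold: float = -1.0
    energy_model: str = ENERGY_SIMPLE_STACK

    def __post_init__(self) -> None:
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be positive")
        if self.seed_scale < 1:
            raise ValueError("seed_scale must be >= 1")


# RNA base (miRNA) vs DNA base (target): Watson-Crick and wobble pairs
_WC_PAIRS = {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "T"), ("U", "G")}


def pair_type(rna_base: str, dna_base: str) -> str:
    if (rna_base, dna_base) in _WC_PAIRS:
        return "wc"
    if (rna_base, dna_base) in _WOBBLE_PAIRS:
        return "wobble"
    return "mismatch"


@dataclass(frozen=True)
class DuplexAlignment:
    """Best local duplex between one miRNA and one target string.

    ``pairs`` maps 0-based miRNA positions (5'->3' on the original sequence)
    to 0-based target positions for every aligned non-gap column.
    """

    score: float
    mirna_start: int
    mirna_end: int
    target_start: int
    target_end: int
    pairs: tuple[tuple[int, int], ...]


_NEG_INF = float("-inf")


def duplex_align(mirna_seq: str, target: str,
                 params: DuplexScanParams = DuplexScanParams()) -> DuplexAlignment:
    """Best-scoring local complementarity alignment (Smith-Waterman with
    affine gaps) of the miRNA, read 3'->5', against the target, read 5'->3'.

    Deterministic: ties resolve to the earliest (target, then miRNA) end
    position and to substitution over gap moves during traceback.
    """
    if not mirna_seq or not target:
        raise SequenceError("cannot align empty sequence")
    rna = mirna_seq.upper().replace("T", "U")
    bad = set(rna) - set("ACGUN")
    if bad:
        raise SequenceError(f"invalid miRNA characters {sorted(bad)}")
    dna = target.upper()
    bad = set(dna) - set("ACGTN")
    if bad:
        raise SequenceError(f"invalid target characters {sorted(bad)}")

    L = len(rna)
    rev = rna[::-1]  # rev[i] is miRNA position L-1-i (0-based from 5' end)
    n, m = len(rev), len(dna)

    def col_score(i: int, j: int) -> float:
        """Score of aligning rev[i-1] with dna[j-1] (1-based DP indices)."""
        rb, db = rev[i - 1], dna[j - 1]
        pos_5p = L - i + 1  # 1-based position from the miRNA 5' end
        pt = pair_type(rb, db)
        if pt == "wc":
            s = params.match_score
        elif pt == "wobble":
            s = params.wobble_score
        else:
            s = params.mismatch_score
        if params.seed_start <= pos_5p <= params.seed_end:
            s *= params.seed_scale
        return s

    # H: best local alignment score ending at (i, j); E: ending with a gap in
    # the miRNA (consumes target); F: ending with a gap in the target.
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    F = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    best_score, best_i, best_j = 0.0, 0, 0
    for i in range(1, n + 1):
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            Ei[j] = max(Hi[j - 1] + params.gap_open, Ei[j - 1] + params.gap_extend)
            Fi[j] = max(Hi1[j] + params.gap_open, Fi1[j] + params.gap_extend)
            h = Hi1[j - 1] + col_score(i, j)
            if Ei[j] > h:
                h = Ei[j]
            if Fi[j] > h:
                h = Fi[j]
            if h < 0.0:
                h = 0.0
            Hi[j] = h
            if h > best_score:
                best_score, best_i, best_j = h, i, j

    if best_score <= 0:
        return DuplexAlignment(0.0, 0, 0, 0, 0, ())

    # traceback from (best_i, best_j); substitution preferred over gap moves
    pairs: list[tuple[int, int]] = []
    i, j = best_i, best_j
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if _eq(H[i][j], 0.0):
                break
            if _eq(H[i][j], H[i - 1][j - 1] + col_score(i, j)):
                pairs.append((L - i, j - 1))  # original-miRNA coordinate
                i, j = i - 1, j - 1
            elif _eq(H[i][j], E[i][j]):
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if _eq(E[i][j], H[i][j - 1] + params.gap_open):
                state = "H"
            j -= 1
        else:
            if _eq(F[i][j], H[i - 1][j] + params.gap_open):
                state = "H"
            i -= 1

    pairs.reverse()
    mir_positions = [p for p, _ in pairs]
    tgt_positions = [t for _, t in pairs]
    return DuplexAlignment(
        score=best_score,
        mirna_start=min(mir_positions),
        mirna_end=max(mir_positions) + 1,
        target_start=min(tgt_positions),
        target_end=max(tgt_positions) + 1,
        pairs=tuple(pairs),
    )


def _eq(a: float, b: float, tol: float = 1e-9) -> bool:
    return abs(a - b) <= tol


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

# Simplified nearest-neighbor stack table for an RNA:DNA hybrid, keyed by the
# 5'->3' dinucleotide on the RNA strand of two stacked Watson-Crick pairs.
# Values are kcal/mol, loosely following hybrid duplex averages; all negative
# so adding pairs can only stabilize.
_STACK_TABLE = {
    "AA": -1.0, "AC": -2.1, "AG": -1.8, "AU": -0.9,
    "CA": -0.9, "CC": -2.1, "CG": -1.7, "CU": -0.9,
    "GA": -1.3, "GC": -2.7, "GG": -2.9, "GU": -1.1,
    "UA": -0.6, "UC": -1.5, "UG": -1.6, "UU": -0.2,
}
_WOBBLE_STACK_PENALTY = 0.5  # wobble-containing stacks are this much weaker


def estimate_duplex_energy(alignment: DuplexAlignment,
                           mirna_seq: str, target: str) -> float:
    """Nearest-neighbor stack sum over adjacent paired columns (kcal/mol).

    Not a thermodynamic folding energy: a deliberately simple, monotone
    stand-in (adding a Watson-Crick pair never raises the energy).
    """
    rna = mirna_seq.upper().replace("T", "U")
    dna = target.upper()
    energy = 0.0
    pairs = alignment.pairs
    for (p1, t1), (p2, t2) in zip(pairs, pairs[1:]):
        if abs(p1 - p2) != 1 or abs(t1 - t2) != 1:
            continue  # not a contiguous stack
        pt1 = pair_type(rna[p1], dna[t1])
        pt2 = pair_type(rna[p2], dna[t2])
        if "mismatch" in (pt1, pt2):
            continue
        lo, hi = min(p1, p2), max(p1, p2)
        stack = _STACK_TABLE[rna[lo] + rna[hi]]
        if "wobble" in (pt1, pt2):
            stack = min(0.0, stack + _WOBBLE_STACK_PENALTY)
        energy += stack
    return energy


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_miranda(mirnas: Sequence[MatureMiRNA],
                   enhancers: Sequence[EnhancerRegion],
                   params: DuplexScanParams = DuplexScanParams()) -> list[DuplexHit]:
    """Best qualifying duplex per (mature miRNA, enhancer).

    Both the + strand and the reverse complement of each enhancer are
    scanned; hit coordinates are always reported on the + strand.
    """
    hits: list[DuplexHit] = []
    for enhancer in enhancers:
        if not enhancer.seq:
            raise SequenceError(
                f"enhancer {enhancer.enhancer_id} has no sequence attached"
            )
        strands = {PLUS: enhancer.seq, MINUS: reverse_complement(enhancer.seq)}
        n = len(enhancer.seq)
        for mirna in mirnas:
            best: DuplexHit | None = None
            for strand in (PLUS, MINUS):
                aln = duplex_align(mirna.mature_seq, strands[strand], params)
                if aln.score < params.score_threshold:
                    continue
                if params.energy_model != ENERGY_NONE:
                    energy = estimate_duplex_energy(
                        aln, mirna.mature_seq, strands[strand])
                    if energy > params.energy_threshold:
                        continue
                else:
                    energy = None
                if strand == PLUS:
                    start, end = aln.target_start, aln.target_end
                else:
                    start, end = n - aln.target_end, n - aln.target_start
                hit = DuplexHit(
                    mirna_mature_name=mirna.mature_name,
                    mirna_family=mirna.family_name,
                    enhancer_id=enhancer.enhancer_id,
                    site_start=start,
                    site_end=end,
                    method="miranda",
                    score=aln.score,
                    orientation=strand,
                    energy=energy,
                )
                if best is None or (hit.score, -hit.site_start) > \
                        (best.score, -best.site_start):
                    best = hit
            if best is not None:
                hits.append(best)
    hits.sort(key=lambda h: (h.enhancer_id, h.mirna_mature_name, h.site_start))
    return hits
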