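"""Seed-anchored duplex detection.

An enhancer is a candidate only if it contains an exact occurrence of a seed
(forward or reverse-complement form).  Each seed site is extended by 14 bp on
the side where the rest of the mature miRNA would lie, the full mature
sequence is globally aligned to that window with affine gap penalties, and
hits are kept when percent identity exceeds a strict threshold (default 50).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .sequence_io import (
    EnhancerRegion,
    MatureMiRNA,
    SequenceError,
    reverse_complement,
)

FORWARD = "forward"
REVERSE_COMPLEMENT = "reverse_complement"

#: bp of flanking enhancer sequence added beyond the seed site so the window
#: can host the full mature miRNA (typical mature length = 7 nt seed + 14).
EXTENSION_BP = 14

DEFAULT_PI_THRESHOLD = 50.0


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap global alignment parameters (DNA aligner defaults)."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0   # positive penalty
    gap_extend: float = 0.5  # positive penalty, per gap column


@dataclass(frozen=True)
class SeedMatch:
    mirna: MatureMiRNA
    enhancer_id: str
    offset: int
    orientation: str  # FORWARD | REVERSE_COMPLEMENT


@dataclass(frozen=True)
class AlignmentResult:
    aligned_mirna: str
    aligned_target: str
    score: float
    matches: int
    alignment_length: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.alignment_length


@dataclass(frozen=True)
class DuplexHit:
    """One predicted miRNA:enhancer binding event."""

    mirna_mature_name: str
    mirna_family: str
    enhancer_id: str
    site_start: int
    site_end: int
    method: str  # "seed_needle" | "miranda"
    score: float
    orientation: str = FORWARD
    percent_identity: float | None = None
    energy: float | None = None


# ---------------------------------------------------------------------------
# seed scanning
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return
        yield pos
        start = pos + 1  # overlapping occurrences kept


def scan_seed(enhancer: EnhancerRegion, mirna: MatureMiRNA) -> list[SeedMatch]:
    """All exact occurrences of either seed form, sorted by offset."""
    if not enhancer.seq:
        raise SequenceError(f"enhancer {enhancer.enhancer_id} has no sequence attached")
    if mirna.seed_fwd is None or mirna.seed_rc is None:
        raise SequenceError(f"{mirna.mature_name} has no seed sequences")
    if len(mirna.seed_fwd) < 4:
        raise SequenceError("seed shorter than 4 nt would match everywhere")

    matches = [
        SeedMatch(mirna, enhancer.enhancer_id, pos, FORWARD)
        for pos in _find_all(enhancer.seq, mirna.seed_fwd)
    ]
    if mirna.seed_rc != mirna.seed_fwd:
        matches += [
            SeedMatch(mirna, enhancer.enhancer_id, pos, REVERSE_COMPLEMENT)
            for pos in _find_all(enhancer.seq, mirna.seed_rc)
        ]
    matches.sort(key=lambda m: (m.offset, m.orientation))
    return matches


def extension_window(match: SeedMatch, seed_len: int, enhancer_len: int,
                     extension: int = EXTENSION_BP) -> tuple[int, int]:
    """Enhancer slice to align the mature miRNA against.

    Forward-seed sites extend downstream (3' of the site); reverse-complement
    sites extend upstream.  Clipped to the enhancer bounds.
    """
    if match.orientation == FORWARD:
        start = match.offset
        end = match.offset + seed_len + extension
    else:
        start = match.offset - extension
        end = match.offset + seed_len
    return max(0, start), min(enhancer_len, end)


# ---------------------------------------------------------------------------
# affine-gap global alignment (Gotoh, deterministic traceback)
# ---------------------------------------------------------------------------

_DIAG, _UP, _LEFT = 0, 1, 2
_NEG_INF = float("-inf")


def global_align(query: str, target: str,
                 params: AlignParams = AlignParams()) -> AlignmentResult:
    """Optimal global alignment with affine gaps.

    A gap of length k costs ``gap_open + k * gap_extend``.  Traceback ties
    prefer diagonal, then up (gap in target), then left (gap in query).
    N never matches anything, including itself.
    """
    for s in (query, target):
        if not s:
            raise SequenceError("cannot align empty sequence")
        bad = set(s) - set("ACGTN")
        if bad:
            raise SequenceError(f"invalid characters {sorted(bad)} for DNA alignment")

    n, m = len(query), len(target)
    open_cost = params.gap_open + params.gap_extend  # cost of a 1-column gap
    ext = params.gap_extend

    # M: query[i-1] aligned to target[j-1]; X: gap in target (consume query);
    # Y: gap in query (consume target).
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(params.gap_open + i * ext)
    for j in range(1, m + 1):
        Y[0][j] = -(params.gap_open + j * ext)

    for i in range(1, n + 1):
        qi = query[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi, Yi1 = Y[i], Y[i - 1]
        for j in range(1, m + 1):
            sub = params.match if (qi == target[j - 1] and qi != "N") else params.mismatch
            Mi[j] = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]) + sub
            Xi[j] = max(Mi1[j] - open_cost, Xi1[j] - ext, Yi1[j] - open_cost)
            Yi[j] = max(Mi[j - 1] - open_cost, Yi[j - 1] - ext, Xi[j - 1] - open_cost)

    # traceback: prefer M (diagonal), then X (up), then Y (left)
    i, j = n, m
    finals = (M[n][m], X[n][m], Y[n][m])
    score = max(finals)
    state = finals.index(score)
    aq: list[str] = []
    at: list[str] = []
    while i > 0 or j > 0:
        if state == _DIAG:
            aq.append(query[i - 1])
            at.append(target[j - 1])
            prev = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            sub = params.match if (query[i - 1] == target[j - 1] and query[i - 1] != "N") \
                else params.mismatch
            state = _best_prev(prev, M[i][j] - sub)
            i, j = i - 1, j - 1
        elif state == _UP:
            aq.append(query[i - 1])
            at.append("-")
            target_val = X[i][j]
            prev = (M[i - 1][j] - open_cost, X[i - 1][j] - ext, Y[i - 1][j] - open_cost)
            state = _best_prev(prev, target_val)
            i -= 1
        else:
            aq.append("-")
            at.append(target[j - 1])
            target_val = Y[i][j]
            prev = (M[i][j - 1] - open_cost, Y[i][j - 1] - ext, X[i][j - 1] - open_cost)
            # prev order here is (M, Y, X): remap to states
            if _close(prev[0], target_val):
                state = _DIAG
            elif _close(prev[2], target_val):
                state = _UP
            else:
                state = _LEFT
            j -= 1
        if i == 0 and j > 0:
            state = _LEFT
        elif j == 0 and i > 0:
            state = _UP

    aligned_q = "".join(reversed(aq))
    aligned_t = "".join(reversed(at))
    matches = sum(
        1 for a, b in zip(aligned_q, aligned_t) if a == b and a not in "-N"
    )
    return AlignmentResult(
        aligned_mirna=aligned_q,
        aligned_target=aligned_t,
        score=score,
        matches=matches,
        alignment_length=len(aligned_q),
    )


def _close(a: float, b: float, tol: float = 1e-9) -> bool:
    return abs(a - b) <= tol


def _best_prev(prev: tuple[float, float, float], target_val: float) -> int:
    for state, val in enumerate(prev):
        if _close(val, target_val):
            return state
    # numeric slack: fall back to argmax
    return max(range(3), key=lambda s: prev[s])


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def align_site(match: SeedMatch, enhancer: EnhancerRegion,
               params: AlignParams = AlignParams()) -> tuple[AlignmentResult, int, int]:
    """Align the full mature miRNA (as DNA, target-strand oriented) to the
    extension window of a seed match.  Returns (alignment, win_start, win_end)."""
    seed_len = len(match.mirna.seed_fwd)
    start, end = extension_window(match, seed_len, len(enhancer.seq))
    window = enhancer.seq[start:end]
    mature = match.mirna.mature_dna
    if match.orientation == REVERSE_COMPLEMENT:
        mature = reverse_complement(mature)
    return global_align(mature, window, params), start, end


def detect_seed_needle(mirnas: Sequence[MatureMiRNA],
                       enhancers: Sequence[EnhancerRegion],
                       pi_threshold: float = DEFAULT_PI_THRESHOLD,
                       params: AlignParams = AlignParams()) -> list[DuplexHit]:
    """One best hit (max PI, then smallest site_start) per (mature, enhancer)
    among seed-anchored sites whose percent identity is strictly above the
    threshold."""
    best: dict[tuple[str, str], DuplexHit] = {}
    for enhancer in enhancers:
        for mirna in mirnas:
            for match in scan_seed(enhancer, mirna):
                aln, start, end = align_site(match, enhancer, params)
                pi = aln.percent_identity
                if pi <= pi_threshold:
                    continue
                hit = DuplexHit(
                    mirna_mature_name=mirna.mature_name,
                    mirna_family=mirna.family_name,
                    enhancer_id=enhancer.enhancer_id,
                    site_start=start,
                    site_end=end,
                    method="seed_needle",
                    score=aln.score,
                    orientation=match.orientation,
                    percent_identity=pi,
                )
                key = (mirna.mature_name, enhancer.enhancer_id)
                prev = best.get(key)
                if prev is None or (hit.percent_identity, -hit.site_start) > \
                        (prev.percent_identity, -prev.site_start):
                    best[key] = hit
    return sorted(
        best.values(),
        key=lambda h: (h.enhancer_id, h.mirna_mature_name, h.site_start),
    )
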