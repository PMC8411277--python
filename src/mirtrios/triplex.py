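"""RNA:DNA:DNA triplex site search between miRNAs and enhancer duplexes.

A triplex-forming window of the miRNA (TFO) lies in the major groove of a
purine-rich stretch of the enhancer duplex (TTS).  The DNA duplex is
represented by its candidate purine strand; both enhancer strands are tried
in that role, with TTS coordinates always reported on the + strand.  Three
canonical Hoogsteen motifs are searched:

* parallel pyrimidine: U.A:T and C.G:C (TFO scanned 5'->3')
* antiparallel purine: A.A:T and G.G:C (TFO scanned 3'->5')
* mixed G/T:           G.G:C and U.A:T (TFO scanned 5'->3')

Windows of length >= ``min_length`` whose invalid-position fraction is at
most ``max_error_rate`` and whose purine-strand guanine fraction reaches
``min_guanine_rate`` qualify; by default only windows not contained in a
longer qualifying window on the same diagonal/motif/strand are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sequence_io import (
    EnhancerRegion,
    MatureMiRNA,
    SequenceError,
    reverse_complement,
)

PARALLEL_PYRIMIDINE = "parallel_pyrimidine"
ANTIPARALLEL_PURINE = "antiparallel_purine"
MIXED_GT = "mixed_GT"
ALL_MOTIFS = (PARALLEL_PYRIMIDINE, ANTIPARALLEL_PURINE, MIXED_GT)

MAXIMAL_ONLY = "maximal_only"
ALL_HITS = "all"

#: RNA base over purine-strand base -> valid Hoogsteen triplet, per motif
_VALID_TRIPLETS = {
    PARALLEL_PYRIMIDINE: {("U", "A"), ("C", "G")},
    ANTIPARALLEL_PURINE: {("A", "A"), ("G", "G")},
    MIXED_GT: {("G", "G"), ("U", "A")},
}

#: antiparallel motifs scan the TFO 3'->5' against the purine strand
_ANTIPARALLEL = {ANTIPARALLEL_PURINE}


@dataclass(frozen=True)
class TriplexParams:
    max_error_rate: float = 0.19
    min_length: int = 11
    motifs: tuple[str, ...] = ALL_MOTIFS
    min_guanine_rate: float = 0.1
    merge_overlaps: str = MAXIMAL_ONLY

    def __post_init__(self) -> None:
        if self.min_length < 5:
            raise ValueError("min_length must be >= 5")
        if not (0 <= self.max_error_rate < 0.5):
            raise ValueError("max_error_rate must be in [0, 0.5)")
        unknown = set(self.motifs) - set(ALL_MOTIFS)
        if unknown:
            raise ValueError(f"unknown motifs: {sorted(unknown)}")


@dataclass(frozen=True)
class TriplexHit:
    mirna_mature_name: str
    mirna_family: str
    enhancer_id: str
    tfo_start: int
    tfo_end: int
    tts_start: int
    tts_end: int
    motif: str
    strand: str  # which enhancer strand served as the purine strand
    length: int
    errors: int

    @property
    def error_rate(self) -> float:
        return self.errors / self.length


def position_valid(rna_base: str, purine_strand_base: str, motif: str) -> bool:
    """Canonical Hoogsteen triplet validity for one aligned position."""
    if motif not in _VALID_TRIPLETS:
        raise ValueError(f"unknown motif {motif!r}")
    return (rna_base, purine_strand_base) in _VALID_TRIPLETS[motif]


def _validity_matrix(rna: str, purine: str, motif: str) -> np.ndarray:
    """Boolean matrix V[i, j]: rna[i] over purine[j] is a valid triplet."""
    triplets = _VALID_TRIPLETS[motif]
    rna_arr = np.frombuffer(rna.encode(), dtype="S1")
    pur_arr = np.frombuffer(purine.encode(), dtype="S1")
    V = np.zeros((len(rna), len(purine)), dtype=bool)
    for rb, pb in triplets:
        V |= (rna_arr[:, None] == rb.encode()) & (pur_arr[None, :] == pb.encode())
    return V


def find_triplexes(mirna: MatureMiRNA, enhancer: EnhancerRegion,
                   params: TriplexParams = TriplexParams()) -> list[TriplexHit]:
    """All qualifying triplex windows between one miRNA and one enhancer.

    Output is sorted by (tts_start, length desc, motif, strand).
    """
    if not enhancer.seq:
        raise SequenceError(f"enhancer {enhancer.enhancer_id} has no sequence attached")
    rna = mirna.mature_seq
    plus = enhancer.seq
    minus = reverse_complement(plus)
    n = len(plus)
    L_rna = len(rna)

    hits: list[TriplexHit] = []
    for motif in params.motifs:
        antiparallel = motif in _ANTIPARALLEL
        tfo = rna[::-1] if antiparallel else rna
        for strand, purine in ((("+"), plus), (("-"), minus)):
            V = _validity_matrix(tfo, purine, motif)
            G = np.frombuffer(purine.encode(), dtype="S1") == b"G"
            for win in _qualifying_windows(V, G, params):
                tfo_off, tts_off, length, errors = win
                if antiparallel:
                    tfo_start = L_rna - (tfo_off + length)
                else:
                    tfo_start = tfo_off
                if strand == "+":
                    tts_start = tts_off
                else:
                    tts_start = n - (tts_off + length)
                hits.append(TriplexHit(
                    mirna_mature_name=mirna.mature_name,
                    mirna_family=mirna.family_name,
                    enhancer_id=enhancer.enhancer_id,
                    tfo_start=tfo_start,
                    tfo_end=tfo_start + length,
                    tts_start=tts_start,
                    tts_end=tts_start + length,
                    motif=motif,
                    strand=strand,
                    length=length,
                    errors=errors,
                ))
    hits.sort(key=lambda h: (h.tts_start, -h.length, h.motif, h.strand, h.tfo_start))
    return hits


def _qualifying_windows(V: np.ndarray, guanine: np.ndarray,
                        params: TriplexParams) -> list[tuple[int, int, int, int]]:
    """Enumerate qualifying (tfo_offset, tts_offset, length, errors) windows.

    Works diagonal by diagonal on the validity matrix; a cheap feasibility
    bound skips diagonals that cannot host a qualifying window.
    """
    m, n = V.shape
    min_len = params.min_length
    max_err = params.max_error_rate
    min_g = params.min_guanine_rate
    maximal_only = params.merge_overlaps == MAXIMAL_ONLY

    out: list[tuple[int, int, int, int]] = []
    for d in range(-(m - 1), n):  # tts_offset - tfo_offset along the diagonal
        diag = np.diagonal(V, offset=d)
        K = diag.size
        if K < min_len:
            continue
        # need at least ceil(min_len * (1 - max_err)) valid positions
        if int(diag.sum()) < min_len - int(max_err * min_len):
            continue
        tfo0 = max(0, -d)
        tts0 = max(0, d)
        g_diag = guanine[tts0:tts0 + K]
        err_prefix = np.concatenate(([0], np.cumsum(~diag)))
        g_prefix = np.concatenate(([0], np.cumsum(g_diag)))

        windows: list[tuple[int, int, int]] = []  # (start-in-diag, length, errors)
        for start in range(K - min_len + 1):
            for length in range(min_len, K - start + 1):
                errors = int(err_prefix[start + length] - err_prefix[start])
                if errors > max_err * length:
                    continue
                g_count = int(g_prefix[start + length] - g_prefix[start])
                if g_count < min_g * length:
                    continue
                windows.append((start, length, errors))
        if maximal_only:
            windows = [
                w for w in windows
                if not any(
                    o is not w and o[1] > w[1] and o[0] <= w[0]
                    and o[0] + o[1] >= w[0] + w[1]
                    for o in windows
                )
            ]
        out.extend((tfo0 + s, tts0 + s, ln, e) for s, ln, e in windows)
    return out


def detect_triplexator(mirnas: Sequence[MatureMiRNA],
                       enhancers: Sequence[EnhancerRegion],
                       params: TriplexParams = TriplexParams(),
                       ) -> tuple[list[TriplexHit], list[TriplexHit]]:
    """Scan all pairs; returns (best hit per miRNA-enhancer pair, full list).

    "Best" is longest, then lowest error rate, then smallest tts_start; the
    full list is kept for audit output.
    """
    all_hits: list[TriplexHit] = []
    best: dict[tuple[str, str], TriplexHit] = {}
    for enhancer in sorted(enhancers, key=lambda e: e.enhancer_id):
        for mirna in mirnas:
            for hit in find_triplexes(mirna, enhancer, params):
                all_hits.append(hit)
                key = (hit.mirna_mature_name, hit.enhancer_id)
                prev = best.get(key)
                if prev is None or (hit.length, -hit.error_rate, -hit.tts_start) > \
                        (prev.length, -prev.error_rate, -prev.tts_start):
                    best[key] = hit
    deduped = sorted(
        best.values(),
        key=lambda h: (h.enhancer_id, h.mirna_mature_name, h.tts_start),
    )
    return deduped, all_hits
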