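"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written from first principles and deliberately shares no
code with the package: alignment scores come from enumerating gap blocks,
seed scanning from a character-by-character substring check, triplex hits
from naive window enumeration, and the statistics from textbook formulas.
"""

from __future__ import annotations

import math
from functools import lru_cache

from scipy.stats import t as t_dist


# ---------------------------------------------------------------------------
# affine-gap global alignment (gap-block recursion)
# ---------------------------------------------------------------------------

def global_affine_score(query: str, target: str, match: float = 5.0,
                        mismatch: float = -4.0, gap_open: float = 10.0,
                        gap_extend: float = 0.5) -> float:
    """Optimal global score where a gap of length k costs open + k*extend.

    An alignment is a sequence of atomic moves: one substitution column, or a
    whole gap block of length k in either sequence.  Enumerated recursively
    over suffixes (memoized); structurally unrelated to the Gotoh DP.
    """
    n, m = len(query), len(target)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == n and j == m:
            return 0.0
        options = []
        if i < n and j < m:
            s = match if (query[i] == target[j] and query[i] != "N") else mismatch
            options.append(s + best(i + 1, j + 1))
        for k in range(1, n - i + 1):  # gap block in target (consume query)
            options.append(-(gap_open + k * gap_extend) + best(i + k, j))
        for k in range(1, m - j + 1):  # gap block in query (consume target)
            options.append(-(gap_open + k * gap_extend) + best(i, j + k))
        return max(options)

    return best(0, 0)


def enumerate_global_alignments(query: str, target: str):
    """Yield every gapped global alignment as (aligned_query, aligned_target).

    Exponential; only for very short inputs.
    """
    def rec(i, j, aq, at):
        if i == len(query) and j == len(target):
            yield aq, at
            return
        if i < len(query) and j < len(target):
            yield from rec(i + 1, j + 1, aq + query[i], at + target[j])
        if i < len(query):
            yield from rec(i + 1, j, aq + query[i], at + "-")
        if j < len(target):
            yield from rec(i, j + 1, aq + "-", at + target[j])

    yield from rec(0, 0, "", "")


def score_alignment(aq: str, at: str, match=5.0, mismatch=-4.0,
                    gap_open=10.0, gap_extend=0.5) -> float:
    """Score one explicit alignment under the affine model."""
    score = 0.0
    gap_len_q = gap_len_t = 0
    for a, b in zip(aq, at):
        if a == "-":
            gap_len_q += 1
            if gap_len_t:
                score -= gap_open + gap_len_t * gap_extend
                gap_len_t = 0
        elif b == "-":
            gap_len_t += 1
            if gap_len_q:
                score -= gap_open + gap_len_q * gap_extend
                gap_len_q = 0
        else:
            for g in (gap_len_q, gap_len_t):
                if g:
                    score -= gap_open + g * gap_extend
            gap_len_q = gap_len_t = 0
            score += match if (a == b and a != "N") else mismatch
    for g in (gap_len_q, gap_len_t):
        if g:
            score -= gap_open + g * gap_extend
    return score


# ---------------------------------------------------------------------------
# seed scanning
# ---------------------------------------------------------------------------

def naive_substring_positions(haystack: str, needle: str) -> list[int]:
    out = []
    for i in range(len(haystack) - len(needle) + 1):
        if all(haystack[i + k] == needle[k] for k in range(len(needle))):
            out.append(i)
    return out


def naive_revcomp(seq: str) -> str:
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# miRanda-style local duplex (exhaustive path enumeration)
# ---------------------------------------------------------------------------

_WC = {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("U", "G")}


def local_duplex_best_score(rna: str, dna: str, match=5.0, wobble=1.0,
                            mismatch=-3.0, gap_open=-9.0, gap_extend=-4.0,
                            seed_scale=4.0, seed_start=2, seed_end=8) -> float:
    """Best local complementarity score, miRNA read 3'->5' vs target 5'->3'.

    Enumerates every alignment path that starts and ends on a paired column
    (gaps strictly inside); optimal alignments have this shape because gap
    scores are negative.  Exponential; inputs must stay tiny.
    """
    rna = rna.replace("T", "U")
    L = len(rna)
    rev = rna[::-1]

    def col(i: int, j: int) -> float:
        rb, db = rev[i], dna[j]
        if (rb, db) in _WC:
            s = match
        elif (rb, db) in _WOBBLE:
            s = wobble
        else:
            s = mismatch
        pos_5p = L - i  # 1-based from the miRNA 5' end
        if seed_start <= pos_5p <= seed_end:
            s *= seed_scale
        return s

    best = 0.0

    def rec(i: int, j: int, score: float, last_was_pair: bool,
            gap_state: str | None) -> None:
        nonlocal best
        if last_was_pair and score > best:
            best = score
        if i >= len(rev) or j >= len(dna):
            return
        rec(i + 1, j + 1, score + col(i, j), True, None)
        # gap in target: consume miRNA
        cost = gap_extend if gap_state == "q" else gap_open
        rec(i + 1, j, score + cost, False, "q")
        cost = gap_extend if gap_state == "t" else gap_open
        rec(i, j + 1, score + cost, False, "t")

    for i in range(len(rev)):
        for j in range(len(dna)):
            rec(i, j, 0.0, False, None)
    return best


# ---------------------------------------------------------------------------
# triplex windows
# ---------------------------------------------------------------------------

HOOGSTEEN_TABLE = {
    "parallel_pyrimidine": {("U", "A"), ("C", "G")},
    "antiparallel_purine": {("A", "A"), ("G", "G")},
    "mixed_GT": {("G", "G"), ("U", "A")},
}


def naive_triplex_windows(rna: str, enhancer: str, motif: str,
                          max_error_rate: float, min_length: int,
                          min_guanine_rate: float,
                          maximal_only: bool = True):
    """All qualifying (tfo_start, tts_start, length, errors, strand) tuples.

    Naive: walks every strand/diagonal/window explicitly, counting errors
    incrementally, and applies the containment filter pairwise.
    """
    valid_set = HOOGSTEEN_TABLE[motif]
    antiparallel = motif == "antiparallel_purine"
    tfo = rna[::-1] if antiparallel else rna
    n = len(enhancer)
    results = []
    for strand in ("+", "-"):
        purine = enhancer if strand == "+" else naive_revcomp(enhancer)
        per_diagonal: dict[int, list] = {}
        for tfo_off in range(len(tfo)):
            for tts_off in range(len(purine)):
                max_len = min(len(tfo) - tfo_off, len(purine) - tts_off)
                errors = 0
                g_count = 0
                for length in range(1, max_len + 1):
                    rb = tfo[tfo_off + length - 1]
                    pb = purine[tts_off + length - 1]
                    if (rb, pb) not in valid_set:
                        errors += 1
                    if pb == "G":
                        g_count += 1
                    if length < min_length:
                        continue
                    if errors > max_error_rate * length:
                        continue
                    if g_count < min_guanine_rate * length:
                        continue
                    per_diagonal.setdefault(tts_off - tfo_off, []).append(
                        (tfo_off, tts_off, length, errors))
        for diag_windows in per_diagonal.values():
            if maximal_only:
                diag_windows = [
                    w for w in diag_windows
                    if not any(
                        o != w and o[2] > w[2]
                        and o[0] <= w[0] and o[0] + o[2] >= w[0] + w[2]
                        for o in diag_windows
                    )
                ]
            for tfo_off, tts_off, length, errors in diag_windows:
                if antiparallel:
                    tfo_start = len(rna) - (tfo_off + length)
                else:
                    tfo_start = tfo_off
                if strand == "+":
                    tts_start = tts_off
                else:
                    tts_start = n - (tts_off + length)
                results.append((tfo_start, tts_start, length, errors, strand))
    return sorted(results)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def average_ranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # 1-based average rank of the tied block
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> tuple[float, float]:
    """Pearson on average ranks; two-sided t p-value with n-2 df."""
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    rho = cov / math.sqrt(vx * vy)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * t_dist.sf(abs(t), df=n - 2)
    return rho, p


def bh_oracle(p_values) -> list[float]:
    """Textbook BH step-up: p_adj(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    for rank_pos, idx in enumerate(order, start=1):
        adj[idx] = min(
            min(m * p_values[order[j - 1]] / j for j in range(rank_pos, m + 1)),
            1.0,
        )
    return adj


# ---------------------------------------------------------------------------
# consensus set algebra
# ---------------------------------------------------------------------------

def consensus_duplex_oracle(needle_a, needle_b, miranda_a, miranda_b,
                            links, scc_rescue=0.8, min_genes=2):
    """Brute-force evaluation of the duplex consensus rules.

    Trios are (mirna, gene, enhancer, scc) tuples; links are (enhancer, gene)
    pairs.  Returns the kept (mirna, gene, enhancer) key set.
    """
    every = [("na", t) for t in needle_a] + [("nb", t) for t in needle_b] + \
            [("ma", t) for t in miranda_a] + [("mb", t) for t in miranda_b]
    genes_per_enh: dict[str, set[str]] = {}
    for enh, gene in links:
        genes_per_enh.setdefault(enh, set()).add(gene)

    kept = set()
    for _, (mir, gene, enh, scc) in every:
        by_needle = any((m, e) == (mir, enh)
                        for src, (m, g, e, _) in every if src in ("na", "nb"))
        by_miranda = any((m, e) == (mir, enh)
                         for src, (m, g, e, _) in every if src in ("ma", "mb"))
        in_a = any((m, g) == (mir, gene)
                   for src, (m, g, e, _) in every if src in ("na", "ma"))
        in_b = any((m, g) == (mir, gene)
                   for src, (m, g, e, _) in every if src in ("nb", "mb"))
        multi = len(genes_per_enh.get(enh, set())) >= min_genes
        if (by_needle and by_miranda and multi and in_a and in_b) \
                or scc >= scc_rescue:
            kept.add((mir, gene, enh))
    return kept


def consensus_triplex_oracle(trios_a, trios_b, links, min_genes=2):
    genes_per_enh: dict[str, set[str]] = {}
    for enh, gene in links:
        genes_per_enh.setdefault(enh, set()).add(gene)
    keys_b = {(m, g, e) for m, g, e, _ in trios_b}
    return {
        (m, g, e) for m, g, e, _ in trios_a
        if (m, g, e) in keys_b and len(genes_per_enh.get(e, set())) >= min_genes
    }
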