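"""From interaction hits to the final miRNA-enhancer-gene trio table.

Hits are expanded through the enhancer:gene link table, each candidate is
scored by the Spearman correlation between the miRNA family's expression and
the gene's expression, p-values are Benjamini-Hochberg adjusted within each
miRNA family's candidate set, and trios passing FDR (default 0.05) with a
positive correlation are written as ``mir_enh_gene_trios.tsv``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sequence_io import EnhancerGeneLink, ExpressionTable
from .seed_needle import DuplexHit
from .triplex import TriplexHit

logger = logging.getLogger(__name__)

METHOD_SEED_NEEDLE = "seed_needle"
METHOD_MIRANDA = "miranda"
METHOD_TRIPLEXATOR = "triplexator"

TRIO_FILENAME = "mir_enh_gene_trios.tsv"

_TINY = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class TrioCandidate:
    mature_mirna: str
    mirna_family: str
    gene_name: str
    enhancer_id: str
    method: str
    pi: float | None = None


@dataclass(frozen=True)
class TrioRecord:
    mature_mirna: str
    gene_name: str
    enhancer_id: str
    scc: float
    p_raw: float
    p_adj: float
    method: str
    pi: float | None = None


def hits_to_candidates(hits: Sequence[DuplexHit | TriplexHit],
                       links: Sequence[EnhancerGeneLink],
                       ) -> tuple[list[TrioCandidate], int]:
    """Cartesian expansion of each hit over the genes linked to its enhancer.

    Returns (candidates, number of hits on enhancers absent from the link
    table).  Hits are assumed deduplicated to one per miRNA-enhancer pair.
    """
    genes_of: dict[str, list[str]] = {}
    for link in links:
        genes_of.setdefault(link.enhancer_id, []).append(link.gene_name)

    candidates: list[TrioCandidate] = []
    seen: set[tuple[str, str, str, str]] = set()
    unlinked = 0
    for hit in hits:
        genes = genes_of.get(hit.enhancer_id)
        if genes is None:
            unlinked += 1
            continue
        if isinstance(hit, TriplexHit):
            method, pi = METHOD_TRIPLEXATOR, None
        else:
            method, pi = hit.method, hit.percent_identity
        for gene in genes:
            key = (hit.mirna_mature_name, gene, hit.enhancer_id, method)
            if key in seen:
                continue
            seen.add(key)
            candidates.append(TrioCandidate(
                mature_mirna=hit.mirna_mature_name,
                mirna_family=hit.mirna_family,
                gene_name=gene,
                enhancer_id=hit.enhancer_id,
                method=method,
                pi=pi,
            ))
    if unlinked:
        logger.info("%d hit(s) on enhancers absent from the link table", unlinked)
    return candidates, unlinked


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks) with a two-sided t-approximation p-value.

    Perfect correlation (|rho| == 1) maps to the smallest positive float
    rather than an exact zero p-value.  Zero variance raises ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance vector: rho undefined")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    p = float(p)
    if abs(rho) >= 1.0 - 1e-12:
        p = _TINY
    return rho, max(p, _TINY)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Standard Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bh_adjust_per_mirna(families: Sequence[str],
                        p_raw: Sequence[float]) -> np.ndarray:
    """BH within each miRNA family's candidate group.

    m for each group is the number of candidate gene pairs of that family.
    """
    families = list(families)
    p = np.asarray(p_raw, dtype=float)
    adj = np.empty_like(p)
    groups: dict[str, list[int]] = {}
    for idx, fam in enumerate(families):
        groups.setdefault(fam, []).append(idx)
    for idxs in groups.values():
        adj[idxs] = bh_adjust(p[idxs])
    return adj


def assemble_trios(candidates: Sequence[TrioCandidate],
                   mirna_expr: ExpressionTable,
                   gene_expr: ExpressionTable,
                   fdr: float = 0.05,
                   positive_only: bool = True) -> list[TrioRecord]:
    """Score candidates, adjust per family, and keep trios with p_adj < fdr
    (and positive correlation when ``positive_only``)."""
    scored: list[tuple[TrioCandidate, float, float]] = []
    for cand in candidates:
        if cand.mirna_family not in mirna_expr:
            logger.warning("miRNA %s missing from expression table; dropped",
                           cand.mirna_family)
            continue
        if cand.gene_name not in gene_expr:
            logger.warning("gene %s missing from expression table; dropped",
                           cand.gene_name)
            continue
        try:
            rho, p = spearman(mirna_expr.row(cand.mirna_family),
                              gene_expr.row(cand.gene_name))
        except ValueError as exc:
            logger.warning("candidate %s/%s dropped: %s",
                           cand.mirna_family, cand.gene_name, exc)
            continue
        scored.append((cand, rho, p))

    if not scored:
        return []

    p_adj = bh_adjust_per_mirna(
        [c.mirna_family for c, _, _ in scored],
        [p for _, _, p in scored],
    )
    records: list[TrioRecord] = []
    for (cand, rho, p), padj in zip(scored, p_adj):
        if padj >= fdr:
            continue
        if positive_only and rho <= 0:
            continue
        records.append(TrioRecord(
            mature_mirna=cand.mature_mirna,
            gene_name=cand.gene_name,
            enhancer_id=cand.enhancer_id,
            scc=rho,
            p_raw=p,
            p_adj=float(padj),
            method=cand.method,
            pi=cand.pi,
        ))
    records.sort(key=lambda r: (r.p_adj, r.mature_mirna, r.gene_name, r.enhancer_id))
    return records


# ---------------------------------------------------------------------------
# trio table I/O
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ["mature_mirna", "Gene.Name", "enhancer",
                 "corr (miRNA, gene)", "p.value adj"]


def write_trios(records: Sequence[TrioRecord], path: str | os.PathLike,
                with_pi: bool | None = None) -> None:
    """Write the trio TSV.  The PI column is appended only for seed-anchored
    runs (auto-detected from the records unless ``with_pi`` is forced)."""
    if with_pi is None:
        with_pi = any(r.method == METHOD_SEED_NEEDLE for r in records)
    columns = _BASE_COLUMNS + (["PI"] if with_pi else [])
    rows = []
    for r in records:
        row = [r.mature_mirna, r.gene_name, r.enhancer_id,
               _fmt(r.scc), _fmt(r.p_adj)]
        if with_pi:
            row.append(_fmt(r.pi) if r.pi is not None else "NA")
        rows.append(row)
    with open(path, "w") as handle:
        handle.write("\t".join(columns) + "\n")
        for row in rows:
            handle.write("\t".join(row) + "\n")


def _fmt(value: float) -> str:
    return format(value, ".6g")


def read_trios(path: str | os.PathLike, method: str = "unknown") -> list[TrioRecord]:
    """Read a trio TSV back (p_raw is not stored; set equal to p_adj)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        pi = None
        if "PI" in df.columns and pd.notna(row["PI"]) and row["PI"] != "NA":
            pi = float(row["PI"])
        records.append(TrioRecord(
            mature_mirna=str(row["mature_mirna"]),
            gene_name=str(row["Gene.Name"]),
            enhancer_id=str(row["enhancer"]),
            scc=float(row["corr (miRNA, gene)"]),
            p_raw=float(row["p.value adj"]),
            p_adj=float(row["p.value adj"]),
            method=method,
            pi=pi,
        ))
    return records


def write_hits_audit(hits: Iterable[DuplexHit], path: str | os.PathLike) -> None:
    """Intermediate duplex hits as TSV for auditing."""
    with open(path, "w") as handle:
        handle.write("mature_mirna\tenhancer\tsite_start\tsite_end\t"
                     "orientation\tscore\tPI\tenergy\n")
        for h in hits:
            pi = _fmt(h.percent_identity) if h.percent_identity is not None else "NA"
            energy = _fmt(h.energy) if h.energy is not None else "NA"
            handle.write(
                f"{h.mirna_mature_name}\t{h.enhancer_id}\t{h.site_start}\t"
                f"{h.site_end}\t{h.orientation}\t{_fmt(h.score)}\t{pi}\t{energy}\n"
            )


def write_triplex_audit(hits: Iterable[TriplexHit], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("mature_mirna\tenhancer\ttfo_start\ttfo_end\ttts_start\t"
                     "tts_end\tmotif\tstrand\tlength\terrors\terror_rate\n")
        for h in hits:
            handle.write(
                f"{h.mirna_mature_name}\t{h.enhancer_id}\t{h.tfo_start}\t"
                f"{h.tfo_end}\t{h.tts_start}\t{h.tts_end}\t{h.motif}\t"
                f"{h.strand}\t{h.length}\t{h.errors}\t{_fmt(h.error_rate)}\n"
            )
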