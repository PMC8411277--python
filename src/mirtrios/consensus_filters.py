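"""Consensus rules combining detection methods and promoter-aggregation modes.

Promoter-level expression (e.g. CAGE) gives several rows per gene; a gene
expression proxy is either the promoter whose expression best correlates with
the miRNA ("best_promoter") or the per-sample sum over promoters
("sum_promoters").  Duplex trios must be supported by both duplex detection
methods, lie on enhancers linked to at least two genes, and survive both
aggregation modes; highly correlated pairs (SCC >= 0.8 by default) are
rescued unconditionally.  Triplex trios need the multi-gene enhancer and
both aggregation modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import EnhancerGeneLink
from .trio_assembly import TrioRecord, spearman

BEST_PROMOTER = "best_promoter"
SUM_PROMOTERS = "sum_promoters"

DEFAULT_SCC_RESCUE = 0.8


@dataclass
class PromoterExpression:
    """Per-promoter expression rows of one gene (promoters x samples)."""

    gene_name: str
    promoter_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.promoter_ids):
            raise ValueError("values must be a promoters x samples matrix")
        if not self.promoter_ids:
            raise ValueError("a gene needs at least one promoter")


def gene_expression_proxy(p: PromoterExpression,
                          mirna_vector: np.ndarray | None,
                          mode: str = BEST_PROMOTER) -> np.ndarray:
    """Collapse promoter rows to one gene-level expression vector."""
    if mode == SUM_PROMOTERS:
        return p.values.sum(axis=0)
    if mode != BEST_PROMOTER:
        raise ValueError(f"unknown mode {mode!r}")
    if mirna_vector is None:
        raise ValueError("best_promoter mode requires the miRNA vector")
    best_idx, best_scc = 0, -np.inf
    for idx in range(p.values.shape[0]):
        try:
            scc, _ = spearman(p.values[idx], mirna_vector)
        except ValueError:
            continue
        if scc > best_scc:  # strict: tie keeps the first promoter
            best_idx, best_scc = idx, scc
    return p.values[best_idx]


# ---------------------------------------------------------------------------
# consensus set logic
# ---------------------------------------------------------------------------

def _trio_key(r: TrioRecord) -> tuple[str, str, str]:
    return (r.mature_mirna, r.gene_name, r.enhancer_id)


def _pair_key(r: TrioRecord) -> tuple[str, str]:
    return (r.mature_mirna, r.gene_name)


def multi_gene_enhancers(links: Iterable[EnhancerGeneLink],
                         min_genes: int = 2) -> set[str]:
    genes_of: dict[str, set[str]] = {}
    for link in links:
        genes_of.setdefault(link.enhancer_id, set()).add(link.gene_name)
    return {enh for enh, genes in genes_of.items() if len(genes) >= min_genes}


def consensus_duplex(trios_needle_a: Sequence[TrioRecord],
                     trios_needle_b: Sequence[TrioRecord],
                     trios_miranda_a: Sequence[TrioRecord],
                     trios_miranda_b: Sequence[TrioRecord],
                     links: Sequence[EnhancerGeneLink],
                     scc_rescue: float = DEFAULT_SCC_RESCUE,
                     min_genes_per_enhancer: int = 2,
                     rescue_min_enhancers: int | None = None,
                     ) -> list[TrioRecord]:
    """Duplex consensus across two methods and two aggregation modes.

    A trio is kept when (1) its miRNA:enhancer duplex was found by both the
    seed-anchored and the scan-based method, (2) its enhancer is linked to at
    least ``min_genes_per_enhancer`` genes, and (3) its miRNA-gene pair is
    supported under both aggregation modes; any trio from any input set with
    SCC >= ``scc_rescue`` is added unconditionally.  With
    ``rescue_min_enhancers`` set, pairs supported by at least that many
    distinct enhancers bypass requirement (3).
    """
    needle = list(trios_needle_a) + list(trios_needle_b)
    miranda = list(trios_miranda_a) + list(trios_miranda_b)
    all_trios = needle + miranda

    duplex_needle = {(r.mature_mirna, r.enhancer_id) for r in needle}
    duplex_miranda = {(r.mature_mirna, r.enhancer_id) for r in miranda}
    both_methods = duplex_needle & duplex_miranda

    pairs_a = {_pair_key(r) for r in list(trios_needle_a) + list(trios_miranda_a)}
    pairs_b = {_pair_key(r) for r in list(trios_needle_b) + list(trios_miranda_b)}
    both_modes = pairs_a & pairs_b

    multi_gene = multi_gene_enhancers(links, min_genes_per_enhancer)

    bypass_pairs: set[tuple[str, str]] = set()
    if rescue_min_enhancers is not None:
        enh_of_pair: dict[tuple[str, str], set[str]] = {}
        for r in all_trios:
            enh_of_pair.setdefault(_pair_key(r), set()).add(r.enhancer_id)
        bypass_pairs = {
            pair for pair, enhs in enh_of_pair.items()
            if len(enhs) >= rescue_min_enhancers
        }

    kept: dict[tuple[str, str, str], TrioRecord] = {}
    for r in all_trios:
        key = _trio_key(r)
        pair_ok = _pair_key(r) in both_modes or _pair_key(r) in bypass_pairs
        consensus_ok = (
            (r.mature_mirna, r.enhancer_id) in both_methods
            and r.enhancer_id in multi_gene
            and pair_ok
        )
        if consensus_ok or r.scc >= scc_rescue:
            kept.setdefault(key, r)
    return sorted(kept.values(), key=_trio_key)


def consensus_triplex(trios_a: Sequence[TrioRecord],
                      trios_b: Sequence[TrioRecord],
                      links: Sequence[EnhancerGeneLink],
                      min_genes_per_enhancer: int = 2) -> list[TrioRecord]:
    """Triplex consensus: both aggregation modes, multi-gene enhancers only."""
    keys_b = {_trio_key(r) for r in trios_b}
    multi_gene = multi_gene_enhancers(links, min_genes_per_enhancer)
    kept: dict[tuple[str, str, str], TrioRecord] = {}
    for r in trios_a:
        key = _trio_key(r)
        if key in keys_b and r.enhancer_id in multi_gene:
            kept.setdefault(key, r)
    return sorted(kept.values(), key=_trio_key)
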