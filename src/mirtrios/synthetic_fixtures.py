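"""Deterministic generator of complete toy input bundles with planted signal.

Each bundle contains every file the pipeline consumes: a per-chromosome
genome, enhancer BED and FASTA, mature miRNA FASTA (flat and one-folder-per-
family layouts), forward/reverse-complement seed tables, an enhancer:gene
link table, and gene and miRNA expression tables.  Planted trios embed (i) a
recoverable binding site in the enhancer (an exact reverse-complement duplex
site or a Hoogsteen-compatible purine run) and (ii) a gene expression vector
rank-calibrated to a target Spearman correlation with the miRNA.  Everything
is reproducible from ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata, spearmanr

from .sequence_io import (
    EnhancerRegion,
    EnhancerGeneLink,
    ExpressionTable,
    reverse_complement,
    rna_to_dna,
    write_bed,
    write_expression_tsv,
    write_fasta,
    write_links_tsv,
)

SEED_SITE = "seed_site"
TRIPLEX_SITE = "triplex_site"

_RNA_BASES = np.array(list("ACGU"))
_DNA_BASES = np.array(list("ACGT"))

#: pyrimidine-rich mature sequence used for triplex-mechanism miRNAs; over
#: the purine run "AG"* every position is a valid parallel-pyrimidine triplet
_TRIPLEX_MATURE = "UCUCUCUCUCUCUCUCUCUCU"

_MATURE_LEN = 21
# Seed = first 7 nt of the mature.  With the 14 bp one-sided extension this
# makes the alignment window of a planted exact-complement site coincide with
# the site itself, so planted hits score PI 100.
_SEED_SPAN = (0, 7)


@dataclass(frozen=True)
class PlantedTrio:
    mirna_idx: int
    enhancer_idx: int
    gene_idx: int
    mechanism: str = SEED_SITE
    target_scc: float = 0.95


@dataclass(frozen=True)
class FixtureConfig:
    rng_seed: int = 0
    n_enhancers: int = 20
    enhancer_len: int = 400
    n_mirnas: int = 3
    n_genes: int = 10
    promoters_per_gene: int = 1
    n_samples: int = 12
    planted_trios: tuple[PlantedTrio, ...] = ()
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise ValueError("n_samples must be >= 8")
        if self.enhancer_len < 2 * _MATURE_LEN + 40:
            raise ValueError(
                f"enhancer_len {self.enhancer_len} too short to host a planted "
                f"site with flanks"
            )
        for trio in self.planted_trios:
            if trio.mechanism not in (SEED_SITE, TRIPLEX_SITE):
                raise ValueError(f"unknown mechanism {trio.mechanism!r}")
            if not (0 <= trio.mirna_idx < self.n_mirnas
                    and 0 <= trio.enhancer_idx < self.n_enhancers
                    and 0 <= trio.gene_idx < self.n_genes):
                raise ValueError("planted trio index out of range")


@dataclass(frozen=True)
class ResolvedTrio:
    family: str
    mature_name: str
    enhancer_id: str
    gene_name: str
    mechanism: str
    target_scc: float


@dataclass
class FixtureBundle:
    """Paths and metadata of one generated input bundle."""

    root: Path
    genome_dir: Path
    enhancer_bed: Path
    enhancer_fasta: Path
    mature_fasta: Path
    mature_dir: Path
    seeds_forward: Path
    seeds_revcomp: Path
    links_tsv: Path
    gene_expression: Path
    mirna_expression: Path
    promoter_expression: Path | None
    families: list[str]
    mature_names: list[str]
    gene_names: list[str]
    enhancers: list[EnhancerRegion]
    links: list[EnhancerGeneLink]
    planted: list[ResolvedTrio]


def _random_seq(rng: np.random.Generator, length: int, bases: np.ndarray) -> str:
    return "".join(rng.choice(bases, size=length))


def _rank_calibrated(rng: np.random.Generator, anchor: np.ndarray,
                     target_scc: float) -> np.ndarray:
    """Non-negative vector whose Spearman correlation with ``anchor`` is
    approximately (just below or equal to) ``target_scc``.

    Starts from the anchor's own rank ordering and swaps randomly chosen
    adjacent rank values (a fine-grained perturbation) until the correlation
    drops to the target; values are log-normal magnitudes placed by rank, so
    the construction is exact under Spearman.
    """
    n = len(anchor)
    ranks = rankdata(anchor).astype(int) - 1  # 0-based, anchor has no ties
    pos_of = np.argsort(ranks)  # pos_of[v] holds rank value v
    for _ in range(100 * n * n):
        rho = spearmanr(ranks, anchor).statistic
        if rho <= target_scc:
            break
        v = int(rng.integers(n - 1))
        i, j = pos_of[v], pos_of[v + 1]
        ranks[i], ranks[j] = ranks[j], ranks[i]
        pos_of[v], pos_of[v + 1] = j, i
    magnitudes = np.sort(np.exp(rng.normal(0.0, 1.0, size=n)))
    return magnitudes[ranks]


def generate_fixture(cfg: FixtureConfig, out_dir: str | Path) -> FixtureBundle:
    """Write a full input bundle under ``out_dir`` and describe it."""
    rng = np.random.default_rng(cfg.rng_seed)
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)

    families = [f"Mir{i + 1}" for i in range(cfg.n_mirnas)]
    mature_names = [f"{fam}_mat1" for fam in families]
    gene_names = [f"Gene{i + 1}" for i in range(cfg.n_genes)]
    sample_ids = [f"sample_{i + 1:02d}" for i in range(cfg.n_samples)]

    # --- mature sequences and seeds -------------------------------------
    triplex_mirnas = {t.mirna_idx for t in cfg.planted_trios
                      if t.mechanism == TRIPLEX_SITE}
    matures: list[str] = []
    for i in range(cfg.n_mirnas):
        if i in triplex_mirnas:
            matures.append(_TRIPLEX_MATURE)
        else:
            matures.append(_random_seq(rng, _MATURE_LEN, _RNA_BASES))
    seeds_fwd = {
        fam: rna_to_dna(seq[_SEED_SPAN[0]:_SEED_SPAN[1]])
        for fam, seq in zip(families, matures)
    }
    seeds_rc = {fam: reverse_complement(s) for fam, s in seeds_fwd.items()}

    # --- genome and enhancers -------------------------------------------
    n_chroms = min(3, cfg.n_enhancers) or 1
    spacing = cfg.enhancer_len + 300
    chrom_of: list[str] = []
    start_of: list[int] = []
    per_chrom_count = [0] * n_chroms
    for i in range(cfg.n_enhancers):
        c = i % n_chroms
        chrom_of.append(f"chr{c + 1}")
        start_of.append(500 + per_chrom_count[c] * spacing)
        per_chrom_count[c] += 1

    chrom_len = {
        f"chr{c + 1}": 500 + per_chrom_count[c] * spacing + 500
        for c in range(n_chroms)
    }
    chroms = {
        name: list(_random_seq(rng, length, _DNA_BASES))
        for name, length in chrom_len.items()
    }

    site_pos = cfg.enhancer_len // 2 - _MATURE_LEN // 2
    for trio in cfg.planted_trios:
        mature_dna = rna_to_dna(matures[trio.mirna_idx])
        if trio.mechanism == SEED_SITE:
            site = reverse_complement(mature_dna)
        else:
            # purine-strand run complementary (Hoogsteen-wise) to the TFO
            site = mature_dna.replace("T", "A").replace("C", "G")
        chrom = chrom_of[trio.enhancer_idx]
        pos = start_of[trio.enhancer_idx] + site_pos
        chroms[chrom][pos:pos + len(site)] = list(site)

    chrom_seqs = {name: "".join(seq) for name, seq in chroms.items()}
    enhancers = [
        EnhancerRegion(
            chrom=chrom_of[i],
            start=start_of[i],
            end=start_of[i] + cfg.enhancer_len,
            seq=chrom_seqs[chrom_of[i]][start_of[i]:start_of[i] + cfg.enhancer_len],
        )
        for i in range(cfg.n_enhancers)
    ]

    # --- enhancer:gene links --------------------------------------------
    links: list[EnhancerGeneLink] = []
    seen_links: set[tuple[str, str]] = set()

    def add_link(enh_id: str, gene: str) -> None:
        if (enh_id, gene) not in seen_links:
            seen_links.add((enh_id, gene))
            links.append(EnhancerGeneLink(enh_id, gene))

    for trio in cfg.planted_trios:
        enh_id = enhancers[trio.enhancer_idx].enhancer_id
        add_link(enh_id, gene_names[trio.gene_idx])
        # a second gene keeps planted enhancers multi-gene for consensus rules
        other = gene_names[(trio.gene_idx + 1) % cfg.n_genes]
        add_link(enh_id, other)
    for i, enh in enumerate(enhancers):
        gene = gene_names[int(rng.integers(cfg.n_genes))]
        add_link(enh.enhancer_id, gene)

    # --- expression ------------------------------------------------------
    mirna_expr = np.exp(rng.normal(0.0, cfg.noise_sd,
                                   size=(cfg.n_mirnas, cfg.n_samples)))
    gene_expr = np.exp(rng.normal(0.0, cfg.noise_sd,
                                  size=(cfg.n_genes, cfg.n_samples)))
    for trio in cfg.planted_trios:
        anchor = np.exp(rng.normal(0.0, 1.0, size=cfg.n_samples))
        mirna_expr[trio.mirna_idx] = anchor
        gene_expr[trio.gene_idx] = _rank_calibrated(rng, anchor, trio.target_scc)

    promoter_path: Path | None = None
    if cfg.promoters_per_gene > 1:
        promoter_ids = []
        promoter_values = []
        planted_genes = {t.gene_idx for t in cfg.planted_trios}
        for g in range(cfg.n_genes):
            for k in range(cfg.promoters_per_gene):
                promoter_ids.append(f"{gene_names[g]}@p{k + 1}")
                if k == 0:
                    promoter_values.append(gene_expr[g])
                else:
                    promoter_values.append(
                        np.exp(rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples))
                    )
        promoter_table = ExpressionTable(
            feature_ids=promoter_ids,
            sample_ids=sample_ids,
            values=np.vstack(promoter_values),
        )
        promoter_path = root / "promoters_expression.tsv"
        write_expression_tsv(promoter_table, promoter_path, index_name="promoter")

    # --- write everything -------------------------------------------------
    genome_dir = root / "genome"
    genome_dir.mkdir(exist_ok=True)
    for name, seq in chrom_seqs.items():
        write_fasta({name: seq}, genome_dir / f"{name}.fa")

    enhancer_bed = root / "enhancers.bed"
    write_bed(enhancers, enhancer_bed)
    enhancer_fasta = root / "enhancers.fasta"
    write_fasta({e.enhancer_id: e.seq for e in enhancers}, enhancer_fasta)

    mature_fasta = root / "mature_mirnas.fa"
    write_fasta(dict(zip(mature_names, matures)), mature_fasta)

    mature_dir = root / "mature_seqs"
    for fam, name, seq in zip(families, mature_names, matures):
        fam_dir = mature_dir / fam
        fam_dir.mkdir(parents=True, exist_ok=True)
        write_fasta({name: seq}, fam_dir / f"{name}.fa")

    seeds_forward = root / "seeds_forward.tsv"
    with open(seeds_forward, "w") as handle:
        for fam in families:
            handle.write(f"{fam}\t{seeds_fwd[fam]}\n")
    seeds_revcomp = root / "seeds_revcomp.tsv"
    with open(seeds_revcomp, "w") as handle:
        for fam in families:
            handle.write(f"{fam}\t{seeds_rc[fam]}\n")

    links_tsv = root / "enh_gene_links.tsv"
    write_links_tsv(links, links_tsv)

    gene_expression = root / "genes_expression.tsv"
    write_expression_tsv(
        ExpressionTable(gene_names, sample_ids, gene_expr),
        gene_expression, index_name="gene",
    )
    mirna_expression = root / "mirnas_expression.tsv"
    write_expression_tsv(
        ExpressionTable(families, sample_ids, mirna_expr),
        mirna_expression, index_name="mirna",
    )

    planted = [
        ResolvedTrio(
            family=families[t.mirna_idx],
            mature_name=mature_names[t.mirna_idx],
            enhancer_id=enhancers[t.enhancer_idx].enhancer_id,
            gene_name=gene_names[t.gene_idx],
            mechanism=t.mechanism,
            target_scc=t.target_scc,
        )
        for t in cfg.planted_trios
    ]
    return FixtureBundle(
        root=root,
        genome_dir=genome_dir,
        enhancer_bed=enhancer_bed,
        enhancer_fasta=enhancer_fasta,
        mature_fasta=mature_fasta,
        mature_dir=mature_dir,
        seeds_forward=seeds_forward,
        seeds_revcomp=seeds_revcomp,
        links_tsv=links_tsv,
        gene_expression=gene_expression,
        mirna_expression=mirna_expression,
        promoter_expression=promoter_path,
        families=families,
        mature_names=mature_names,
        gene_names=gene_names,
        enhancers=enhancers,
        links=links,
        planted=planted,
    )
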