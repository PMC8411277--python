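# mirtrios

Detection of candidate **miRNA–enhancer–gene activation trios**: miRNAs
predicted to bind an enhancer (as an RNA:DNA duplex or an RNA:DNA:DNA
triplex) whose expression correlates positively with the genes that enhancer
is assumed to regulate.

All interaction predictors are implemented in-house, so the pipeline runs
with zero external binaries:

| stage | module | what it does |
|---|---|---|
| detection 1 | `seed_needle` | exact seed match in the enhancer, 14 bp extension, affine-gap global alignment, percent-identity filter (PI > 50) |
| detection 2 | `duplex_miranda` | miRanda-style local duplex scan (match +5, G:T wobble +1, mismatch −3, gaps −9/−4, 4× seed weighting over miRNA positions 2–8, score ≥ 140, simple stacking-energy filter) |
| detection 3 | `triplex` | Hoogsteen triplex motif search (parallel pyrimidine / antiparallel purine / mixed G-T) with relaxed error rate 0.19 and minimum length 11 |
| assembly | `trio_assembly` | expand hits through the enhancer:gene link table, Spearman correlation of miRNA vs gene expression, per-miRNA Benjamini–Hochberg adjustment, FDR < 0.05 |
| consensus | `consensus_filters` | cross-method and cross-aggregation-mode intersection, ≥ 2-genes-per-enhancer rule, SCC ≥ 0.8 rescue, promoter-level expression proxies |
| fixtures | `synthetic_fixtures` | deterministic generator of complete toy input bundles with planted, recoverable signal |
| plumbing | `sequence_io`, `cli` | FASTA/BED/TSV readers and the command-line surface |

## Running the pipeline

One invocation runs one detection mode end-to-end and writes
`mir_enh_gene_trios.tsv` (plus audit files and a run log) into the output
directory:

```bash
mirtrios -d miranda \
    -e enhancers.fasta -o out/miranda/ \
    -ge gene_expression.tsv -me mirna_expression.tsv \
    -ei enh_gene_links.tsv -m mature_mirnas.fa
```

`-d` accepts `seed_match_needle`, `miranda` or `triplexator`.  The
`seed_match_needle` mode additionally requires:

```bash
    -g genome_dir/            # one FASTA per chromosome
    -s seeds_forward.tsv      # 2 columns: miRNA family, seed (DNA)
    -sr seeds_revcomp.tsv     # reverse-complement seeds
    -eb enhancers.bed         # enhancer coordinates (BED3+)
    -ms mature_seqs/          # one folder per family, one FASTA per mature
```

The output table has columns `mature_mirna`, `Gene.Name`, `enhancer`,
`corr (miRNA, gene)`, `p.value adj`, and — only in `seed_match_needle`
mode — `PI`.

Numeric defaults (PI threshold, scan scores, triplex parameters, FDR) can
be overridden with `--config file` containing `key = value` lines, e.g.
`miranda_score_threshold = 120`.

### Extra subcommands

```bash
# generate a synthetic input bundle with two planted trios
mirtrios fixture --seed 7 --out bundle/ \
    --plant 0:3:1:seed_site:0.95 --plant 1:8:5:triplex_site:0.95

# consensus filtering across methods (duplex) or aggregation modes (triplex)
mirtrios consensus --needle-a a.tsv --needle-b b.tsv \
    --miranda-a c.tsv --miranda-b d.tsv \
    --links enh_gene_links.tsv --out consensus.tsv
```

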