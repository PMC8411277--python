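"""Readers, writers and canonical in-memory types shared by the whole pipeline.

All coordinates are BED-style: 0-based, half-open.  Enhancer identifiers are
``chrom:start-end`` strings using those same numbers.  Enhancer sequences are
always stored as the + strand of the reference; strandedness of binding is the
detectors' concern, not the loader's.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_CHARS = re.compile(r"^[ACGTUN]*$")


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad alphabet, bad FASTA/BED)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatureMiRNA:
    """One mature miRNA sequence with its family name and optional seed forms.

    ``mature_seq`` is RNA alphabet (ACGU); the seed strings are DNA alphabet
    (ACGT) as supplied by the user, ``seed_rc`` being the reverse complement
    of ``seed_fwd``.
    """

    family_name: str
    mature_name: str
    mature_seq: str
    seed_fwd: str | None = None
    seed_rc: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mature_seq", _check_alphabet(self.mature_seq.upper(), "ACGUN"))
        if self.seed_fwd is not None:
            object.__setattr__(self, "seed_fwd", _check_alphabet(self.seed_fwd.upper(), "ACGTN"))
        if self.seed_rc is not None:
            object.__setattr__(self, "seed_rc", _check_alphabet(self.seed_rc.upper(), "ACGTN"))
        if self.seed_fwd is not None and self.seed_rc is not None:
            if reverse_complement(self.seed_fwd) != self.seed_rc:
                raise SequenceError(
                    f"seed_rc for {self.mature_name!r} is not the reverse "
                    f"complement of seed_fwd"
                )
        if self.seed_fwd is not None:
            if self.seed_fwd not in rna_to_dna(self.mature_seq):
                logger.warning(
                    "seed %s is not a substring of mature sequence %s",
                    self.seed_fwd, self.mature_name,
                )

    @property
    def mature_dna(self) -> str:
        return rna_to_dna(self.mature_seq)


@dataclass
class EnhancerRegion:
    chrom: str
    start: int
    end: int
    seq: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SequenceError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.seq:
            self.seq = _check_alphabet(self.seq.upper(), "ACGTN")
            if len(self.seq) != self.end - self.start:
                raise SequenceError(
                    f"sequence length {len(self.seq)} != interval length "
                    f"{self.end - self.start} for {self.enhancer_id}"
                )

    @property
    def enhancer_id(self) -> str:
        return format_region_id(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class EnhancerGeneLink:
    enhancer_id: str
    gene_name: str


@dataclass
class ExpressionTable:
    """Features x samples matrix of normalized, non-negative expression."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        self._index = {f: i for i, f in enumerate(self.feature_ids)}

    def __contains__(self, feature: str) -> bool:
        return feature in self._index

    def row(self, feature: str) -> np.ndarray:
        return self.values[self._index[feature]]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


# ---------------------------------------------------------------------------
# sequence primitives
# ---------------------------------------------------------------------------

def _check_alphabet(seq: str, allowed: str) -> str:
    bad = set(seq) - set(allowed)
    if bad:
        raise SequenceError(f"invalid characters {sorted(bad)} in sequence")
    return seq


def rna_to_dna(seq: str) -> str:
    """U -> T, uppercased; accepts ACGTUN."""
    seq = _check_alphabet(seq.upper(), "ACGTUN")
    return seq.replace("U", "T")


def dna_to_rna(seq: str) -> str:
    seq = _check_alphabet(seq.upper(), "ACGTUN")
    return seq.replace("T", "U")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G, N->N)."""
    seq = _check_alphabet(seq.upper(), "ACGTN")
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def format_region_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


_REGION_ID = re.compile(r"^(?P<chrom>.+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_region_id(region_id: str) -> tuple[str, int, int]:
    m = _REGION_ID.match(region_id)
    if m is None:
        raise SequenceError(f"cannot parse region id {region_id!r}")
    return m["chrom"], int(m["start"]), int(m["end"])


# ---------------------------------------------------------------------------
# FASTA / BED
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Parse a FASTA file into an ordered ``{id: uppercase sequence}`` mapping.

    The record id is the header token before the first whitespace.  Duplicate
    ids warn and last-wins.  A sequence line before any header is a parse
    error naming the line number.
    """
    records: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    _store_fasta_record(records, current, chunks, path)
                current = line[1:].split()[0] if line[1:].split() else ""
                if not current:
                    raise SequenceError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if current is None:
                    raise SequenceError(
                        f"{path}: sequence line before any header at line {lineno}"
                    )
                chunks.append(line.upper())
    if current is not None:
        _store_fasta_record(records, current, chunks, path)
    return records


def _store_fasta_record(records: dict[str, str], name: str,
                        chunks: list[str], path: object) -> None:
    if name in records:
        logger.warning("%s: duplicate FASTA id %r, keeping last record", path, name)
    records[name] = "".join(chunks)


def write_fasta(records: Mapping[str, str], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in records.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


def read_bed(path: str | os.PathLike) -> list[EnhancerRegion]:
    """Read a BED3+ file into regions (sequences left empty).

    ``track``/``browser``/``#`` lines are skipped; extra columns ignored.
    """
    regions: list[EnhancerRegion] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SequenceError(f"{path}: fewer than 3 columns at line {lineno}")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise SequenceError(f"{path}: non-integer coordinate at line {lineno}") from exc
            if start >= end:
                raise SequenceError(
                    f"{path}: start >= end ({start} >= {end}) at line {lineno}"
                )
            regions.append(EnhancerRegion(chrom=chrom, start=start, end=end))
    return regions


def write_bed(regions: Iterable[EnhancerRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for r in regions:
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def attach_sequences(regions: Sequence[EnhancerRegion],
                     genome_dir: str | os.PathLike | None = None,
                     enhancer_fasta: str | os.PathLike | Mapping[str, str] | None = None,
                     ) -> list[EnhancerRegion]:
    """Return copies of ``regions`` with their + strand sequences filled in.

    Either ``genome_dir`` (one FASTA per chromosome; interval is sliced out)
    or ``enhancer_fasta`` (records keyed by enhancer_id) must be given.
    Idempotent: regions that already carry the right sequence are re-sliced to
    the same value.
    """
    if (genome_dir is None) == (enhancer_fasta is None):
        raise ValueError("provide exactly one of genome_dir / enhancer_fasta")

    out: list[EnhancerRegion] = []
    if genome_dir is not None:
        chroms = _load_genome_dir(genome_dir, {r.chrom for r in regions})
        for r in regions:
            chrom_seq = chroms[r.chrom]
            if r.end > len(chrom_seq):
                raise SequenceError(
                    f"{r.enhancer_id} extends past end of {r.chrom} "
                    f"(length {len(chrom_seq)})"
                )
            out.append(replace(r, seq=chrom_seq[r.start:r.end]))
    else:
        if isinstance(enhancer_fasta, (str, os.PathLike)):
            fasta = read_fasta(enhancer_fasta)
        else:
            fasta = dict(enhancer_fasta)
        for r in regions:
            if r.enhancer_id not in fasta:
                raise SequenceError(f"{r.enhancer_id} not found in enhancer FASTA")
            out.append(replace(r, seq=fasta[r.enhancer_id]))
    return out


def _load_genome_dir(genome_dir: str | os.PathLike,
                     wanted: set[str]) -> dict[str, str]:
    genome_dir = Path(genome_dir)
    chroms: dict[str, str] = {}
    fasta_paths = sorted(
        p for p in genome_dir.iterdir()
        if p.suffix.lower() in {".fa", ".fasta", ".fna"}
    )
    for p in fasta_paths:
        for name, seq in read_fasta(p).items():
            if name in wanted:
                chroms[name] = seq
    missing = wanted - chroms.keys()
    if missing:
        raise SequenceError(
            f"chromosomes {sorted(missing)} not found in {genome_dir}"
        )
    return chroms


def regions_from_fasta(path: str | os.PathLike) -> list[EnhancerRegion]:
    """Build enhancer regions straight from a FASTA keyed by region ids.

    Headers that do not look like ``chrom:start-end`` become single-"chrom"
    regions spanning the whole record.
    """
    regions = []
    for name, seq in read_fasta(path).items():
        try:
            chrom, start, end = parse_region_id(name)
            if end - start != len(seq):
                raise SequenceError(
                    f"{path}: record {name} length {len(seq)} does not match its id"
                )
        except SequenceError as exc:
            if "cannot parse" not in str(exc):
                raise
            chrom, start, end = name, 0, len(seq)
        regions.append(EnhancerRegion(chrom=chrom, start=start, end=end, seq=seq))
    return regions


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_seed_tsv(path: str | os.PathLike) -> dict[str, str]:
    """2-column headerless TSV: miRNA family name, seed (DNA alphabet)."""
    seeds: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SequenceError(f"{path}: expected 2 columns at line {lineno}")
            name, seed = fields[0].strip(), fields[1].strip().upper()
            seeds[name] = _check_alphabet(seed, "ACGTN")
    return seeds


def read_links_tsv(path: str | os.PathLike,
                   known_genes: set[str] | None = None) -> list[EnhancerGeneLink]:
    """2-column TSV of enhancer_id, gene_name; duplicates collapsed with a warning.

    Header presence is auto-detected: the first row is treated as a header
    when its second field matches no known gene name (if ``known_genes`` is
    given) or when its first field does not parse as a region id.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SequenceError(f"{path}: expected 2 columns at line {lineno}")
            rows.append((fields[0].strip(), fields[1].strip()))
    if rows:
        first_enh, first_gene = rows[0]
        is_header = False
        try:
            parse_region_id(first_enh)
        except SequenceError:
            is_header = True
        if known_genes is not None:
            is_header = first_gene not in known_genes
        if is_header:
            rows = rows[1:]

    seen: set[tuple[str, str]] = set()
    links: list[EnhancerGeneLink] = []
    for enh, gene in rows:
        key = (enh, gene)
        if key in seen:
            logger.warning("%s: duplicate link %s -> %s collapsed", path, enh, gene)
            continue
        seen.add(key)
        links.append(EnhancerGeneLink(enhancer_id=enh, gene_name=gene))
    return links


def write_links_tsv(links: Iterable[EnhancerGeneLink], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for link in links:
            handle.write(f"{link.enhancer_id}\t{link.gene_name}\n")


def read_expression_tsv(path: str | os.PathLike) -> ExpressionTable:
    """TSV with a header row; first column is the feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in expression table")
    return ExpressionTable(
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression_tsv(table: ExpressionTable, path: str | os.PathLike,
                         index_name: str = "feature") -> None:
    df = pd.DataFrame(table.values, index=table.feature_ids, columns=table.sample_ids)
    df.index.name = index_name
    df.to_csv(path, sep="\t")


def check_sample_alignment(gene_expr: ExpressionTable,
                           mirna_expr: ExpressionTable,
                           min_samples: int = 8) -> None:
    """Pipeline-entry validation of the two expression tables."""
    if gene_expr.sample_ids != mirna_expr.sample_ids:
        raise ValueError(
            "gene and miRNA expression tables must share an identical "
            "sample ordering"
        )
    if gene_expr.n_samples < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples, got {gene_expr.n_samples}"
        )


# ---------------------------------------------------------------------------
# mature miRNA loading
# ---------------------------------------------------------------------------

def load_matures_fasta(path: str | os.PathLike,
                       seeds_fwd: Mapping[str, str] | None = None,
                       seeds_rc: Mapping[str, str] | None = None,
                       family_of: Mapping[str, str] | None = None,
                       ) -> list[MatureMiRNA]:
    """Load mature miRNAs from one multi-FASTA.

    Family defaults to the record id itself unless ``family_of`` maps mature
    names to family names.  Seed tables are keyed by family name.
    """
    mirnas = []
    for name, seq in read_fasta(path).items():
        family = family_of.get(name, name) if family_of else name
        mirnas.append(MatureMiRNA(
            family_name=family,
            mature_name=name,
            mature_seq=dna_to_rna(seq),
            seed_fwd=seeds_fwd.get(family) if seeds_fwd else None,
            seed_rc=seeds_rc.get(family) if seeds_rc else None,
        ))
    return mirnas


def load_matures_dir(root: str | os.PathLike,
                     seeds_fwd: Mapping[str, str] | None = None,
                     seeds_rc: Mapping[str, str] | None = None,
                     ) -> list[MatureMiRNA]:
    """Load the one-folder-per-family layout.

    ``root/<Family>/<mature_name>.fa`` each holding one mature sequence; the
    FASTA file's basename is used as the mature name.
    """
    root = Path(root)
    mirnas: list[MatureMiRNA] = []
    for family_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        family = family_dir.name
        for fa in sorted(family_dir.iterdir()):
            if fa.suffix.lower() not in {".fa", ".fasta"}:
                continue
            records = read_fasta(fa)
            if len(records) != 1:
                raise SequenceError(
                    f"{fa}: expected exactly one mature sequence, found {len(records)}"
                )
            (seq,) = records.values()
            mirnas.append(MatureMiRNA(
                family_name=family,
                mature_name=fa.stem,
                mature_seq=dna_to_rna(seq),
                seed_fwd=seeds_fwd.get(family) if seeds_fwd else None,
                seed_rc=seeds_rc.get(family) if seeds_rc else None,
            ))
    return mirnas
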