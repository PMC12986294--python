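"""Readers and writers for the on-disk formats the pipeline touches.

All genomic coordinates are 0-based half-open internally (the BED
convention); SAM positions (1-based) are shifted at the boundary. FASTQ
quality encoding is fixed to phred+33. miRBase-style RNA sequences are
transliterated U->T at load time, since sequenced reads are in DNA space.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_DNA_ALPHABET = set("ACGTN")
PHRED_OFFSET = 33
PHRED_MAX = 93


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRead:
    """One FASTQ record: identifier, bases over {A,C,G,T,N}, phred qualities."""

    read_id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class MatureRef:
    """A mature miRNA reference sequence (DNA space after U->T)."""

    name: str
    sequence: str
    species: str = ""
    aliases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.name!r} has an empty sequence")


@dataclass(frozen=True)
class GenomicFeature:
    """A stranded genomic interval (0-based half-open) carrying a miRNA name."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.name!r}: strand must be '+' or '-'")


@dataclass(frozen=True)
class SamAlignment:
    """Minimal primary-alignment record ingested from SAM."""

    read_id: str
    chrom: str
    pos0: int
    strand: str
    aligned_length: int


@dataclass
class SamIngestReport:
    mapped: int = 0
    unmapped: int = 0
    secondary: int = 0


class CountMatrix:
    """miRNA x sample matrix of non-negative integer counts.

    Optionally carries a per-cell provenance split into ``precount`` and
    ``feature_count`` components which must sum to the totals.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        precount: Optional[pd.DataFrame] = None,
        feature_count: Optional[pd.DataFrame] = None,
    ) -> None:
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dups}")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample names")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        if (precount is None) != (feature_count is None):
            raise ValueError("provide both provenance components or neither")
        if precount is not None:
            merged = precount.add(feature_count, fill_value=0)
            merged = merged.reindex(index=counts.index, columns=counts.columns,
                                    fill_value=0)
            if not (merged.to_numpy() == counts.to_numpy()).all():
                raise ValueError("provenance components do not sum to counts")
        self.precount = precount
        self.feature_count = feature_count

    @property
    def feature_names(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.counts.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | os.PathLike) -> Iterator[SequenceRead]:
    """Stream FASTQ records (phred+33) in file order.

    A malformed record aborts with the offending record's position in the
    error message; a length mismatch between bases and qualities is an error.
    """
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        n = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record #{n + 1}: {exc}") from exc
            n += 1
            quals = [ord(c) - PHRED_OFFSET for c in qual]
            bad = [q for q in quals if not 0 <= q <= PHRED_MAX]
            if bad:
                raise ValueError(
                    f"record #{n} ({title!r}): quality out of phred+33 range"
                )
            try:
                yield SequenceRead(title.split()[0], seq.upper(), quals)
            except ValueError as exc:
                raise ValueError(f"record #{n}: {exc}") from exc


def write_fastq(reads: Iterable[SequenceRead], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.quals)
            handle.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA (mature miRNA references)
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, species_prefix: str = "") -> list[MatureRef]:
    """Load mature reference sequences from FASTA.

    Headers are parsed as the first whitespace-delimited token; U is
    transliterated to T. ``species_prefix`` (e.g. ``"hsa-"``) keeps only
    matching entries, mirroring a species/biotype-filtered mature database.
    Duplicate headers are an error; duplicate sequences are legal here and
    grouped later when the precount index is built.
    """
    records: list[MatureRef] = []
    seen: set[str] = set()
    name: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence under header {name!r}")
        if not species_prefix or name.startswith(species_prefix):
            records.append(MatureRef(name=name, sequence=seq, species=species_prefix))

    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ValueError(f"line {lineno}: empty FASTA header")
                if name in seen:
                    raise ValueError(f"duplicate FASTA header {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"line {lineno}: sequence before any header")
                chunks.append(line.strip())
    flush()
    return records


def write_fasta(records: Iterable[MatureRef] | dict[str, str],
                path: str | os.PathLike) -> None:
    if isinstance(records, dict):
        items = records.items()
    else:
        items = ((r.name, r.sequence) for r in records)
    with open(path, "w") as handle:
        for name, seq in items:
            handle.write(f">{name}\n{seq}\n")


def read_genome_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a genome FASTA as {chrom: sequence} (upper-case DNA)."""
    genome: dict[str, str] = {}
    name: Optional[str] = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                if name in genome:
                    raise ValueError(f"duplicate chromosome {name!r}")
                chunks = []
            elif line:
                chunks.append(line.strip())
    if name is not None:
        genome[name] = "".join(chunks).upper()
    return genome


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def read_bed6(path: str | os.PathLike) -> list[GenomicFeature]:
    """Parse BED6 (0-based half-open, as stored internally)."""
    features: list[GenomicFeature] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"line {lineno}: expected 6 tab-separated columns")
            chrom, start, end, name, _score, strand = cols[:6]
            try:
                feature = GenomicFeature(chrom, int(start), int(end), strand, name)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            features.append(feature)
    return features


def write_bed6(features: Iterable[GenomicFeature], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for f in features:
            handle.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\n")


# ---------------------------------------------------------------------------
# SAM ingestion (minimal)
# ---------------------------------------------------------------------------

def read_sam_minimal(
    path: str | os.PathLike,
) -> tuple[list[SamAlignment], SamIngestReport]:
    """Ingest primary mapped alignments from a SAM (or BAM) file.

    Secondary/supplementary records are skipped; unmapped records are skipped
    and counted in the report. SAM's 1-based POS becomes a 0-based ``pos0``;
    FLAG bit 0x10 maps to strand '-'.
    """
    import pysam

    alignments: list[SamAlignment] = []
    report = SamIngestReport()
    save = pysam.set_verbosity(0)  # silence missing-index warning on SAM text
    try:
        with pysam.AlignmentFile(os.fspath(path), check_sq=False) as handle:
            for rec in handle:
                if rec.is_unmapped:
                    report.unmapped += 1
                    continue
                if rec.is_secondary or rec.is_supplementary:
                    report.secondary += 1
                    continue
                report.mapped += 1
                alignments.append(
                    SamAlignment(
                        read_id=rec.query_name,
                        chrom=rec.reference_name,
                        pos0=rec.reference_start,
                        strand="-" if rec.is_reverse else "+",
                        aligned_length=rec.query_alignment_length
                        or len(rec.query_sequence or ""),
                    )
                )
    finally:
        pysam.set_verbosity(save)
    return alignments, report


# ---------------------------------------------------------------------------
# Count matrix TSV
# ---------------------------------------------------------------------------

def write_counts_tsv(matrix: CountMatrix, path: str | os.PathLike) -> None:
    """Write feature rows x sample columns; first column header is 'mirna'."""
    out = matrix.counts.copy()
    out.index.name = "mirna"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path: str | os.PathLike) -> CountMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.has_duplicates:
        raise ValueError("duplicate feature names in count matrix")
    if (table.to_numpy() < 0).any():
        raise ValueError("negative count in matrix")
    table.index.name = None
    table.index = table.index.astype(str)
    return CountMatrix(table.astype(int) if (table.to_numpy() % 1 == 0).all()
                       else table)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ("sample_id", "fastq_path", "condition", "subject_id")


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read the TSV sample sheet (sample_id, fastq_path, condition[, subject_id])."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    return sheet
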