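"""Adapter location, UMI extraction, quality/length trimming and UMI dedup.

The expected library layout is the QIAseq small-RNA structure: a short
insert (the mature miRNA), the kit's 3' adapter, a fixed-length UMI, then
filler up to the machine read length. Stages run in the order adapter/UMI
extraction -> 3' quality trim -> length filter -> UMI deduplication.

Adapter matching is substitution-only: the adapter is slid over every start
position, possibly truncated at the read's 3' end, and accepted where the
mismatch count is within ``floor(max_error_rate * aligned_length)`` with at
least 6 aligned bases. Quality trimming is the BWA-style algorithm: cut at
the 3' position maximizing the running sum of (threshold - q) from the end.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

from .io_formats import SequenceRead, read_fastq

# QIAseq miRNA kit defaults; the simulator uses the same values.
DEFAULT_ADAPTER = "AACTGTAGGCACCATCAAT"
DEFAULT_UMI_LEN = 12

MIN_ADAPTER_OVERLAP = 6


@dataclass
class TrimConfig:
    """Read-preparation parameters for a QIAseq-style library."""

    adapter: str = DEFAULT_ADAPTER
    umi_len: int = DEFAULT_UMI_LEN
    max_adapter_error_rate: float = 0.1
    phred_threshold: int = 10
    min_len: int = 10
    max_len: int = 40
    keep_no_adapter: bool = True

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if not 0 <= self.max_adapter_error_rate < 0.5:
            raise ValueError("max_adapter_error_rate must be in [0, 0.5)")
        if self.umi_len < 0:
            raise ValueError("umi_len must be >= 0")
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")


@dataclass
class ProcessedRead:
    """A read after adapter/UMI extraction and trimming."""

    read_id: str
    insert: str
    insert_quals: list[int]
    umi: str
    status: str  # ok | no_adapter | too_short | too_long

    def dedup_key(self) -> tuple[str, str]:
        return (self.insert, self.umi)


@dataclass
class PrepReport:
    """Counters for one sample's preparation run."""

    input_reads: int = 0
    adapter_found: int = 0
    no_adapter: int = 0
    discarded_no_adapter: int = 0
    discarded_short: int = 0
    discarded_long: int = 0
    kept: int = 0
    unique_after_dedup: int = 0
    duplicates_removed: int = 0

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2)


def locate_adapter(bases: str, adapter: str,
                   max_error_rate: float = 0.1) -> Optional[int]:
    """Leftmost start index of the (possibly 3'-truncated) adapter, or None.

    Substitutions only; an alignment of length L is accepted with at most
    floor(max_error_rate * L) mismatches, requiring L >= 6.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n, m = len(bases), len(adapter)
    for start in range(0, n - MIN_ADAPTER_OVERLAP + 1):
        aligned = min(m, n - start)
        allowed = int(max_error_rate * aligned)
        mismatches = 0
        for k in range(aligned):
            if bases[start + k] != adapter[k]:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return start
    return None


def extract_umi(read: SequenceRead, cfg: TrimConfig) -> ProcessedRead:
    """Split a raw read into insert and UMI around the located adapter.

    The UMI is the ``umi_len`` bases immediately 3' of the adapter; if fewer
    than ``umi_len`` bases remain the UMI is recorded as empty rather than
    padded. Without an adapter the whole read is kept as insert, flagged.
    """
    pos = locate_adapter(read.bases, cfg.adapter, cfg.max_adapter_error_rate)
    if pos is None:
        return ProcessedRead(read.read_id, read.bases, list(read.quals),
                             umi="", status="no_adapter")
    umi_start = pos + len(cfg.adapter)
    umi = read.bases[umi_start:umi_start + cfg.umi_len]
    if len(umi) < cfg.umi_len:
        umi = ""
    return ProcessedRead(read.read_id, read.bases[:pos], list(read.quals[:pos]),
                         umi=umi, status="ok")


def quality_trim_3prime(bases: str, quals: list[int],
                        phred_threshold: int) -> tuple[str, list[int]]:
    """BWA-style 3' quality trim.

    Keeps the prefix [0, cut) where cut maximizes sum(threshold - q) over the
    removed suffix; an all-high-quality read is unchanged. Equivalent to the
    quality-trimming rule of the common read trimmers.
    """
    if phred_threshold < 0:
        raise ValueError("phred_threshold must be >= 0")
    best_cut = len(bases)
    best_score = 0
    running = 0
    for j in range(len(bases) - 1, -1, -1):
        running += phred_threshold - quals[j]
        if running > best_score:
            best_score = running
            best_cut = j
    return bases[:best_cut], quals[:best_cut]


def length_filter(insert_len: int, min_len: int, max_len: int) -> str:
    """'ok', 'too_short' or 'too_long' for an insert length (bounds inclusive)."""
    if insert_len < min_len:
        return "too_short"
    if insert_len > max_len:
        return "too_long"
    return "ok"


def deduplicate(reads: Iterable[ProcessedRead]) -> tuple[list[ProcessedRead], int]:
    """Collapse reads on (insert, UMI), keeping the first representative.

    Reads with an empty UMI collapse on insert alone (their key is
    (insert, "")). Returns (unique reads in first-occurrence order,
    number of duplicates removed). Idempotent.
    """
    seen: dict[tuple[str, str], None] = {}
    unique: list[ProcessedRead] = []
    removed = 0
    for read in reads:
        key = read.dedup_key()
        if key in seen:
            removed += 1
        else:
            seen[key] = None
            unique.append(read)
    return unique, removed


def prep_reads(reads: Iterable[SequenceRead],
               cfg: TrimConfig) -> tuple[list[ProcessedRead], PrepReport]:
    """Run the full preparation pipeline over an iterable of raw reads."""
    report = PrepReport()
    staged: list[ProcessedRead] = []
    for read in reads:
        report.input_reads += 1
        processed = extract_umi(read, cfg)
        if processed.status == "no_adapter":
            if not cfg.keep_no_adapter:
                report.discarded_no_adapter += 1
                continue
            report.no_adapter += 1
        else:
            report.adapter_found += 1
        insert, quals = quality_trim_3prime(processed.insert,
                                            processed.insert_quals,
                                            cfg.phred_threshold)
        processed.insert, processed.insert_quals = insert, quals
        verdict = length_filter(len(insert), cfg.min_len, cfg.max_len)
        if verdict == "too_short":
            report.discarded_short += 1
            continue
        if verdict == "too_long":
            report.discarded_long += 1
            continue
        staged.append(processed)
    report.kept = len(staged)
    unique, removed = deduplicate(staged)
    report.unique_after_dedup = len(unique)
    report.duplicates_removed = removed
    return unique, report


def prep_sample(fastq_path: str | os.PathLike,
                cfg: TrimConfig) -> tuple[list[ProcessedRead], PrepReport]:
    """Prepare one sample's FASTQ file: trim, filter, deduplicate."""
    return prep_reads(read_fastq(fastq_path), cfg)
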