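"""Two-step miRNA quantification.

Step one ("precounting") assigns a read to a mature miRNA by exact
full-length sequence identity against the reference set, with identical
reference sequences grouped under one canonical name. Step two takes the
unmatched reads through an ungapped seed-and-extend genomic aligner
(substitutions only, best mismatch stratum) and counts uniquely placed
reads against stranded miRNA features, allowing a read to increment every
feature it overlaps on its own strand. Per-sample precounts and feature
counts are merged into the total-abundance matrix.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io_formats import CountMatrix, GenomicFeature, MatureRef, SamAlignment
from .read_prep import ProcessedRead

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Precounting
# ---------------------------------------------------------------------------

@dataclass
class PrecountEntry:
    canonical: str
    aliases: list[str] = field(default_factory=list)


class PrecountIndex:
    """Exact-sequence lookup from insert DNA to a canonical miRNA name.

    References sharing an identical sequence are grouped: the
    lexicographically smallest name becomes canonical, the rest aliases.
    """

    def __init__(self, refs: Sequence[MatureRef]) -> None:
        by_seq: dict[str, list[str]] = defaultdict(list)
        for ref in refs:
            by_seq[ref.sequence].append(ref.name)
        self._index: dict[str, PrecountEntry] = {}
        for seq, names in by_seq.items():
            names = sorted(names)
            self._index[seq] = PrecountEntry(canonical=names[0], aliases=names[1:])

    def __len__(self) -> int:
        return len(self._index)

    def lookup(self, sequence: str) -> Optional[str]:
        entry = self._index.get(sequence)
        return entry.canonical if entry else None

    @property
    def canonical_names(self) -> list[str]:
        return sorted(e.canonical for e in self._index.values())

    @property
    def aliases(self) -> dict[str, str]:
        """alias -> canonical for every grouped duplicate name."""
        return {a: e.canonical for e in self._index.values() for a in e.aliases}


def build_precount_index(refs: Sequence[MatureRef]) -> PrecountIndex:
    return PrecountIndex(refs)


def precount(
    reads: Iterable[ProcessedRead], index: PrecountIndex
) -> tuple[dict[str, int], list[ProcessedRead]]:
    """Assign reads by exact full-sequence identity; return the rest unmatched."""
    counts: dict[str, int] = defaultdict(int)
    unmatched: list[ProcessedRead] = []
    for read in reads:
        name = index.lookup(read.insert)
        if name is None:
            unmatched.append(read)
        else:
            counts[name] += 1
    return dict(counts), unmatched


# ---------------------------------------------------------------------------
# Ungapped seed-and-extend alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    chrom: str
    pos0: int
    strand: str
    mismatches: int


class GenomeIndex:
    """Seed-and-extend ungapped alignment over both strands of a small genome.

    The query is partitioned into ``max_mismatches + 1`` pieces; by the
    pigeonhole principle at least one piece is error-free in any placement
    within the mismatch budget, so locating every exact occurrence of each
    piece and verifying the full-length extension (substitutions only)
    enumerates *all* valid placements. Hits are reported in the best
    (minimum) mismatch stratum, ordered by (chrom, pos, strand). ``k`` is
    the minimum read length that will be aligned.
    """

    def __init__(self, genome: dict[str, str], k: int = 12) -> None:
        if k < 1:
            raise ValueError("minimum seedable length k must be >= 1")
        self.genome = genome
        self.k = k
        self._chroms = sorted(genome)

    def _seed_occurrences(self, piece: str, chrom: str):
        seq = self.genome[chrom]
        pos = seq.find(piece)
        while pos != -1:
            yield pos
            pos = seq.find(piece, pos + 1)

    def align(self, read_id: str, sequence: str,
              max_mismatches: int = 1) -> list[AlignmentHit]:
        """All best-stratum ungapped placements of ``sequence``.

        The '-' strand is searched by aligning the reverse complement; the
        reported interval is the forward-strand footprint in both cases.
        A read shorter than k is considered unalignable and returns no hits.
        """
        if len(sequence) < self.k:
            return []
        candidates: dict[tuple[str, int, str], int] = {}
        n_pieces = max_mismatches + 1
        for strand, query in (("+", sequence), ("-", reverse_complement(sequence))):
            length = len(query)
            bounds = [round(i * length / n_pieces) for i in range(n_pieces + 1)]
            for i in range(n_pieces):
                offset, stop = bounds[i], bounds[i + 1]
                piece = query[offset:stop]
                if not piece:
                    continue
                for chrom in self._chroms:
                    for seed_pos in self._seed_occurrences(piece, chrom):
                        start = seed_pos - offset
                        key = (chrom, start, strand)
                        if key in candidates:
                            continue
                        mm = self._verify(chrom, start, query, max_mismatches)
                        if mm is not None:
                            candidates[key] = mm
        if not candidates:
            return []
        best = min(candidates.values())
        return [
            AlignmentHit(read_id, chrom, pos, strand, mm)
            for (chrom, pos, strand), mm in sorted(candidates.items())
            if mm == best
        ]

    def _verify(self, chrom: str, start: int, query: str,
                max_mismatches: int) -> Optional[int]:
        ref = self.genome[chrom]
        if start < 0 or start + len(query) > len(ref):
            return None
        mismatches = 0
        for a, b in zip(query, ref[start:start + len(query)]):
            if a != b:
                mismatches += 1
                if mismatches > max_mismatches:
                    return None
        return mismatches


def align_ungapped(read: ProcessedRead, index: GenomeIndex,
                   max_mismatches: int = 1) -> list[AlignmentHit]:
    return index.align(read.read_id, read.insert, max_mismatches)


# ---------------------------------------------------------------------------
# Feature counting
# ---------------------------------------------------------------------------

def count_features(
    hits_by_read: dict[str, list[AlignmentHit]],
    features: Sequence[GenomicFeature],
    read_lengths: dict[str, int],
    stranded: bool = True,
) -> tuple[dict[str, int], int]:
    """Count uniquely placed reads against stranded features.

    A read contributes only if it has exactly one genomic placement;
    multi-placement reads are discarded as ambiguous and tallied in the
    returned ``unassigned`` count (together with reads overlapping no
    feature). A uniquely placed read increments *every* feature it overlaps
    by >= 1 bp on the matching strand.
    """
    counts: dict[str, int] = defaultdict(int)
    unassigned = 0
    for read_id in sorted(hits_by_read):
        hits = hits_by_read[read_id]
        if len(hits) != 1:
            unassigned += 1
            continue
        hit = hits[0]
        read_start = hit.pos0
        read_end = hit.pos0 + read_lengths[read_id]
        assigned = False
        for feat in features:
            if feat.chrom != hit.chrom:
                continue
            if stranded and feat.strand != hit.strand:
                continue
            if read_start < feat.end and feat.start < read_end:
                counts[feat.name] += 1
                assigned = True
        if not assigned:
            unassigned += 1
    return dict(counts), unassigned


def hits_from_sam(alignments: Sequence[SamAlignment]) -> tuple[
        dict[str, list[AlignmentHit]], dict[str, int]]:
    """Convert ingested SAM records into the hit/length maps count_features takes."""
    hits: dict[str, list[AlignmentHit]] = defaultdict(list)
    lengths: dict[str, int] = {}
    for aln in alignments:
        hits[aln.read_id].append(
            AlignmentHit(aln.read_id, aln.chrom, aln.pos0, aln.strand, 0))
        lengths[aln.read_id] = aln.aligned_length
    return dict(hits), lengths


# ---------------------------------------------------------------------------
# Merging and matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class SampleQuant:
    """One sample's quantification: precounts, feature counts, leftovers."""

    sample_id: str
    precounts: dict[str, int] = field(default_factory=dict)
    feature_counts: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.precounts.values()) or any(
                v < 0 for v in self.feature_counts.values()):
            raise ValueError("counts must be non-negative")


def merge_counts(quant: SampleQuant,
                 aliases: Optional[dict[str, str]] = None) -> dict[str, int]:
    """Total abundance per miRNA: precount + feature count, name-reconciled.

    Feature names are mapped onto canonical reference names through the
    alias table where they coincide; unknown feature names stay as rows of
    their own.
    """
    aliases = aliases or {}
    totals: dict[str, int] = defaultdict(int)
    for name, n in quant.precounts.items():
        totals[aliases.get(name, name)] += n
    for name, n in quant.feature_counts.items():
        totals[aliases.get(name, name)] += n
    return dict(totals)


def assemble_matrix(quants: Sequence[SampleQuant],
                    aliases: Optional[dict[str, str]] = None) -> CountMatrix:
    """Assemble the final miRNA x sample matrix with provenance retained.

    Rows are the union of names across samples (missing -> 0), ordered
    lexicographically; columns follow the given sample order.
    """
    if not quants:
        raise ValueError("need at least one sample")
    sample_ids = [q.sample_id for q in quants]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    aliases = aliases or {}

    def canon(counts: dict[str, int]) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for name, n in counts.items():
            out[aliases.get(name, name)] += n
        return out

    pre = {q.sample_id: canon(q.precounts) for q in quants}
    fc = {q.sample_id: canon(q.feature_counts) for q in quants}
    names = sorted({n for d in (*pre.values(), *fc.values()) for n in d})
    pre_df = pd.DataFrame(
        {s: [pre[s].get(n, 0) for n in names] for s in sample_ids},
        index=names, dtype=int)
    fc_df = pd.DataFrame(
        {s: [fc[s].get(n, 0) for n in names] for s in sample_ids},
        index=names, dtype=int)
    return CountMatrix(pre_df + fc_df, precount=pre_df, feature_count=fc_df)


# ---------------------------------------------------------------------------
# One-call sample quantification
# ---------------------------------------------------------------------------

def quantify_sample(
    sample_id: str,
    reads: Sequence[ProcessedRead],
    index: PrecountIndex,
    genome_index: Optional[GenomeIndex] = None,
    features: Sequence[GenomicFeature] = (),
    max_mismatches: int = 1,
    sam_alignments: Optional[Sequence[SamAlignment]] = None,
) -> tuple[SampleQuant, list[ProcessedRead]]:
    """Precount, then (optionally) align-and-count the unmatched reads.

    Pre-aligned SAM records, when provided, replace the built-in aligner for
    the fallback step. Returns the per-sample quantification and the reads
    that matched nothing (for optional export as a leftover FASTQ).
    """
    precounts, unmatched = precount(reads, index)
    quant = SampleQuant(sample_id=sample_id, precounts=precounts)
    if not unmatched or (genome_index is None and sam_alignments is None):
        quant.unassigned = len(unmatched)
        return quant, unmatched

    if sam_alignments is not None:
        unmatched_ids = {r.read_id for r in unmatched}
        hits, lengths = hits_from_sam(
            [a for a in sam_alignments if a.read_id in unmatched_ids])
    else:
        hits = {}
        lengths = {}
        for read in unmatched:
            found = align_ungapped(read, genome_index, max_mismatches)
            if found:
                hits[read.read_id] = found
                lengths[read.read_id] = len(read.insert)
    feature_counts, ambiguous_or_bare = count_features(hits, features, lengths)
    quant.feature_counts = feature_counts
    unplaced = len(unmatched) - len(hits)
    quant.unassigned = unplaced + ambiguous_or_bare
    leftovers = [r for r in unmatched if r.read_id not in hits]
    return quant, leftovers
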