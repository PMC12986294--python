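"""Synthetic small-RNA data generator with full ground truth.

Emulates, at reduced scale, a QIAseq-style single-end miRNA library: each
molecule is read as mature insert + 3' kit adapter + random UMI + random
filler up to the 72 nt machine read length, with optional per-base
substitution errors and exact PCR duplicates (copying sequence and UMI).
Two-condition count structure is negative binomial with a known per-miRNA
log2 fold change. Everything is a pure function of (config, seed): each
operation draws from its own RNG stream keyed by (seed, operation name
[, sample index]), so regenerating one sample never perturbs another.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import (GenomicFeature, MatureRef, SequenceRead,
                         write_bed6, write_fasta, write_fastq)
from .read_prep import DEFAULT_ADAPTER, DEFAULT_UMI_LEN, locate_adapter

DEFAULT_SEED = 20770305
READ_LENGTH = 72
_BASES = np.array(list("ACGT"))


def _rng(seed: int, op: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(op.encode()), index])


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment."""

    n_mirnas: int = 200
    genome_len: int = 50_000
    mirna_len: tuple[int, int] = (20, 24)
    n_samples: int = 6              # per condition
    mean_expression: tuple[float, float] = (10.0, 500.0)
    dispersion: float = 0.2
    de_fraction: float = 0.1
    true_lfc: float = 2.0
    duplication_rate: float = 0.3
    base_error_rate: float = 0.001
    isomir_rate: float = 0.0       # fraction of molecules 3'-truncated 1-2 nt
    adapter: str = DEFAULT_ADAPTER
    umi_len: int = DEFAULT_UMI_LEN
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in ("de_fraction", "duplication_rate", "base_error_rate",
                     "isomir_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated experiment."""

    counts: pd.DataFrame                  # true molecule counts
    true_log2fc: pd.Series
    de_flags: pd.Series
    conditions: pd.Series                 # sample -> condition
    n_reads: dict[str, int] = field(default_factory=dict)
    n_unique_pairs: dict[str, int] = field(default_factory=dict)
    config: Optional[SimConfig] = None

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "counts": {s: self.counts[s].to_dict() for s in self.counts},
            "true_log2fc": self.true_log2fc.to_dict(),
            "de_flags": {k: bool(v) for k, v in self.de_flags.items()},
            "conditions": self.conditions.to_dict(),
            "n_reads": self.n_reads,
            "n_unique_pairs": self.n_unique_pairs,
            "config": asdict(self.config) if self.config else None,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SimTruth":
        with open(path) as handle:
            payload = json.load(handle)
        cfg = payload.get("config")
        if cfg is not None:
            cfg["mirna_len"] = tuple(cfg["mirna_len"])
            cfg["mean_expression"] = tuple(cfg["mean_expression"])
            cfg = SimConfig(**cfg)
        return cls(
            counts=pd.DataFrame(payload["counts"]).fillna(0).astype(int),
            true_log2fc=pd.Series(payload["true_log2fc"], dtype=float),
            de_flags=pd.Series(payload["de_flags"], dtype=bool),
            conditions=pd.Series(payload["conditions"]),
            n_reads=payload["n_reads"],
            n_unique_pairs=payload["n_unique_pairs"],
            config=cfg,
        )


# ---------------------------------------------------------------------------
# Reference synthesis
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def make_reference(cfg: SimConfig) -> tuple[
        dict[str, str], list[MatureRef], list[GenomicFeature]]:
    """Random genome with non-overlapping planted miRNA loci.

    Each mature sequence equals its genomic locus ('+' strand) or the
    locus's reverse complement ('-'). Mature sequences containing anything
    the adapter locator would fire on are redrawn, so trimming recovers
    inserts exactly. Deterministic in cfg.seed.
    """
    rng = _rng(cfg.seed, "make_reference")
    lo, hi = cfg.mirna_len
    if cfg.n_mirnas > 0:
        stride = cfg.genome_len // cfg.n_mirnas
        if stride < hi + 2:
            raise ValueError("genome too short to place loci without overlap")
    genome = list(_random_dna(rng, cfg.genome_len))
    refs: list[MatureRef] = []
    features: list[GenomicFeature] = []
    seen: set[str] = set()
    width = max(3, len(str(max(cfg.n_mirnas, 1))))
    for i in range(cfg.n_mirnas):
        name = f"sim-miR-{i + 1:0{width}d}"
        start = i * stride
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        while True:
            locus = _random_dna(rng, length)
            mature = locus if strand == "+" else _revcomp(locus)
            if locate_adapter(mature, cfg.adapter) is not None:
                continue
            if mature in seen:
                continue
            break
        seen.add(mature)
        genome[start:start + length] = list(locus)
        refs.append(MatureRef(name=name, sequence=mature))
        features.append(GenomicFeature("chrSim", start, start + length,
                                       strand, name))
    return {"chrSim": "".join(genome)}, refs, features


# ---------------------------------------------------------------------------
# Count synthesis
# ---------------------------------------------------------------------------

def _sample_names(cfg: SimConfig) -> tuple[list[str], pd.Series]:
    names = [f"ref_{i + 1}" for i in range(cfg.n_samples)] + \
            [f"trt_{i + 1}" for i in range(cfg.n_samples)]
    conditions = pd.Series(
        ["reference"] * cfg.n_samples + ["treatment"] * cfg.n_samples,
        index=names, name="condition")
    return names, conditions


def simulate_counts(cfg: SimConfig,
                    mirna_names: Optional[list[str]] = None) -> tuple[
                        pd.DataFrame, SimTruth]:
    """Two-condition NB count table with known per-miRNA log2FC.

    Base means are log-uniform over ``mean_expression``; a
    round(de_fraction * n_mirnas)-sized subset carries log2FC of
    ``+/- true_lfc`` (random sign) applied to the treatment condition;
    counts are NB(mean, dispersion) (Poisson when dispersion == 0).
    """
    rng = _rng(cfg.seed, "simulate_counts")
    n = cfg.n_mirnas
    if mirna_names is None:
        width = max(3, len(str(max(n, 1))))
        mirna_names = [f"sim-miR-{i + 1:0{width}d}" for i in range(n)]
    lo, hi = cfg.mean_expression
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    n_de = round(cfg.de_fraction * n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    lfc = np.zeros(n)
    lfc[de_idx] = cfg.true_lfc * rng.choice([-1.0, 1.0], size=n_de)
    names, conditions = _sample_names(cfg)
    columns = {}
    for sample in names:
        mu = means * np.where(conditions[sample] == "treatment",
                              2.0 ** lfc, 1.0)
        if cfg.dispersion > 0:
            r = 1.0 / cfg.dispersion
            columns[sample] = rng.negative_binomial(r, r / (r + mu))
        else:
            columns[sample] = rng.poisson(mu)
    counts = pd.DataFrame(columns, index=mirna_names, dtype=int)
    truth = SimTruth(
        counts=counts,
        true_log2fc=pd.Series(lfc, index=mirna_names, name="true_log2fc"),
        de_flags=pd.Series(lfc != 0, index=mirna_names, name="de"),
        conditions=conditions,
        config=cfg,
    )
    return counts, truth


# ---------------------------------------------------------------------------
# Read synthesis
# ---------------------------------------------------------------------------

def synthesize_reads(counts: pd.DataFrame, refs: list[MatureRef],
                     cfg: SimConfig, truth: Optional[SimTruth] = None
                     ) -> dict[str, list[SequenceRead]]:
    """Emit UMI-tagged reads for every molecule in ``counts``.

    Layout: insert + adapter + UMI + filler to 72 nt. A molecule is
    3'-truncated by 1-2 nt with probability ``isomir_rate`` (isomiR-style
    heterogeneity, routing it past the exact-match precounter).
    Substitution errors hit each base independently at ``base_error_rate``
    *before* duplication, so a PCR duplicate is an exact copy of its parent
    (same bases, same UMI) and collapses in deduplication. Fillers that the
    adapter locator would fire on are rejected and redrawn. Qualities are
    constant Q40.
    """
    by_name = {r.name: r.sequence for r in refs}
    libraries: dict[str, list[SequenceRead]] = {}
    for sample_index, sample in enumerate(counts.columns):
        rng = _rng(cfg.seed, "synthesize_reads", sample_index)
        reads: list[SequenceRead] = []
        pairs: set[tuple[str, str]] = set()
        serial = 0
        for name in counts.index:
            n_molecules = int(counts.loc[name, sample])
            for _ in range(n_molecules):
                insert = by_name[name]
                if cfg.isomir_rate > 0 and rng.random() < cfg.isomir_rate:
                    insert = insert[:len(insert) - int(rng.integers(1, 3))]
                umi = _random_dna(rng, cfg.umi_len)
                fill_len = READ_LENGTH - len(insert) - len(cfg.adapter) \
                    - cfg.umi_len
                while True:
                    filler = _random_dna(rng, max(0, fill_len))
                    if locate_adapter(filler, cfg.adapter) is None:
                        break
                bases = insert + cfg.adapter + umi + filler
                if cfg.base_error_rate > 0:
                    arr = np.array(list(bases))
                    hits = rng.random(len(arr)) < cfg.base_error_rate
                    for pos in np.flatnonzero(hits):
                        arr[pos] = rng.choice(
                            _BASES[_BASES != arr[pos]])
                    bases = "".join(arr)
                serial += 1
                read_id = f"{sample}:r{serial}:{name}"
                quals = [40] * len(bases)
                reads.append(SequenceRead(read_id, bases, quals))
                pairs.add((bases[:len(insert)], umi))
                if rng.random() < cfg.duplication_rate:
                    reads.append(SequenceRead(f"{read_id}:dup", bases,
                                              list(quals)))
        libraries[sample] = reads
        if truth is not None:
            truth.n_reads[sample] = len(reads)
            truth.n_unique_pairs[sample] = len(pairs)
    return libraries


# ---------------------------------------------------------------------------
# Fixture suites
# ---------------------------------------------------------------------------

PRESETS: dict[str, SimConfig] = {
    # small full-artifact run: FASTQ through matrix in seconds
    "tiny": SimConfig(n_mirnas=10, genome_len=5_000, n_samples=2,
                      mean_expression=(20.0, 80.0), dispersion=0.2,
                      de_fraction=0.2, true_lfc=2.0,
                      duplication_rate=0.0, base_error_rate=0.0),
    # count-level preset for DE sensitivity/specificity
    "de_recovery": SimConfig(n_mirnas=200, genome_len=50_000, n_samples=6,
                             mean_expression=(10.0, 500.0), dispersion=0.2,
                             de_fraction=0.1, true_lfc=2.0),
    # count-level preset under the global null
    "null_calibration": SimConfig(n_mirnas=500, genome_len=100_000,
                                  n_samples=6,
                                  mean_expression=(100.0, 100.0),
                                  dispersion=0.2, de_fraction=0.0),
}


def make_fixture_suite(preset: str, out_dir: str | os.PathLike,
                       seed: int = DEFAULT_SEED) -> Path:
    """Write a self-contained fixture directory for a named preset.

    Always written: genome.fa, mature.fa, features.bed, counts.tsv,
    samples.tsv, truth.json. The ``tiny`` preset additionally writes one
    FASTQ per sample (the count-level presets exist to exercise the
    statistics and skip read synthesis).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(PRESETS)}")
    cfg_base = PRESETS[preset]
    cfg = SimConfig(**{**asdict(cfg_base), "seed": seed,
                       "mirna_len": cfg_base.mirna_len,
                       "mean_expression": cfg_base.mean_expression})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, refs, features = make_reference(cfg)
    write_fasta({c: s for c, s in genome.items()}, out / "genome.fa")
    write_fasta(refs, out / "mature.fa")
    write_bed6(features, out / "features.bed")
    counts, truth = simulate_counts(cfg, mirna_names=[r.name for r in refs])
    counts.index.name = "mirna"
    counts.to_csv(out / "counts.tsv", sep="\t")
    counts.index.name = None
    fastq_paths: dict[str, str] = {}
    if preset == "tiny":
        libraries = synthesize_reads(counts, refs, cfg, truth)
        for sample, reads in libraries.items():
            path = out / f"{sample}.fastq"
            write_fastq(reads, path)
            fastq_paths[sample] = path.name
    sheet = pd.DataFrame({
        "sample_id": truth.conditions.index,
        "fastq_path": [fastq_paths.get(s, "") for s in truth.conditions.index],
        "condition": truth.conditions.to_numpy(),
        "subject_id": ["" for _ in truth.conditions.index],
    })
    sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
    return out
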