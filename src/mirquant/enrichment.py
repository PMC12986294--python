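"""Hypergeometric pathway over-representation for miRNA target genes.

Differentially expressed miRNAs are mapped to their target genes through a
user-supplied annotation; the union of targets is tested one pathway at a
time with the one-sided hypergeometric tail P(X >= k), BH-adjusted across
the tested pathways. The background defaults to every gene with at least
one pathway annotation. A shared-gene overlap matrix between enriched
pathways is also produced (the structure behind pathway-network figures).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de_stats import bh_adjust


@dataclass
class AnnotationMap:
    """miRNA -> target genes and gene -> pathways lookup tables."""

    mirna_to_genes: dict[str, set[str]]
    gene_to_pathways: dict[str, set[str]]
    pathway_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.mirna_to_genes, self.gene_to_pathways):
            empty = [k for k, v in table.items() if not v]
            if empty:
                raise ValueError(f"empty annotation sets for: {empty}")

    @property
    def pathways(self) -> dict[str, set[str]]:
        """pathway id -> gene set (inverted gene_to_pathways)."""
        out: dict[str, set[str]] = {}
        for gene, pws in self.gene_to_pathways.items():
            for pw in pws:
                out.setdefault(pw, set()).add(gene)
        return out

    @property
    def background(self) -> set[str]:
        return set(self.gene_to_pathways)

    @classmethod
    def from_tsv(cls, targets_path: str | os.PathLike,
                 pathways_path: str | os.PathLike) -> "AnnotationMap":
        """targets: columns (mirna, gene); pathways: (gene, pathway_id[, pathway_name])."""
        targets = pd.read_csv(targets_path, sep="\t", dtype=str)
        pathways = pd.read_csv(pathways_path, sep="\t", dtype=str)
        m2g: dict[str, set[str]] = {}
        for row in targets.itertuples(index=False):
            m2g.setdefault(row.mirna, set()).add(row.gene)
        g2p: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for row in pathways.itertuples(index=False):
            g2p.setdefault(row.gene, set()).add(row.pathway_id)
            if hasattr(row, "pathway_name"):
                names[row.pathway_id] = row.pathway_name
        return cls(m2g, g2p, names)


def map_mirnas_to_genes(
    mirnas: Iterable[str], annotation: AnnotationMap
) -> tuple[set[str], list[str]]:
    """Union of the target-gene sets of the given miRNAs.

    Returns (query gene set, miRNAs with no annotation). An empty miRNA
    list is an error — there is nothing to test.
    """
    mirnas = list(mirnas)
    if not mirnas:
        raise ValueError("empty miRNA list")
    genes: set[str] = set()
    unannotated: list[str] = []
    for m in mirnas:
        targets = annotation.mirna_to_genes.get(m)
        if targets is None:
            unannotated.append(m)
        else:
            genes |= targets
    return genes, unannotated


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), stable in log
    space (scipy's survival function)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_ora(query_genes: set[str], annotation: AnnotationMap,
            background: Optional[set[str]] = None,
            p_cutoff: float = 0.01) -> pd.DataFrame:
    """Over-representation table, one row per pathway hit by >= 1 query gene.

    Columns: pathway, name, k (overlap), K (pathway size in background),
    n (query size), N (background size), p_hyper, p_adj, significant
    (p_hyper < p_cutoff), genes. Sorted by ascending p, ties by pathway id.
    """
    if background is None:
        background = annotation.background
    stray = query_genes - background
    if stray:
        raise ValueError(f"query genes absent from background: {sorted(stray)}")
    N = len(background)
    n = len(query_genes)
    rows = []
    for pw_id in sorted(annotation.pathways):
        members = annotation.pathways[pw_id] & background
        overlap = sorted(members & query_genes)
        if not overlap:
            continue
        p = hypergeom_upper(len(overlap), len(members), n, N)
        rows.append({"pathway": pw_id,
                     "name": annotation.pathway_names.get(pw_id, pw_id),
                     "k": len(overlap), "K": len(members), "n": n, "N": N,
                     "p_hyper": p, "genes": ",".join(overlap)})
    table = pd.DataFrame(rows, columns=["pathway", "name", "k", "K", "n", "N",
                                        "p_hyper", "genes"])
    if len(table):
        table["p_adj"] = bh_adjust(table["p_hyper"].to_numpy())
        table["significant"] = table["p_hyper"] < p_cutoff
        table = table.sort_values(["p_hyper", "pathway"],
                                  kind="mergesort").reset_index(drop=True)
    else:
        table["p_adj"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table[["pathway", "name", "k", "K", "n", "N", "p_hyper", "p_adj",
                  "significant", "genes"]]


def pathway_overlap(rows: pd.DataFrame) -> pd.DataFrame:
    """Pathway x pathway shared-gene count matrix from an ORA table.

    Symmetric; the diagonal is each pathway's own overlap-gene count.
    """
    gene_sets = {row.pathway: set(row.genes.split(","))
                 for row in rows.itertuples(index=False)}
    ids = list(gene_sets)
    mat = np.zeros((len(ids), len(ids)), dtype=int)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            mat[i, j] = len(gene_sets[a] & gene_sets[b])
    return pd.DataFrame(mat, index=ids, columns=ids)
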