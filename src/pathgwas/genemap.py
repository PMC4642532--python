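"""SNP-to-gene assignment with flanking windows, and gene-level statistics.

A SNP belongs to a gene when it lies on the same chromosome inside the
gene span extended by ``window_bp`` on both sides (20 kb by default, both
extended boundaries inclusive).  A SNP may belong to several genes.  Each
gene is then represented by the largest test statistic among its SNPs
(the max-SNP rule), and genes are ranked by that statistic, largest first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigurationError
from .types import GeneAnnotation

__all__ = ["SnpGeneIndex", "map_snps_to_genes", "gene_statistics", "rank_genes"]


@dataclass
class SnpGeneIndex:
    """Pairs (snp_id, gene_id) plus bookkeeping for fast gene maxima.

    ``pairs`` is sorted by gene then SNP; ``unmapped`` lists SNP ids that
    fell outside every window.
    """

    pairs: pd.DataFrame  # columns: snp_id, gene_id
    unmapped: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return self.pairs["gene_id"].drop_duplicates().tolist()

    def genes_for_snp(self, snp_id: str) -> list[str]:
        return self.pairs.loc[self.pairs["snp_id"] == snp_id, "gene_id"].tolist()


def map_snps_to_genes(
    snp_map: pd.DataFrame,
    annotation: GeneAnnotation,
    window_bp: int = 20_000,
) -> SnpGeneIndex:
    """Assign each SNP to every gene whose +/- ``window_bp`` window covers it.

    ``snp_map`` needs columns chrom, snp_id, bp (1-based).  Gene spans are
    1-based inclusive; the extended interval
    ``[start - window_bp, end + window_bp]`` is closed at both ends.
    """
    if len(annotation) == 0:
        raise ConfigurationError("empty gene annotation")
    trees: dict[str, IntervalTree] = {}
    for row in annotation.table.itertuples(index=False):
        lo = int(row.start) - window_bp
        hi = int(row.end) + window_bp + 1  # half-open upper end
        trees.setdefault(str(row.chrom), IntervalTree()).addi(lo, hi, row.gene_id)
    snp_rows, gene_rows, unmapped = [], [], []
    for row in snp_map.itertuples(index=False):
        tree = trees.get(str(row.chrom))
        hits = tree[int(row.bp)] if tree is not None else set()
        if not hits:
            unmapped.append(row.snp_id)
            continue
        for iv in hits:
            snp_rows.append(row.snp_id)
            gene_rows.append(iv.data)
    pairs = (
        pd.DataFrame({"snp_id": snp_rows, "gene_id": gene_rows})
        .sort_values(["gene_id", "snp_id"], kind="stable")
        .reset_index(drop=True)
    )
    return SnpGeneIndex(pairs=pairs, unmapped=unmapped)


def gene_statistics(assoc: pd.DataFrame, index: SnpGeneIndex) -> pd.DataFrame:
    """Max-SNP statistic per gene.

    ``assoc`` is an association-scan frame (snp_id, statistic, flagged);
    flagged SNPs (undefined statistic) never represent a gene, and genes
    whose mapped SNPs were all removed or flagged are omitted.  Returns a
    frame gene_id, rep_snp, statistic.
    """
    usable = assoc.loc[~assoc["flagged"].astype(bool), ["snp_id", "statistic"]]
    merged = index.pairs.merge(usable, on="snp_id", how="inner")
    if merged.empty:
        raise ConfigurationError("no gene retains any usable SNP")
    top = (
        merged.sort_values(
            ["gene_id", "statistic", "snp_id"],
            ascending=[True, False, True],
            kind="stable",
        )
        .groupby("gene_id", sort=True)
        .head(1)
        .rename(columns={"snp_id": "rep_snp"})
        .reset_index(drop=True)
    )
    return top[["gene_id", "rep_snp", "statistic"]]


def rank_genes(stats: pd.DataFrame) -> pd.DataFrame:
    """Sort genes by statistic, largest first; ties broken by gene id.

    Adds a 1-based ``rank`` column.  The output is invariant to the input
    row order, which permutation reproducibility depends on.
    """
    if len(stats) < 2:
        raise ConfigurationError("ranking needs at least two genes")
    ranked = stats.sort_values(
        ["statistic", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked
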