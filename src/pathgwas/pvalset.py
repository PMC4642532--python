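"""Pathway tests from per-SNP P values alone (replication mode).

When only summary statistics are available — no genotypes or phenotypes,
as with consortium meta-analysis downloads — pathways can still be tested:
each gene is scored as -log10 of the k-th smallest P among its SNPs
(k = 2 by default, which damps single-SNP artifacts), and each set is
compared to the gene-score universe with a Z statistic
``z = (mean member score - mean universe score) / (universe SD / sqrt(m))``,
followed by Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import genemap
from .errors import ConfigurationError, StageError
from .types import GeneAnnotation, GeneSetCollection

__all__ = ["gene_pscore", "set_z_test", "bh_fdr", "run_gsasnp"]


def gene_pscore(p_values, k: int = 2) -> float:
    """-log10 of the k-th smallest P among a gene's SNPs.

    Falls back to the largest available order statistic when the gene has
    fewer than k SNPs.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ConfigurationError("gene has no P values")
    if k < 1:
        raise ConfigurationError("order k must be >= 1")
    if (p <= 0).any() or (p > 1).any():
        raise ConfigurationError("P values must lie in (0, 1]")
    kth = np.sort(p)[min(k, p.size) - 1]
    return float(-np.log10(kth))


def set_z_test(gene_scores: pd.Series, members) -> dict:
    """Z test of a set's mean gene score against the score universe.

    ``gene_scores`` is indexed by gene id.  Returns a dict with keys
    set-size ``m``, ``mean_score``, ``z`` and one-sided upper-tail ``p``;
    returns None-like (raises) when fewer than two members are scored.
    """
    members = [g for g in members if g in gene_scores.index]
    m = len(members)
    if m < 2:
        raise ConfigurationError("set has fewer than two scored genes")
    universe = gene_scores.to_numpy(dtype=float)
    mu, sd = universe.mean(), universe.std(ddof=1)
    if not sd > 0:
        raise ConfigurationError("gene-score universe has zero variance")
    mean_score = float(gene_scores.loc[members].mean())
    z = (mean_score - mu) / (sd / np.sqrt(m))
    return {
        "m": m,
        "mean_score": mean_score,
        "z": float(z),
        "p": float(np.clip(sps.norm.sf(z), 1e-300, 1.0)),
    }


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ConfigurationError("P values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_gsasnp(
    table: pd.DataFrame,
    annotation: GeneAnnotation,
    pathways: GeneSetCollection,
    k: int = 2,
    window_bp: int = 20_000,
    set_size_min: int = 10,
    set_size_max: int = 200,
) -> pd.DataFrame:
    """Summary-statistic pathway scan.

    ``table`` needs columns chrom, snp_id, bp, p (a PLINK ``.assoc``-style
    table).  SNPs are mapped to genes with the same windows as the
    genotype pipeline, genes scored by :func:`gene_pscore`, sets tested by
    :func:`set_z_test` and corrected by :func:`bh_fdr`.  Sets outside the
    effective-size bounds, or with fewer than two scored genes, are
    skipped.  Returns a frame sorted by q then z.
    """
    for col in ("chrom", "snp_id", "bp", "p"):
        if col not in table.columns:
            raise ConfigurationError(f"P-value table missing column {col!r}")
    if len(pathways) == 0:
        return pd.DataFrame(
            columns=["set_id", "source", "m", "mean_score", "z", "p", "q"]
        )
    try:
        index = genemap.map_snps_to_genes(
            table[["chrom", "snp_id", "bp"]], annotation, window_bp=window_bp
        )
        merged = index.pairs.merge(
            table[["snp_id", "p"]], on="snp_id", how="inner"
        )
        if merged.empty:
            raise ConfigurationError("no SNP maps to any gene")
        scores = merged.groupby("gene_id")["p"].apply(
            lambda s: gene_pscore(s.to_numpy(), k=k)
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage name
        raise StageError("gene_scores", exc) from exc

    restricted = pathways.restrict(
        set(scores.index), size_min=max(2, set_size_min), size_max=set_size_max
    )
    rows = []
    for sid, members in restricted:
        try:
            res = set_z_test(scores, members)
        except ConfigurationError:
            continue  # skipped with reason: too few scored genes
        res["set_id"] = sid
        res["source"] = restricted.sources[sid]
        rows.append(res)
    if not rows:
        return pd.DataFrame(
            columns=["set_id", "source", "m", "mean_score", "z", "p", "q"]
        )
    out = pd.DataFrame(rows)[["set_id", "source", "m", "mean_score", "z", "p"]]
    out["q"] = bh_fdr(out["p"])
    return out.sort_values(["q", "z"], ascending=[True, False], kind="stable").reset_index(
        drop=True
    )
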