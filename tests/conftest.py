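"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-derivations (pure-Python loops,
full enumerations) kept separate from the library code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from pathgwas import synthdata
from pathgwas.types import GeneAnnotation, GeneSetCollection, GenotypeMatrix


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_es(stats, member_mask, weight_p: float = 1.0) -> float:
    """Naive running-sum ES: plain loop, no vectorization."""
    n = len(stats)
    n_h = sum(bool(m) for m in member_mask)
    n_r = sum(abs(s) ** weight_p for s, m in zip(stats, member_mask) if m)
    run, best = 0.0, -math.inf
    for s, m in zip(stats, member_mask):
        if m:
            run += abs(s) ** weight_p / n_r
        else:
            run -= 1.0 / (n - n_h)
        best = max(best, run)
    return best


def brute_force_hwe(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE P by direct enumeration with exact rational arithmetic
    on the unnormalized table probabilities."""
    from fractions import Fraction

    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        w = Fraction(2**h * math.factorial(n),
                     math.factorial(hom_r) * math.factorial(h) * math.factorial(hom_c))
        weights[h] = w
    total = sum(weights.values())
    obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= obs) / total)


def brute_force_bh(p):
    """Step-up BH by the textbook definition: q_i = min over j with
    p_(j) >= p_(i) of p_(j) * m / rank(j), computed via sorting."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def brute_force_overlap_pairs(snp_map: pd.DataFrame, annotation: GeneAnnotation,
                              window_bp: int) -> set:
    """O(SNPs x genes) interval check."""
    pairs = set()
    for s in snp_map.itertuples(index=False):
        for g in annotation.table.itertuples(index=False):
            if str(s.chrom) == str(g.chrom) and (
                g.start - window_bp <= s.bp <= g.end + window_bp
            ):
                pairs.add((s.snp_id, g.gene_id))
    return pairs


# ---------------------------------------------------------------------------
# Small simulated fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def tiny_sim():
    """A small cohort with a causal pathway, for fast pipeline tests."""
    cfg = synthdata.SimulationConfig(
        n_samples=120,
        n_snps=60,
        n_genes=12,
        snps_per_gene=4,
        n_pathways=4,
        pathway_size_range=(3, 5),
        causal_pathway_id="PW_000",
        n_causal_genes=3,
        effect_size_beta=0.8,
        noise_sd=1.0,
        seed=7,
    )
    genotypes = synthdata.simulate_genotypes(cfg)
    annotation, pathways = synthdata.simulate_annotation_and_pathways(cfg)
    phenotype = synthdata.simulate_phenotype(genotypes, annotation, pathways, cfg)
    return cfg, genotypes, annotation, pathways, phenotype


@pytest.fixture()
def handmade_annotation():
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["GA", "GB"],
                "chrom": ["1", "1"],
                "start": [100_000, 300_000],
                "end": [150_000, 350_000],
            }
        )
    )
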