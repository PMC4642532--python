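"""Pathway enrichment for GWAS by the modified gene-set enrichment method.

Genes are ranked by their max-SNP association statistic r(1) >= ... >= r(N).
For a set S of N_H genes a weighted running sum walks the ranking, adding
``|r(j)|^p / N_R`` on member genes (``N_R = sum over S of |r|^p``) and
subtracting ``1 / (N - N_H)`` on non-members; the enrichment score ES is
the maximum of that sum (one-sided, top-of-list enrichment).  Significance
comes from phenotype-label permutation: the whole SNP-to-gene pipeline is
recomputed for each shuffled phenotype, giving per-set null ES
distributions from which the normalized score NES, an empirical P, a
pooled-null FDR and a max-statistic FWER are derived.

Genotypes, QC masks and the SNP-to-gene index do not depend on the
phenotype, so they are computed once and reused across permutations; each
permutation only re-scores SNPs against a shuffled phenotype vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import genemap
from .config import RunConfig
from .errors import ConfigurationError, PhenotypeError, StageError
from .types import CASE, CONTROL, GeneSetCollection, GenotypeMatrix, PhenotypeTable

__all__ = [
    "enrichment_score",
    "running_sum",
    "PermutationNull",
    "EnrichmentEngine",
    "permutation_null",
    "score_significance",
    "nes_fdr",
    "nes_fwer",
    "run_gengen",
]


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def running_sum(
    ranked_stats: np.ndarray, is_member: np.ndarray, weight_p: float = 1.0
) -> np.ndarray:
    """The ES running sum over a ranked gene list.

    ``ranked_stats`` are the gene statistics in rank order (largest first);
    ``is_member`` flags the set members at each rank.
    """
    r = np.asarray(ranked_stats, dtype=float)
    m = np.asarray(is_member, dtype=bool)
    n = r.size
    n_h = int(m.sum())
    if n_h < 1:
        raise ConfigurationError("gene set has no members in the ranked list")
    if n_h >= n:
        raise ConfigurationError("gene set covers the whole ranked list")
    w = np.abs(r) ** weight_p
    n_r = w[m].sum()
    if n_r == 0:
        raise ConfigurationError("all member statistics are zero (N_R = 0)")
    steps = np.where(m, w / n_r, -1.0 / (n - n_h))
    return np.cumsum(steps)


def enrichment_score(ranked: pd.DataFrame, members, weight_p: float = 1.0) -> float:
    """ES of a gene set against a ranked gene list.

    ``ranked`` is the output of :func:`pathgwas.genemap.rank_genes`
    (columns gene_id, statistic, in descending order).  ``members`` must
    already be restricted to genes present in the ranking.
    """
    gene_ids = ranked["gene_id"].to_numpy()
    member_set = frozenset(members)
    missing = member_set - set(gene_ids)
    if missing:
        raise ConfigurationError(
            f"set members absent from ranked list (restrict first): {sorted(missing)[:3]}"
        )
    mask = np.isin(gene_ids, list(member_set))
    return float(running_sum(ranked["statistic"].to_numpy(), mask, weight_p).max())


def _es_matrix(
    stats_sorted: np.ndarray, members_sorted: np.ndarray, weight_p: float
) -> np.ndarray:
    """Vectorized ES for many sets over one ranking.

    ``members_sorted``: (n_sets, n_genes) boolean indicators in rank order.
    """
    w = np.abs(stats_sorted) ** weight_p
    M = members_sorted.astype(float)
    n = stats_sorted.size
    n_h = M.sum(axis=1)
    n_r = M @ w
    steps = M * w[None, :] / n_r[:, None] - (1.0 - M) / (n - n_h)[:, None]
    return np.cumsum(steps, axis=1).max(axis=1)


# ---------------------------------------------------------------------------
# Permutation engine
# ---------------------------------------------------------------------------

@dataclass
class PermutationNull:
    """Null ES distributions from phenotype-label permutation."""

    set_ids: list[str]
    perm_es: np.ndarray  # (n_sets, K)
    seed: int
    @property
    def K(self) -> int:
        return self.perm_es.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.perm_es.mean(axis=1)

    @property
    def sd(self) -> np.ndarray:
        return self.perm_es.std(axis=1)


class EnrichmentEngine:
    """Precomputed state shared by the observed scan and every permutation.

    Holds the post-QC genotype matrix restricted to the analysis samples,
    the expanded SNP-gene pair arrays for fast per-gene maxima, the fixed
    gene universe (genes with at least one usable SNP), and the membership
    indicator matrix of the restricted gene sets.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        index: genemap.SnpGeneIndex,
        pathways: GeneSetCollection | None,
        *,
        binary: bool,
        weight_p: float = 1.0,
    ):
        self.binary = binary
        self.weight_p = weight_p
        self.values = genotypes.values
        self._flagged = assoc_mod._monomorphic_mask(self.values)
        snp_pos = {s: i for i, s in enumerate(genotypes.snp_map["snp_id"])}
        pairs = index.pairs[index.pairs["snp_id"].isin(snp_pos)]
        if pairs.empty:
            raise ConfigurationError("no SNP maps to any gene")
        # expanded arrays sorted by gene (pairs already are)
        self._pair_snp = pairs["snp_id"].map(snp_pos).to_numpy()
        gene_codes, gene_ids = pd.factorize(pairs["gene_id"], sort=True)
        starts = np.flatnonzero(np.r_[True, np.diff(gene_codes) > 0])
        # drop genes whose SNPs are all flagged (undefined statistic):
        # flagged status is genotype-only, so the universe is permutation-fixed
        probe = np.where(self._flagged, -np.inf, 0.0)[self._pair_snp]
        gene_ok = np.maximum.reduceat(probe, starts) > -np.inf
        self._starts = starts
        self._gene_keep = gene_ok
        self.gene_ids = np.asarray(gene_ids)[gene_ok]
        if self.gene_ids.size < 2:
            raise ConfigurationError("fewer than two genes retain a usable SNP")
        if pathways is None:  # universe-only engine (no sets yet)
            self.set_ids, self.sources = [], {}
            self._members = np.zeros((0, self.gene_ids.size), dtype=bool)
            return
        gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self.set_ids = list(pathways.sets)
        self.sources = dict(pathways.sources)
        self._members = np.zeros((len(self.set_ids), self.gene_ids.size), dtype=bool)
        for si, sid in enumerate(self.set_ids):
            cols = [gene_index[g] for g in pathways.sets[sid] if g in gene_index]
            if not cols:
                raise ConfigurationError(
                    f"set {sid!r} has no members in the gene universe (restrict first)"
                )
            self._members[si, cols] = True
        if (self._members.sum(axis=1) >= self.gene_ids.size).any():
            raise ConfigurationError("a set covers the whole gene universe")

    @property
    def n_sets(self) -> int:
        return len(self.set_ids)

    def gene_maxima(self, Y: np.ndarray) -> np.ndarray:
        """(n_genes, K) max-SNP statistics for each phenotype column."""
        stats = assoc_mod.stats_for_phenotypes(self.values, Y, self.binary)
        stats[self._flagged] = -np.inf
        expanded = stats[self._pair_snp]
        gmax = np.maximum.reduceat(expanded, self._starts, axis=0)
        return gmax[self._gene_keep]

    def es_for_phenotypes(self, Y: np.ndarray) -> np.ndarray:
        """(n_sets, K) enrichment scores for each phenotype column."""
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        gmax = self.gene_maxima(Y)
        n_genes = gmax.shape[0]
        idx = np.arange(n_genes)  # gene_ids are ascending: index = tie-break key
        out = np.empty((self.n_sets, Y.shape[1]))
        for k in range(Y.shape[1]):
            order = np.lexsort((idx, -gmax[:, k]))
            out[:, k] = _es_matrix(
                gmax[order, k], self._members[:, order], self.weight_p
            )
        return out

    def ranked_genes(self, y: np.ndarray) -> pd.DataFrame:
        """Observed ranked gene list (gene_id, rep_snp index dropped)."""
        gmax = self.gene_maxima(np.asarray(y, dtype=float)[:, None])[:, 0]
        df = pd.DataFrame({"gene_id": self.gene_ids, "statistic": gmax})
        return genemap.rank_genes(df)


def _check_phenotype_variance(y: np.ndarray, binary: bool) -> None:
    if binary:
        if len(np.unique(y)) < 2:
            raise PhenotypeError("binary phenotype has a single class")
    elif np.std(y) == 0:
        raise PhenotypeError("phenotype has zero variance")


def permutation_matrix(y: np.ndarray, K: int, seed: int) -> np.ndarray:
    """(n, K) matrix of label-shuffled phenotype vectors.

    One master seed spawns an independent substream per permutation, so
    increasing K extends the matrix without altering earlier columns.
    """
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    n = y.shape[0]
    children = np.random.SeedSequence(seed).spawn(K)
    Y = np.empty((n, K))
    for k, child in enumerate(children):
        Y[:, k] = y[np.random.default_rng(child).permutation(n)]
    return Y


def permutation_null(
    genotypes: GenotypeMatrix,
    prepared_phenotype: np.ndarray,
    pathways: GeneSetCollection,
    index: genemap.SnpGeneIndex,
    *,
    binary: bool,
    weight_p: float = 1.0,
    K: int = 1000,
    seed: int = 0,
) -> PermutationNull:
    """Null ES distributions from K phenotype-label permutations.

    ``prepared_phenotype`` is aligned with ``genotypes.sample_ids``
    (prepared trait values, or 0/1 control/case indicators when
    ``binary``).  QC must already have been applied to ``genotypes``.
    """
    y = np.asarray(prepared_phenotype, dtype=float)
    _check_phenotype_variance(y, binary)
    engine = EnrichmentEngine(
        genotypes, index, pathways, binary=binary, weight_p=weight_p
    )
    Y = permutation_matrix(y, K, seed)
    return PermutationNull(set_ids=engine.set_ids, perm_es=engine.es_for_phenotypes(Y), seed=seed)


# ---------------------------------------------------------------------------
# Significance: NES, empirical P, FDR, FWER
# ---------------------------------------------------------------------------

def nes_fdr(obs_nes: np.ndarray, perm_nes: np.ndarray) -> np.ndarray:
    """Permutation FDR at each observed NES.

    ``FDR(NES*) = [fraction of pooled null NES >= NES*] /
    [fraction of observed NES >= NES*]``, clipped to [0, 1] and made
    monotone non-increasing in NES* by a running minimum from the top of
    the NES ordering (the raw ratio can invert locally).
    """
    obs = np.asarray(obs_nes, dtype=float)
    pooled = np.asarray(perm_nes, dtype=float).ravel()
    out = np.empty_like(obs)
    for i, star in enumerate(obs):
        num = (pooled >= star).mean()
        den = (obs >= star).mean()
        out[i] = min(1.0, num / den)
    order = np.argsort(-obs, kind="stable")
    out[order] = np.minimum.accumulate(out[order])
    return out

def nes_fwer(obs_nes: np.ndarray, perm_nes: np.ndarray) -> np.ndarray:
    """Family-wise error rate: fraction of permutations whose maximum NES
    over all sets reaches the observed NES."""
    perm_max = np.asarray(perm_nes, dtype=float).max(axis=0)
    return np.array([(perm_max >= star).mean() for star in np.asarray(obs_nes)])


def format_empirical_p(p: float, K: int) -> str:
    """Render an add-one empirical P, using '<1/K' when no null value
    reached the observed score."""
    if p <= 1.0 / (K + 1):
        return f"<{1.0 / K:g}"
    return f"{p:g}"


def score_significance(
    obs_es: np.ndarray, null: PermutationNull, sources: dict | None = None,
    n_effective: dict | None = None,
) -> pd.DataFrame:
    """NES, empirical P, FDR and FWER for each set given its null.

    NES standardizes the observed ES by its own set's permutation mean and
    SD; each permutation ES is standardized the same way, and the FDR
    pools those null NES over all sets.  Sets with zero permutation SD are
    flagged (NES undefined) and excluded from the pooling.  The empirical
    P uses the add-one estimator ``(1 + #{ES_perm >= ES_obs}) / (K + 1)``.
    """
    obs = np.asarray(obs_es, dtype=float)
    if obs.shape[0] != len(null.set_ids):
        raise ConfigurationError("observed ES and null cover different sets")
    K = null.K
    mean, sd = null.mean, null.sd
    valid = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        nes = np.where(valid, (obs - mean) / sd, np.nan)
        perm_nes = (null.perm_es - mean[:, None]) / sd[:, None]
    emp = (1.0 + (null.perm_es >= obs[:, None]).sum(axis=1)) / (K + 1.0)
    fdr = np.full_like(obs, np.nan)
    fwer = np.full_like(obs, np.nan)
    if valid.any():
        fdr[valid] = nes_fdr(nes[valid], perm_nes[valid])
        fwer[valid] = nes_fwer(nes[valid], perm_nes[valid])
    table = pd.DataFrame(
        {
            "set_id": null.set_ids,
            "source": [
                (sources or {}).get(s, "self-defined") for s in null.set_ids
            ],
            "n_genes": [
                (n_effective or {}).get(s, np.nan) for s in null.set_ids
            ],
            "es": obs,
            "nes": nes,
            "empirical_p": emp,
            "empirical_p_display": [format_empirical_p(p, K) for p in emp],
            "fdr": fdr,
            "fwer": fwer,
        }
    )
    return table.sort_values(
        ["empirical_p", "nes"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _stage(name):
    class _Ctx:
        def __enter__(self):
            return None

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def run_gengen(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeTable,
    annotation,
    pathways: GeneSetCollection,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """The full pathway association pipeline.

    QC -> phenotype preparation (and dichotomization in binary mode) ->
    per-SNP statistics -> max-SNP gene scores -> ranking -> per-set ES ->
    phenotype-permutation null -> NES / empirical P / FDR / FWER.  Returns
    the enrichment table sorted by empirical P then NES.
    """
    config = config or RunConfig()
    binary = config.mode == "binary"

    with _stage("qc"):
        filtered, _report = assoc_mod.qc_filter(
            genotypes, maf_min=config.maf_min, hwe_min=config.hwe_min
        )

    with _stage("phenotype"):
        pheno = assoc_mod.prepare_phenotype(
            phenotype, mode=config.phenotype_mode, outlier_sd=config.outlier_sd
        )
        if binary:
            pheno = assoc_mod.dichotomize(
                pheno, case_min=config.case_min, control_max=config.control_max
            )
        df = pheno.data.set_index("sample_id")
        df = df.reindex(genotypes.sample_ids)
        if binary:
            status = df["status"].to_numpy()
            keep = np.isin(status, (CASE, CONTROL))
            y = (status[keep] == CASE).astype(float)
        else:
            prepared = df["prepared"].to_numpy(dtype=float)
            keep = np.isfinite(prepared)
            y = prepared[keep]
        if keep.sum() < 4:
            raise PhenotypeError("fewer than four analysis samples")
        analysis = GenotypeMatrix(
            values=filtered.values[keep],
            snp_map=filtered.snp_map,
            sample_ids=[s for s, k in zip(genotypes.sample_ids, keep) if k],
        )
        _check_phenotype_variance(y, binary)

    with _stage("genemap"):
        index = genemap.map_snps_to_genes(
            analysis.snp_map, annotation, window_bp=config.window_bp
        )

    with _stage("gsea"):
        # the size restriction needs the gene universe, which depends only
        # on genotypes and the index — build a set-free engine first
        probe_engine = EnrichmentEngine(
            analysis, index, None, binary=binary, weight_p=config.weight_p
        )
        universe = set(probe_engine.gene_ids)
        restricted = pathways.restrict(
            universe, size_min=config.set_size_min, size_max=config.set_size_max
        )
        if len(restricted) == 0:
            raise ConfigurationError(
                "no gene set survives the size restriction "
                f"[{config.set_size_min}, {config.set_size_max}]"
            )
        engine = EnrichmentEngine(
            analysis, index, restricted, binary=binary, weight_p=config.weight_p
        )
        obs_es = engine.es_for_phenotypes(y)[:, 0]
        Y = permutation_matrix(y, config.n_permutations, config.seed)
        null = PermutationNull(
            set_ids=engine.set_ids,
            perm_es=engine.es_for_phenotypes(Y),
            seed=config.seed,
        )
        n_eff = {s: len(restricted.sets[s]) for s in engine.set_ids}
        table = score_significance(
            obs_es, null, sources=restricted.sources, n_effective=n_eff
        )
    table.attrs["config_digest"] = config.digest()
    table.attrs["seed"] = config.seed
    table.attrs["n_permutations"] = config.n_permutations
    return table
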