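"""Phenotype preparation, SNP quality control, and per-SNP association tests.

This is the single-marker layer of the pipeline: an allelic 1-df chi-square
for a dichotomous phenotype, a simple-regression F test (1, n-2 df) for a
quantitative one, the Hardy-Weinberg exact test used for QC, trait
transformation (log10 or covariate-adjusted standardized residuals) with
+/-3 SD outlier removal, and case/control dichotomization with a gray zone.

Internally the statistics are computed from sufficient sums so that a whole
matrix of permuted phenotypes can be scored with a handful of matrix
products (see :func:`stats_for_phenotypes`); the public
:func:`snp_statistic` is a one-column view of the same arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special
from scipy import stats as sps

from .errors import ConfigurationError, PhenotypeError, QCError
from .types import CASE, CONTROL, EXCLUDED, GenotypeMatrix, PhenotypeTable

P_FLOOR = 1e-300

__all__ = [
    "SnpAssocResult",
    "hwe_exact_p",
    "qc_filter",
    "prepare_phenotype",
    "dichotomize",
    "snp_statistic",
    "association_scan",
    "stats_for_phenotypes",
]


@dataclass
class SnpAssocResult:
    """Association result for one SNP."""

    snp_id: str
    statistic: float  # chi-square (1 df) or F (1, n-2)
    p_value: float
    maf: float
    hwe_p: float
    n_used: int
    flagged: bool = False  # monomorphic: statistic undefined, reported as 0


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test P for the observed heterozygote count.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all tables no more probable than
    the observed one (the two-sided exact convention).  Returns 1.0 when a
    single table is possible (e.g. a monomorphic site).
    """
    if n_AA < 0 or n_Aa < 0 or n_aa < 0:
        raise ConfigurationError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ConfigurationError("at least one genotyped sample required")
    n_a = 2 * n_aa + n_Aa  # count of one allele
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    # log-probability of each possible heterozygote count h (same parity
    # as `rare`), from the hypergeometric-style exact distribution:
    # P(h) ∝ n! / (n_hom1! n_het! n_hom2!) * 2^h, with allele totals fixed.
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * math.log(2.0)
        - special.gammaln(hom_rare + 1)
        - special.gammaln(hets + 1)
        - special.gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_Aa)]
    # small relative slack so exactly-tied tables are always included
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _genotype_counts(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (n_0, n_1, n_2) genotype counts over non-missing calls."""
    valid = np.isfinite(values)
    n0 = ((values == 0) & valid).sum(axis=0)
    n1 = ((values == 1) & valid).sum(axis=0)
    n2 = ((values == 2) & valid).sum(axis=0)
    return n0, n1, n2


def snp_maf(values: np.ndarray) -> np.ndarray:
    """Per-SNP folded minor allele frequency over non-missing calls."""
    valid = np.isfinite(values)
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, np.nansum(values, axis=0) / (2.0 * n), np.nan)
    return np.minimum(f, 1.0 - f)


def qc_filter(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_min: float = 0.001,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNPs with MAF < ``maf_min`` or HWE exact P < ``hwe_min``.

    Returns the filtered matrix and a per-SNP report (snp_id, maf, hwe_p,
    kept, reason).  Raises :class:`QCError` (with the report attached as
    ``.report``) if nothing survives.
    """
    if genotypes.n_snps < 1:
        raise QCError("no SNPs to filter")
    n0, n1, n2 = _genotype_counts(genotypes.values)
    maf = snp_maf(genotypes.values)
    hwe = np.array(
        [hwe_exact_p(int(a), int(b), int(c)) for a, b, c in zip(n0, n1, n2)]
    )
    fail_maf = ~(maf >= maf_min)  # NaN maf (all-missing SNP) also fails
    fail_hwe = hwe < hwe_min
    reason = np.where(
        fail_maf & fail_hwe, "maf+hwe",
        np.where(fail_maf, "maf", np.where(fail_hwe, "hwe", "")),
    )
    report = pd.DataFrame(
        {
            "snp_id": genotypes.snp_map["snp_id"],
            "maf": maf,
            "hwe_p": hwe,
            "kept": ~(fail_maf | fail_hwe),
            "reason": reason,
        }
    )
    keep = report["kept"].to_numpy()
    if not keep.any():
        err = QCError("all SNPs removed by QC")
        err.report = report
        raise err
    return genotypes.subset_snps(keep), report


# ---------------------------------------------------------------------------
# Phenotype preparation
# ---------------------------------------------------------------------------

def prepare_phenotype(
    table: PhenotypeTable,
    mode: str = "covariate_adjusted",
    outlier_sd: float = 3.0,
) -> PhenotypeTable:
    """Outlier exclusion plus trait transformation.

    A single pass on the raw trait flags samples with
    ``|trait - mean| > outlier_sd * SD`` as excluded.  The remaining samples
    then get a ``prepared`` value: the raw trait (``mode='raw'``), its
    common log (``'log10'``), or OLS residuals of trait on covariate scaled
    to mean 0 / SD 1 (``'covariate_adjusted'`` — the BMI-adjustment used
    for adiponectin-style traits).
    """
    if mode not in ("raw", "log10", "covariate_adjusted"):
        raise PhenotypeError(f"unknown phenotype mode {mode!r}")
    df = table.data.copy()
    trait = df["trait"].to_numpy(dtype=float)
    mean, sd = trait.mean(), trait.std(ddof=1)
    if not sd > 0:
        raise PhenotypeError("trait has zero variance")
    excluded = np.abs(trait - mean) > outlier_sd * sd
    df["excluded"] = excluded
    prepared = np.full(len(df), np.nan)
    kept = ~excluded
    t = trait[kept]
    if mode == "raw":
        prepared[kept] = t
    elif mode == "log10":
        if (t <= 0).any():
            raise PhenotypeError("log10 mode requires strictly positive trait")
        prepared[kept] = np.log10(t)
    else:
        if "covariate" not in df.columns:
            raise PhenotypeError("covariate_adjusted mode requires a covariate column")
        c = df.loc[kept, "covariate"].to_numpy(dtype=float)
        resid = sm.OLS(t, sm.add_constant(c)).fit().resid
        rsd = resid.std(ddof=1)
        if not rsd > 0:
            raise PhenotypeError("residuals have zero variance")
        prepared[kept] = resid / rsd
    df["prepared"] = prepared
    return PhenotypeTable(df)


def dichotomize(
    table: PhenotypeTable,
    case_min: float = 10.4,
    control_max: float = 7.4,
) -> PhenotypeTable:
    """Assign case/control status with a gray zone in between.

    ``trait > case_min`` -> case, ``trait < control_max`` -> control,
    anything else (including the boundary values) -> excluded.  Samples
    already excluded as outliers stay excluded.
    """
    if not control_max < case_min:
        raise PhenotypeError(
            f"control_max ({control_max}) must be below case_min ({case_min})"
        )
    df = table.data.copy()
    trait = df["trait"].to_numpy(dtype=float)
    status = np.where(
        trait > case_min, CASE, np.where(trait < control_max, CONTROL, EXCLUDED)
    )
    if "excluded" in df.columns:
        status = np.where(df["excluded"].to_numpy(bool), EXCLUDED, status)
    df["status"] = status
    if not (status == CASE).any() or not (status == CONTROL).any():
        raise PhenotypeError("no cases/controls after dichotomization")
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# Association statistics (vectorized core + single-SNP view)
# ---------------------------------------------------------------------------

def stats_for_phenotypes(
    values: np.ndarray, Y: np.ndarray, binary: bool
) -> np.ndarray:
    """Test statistics for every SNP against every phenotype column.

    Parameters
    ----------
    values
        ``(n_samples, n_snps)`` dosages, NaN = missing (pairwise-dropped).
    Y
        ``(n_samples, K)`` phenotype matrix: prepared trait values, or
        0/1 control/case indicators when ``binary``.  No NaN.
    binary
        choose the allelic chi-square (True) or regression F (False).

    Returns
    -------
    ``(n_snps, K)`` statistics; monomorphic SNPs get 0 in every column.
    """
    values = np.asarray(values, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    mask = np.isfinite(values)
    G0 = np.where(mask, values, 0.0)
    Mf = mask.astype(float)
    n = Mf.sum(axis=0)  # (m,) non-missing per SNP
    Sx = G0.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if binary:
            n1 = Mf.T @ Y  # (m, K) cases with a genotype call
            a = G0.T @ Y  # minor alleles among cases
            N = 2.0 * n[:, None]
            r1 = 2.0 * n1  # case alleles
            r2 = N - r1  # control alleles
            c1 = Sx[:, None]  # minor alleles total
            c2 = N - c1
            b = r1 - a
            c = c1 - a
            d = r2 - c
            denom = r1 * r2 * c1 * c2
            stat = np.where(denom > 0, N * (a * d - b * c) ** 2 / denom, 0.0)
            mono = (c1 <= 0) | (c2 <= 0)
            stat = np.where(mono, 0.0, stat)
        else:
            Sxx = (G0 * G0).sum(axis=0)
            Sy = Mf.T @ Y  # (m, K)
            Syy = Mf.T @ (Y * Y)
            Sxy = G0.T @ Y
            nn = n[:, None]
            sxy = Sxy - Sx[:, None] * Sy / nn
            sxx = (Sxx - Sx**2 / n)[:, None]
            syy = Syy - Sy**2 / nn
            ssreg = np.where(sxx > 0, sxy**2 / sxx, 0.0)
            ssres = syy - ssreg
            # perfect fits: keep the statistic finite and let the caller
            # floor the P value
            ssres = np.maximum(ssres, np.maximum(syy, 1.0) * 1e-14)
            df2 = nn - 2.0
            stat = np.where((sxx > 0) & (df2 > 0), ssreg / (ssres / df2), 0.0)
    return np.maximum(stat, 0.0)


def _monomorphic_mask(values: np.ndarray) -> np.ndarray:
    """SNPs with fewer than two distinct non-missing genotype values."""
    n0, n1, n2 = _genotype_counts(values)
    return ((n0 > 0).astype(int) + (n1 > 0).astype(int) + (n2 > 0).astype(int)) < 2


def _p_from_stat(stat: np.ndarray, n_used: np.ndarray, binary: bool) -> np.ndarray:
    if binary:
        p = sps.chi2.sf(stat, df=1)
    else:
        p = sps.f.sf(stat, 1, np.maximum(n_used - 2, 1))
    return np.clip(p, P_FLOOR, 1.0)


def snp_statistic(genotype_column: np.ndarray, phenotype: np.ndarray) -> SnpAssocResult:
    """Association test for a single SNP.

    ``phenotype`` is either a numeric prepared trait (quantitative F test)
    or case/control labels — strings ``{'case','control'}`` or booleans —
    for the allelic chi-square.  Missing genotypes are dropped pairwise.
    """
    g = np.asarray(genotype_column, dtype=float)
    ph = np.asarray(phenotype)
    binary = ph.dtype.kind in ("U", "S", "O", "b")
    if binary and ph.dtype.kind != "b":
        keep = np.isin(ph, (CASE, CONTROL))
        g, ph = g[keep], ph[keep]
        y = (ph == CASE).astype(float)
    elif binary:
        y = ph.astype(float)
    else:
        keep = np.isfinite(ph.astype(float))
        g, y = g[keep], ph.astype(float)[keep]
    valid = np.isfinite(g)
    n_used = int(valid.sum())
    if binary:
        for arm in (0.0, 1.0):
            if (y[valid] == arm).sum() < 2:
                raise PhenotypeError("binary test needs >=2 samples per arm")
    col = g[:, None]
    flagged = bool(_monomorphic_mask(col)[0])
    stat = 0.0 if flagged else float(
        stats_for_phenotypes(col, y[:, None], binary)[0, 0]
    )
    p = float(_p_from_stat(np.array([stat]), np.array([n_used]), binary)[0])
    if flagged:
        p = 1.0
    n0, n1, n2 = (int(x[0]) for x in _genotype_counts(col))
    return SnpAssocResult(
        snp_id="",
        statistic=stat,
        p_value=p,
        maf=float(snp_maf(col)[0]),
        hwe_p=hwe_exact_p(n0, n1, n2),
        n_used=n_used,
        flagged=flagged,
    )


def association_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    binary: bool,
) -> pd.DataFrame:
    """Genome-wide scan: one association test per SNP.

    ``phenotype`` must align with ``genotypes.sample_ids`` and contain no
    NaN (restrict both to the analysis samples first).  Returns a frame
    with columns chrom, snp_id, bp, statistic, p, maf, hwe_p, n_used,
    flagged — the in-memory form of a PLINK ``.assoc`` table.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != genotypes.n_samples:
        raise ConfigurationError("phenotype length does not match sample count")
    values = genotypes.values
    flagged = _monomorphic_mask(values)
    stat = stats_for_phenotypes(values, y[:, None], binary)[:, 0]
    stat = np.where(flagged, 0.0, stat)
    n_used = np.isfinite(values).sum(axis=0)
    p = _p_from_stat(stat, n_used, binary)
    p = np.where(flagged, 1.0, p)
    n0, n1, n2 = _genotype_counts(values)
    hwe = np.array(
        [hwe_exact_p(int(a), int(b), int(c)) for a, b, c in zip(n0, n1, n2)]
    )
    return pd.DataFrame(
        {
            "chrom": genotypes.snp_map["chrom"],
            "snp_id": genotypes.snp_map["snp_id"],
            "bp": genotypes.snp_map["bp"],
            "statistic": stat,
            "p": p,
            "maf": snp_maf(values),
            "hwe_p": hwe,
            "n_used": n_used,
            "flagged": flagged,
        }
    )
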