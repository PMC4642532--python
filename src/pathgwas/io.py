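"""Readers and writers for the standard text formats.

Formats: GMT gene sets; BED-like gene annotation (0-based half-open on
disk, converted to 1-based inclusive in memory); genotypes as a
sample x SNP TSV of {0,1,2,NA} with a MAP-like SNP table, or as PED/MAP
text; phenotype TSV; PLINK ``.assoc``-style association tables; and the
enrichment reports.  Every writer produces files its paired reader parses
losslessly, and reports are byte-stable for a fixed configuration and
seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .types import GeneAnnotation, GeneSetCollection, GenotypeMatrix, PhenotypeTable

_SOURCES = ("BioCarta", "KEGG", "GO")
_FLOAT_FMT = "%.10g"

__all__ = [
    "read_gmt", "write_gmt",
    "read_annotation", "write_annotation",
    "read_genotypes", "write_genotypes", "read_ped",
    "read_phenotype", "write_phenotype",
    "read_assoc", "write_assoc",
    "write_enrichment_report", "write_setz_report",
]


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: set_id TAB description TAB member genes...

    Duplicate members are de-duplicated; a description naming a known
    database (BioCarta/KEGG/GO) becomes the source label.
    """
    sets: dict[str, frozenset] = {}
    sources: dict[str, str] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{ln}: GMT line needs >= 3 tab-separated fields")
        sid, desc, members = fields[0], fields[1], fields[2:]
        members = [m for m in members if m]
        if not members:
            raise ParseError(f"{path}:{ln}: gene set {sid!r} has no members")
        sets[sid] = frozenset(members)
        sources[sid] = desc if desc in _SOURCES else "self-defined"
    return GeneSetCollection(sets=sets, sources=sources)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Canonical GMT: sets in id order, members sorted."""
    lines = []
    for sid in sorted(collection.sets):
        members = "\t".join(sorted(collection.sets[sid]))
        lines.append(f"{sid}\t{collection.sources[sid]}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation (BED-like)
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> GeneAnnotation:
    """BED-like annotation: chrom, start (0-based), end (exclusive), gene_id."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "gene_id"],
            dtype={"chrom": str, "gene_id": str},
        )
    except Exception as exc:
        raise ParseError(f"{path}: not a 4-column BED-like file: {exc}") from exc
    df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(int)
    return GeneAnnotation(df[["gene_id", "chrom", "start", "end"]])


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    df = annotation.table.copy()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int) - 1,  # back to 0-based half-open
            "end": df["end"].astype(int),
            "gene_id": df["gene_id"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _read_snp_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] == 3:
        df.columns = ["chrom", "snp_id", "bp"]
    elif df.shape[1] >= 4:  # PLINK .map: chrom, snp_id, cm, bp
        df = df.iloc[:, [0, 1, 3]]
        df.columns = ["chrom", "snp_id", "bp"]
    else:
        raise ParseError(f"{path}: SNP map needs 3 or 4 columns")
    df["bp"] = df["bp"].astype(int)
    return df


def write_genotypes(
    genotypes: GenotypeMatrix, path_genotypes: str | Path, path_map: str | Path
) -> None:
    """Sample x SNP TSV ({0,1,2,NA}) plus a 3-column MAP-like SNP table."""
    vals = genotypes.values
    df = pd.DataFrame(
        np.where(np.isfinite(vals), vals, np.nan),
        columns=genotypes.snp_map["snp_id"],
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
    )
    df.to_csv(path_genotypes, sep="\t", na_rep="NA", float_format="%.0f")
    genotypes.snp_map[["chrom", "snp_id", "bp"]].to_csv(
        path_map, sep="\t", header=False, index=False
    )


def read_genotypes(path_genotypes: str | Path, path_map: str | Path) -> GenotypeMatrix:
    """Read the sample x SNP TSV with its MAP-like table.

    The map defines the SNP order; TSV columns are matched by id and must
    agree with the map exactly.
    """
    snp_map = _read_snp_map(path_map)
    df = pd.read_csv(path_genotypes, sep="\t", index_col=0, na_values=["NA"])
    tsv_ids = list(df.columns)
    map_ids = snp_map["snp_id"].tolist()
    if sorted(tsv_ids) != sorted(map_ids):
        raise ParseError(
            f"{path_genotypes}: SNP columns do not match {path_map} "
            f"({len(tsv_ids)} vs {len(map_ids)} SNPs)"
        )
    df = df[map_ids]
    return GenotypeMatrix(
        values=df.to_numpy(dtype=float),
        snp_map=snp_map,
        sample_ids=[str(s) for s in df.index],
    )


def read_ped(path_ped: str | Path, path_map: str | Path) -> GenotypeMatrix:
    """PED/MAP text genotypes, coded additively against the minor allele.

    Each PED row is FID IID PAT MAT SEX PHENO followed by two allele
    columns per SNP ('0' = missing).  Sites with more than two alleles
    raise a :class:`ParseError` naming the SNP; at a site with equally
    frequent alleles the lexicographically larger one counts as minor.
    """
    snp_map = _read_snp_map(path_map)
    m = len(snp_map)
    sample_ids: list[str] = []
    rows: list[list[str]] = []
    for ln, raw in enumerate(Path(path_ped).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split()
        if len(fields) != 6 + 2 * m:
            raise ParseError(
                f"{path_ped}:{ln}: expected {6 + 2 * m} fields for {m} SNPs, "
                f"got {len(fields)}"
            )
        sample_ids.append(fields[1])
        rows.append(fields[6:])
    alleles = np.array(rows, dtype=object).reshape(len(rows), m, 2)
    values = np.full((len(rows), m), np.nan)
    for j in range(m):
        site = alleles[:, j, :]
        observed = site[site != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if uniq.size > 2:
            raise ParseError(
                f"{path_ped}: SNP {snp_map['snp_id'].iloc[j]} is not biallelic "
                f"(alleles {sorted(uniq)})"
            )
        if uniq.size == 0:
            continue  # all missing
        if uniq.size == 1:
            minor = uniq[0]  # monomorphic: dosage counts the only allele
            values[:, j] = (site == minor).sum(axis=1)
        else:
            order = np.argsort(counts, kind="stable")
            if counts[0] == counts[1]:
                minor = max(uniq)
            else:
                minor = uniq[order[0]]
            values[:, j] = (site == minor).sum(axis=1)
        missing = (site == "0").any(axis=1)
        values[missing, j] = np.nan
    return GenotypeMatrix(values=values, snp_map=snp_map, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def write_phenotype(table: PhenotypeTable, path: str | Path) -> None:
    cols = [c for c in ("sample_id", "trait", "covariate") if c in table.data.columns]
    table.data[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_phenotype(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "trait" not in df.columns:
        raise ParseError(f"{path}: phenotype TSV needs sample_id and trait columns")
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# Association tables (PLINK .assoc style)
# ---------------------------------------------------------------------------

def write_assoc(scan: pd.DataFrame, path: str | Path, binary: bool) -> None:
    """PLINK-compatible association TSV: CHR SNP BP CHISQ|F P MAF."""
    stat_col = "CHISQ" if binary else "F"
    out = pd.DataFrame(
        {
            "CHR": scan["chrom"],
            "SNP": scan["snp_id"],
            "BP": scan["bp"],
            stat_col: scan["statistic"],
            "P": scan["p"],
            "MAF": scan["maf"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_assoc(path: str | Path) -> pd.DataFrame:
    """Read a PLINK ``.assoc``-style table; needs CHR, SNP, BP, P (extra
    columns are ignored).  Returns columns chrom, snp_id, bp, p."""
    df = pd.read_csv(path, sep=r"\s+", dtype={"CHR": str, "SNP": str})
    missing = [c for c in ("CHR", "SNP", "BP", "P") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: association table missing columns {missing}")
    out = df.rename(columns={"CHR": "chrom", "SNP": "snp_id", "BP": "bp", "P": "p"})
    out["bp"] = out["bp"].astype(int)
    out["p"] = out["p"].astype(float)
    return out[["chrom", "snp_id", "bp", "p"]]


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _header_lines(table: pd.DataFrame, kind: str) -> list[str]:
    lines = [f"# pathgwas {kind} report"]
    meta = []
    for key in ("config_digest", "seed", "n_permutations"):
        if key in table.attrs:
            meta.append(f"{key}={table.attrs[key]}")
    if meta:
        lines.append("# " + " ".join(meta))
    return lines


def write_enrichment_report(table: pd.DataFrame, path: str | Path) -> None:
    """Enrichment report: set_id, database, n_genes, ES, NES,
    empirical_P, FDR, FWER, with a '#' header recording config and seed."""
    out = pd.DataFrame(
        {
            "set_id": table["set_id"],
            "database": table["source"],
            "n_genes": table["n_genes"],
            "ES": table["es"],
            "NES": table["nes"],
            "empirical_P": table["empirical_p_display"],
            "empirical_P_value": table["empirical_p"],
            "FDR": table["fdr"],
            "FWER": table["fwer"],
        }
    )
    body = out.to_csv(sep="\t", index=False, float_format="%.6g")
    text = "\n".join(_header_lines(table, "gengen")) + "\n" + body
    Path(path).write_text(text)


def write_setz_report(table: pd.DataFrame, path: str | Path) -> None:
    """Replication-mode report: set_id, database, m, mean_score, z, P, q."""
    out = pd.DataFrame(
        {
            "set_id": table["set_id"],
            "database": table["source"],
            "m": table["m"],
            "mean_score": table["mean_score"],
            "z": table["z"],
            "P": table["p"],
            "q": table["q"],
        }
    )
    body = out.to_csv(sep="\t", index=False, float_format="%.6g")
    text = "\n".join(_header_lines(table, "gsasnp")) + "\n" + body
    Path(path).write_text(text)
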