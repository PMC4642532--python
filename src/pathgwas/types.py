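"""Core in-memory containers shared by all pipeline stages.

Coordinates are 1-based inclusive internally (converted from 0-based
half-open BED at the file boundary).  Genotypes use additive minor-allele
dosage coding {0, 1, 2} stored as floats with NaN for missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

MISSING = np.nan

#: phenotype status codes for the dichotomous analysis
CASE = "case"
CONTROL = "control"
EXCLUDED = "excluded"


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosages with a physical SNP map.

    Parameters
    ----------
    values
        float array of shape ``(n_samples, n_snps)`` with entries in
        ``{0, 1, 2}`` or NaN for missing calls.
    snp_map
        DataFrame with columns ``chrom`` (str), ``snp_id`` (str, unique)
        and ``bp`` (1-based int position); optional extra columns (e.g.
        ``maf_true`` from the simulator) are carried along.
    sample_ids
        one identifier per row of ``values``.
    """

    values: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("genotype values must be 2-D (samples x SNPs)")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ConfigurationError(
                f"{len(self.sample_ids)} sample ids for {n} genotype rows"
            )
        if len(self.snp_map) != m:
            raise ConfigurationError(
                f"snp_map has {len(self.snp_map)} rows for {m} SNP columns"
            )
        for col in ("chrom", "snp_id", "bp"):
            if col not in self.snp_map.columns:
                raise ConfigurationError(f"snp_map missing column {col!r}")
        if self.snp_map["snp_id"].duplicated().any():
            raise ConfigurationError("snp_ids must be unique")
        if (self.snp_map["bp"] < 1).any():
            raise ConfigurationError("bp positions must be >= 1")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ConfigurationError("genotype dosages must be 0, 1, 2 or missing")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_map["snp_id"].tolist()

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to SNP columns selected by ``keep``
        (boolean mask or integer index array)."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            values=self.values[:, keep],
            snp_map=self.snp_map.iloc[keep].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class PhenotypeTable:
    """Per-sample trait, covariate and derived columns.

    ``data`` always has ``sample_id`` and ``trait``; ``covariate`` is
    optional.  :func:`pathgwas.assoc.prepare_phenotype` adds ``prepared``
    and ``excluded`` (outlier mask); :func:`pathgwas.assoc.dichotomize`
    adds ``status`` in {case, control, excluded}.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.data.columns or "trait" not in self.data.columns:
            raise ConfigurationError("phenotype table needs sample_id and trait")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(self.data.copy())


@dataclass
class GeneAnnotation:
    """Gene spans, 1-based inclusive.

    ``table`` columns: ``gene_id`` (unique), ``chrom``, ``start``, ``end``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("gene_id", "chrom", "start", "end"):
            if col not in self.table.columns:
                raise ConfigurationError(f"annotation missing column {col!r}")
        if self.table["gene_id"].duplicated().any():
            raise ConfigurationError("gene_ids must be unique")
        if (self.table["start"] > self.table["end"]).any():
            raise ConfigurationError("gene start must be <= end")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()


@dataclass
class GeneSetCollection:
    """Named pathways -> member gene ids, with a source-database label.

    ``sets`` maps set_id -> frozenset of gene ids; ``sources`` maps
    set_id -> one of {BioCarta, KEGG, GO, self-defined}.
    """

    sets: dict[str, frozenset]
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if not members:
                raise ConfigurationError(f"gene set {sid!r} is empty")
            self.sets[sid] = frozenset(members)
        for sid in self.sets:
            self.sources.setdefault(sid, "self-defined")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restrict(self, universe, size_min: int = 1, size_max: int | None = None
                 ) -> "GeneSetCollection":
        """Intersect every set with ``universe`` and drop sets whose
        effective size falls outside ``[size_min, size_max]`` or equals the
        whole universe (the miss increment would be undefined)."""
        universe = frozenset(universe)
        out: dict[str, frozenset] = {}
        src: dict[str, str] = {}
        for sid, members in self.sets.items():
            eff = members & universe
            if len(eff) < size_min:
                continue
            if size_max is not None and len(eff) > size_max:
                continue
            if len(eff) >= len(universe):
                continue
            out[sid] = eff
            src[sid] = self.sources[sid]
        return GeneSetCollection(sets=out, sources=src)
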