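"""Synthetic cohorts with the structure the pathway pipeline assumes.

Generates biallelic SNPs in Hardy-Weinberg equilibrium (independent sites,
no LD), genes tiled along a chromosome with their SNPs inside the span
plus extra SNPs in the +/-20 kb flanks, pathways drawn from the gene pool,
and a quantitative trait with additive effects concentrated in one
designated causal pathway (one causal SNP per causal gene) plus a
standard-normal covariate.  Everything is reproducible from a single seed,
and the causal structure is recorded so downstream tests can check
recovery against the simulated truth.

The default configuration is the study condition used throughout the test
suite: 500 samples, 2000 SNPs over 200 genes, 50 pathways of 10-20 genes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_mod
from .errors import ConfigurationError, SimulationError
from .types import GeneAnnotation, GeneSetCollection, GenotypeMatrix, PhenotypeTable

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_annotation_and_pathways",
    "simulate_phenotype",
    "make_fixture",
    "scenario_config",
    "SCENARIOS",
]

_SNP_SPACING_BP = 1_000
_CHROM = "1"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    ``snps_per_gene`` is either an int (fixed count per gene) or a
    ``(lo, hi)`` pair drawn uniformly per gene; any SNPs left over after
    the per-gene allocation are placed alternately in 20 kb flanks and in
    deep intergenic space, to exercise the window logic.
    """

    n_samples: int = 500
    n_snps: int = 2000
    maf_range: tuple = (0.05, 0.5)
    n_genes: int = 200
    snps_per_gene: int | tuple = 9
    intergenic_gap_bp: int = 50_000
    n_pathways: int = 50
    pathway_size_range: tuple = (10, 20)
    causal_pathway_id: str | None = None
    n_causal_genes: int = 10
    effect_size_beta: float = 0.0
    covariate_effect: float = 0.5
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    trait_mean: float | None = None
    trait_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for name in ("n_samples", "n_snps", "n_genes", "n_pathways"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not self.noise_sd > 0:
            raise ConfigurationError("noise_sd must be > 0")
        slo, shi = self.pathway_size_range
        if not (1 <= slo <= shi):
            raise ConfigurationError("invalid pathway_size_range")
        if shi > self.n_genes:
            raise ConfigurationError(
                f"pathway_size_range max {shi} exceeds n_genes {self.n_genes}"
            )
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.causal_pathway_id is not None and self.n_causal_genes > shi:
            raise ConfigurationError(
                "n_causal_genes exceeds the maximum pathway size"
            )

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _gene_counts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    spg = config.snps_per_gene
    if isinstance(spg, tuple):
        lo, hi = spg
        counts = rng.integers(lo, hi + 1, size=config.n_genes)
    else:
        counts = np.full(config.n_genes, int(spg))
    if (counts < 1).any():
        raise ConfigurationError("snps_per_gene must be >= 1")
    if counts.sum() > config.n_snps:
        raise ConfigurationError(
            f"per-gene allocation ({counts.sum()}) exceeds n_snps ({config.n_snps})"
        )
    return counts


def _layout(config: SimulationConfig):
    """Deterministic genome layout shared by the genotype and annotation ops.

    Returns (gene table, sorted SNP position array).  Uses its own seed
    stream so both operations agree given the same config.
    """
    rng = config._rng(1)
    counts = _gene_counts(config, rng)
    cursor = 100_000
    genes = []
    positions: list[int] = []
    for g, c in enumerate(counts):
        start = cursor
        end = start + (int(c) + 1) * _SNP_SPACING_BP - 1
        genes.append(
            {"gene_id": f"G{g:04d}", "chrom": _CHROM, "start": start, "end": end}
        )
        positions.extend(start + _SNP_SPACING_BP * (i + 1) for i in range(int(c)))
        cursor = end + 1 + config.intergenic_gap_bp
    leftover = config.n_snps - int(counts.sum())
    flank_reps: dict[int, int] = {}
    for i in range(leftover):
        g = i % config.n_genes
        rep = flank_reps.get(g, 0)
        flank_reps[g] = rep + 1
        end = genes[g]["end"]
        if i % 2 == 0:  # inside the 20 kb flank
            positions.append(end + 10_000 + 7 * rep)
        else:  # deep intergenic: outside every window when the gap allows
            positions.append(end + 25_000 + 7 * rep)
    positions = np.asarray(sorted(set(positions)), dtype=int)
    if positions.size != config.n_snps:
        raise SimulationError("SNP position collision in layout")
    gene_table = pd.DataFrame(genes)
    return gene_table, positions


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw HWE genotypes: per-SNP MAF ~ Uniform(maf_range), dosages
    i.i.d. Binomial(2, f).  The drawn frequency is stored in the SNP map
    as ``maf_true``."""
    _, positions = _layout(config)
    rng = config._rng(0)
    f = rng.uniform(*config.maf_range, size=config.n_snps)
    values = rng.binomial(2, f, size=(config.n_samples, config.n_snps)).astype(float)
    if config.missing_rate > 0:
        miss = rng.random(values.shape) < config.missing_rate
        values[miss] = np.nan
    snp_map = pd.DataFrame(
        {
            "chrom": _CHROM,
            "snp_id": [f"rs{i + 1:06d}" for i in range(config.n_snps)],
            "bp": positions,
            "maf_true": f,
        }
    )
    return GenotypeMatrix(
        values=values,
        snp_map=snp_map,
        sample_ids=[f"S{i + 1:04d}" for i in range(config.n_samples)],
    )


def simulate_annotation_and_pathways(
    config: SimulationConfig,
) -> tuple[GeneAnnotation, GeneSetCollection]:
    """Tile genes without overlap and draw pathways from the gene pool.

    Pathway ids are ``PW_000``..; when ``config.causal_pathway_id`` names
    one of them, that pathway's size is drawn no smaller than
    ``n_causal_genes`` so the causal genes fit inside it.
    """
    gene_table, _ = _layout(config)
    rng = config._rng(1)
    _gene_counts(config, rng)  # advance the stream identically to _layout
    lo, hi = config.pathway_size_range
    gene_ids = gene_table["gene_id"].to_numpy()
    sets: dict[str, frozenset] = {}
    for p in range(config.n_pathways):
        pid = f"PW_{p:03d}"
        p_lo = lo
        if pid == config.causal_pathway_id:
            p_lo = max(lo, config.n_causal_genes)
        size = int(rng.integers(p_lo, hi + 1))
        members = rng.choice(gene_ids, size=size, replace=False)
        sets[pid] = frozenset(members.tolist())
    if config.causal_pathway_id is not None and config.causal_pathway_id not in sets:
        raise ConfigurationError(
            f"causal_pathway_id {config.causal_pathway_id!r} is not a generated id"
        )
    sources = {pid: "self-defined" for pid in sets}
    return GeneAnnotation(gene_table), GeneSetCollection(sets=sets, sources=sources)


def _causal_genes(pathways: GeneSetCollection, config: SimulationConfig) -> list[str]:
    members = sorted(pathways.sets[config.causal_pathway_id])
    return members[: config.n_causal_genes]


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    annotation: GeneAnnotation,
    pathways: GeneSetCollection,
    config: SimulationConfig,
) -> PhenotypeTable:
    """Additive quantitative trait with effects in the causal pathway.

    ``y_i = sum_j beta * (g_ij - 2 f_j) + gamma * c_i + eps_i`` over one
    causal SNP per causal gene (the first SNP inside the gene span), with
    ``c ~ N(0,1)`` and ``eps ~ N(0, noise_sd^2)``.  The causal gene/SNP
    ids are recorded in ``table.data.attrs['truth']``.
    """
    rng = config._rng(2)
    n = genotypes.n_samples
    y = np.zeros(n)
    truth = {"causal_pathway": config.causal_pathway_id, "causal_genes": [],
             "causal_snps": []}
    if config.causal_pathway_id is not None and config.effect_size_beta != 0:
        gene_rows = annotation.table.set_index("gene_id")
        bp = genotypes.snp_map["bp"].to_numpy()
        chrom = genotypes.snp_map["chrom"].to_numpy()
        if "maf_true" in genotypes.snp_map.columns:
            f_all = genotypes.snp_map["maf_true"].to_numpy(dtype=float)
        else:
            f_all = np.nanmean(genotypes.values, axis=0) / 2.0
        for gid in _causal_genes(pathways, config):
            row = gene_rows.loc[gid]
            inside = np.flatnonzero(
                (chrom == str(row["chrom"]))
                & (bp >= int(row["start"]))
                & (bp <= int(row["end"]))
            )
            if inside.size == 0:
                raise SimulationError(f"causal gene {gid} has no SNP in its span")
            j = int(inside[0])
            g = genotypes.values[:, j]
            g = np.where(np.isfinite(g), g, 2.0 * f_all[j])  # mean-impute missing
            y = y + config.effect_size_beta * (g - 2.0 * f_all[j])
            truth["causal_genes"].append(gid)
            truth["causal_snps"].append(genotypes.snp_map["snp_id"].iloc[j])
    covariate = rng.standard_normal(n)
    y = y + config.covariate_effect * covariate
    y = y + rng.normal(0.0, config.noise_sd, size=n)
    if config.trait_mean is not None:
        sd = config.trait_sd if config.trait_sd is not None else 1.0
        y = (y - y.mean()) / y.std(ddof=0) * sd + config.trait_mean
    table = PhenotypeTable(
        pd.DataFrame(
            {"sample_id": genotypes.sample_ids, "trait": y, "covariate": covariate}
        )
    )
    table.data.attrs["truth"] = truth
    return table


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------

SCENARIOS = ("null", "causal_pathway", "tiny_worked_example")


def scenario_config(scenario: str, seed: int) -> SimulationConfig:
    """The fixed study conditions behind each named fixture scenario."""
    if scenario == "null":
        return SimulationConfig(seed=seed)
    if scenario == "causal_pathway":
        return SimulationConfig(
            causal_pathway_id="PW_000",
            n_causal_genes=10,
            effect_size_beta=0.5,
            noise_sd=1.0,
            seed=seed,
        )
    if scenario == "tiny_worked_example":
        return SimulationConfig(
            n_samples=60,
            n_snps=12,
            n_genes=5,
            snps_per_gene=2,
            n_pathways=2,
            pathway_size_range=(2, 2),
            causal_pathway_id="PW_000",
            n_causal_genes=2,
            effect_size_beta=1.0,
            noise_sd=1.0,
            seed=seed,
        )
    raise ConfigurationError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")


def make_fixture(scenario: str, seed: int, out_dir: str | Path) -> dict:
    """Simulate a scenario and write it to disk in the standard formats.

    Writes genotypes.tsv, snps.map, phenotype.tsv, genes.bed, sets.gmt and
    a truth.json sidecar; returns the path dict.
    """
    config = scenario_config(scenario, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes = simulate_genotypes(config)
    annotation, pathways = simulate_annotation_and_pathways(config)
    phenotype = simulate_phenotype(genotypes, annotation, pathways, config)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "snp_map": out / "snps.map",
        "phenotype": out / "phenotype.tsv",
        "annotation": out / "genes.bed",
        "gmt": out / "sets.gmt",
        "truth": out / "truth.json",
    }
    io_mod.write_genotypes(genotypes, paths["genotypes"], paths["snp_map"])
    io_mod.write_phenotype(phenotype, paths["phenotype"])
    io_mod.write_annotation(annotation, paths["annotation"])
    io_mod.write_gmt(pathways, paths["gmt"])
    truth = dict(phenotype.data.attrs.get("truth", {}))
    truth.update({"scenario": scenario, "seed": seed, "config": asdict(config)})
    paths["truth"].write_text(json.dumps(truth, indent=2, default=str) + "\n")
    return {k: str(v) for k, v in paths.items()}
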