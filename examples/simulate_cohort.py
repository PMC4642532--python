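"""Simulate a GWAS cohort with a causal pathway and write it to disk.

The generator tiles genes along a chromosome, draws HWE genotypes with
MAF in [0.05, 0.5], samples pathways from the gene pool, and builds a
quantitative trait whose additive genetic signal sits entirely inside one
designated pathway (one causal SNP per causal gene).
"""

import json
from pathlib import Path

from pathgwas import synthdata

out = Path("scratch/example_cohort")
paths = synthdata.make_fixture("causal_pathway", seed=7, out_dir=out)
truth = json.loads(Path(paths["truth"]).read_text())

cfg = synthdata.scenario_config("causal_pathway", 7)
print(f"cohort: {cfg.n_samples} samples, {cfg.n_snps} SNPs, "
      f"{cfg.n_genes} genes, {cfg.n_pathways} pathways")
print(f"causal pathway: {truth['causal_pathway']} "
      f"({len(truth['causal_genes'])} causal genes, beta = {cfg.effect_size_beta})")
print("files:")
for name, p in paths.items():
    print(f"  {name:10s} {p}")
# The truth sidecar names the causal genes/SNPs so downstream analyses can
# be scored against the simulated ground truth.
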