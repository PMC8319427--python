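"""Generate the synthetic multibreed cohort used by the downstream steps.

Writes genotypes (VCF + TSV dialect), the taxon relative-abundance table,
and sample metadata (breed group/fraction, sex, age, body weights, IgG1)
under results/data/, plus a ground-truth sidecar for later comparison.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from herdscan import io
from herdscan.synth import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2026

config = SimulationConfig(
    seed=SEED,
    n_individuals=200,
    n_snps=2000,
    n_taxa=100,
    taxon_h2=np.linspace(0.05, 0.5, 100),  # a spread of heritabilities
    breed_slope=np.where(np.arange(100) < 15, 1.5, 0.0),
    phenotype_m2={"WG": 0.106, "IgG1": 0.100},
)

OUT.mkdir(parents=True, exist_ok=True)
truth, geno, abundance, meta = simulate_cohort(config)
io.write_vcf(geno, OUT / "genotypes.vcf")
io.write_genotype_tsv(geno, OUT / "genotypes.tsv")
io.write_abundance_tsv(abundance, OUT / "abundance.tsv")
io.write_metadata_csv(meta, OUT / "metadata.csv")
pd.DataFrame(
    {"taxon": abundance.columns, "true_h2": truth.true_h2,
     "breed_slope": np.where(np.arange(100) < 15, 1.5, 0.0)}
).to_csv(OUT / "truth_taxa.tsv", sep="\t", index=False)

print(f"cohort: {geno.n_individuals} animals x {geno.n_snps} SNPs, "
      f"{abundance.shape[1]} taxa, seed {SEED}")
print(f"breed groups: {meta['breed_group'].value_counts().sort_index().to_dict()}")
print(f"wrote inputs to {OUT}")
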