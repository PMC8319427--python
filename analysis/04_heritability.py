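"""Estimate the heritability of every core taxon's log abundance with the
single-random-effect animal model (VanRaden GRM, REML), and compare the
estimates with the planted ground truth."""

from pathlib import Path

import numpy as np
import pandas as pd

from herdscan import io
from herdscan.diversity import core_taxa_filter, log10_floor_transform
from herdscan.mixed_model import genomic_relationship_matrix, reml_single_component

BASE = Path(__file__).resolve().parent.parent / "results"
geno = io.read_genotype_tsv(BASE / "qc" / "genotypes_postqc.tsv")
abundance = io.read_abundance_tsv(BASE / "data" / "abundance.tsv").loc[
    geno.individuals
]
meta = io.read_metadata_csv(BASE / "data" / "metadata.csv").loc[geno.individuals]
truth = pd.read_csv(BASE / "data" / "truth_taxa.tsv", sep="\t").set_index("taxon")

core = core_taxa_filter(abundance)
log_core = log10_floor_transform(core)
grm = genomic_relationship_matrix(geno)
age_c = meta["age_days"].to_numpy(float)
x = np.column_stack(
    [np.ones(len(meta)), (meta["sex"] == "M").astype(float),
     age_c - age_c.mean()]
)

rows = []
for taxon in log_core.columns:
    vc = reml_single_component(log_core[taxon].to_numpy(), x, grm)
    rows.append({"taxon": taxon, "h2_hat": vc.ratio,
                 "true_h2": truth.at[taxon, "true_h2"],
                 "flat": vc.flat_likelihood})
h2 = pd.DataFrame(rows).set_index("taxon")
out = BASE / "heritability"
out.mkdir(parents=True, exist_ok=True)
h2.to_csv(out / "heritability.tsv", sep="\t")

ok = ~h2["flat"]
bias = (h2.loc[ok, "h2_hat"] - h2.loc[ok, "true_h2"]).mean()
print(f"{len(h2)} core taxa; REML h2 range "
      f"{h2['h2_hat'].min():.2f}-{h2['h2_hat'].max():.2f}")
print(f"mean(estimate - planted) over core taxa: {bias:+.3f}")
print("note: single-cohort per-taxon estimates at n=200 carry large "
      "sampling noise (sd ~0.3); unbiasedness holds across replicate "
      "cohorts, not within one (see the recovery simulations)")
print("top 5 taxa by estimated h2 (winner's curse expected):")
print(h2.sort_values('h2_hat', ascending=False).head(5).round(3))
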