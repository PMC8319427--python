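"""Link the microbiota to host phenotypes: breed-composition association
scan over core taxa, microbiability of weight gain and IgG1, and per-taxon
phenotype scans with and without the animal effect."""

from pathlib import Path

import numpy as np

from herdscan import io
from herdscan.association import (
    breed_association_scan,
    phenotype_association_scan,
    summarize_scan,
)
from herdscan.diversity import core_taxa_filter, log10_floor_transform
from herdscan.mixed_model import (
    genomic_relationship_matrix,
    microbial_relationship_matrix,
    reml_single_component,
)

BASE = Path(__file__).resolve().parent.parent / "results"
geno = io.read_genotype_tsv(BASE / "qc" / "genotypes_postqc.tsv")
abundance = io.read_abundance_tsv(BASE / "data" / "abundance.tsv").loc[
    geno.individuals
]
meta = io.read_metadata_csv(BASE / "data" / "metadata.csv").loc[geno.individuals]

log_core = log10_floor_transform(core_taxa_filter(abundance))
out = BASE / "associations"
out.mkdir(parents=True, exist_ok=True)

breed = breed_association_scan(log_core, meta)
breed.to_csv(out / "breed_scan.tsv", sep="\t")
summary = summarize_scan(breed)
print(f"breed composition: {summary['n_associated']} of "
      f"{summary['n_total']} core taxa associated or tendency "
      f"({summary['percent_associated']}%)")

m_mat = microbial_relationship_matrix(log_core)
age_c = meta["age_days"].to_numpy(float)
x = np.column_stack(
    [np.ones(len(meta)), (meta["sex"] == "M").astype(float),
     age_c - age_c.mean()]
)
for col, label in (("WG_preweaning", "weight gain"), ("IgG1", "IgG1")):
    vc = reml_single_component(meta[col].to_numpy(float), x, m_mat)
    print(f"microbiability of {label}: m2 = {vc.ratio:.3f}")

grm = genomic_relationship_matrix(geno)
vc_wg = reml_single_component(
    meta["WG_preweaning"].to_numpy(float), x, grm
)
plain = phenotype_association_scan(meta, log_core, "WG", "preweaning")
mixed = phenotype_association_scan(
    meta, log_core, "WG", "preweaning",
    with_animal_effect=True, grm=grm, vc=vc_wg,
)
plain.to_csv(out / "wg_scan_ols.tsv", sep="\t")
mixed.to_csv(out / "wg_scan_animal_model.tsv", sep="\t")
kept = (
    plain["class"].isin(["significant", "tendency"])
    & mixed["class"].isin(["significant", "tendency"])
).sum()
print(f"weight-gain scan: {summarize_scan(plain)['n_associated']} taxa "
      f"(multiple regression), of which {int(kept)} remain when the "
      "animal effect is controlled")
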