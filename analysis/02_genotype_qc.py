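"""Quality-control the simulated genotypes with the five-step filter chain
(call rate, het/IBS outliers, MAF, HWE, Y chromosome) and report what was
removed and why."""

from pathlib import Path

from herdscan import io
from herdscan.qc import apply_qc

BASE = Path(__file__).resolve().parent.parent / "results"
geno = io.read_genotype_tsv(BASE / "data" / "genotypes.tsv")

kept, report = apply_qc(geno)
out = BASE / "qc"
out.mkdir(parents=True, exist_ok=True)
io.write_genotype_tsv(kept, out / "genotypes_postqc.tsv")
report.removed_snps.to_csv(out / "removed_snps.tsv", sep="\t", index=False)
report.removed_individuals.to_csv(
    out / "removed_individuals.tsv", sep="\t", index=False
)

print(f"input: {geno.n_individuals} animals x {geno.n_snps} SNPs")
print(f"kept:  {kept.n_individuals} animals x {kept.n_snps} SNPs")
if len(report.removed_snps):
    print("SNP removals by reason:",
          report.removed_snps["reason"].value_counts().to_dict())
if len(report.removed_individuals):
    print("individual removals by reason:",
          report.removed_individuals["reason"].value_counts().to_dict())
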