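"""End-to-end orchestration of the per-stage workflow.

Order of stages for one growth-stage cohort: genotype QC -> core-taxon
filter and floor-log transform -> diversity (Shannon, Bray-Curtis, PCoA,
PERMANOVA over breed groups) -> heritability per core taxon -> breed and
phenotype association scans -> two-step GWAS for selected taxa ->
microbiability -> co-occurrence network -> genotype-breed correlation.
Every run writes a manifest recording the seed, thresholds and design
flags so a config + seed reproduces the output directory exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, association, diversity, io, network, qc
from . import mixed_model as mm
from .datatypes import PipelineError
from .synth import SimulationConfig, simulate_cohort

log = logging.getLogger("herdscan")

ALL_STAGES = (
    "qc",
    "diversity",
    "heritability",
    "assoc",
    "gwas",
    "microbiability",
    "network",
    "maf_breed",
)


@dataclass
class PipelineConfig:
    """Run configuration; thresholds default to the study's printed values."""

    seed: int
    out_dir: str
    genotype_path: str | None = None
    abundance_path: str | None = None
    metadata_path: str | None = None
    simulate: dict | None = None  # SimulationConfig kwargs
    stages: tuple = ALL_STAGES
    growth_stage: str = "preweaning"
    thresholds: dict = field(
        default_factory=lambda: {
            "min_call_rate": 0.95,
            "min_maf": 0.05,
            "hwe_alpha": 0.05,
            "outlier_fdr": 0.01,
            "core_prevalence": 0.5,
            "half_floor": diversity.HALF_DETECTION_LIMIT,
            "permanova_permutations": 999,
            "network_min_rho": network.MIN_ABS_RHO,
            "network_max_q": network.MAX_Q,
            "fdr_significant": 0.05,
            "p_significant": 0.05,
            "p_tendency": 0.10,
        }
    )
    gwas_taxa: tuple = ()  # taxa to scan; default: top heritability taxon
    outlier_filters: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(seed=raw["seed"], out_dir=raw["out_dir"])
        for key, value in raw.items():
            if key == "thresholds":
                cfg.thresholds.update(value)
            elif key == "stages":
                cfg.stages = tuple(value)
            elif key == "gwas_taxa":
                cfg.gwas_taxa = tuple(value)
            else:
                setattr(cfg, key, value)
        for key in ("genotype_path", "abundance_path", "metadata_path"):
            path_val = getattr(cfg, key)
            if path_val is not None and not Path(path_val).exists():
                raise FileNotFoundError(f"{key}: {path_val}")
        return cfg


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = SimulationConfig(
            seed=config.simulate.get("seed", config.seed),
            **{k: v for k, v in config.simulate.items() if k != "seed"},
        )
        truth, geno, abundance, meta = simulate_cohort(sim)
        return geno, abundance, meta
    if config.genotype_path is None:
        raise PipelineError("either input paths or a simulate block required")
    path = Path(config.genotype_path)
    geno = (
        io.read_vcf(path)
        if path.suffix == ".vcf"
        else io.read_genotype_tsv(path)
    )
    abundance = io.read_abundance_tsv(config.abundance_path)
    meta = io.read_metadata_csv(config.metadata_path)
    return geno, abundance, meta


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the selected stages, write results + manifest, return paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "growth_stage": config.growth_stage,
        "stages": list(config.stages),
        "thresholds": dict(thr),
        "design_flags": {
            "grm": "VanRaden method 1, cohort allele frequencies",
            "reml": "restricted likelihood profiled on the ratio (EMMA-style)",
            "genomic_control": "median-based, lambda clipped at 1",
            "outlier_rule": "one-sided z + BH",
            "breed_encoding": "continuous Brahman fraction in regressions",
            "relative_abundance": "computed from rarefied counts when "
            "rarefaction is used",
        },
        "outputs": {},
    }
    geno, abundance, meta = _load_inputs(config)
    stage = config.growth_stage
    current_geno = geno
    results: dict = {"out_dir": str(out)}

    def record(name: str, path: Path):
        manifest["outputs"][name] = path.name
        results[name] = path

    if "qc" in config.stages:
        log.info("stage qc: %d x %d input", geno.n_individuals, geno.n_snps)
        thresholds = qc.QcThresholds(
            min_call_rate=thr["min_call_rate"],
            min_maf=thr["min_maf"],
            hwe_alpha=thr["hwe_alpha"],
            outlier_fdr=thr["outlier_fdr"],
        )
        current_geno, report = qc.apply_qc(
            geno, thresholds, outlier_filters=config.outlier_filters
        )
        path = out / "qc_removed_snps.tsv"
        report.removed_snps.to_csv(path, sep="\t", index=False)
        record("qc_removed_snps", path)
        path = out / "qc_removed_individuals.tsv"
        report.removed_individuals.to_csv(path, sep="\t", index=False)
        record("qc_removed_individuals", path)
        io.write_genotype_tsv(current_geno, out / "genotypes_postqc.tsv")
        record("genotypes_postqc", out / "genotypes_postqc.tsv")
        # abundance/metadata restricted to surviving animals
        keep = [i for i in current_geno.individuals if i in abundance.index]
        abundance = abundance.loc[keep]
        meta = meta.loc[keep]
        current_geno = current_geno.subset(individuals=keep)

    core = diversity.core_taxa_filter(abundance, thr["core_prevalence"])
    log_core = diversity.log10_floor_transform(core, thr["half_floor"])

    if "diversity" in config.stages:
        shannon = abundance.apply(diversity.shannon_index, axis=1)
        shannon.rename("shannon").to_csv(out / "shannon.tsv", sep="\t")
        record("shannon", out / "shannon.tsv")
        dm = diversity.bray_curtis(abundance)
        io.write_square_tsv(
            list(dm.ids), dm.data, out / "bray_curtis.tsv"
        )
        record("bray_curtis", out / "bray_curtis.tsv")
        ordination = diversity.pcoa(dm, k_axes=3)
        ordination.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
        record("pcoa", out / "pcoa.tsv")
        perm = diversity.permanova(
            dm,
            meta["breed_group"].to_numpy(),
            n_perm=thr["permanova_permutations"],
            seed=config.seed,
        )
        path = out / "permanova.json"
        path.write_text(
            json.dumps(
                {
                    "pseudo_F": perm.statistic,
                    "p": perm.p_value,
                    "n_permutations": perm.n_permutations,
                    "method": perm.method,
                }
            )
        )
        record("permanova", path)

    grm = vc_by_taxon = None
    if {"heritability", "gwas", "assoc", "microbiability"} & set(
        config.stages
    ):
        grm = mm.genomic_relationship_matrix(current_geno)

    age_c = meta["age_days"].to_numpy(float)
    age_c = age_c - age_c.mean()
    x_base = np.column_stack(
        [
            np.ones(len(meta)),
            (meta["sex"] == "M").astype(float).to_numpy(),
            age_c,
        ]
    )

    if "heritability" in config.stages:
        rows = []
        vc_by_taxon = {}
        for taxon in log_core.columns:
            vc = mm.reml_single_component(
                log_core[taxon].to_numpy(), x_base, grm
            )
            vc_by_taxon[taxon] = vc
            rows.append(
                {
                    "taxon": taxon,
                    "h2": vc.ratio,
                    "sigma2_u": vc.sigma2_u,
                    "sigma2_e": vc.sigma2_e,
                    "flat_likelihood": vc.flat_likelihood,
                }
            )
        h2_table = pd.DataFrame(rows).set_index("taxon")
        h2_table.to_csv(out / "heritability.tsv", sep="\t")
        record("heritability", out / "heritability.tsv")
        results["heritability_table"] = h2_table

    if "assoc" in config.stages:
        breed_scan = association.breed_association_scan(log_core, meta)
        breed_scan.to_csv(out / "breed_association.tsv", sep="\t")
        record("breed_association", out / "breed_association.tsv")
        summary = association.summarize_scan(breed_scan)
        (out / "breed_association_summary.json").write_text(
            json.dumps(summary)
        )
        record(
            "breed_association_summary",
            out / "breed_association_summary.json",
        )
        results["breed_scan"] = breed_scan
        for response in ("WG", "IgG1"):
            try:
                scan = association.phenotype_association_scan(
                    meta, log_core, response, stage
                )
            except ValueError:
                continue
            path = out / f"{response.lower()}_association.tsv"
            scan.to_csv(path, sep="\t")
            record(f"{response.lower()}_association", path)

    if "gwas" in config.stages:
        taxa = list(config.gwas_taxa)
        if not taxa:
            if vc_by_taxon:
                ranked = sorted(
                    vc_by_taxon,
                    key=lambda t: -np.nan_to_num(vc_by_taxon[t].ratio),
                )
                taxa = ranked[:1]
            else:
                taxa = [log_core.columns[0]]
        for taxon in taxa:
            y = log_core[taxon].to_numpy()
            vc = (
                vc_by_taxon[taxon]
                if vc_by_taxon and taxon in vc_by_taxon
                else mm.reml_single_component(y, x_base, grm)
            )
            if vc.flat_likelihood:
                log.warning("flat likelihood for %s; skipping scan", taxon)
                continue
            scan = mm.gwas_scan(y, x_base, grm, current_geno, vc)
            scan = mm.genomic_control(scan)
            scan["q_bh"] = mm.bh_adjust(scan["p_gc"].to_numpy())
            scan["significant"] = scan["q_bh"] < thr["fdr_significant"]
            path = out / f"gwas_{taxon}.tsv"
            scan.to_csv(path, sep="\t")
            record(f"gwas_{taxon}", path)

    if "microbiability" in config.stages:
        m_mat = mm.microbial_relationship_matrix(log_core)
        rows = []
        for response in ("WG", "IgG1"):
            col = (
                association.STAGE_WG_COLUMNS[stage][1]
                if response == "WG"
                else "IgG1"
            )
            if col not in meta.columns:
                continue
            vc = mm.reml_single_component(
                meta[col].to_numpy(float), x_base, m_mat
            )
            rows.append(
                {
                    "phenotype": col,
                    "m2": vc.ratio,
                    "sigma2_m": vc.sigma2_u,
                    "sigma2_e": vc.sigma2_e,
                    "flat_likelihood": vc.flat_likelihood,
                }
            )
        m2_table = pd.DataFrame(rows).set_index("phenotype")
        m2_table.to_csv(out / "microbiability.tsv", sep="\t")
        record("microbiability", out / "microbiability.tsv")
        results["microbiability_table"] = m2_table

    if "network" in config.stages:
        rho, pmat = network.spearman_matrix(core)
        net = network.build_network(
            rho,
            pmat,
            min_rho=thr["network_min_rho"],
            max_q=thr["network_max_q"],
        )
        network.write_edge_list(net, out / "network_edges.tsv")
        record("network_edges", out / "network_edges.tsv")
        network.write_graphml(net, out / "network.graphml")
        record("network_graphml", out / "network.graphml")
        (out / "network_hubs.json").write_text(json.dumps(net.hubs))
        record("network_hubs", out / "network_hubs.json")
        results["network"] = net

    if "maf_breed" in config.stages:
        subset = current_geno.snp_ids[: min(20, current_geno.n_snps)]
        per_snp, maf_by_bg = association.genotype_breed_correlation(
            current_geno, meta, subset
        )
        per_snp.to_csv(out / "snp_breed_correlation.tsv", sep="\t")
        record("snp_breed_correlation", out / "snp_breed_correlation.tsv")
        maf_by_bg.to_csv(out / "maf_by_breed_group.tsv", sep="\t")
        record("maf_by_breed_group", out / "maf_by_breed_group.tsv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = out / "manifest.json"
    return results
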