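"""End-to-end orchestration: simulate -> index -> gwas -> candidates ->
caps -> expression, with a run manifest for reproducibility."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .association import diagnostics, emmax_scan, kinship, qc_filter, significance_filter
from .candidates import (
    allele_freq_table, candidate_table, default_enzymes, caps_scan,
    haplotype_matrix, ld_matrix,
)
from .expression import ddct, group_contrast
from .index import evaluate_panel
from .synthetic import (
    GenoSpec, PanelSpec, generate_annotation, generate_ct_table,
    generate_panel, plant_ref_alleles,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run.

    Thresholds default to the published analysis settings: MAF > 0.05,
    missing rate < 0.5, -log10(p) > 5.75, ±75 kb candidate windows,
    Duncan letters at alpha = 0.01.
    """

    phenotype: str = "phenotypes.csv"
    genotype: str = "genotypes.tsv"
    annotation: str | None = None
    sequence: str | None = None
    ct: str | None = None
    enzymes: str | None = None
    out_dir: str = "out"
    retain_rule: str = "kaiser"
    k_groups: int = 4
    maf_min: float = 0.05
    miss_max: float = 0.5
    threshold: float = 5.75
    flank: int = 75_000
    top_k: int = 20
    alpha: float = 0.01
    calibrator: str = "control"
    trait: str = "D"
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0 < self.miss_max <= 1:
            raise ValueError("miss_max must be in (0, 1]")
        if self.threshold <= 0 or self.flank <= 0:
            raise ValueError("threshold and flank must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = io.load_yaml(path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def simulate_bundle(
    out_dir,
    panel_spec: PanelSpec | None = None,
    geno_spec: GenoSpec | None = None,
    n_genes: int = 50,
    ct_effect_log2: float = 2.0,
    seed: int | None = None,
) -> dict:
    """Generate and write every input the pipeline consumes.

    Returns a dict of the paths written.  With ``seed`` given it overrides
    the seeds in both specs so one integer reproduces the whole bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel_spec = panel_spec or PanelSpec()
    geno_spec = geno_spec or GenoSpec()
    if seed is not None:
        panel_spec.seed = seed
        geno_spec.seed = seed

    table, panel, latent = generate_panel(panel_spec, geno_spec)
    genes, sequence = generate_annotation(geno_spec, n_genes=n_genes, seed=geno_spec.seed)
    sequence = plant_ref_alleles(sequence, panel.sites)
    ct = generate_ct_table(effect_log2=ct_effect_log2, seed=geno_spec.seed)

    paths = {
        "phenotype": out / "phenotypes.csv",
        "genotype": out / "genotypes.tsv",
        "vcf": out / "genotypes.vcf",
        "annotation": out / "genes.gff3",
        "sequence": out / "chromosome.fa",
        "ct": out / "ct.csv",
        "latent": out / "latent_tolerance.tsv",
        "enzymes": out / "enzymes.tsv",
    }
    io.write_phenotypes(table, paths["phenotype"])
    io.write_genotypes_tsv(panel, paths["genotype"])
    io.write_vcf(panel, paths["vcf"])
    io.write_gff3(genes, paths["annotation"])
    io.write_fasta({geno_spec.chrom: sequence}, paths["sequence"])
    io.write_ct(ct, paths["ct"])
    io.write_enzymes(default_enzymes(), paths["enzymes"])
    io.write_table(
        pd.DataFrame({"accession": panel.accessions, "latent": latent}),
        paths["latent"],
    )
    return {k: str(v) for k, v in paths.items()}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run index -> gwas -> candidates (+ caps, expression when inputs are
    configured); returns the manifest dict, also written as JSON."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    # ------------------------------------------------------------ index
    try:
        pheno = io.read_phenotypes(config.phenotype)
        scores, model, z, newick = evaluate_panel(
            pheno, retain_rule=config.retain_rule, k_groups=config.k_groups
        )
        io.write_table(scores, out / "scores.tsv", index=True)
        from .index import average_replicates, drought_indices

        io.write_table(
            drought_indices(average_replicates(pheno)), out / "indices.tsv", index=True
        )
        factor_report = pd.DataFrame(
            {
                "factor": [f"F{i+1}" for i in range(len(model.eigenvalues))],
                "eigenvalue": model.eigenvalues,
                "contribution_pct": model.contributions,
                "cumulative_pct": model.cumulative,
                "retained": [i in model.retained for i in range(len(model.eigenvalues))],
            }
        )
        io.write_table(factor_report, out / "factor_report.tsv")
        io.write_table(model.loadings, out / "loadings.tsv", index=True)
        io.write_table(model.score_coefficients, out / "score_coefficients.tsv", index=True)
        (out / "dendrogram.nwk").write_text(newick + "\n")
        manifest["stages"]["index"] = {"n_accessions": len(scores)}
    except Exception as e:  # noqa: BLE001
        raise StageError("index", e) from e

    # ------------------------------------------------------------- gwas
    try:
        panel = io.read_genotypes(config.genotype)
        panel_qc, qc_report = qc_filter(panel, config.maf_min, config.miss_max)
        y = scores.loc[panel_qc.accessions, config.trait].to_numpy(float)
        k = kinship(panel_qc)
        result = emmax_scan(panel_qc, y, k=k, threshold=config.threshold)
        io.write_table(result.table, out / "association.tsv")
        qq, lam = diagnostics(result)
        io.write_table(qq, out / "qq.tsv")
        sig = significance_filter(result)
        io.write_table(sig, out / "significant.tsv")
        manifest["stages"]["gwas"] = {
            **qc_report,
            "n_significant": int(len(sig)),
            "lambda_gc": round(lam, 4),
            "sigma_g2": result.sigma_g2,
            "sigma_e2": result.sigma_e2,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("gwas", e) from e

    # ------------------------------------------------- candidates (+LD)
    try:
        if config.annotation:
            genes = io.read_gff3(config.annotation)
            cands = candidate_table(sig, genes, flank=config.flank)
            io.write_table(cands, out / "candidates.tsv")
            manifest["stages"]["candidates"] = {
                "n_windows": int(sig.shape[0]),
                "n_gene_hits": int((cands["gene_id"] != ".").sum()),
            }
        sig_idx = [
            int(np.flatnonzero(
                (panel_qc.sites["chrom"] == s.chrom) & (panel_qc.sites["pos"] == s.pos)
            )[0])
            for s in sig.itertuples()
        ]
        if sig_idx:
            io.write_table(allele_freq_table(panel_qc, sig_idx), out / "allele_freq.tsv")
            top_k = min(config.top_k, panel_qc.n_accessions // 2)
            hap = haplotype_matrix(panel_qc, sig_idx, scores["D"], top_k=top_k)
            io.write_table(hap, out / "haplotypes.tsv", index=True)
            if len(sig_idx) > 1:
                io.write_table(ld_matrix(panel_qc, sig_idx), out / "ld.tsv", index=True)
    except Exception as e:  # noqa: BLE001
        raise StageError("candidates", e) from e

    # ------------------------------------------------------------- caps
    if config.sequence:
        try:
            seqs = io.read_fasta(config.sequence)
            enzymes = io.read_enzymes(config.enzymes) if config.enzymes else default_enzymes()
            rows = []
            for s in sig.itertuples():
                if s.chrom not in seqs:
                    continue
                rep = caps_scan(seqs[s.chrom], int(s.pos), s.ref, s.alt, enzymes)
                rep.insert(0, "chrom", s.chrom)
                rep.insert(1, "pos", int(s.pos))
                rows.append(rep)
            caps = (
                pd.concat(rows, ignore_index=True)
                if rows
                else pd.DataFrame(
                    columns=["chrom", "pos", "enzyme", "site", "ref_sites",
                             "alt_sites", "polymorphic"]
                )
            )
            io.write_table(caps, out / "caps.tsv")
            manifest["stages"]["caps"] = {
                "n_polymorphic": int(caps["polymorphic"].sum()) if len(caps) else 0
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("caps", e) from e

    # ------------------------------------------------------- expression
    if config.ct:
        try:
            ct = io.read_ct(config.ct)
            rel = ddct(ct, calibrator=config.calibrator)
            io.write_table(rel, out / "expression.tsv")
            duncan = group_contrast(rel, condition="drought", alpha=config.alpha)
            io.write_table(duncan, out / "duncan.tsv")
            manifest["stages"]["expression"] = {
                "n_samples": int(len(rel)),
                "anova_F": duncan.attrs["F"],
                "anova_p": duncan.attrs["p"],
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("expression", e) from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
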