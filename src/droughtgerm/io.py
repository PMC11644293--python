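"""Readers and writers for the pipeline's file surfaces.

Tabular outputs are tab-separated with '.' for missing values, a fixed
column order and 6 significant digits for floats (p-values in scientific
notation) so that reruns diff cleanly.  Genotypes travel as either a plain
TSV (one row per SNP: chrom, pos, ref, alt, then 0/1/2/'.' per accession)
or VCF v4.2; coordinates are 1-based inclusive everywhere (GFF3
convention).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import GenotypePanel

logger = logging.getLogger(__name__)

MISSING = "."
_MISSING_TOKENS = {".", "NA", "", "NaN", "nan"}


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# generic table writer
# ---------------------------------------------------------------------------

def format_value(v, sci: bool = False) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return MISSING
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, (float, np.floating)):
        return f"{v:.6e}" if sci else f"{v:.6g}"
    return str(v)


def write_table(df: pd.DataFrame, path, p_cols: tuple = ("p",), index: bool = False) -> None:
    """Write a DataFrame in the package's canonical TSV dialect."""
    out = df.copy()
    if index:
        out = out.reset_index()
    for col in out.columns:
        sci = col in p_cols
        out[col] = [format_value(v, sci=sci) for v in out[col]]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes / Ct / scores
# ---------------------------------------------------------------------------

PHENO_COLS = ["accession", "treatment", "replicate", "GP", "FW", "SL", "RL"]


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table[PHENO_COLS].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENO_COLS) - set(df.columns)
    if missing:
        raise IOError_(f"{path}: phenotype CSV lacks columns {sorted(missing)}")
    return df


CT_COLS = ["accession", "group", "condition", "gene", "tech_rep", "Ct"]


def write_ct(table: pd.DataFrame, path) -> None:
    table[CT_COLS].to_csv(path, index=False)


def read_ct(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CT_COLS) - set(df.columns)
    if missing:
        raise IOError_(f"{path}: Ct CSV lacks columns {sorted(missing)}")
    return df


def read_scores(path) -> pd.DataFrame:
    """Composite-score TSV written by the index stage."""
    return pd.read_csv(path, sep="\t", index_col="accession")


# ---------------------------------------------------------------------------
# genotypes: TSV and VCF v4.2
# ---------------------------------------------------------------------------

def write_genotypes_tsv(panel: GenotypePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "pos", "ref", "alt", *panel.accessions]) + "\n")
        for j in range(panel.n_snps):
            site = panel.sites.iloc[j]
            calls = [
                MISSING if np.isnan(v) else str(int(v))
                for v in panel.genotypes[:, j]
            ]
            fh.write(
                "\t".join([site.chrom, str(int(site.pos)), site.ref, site.alt, *calls])
                + "\n"
            )


def _read_genotypes_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["chrom", "pos", "ref", "alt"]
    if list(df.columns[:4]) != fixed:
        raise IOError_(f"{path}: genotype TSV must start with columns {fixed}")
    accessions = list(df.columns[4:])
    raw = df[accessions].to_numpy()
    geno = np.full(raw.shape, np.nan)
    for code in ("0", "1", "2"):
        geno[raw == code] = float(code)
    known = np.isin(raw, list(_MISSING_TOKENS) + ["0", "1", "2"])
    if not known.all():
        row, col = np.argwhere(~known)[0]
        raise IOError_(
            f"{path}: malformed genotype {raw[row, col]!r} at line {row + 2}, "
            f"accession {accessions[col]}"
        )
    sites = df[fixed].copy()
    sites["pos"] = sites["pos"].astype(int)
    _check_sorted(sites, path)
    return GenotypePanel(accessions=accessions, sites=sites, genotypes=geno.T)


def _check_sorted(sites: pd.DataFrame, path) -> None:
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise IOError_(f"{path}: positions not strictly increasing on {chrom}")


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal VCF v4.2 with unphased GT calls."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    chroms = panel.sites["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=droughtgerm\n")
        for c in chroms:
            length = int(panel.sites.loc[panel.sites["chrom"] == c, "pos"].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.accessions)
            + "\n"
        )
        for j in range(panel.n_snps):
            site = panel.sites.iloc[j]
            calls = [
                "./." if np.isnan(v) else gt_map[int(v)]
                for v in panel.genotypes[:, j]
            ]
            fh.write(
                "\t".join(
                    [
                        site.chrom, str(int(site.pos)),
                        f"{site.chrom}_{int(site.pos)}",
                        site.ref, site.alt, ".", "PASS", ".", "GT", *calls,
                    ]
                )
                + "\n"
            )


def _read_genotypes_vcf(path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    accessions = list(vcf.samples)
    rows, geno_rows = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        g = v.gt_types.astype(float)
        g[g == 3] = np.nan
        rows.append({"chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0]})
        geno_rows.append(g)
    if n_multi:
        logger.warning("skipped %d multiallelic VCF record(s)", n_multi)
    sites = pd.DataFrame(rows)
    _check_sorted(sites, path)
    return GenotypePanel(
        accessions=accessions,
        sites=sites,
        genotypes=np.vstack(geno_rows).T if geno_rows else np.empty((len(accessions), 0)),
    )


def read_genotypes(path) -> GenotypePanel:
    """Dispatch on extension: ``.vcf`` -> VCF v4.2, anything else -> TSV."""
    path = Path(path)
    if path.suffix.lower() == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_genotypes_vcf(path)
    return _read_genotypes_tsv(path)


# ---------------------------------------------------------------------------
# annotation + sequence
# ---------------------------------------------------------------------------

def write_gff3(genes: pd.DataFrame, path, source: str = "droughtgerm") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(
                "\t".join(
                    [
                        g.chrom, source, "gene", str(int(g.start)), str(int(g.end)),
                        ".", g.strand, ".", f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def read_gff3(path, feature: str = "gene") -> pd.DataFrame:
    """Gene records from a GFF3 file (1-based inclusive coordinates)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
        dtype={"chrom": str},
    )
    df = df[df["type"] == feature].copy()
    ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    out = pd.DataFrame(
        {
            "gene_id": ids.fillna("."),
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "strand": df["strand"],
        }
    ).reset_index(drop=True)
    if (out["start"] > out["end"]).any():
        raise IOError_(f"{path}: gene with start > end")
    return out


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict:
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# enzyme catalogue
# ---------------------------------------------------------------------------

def read_enzymes(path) -> list:
    from .candidates import Enzyme

    df = pd.read_csv(path, sep="\t")
    if not {"name", "site"} <= set(df.columns):
        raise IOError_(f"{path}: enzyme TSV needs 'name' and 'site' columns")
    return [Enzyme(name, site) for name, site in zip(df["name"], df["site"])]


def write_enzymes(enzymes, path) -> None:
    pd.DataFrame(
        [{"name": e.name, "site": e.site} for e in enzymes]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise IOError_(f"{path}: configuration must be a YAML mapping")
    return data
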