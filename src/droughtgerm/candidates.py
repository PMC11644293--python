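"""Candidate-gene mapping around significant SNPs.

Fixed ±75 kb windows, SNP–gene physical distances, allele-frequency and
0/1/2 haplotype summaries for extreme-D accession blocks, pairwise LD r²,
and CAPS (cleaved amplified polymorphic sequence) restriction-site
screening.  Coordinates are 1-based inclusive throughout, the GFF3
convention, and distances come from simple coordinate subtraction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import DEFAULT_ENZYMES, GenotypePanel


class CandidateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# windows and distances
# ---------------------------------------------------------------------------

def extract_window(
    snp_chrom: str, snp_pos: int, genes: pd.DataFrame, flank: int = 75_000
) -> tuple[tuple[int, int], pd.DataFrame]:
    """Genes overlapping the ±``flank`` bp window around a SNP.

    The window is [pos - flank, pos + flank], clipped at 1; a gene is
    reported iff its closed interval intersects the closed window by at
    least one base.
    """
    if flank <= 0:
        raise CandidateError("flank must be positive")
    if snp_chrom not in set(genes["chrom"]):
        raise CandidateError(f"unknown chromosome: {snp_chrom!r}")
    lo, hi = max(1, snp_pos - flank), snp_pos + flank
    sel = genes[
        (genes["chrom"] == snp_chrom) & (genes["start"] <= hi) & (genes["end"] >= lo)
    ].copy()
    sel["distance_bp"] = [
        snp_gene_distance(snp_pos, row.start, row.end) for row in sel.itertuples()
    ]
    return (lo, hi), sel.reset_index(drop=True)


def snp_gene_distance(snp_pos: int, gene_start: int, gene_end: int) -> int:
    """Physical distance in bp between a SNP and a gene interval.

    Zero inside the gene, otherwise the distance to the nearer gene end by
    plain coordinate subtraction.
    """
    if gene_start > gene_end:
        raise CandidateError("gene start must not exceed end")
    if gene_start <= snp_pos <= gene_end:
        return 0
    return min(abs(snp_pos - gene_start), abs(snp_pos - gene_end))


def candidate_table(
    significant: pd.DataFrame, genes: pd.DataFrame, flank: int = 75_000
) -> pd.DataFrame:
    """Window + overlap mapping for every significant SNP (long format)."""
    rows = []
    for snp in significant.itertuples():
        (lo, hi), hits = extract_window(snp.chrom, snp.pos, genes, flank=flank)
        if hits.empty:
            rows.append(
                {
                    "chrom": snp.chrom, "pos": snp.pos,
                    "window_start": lo, "window_end": hi,
                    "gene_id": ".", "distance_bp": np.nan,
                }
            )
        for hit in hits.itertuples():
            rows.append(
                {
                    "chrom": snp.chrom, "pos": snp.pos,
                    "window_start": lo, "window_end": hi,
                    "gene_id": hit.gene_id, "distance_bp": hit.distance_bp,
                }
            )
    columns = ["chrom", "pos", "window_start", "window_end", "gene_id", "distance_bp"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# allele frequencies / haplotypes / LD
# ---------------------------------------------------------------------------

def allele_freq_table(panel: GenotypePanel, snp_indices) -> pd.DataFrame:
    """Reference/variant allele percentages over non-missing allele counts."""
    rows = []
    for j in snp_indices:
        site = panel.sites.iloc[j]
        g = panel.genotypes[:, j]
        ok = ~np.isnan(g)
        total = 2 * int(ok.sum())
        if total == 0:
            rows.append(
                {
                    "chrom": site.chrom, "pos": int(site.pos),
                    "ref": site.ref, "ref_pct": np.nan,
                    "alt": site.alt, "alt_pct": np.nan, "all_missing": True,
                }
            )
            continue
        alt_count = int(g[ok].sum())
        alt_pct = 100.0 * alt_count / total
        rows.append(
            {
                "chrom": site.chrom, "pos": int(site.pos),
                "ref": site.ref, "ref_pct": 100.0 - alt_pct,
                "alt": site.alt, "alt_pct": alt_pct, "all_missing": False,
            }
        )
    return pd.DataFrame(rows)


def haplotype_matrix(
    panel: GenotypePanel, snp_indices, d_values: pd.Series, top_k: int = 20
) -> pd.DataFrame:
    """0/1/2 genotype block for the ``top_k`` most tolerant accessions
    (descending D) stacked on the ``top_k`` most sensitive (ascending D).

    ``d_values`` must be indexed by accession and cover the panel; missing
    genotypes appear as NaN.  Contrasting the extreme-D blocks makes causal
    alleles visually obvious when they are near-fixed within a tail.
    """
    missing = [a for a in panel.accessions if a not in d_values.index]
    if missing:
        raise CandidateError(f"ranking lacks accessions: {missing[:5]}")
    if top_k > panel.n_accessions // 2:
        raise CandidateError("top_k exceeds half the panel")
    ranked = d_values.loc[panel.accessions].sort_values(ascending=False)
    chosen = list(ranked.index[:top_k]) + list(ranked.index[-top_k:][::-1])
    blocks = ["tolerant"] * top_k + ["sensitive"] * top_k
    acc_idx = {a: i for i, a in enumerate(panel.accessions)}
    cols = {
        f"{panel.sites.iloc[j].chrom}_{int(panel.sites.iloc[j].pos)}": panel.genotypes[
            [acc_idx[a] for a in chosen], j
        ]
        for j in snp_indices
    }
    out = pd.DataFrame(cols, index=pd.Index(chosen, name="accession"))
    out.insert(0, "block", blocks)
    out.insert(1, "D", d_values.loc[chosen].to_numpy())
    return out


def ld_r2(panel: GenotypePanel, snp_a: int, snp_b: int) -> float:
    """Squared Pearson correlation of 0/1/2 dosages over pairwise-complete
    accessions."""
    ga = panel.genotypes[:, snp_a]
    gb = panel.genotypes[:, snp_b]
    ok = ~np.isnan(ga) & ~np.isnan(gb)
    if ok.sum() < 3:
        raise CandidateError("fewer than 3 pairwise-complete accessions")
    a, b = ga[ok], gb[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise CandidateError("monomorphic SNP among pairwise-complete accessions")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_matrix(panel: GenotypePanel, snp_indices) -> pd.DataFrame:
    """Pairwise r² over a SNP set (1.0 on the diagonal)."""
    ids = [
        f"{panel.sites.iloc[j].chrom}_{int(panel.sites.iloc[j].pos)}"
        for j in snp_indices
    ]
    k = len(snp_indices)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = ld_r2(panel, snp_indices[i], snp_indices[j])
    return pd.DataFrame(out, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# CAPS restriction-site screening
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease recognition site (IUPAC alphabet)."""

    name: str
    site: str

    def __post_init__(self):
        site = self.site.upper()
        if len(site) < 4:
            raise CandidateError(f"{self.name}: recognition site shorter than 4 bp")
        bad = set(site) - set(_IUPAC)
        if bad:
            raise CandidateError(f"{self.name}: non-IUPAC symbols {sorted(bad)}")
        object.__setattr__(self, "site", site)

    @property
    def is_palindromic(self) -> bool:
        return self.site == self.site.translate(_COMPLEMENT)[::-1]

    def pattern(self) -> re.Pattern:
        return re.compile("".join(_IUPAC[c] for c in self.site))


def default_enzymes() -> list[Enzyme]:
    return [Enzyme(name, site) for name, site in DEFAULT_ENZYMES.items()]


def find_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """1-based start positions of all (possibly overlapping) recognition
    sites on the forward strand; non-palindromic sites are additionally
    matched via their reverse complement."""
    seq = sequence.upper()
    motifs = [enzyme.site]
    if not enzyme.is_palindromic:
        motifs.append(enzyme.site.translate(_COMPLEMENT)[::-1])
    hits: set[int] = set()
    for motif in motifs:
        # lookahead so overlapping occurrences are all reported
        pat = re.compile("(?=" + "".join(_IUPAC[c] for c in motif) + ")")
        hits.update(m_.start() + 1 for m_ in pat.finditer(seq))
    return sorted(hits)


def caps_scan(
    sequence: str,
    snp_pos: int,
    ref: str,
    alt: str,
    enzymes: list[Enzyme] | None = None,
) -> pd.DataFrame:
    """Does a SNP create or destroy a restriction site?

    Scans the ±(site length − 1) bp neighbourhood of ``snp_pos`` (1-based)
    in the reference-allele and the alternate-allele version of the
    sequence.  An enzyme whose site count differs between alleles is a CAPS
    candidate: the digestion pattern distinguishes the genotypes.
    """
    if enzymes is None:
        enzymes = default_enzymes()
    seq = sequence.upper()
    if not 1 <= snp_pos <= len(seq):
        raise CandidateError(f"SNP position {snp_pos} outside sequence")
    if seq[snp_pos - 1] != ref.upper():
        raise CandidateError(
            f"reference allele {ref!r} disagrees with sequence base "
            f"{seq[snp_pos - 1]!r} at position {snp_pos}"
        )
    alt_seq = seq[: snp_pos - 1] + alt.upper() + seq[snp_pos:]
    rows = []
    for enz in enzymes:
        halo = len(enz.site) - 1
        lo = max(0, snp_pos - 1 - halo)
        hi = min(len(seq), snp_pos + halo)
        ref_hits = find_sites(seq[lo:hi], enz)
        alt_hits = find_sites(alt_seq[lo:hi], enz)
        rows.append(
            {
                "enzyme": enz.name,
                "site": enz.site,
                "ref_sites": len(ref_hits),
                "alt_sites": len(alt_hits),
                "polymorphic": len(ref_hits) != len(alt_hits),
            }
        )
    return pd.DataFrame(rows)
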