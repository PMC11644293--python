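"""Synthetic germination-panel generator.

Emulates a rapeseed diversity panel phenotyped at germination under control
(0 MPa) and PEG-simulated drought (-0.8 MPa): 196 accessions, four traits
(GP %, FW mg, SL mm, RL mm) measured on 3 replicates of 50 seeds, a
structured genotype panel (5 subpopulations) with optional causal loci, a
toy annotated chromosome, and qPCR Ct tables for tolerant vs sensitive
accession groups.  Everything is driven by a single latent tolerance value
per accession so that every downstream stage of the pipeline (composite
D-value, mixed-model association, haplotype contrast, expression contrast)
sees the statistical structure it assumes.

Model sketch
------------
* Latent tolerance  T = subpopulation effect + sum_j beta_j (g_j - 2 p_j)
  + noise, standardised across the panel.
* Per-trait latents U (one per accession x trait) carry exactly the
  configured trait correlation matrix R:  U = rho * T + E with rho the
  first eigen-component of R and cov(E) = R - rho rho^T (positive
  semi-definite by construction), so cov(U) = R.
* Drought response enters through a truncated-linear multiplier whose
  square is linear in U; the drought tolerance index computed downstream is
  quadratic in the trait value, so this keeps the DI correlation structure
  close to R instead of attenuating it.
* GP is generated as a 50-seed binomial count per replicate; the other
  traits get multiplicative replicate noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .index import TRAITS

_TABLE_CORR = np.array(
    [
        [1.000, 0.733, 0.718, 0.691],
        [0.733, 1.000, 0.875, 0.798],
        [0.718, 0.875, 1.000, 0.807],
        [0.691, 0.798, 0.807, 1.000],
    ]
)


@dataclass
class PanelSpec:
    """Study-condition parameters for the phenotype panel.

    Defaults reproduce the published panel summaries: 196 accessions, three
    50-seed replicates, control means GP 97.2 %, FW 29.3 mg, SL 10.9 mm,
    RL 33.3 mm, drought reductions of 72.09/71.88/83.62/83.86 % and the
    published inter-trait DI correlation structure.
    """

    n_accessions: int = 196
    n_reps: int = 3
    n_seeds: int = 50
    trait_means_control: dict = field(
        default_factory=lambda: {"GP": 97.2, "FW": 29.3, "SL": 10.9, "RL": 33.3}
    )
    reduction_fractions: dict = field(
        default_factory=lambda: {"GP": 0.7209, "FW": 0.7188, "SL": 0.8362, "RL": 0.8386}
    )
    #: control-condition coefficients of variation (fractions)
    control_cvs: dict = field(
        default_factory=lambda: {"GP": 0.02, "FW": 0.64, "SL": 0.363, "RL": 0.242}
    )
    #: drought-condition coefficients of variation (fractions); these set
    #: how strongly the latent tolerance spreads the stressed trait values
    drought_cvs: dict = field(
        default_factory=lambda: {"GP": 0.994, "FW": 0.439, "SL": 1.122, "RL": 1.009}
    )
    trait_correlation: np.ndarray = field(default_factory=lambda: _TABLE_CORR.copy())
    #: share of control-condition log-variance from a common seed-size factor
    size_factor_share: float = 0.5
    replicate_cv: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        r = np.asarray(self.trait_correlation, dtype=float)
        if r.shape != (4, 4) or not np.allclose(r, r.T):
            raise ValueError("trait_correlation must be a symmetric 4x4 matrix")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("trait_correlation must have a unit diagonal")
        if np.linalg.eigvalsh(r).min() <= 0:
            raise ValueError("trait_correlation must be positive definite")
        for t in TRAITS:
            f = self.reduction_fractions[t]
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"reduction fraction for {t} outside [0, 1]: {f}")
        if self.n_accessions < 2 or self.n_reps < 1:
            raise ValueError("need at least 2 accessions and 1 replicate")


@dataclass
class GenoSpec:
    """Parameters of the structured genotype panel on one toy chromosome."""

    n_snps: int = 5000
    n_subpops: int = 5
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.02
    #: (snp index, additive effect on the latent tolerance) pairs
    causal_snps: tuple = ()
    chrom: str = "A01"
    chrom_length: int = 20_000_000
    #: Wright's fixation index controlling subpopulation differentiation
    fst: float = 0.1
    #: standard deviation of subpopulation-level shifts of the latent tolerance
    subpop_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5]: {self.maf_range}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for idx, _ in self.causal_snps:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"causal SNP index {idx} out of range")
        if self.n_snps > self.chrom_length:
            raise ValueError("more SNPs than base pairs on the chromosome")


@dataclass
class GenotypePanel:
    """0/1/2-coded SNP matrix (accessions x SNPs) with site metadata.

    ``genotypes`` is float with NaN for missing calls.  ``sites`` holds one
    row per SNP: chrom, pos (1-based, strictly increasing), ref, alt.
    """

    accessions: list
    sites: pd.DataFrame
    genotypes: np.ndarray

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_snps(self) -> int:
        return len(self.sites)

    def maf(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.genotypes, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.genotypes).mean(axis=0)


_BASES = np.array(list("ACGT"))


def _draw_genotypes(n_accessions: int, geno: GenoSpec, rng: np.random.Generator):
    """Subpopulation-structured genotypes via the Balding–Nichols model."""
    lo, hi = geno.maf_range
    p0 = rng.uniform(lo, hi, size=geno.n_snps)
    assignment = np.repeat(
        np.arange(geno.n_subpops),
        np.diff(np.linspace(0, n_accessions, geno.n_subpops + 1).astype(int)),
    )
    f = geno.fst
    if f > 0:
        a = p0 * (1 - f) / f
        b = (1 - p0) * (1 - f) / f
        sub_p = rng.beta(a, b, size=(geno.n_subpops, geno.n_snps))
    else:
        sub_p = np.tile(p0, (geno.n_subpops, 1))
    sub_p = np.clip(sub_p, 0.005, 0.995)
    g = rng.binomial(2, sub_p[assignment, :]).astype(float)
    if geno.missing_rate > 0:
        g[rng.random(g.shape) < geno.missing_rate] = np.nan

    pos = np.sort(rng.choice(geno.chrom_length, size=geno.n_snps, replace=False)) + 1
    ref_idx = rng.integers(0, 4, size=geno.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=geno.n_snps)) % 4
    sites = pd.DataFrame(
        {
            "chrom": geno.chrom,
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )
    return sites, g, assignment, p0


def _latent_tolerance(g, assignment, p0, geno: GenoSpec, rng: np.random.Generator):
    subpop_shift = rng.normal(0.0, geno.subpop_sd, size=geno.n_subpops)
    t = subpop_shift[assignment].copy()
    for idx, effect in geno.causal_snps:
        dose = g[:, idx].copy()
        m = np.isnan(dose)
        if m.any():
            dose[m] = np.nanmean(dose)
        t += effect * (dose - 2 * p0[idx])
    t += rng.normal(0.0, 1.0, size=t.size)
    return t


def _trunclin_mean(c: float) -> float:
    """E[max(0, 1 + c U)] for standard normal U (truncated-linear link)."""
    from scipy.stats import norm

    if c <= 0:
        return 1.0
    return float(norm.cdf(1.0 / c) + c * norm.pdf(1.0 / c))


def generate_panel(spec: PanelSpec, geno: GenoSpec):
    """Generate phenotypes and genotypes for one panel.

    Returns ``(trait_table, genotype_panel, latent_tolerance)`` where
    ``trait_table`` is the replicate-level long-format phenotype table,
    ``genotype_panel`` a :class:`GenotypePanel` and ``latent_tolerance`` the
    per-accession latent value the drought response was driven by (useful
    for parameter-recovery checks).
    """
    spec.validate()
    geno.validate()
    rng = np.random.default_rng([spec.seed, geno.seed, 0x9E3779B9 % (2**31)])
    n = spec.n_accessions
    accessions = [f"R{4000 + i}" for i in range(n)]

    sites, g, assignment, p0 = _draw_genotypes(n, geno, rng)
    latent = _latent_tolerance(g, assignment, p0, geno, rng)
    t_std = (latent - latent.mean()) / latent.std()

    # the tolerance-driven dispersion scales with stress severity: at the
    # calibrated reduction the drought CVs apply as configured, with no
    # stress (reduction 0) there is nothing for tolerance to modulate
    defaults = PanelSpec().reduction_fractions
    eff_cv = {
        t: spec.drought_cvs[t] * spec.reduction_fractions[t] / defaults[t]
        for t in TRAITS
    }

    # per-trait latents: drawn with a pre-compensated correlation so that
    # after the censored tolerance link the *trait-index* correlations land
    # on the configured matrix
    r = _compensate_correlation(
        np.asarray(spec.trait_correlation, dtype=float),
        np.array([2.0 * eff_cv[t] for t in TRAITS]),
    )
    lam, vec = np.linalg.eigh(r)
    v1 = vec[:, -1]
    if v1.sum() < 0:
        v1 = -v1
    rho = np.sqrt(lam[-1]) * v1
    resid = r - np.outer(rho, rho)
    # eigh guarantees resid is PSD up to round-off; clip tiny negatives
    w, q = np.linalg.eigh(resid)
    w = np.clip(w, 0.0, None)
    chol_like = q * np.sqrt(w)
    e = rng.standard_normal((n, 4)) @ chol_like.T
    u = rho[None, :] * t_std[:, None] + e

    # control-condition accession values: lognormal with a shared size factor
    size = rng.standard_normal(n)
    ctl = {}
    a = spec.size_factor_share
    for j, trait in enumerate(TRAITS):
        if trait == "GP":
            mu_p = spec.trait_means_control["GP"] / 100.0
            sd_logit = 0.5
            logit = np.log(mu_p / (1 - mu_p)) + sd_logit * rng.standard_normal(n)
            ctl["GP"] = 1.0 / (1.0 + np.exp(-logit))
        else:
            cv = spec.control_cvs[trait]
            sigma = np.sqrt(np.log1p(cv**2))
            mu = np.log(spec.trait_means_control[trait]) - sigma**2 / 2
            zmix = a * size + np.sqrt(1 - a**2) * rng.standard_normal(n)
            ctl[trait] = np.exp(mu + sigma * zmix)

    # drought accession values: the tolerance link's square is linear in U,
    # so the DI (quadratic in the trait value) inherits the configured
    # correlation structure.  Constitutive size carries into the stressed
    # value with exponent 1/2, which makes the DI ratio cancel size noise
    # exactly: stressed performance is driven by tolerance, not by how big
    # the plant grows unstressed.
    dr = {}
    for j, trait in enumerate(TRAITS):
        c = eff_cv[trait]
        m2 = np.clip(1.0 + 2.0 * c * u[:, j], 0.0, None)
        m = np.sqrt(m2) / _trunclin_mean_sqrt(2.0 * c)
        keep = 1.0 - spec.reduction_fractions[trait]
        if trait == "GP":
            dr["GP"] = np.clip(ctl["GP"] * keep * m, 0.0, 1.0)
        else:
            mean_t = spec.trait_means_control[trait]
            rel = ctl[trait] / mean_t
            sigma = np.sqrt(np.log1p(spec.control_cvs[trait] ** 2))
            carry = np.sqrt(rel) * np.exp(sigma**2 / 8.0)
            dr[trait] = mean_t * keep * m * carry

    rows = []
    for rep in range(1, spec.n_reps + 1):
        for treatment, level in (("control", ctl), ("drought", dr)):
            gp_prob = level["GP"]
            counts = rng.binomial(spec.n_seeds, gp_prob)
            gp = 100.0 * counts / spec.n_seeds
            noise = {
                t: level[t] * rng.lognormal(0.0, spec.replicate_cv, size=n)
                for t in ("FW", "SL", "RL")
            }
            for i, acc in enumerate(accessions):
                rows.append(
                    {
                        "accession": acc,
                        "treatment": treatment,
                        "replicate": rep,
                        "GP": gp[i],
                        "FW": noise["FW"][i],
                        "SL": noise["SL"][i],
                        "RL": noise["RL"][i],
                    }
                )
    table = pd.DataFrame(rows)
    panel = GenotypePanel(accessions=accessions, sites=sites, genotypes=g)
    return table, panel, latent


def _censored_corr(rho: float, a_s: float, a_t: float) -> float:
    """corr(max(0, 1 + a_s U), max(0, 1 + a_t V)) for standard bivariate
    normal (U, V) with correlation rho, by Gauss–Hermite quadrature."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    w = weights / np.sqrt(2 * np.pi)
    u = nodes[:, None]
    vgrid = rho * u + np.sqrt(max(0.0, 1 - rho**2)) * nodes[None, :]
    ps = np.clip(1 + a_s * u, 0, None)
    pt = np.clip(1 + a_t * vgrid, 0, None)
    e_st = float((w[:, None] * w[None, :] * ps * pt).sum())

    def moments(a):
        v1 = np.clip(1 + a * nodes, 0, None)
        m1 = float((w * v1).sum())
        m2 = float((w * v1**2).sum())
        return m1, m2 - m1**2

    m_s, var_s = moments(a_s)
    m_t, var_t = moments(a_t)
    return (e_st - m_s * m_t) / np.sqrt(var_s * var_t)


def _compensate_correlation(r: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Invert the censored-link attenuation: find a latent correlation
    matrix whose image under the link has the target correlations.

    Capped at 0.999 per pair; shrunk toward the target if the compensated
    matrix loses positive definiteness.
    """
    from scipy.optimize import brentq

    rc = r.copy()
    k = r.shape[0]
    for i in range(k):
        for j in range(i + 1, k):
            target = r[i, j]
            if abs(target) < 1e-12 or a[i] <= 1e-9 or a[j] <= 1e-9:
                continue  # degenerate link: no attenuation to undo
            f = lambda x: _censored_corr(x, a[i], a[j]) - target
            lo, hi = (-0.999, 0.0) if target < 0 else (0.0, 0.999)
            if f(lo) * f(hi) > 0:  # unreachable target: cap at the bound
                rc[i, j] = rc[j, i] = lo if target < 0 else hi
            else:
                rc[i, j] = rc[j, i] = brentq(f, lo, hi, xtol=1e-6)
    for shrink in np.linspace(0.0, 1.0, 21):
        cand = (1 - shrink) * rc + shrink * r
        if np.linalg.eigvalsh(cand).min() > 1e-8:
            return cand
    return r


def _trunclin_mean_sqrt(c2: float) -> float:
    """E[sqrt(max(0, 1 + c2 U))] for standard normal U, by quadrature."""
    from scipy.stats import norm

    if c2 <= 0:
        return 1.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    vals = np.sqrt(np.clip(1.0 + c2 * nodes, 0.0, None))
    return float((weights * vals).sum() / np.sqrt(2 * np.pi))


# ---------------------------------------------------------------------------
# annotation + sequence
# ---------------------------------------------------------------------------

#: default CAPS enzyme catalogue (palindromic recognition sites)
DEFAULT_ENZYMES = {"SalI": "GTCGAC", "BclI": "TGATCA", "SspI": "AATATT"}


def generate_annotation(
    geno: GenoSpec,
    n_genes: int = 50,
    seed: int = 0,
    gene_length_range: tuple = (800, 3000),
    enzymes: dict | None = None,
):
    """A toy annotated chromosome: non-overlapping genes plus a sequence.

    Returns ``(genes, sequence)`` where ``genes`` has 1-based inclusive
    ``start``/``end`` coordinates and ``sequence`` is an upper-case DNA
    string of length ``geno.chrom_length`` containing at least one planted
    occurrence of every enzyme recognition site.
    """
    if enzymes is None:
        enzymes = DEFAULT_ENZYMES
    rng = np.random.default_rng([seed, 0x5F3759DF % (2**31)])
    lo, hi = gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    total = int(lengths.sum())
    free = geno.chrom_length - total
    if free < n_genes + 1:
        raise ValueError(
            f"cannot place {n_genes} non-overlapping genes of total length "
            f"{total} on a {geno.chrom_length} bp chromosome"
        )
    cuts = np.sort(rng.choice(free, size=n_genes, replace=False))
    gaps = np.diff(np.concatenate(([0], cuts, [free])))
    starts = np.cumsum(gaps[:-1]) + np.concatenate(([0], np.cumsum(lengths[:-1]))) + 1
    ends = starts + lengths - 1
    strands = rng.choice(["+", "-"], size=n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"Gene{geno.chrom}g{i * 10 + 10:05d}" for i in range(n_genes)],
            "chrom": geno.chrom,
            "start": starts.astype(int),
            "end": ends.astype(int),
            "strand": strands,
        }
    )

    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytearray(lut[rng.integers(0, 4, size=geno.chrom_length, dtype=np.uint8)].tobytes())
    for site in enzymes.values():
        where = int(rng.integers(0, geno.chrom_length - len(site)))
        seq[where : where + len(site)] = site.encode("ascii")
    return genes, seq.decode("ascii")


def plant_ref_alleles(sequence: str, sites: pd.DataFrame) -> str:
    """Overwrite the sequence with each SNP's reference base at its 1-based
    position, so genotype records and the reference sequence agree (as a
    real reference genome would)."""
    seq = bytearray(sequence.encode("ascii"))
    for pos, ref in zip(sites["pos"].to_numpy(int), sites["ref"]):
        seq[pos - 1] = ord(ref)
    return seq.decode("ascii")


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def generate_ct_table(
    n_tolerant: int = 5,
    n_sensitive: int = 5,
    effect_log2: float = 2.0,
    seed: int = 0,
    n_tech_reps: int = 3,
    baseline_induction_log2: float = 1.0,
    accession_sd: float = 0.15,
    tech_sd: float = 0.05,
) -> pd.DataFrame:
    """Ct values for a target and a reference gene across two accession
    groups and two conditions.

    Under drought the target gene is induced by ``baseline_induction_log2``
    doublings in every accession and by ``effect_log2`` additional doublings
    in the tolerant group, so the expected drought-vs-control fold-change
    ratio between groups is ``2 ** effect_log2``.  The reference gene is
    stable across conditions, as a normaliser must be.
    """
    if n_tolerant < 1 or n_sensitive < 1:
        raise ValueError("need at least one accession per group")
    rng = np.random.default_rng([seed, 0xC7])
    rows = []
    groups = [("tolerant", n_tolerant), ("sensitive", n_sensitive)]
    k = 0
    for group, count in groups:
        for _ in range(count):
            acc = f"Q{5000 + k}"
            k += 1
            ref_base = 20.0 + rng.normal(0.0, accession_sd)
            tgt_base = 25.0 + rng.normal(0.0, accession_sd)
            for condition in ("control", "drought"):
                shift = 0.0
                if condition == "drought":
                    shift = -baseline_induction_log2
                    if group == "tolerant":
                        shift -= effect_log2
                for gene, base in (("target", tgt_base + shift), ("reference", ref_base)):
                    for rep in range(1, n_tech_reps + 1):
                        rows.append(
                            {
                                "accession": acc,
                                "group": group,
                                "condition": condition,
                                "gene": gene,
                                "tech_rep": rep,
                                "Ct": base + rng.normal(0.0, tech_sd),
                            }
                        )
    return pd.DataFrame(rows)
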