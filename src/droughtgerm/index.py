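"""Composite drought-tolerance evaluation from germination traits.

A diversity panel is phenotyped for four germination traits — germination
percentage (GP, %), fresh weight per plant (FW, mg), shoot length (SL, mm)
and root length (RL, mm) — under a control and an osmotic-stress (drought)
treatment.  Per accession and trait, a drought tolerance coefficient

    DC = X_drought / X_control

and a drought tolerance index

    DI = DC * X_drought / mean(X_drought)

are computed; DI rewards both relative stability and absolute performance
under stress.  The four DI columns are condensed by a principal-component
style factor analysis of their Pearson correlation matrix, retained factor
scores are min–max normalised into membership values DM in [0, 1], and a
weighted sum with weights proportional to the retained factors' variance
contributions yields the composite tolerance score

    D = sum_i DM_i * w_i            (D in [0, 1])

which ranks accessions from most sensitive (0) to most tolerant (1) and is
the phenotype carried into genome-wide association.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

#: canonical trait order used throughout the package
TRAITS = ("GP", "FW", "SL", "RL")

#: tolerance classes, highest band first; bands are lower-inclusive /
#: upper-exclusive except the top band which is closed at 1.0
DEFAULT_BANDS: tuple[tuple[float, str], ...] = (
    (0.700, "extremely strong"),
    (0.400, "strong"),
    (0.100, "moderate"),
    (0.040, "susceptible"),
    (0.000, "poorest"),
)


class DroughtIndexError(ValueError):
    """Raised for invalid phenotype input (zero control values, constant
    factor scores, degenerate correlation structure, ...)."""


# ---------------------------------------------------------------------------
# replicate averaging and descriptive statistics
# ---------------------------------------------------------------------------

def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average biological replicates per accession x treatment.

    Parameters
    ----------
    table : DataFrame
        Long-format phenotype table with columns ``accession``,
        ``treatment`` (``control``/``drought``), ``replicate`` and the four
        trait columns ``GP``, ``FW``, ``SL``, ``RL``.  Missing replicate
        values are ignored (with a logged count).

    Returns
    -------
    DataFrame with one row per (accession, treatment) holding trait means.
    Accessions missing an entire treatment are dropped with a warning.
    """
    required = {"accession", "treatment", *TRAITS}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise DroughtIndexError(f"phenotype table lacks columns: {sorted(missing_cols)}")

    n_missing = int(table[list(TRAITS)].isna().sum().sum())
    if n_missing:
        logger.info("ignoring %d missing replicate measurements", n_missing)

    means = (
        table.groupby(["accession", "treatment"], sort=True)[list(TRAITS)]
        .mean()
        .reset_index()
    )
    counts = means.groupby("accession")["treatment"].nunique()
    incomplete = counts.index[counts < 2]
    if len(incomplete):
        warnings.warn(
            f"excluding {len(incomplete)} accession(s) missing a treatment: "
            f"{list(incomplete[:5])}...",
            stacklevel=2,
        )
        means = means[~means["accession"].isin(incomplete)]
    return means.reset_index(drop=True)


def percent_reduction(mean_control: float, mean_drought: float) -> float:
    """Percent decline of a trait mean under drought relative to control."""
    if mean_control == 0:
        return float("nan")
    return 100.0 * (mean_control - mean_drought) / mean_control


def descriptive_stats(means: pd.DataFrame) -> pd.DataFrame:
    """Per trait x treatment summary: min, max, mean, CV%, plus the percent
    reduction under drought and a Welch t statistic between treatments.

    ``means`` is the output of :func:`average_replicates`.  CV% uses the
    sample standard deviation (ddof=1).  The Welch test is used because
    treatment variances differ strongly for germination data.
    """
    if means["accession"].nunique() < 2:
        raise DroughtIndexError("descriptive statistics need at least 2 accessions")
    rows = []
    for trait in TRAITS:
        per_treat = {}
        for treatment in ("control", "drought"):
            v = means.loc[means["treatment"] == treatment, trait].to_numpy(float)
            per_treat[treatment] = v
            m = v.mean()
            sd = v.std(ddof=1)
            rows.append(
                {
                    "trait": trait,
                    "treatment": treatment,
                    "min": v.min(),
                    "max": v.max(),
                    "mean": m,
                    "cv_pct": 100.0 * sd / m if m != 0 else np.nan,
                }
            )
        reduction = percent_reduction(
            per_treat["control"].mean(), per_treat["drought"].mean()
        )
        if np.allclose(per_treat["control"], per_treat["drought"]):
            t = 0.0
        else:
            t = stats.ttest_ind(
                per_treat["control"], per_treat["drought"], equal_var=False
            ).statistic
        rows[-2]["reduction_pct"] = reduction
        rows[-2]["welch_t"] = t
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DC / DI
# ---------------------------------------------------------------------------

def compute_dc(x_drought, x_control):
    """Drought tolerance coefficient DC = X_drought / X_control.

    Raises on non-positive control values: a trait with zero control
    performance carries no information about stress response.
    """
    x_drought = np.asarray(x_drought, dtype=float)
    x_control = np.asarray(x_control, dtype=float)
    bad = x_control <= 0
    if np.any(bad):
        raise DroughtIndexError(
            f"non-positive control value(s) at positions {np.flatnonzero(bad)[:10].tolist()}"
        )
    return x_drought / x_control


def compute_di(dc, x_drought, x_mean_drought):
    """Drought tolerance index DI = DC * X_drought / panel mean under drought."""
    x_mean_drought = float(x_mean_drought)
    if x_mean_drought <= 0:
        raise DroughtIndexError(
            "panel mean under drought is non-positive; trait uninformative"
        )
    return np.asarray(dc, float) * np.asarray(x_drought, float) / x_mean_drought


def drought_indices(means: pd.DataFrame) -> pd.DataFrame:
    """DC and DI for every accession and trait.

    Returns a DataFrame indexed by accession with columns ``DC_<trait>`` and
    ``DI_<trait>``.
    """
    wide = means.pivot(index="accession", columns="treatment", values=list(TRAITS))
    out = pd.DataFrame(index=wide.index)
    for trait in TRAITS:
        ctl = wide[(trait, "control")].to_numpy(float)
        dr = wide[(trait, "drought")].to_numpy(float)
        if np.any(ctl <= 0):
            offenders = wide.index[ctl <= 0][:5].tolist()
            raise DroughtIndexError(
                f"trait {trait}: non-positive control values for accessions {offenders}"
            )
        dc = compute_dc(dr, ctl)
        out[f"DC_{trait}"] = dc
        out[f"DI_{trait}"] = compute_di(dc, dr, dr.mean())
    return out


def di_matrix(indices: pd.DataFrame) -> pd.DataFrame:
    """The DI block of :func:`drought_indices`, columns renamed to traits."""
    di = indices[[f"DI_{t}" for t in TRAITS]].copy()
    di.columns = list(TRAITS)
    return di


# ---------------------------------------------------------------------------
# correlation and factor analysis
# ---------------------------------------------------------------------------

def correlation_matrix(di: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between DI columns with pairwise p-values."""
    if len(di) < 3:
        raise DroughtIndexError("correlation needs at least 3 accessions")
    sd = di.std(ddof=1)
    flat = sd.index[sd == 0]
    if len(flat):
        raise DroughtIndexError(f"zero-variance trait(s): {list(flat)}")
    r = di.corr(method="pearson")
    n = len(di)
    rv = r.to_numpy().copy()
    np.clip(rv, -0.9999999999, 0.9999999999, out=rv)
    t = rv * np.sqrt((n - 2) / (1 - rv**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    return r, pd.DataFrame(p, index=r.index, columns=r.columns)


@dataclass
class FactorModel:
    """Principal-component style factor extraction of the DI correlations.

    Eigen-decomposition of the Pearson correlation matrix of standardised
    DI values; loadings are eigenvectors scaled by sqrt(eigenvalue), factor
    score coefficients follow the regression method (R^-1 L), and factor
    scores are standardised DI times the score coefficients.
    """

    eigenvalues: np.ndarray          # descending
    contributions: np.ndarray        # percent of total variance, sums to 100
    cumulative: np.ndarray           # non-decreasing, ends at 100
    loadings: pd.DataFrame           # trait x factor
    score_coefficients: pd.DataFrame # trait x factor
    scores: pd.DataFrame             # accession x factor
    retained: list[int] = field(default_factory=list)  # 0-based factor indices

    @property
    def retained_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, self.retained]

    @property
    def retained_contributions(self) -> np.ndarray:
        return self.contributions[self.retained]


def factor_extract(di: pd.DataFrame, retain_rule: str | int = "kaiser") -> FactorModel:
    """Extract factors from the DI correlation matrix.

    Parameters
    ----------
    di : DataFrame
        Accession x trait DI values.
    retain_rule : "kaiser" | "all" | int
        Kaiser keeps eigenvalues > 1.0 (falling back to the first factor if
        none qualifies); "all" keeps every factor; an integer keeps the
        leading k factors.
    """
    r, _ = correlation_matrix(di)
    rmat = r.to_numpy()
    lam, vec = np.linalg.eigh(rmat)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    if lam[-1] <= 1e-10:
        raise DroughtIndexError(
            "singular DI correlation matrix; remove a redundant trait"
        )
    # eigenvectors are sign-ambiguous: orient so the first trait (GP) loads
    # positively, making scores comparable across runs
    signs = np.where(vec[0, :] >= 0, 1.0, -1.0)
    vec = vec * signs

    contributions = 100.0 * lam / lam.sum()
    cumulative = np.cumsum(contributions)
    factors = [f"F{i + 1}" for i in range(len(lam))]
    loadings = pd.DataFrame(vec * np.sqrt(lam), index=di.columns, columns=factors)
    coef = pd.DataFrame(
        np.linalg.solve(rmat, loadings.to_numpy()), index=di.columns, columns=factors
    )
    z = (di - di.mean()) / di.std(ddof=1)
    scores = pd.DataFrame(z.to_numpy() @ coef.to_numpy(), index=di.index, columns=factors)

    if retain_rule == "kaiser":
        retained = [i for i, l in enumerate(lam) if l > 1.0]
        if not retained:
            warnings.warn(
                "no eigenvalue exceeds 1.0; retaining the first factor",
                stacklevel=2,
            )
            retained = [0]
    elif retain_rule == "all":
        retained = list(range(len(lam)))
    elif isinstance(retain_rule, int) and retain_rule >= 1:
        retained = list(range(min(retain_rule, len(lam))))
    else:
        raise DroughtIndexError(f"unknown retention rule: {retain_rule!r}")

    return FactorModel(
        eigenvalues=lam,
        contributions=contributions,
        cumulative=cumulative,
        loadings=loadings,
        score_coefficients=coef,
        scores=scores,
        retained=retained,
    )


# ---------------------------------------------------------------------------
# membership, weights, composite D
# ---------------------------------------------------------------------------

def compute_membership(scores) -> np.ndarray:
    """Min–max membership normalisation of factor scores, column-wise.

    DM = (v - v_min) / (v_max - v_min); the extreme accessions map to 0
    and 1 exactly.  A constant column has no discriminating power and is
    rejected.
    """
    v = np.atleast_2d(np.asarray(scores, dtype=float))
    if v.shape[0] == 1 and np.ndim(scores) == 1:
        v = v.T
    vmin, vmax = v.min(axis=0), v.max(axis=0)
    flat = vmax <= vmin
    if np.any(flat):
        raise DroughtIndexError(
            f"constant factor score column(s) {np.flatnonzero(flat).tolist()}: "
            "no discrimination between accessions"
        )
    dm = (v - vmin) / (vmax - vmin)
    return dm if np.ndim(scores) > 1 else dm.ravel()


def compute_weights(contributions) -> np.ndarray:
    """Factor weights w_i = P_i / sum(P) over the retained factors."""
    p = np.asarray(contributions, dtype=float)
    if p.size == 0:
        raise DroughtIndexError("no retained factors to weight")
    if np.any(p <= 0):
        raise DroughtIndexError("factor contributions must be positive")
    return p / p.sum()


def compute_d(dm, weights) -> np.ndarray:
    """Composite tolerance D = sum_i DM_i * w_i, in [0, 1]."""
    dm = np.atleast_2d(np.asarray(dm, dtype=float))
    w = np.asarray(weights, dtype=float)
    if dm.shape[1] != w.size:
        raise DroughtIndexError(
            f"DM has {dm.shape[1]} factor column(s) but {w.size} weight(s) given"
        )
    return dm @ w


def classify_d(d, bands: tuple[tuple[float, str], ...] = DEFAULT_BANDS):
    """Map composite D values onto tolerance classes.

    Bands are lower-inclusive and upper-exclusive, the top band closed at
    1.0, so every value in [0, 1] belongs to exactly one class.
    """
    arr = np.atleast_1d(np.asarray(d, dtype=float))
    if np.any((arr < 0) | (arr > 1)):
        raise DroughtIndexError("D values must lie in [0, 1]")
    bounds = sorted(bands, key=lambda b: -b[0])
    out = np.empty(arr.shape, dtype=object)
    out[:] = None
    remaining = np.ones(arr.shape, dtype=bool)
    for lo, label in bounds:
        pick = remaining & (arr >= lo)
        out[pick] = label
        remaining &= ~pick
    out[remaining] = bounds[-1][1]  # only reachable with a nonzero lowest bound
    return out if np.ndim(d) else out.item()


# ---------------------------------------------------------------------------
# WPGMA clustering of D values
# ---------------------------------------------------------------------------

def wpgma_cluster(d, k_groups: int = 4, labels=None):
    """WPGMA (weighted average linkage) clustering of accessions on |D_i - D_j|.

    Returns ``(linkage_matrix, groups, newick)`` where ``groups`` maps each
    accession to a cluster id in 1..k obtained by cutting the tree, and
    ``newick`` is the dendrogram in Newick format with merge-height branch
    lengths.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    if n < 2:
        raise DroughtIndexError("clustering needs at least 2 accessions")
    if k_groups > n:
        raise DroughtIndexError(f"cannot cut {n} accessions into {k_groups} groups")
    if labels is None:
        labels = [f"acc{i}" for i in range(n)]
    z = hierarchy.linkage(pdist(d.reshape(-1, 1)), method="weighted")
    groups = hierarchy.fcluster(z, t=k_groups, criterion="maxclust")
    return z, pd.Series(groups, index=pd.Index(labels, name="accession"), name="group"), _newick(z, labels)


def _newick(z: np.ndarray, labels) -> str:
    tree = hierarchy.to_tree(z)

    def fmt(node, parent_height):
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    body = fmt(tree, tree.dist)
    # strip the root's zero-length branch
    return body.rsplit(":", 1)[0] + ";"


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def evaluate_panel(
    table: pd.DataFrame,
    retain_rule: str | int = "kaiser",
    k_groups: int = 4,
    bands=DEFAULT_BANDS,
):
    """Full composite evaluation: replicate averaging through D and classes.

    Returns ``(scores_df, factor_model, linkage, newick)`` where
    ``scores_df`` is indexed by accession with DM columns (one per retained
    factor), the composite ``D``, its tolerance ``class`` and the WPGMA
    cluster ``group``.
    """
    means = average_replicates(table)
    indices = drought_indices(means)
    di = di_matrix(indices)
    model = factor_extract(di, retain_rule=retain_rule)
    dm = compute_membership(model.retained_scores.to_numpy())
    w = compute_weights(model.retained_contributions)
    dvals = compute_d(dm, w)
    z, groups, newick = wpgma_cluster(
        dvals, k_groups=min(k_groups, len(dvals)), labels=di.index.tolist()
    )
    out = pd.DataFrame(
        dm, index=di.index, columns=[f"DM_F{i + 1}" for i in model.retained]
    )
    out["D"] = dvals
    out["class"] = classify_d(dvals, bands=bands)
    out["group"] = groups.to_numpy()
    return out, model, z, newick
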