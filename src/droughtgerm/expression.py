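"""qRT-PCR relative expression and group comparison.

Relative quantification uses the Livak 2^-ddCt method: target-gene Ct is
normalised against a reference gene (dCt = Ct_target - Ct_reference), then
against a calibrator condition of the same accession
(ddCt = dCt_sample - dCt_calibrator), so the calibrator sample itself is
exactly 1 by construction.  Group contrasts use one-way fixed-effects ANOVA
followed by Duncan's multiple range test, with critical values from the
studentized range distribution rather than printed tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionError(ValueError):
    pass


def ddct(table: pd.DataFrame, calibrator: str = "control") -> pd.DataFrame:
    """Relative expression 2^-ddCt per accession x condition.

    ``table`` holds one row per technical replicate with columns
    ``accession``, ``condition``, ``gene`` (``target``/``reference``) and
    ``Ct``; a ``group`` column is carried through when present.  Technical
    replicates are averaged on the Ct scale before any differencing.
    """
    required = {"accession", "condition", "gene", "Ct"}
    missing = required - set(table.columns)
    if missing:
        raise ExpressionError(f"Ct table lacks columns: {sorted(missing)}")

    mean_ct = (
        table.groupby(["accession", "condition", "gene"])["Ct"].mean().unstack("gene")
    )
    for gene in ("target", "reference"):
        if gene not in mean_ct.columns or mean_ct[gene].isna().any():
            bad = (
                mean_ct.index[mean_ct[gene].isna()].tolist()[:5]
                if gene in mean_ct.columns
                else "all samples"
            )
            raise ExpressionError(f"missing {gene} gene Ct for: {bad}")
    dct = (mean_ct["target"] - mean_ct["reference"]).rename("dCt").reset_index()

    cal = dct[dct["condition"] == calibrator].set_index("accession")["dCt"]
    missing_cal = set(dct["accession"]) - set(cal.index)
    if missing_cal:
        raise ExpressionError(
            f"no {calibrator!r} calibrator for accessions: {sorted(missing_cal)[:5]}"
        )
    dct["ddCt"] = dct["dCt"] - cal.loc[dct["accession"]].to_numpy()
    dct["rel_expr"] = np.exp2(-dct["ddCt"])
    if "group" in table.columns:
        groups = table.drop_duplicates("accession").set_index("accession")["group"]
        dct.insert(1, "group", groups.loc[dct["accession"]].to_numpy())
    return dct


# ---------------------------------------------------------------------------
# one-way ANOVA + Duncan's multiple range test
# ---------------------------------------------------------------------------

def _duncan_ranges(k: int, df_error: int, mse: float, n_h: float, alpha: float):
    """Critical range for spans p = 2..k at Duncan's protection levels
    alpha_p = 1 - (1 - alpha)^(p-1)."""
    ranges = {}
    for p in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = stats.studentized_range.ppf(1.0 - alpha_p, p, df_error)
        ranges[p] = q * np.sqrt(mse / n_h)
    return ranges


def _letters_from_nonsig(order: list, nonsig: np.ndarray) -> dict:
    """Compact letter display from a non-significance matrix over means
    sorted descending.  Maximal runs of mutually non-different means share
    a letter."""
    k = len(order)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        intervals.append((i, j))
    keep = [
        (a, b)
        for a, b in dict.fromkeys(intervals)
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in intervals)
    ]
    letters = {g: "" for g in order}
    for idx, (a, b) in enumerate(sorted(set(keep))):
        ch = chr(ord("a") + idx)
        for i in range(a, b + 1):
            letters[order[i]] += ch
    return letters


def anova_duncan(groups: dict, alpha: float = 0.01) -> pd.DataFrame:
    """One-way ANOVA with Duncan's multiple range letters.

    Parameters
    ----------
    groups : dict[label, array-like]
        Observations per group (>= 2 groups, >= 2 observations each).
    alpha : float
        Significance level for the range test (default 0.01, matching a
        p < 0.01 letter display).

    Returns
    -------
    DataFrame with one row per group (sorted by descending mean): n, mean,
    se, letter, plus the ANOVA F and p in ``attrs``.  Groups that share no
    letter differ at the chosen level.
    """
    if len(groups) < 2:
        raise ExpressionError("need at least two groups")
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in data.items():
        if v.size < 2:
            raise ExpressionError(f"group {g!r} has fewer than 2 observations")

    k = len(data)
    ns = np.array([v.size for v in data.values()])
    means = {g: v.mean() for g, v in data.items()}
    n_total = int(ns.sum())
    df_error = n_total - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    mse = sse / df_error
    order = sorted(data, key=lambda g: -means[g])

    if mse == 0:
        if len({round(m, 12) for m in means.values()}) > 1:
            warnings.warn(
                "zero within-group variance with differing means; letters "
                "assigned by distinct means without a test",
                stacklevel=2,
            )
            distinct = sorted({means[g] for g in order}, reverse=True)
            letters = {g: chr(ord("a") + distinct.index(means[g])) for g in order}
            f_stat, p_val = np.inf, 0.0
        else:
            letters = {g: "a" for g in order}
            f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*data.values())
        n_h = k / np.sum(1.0 / ns)  # harmonic mean group size
        ranges = _duncan_ranges(k, df_error, mse, n_h, alpha)
        # significance with the containment rule: a range nested inside a
        # non-significant wider range is itself declared non-significant
        nonsig = np.zeros((k, k), dtype=bool)
        np.fill_diagonal(nonsig, True)
        for span in range(k, 1, -1):
            for i in range(0, k - span + 1):
                j = i + span - 1
                diff = means[order[i]] - means[order[j]]
                inside_ns = any(
                    nonsig[a, b]
                    for a in range(0, i + 1)
                    for b in range(j, k)
                    if (b - a + 1) > span
                )
                if diff <= ranges[span] or inside_ns:
                    nonsig[i, j] = nonsig[j, i] = True
        letters = _letters_from_nonsig(order, nonsig)

    out = pd.DataFrame(
        {
            "group": order,
            "n": [data[g].size for g in order],
            "mean": [means[g] for g in order],
            "se": [data[g].std(ddof=1) / np.sqrt(data[g].size) for g in order],
            "letter": [letters[g] for g in order],
        }
    )
    out.attrs["F"] = float(f_stat)
    out.attrs["p"] = float(p_val)
    out.attrs["df"] = (k - 1, df_error)
    out.attrs["mse"] = float(mse)
    return out


def group_contrast(
    rel: pd.DataFrame, condition: str = "drought", alpha: float = 0.01
) -> pd.DataFrame:
    """Duncan letters for tolerant-vs-sensitive relative expression under
    one condition, with accessions as biological replicates."""
    if "group" not in rel.columns:
        raise ExpressionError("relative-expression table lacks a 'group' column")
    sub = rel[rel["condition"] == condition]
    groups = {g: v["rel_expr"].to_numpy() for g, v in sub.groupby("group")}
    return anova_duncan(groups, alpha=alpha)
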