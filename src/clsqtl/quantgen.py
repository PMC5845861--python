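"""Heritability, transgressive segregation, and trait correlation structure.

For a haploid biparental cross analysed one condition at a time, dominance
and gene-environment variance vanish, so the broad-sense heritability
H2 = V_G / V_P reduces to (V_P - V_E) / V_P with V_E estimated from
replicate measurements of the two (genetically uniform) parents.  The
narrow-sense heritability h2 = V_A / V_P is estimated as the slope of the
parent-offspring regression: segregant population mean against midparent
value across trait x condition combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "HeritabilityEstimate",
    "pooled_parental_variance",
    "broad_sense_h2",
    "narrow_sense_h2",
    "transgression_summary",
    "trait_correlations",
    "cluster_conditions",
    "normality_check",
]


@dataclass
class HeritabilityEstimate:
    """Variance decomposition for one trait x condition.

    v_p: phenotypic variance of the segregants; v_e: environmental variance
    (pooled parental replicate variance); v_g = v_p - v_e; h2_broad is
    v_g / v_p clipped into [0, 1] (the unclipped value is kept in
    h2_broad_raw).  In a haploid cross v_g contains additive and epistatic
    variance only.
    """

    v_p: float
    v_e: float
    v_g: float
    h2_broad: float
    h2_broad_raw: float
    n_segregants: int


def pooled_parental_variance(parent_replicates: pd.DataFrame) -> float:
    """Environmental variance from replicate measurements of uniform parents.

    parent_replicates: long table with columns (strain_id, value).  Returns
    the df-weighted pooled within-parent sample variance:
    V_E = sum (n_i - 1) s_i^2 / sum (n_i - 1).  Every parent needs >= 2
    replicates.
    """
    if not {"strain_id", "value"} <= set(parent_replicates.columns):
        raise ValueError("parent_replicates needs columns (strain_id, value)")
    num = den = 0.0
    for strain, grp in parent_replicates.groupby("strain_id"):
        vals = grp["value"].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"parent {strain!r} has fewer than 2 replicates")
        num += (len(vals) - 1) * np.var(vals, ddof=1)
        den += len(vals) - 1
    return float(num / den)


def broad_sense_h2(segregant_values, v_e: float) -> HeritabilityEstimate:
    """Broad-sense heritability H2 = (V_P - V_E) / V_P, clipped to [0, 1]."""
    vals = pd.Series(segregant_values).dropna().to_numpy(dtype=float)
    if len(vals) < 10:
        raise ValueError("need >= 10 segregants")
    v_p = float(np.var(vals, ddof=1))
    if v_p == 0:
        raise ValueError("segregant variance is zero; H2 undefined")
    if v_e < 0:
        raise ValueError("V_E must be >= 0")
    raw = (v_p - v_e) / v_p
    return HeritabilityEstimate(
        v_p=v_p, v_e=float(v_e), v_g=v_p - float(v_e),
        h2_broad=float(np.clip(raw, 0.0, 1.0)), h2_broad_raw=float(raw),
        n_segregants=len(vals),
    )


def narrow_sense_h2(points: pd.DataFrame) -> dict:
    """Narrow-sense heritability as the parent-offspring regression slope.

    points: one row per trait x condition with columns midparent (mean of
    the two parental values) and offspring_mean (segregant population
    mean).  Ordinary least squares of offspring_mean on midparent across all
    points; the slope estimates h2 = V_A / V_P.  Returns slope, intercept,
    r, p_value, stderr and n.
    """
    if not {"midparent", "offspring_mean"} <= set(points.columns):
        raise ValueError("points needs columns (midparent, offspring_mean)")
    pts = points[["midparent", "offspring_mean"]].dropna()
    if len(pts) < 3:
        raise ValueError("need >= 3 (midparent, offspring) points")
    if np.var(pts["midparent"].to_numpy()) == 0:
        raise ValueError("midparent values are constant; slope undefined")
    fit = stats.linregress(pts["midparent"], pts["offspring_mean"])
    return {
        "h2": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": float(fit.rvalue),
        "p_value": float(fit.pvalue),
        "stderr": float(fit.stderr),
        "n": int(len(pts)),
    }


def transgression_summary(
    segregant_values,
    parent_means: tuple[float, float],
    parent_sd: float,
    k: float = 2.0,
) -> dict:
    """Count segregants beyond the parental extremes.

    A segregant is transgressive-high if its value exceeds
    max(parent means) + k * parent_sd, and transgressive-low below
    min(parent means) - k * parent_sd.  Returns counts and fractions for
    both tails plus n.
    """
    if parent_sd < 0:
        raise ValueError("parent_sd must be >= 0")
    vals = pd.Series(segregant_values).dropna().to_numpy(dtype=float)
    hi_cut = max(parent_means) + k * parent_sd
    lo_cut = min(parent_means) - k * parent_sd
    n_hi = int(np.sum(vals > hi_cut))
    n_lo = int(np.sum(vals < lo_cut))
    n = len(vals)
    return {
        "n": n,
        "n_high": n_hi,
        "n_low": n_lo,
        "frac_high": n_hi / n if n else float("nan"),
        "frac_low": n_lo / n if n else float("nan"),
        "cut_high": float(hi_cut),
        "cut_low": float(lo_cut),
    }


def trait_correlations(matrix: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise complete-case Pearson correlations between columns.

    matrix: strains x conditions (or strains x traits), replicates already
    averaged.  Returns a long table (var_a, var_b, r, p_value, n, note) for
    each unordered pair; pairs with fewer than min_pairs complete cases or a
    constant vector get r = NaN with the reason in note.
    """
    cols = list(matrix.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            sub = matrix[[a, b]].dropna()
            note = ""
            r = p = float("nan")
            if len(sub) < min_pairs:
                note = f"only {len(sub)} complete pairs"
            elif sub[a].nunique() < 2 or sub[b].nunique() < 2:
                note = "constant vector"
            else:
                res = stats.pearsonr(sub[a], sub[b])
                r, p = float(res.statistic), float(res.pvalue)
            rows.append({"var_a": a, "var_b": b, "r": r, "p_value": p,
                         "n": len(sub), "note": note})
    return pd.DataFrame(rows)


def correlation_matrix(matrix: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Square symmetric Pearson R matrix (unit diagonal) from trait_correlations."""
    long = trait_correlations(matrix, min_pairs=min_pairs)
    cols = list(matrix.columns)
    R = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for _, row in long.iterrows():
        R.loc[row["var_a"], row["var_b"]] = row["r"]
        R.loc[row["var_b"], row["var_a"]] = row["r"]
    return R


def cluster_conditions(
    R: pd.DataFrame, k: int = 2
) -> tuple[np.ndarray, dict[str, int]]:
    """Hierarchically cluster conditions on correlation distance 1 - R.

    Agglomerative, average linkage, deterministic for a given input.
    Returns (scipy linkage matrix, flat assignment of each condition to one
    of k groups).
    """
    if not np.allclose(R.to_numpy(), R.to_numpy().T, atol=1e-10):
        raise ValueError("correlation matrix is not symmetric")
    D = 1.0 - R.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Z, dict(zip(R.columns, (int(c) for c in flat)))


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.left, node.right
        bl_l = node.dist - left.dist
        bl_r = node.dist - right.dist
        return f"({walk(left)}:{bl_l:.6g},{walk(right)}:{bl_r:.6g})"

    return walk(tree) + ";"


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk test of normality: returns (W, p).

    The null hypothesis is that the sample is Gaussian; heavy floor
    censoring (e.g. many Survival Integrals piled at the 0.5 assay floor)
    drives W down and rejects.  Requires 3 <= n <= 5000.
    """
    vals = pd.Series(values).dropna().to_numpy(dtype=float)
    if len(vals) < 3 or len(vals) > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = stats.shapiro(vals)
    return float(res.statistic), float(res.pvalue)
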