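"""Individual Segregant Analysis: single-marker LOD scans with permutation thresholds.

Each marker is tested by marker regression: segregants are split by parent-of-
origin allele and the LOD score compares the two-mean model against the grand
mean,

    LOD = (n/2) * log10(RSS0 / RSS1),

with n the complete-case count at that marker.  Genome-wide significance uses
the standard permutation null: the phenotype vector is shuffled against the
genotypes, the maximum LOD of each permuted scan is recorded, and the
threshold is the empirical (1 - alpha) quantile of those maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScanResult",
    "lod_scan",
    "permutation_threshold",
    "support_intervals",
    "isa_scan",
]

# markers with fewer complete-case segregants than this in either allele
# group are skipped (their group mean is too unstable to test)
MIN_GROUP = 2


def _marker_sums(G: np.ndarray, Y: np.ndarray):
    """Sufficient statistics for marker regression of every column of Y.

    G: (n x m) genotype matrix with NaN missing; Y: (n x p) phenotype
    matrix.  Complete-case handling is per marker: rows missing at marker j
    drop out of marker j's sums only.  Returns per-marker RSS0, RSS1 and n
    as (m x p) / (m,) arrays.
    """
    M = (~np.isnan(G)).astype(float)
    G0 = np.nan_to_num(G, nan=0.0)
    A = M * G0
    n1 = A.sum(axis=0)
    ntot = M.sum(axis=0)
    n0 = ntot - n1
    s1 = A.T @ Y                      # sum of y in allele-1 group, per marker
    tot = M.T @ Y
    ssq = M.T @ (Y * Y)
    s0 = tot - s1
    with np.errstate(divide="ignore", invalid="ignore"):
        rss0 = ssq - tot**2 / ntot[:, None]
        rss1 = ssq - np.where(n1[:, None] > 0, s1**2 / n1[:, None], 0.0) \
                   - np.where(n0[:, None] > 0, s0**2 / n0[:, None], 0.0)
    return rss0, rss1, ntot, n1, n0


def _lod_from_rss(rss0, rss1, ntot, n1, n0):
    """(m x p) LOD matrix; NaN marks skipped markers, inf perfect fits."""
    rss0 = np.maximum(rss0, 0.0)
    rss1 = np.maximum(rss1, 0.0)
    lod = np.full(rss0.shape, np.nan)
    testable = (n1 >= MIN_GROUP) & (n0 >= MIN_GROUP)
    mono = (~testable) & ((n1 == 0) | (n0 == 0)) & (ntot > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rss1 > 0, rss0 / rss1, np.inf)
        val = (ntot[:, None] / 2.0) * np.log10(ratio)
    val = np.where(rss0 <= 1e-300, 0.0, val)          # constant phenotype
    val = np.where((rss1 <= 1e-300) & (rss0 > 1e-300), np.inf, val)
    lod[testable] = val[testable]
    lod[mono] = 0.0
    return np.maximum(lod, 0.0, out=lod, where=~np.isnan(lod))


def lod_scan(genotypes: pd.DataFrame, phenotype: pd.Series) -> pd.DataFrame:
    """Single-marker LOD scan of one phenotype over all markers.

    genotypes: segregants x markers (0/1/NaN); phenotype: indexed by
    segregant id, NaN entries dropped.  Returns a DataFrame indexed like the
    marker columns with lod, n_used and a status flag: "ok", "monomorphic"
    (LOD defined 0), "skipped" (an allele group below MIN_GROUP), or
    "perfect_fit" (RSS1 = 0; LOD infinite, excluded from thresholds).
    """
    y = phenotype.dropna()
    common = genotypes.index.intersection(y.index)
    if len(common) < 10:
        raise ValueError("phenotype present for fewer than 10 segregants")
    G = genotypes.loc[common].to_numpy(dtype=float)
    Y = y.loc[common].to_numpy(dtype=float)[:, None]
    rss0, rss1, ntot, n1, n0 = _marker_sums(G, Y)
    lod = _lod_from_rss(rss0, rss1, ntot, n1, n0)[:, 0]
    status = np.where(np.isnan(lod), "skipped", "ok")
    status = np.where((n1 == 0) | (n0 == 0), "monomorphic", status)
    status = np.where(np.isinf(lod), "perfect_fit", status)
    out = pd.DataFrame(
        {"lod": lod, "n_used": ntot.astype(int), "status": status},
        index=pd.Index(genotypes.columns, name="marker_id"),
    )
    out.attrs["constant_phenotype"] = bool(np.nanstd(Y) == 0)
    return out


def permutation_threshold(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide LOD threshold from the max-statistic permutation null.

    The phenotype is permuted n_perm times against the (fixed) genotypes;
    the threshold is the nearest-rank (1 - alpha) empirical quantile of the
    per-permutation maximum LOD.  Infinite LODs are excluded from the
    maxima.  alpha = 1 degenerates to the minimum of the permuted maxima.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = phenotype.dropna()
    common = genotypes.index.intersection(y.index)
    G = genotypes.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    Y = np.empty((len(yv), n_perm))
    for p in range(n_perm):
        Y[:, p] = rng.permutation(yv)
    rss0, rss1, ntot, n1, n0 = _marker_sums(G, Y)
    lod = _lod_from_rss(rss0, rss1, ntot, n1, n0)
    lod[np.isinf(lod)] = np.nan
    with np.errstate(all="ignore"):
        maxima = np.nanmax(lod, axis=0)
    maxima = maxima[~np.isnan(maxima)]
    maxima.sort()
    k = max(1, int(np.ceil((1.0 - alpha) * len(maxima))))
    return float(maxima[k - 1])


def support_intervals(
    scan: pd.DataFrame,
    marker_map: pd.DataFrame,
    threshold: float,
    lod_drop: float = 1.5,
) -> pd.DataFrame:
    """LOD-drop support intervals around peaks exceeding the threshold.

    Each maximal run of contiguous markers at or above the threshold yields
    one peak (the run's LOD maximum); its interval is the contiguous stretch
    of markers around the peak whose LOD stays within lod_drop of it.
    Returns (chrom, start_bp, end_bp, peak_marker, peak_lod, width_kb).
    """
    merged = marker_map.merge(
        scan.reset_index(), on="marker_id", how="inner", validate="one_to_one"
    )
    rows = []
    for chrom, grp in merged.groupby("chrom", sort=False):
        grp = grp.sort_values("pos_bp").reset_index(drop=True)
        lod = grp["lod"].to_numpy()
        lod = np.where(np.isnan(lod), 0.0, lod)
        sig = (lod >= threshold) & (threshold == threshold)
        i = 0
        while i < len(sig):
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            p = i + int(np.argmax(lod[i : j + 1]))
            peak = lod[p]
            lo = p
            while lo > 0 and lod[lo - 1] >= peak - lod_drop:
                lo -= 1
            hi = p
            while hi < len(lod) - 1 and lod[hi + 1] >= peak - lod_drop:
                hi += 1
            start_bp = int(grp.loc[lo, "pos_bp"])
            end_bp = int(grp.loc[hi, "pos_bp"])
            rows.append(
                {
                    "chrom": chrom,
                    "start_bp": start_bp,
                    "end_bp": end_bp,
                    "peak_marker": grp.loc[p, "marker_id"],
                    "peak_lod": float(peak),
                    "width_kb": (end_bp - start_bp) / 1000.0,
                }
            )
            i = j + 1
    return pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "peak_marker", "peak_lod", "width_kb"]
    )


@dataclass
class ScanResult:
    """A complete ISA scan: per-marker LOD, threshold, and intervals."""

    scan: pd.DataFrame
    threshold: float
    alpha: float
    n_perm: int
    intervals: pd.DataFrame = field(default_factory=pd.DataFrame)


def isa_scan(
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    phenotype: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    lod_drop: float = 1.5,
    seed: int = 0,
) -> ScanResult:
    """Run the full ISA pipeline: scan, permutation threshold, intervals."""
    scan = lod_scan(genotypes, phenotype)
    thr = permutation_threshold(genotypes, phenotype, n_perm=n_perm, alpha=alpha, seed=seed)
    intervals = support_intervals(scan, marker_map, thr, lod_drop=lod_drop)
    return ScanResult(scan=scan, threshold=thr, alpha=alpha, n_perm=n_perm,
                      intervals=intervals)
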