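"""Bulk Segregant Analysis: G statistic, tricube-smoothed G', FDR thresholds.

Two bulks of phenotypically extreme segregants (by default the 50 longest-
and 50 shortest-lived) are formed in silico from individually genotyped
segregants.  At each marker the 2x2 table of bulk x allele counts yields the
likelihood-ratio statistic

    G = 2 * sum n_ij * ln(n_ij / e_ij),

with expectations e_ij from the table margins.  G is smoothed along each
chromosome with a tricube kernel (G'), which pools information across linked
markers and damps single-marker noise.  Significance comes from a robust
log-normal null fitted to G' by median/MAD — resistant to inflation by true
QTL regions — with Benjamini-Hochberg control of the false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BulkSelection",
    "GPrimeScan",
    "select_bulks",
    "allele_counts",
    "g_statistic",
    "smooth_gprime",
    "gprime_significance",
    "significant_regions",
    "genes_in_interval",
    "bsa_scan",
]


@dataclass
class BulkSelection:
    """Ids of the high- and low-phenotype bulks (disjoint, equal size)."""

    high_bulk: list[str]
    low_bulk: list[str]

    def __post_init__(self) -> None:
        if set(self.high_bulk) & set(self.low_bulk):
            raise ValueError("bulks overlap")
        if len(self.high_bulk) != len(self.low_bulk):
            raise ValueError("bulks must have equal size")

    @property
    def size(self) -> int:
        return len(self.high_bulk)


def select_bulks(phenotype: pd.Series, size: int = 50) -> BulkSelection:
    """Pick the `size` highest- and lowest-phenotype segregants.

    Deterministic: segregants are ordered by (value, id) ascending; the low
    bulk is the first `size`, the high bulk the last `size`.  Ties are thus
    resolved purely by id order, and the two bulks can never overlap as long
    as 2 * size <= n.
    """
    y = phenotype.dropna()
    if 2 * size > len(y):
        raise ValueError(f"2*size = {2 * size} exceeds {len(y)} phenotyped segregants")
    order = sorted(y.index, key=lambda i: (y[i], str(i)))
    return BulkSelection(high_bulk=list(order[-size:]), low_bulk=list(order[:size]))


def allele_counts(genotypes: pd.DataFrame, bulks: BulkSelection) -> pd.DataFrame:
    """Per-marker allele counts within each bulk.

    Returns a DataFrame indexed by marker with columns n_high_allele1,
    n_high_allele0, n_low_allele1, n_low_allele0 (allele 1 = parent-2
    origin).  Missing genotypes are excluded from both counts, so the counts
    in a bulk sum to at most the bulk size.
    """
    for bid in bulks.high_bulk + bulks.low_bulk:
        if bid not in genotypes.index:
            raise KeyError(f"bulk member {bid!r} not in genotype matrix")
    out = {}
    for name, ids in (("high", bulks.high_bulk), ("low", bulks.low_bulk)):
        sub = genotypes.loc[ids].to_numpy(dtype=float)
        n1 = np.nansum(sub, axis=0)
        nobs = (~np.isnan(sub)).sum(axis=0)
        out[f"n_{name}_allele1"] = n1.astype(int)
        out[f"n_{name}_allele0"] = (nobs - n1).astype(int)
    return pd.DataFrame(out, index=pd.Index(genotypes.columns, name="marker_id"))


def g_statistic(
    n_high_allele1, n_high_allele0, n_low_allele1, n_low_allele0
):
    """Likelihood-ratio G for the 2x2 bulk x allele table(s).

    G = 2 * sum n * ln(n / e) over the four cells, with e the usual
    independence expectation from row and column margins; empty cells
    contribute 0.  Accepts scalars or aligned arrays (one table per marker).
    """
    cells = [np.asarray(c, dtype=float) for c in
             (n_high_allele1, n_high_allele0, n_low_allele1, n_low_allele0)]
    a, b, c, d = cells
    total = a + b + c + d
    if np.any(total <= 0):
        raise ValueError("all-zero contingency table")
    rows = [a + b, c + d]
    cols = [a + c, b + d]
    g = np.zeros_like(total)
    for n, r, col in ((a, 0, 0), (b, 0, 1), (c, 1, 0), (d, 1, 1)):
        e = rows[r] * cols[col] / total
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(n > 0, n * np.log(np.where(n > 0, n / np.where(e > 0, e, 1.0), 1.0)), 0.0)
        g = g + term
    g = 2.0 * g
    return float(g) if g.ndim == 0 else g


def smooth_gprime(
    g: pd.Series, marker_map: pd.DataFrame, window_kb: float = 100.0
) -> pd.Series:
    """Tricube-weighted smoothing of G along each chromosome.

    G' at a focal marker is the weighted mean of G over markers within
    +/- window_kb on the same chromosome, with tricube weights
    w = (1 - (d/D)^3)^3 normalized to sum to 1 (D = window_kb in bp).  A
    marker with no neighbours in the window keeps its own G.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    merged = marker_map.merge(
        g.rename("g").reset_index().rename(columns={g.index.name or "index": "marker_id"}),
        on="marker_id", how="inner", validate="one_to_one",
    )
    half = window_kb * 1000.0
    gp = pd.Series(index=g.index, dtype=float, name="g_prime")
    for _, grp in merged.groupby("chrom", sort=False):
        pos = grp["pos_bp"].to_numpy(dtype=float)
        gv = grp["g"].to_numpy(dtype=float)
        d = np.abs(pos[:, None] - pos[None, :])
        w = np.where(d <= half, (1.0 - (d / half) ** 3) ** 3, 0.0)
        gp.loc[grp["marker_id"].to_numpy()] = (w @ gv) / w.sum(axis=1)
    return gp


def gprime_significance(
    g_prime: pd.Series, fdr_level: float = 0.05
) -> tuple[pd.Series, pd.Series, float]:
    """Per-marker p- and q-values for G' under a robust log-normal null.

    ln G' is modeled as Normal with location the median and scale
    1.4826 * MAD of ln G' across all markers — estimators that a minority of
    true QTL markers cannot inflate.  Right-tail p-values are corrected with
    Benjamini-Hochberg; the returned threshold is the smallest G' with
    q <= fdr_level (NaN when nothing is significant).
    """
    if len(g_prime) < 50:
        raise ValueError("need >= 50 markers for a stable null fit")
    gp = np.maximum(g_prime.to_numpy(dtype=float), np.finfo(float).eps)
    lng = np.log(gp)
    loc = np.median(lng)
    scale = stats.median_abs_deviation(lng, scale="normal")
    if scale <= 0:
        p = np.ones_like(lng)
    else:
        p = stats.norm.sf(lng, loc=loc, scale=scale)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    sig = q <= fdr_level
    threshold = float(gp[sig].min()) if sig.any() else float("nan")
    return (
        pd.Series(p, index=g_prime.index, name="p_value"),
        pd.Series(q, index=g_prime.index, name="q_value"),
        threshold,
    )


def significant_regions(
    scan: pd.DataFrame, marker_map: pd.DataFrame, fdr_level: float = 0.05
) -> pd.DataFrame:
    """Merge contiguous significant markers into QTL regions.

    scan must carry q_value and g_prime per marker.  Maximal runs of
    adjacent markers (map order, same chromosome) with q <= fdr_level become
    regions (chrom, start_bp, end_bp, peak_marker, peak_gprime, width_kb);
    a single non-significant marker splits a run in two.
    """
    merged = marker_map.merge(
        scan.reset_index(), on="marker_id", how="inner", validate="one_to_one"
    )
    rows = []
    for chrom, grp in merged.groupby("chrom", sort=False):
        grp = grp.sort_values("pos_bp").reset_index(drop=True)
        sig = (grp["q_value"] <= fdr_level).to_numpy()
        i = 0
        while i < len(sig):
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            run = grp.iloc[i : j + 1]
            peak = run.loc[run["g_prime"].idxmax()]
            rows.append(
                {
                    "chrom": chrom,
                    "start_bp": int(run["pos_bp"].iloc[0]),
                    "end_bp": int(run["pos_bp"].iloc[-1]),
                    "peak_marker": peak["marker_id"],
                    "peak_gprime": float(peak["g_prime"]),
                    "width_kb": (int(run["pos_bp"].iloc[-1]) - int(run["pos_bp"].iloc[0])) / 1000.0,
                }
            )
            i = j + 1
    return pd.DataFrame(
        rows,
        columns=["chrom", "start_bp", "end_bp", "peak_marker", "peak_gprime", "width_kb"],
    )


def genes_in_interval(
    region: dict | pd.Series, annotation: pd.DataFrame
) -> tuple[list[str], int]:
    """Genes overlapping a region (1-based inclusive, any overlap counts).

    annotation columns: gene, chrom, start_bp, end_bp.  A gene abutting the
    region boundary (gene start == region end) is included.  Malformed rows
    (missing fields, non-numeric or inverted coordinates) are skipped;
    returns (gene list in coordinate order, number of rows skipped).
    """
    required = {"gene", "chrom", "start_bp", "end_bp"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    chrom, start, end = region["chrom"], region["start_bp"], region["end_bp"]
    hits, skipped = [], 0
    for _, row in annotation.iterrows():
        try:
            gs, ge = int(row["start_bp"]), int(row["end_bp"])
            gname, gchrom = row["gene"], row["chrom"]
            if pd.isna(gname) or pd.isna(gchrom) or gs > ge:
                raise ValueError
        except (ValueError, TypeError):
            skipped += 1
            continue
        if gchrom == chrom and gs <= end and ge >= start:
            hits.append((gs, str(gname)))
    return [name for _, name in sorted(hits)], skipped


@dataclass
class GPrimeScan:
    """A complete BSA scan: per-marker G/G'/p/q, threshold, and regions."""

    scan: pd.DataFrame
    threshold: float
    fdr_level: float
    window_kb: float
    bulks: BulkSelection
    regions: pd.DataFrame = field(default_factory=pd.DataFrame)


def bsa_scan(
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    phenotype: pd.Series,
    bulk_size: int = 50,
    window_kb: float = 100.0,
    fdr_level: float = 0.05,
) -> GPrimeScan:
    """Run the full BSA pipeline: bulks, counts, G, G', FDR, regions."""
    bulks = select_bulks(phenotype, size=bulk_size)
    counts = allele_counts(genotypes, bulks)
    g = pd.Series(
        g_statistic(
            counts["n_high_allele1"], counts["n_high_allele0"],
            counts["n_low_allele1"], counts["n_low_allele0"],
        ),
        index=counts.index, name="g",
    )
    gp = smooth_gprime(g, marker_map, window_kb=window_kb)
    p, q, threshold = gprime_significance(gp, fdr_level=fdr_level)
    scan = pd.DataFrame(
        {"g": g, "g_prime": gp, "p_value": p, "q_value": q}
    )
    regions = significant_regions(scan, marker_map, fdr_level=fdr_level)
    return GPrimeScan(scan=scan, threshold=threshold, fdr_level=fdr_level,
                      window_kb=window_kb, bulks=bulks, regions=regions)
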