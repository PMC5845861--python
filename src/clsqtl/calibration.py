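"""Frequentist calibration studies for the two genome-scan procedures.

These simulation studies measure, under the generator's own study
conditions (a 488-spore haploid cross over a 16-chromosome, ~300 marker
yeast-scale map), the operating characteristics the scans advertise:

* the genome-wide type-I error of the LOD scan at its permutation-derived
  threshold, which should equal the nominal alpha; and
* the realized false-discovery proportion of the smoothed G' scan at its
  Benjamini-Hochberg level, counting a called marker false when it lies
  more than one smoothing window from the causal locus (or anywhere in a
  cross simulated without a QTL).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import qtl_bsa, qtl_isa, synthetic_data

__all__ = ["assay_floor_si", "isa_type_i_error", "bsa_false_discovery_proportion"]


def default_map() -> pd.DataFrame:
    """The calibration map: 16 chromosomes x 19 markers, 15 cM / 40.5 kb apart."""
    return synthetic_data.make_marker_map(16, 19, 15.0, 2700.0)


def assay_floor_si() -> float:
    """Smallest Survival Integral measurable for a strain viable at day 1.

    Daily sampling from day 1 with trapezoidal integration: a strain fully
    viable at day 1 and dead by day 2 integrates to half the first interval.
    """
    from .cls_quant import SurvivalCurve, survival_integral

    curve = SurvivalCurve(aging_day=[1, 2], viability=[1.0, 0.0], reference_day=1)
    return survival_integral(curve)


def effect_for_h2(h2: float, env_sd: float = 1.0) -> float:
    """Additive effect size a such that one Bernoulli(1/2) locus explains
    h2 of the phenotypic variance: a^2/4 = h2 * (a^2/4 + env_sd^2)."""
    return 2.0 * env_sd * np.sqrt(h2 / (1.0 - h2))


def isa_type_i_error(
    n_crosses: int = 200,
    n_segregants: int = 488,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    marker_map: pd.DataFrame | None = None,
) -> dict:
    """Fraction of no-QTL crosses whose LOD scan exceeds its own threshold.

    Each cross gets an independent meiosis and a pure-noise phenotype; the
    genome-wide threshold is recomputed per cross from n_perm permutations.
    A calibrated procedure yields a fraction near alpha.
    """
    mm = default_map() if marker_map is None else marker_map
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_crosses):
        cross = synthetic_data.simulate_cross(
            mm, n_segregants, seed=int(rng.integers(2**31))
        )
        y = pd.Series(
            rng.normal(0.0, 1.0, n_segregants), index=cross.genotypes.index
        )
        scan = qtl_isa.lod_scan(cross.genotypes, y)
        thr = qtl_isa.permutation_threshold(
            cross.genotypes, y, n_perm=n_perm, alpha=alpha,
            seed=int(rng.integers(2**31)),
        )
        lod = scan["lod"].to_numpy()
        lod = lod[np.isfinite(lod)]
        hits += bool((lod >= thr).any())
    return {"value": hits / n_crosses, "n": n_crosses, "alpha": alpha}


def bsa_false_discovery_proportion(
    n_crosses: int = 200,
    n_segregants: int = 488,
    qtl_h2: float = 0.30,
    bulk_size: int = 50,
    window_kb: float = 100.0,
    fdr_level: float = 0.05,
    seed: int = 0,
    marker_map: pd.DataFrame | None = None,
) -> dict:
    """Pooled realized FDP of the G' scan over a null/one-QTL cross mixture.

    Half the crosses carry no QTL (every call false); the other half carry
    one additive QTL, placed uniformly at random, explaining qtl_h2 of the
    phenotypic variance.  A call is false when its marker lies more than one
    smoothing-window span (the window's full 2 x window_kb extent) from the
    causal marker — the distance beyond which the tricube kernel centred
    anywhere near the locus carries no weight.  Returns the pooled
    proportion, its binomial standard error, and call counts.
    """
    mm = default_map() if marker_map is None else marker_map
    pos = mm.set_index("marker_id")
    markers = list(mm["marker_id"])
    rng = np.random.default_rng(seed)
    a = effect_for_h2(qtl_h2)
    n_false = n_calls = 0
    for i in range(n_crosses):
        cross = synthetic_data.simulate_cross(
            mm, n_segregants, seed=int(rng.integers(2**31))
        )
        noise = rng.normal(0.0, 1.0, n_segregants)
        causal = None
        if i % 2 == 1:
            causal = markers[int(rng.integers(len(markers)))]
            noise = noise + a * cross.genotypes[causal].to_numpy()
        y = pd.Series(noise, index=cross.genotypes.index)
        res = qtl_bsa.bsa_scan(
            cross.genotypes, mm, y, bulk_size=bulk_size,
            window_kb=window_kb, fdr_level=fdr_level,
        )
        called = res.scan.index[res.scan["q_value"] <= fdr_level]
        n_calls += len(called)
        for mk in called:
            if causal is None:
                n_false += 1
                continue
            same_chrom = pos.loc[mk, "chrom"] == pos.loc[causal, "chrom"]
            dist = abs(int(pos.loc[mk, "pos_bp"]) - int(pos.loc[causal, "pos_bp"]))
            if not (same_chrom and dist <= 2.0 * window_kb * 1000.0):
                n_false += 1
    fdp = n_false / n_calls if n_calls else 0.0
    se = float(np.sqrt(fdr_level * (1 - fdr_level) / n_calls)) if n_calls else 0.0
    return {
        "value": fdp, "n": n_crosses, "n_calls": n_calls,
        "n_false": n_false, "binomial_se": se, "fdr_level": fdr_level,
    }
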