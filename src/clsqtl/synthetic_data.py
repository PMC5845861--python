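"""Simulation of biparental yeast crosses and plate-reader aging assays.

This module generates the three kinds of data the rest of the package
consumes: marker maps and haploid segregant genotypes (meiosis under the
Haldane map function, no crossover interference), additive per-condition
quantitative phenotypes (Survival Integrals, in day units), and plate-reader
outgrowth time series in which the viability of an aged culture is encoded
as a time shift of its growth curve.

Genotypes are coded by parent of origin: 0 = parent-1 allele, 1 = parent-2
allele, NaN = missing.  All stochastic functions take an integer seed and
are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "QTLTruth",
    "SimulatedCross",
    "GrowthModelParams",
    "make_marker_map",
    "haldane_r",
    "simulate_cross",
    "simulate_phenotypes",
    "simulate_outgrowth",
    "viability_schedule_for_si",
    "logistic_od",
    "roman_chromosomes",
]

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
]


def roman_chromosomes(n: int) -> list[str]:
    """Chromosome labels in the yeast style (I..XVI, then chr17, chr18, ...)."""
    if n <= len(_ROMAN):
        return _ROMAN[:n]
    return _ROMAN + [f"chr{i}" for i in range(len(_ROMAN) + 1, n + 1)]


def haldane_r(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a map distance in centimorgans.

    Haldane's map function without interference: r = (1 - exp(-2d)) / 2 with
    d in Morgans.  r(0) = 0; r -> 1/2 for unlinked loci.
    """
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def make_marker_map(
    n_chrom: int,
    markers_per_chrom: int,
    spacing_cm: float,
    bp_per_cm: float = 2700.0,
) -> pd.DataFrame:
    """Build an evenly spaced marker map.

    Markers sit at 0, spacing_cm, 2*spacing_cm, ... from each chromosome
    start; physical positions are pos_bp = round(pos_cm * bp_per_cm) + 1 so
    the first marker of every chromosome is at 1 bp (1-based coordinates).

    Returns a DataFrame with columns (marker_id, chrom, pos_bp, pos_cm).
    Deterministic: no randomness is involved.
    """
    if n_chrom < 1 or markers_per_chrom < 1:
        raise ValueError("n_chrom and markers_per_chrom must be >= 1")
    if spacing_cm <= 0 or bp_per_cm <= 0:
        raise ValueError("spacing_cm and bp_per_cm must be positive")
    chroms = roman_chromosomes(n_chrom)
    rows = []
    for chrom in chroms:
        for j in range(markers_per_chrom):
            pos_cm = j * spacing_cm
            rows.append(
                {
                    "marker_id": f"{chrom}_m{j + 1:03d}",
                    "chrom": chrom,
                    "pos_bp": int(round(pos_cm * bp_per_cm)) + 1,
                    "pos_cm": float(pos_cm),
                }
            )
    return pd.DataFrame(rows)


def validate_marker_map(marker_map: pd.DataFrame) -> None:
    """Raise ValueError if the map violates its schema or ordering invariants."""
    required = {"marker_id", "chrom", "pos_bp", "pos_cm"}
    missing = required - set(marker_map.columns)
    if missing:
        raise ValueError(f"marker map missing columns: {sorted(missing)}")
    if marker_map["marker_id"].duplicated().any():
        dup = marker_map.loc[marker_map["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"duplicate marker_id {dup!r}")
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        if not grp["pos_bp"].is_monotonic_increasing or grp["pos_bp"].duplicated().any():
            raise ValueError(f"pos_bp not strictly increasing on chromosome {chrom}")
        if not grp["pos_cm"].is_monotonic_increasing:
            raise ValueError(f"pos_cm decreasing on chromosome {chrom}")


@dataclass
class QTLTruth:
    """Ground-truth additive genetic architecture for a simulated cross.

    effects maps condition -> per-causal-marker additive effect (day units of
    Survival Integral); allele 1 (parent-2 origin) carries the effect.
    baseline maps condition -> mean SI of the all-zero genotype; env_sd is
    the residual (environmental) standard deviation shared by all conditions.
    """

    causal_markers: list[str] = field(default_factory=list)
    effects: dict[str, np.ndarray] = field(default_factory=dict)
    baseline: dict[str, float] = field(default_factory=dict)
    env_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.env_sd < 0:
            raise ValueError("env_sd must be >= 0")
        self.effects = {
            cond: np.asarray(eff, dtype=float) for cond, eff in self.effects.items()
        }
        for cond, eff in self.effects.items():
            if len(eff) != len(self.causal_markers):
                raise ValueError(
                    f"effects for condition {cond!r} have length {len(eff)}, "
                    f"expected {len(self.causal_markers)}"
                )

    @property
    def conditions(self) -> list[str]:
        return list(self.baseline)


@dataclass
class SimulatedCross:
    """A haploid biparental cross: genotype matrix, marker map, and optional truth.

    genotypes: DataFrame, rows = segregants, columns = markers (map order),
    values 0.0 / 1.0 / NaN.
    """

    genotypes: pd.DataFrame
    marker_map: pd.DataFrame
    truth: QTLTruth | None = None


def simulate_cross(
    marker_map: pd.DataFrame,
    n_segregants: int,
    seed: int,
    missing_rate: float = 0.0,
) -> SimulatedCross:
    """Simulate haploid meiotic segregants over a marker map.

    Each chromosome is generated independently: the first marker's allele is
    Bernoulli(1/2), and each subsequent marker switches parent of origin with
    the Haldane recombination fraction of the inter-marker distance.  Missing
    genotypes (NaN) are injected uniformly at missing_rate.
    """
    validate_marker_map(marker_map)
    if n_segregants < 1:
        raise ValueError("n_segregants must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    blocks = []
    for _, grp in marker_map.groupby("chrom", sort=False):
        m = len(grp)
        alleles = np.empty((n_segregants, m), dtype=float)
        alleles[:, 0] = rng.random(n_segregants) < 0.5
        if m > 1:
            d = np.diff(grp["pos_cm"].to_numpy())
            r = haldane_r(d)
            switches = rng.random((n_segregants, m - 1)) < r
            # parent of origin along the chromosome = initial allele XOR the
            # cumulative parity of crossovers in the preceding intervals
            parity = np.cumsum(switches, axis=1) % 2
            alleles[:, 1:] = np.abs(alleles[:, [0]] - parity)
        blocks.append(alleles)
    geno = np.hstack(blocks)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = np.nan
    segregant_ids = [f"seg{i + 1:04d}" for i in range(n_segregants)]
    genotypes = pd.DataFrame(
        geno, index=segregant_ids, columns=marker_map["marker_id"].tolist()
    )
    genotypes.index.name = "segregant_id"
    return SimulatedCross(genotypes=genotypes, marker_map=marker_map)


def simulate_phenotypes(
    cross: SimulatedCross,
    truth: QTLTruth,
    n_parent_replicates: int = 3,
    seed: int = 0,
    floor: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw additive phenotypes for segregants and parental replicates.

    Segregant value = baseline + sum(effect * allele) + N(0, env_sd) per
    condition.  Parent 1 is the all-0 genotype, parent 2 the all-1 genotype.
    Missing genotypes at causal markers are imputed as 0.5 (expected dosage).
    With floor set, values are clipped from below at the assay's minimum
    measurable Survival Integral.

    Returns (segregant table, parent replicate table), both long-format with
    columns (strain_id, condition, value) and additionally replicate for the
    parents.
    """
    for mk in truth.causal_markers:
        if mk not in cross.genotypes.columns:
            raise ValueError(f"causal marker {mk!r} not present in the marker map")
    if n_parent_replicates < 1:
        raise ValueError("n_parent_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if truth.causal_markers:
        dosage = cross.genotypes[truth.causal_markers].to_numpy(dtype=float)
        dosage = np.where(np.isnan(dosage), 0.5, dosage)
    else:
        dosage = np.zeros((len(cross.genotypes), 0))
    seg_rows = []
    parent_rows = []
    for cond in truth.conditions:
        eff = truth.effects.get(cond, np.zeros(len(truth.causal_markers)))
        base = truth.baseline[cond]
        genetic = dosage @ eff
        values = base + genetic + rng.normal(0.0, truth.env_sd, size=len(genetic))
        if floor is not None:
            values = np.maximum(values, floor)
        seg_rows.append(
            pd.DataFrame(
                {
                    "strain_id": cross.genotypes.index,
                    "condition": cond,
                    "value": values,
                }
            )
        )
        p1 = base + rng.normal(0.0, truth.env_sd, size=n_parent_replicates)
        p2 = base + float(np.sum(eff)) + rng.normal(0.0, truth.env_sd, size=n_parent_replicates)
        if floor is not None:
            p1, p2 = np.maximum(p1, floor), np.maximum(p2, floor)
        for name, vals in (("parent1", p1), ("parent2", p2)):
            parent_rows.append(
                pd.DataFrame(
                    {
                        "strain_id": name,
                        "condition": cond,
                        "replicate": np.arange(1, n_parent_replicates + 1),
                        "value": vals,
                    }
                )
            )
    segregants = pd.concat(seg_rows, ignore_index=True)
    parents = pd.concat(parent_rows, ignore_index=True)
    return segregants, parents


@dataclass
class GrowthModelParams:
    """Logistic growth model for outgrowth wells.

    carrying_capacity: plateau OD; mu: maximum specific growth rate (1/h);
    initial_od: total inoculum OD (viable + dead cells).  The doubling time
    is ln(2)/mu hours.
    """

    carrying_capacity: float = 1.0
    mu: float = 0.4
    initial_od: float = 0.001

    def __post_init__(self) -> None:
        if self.carrying_capacity <= self.initial_od:
            raise ValueError("carrying_capacity must exceed initial_od")
        if self.mu <= 0 or self.initial_od <= 0:
            raise ValueError("mu and initial_od must be positive")

    @property
    def doubling_time(self) -> float:
        return math.log(2) / self.mu


def logistic_od(
    t: np.ndarray, params: GrowthModelParams, viability: float
) -> np.ndarray:
    """Well OD over time for a culture inoculated at viable fraction v.

    The viable sub-population (v * initial_od) grows logistically to the
    carrying capacity; dead cells contribute a constant (1 - v) * initial_od.
    v = 0 gives a flat curve at the initial OD.  Because the viable inoculum
    is small relative to capacity, halving v delays the threshold crossing by
    one doubling time — the principle the viability quantification inverts.
    """
    t = np.asarray(t, dtype=float)
    n0 = params.initial_od * viability
    dead = params.initial_od * (1.0 - viability)
    if n0 <= 0:
        return np.full_like(t, params.initial_od)
    k = params.carrying_capacity
    viable = k / (1.0 + (k - n0) / n0 * np.exp(-params.mu * t))
    return dead + viable


def simulate_outgrowth(
    viability: Mapping[int, float],
    params: GrowthModelParams,
    time_grid_h: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    strain_id: str = "strain",
    condition: str = "SC",
) -> pd.DataFrame:
    """Simulate one strain x condition's outgrowth curves over aging days.

    viability maps aging_day -> viable fraction in [0, 1] at that day.
    Returns a long-format plate table (strain, condition, aging_day, time_h,
    od) with i.i.d. Gaussian OD noise of noise_sd (negative ODs clipped to 0).
    """
    t = np.asarray(list(time_grid_h), dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time_grid_h must be strictly increasing with >= 2 points")
    if np.any(t < 0):
        raise ValueError("time_grid_h must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    for day in sorted(viability):
        v = float(viability[day])
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"viability {v} at aging day {day} outside [0, 1]")
        od = logistic_od(t, params, v)
        if noise_sd > 0:
            od = od + rng.normal(0.0, noise_sd, size=od.shape)
        od = np.maximum(od, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "strain_id": strain_id,
                    "condition": condition,
                    "aging_day": int(day),
                    "time_h": t,
                    "od": od,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def viability_schedule_for_si(
    si: float, days: Sequence[int]
) -> dict[int, float]:
    """Exponential-decay viability schedule whose trapezoidal area is si.

    The schedule v(d) = exp(-lam * (d - d0)) over the sampling days is the
    single-parameter family used to turn a target Survival Integral back into
    per-day viabilities when generating outgrowth data.  The reachable range
    is (half the first sampling interval, last_day - first_day); targets are
    clipped into it.
    """
    days = sorted(int(d) for d in days)
    if len(days) < 2:
        raise ValueError("need at least two sampling days")
    d = np.asarray(days, dtype=float)

    def area(lam: float) -> float:
        return float(np.trapezoid(np.exp(-lam * (d - d[0])), d))

    lo_lam, hi_lam = 0.0, 60.0
    si_max, si_min = area(lo_lam), area(hi_lam)
    si = float(np.clip(si, si_min + 1e-9, si_max - 1e-9))
    lam = brentq(lambda x: area(x) - si, lo_lam, hi_lam, xtol=1e-12)
    return {day: float(np.exp(-lam * (day - d[0]))) for day in days}


def write_genotypes_tsv(cross: SimulatedCross, path) -> None:
    """Write the genotype matrix as TSV (rows = segregants, cells 0/1/NA)."""
    out = cross.genotypes.copy()
    out = out.map(lambda x: "NA" if pd.isna(x) else str(int(x)))
    out.to_csv(path, sep="\t")


def write_marker_map_tsv(marker_map: pd.DataFrame, path) -> None:
    marker_map.to_csv(path, sep="\t", index=False)
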