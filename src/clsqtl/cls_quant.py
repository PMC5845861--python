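"""Chronological life span quantification from outgrowth kinetics.

A culture aged for d days is re-inoculated into fresh medium and its OD
followed over time.  Dead cells do not re-grow, so a culture with viable
fraction v reaches a fixed OD threshold later than a fully viable one: each
lost doubling of viable cells costs one doubling time of delay,

    v = 2 ** (-(t_cross - t_cross_ref) / Td).

Viabilities across aging days form a survival curve, and its area under the
curve (trapezoidal rule, day units) is the Survival Integral (SI) — the
quantitative CLS phenotype.  With daily sampling starting at day 1, a strain
alive at day 1 but dead by day 2 scores SI = 0.5, the assay floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GrowthFit",
    "SurvivalCurve",
    "fit_growth",
    "viability_from_shift",
    "build_survival_curve",
    "survival_integral",
    "quantify_plate",
]


@dataclass
class GrowthFit:
    """Growth parameters of one outgrowth curve.

    mu: maximum specific growth rate (1/h), the steepest log-OD slope;
    td: doubling time ln(2)/mu (h); t_cross: time to the OD threshold (h),
    NaN when the threshold is never reached; yield_biomass: max OD minus
    initial OD; grew: whether the threshold was crossed.
    """

    mu: float
    td: float
    t_cross: float
    yield_biomass: float
    grew: bool


@dataclass
class SurvivalCurve:
    """Per-aging-day viable fractions for one strain x condition."""

    aging_day: np.ndarray
    viability: np.ndarray
    reference_day: int

    def __post_init__(self) -> None:
        self.aging_day = np.asarray(self.aging_day, dtype=int)
        self.viability = np.asarray(self.viability, dtype=float)
        if len(self.aging_day) != len(self.viability):
            raise ValueError("aging_day and viability lengths differ")
        if np.any((self.viability < 0) | (self.viability > 1)):
            raise ValueError("viability outside [0, 1]")


def fit_growth(
    time_h: np.ndarray,
    od: np.ndarray,
    od_threshold: float,
    window: int = 5,
    blank_od: float = 0.0,
) -> GrowthFit:
    """Fit growth parameters to a single outgrowth curve.

    mu is the maximum specific growth rate: sliding windows of `window`
    points give local slopes of ln(OD - blank), each corrected for logistic
    saturation by dividing by (1 - OD/K) with K the plateau OD; the median
    over windows is mu.  (On a noise-free logistic curve every corrected
    window slope equals mu; the median makes the estimate robust to OD
    noise, whose influence is largest in the near-inoculum windows that a
    raw max-slope rule would chase.)  Windows overlapping the pre-growth
    noise floor — estimated from the early-timepoint OD increments — or the
    saturated plateau (> 90% of K) are excluded.

    t_cross is found by linear interpolation between the two samples
    bracketing the threshold.  A curve that never exceeds the threshold has
    grew = False and t_cross = NaN; the biomass yield is computed
    regardless.  blank_od is the cell-free medium signal (0 for already
    blank-subtracted readings).
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.ndim != 1 or len(t) < 5:
        raise ValueError("need at least 5 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if np.all(np.isnan(y)):
        raise ValueError("all OD values are NaN")
    if window < 3:
        raise ValueError("window must be >= 3")

    yield_biomass = float(np.nanmax(y) - y[0])

    corrected = np.clip(y - blank_od, 0.0, None)
    # light 3-point smoothing (ends kept) before slope estimation
    ys = np.convolve(corrected, np.ones(3) / 3.0, mode="same")
    ys[0], ys[-1] = corrected[0], corrected[-1]
    early = np.diff(corrected[: min(9, len(corrected))])
    noise = 1.4826 * np.median(np.abs(early - np.median(early))) / math.sqrt(2)
    k_hat = float(np.nanmax(ys))
    floor = ys[0] + max(5.0 * noise, 1e-9)
    mus = []
    for i in range(0, len(t) - window + 1):
        tw, yw = t[i : i + window], ys[i : i + window]
        if np.isnan(yw).any() or (yw <= floor).any() or yw.mean() > 0.9 * k_hat:
            continue
        slope = np.polyfit(tw, np.log(yw), 1)[0]
        mus.append(slope / (1.0 - yw.mean() / k_hat))
    mu = float(np.median(mus)) if mus else float("nan")
    td = math.log(2) / mu if (mu == mu and mu > 0) else float("nan")

    above = y >= od_threshold
    if not above.any():
        return GrowthFit(mu=mu, td=td, t_cross=float("nan"),
                         yield_biomass=yield_biomass, grew=False)
    j = int(np.argmax(above))
    if j == 0:
        t_cross = float(t[0])
    else:
        t0, t1 = t[j - 1], t[j]
        y0, y1 = y[j - 1], y[j]
        t_cross = float(t0 + (od_threshold - y0) / (y1 - y0) * (t1 - t0))
    return GrowthFit(mu=mu, td=td, t_cross=t_cross,
                     yield_biomass=yield_biomass, grew=True)


def viability_from_shift(t_cross: float, t_cross_ref: float, td: float) -> float:
    """Viable fraction from the threshold-crossing delay vs the reference.

    v = 2^(-(t_cross - t_cross_ref)/td), capped at 1 when the sample crosses
    earlier than the reference (negative shifts arise from noise).  A missing
    crossing (NaN t_cross) means the culture never grew: v = 0.
    """
    if td is None or not td > 0:
        raise ValueError("doubling time must be positive")
    if t_cross is None or np.isnan(t_cross):
        return 0.0
    return float(min(1.0, 2.0 ** (-(t_cross - t_cross_ref) / td)))


def build_survival_curve(fits: Mapping[int, GrowthFit]) -> SurvivalCurve:
    """Convert per-aging-day growth fits into a survival curve.

    The earliest sampled day is the reference, defined to be 100% viable; its
    doubling time is reused for every later day (outgrowth of dying cultures
    gives unreliable slope estimates).  Days at or after the first
    non-growing day are forced to viability 0 — dead cultures do not regrow,
    so any later apparent growth is treated as an artifact (censoring).
    """
    if not fits:
        raise ValueError("no growth fits supplied")
    days = sorted(fits)
    ref = fits[days[0]]
    if not ref.grew or np.isnan(ref.t_cross):
        raise ValueError("no viable reference: the earliest aging day did not grow")
    viab = []
    dead = False
    for day in days:
        fit = fits[day]
        if dead or not fit.grew:
            dead = dead or not fit.grew
            viab.append(0.0)
            continue
        viab.append(viability_from_shift(fit.t_cross, ref.t_cross, ref.td))
    viab[0] = 1.0
    return SurvivalCurve(aging_day=np.asarray(days), viability=np.asarray(viab),
                         reference_day=days[0])


def survival_integral(curve: SurvivalCurve) -> float:
    """Survival Integral: trapezoidal area of viability over aging days (day units)."""
    if len(curve.aging_day) < 2:
        raise ValueError("survival integral needs at least two aging days")
    return float(np.trapezoid(curve.viability, curve.aging_day))


def _default_threshold(ref_od: np.ndarray) -> float:
    """Midpoint of the reference curve's initial and plateau OD."""
    return float((ref_od[0] + np.nanmax(ref_od)) / 2.0)


def quantify_plate(
    plate: pd.DataFrame,
    od_threshold: float | None = None,
    window: int = 5,
) -> pd.DataFrame:
    """Quantify a long-format plate table into per-strain phenotypes.

    plate columns: strain_id, condition, aging_day, time_h, od.  For each
    strain x condition the day-1 (earliest) curve serves as the fully viable
    reference; its fitted mu, td and yield are reported together with the
    Survival Integral.  When od_threshold is None it defaults per strain x
    condition to the midpoint of the reference curve's initial and plateau OD.

    Returns a phenotype table (strain_id, condition, si, mu, td, yield_biomass).
    """
    required = {"strain_id", "condition", "aging_day", "time_h", "od"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    rows = []
    for (strain, cond), grp in plate.groupby(["strain_id", "condition"], sort=False):
        days = sorted(grp["aging_day"].unique())
        ref_grp = grp[grp["aging_day"] == days[0]].sort_values("time_h")
        thr = od_threshold
        if thr is None:
            thr = _default_threshold(ref_grp["od"].to_numpy())
        fits: dict[int, GrowthFit] = {}
        for day in days:
            g = grp[grp["aging_day"] == day].sort_values("time_h")
            fits[int(day)] = fit_growth(
                g["time_h"].to_numpy(), g["od"].to_numpy(), od_threshold=thr,
                window=window,
            )
        curve = build_survival_curve(fits)
        si = survival_integral(curve)
        ref = fits[int(days[0])]
        rows.append(
            {
                "strain_id": strain,
                "condition": cond,
                "si": si,
                "mu": ref.mu,
                "td": ref.td,
                "yield_biomass": ref.yield_biomass,
            }
        )
    return pd.DataFrame(rows)
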