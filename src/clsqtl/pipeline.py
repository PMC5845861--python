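"""End-to-end study orchestration: simulate -> quantify -> map -> report.

A RunConfig describes one in-silico study: the cross (population size,
marker map), the true genetic architecture per condition, the aging assay
(sampling days, growth model, OD noise), and the mapping parameters for the
individual-segregant (LOD) and bulk-segregant (G') scans.  run_study
executes every stage deterministically for a given seed, persists all
intermediates to the output directory, and returns a StudyReport comparing
detected QTL intervals with the configured truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cls_quant, qtl_bsa, qtl_isa, quantgen, synthetic_data
from .synthetic_data import GrowthModelParams, QTLTruth

logger = logging.getLogger("clsqtl")

__all__ = ["RunConfig", "StudyReport", "default_config", "load_config", "run_study", "load_tables"]

# default in-silico architecture: two major loci plus a minor one, each
# active only in a subset of conditions (a carbon-source dependent pattern),
# on a 488-spore haploid cross
_DEFAULT_QTLS = [
    {"marker": "VI_m003", "effects": {"SC": 0.6, "CR": 1.2, "Glu10": 0.0, "Gal": 0.0}},
    {"marker": "XV_m014", "effects": {"SC": 0.7, "CR": 0.0, "Glu10": 0.6, "Gal": 0.6}},
    {"marker": "XIV_m008", "effects": {"SC": 0.4, "CR": 0.0, "Glu10": 0.4, "Gal": 0.0}},
]
_DEFAULT_BASELINE = {"SC": 2.0, "CR": 5.0, "Glu10": 1.2, "Gal": 2.2}


@dataclass
class RunConfig:
    """Parameters of one simulated mapping study."""

    seed: int = 0
    outdir: str = "clsqtl_out"
    # cross
    n_segregants: int = 488
    n_chrom: int = 16
    markers_per_chrom: int = 19
    spacing_cm: float = 15.0
    bp_per_cm: float = 2700.0
    missing_rate: float = 0.0
    # truth
    qtls: list = field(default_factory=lambda: [dict(q) for q in _DEFAULT_QTLS])
    baseline: dict = field(default_factory=lambda: dict(_DEFAULT_BASELINE))
    env_sd: float = 0.4
    n_parent_replicates: int = 3
    # aging assay
    simulate_plate: bool = True
    aging_days: list = field(default_factory=lambda: list(range(1, 11)))
    outgrowth_hours: float = 48.0
    outgrowth_step_h: float = 0.5
    od_noise_sd: float = 0.0
    carrying_capacity: float = 1.0
    growth_mu: float = 0.4
    initial_od: float = 0.001
    # ISA
    n_perm: int = 1000
    alpha: float = 0.05
    lod_drop: float = 1.5
    # BSA
    bulk_size: int = 50
    window_kb: float = 100.0
    fdr_level: float = 0.05

    def validate(self) -> None:
        if self.n_segregants < 2:
            raise ValueError("n_segregants must be >= 2")
        if 2 * self.bulk_size > self.n_segregants:
            raise ValueError("2 * bulk_size exceeds n_segregants")
        if not 0 < self.alpha <= 1 or not 0 < self.fdr_level < 1:
            raise ValueError("alpha must be in (0,1], fdr_level in (0,1)")
        if len(self.aging_days) < 2:
            raise ValueError("need >= 2 aging days")
        if sorted(self.aging_days) != list(self.aging_days):
            raise ValueError("aging_days must be increasing")

    @property
    def conditions(self) -> list[str]:
        return list(self.baseline)

    def truth(self) -> QTLTruth:
        markers = [q["marker"] for q in self.qtls]
        effects = {
            cond: np.array([float(q["effects"].get(cond, 0.0)) for q in self.qtls])
            for cond in self.conditions
        }
        return QTLTruth(
            causal_markers=markers, effects=effects,
            baseline={c: float(v) for c, v in self.baseline.items()},
            env_sd=float(self.env_sd),
        )

    def growth_params(self) -> GrowthModelParams:
        return GrowthModelParams(
            carrying_capacity=self.carrying_capacity,
            mu=self.growth_mu,
            initial_od=self.initial_od,
        )


def default_config(**overrides) -> RunConfig:
    return dataclasses.replace(RunConfig(), **overrides)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file; unknown keys raise."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def load_tables(
    genotypes_path=None, marker_map_path=None, phenotypes_path=None, plate_path=None
):
    """Load and validate any subset of the study's input tables.

    Returns a dict with keys among (genotypes, marker_map, phenotypes,
    plate).  Validation failures raise io.TableFormatError with the file
    and line; cross-file consistency (every genotype marker in the map) is
    checked when both are given.
    """
    from . import io as _io

    out = {}
    if marker_map_path is not None:
        out["marker_map"] = _io.read_marker_map(marker_map_path)
        logger.info("marker map: %d markers, %d chromosomes",
                    len(out["marker_map"]), out["marker_map"]["chrom"].nunique())
    if genotypes_path is not None:
        out["genotypes"] = _io.read_genotypes(genotypes_path)
        logger.info("genotypes: %d segregants x %d markers", *out["genotypes"].shape)
        if "marker_map" in out:
            extra = set(out["genotypes"].columns) - set(out["marker_map"]["marker_id"])
            if extra:
                raise _io.TableFormatError(
                    f"genotype markers absent from map: {sorted(extra)[:5]}"
                )
    if phenotypes_path is not None:
        out["phenotypes"] = _io.read_phenotypes(phenotypes_path)
        logger.info("phenotypes: %d rows", len(out["phenotypes"]))
    if plate_path is not None:
        out["plate"] = _io.read_plate(plate_path)
        logger.info("plate: %d OD readings", len(out["plate"]))
    return out


@dataclass
class StudyReport:
    """All results of one run_study invocation (also persisted to outdir)."""

    config: RunConfig
    phenotypes: pd.DataFrame
    parent_phenotypes: pd.DataFrame
    isa: dict
    bsa: dict
    heritability: pd.DataFrame
    h2_narrow: dict
    transgression: pd.DataFrame
    correlations: pd.DataFrame
    condition_groups: dict
    normality: pd.DataFrame
    truth_comparison: pd.DataFrame
    outdir: Path


def _simulate_plate_tables(
    cfg: RunConfig,
    seg_truth: pd.DataFrame,
    parent_truth: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Turn true SI values into outgrowth OD time series for every well."""
    params = cfg.growth_params()
    grid = np.arange(0.0, cfg.outgrowth_hours + 1e-9, cfg.outgrowth_step_h)
    days = list(cfg.aging_days)
    frames = []
    for _, row in seg_truth.iterrows():
        sched = synthetic_data.viability_schedule_for_si(row["value"], days)
        frames.append(
            synthetic_data.simulate_outgrowth(
                sched, params, grid, noise_sd=cfg.od_noise_sd,
                seed=int(rng.integers(2**31)),
                strain_id=row["strain_id"], condition=row["condition"],
            )
        )
    for _, row in parent_truth.iterrows():
        sched = synthetic_data.viability_schedule_for_si(row["value"], days)
        frames.append(
            synthetic_data.simulate_outgrowth(
                sched, params, grid, noise_sd=cfg.od_noise_sd,
                seed=int(rng.integers(2**31)),
                strain_id=f"{row['strain_id']}_rep{int(row['replicate'])}",
                condition=row["condition"],
            )
        )
    return pd.concat(frames, ignore_index=True)


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_study(cfg: RunConfig, write_plate: bool = False) -> StudyReport:
    """Run the full in-silico study described by cfg.

    Stages: simulate the cross and phenotypes; render and quantify the
    aging assay (optional); ISA and BSA scans per condition; heritability,
    transgression, correlation and normality analyses; truth-vs-detected
    comparison.  Fully deterministic for a fixed config.  All intermediates
    are written under cfg.outdir.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = cfg.truth()
    master = np.random.default_rng(cfg.seed)

    t0 = _stage("simulate cross")
    marker_map = synthetic_data.make_marker_map(
        cfg.n_chrom, cfg.markers_per_chrom, cfg.spacing_cm, cfg.bp_per_cm
    )
    for mk in truth.causal_markers:
        if mk not in set(marker_map["marker_id"]):
            raise ValueError(f"configured causal marker {mk!r} not in map")
    cross = synthetic_data.simulate_cross(
        marker_map, cfg.n_segregants, seed=int(master.integers(2**31)),
        missing_rate=cfg.missing_rate,
    )
    cross.truth = truth
    synthetic_data.write_genotypes_tsv(cross, outdir / "genotypes.tsv")
    synthetic_data.write_marker_map_tsv(marker_map, outdir / "marker_map.tsv")
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "causal_markers": truth.causal_markers,
                "effects": {c: e.tolist() for c, e in truth.effects.items()},
                "baseline": truth.baseline,
                "env_sd": truth.env_sd,
            },
            fh,
        )
    logger.info("simulate cross done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("simulate phenotypes")
    si_floor = 0.5 * (cfg.aging_days[1] - cfg.aging_days[0])
    seg_truth, parent_truth = synthetic_data.simulate_phenotypes(
        cross, truth, n_parent_replicates=cfg.n_parent_replicates,
        seed=int(master.integers(2**31)), floor=si_floor,
    )

    if cfg.simulate_plate:
        t0 = _stage("simulate + quantify outgrowth")
        plate = _simulate_plate_tables(cfg, seg_truth, parent_truth, master)
        if write_plate:
            plate.to_csv(outdir / "plate.csv", index=False)
        quantified = cls_quant.quantify_plate(plate)
        is_parent = quantified["strain_id"].str.startswith("parent")
        phen = quantified[~is_parent].copy()
        parents = quantified[is_parent].copy()
        parts = parents["strain_id"].str.rsplit("_rep", n=1, expand=True)
        parents["strain_id"] = parts[0]
        parents["replicate"] = parts[1].astype(int)
        parents = parents.rename(columns={"si": "value"})[
            ["strain_id", "condition", "replicate", "value"]
        ]
        logger.info("quantified %d wells in %.1fs", len(quantified),
                    time.perf_counter() - t0)
    else:
        phen = seg_truth.rename(columns={"value": "si"}).copy()
        phen["mu"] = np.nan
        phen["td"] = np.nan
        phen["yield_biomass"] = np.nan
        parents = parent_truth.copy()
    phen.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    parents.to_csv(outdir / "parent_phenotypes.tsv", sep="\t", index=False)

    isa_results, bsa_results = {}, {}
    for cond in cfg.conditions:
        t0 = _stage(f"ISA scan [{cond}]")
        y = phen[phen["condition"] == cond].set_index("strain_id")["si"]
        res = qtl_isa.isa_scan(
            cross.genotypes, marker_map, y, n_perm=cfg.n_perm, alpha=cfg.alpha,
            lod_drop=cfg.lod_drop, seed=int(master.integers(2**31)),
        )
        isa_results[cond] = res
        scan_out = marker_map.merge(res.scan.reset_index(), on="marker_id")
        scan_out.to_csv(outdir / f"isa_{cond}.tsv", sep="\t", index=False)
        from . import io as _io

        _io.write_bed(res.intervals, outdir / f"isa_intervals_{cond}.bed")
        logger.info("ISA [%s]: threshold %.2f, %d interval(s), %.1fs",
                    cond, res.threshold, len(res.intervals), time.perf_counter() - t0)

        t0 = _stage(f"BSA scan [{cond}]")
        bres = qtl_bsa.bsa_scan(
            cross.genotypes, marker_map, y, bulk_size=cfg.bulk_size,
            window_kb=cfg.window_kb, fdr_level=cfg.fdr_level,
        )
        bsa_results[cond] = bres
        bscan_out = marker_map.merge(bres.scan.reset_index(), on="marker_id")
        bscan_out.to_csv(outdir / f"bsa_{cond}.tsv", sep="\t", index=False)
        _io.write_bed(bres.regions, outdir / f"bsa_regions_{cond}.bed")
        logger.info("BSA [%s]: %d region(s), %.1fs", cond, len(bres.regions),
                    time.perf_counter() - t0)

    t0 = _stage("quantitative genetics")
    herit_rows, trans_rows, norm_rows, h2_points = [], [], [], []
    for cond in cfg.conditions:
        seg = phen[phen["condition"] == cond]["si"]
        par = parents[parents["condition"] == cond]
        v_e = quantgen.pooled_parental_variance(par)
        est = quantgen.broad_sense_h2(seg, v_e)
        herit_rows.append(
            {"condition": cond, "v_p": est.v_p, "v_e": est.v_e, "v_g": est.v_g,
             "H2": est.h2_broad, "H2_raw": est.h2_broad_raw, "n": est.n_segregants}
        )
        pmeans = par.groupby("strain_id")["value"].mean()
        psd = float(par.groupby("strain_id")["value"].std(ddof=1).mean())
        trans = quantgen.transgression_summary(
            seg, (pmeans.min(), pmeans.max()), psd, k=2.0
        )
        trans_rows.append({"condition": cond, **trans})
        w, p = quantgen.normality_check(seg)
        norm_rows.append({"condition": cond, "shapiro_w": w, "p_value": p})
        h2_points.append(
            {"condition": cond, "midparent": float(pmeans.mean()),
             "offspring_mean": float(seg.mean())}
        )
    heritability = pd.DataFrame(herit_rows)
    transgression = pd.DataFrame(trans_rows)
    normality = pd.DataFrame(norm_rows)
    pts = pd.DataFrame(h2_points)
    if len(pts) >= 3 and pts["midparent"].nunique() > 1:
        h2_narrow = quantgen.narrow_sense_h2(pts)
    else:
        # the parent-offspring regression needs >= 3 trait x condition points
        h2_narrow = {"h2": float("nan"), "n": len(pts)}
    heritability.to_csv(outdir / "heritability.tsv", sep="\t", index=False)
    transgression.to_csv(outdir / "transgression.tsv", sep="\t", index=False)

    wide = phen.pivot_table(index="strain_id", columns="condition", values="si")
    R = quantgen.correlation_matrix(wide)
    R.to_csv(outdir / "condition_correlations.csv")
    if len(cfg.conditions) >= 2:
        Z, groups = quantgen.cluster_conditions(R)
        with open(outdir / "condition_dendrogram.nwk", "w") as fh:
            fh.write(quantgen.linkage_to_newick(Z, list(R.columns)) + "\n")
    else:
        groups = {cfg.conditions[0]: 1}
    logger.info("quantgen done in %.1fs", time.perf_counter() - t0)

    comparison = _compare_truth(cfg, truth, marker_map, isa_results, bsa_results)
    comparison.to_csv(outdir / "truth_vs_detected.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(
            {
                "n_segregants": cfg.n_segregants,
                "conditions": cfg.conditions,
                "isa_thresholds": {c: isa_results[c].threshold for c in cfg.conditions},
                "isa_n_intervals": {c: len(isa_results[c].intervals) for c in cfg.conditions},
                "bsa_n_regions": {c: len(bsa_results[c].regions) for c in cfg.conditions},
                "H2": {r["condition"]: r["H2"] for r in herit_rows},
                "h2_narrow": h2_narrow["h2"],
                "condition_groups": groups,
            },
            fh, indent=2,
        )

    return StudyReport(
        config=cfg, phenotypes=phen, parent_phenotypes=parents,
        isa=isa_results, bsa=bsa_results, heritability=heritability,
        h2_narrow=h2_narrow, transgression=transgression, correlations=R,
        condition_groups=groups, normality=normality,
        truth_comparison=comparison, outdir=outdir,
    )


def _compare_truth(cfg, truth, marker_map, isa_results, bsa_results) -> pd.DataFrame:
    """Per causal marker x condition: was the locus detected by each method?

    ISA detects when a support interval (extended by one marker spacing on
    each side) covers the causal position; BSA when a significant region
    lies within one smoothing window of it.
    """
    pos = marker_map.set_index("marker_id")
    slack_bp = cfg.spacing_cm * cfg.bp_per_cm
    rows = []
    for i, mk in enumerate(truth.causal_markers):
        chrom = pos.loc[mk, "chrom"]
        bp = int(pos.loc[mk, "pos_bp"])
        for cond in cfg.conditions:
            effect = float(truth.effects[cond][i])
            isa_hit = any(
                (iv["chrom"] == chrom)
                and iv["start_bp"] - slack_bp <= bp <= iv["end_bp"] + slack_bp
                for _, iv in isa_results[cond].intervals.iterrows()
            )
            bsa_hit = any(
                (rg["chrom"] == chrom)
                and rg["start_bp"] - cfg.window_kb * 1000 <= bp <= rg["end_bp"] + cfg.window_kb * 1000
                for _, rg in bsa_results[cond].regions.iterrows()
            )
            rows.append(
                {"marker": mk, "condition": cond, "true_effect": effect,
                 "isa_detected": isa_hit, "bsa_detected": bsa_hit}
            )
    return pd.DataFrame(rows)
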