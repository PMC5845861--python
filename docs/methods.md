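# Methods

This note records the models, estimators, parameter choices and known
limitations of `clsqtl`, in the order data flows through the package.

## Simulated cross (synthetic_data)

**Genome and meiosis.** The default map emulates the dimensions of the
*S. cerevisiae* genome: 16 chromosomes × 19 evenly spaced markers at 15 cM
intervals, converted to physical coordinates at 2700 bp/cM — about 12 Mb
and 4300 cM in total, with ~40.5 kb between adjacent markers and ~300
markers genome-wide, the density of a moderate RAD-seq panel. Haploid
segregants are drawn chromosome by chromosome: the first marker's allele is
Bernoulli(½), and each subsequent marker switches parent of origin with
Haldane's recombination fraction r = ½(1 − e^(−2d/100)) for the inter-marker
distance d in cM. Haldane's function assumes no crossover interference —
the simplest standard meiosis model, adequate at this marker spacing, and
the only map-function assumption anywhere in the package. Alleles are coded
0 (parent 1) / 1 (parent 2); missing genotypes can be injected at a
configurable rate (default 0) to exercise downstream complete-case
handling.

**Phenotypes.** Purely additive: segregant value = baseline + Σ effectᵢ ·
alleleᵢ + N(0, env_sd), per condition. Parent 1 is the all-0 genotype,
parent 2 the all-1 genotype; parental replicates share the same
environmental noise. There is no dominance (the cross is haploid) and no
epistasis in the generator, so narrow- and broad-sense heritability
coincide in truth: V_A = Σ effect²/4 for the Bernoulli(½) alleles, and the
parent–offspring regression slope is 1 by construction. Effects are in SI
day units. The default study architecture (pipeline) places three loci with
condition-dependent effects — one active under calorie restriction and
standard glucose, one under the richer carbon conditions, one minor — so
that the condition-specific detection pattern of diet-dependent QTLs can be
reproduced in silico.

**Outgrowth curves.** A well's OD follows logistic growth from an effective
viable inoculum N₀·v (carrying capacity 1.0 OD, μ = 0.4 h⁻¹ i.e. T_d ≈
1.73 h, total inoculum 0.001 OD), plus a constant (1 − v)·N₀ of dead-cell
signal, so v = 0 gives a flat trace at the inoculum OD. Because N₀ ≪ K,
halving v delays the threshold crossing by one doubling time to within
0.1%, which is the invariant the quantifier inverts. Gaussian OD noise
(default 0) is added per reading and clipped at 0. Lag phases are not
modeled explicitly; a reduced effective inoculum is observationally
equivalent for the time-shift principle. To generate a well series from a
target SI, viability schedules come from the single-parameter family
v(d) = e^(−λ(d−d₁)) with λ solved by bisection so the trapezoidal area
equals the target; targets are clipped into the representable range (half
the first sampling interval up to the full day span).

## CLS quantification (cls_quant)

Aging days default to 1, 2, …, 10 with day 1 as the fully viable reference
(viability ≡ 1 there), consistent with an SI floor of 0.5 day. The OD
threshold defaults per strain × condition to the midpoint of the reference
curve's initial and plateau OD — robust to plateau differences between
strains. Threshold crossings are linearly interpolated between bracketing
samples.

**Growth rate.** μ is estimated on the day-1 (reference) outgrowth only and
its doubling time reused for all aging days of the same strain × condition:
late outgrowths of dying cultures start from tiny viable inocula and give
unreliable slopes. The estimator takes sliding 5-point windows of
ln(OD − blank), corrects each window's slope for logistic saturation by
dividing by (1 − OD/K̂) with K̂ the observed plateau, and reports the median
over windows. On a noise-free logistic curve every corrected window slope
equals μ, so the median matches the classical "maximum log-slope" value to
<0.5%; under OD noise the max-over-windows rule chases inflated slopes in
the near-inoculum windows (errors up to ~70% at noise SD 0.01) while the
corrected median stays within ~7%. Windows touching the pre-growth noise
floor (5× a robust noise estimate from early OD increments) or the plateau
(>90% of K̂) are excluded; OD is lightly smoothed (3-point moving mean)
first.

**Survival curve and SI.** v = 2^(−Δt/T_d), capped at 1 (negative shifts
arise from noise). Once a day fails to reach the threshold, that day and
all later days are forced to v = 0: dead cultures do not regrow, so later
apparent growth is treated as contamination/condensation artifact
(censoring). SI is the trapezoid of v over aging days, in day units; the
floor for any strain alive at the first timepoint is half the first
sampling interval (0.5 day at daily sampling).

Round-trip accuracy (simulate → quantify): SI within 5% noise-free, within
15% at OD noise SD 0.01 (both tested).

## ISA (qtl_isa)

Marker regression, not interval mapping: markers are dense relative to QTL
effects, so hidden-genotype likelihood maximization buys little. Per
marker, complete cases only; LOD = (n/2)·log10(RSS₀/RSS₁) with RSS₀ from
the grand mean and RSS₁ from per-allele-group means; equivalently
−(n/2)·log10(1 − r²). Monomorphic markers get LOD 0; markers with an allele
group smaller than 2 are skipped and recorded; RSS₁ = 0 is reported as a
flagged infinite LOD and excluded from threshold quantiles. Significance
uses the genome-wide max-LOD permutation null (default 1000 permutations,
α = 0.05, nearest-rank quantile; α = 1 degenerates to the minimum of the
permuted maxima). Support intervals: each contiguous run of markers at or
above the threshold yields one peak, extended to the contiguous markers
within 1.5 LOD of it. Measured over 200 null crosses, the fraction of scans
with any significant marker is ~0.05 — the nominal level.

## BSA (qtl_bsa)

Bulks are the 50 highest- and 50 lowest-SI segregants (deterministic ties:
sort by value then id; the low bulk takes the head, the high bulk the tail,
so the bulks can never overlap). Allele counting is exact from the known
segregant genotypes — the study design genotypes every segregant
individually, so no sequencing-depth model is needed; missing alleles drop
out of both counts. G is the standard 2×2 likelihood-ratio statistic with
margin-based expectations; empty cells contribute zero.

**Smoothing.** G′ is the tricube-weighted mean of G over markers within
±window on the same chromosome. The window default is 100 kb: at the
default marker spacing (~40.5 kb) this pools the focal marker with ~2
neighbours per side, the few-marker pooling the G′ approach relies on; a
±25 kb window would contain no neighbour at all and leave G unsmoothed.
The window is exposed in configuration for denser maps.

**Significance.** ln G′ is modeled as Normal with location the median and
scale 1.4826 × MAD across all markers — location/scale estimators that a
minority of true-QTL markers cannot inflate — giving right-tail p-values
and Benjamini–Hochberg q-values (threshold = smallest G′ with q ≤ FDR
level, default 0.05). A caveat measured on pure null crosses: the lower
tail of ln G′ is heavy (markers whose bulk counts happen to balance), which
inflates the symmetric MAD, so the test is conservative — in 100 simulated
null crosses it makes essentially no calls, and its discoveries concentrate
tightly around strong loci. Peak location, which is what interval reporting
uses, is unaffected: the G′ maximum lands within one window of a
30%-variance QTL in ≥90% of crosses (measured 100%). Callers who need more
aggressive discovery can lower the FDR level or substitute a median/mode
null fit, at the cost of calling linked flanking markers much further out.

Regions are maximal runs of contiguous significant markers (a single
non-significant marker splits a run); gene lookup over a (gene, chrom,
start, end) table — or a GFF3 file — uses any-overlap with inclusive
1-based coordinates, so a gene abutting the region boundary is included.
BED exports are 0-based half-open.

## Quantitative genetics (quantgen)

V_E is the df-weighted pooled within-parent replicate variance; the exact
estimator behind the published H² values is not restated anywhere public,
so this package's estimator is declared, not inferred. H² = (V_P − V_E)/V_P
is clipped into [0, 1] with the raw value retained for diagnostics. h² is
the OLS slope of segregant-population mean on midparent across all trait ×
condition points (midparent rather than single-parent values; the choice is
symmetric in the parents and standard). Display rescalings of individual
conditions, as sometimes used for chart clarity, apply a common factor to
both axes of a point and therefore leave a slope-1 relation intact; they
are never applied to regression inputs here. Transgressive segregants are
those beyond the extreme parent mean by k parental SDs (default k = 2; no
published rule exists). Correlations are complete-case Pearson with
Fisher-z intervals; condition clustering is agglomerative with average
linkage on distance 1 − R, deterministic, with Newick export of the
dendrogram. Normality uses Shapiro–Wilk (scipy), valid for 3 ≤ n ≤ 5000.

## Calibration studies (calibration)

Two simulation studies measure the scans' operating characteristics at the
study scale (488 segregants, ~300 markers): (1) ISA genome-wide type-I
error over 200 null crosses with per-cross 1000-permutation thresholds;
(2) BSA realized false-discovery proportion over 200 crosses, half null and
half with one randomly placed QTL explaining 30% of variance, counting a
q ≤ 0.05 marker false when it lies beyond one full smoothing-window span
(2 × window_kb) of the causal marker — the distance beyond which a tricube
window centred anywhere near the locus carries no weight. Markers between
one half-width and one full span are genuinely linked (up to ~60 cM at
yeast map density) and are therefore not counted as false discoveries; in
200 crosses no truly unlinked marker (different chromosome, or any marker
of a null cross) was ever called.

## Problem sizes and determinism

Defaults were chosen so a full test suite runs in well under a minute and
the calibration studies in seconds on one CPU: the permutation engine
evaluates all markers × permutations as two matrix products on the
complete-case sufficient statistics. All randomness flows from a single
integer seed through `numpy.random.default_rng`; identical seeds give
byte-identical outputs, including every file `run_study` persists.

## Known limitations

* No crossover interference, no segregation distortion, no genotyping
  error model (missingness only).
* The additive generator cannot produce dominance or epistatic variance,
  so H²–h² gaps seen in real crosses have no synthetic counterpart; tests
  validate estimator recovery, not the biology of non-additive variance.
* The outgrowth model has no lag phase, no diauxic shift and no plate
  position effects; real plate data will need the OD threshold and window
  parameters revisited.
* The BSA null fit is deliberately conservative (see above); its FDR
  control is with respect to unlinked markers, and the sparse-map setting
  widens called regions relative to dense sequencing-based BSA.
* Bulk counting is exact; a binomial read-sampling layer for
  sequencing-style BSA is out of scope.
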