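# Methods

## Quantification model

Each metabolite in the standards library carries a quantification mode.

**Stable isotope dilution.** The extraction mix spikes a ¹³C-labeled copy of
the metabolite into every sample (biological samples and pool-dilution
injections alike). Because the labeled standard comes from labeled yeast
extract, its concentration is unknown a priori and is estimated from the
external standard pools: at each usable dilution level,

    estimate(level) = C_nominal(level) * area_labeled / area_unlabeled,

and the per-standard estimate is the **median** over usable levels (robust to
one saturated or censored level; the spread is reported as a CV). A level is
usable when both areas are present and the nominal concentration is at or
above the metabolite's LOD. Biological samples are then quantified by

    C(s, m) = area_unlabeled(s, m) / area_labeled(s, IS(m)) * [IS(m)].

Both species co-elute and share the sample's ion-suppression factor, which
cancels in the ratio — the path is matrix-robust by construction. The labeled
and unlabeled forms are assumed to have equal response factors (no
isotope-response correction), which the ratio arithmetic presumes.

**External calibration.** Metabolites without a labeled twin are normalized
to an RT-paired labeled amino acid standard, y = area_analyte /
area_normalizer, in pool dilutions and biological samples alike. An
unweighted ordinary-least-squares line y = slope·C + intercept is fitted over
the usable levels (≥ 3 required) and must reach **r² ≥ 0.95** (configurable)
to pass QC; failing metabolites are excluded from every downstream table, and
the exclusion is recorded rather than silently dropped. Sample concentrations
come from inverting the line; results at or below zero, or below the LOD, are
censored as below-LOD. Because the normalizer only roughly co-elutes with the
analyte, normalization corrects recovery but not the analyte's own
matrix-dependent ionization: these values are semi-quantitative, and the
package treats that as a property to verify, not a footnote (see the
generator below).

**Censoring and filtering.** Missing peaks and below-LOD results carry status
flags, never numbers; downstream statistics use pairwise-complete quantified
values. An optional LOD/2 imputation accessor exists for sensitivity
analyses and is off by default. A metabolite is kept only if quantified in at
least 80% (configurable) of the samples of at least one biological group.
Concentrations are reported in original-fluid units on the convention that
the 5 µL sample + 45 µL extraction-mix dilution is identical for standards
and samples and therefore cancels.

**LOD.** Library-provided LODs take precedence. Otherwise the LOD is the
lowest dilution level whose area exceeds blank mean + k·SD (k = 3 default) in
every replicate injection — a documented substitute for an unpublished
procedure.

## LDH assay

Activity is read from the linear loss of NADH absorbance at 340 nm: the OLS
slope of A340 vs time (per minute, magnitude), optionally over an early-time
window since no linear-range rule is published. A standard curve of slope vs
known activity is fitted over six points (a blank and five activities from
0.005838 to 0.0467 units) and inverted with dilution correction (TIF is read
at 1:10). The TIF-purity statistic is total TIF activity
(activity/µL × isolated volume) over the whole-tumor total, where the lysate
measured at 10 mg/mL resuspension is scaled by tumor mass.

## Statistical layer

Concentration matrices are auto-scaled per metabolite (mean 0, sample SD 1;
metabolites with censored cells in the subset, or zero variance, are dropped
and recorded). PCA and agglomerative Ward clustering (squared-Euclidean
Ward.D2 variant, deterministic for a fixed input order) run on the scaled
matrix. Two-group screening applies Shapiro–Wilk (α = 0.05 per group, both
must pass) to choose between Welch's t test and the two-sided
Wilcoxon–Mann–Whitney test per metabolite, with Benjamini–Hochberg FDR across
tested metabolites; fold changes are ratios of arithmetic group means.
Volcano selection requires |fold change| ≥ 1.5 and significance below the
threshold in the chosen mode (raw p < 0.01 or BH q < 0.1 conventions both
supported). The ratio regression averages per-animal TIF/plasma ratios within
each condition and fits OLS of one condition on the other, with a log-space
switch; the axis orientation is a parameter because a near-identity fit is
orientation-ambiguous.

## The synthetic study generator

The generator emulates the instrument-facing outputs of the assay from known
ground truth so recovery is checkable cell by cell:

    area(s, j) = response_factor(j) * amount(s, j) * matrix(s, j) * eps

with multiplicative lognormal noise (unit mean, configurable CV — LC/MS areas
are strictly positive and scale-dependent, so noise is never additive), and
censoring to missing whenever the noiseless effective concentration falls
below the metabolite's true LOD.

The matrix model has three layers, each tied to a claim the pipeline must
support:

* a **per-sample factor** (lognormal gSD 1.6 for plasma/TIF by default,
  uniform or fixed available) shared by co-eluting species — what isotope
  dilution cancels;
* a **per-metabolite susceptibility** per matrix class (lognormal gSD 1.6,
  shared by the labeled twin, constant across samples of a class) — without
  it, equal spikes in water vs plasma would differ by a single shared number
  instead of the wide two-signed per-standard spread the matrix-effect
  experiment shows;
* an **RT-pairing fidelity** w (default 0.5): a normalizer amino acid sees
  the sample factor raised to w times an independent residual. At w = 1 the
  factor would cancel in normalized areas and external calibration would be
  as matrix-robust as isotope dilution, contradicting its semi-quantitative
  character; at w = 0 every sample's whole external panel would swing
  coherently by the full matrix spread, which real RT-paired normalization
  does not leave. The default models "roughly the same retention time" as
  sharing about half of the log-ionization variation.

Biological truth: per-metabolite baselines lognormal (median 20 µM, gSD 4,
spanning nM–mM as plasma metabolomes do), within-group biological variation
lognormal (gSD 1.3), group effects on a log2 scale applied to all metabolites
or a random signed subset. The library defaults mirror the real assay: 149
metabolites, 7 pools, 8 stock levels from ~5 mM to ~1 µM (with ±15%
per-metabolite weighing jitter), ~47% on the isotope-dilution path, LODs
log-uniform on 0.1–3 µM, 17 normalizer amino acids (the size of a standard
labeled amino-acid mix), internal-standard concentrations lognormal around
40 µM. LDH traces are linear A340 decays (gain 4 ΔA340/min per unit, 5 min,
61 points) with additive read noise scaled to each trace's absorbance span,
so relative slope uncertainty is activity-independent; a blank stays flat.
All draws descend from one seed through named spawn streams, so cohort,
dilution series and matrix injections are mutually consistent and
byte-reproducible.

What the generator does **not** emulate: chromatographic peak shapes and
integration, isotopologue fine structure and purity, injection-order drift,
carryover, metabolite–metabolite correlation structure, and heavy-tailed
biological outliers. Passing tests therefore demonstrate the arithmetic and
statistical machinery under the stated noise model — not performance on real
chromatograms.

## Numerical and design choices

* OLS everywhere a line is fitted (scipy linregress); external curves are
  unweighted with a free intercept — the QC gate is a level, not a weighting
  scheme. A constant-response curve is reported as slope 0, r² 0 (fails QC)
  rather than a numerical accident.
* Ward heights follow the squared-Euclidean (Ward.D2-equivalent) update;
  merge order is deterministic given the input row order, verified against a
  naive Lance–Williams recursion on small instances.
* BH q-values via statsmodels, cross-checked against a brute-force step-up.
* The matrix-effect statistic is log2(mean water area / mean plasma area)
  per standard, with a direction switch since either orientation is
  defensible.
* The per-sample external-calibration error is summarized as the geometric
  mean of estimated/true (mean of logs): errors are multiplicative, and the
  geometric mean is the scale-appropriate per-sample summary.
* Degenerate inputs fail loudly and specifically: duplicated IDs, negative
  areas, non-monotone dilution series, missing columns, all-constant
  matrices, k larger than the sample count, uninformative standard curves.

## Problem sizes

The bundled experiments use a 149-metabolite library with 25-sample cohorts
for recovery, 20-sample two-group cohorts for separation, 100 randomized
12-metabolite libraries for the QC-gate leak check, and 5,000 null
metabolites (n = 10 vs 10) for type-I-error calibration — sizes chosen so
every property is measured on the same order as the real study design while
a full run stays interactive. Under these conditions the isotope-dilution
path recovers truth with ~5% median error, external calibration shows
per-sample bias tracking the matrix factor (Spearman ρ mostly 0.8–0.97
across seeds), and the two-group Ward cut recovers the partition perfectly
in most seeds (silhouette ≈ 0.5); exact values for a given seed are written
by `scripts/acceptance.py`.

## Known limitations

External-calibration accuracy in the simulation depends directly on the
assumed RT-pairing fidelity, which is not identifiable from the outputs the
package consumes; it is a model input, not an estimate. The LOD rule and the
detection-filter threshold stand in for unpublished procedures and are
configurable. The ratio-regression comparison against the published fit
requires the original supplementary table, which is not redistributable;
without it the regression is validated only on closed-form and synthetic
oracles.
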