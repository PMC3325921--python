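# Methods

## Study design modelled

The pipeline targets a single-dose in vivo screen: ten model compounds —
seven genotoxins (DMN, DEN, ENU, DPN, AAT, DBP, DMBA; DEN run as two
independent replicate conditions) and three non-genotoxins (EtOH, PB,
DEHP) — profiled in mouse liver at 4 h, 20 h, 2 weeks and 4 weeks after
administration. Each treatment cell (chemical replicate × timepoint) is one
pooled RNA sample; solvent controls (corn oil or saline, matched to each
chemical's vehicle) are individual animals. The number of control animals
per solvent × timepoint is not fixed by the design description; the default
is 8, configurable via `StudyDesign.n_control_animals`.

## Normalization and regulation calls

Per-chip normalization scales every sample to median intensity 1; per-gene
normalization divides each value by the median of its matched controls
(same solvent and timepoint). Treated/control ratios use the mean of
matched controls as denominator and are invariant to the per-gene step
(the matched-control divisor cancels), so the call matrix is computed on
per-chip-normalized data.

Calls follow a step-wise, intensity-dependent criterion. The published
thresholds for this family of studies are not available in the primary
record, so the defaults are a two-band rule expressing the same principle
(stricter where the signal is dim): matched-control intensity below 0.5 on
the per-chip scale requires ratio ≥ 3 (up) or ≤ 1/3 (down); above 0.5,
ratio ≥ 2 or ≤ 0.5. The band is chosen by the *control-side* intensity so a
cell's ratio never influences its own threshold. Criteria are plain data
(`CallCriteria`) and fully overridable from YAML, so laboratory-specific
step tables can be dropped in.

Two readings of the original procedure could not be settled from the
primary record and are implemented as stated assumptions: ratios are taken
against per-(solvent, timepoint) controls rather than one pooled control,
and the intensity band uses the matched-control mean.

## Parameters, bin tables and the total

The eight per-gene parameters are defined in the README. Conventions worth
noting:

* Specificity and reverse change use unweighted cell counts; the
  replication weight (0.5 per duplicated-chemical cell) applies only to the
  positive-condition count. Both printed fractional specificities and the
  integer reverse-change values in the reference panel are consistent with
  this reading.
* The t test is Welch's (unequal variances), two-sided, on normalized
  per-condition treatment intensities across all timepoints, GTX vs NGTX,
  with duplicated-chemical conditions entering at weight 1. A pooled-variance
  variant is available (`equal_var=True`). If both groups are degenerate
  (zero variance), the p-value is 1 when the means agree and 0 otherwise.
  No multiple-testing correction is applied: the p-value enters the score
  only through its 0–5 bin.
* Basal is log₁₀ of the mean control intensity (the alternative, mean of
  per-animal log₁₀ values, is behind `basal_log_of_mean=False`). CV% uses
  the sample SD (ddof = 1). Both are computed on the per-chip-normalized
  scale over *all* control animals; per-gene normalization would pin the
  control mean near 1 and destroy the dynamic range these parameters carry
  (reference-panel basal values span 0.92–3.16, i.e. intensities ≈ 8–1400
  on a median-1 chip).
* Genes with no up-call anywhere, or none in GTX conditions (average ratio
  undefined), are excluded from scoring and reported under
  `.attrs["excluded"]` — never silently scored 0.

The exact bin boundaries behind the published component scores are not in
the primary record. The shipped defaults are therefore *inferred* from the
20-row reference panel by constraint satisfaction: for each parameter the
(value, score) pairs must be monotone; interval boundaries are placed at
midpoints between the closest observed values with different scores, and
the first/last intervals extend to the parameter's domain bounds. This
reproduces all 160 printed assignments by construction and is the least
committal monotone completion; score levels unobserved in the panel
(e.g. CV score 1) simply have empty intervals. Alternative tables load from
YAML.

Ranking sorts by total descending with ties broken by gene id ascending —
the deterministic rule that reproduces the published panel order exactly
(the published tie groups are ordered by probe id).

## Clustering

Profiles are log₂ treated/control ratios (ratios clipped at 1e−6) of the
top-N ranked genes (N = 50 by default, clamped with a warning when fewer
genes were scored). Linkage is UPGMA (average linkage): inter-cluster
distance is the unweighted mean of cross-pair distances, which guarantees
monotone merge heights; the implementation delegates to
`scipy.cluster.hierarchy` and is verified in tests against a brute-force
oracle on small instances. Trees export to Newick via scikit-bio.

Genes are compared with the uncentered-Pearson correlation distance
1 − ⟨x,y⟩/(‖x‖‖y‖), the historical default of the Eisen clustering tools,
which groups genes by the *shape* of their induction profile. Conditions
default to Euclidean distance instead: a non-responding condition's profile
is a near-zero vector whose direction is pure noise, so correlation-type
distances between such profiles are uninformative and the expected
GTX/NGTX root bipartition becomes unstable — measured over 20 simulation
seeds, the root split separated the classes 20/20 under Euclidean and 0/20
under uncentered correlation. Both metrics are selectable per axis
(`gene_metric=`, `condition_metric=`).

## Synthetic data

The generator works on a multiplicative (log-normal) intensity scale.
Per-gene baselines are 10^Normal(2.0, 0.5) (median intensity ~100 with a
realistic spread of quiet and bright genes). Control animals multiply the
baseline by exp Normal(0, σ) with σ = √log(1 + cv²), so the natural-scale
CV among control animals matches the target; the default CV of 30% sits in
the middle of the 12–107% range the reference panel reports for real
control animals. A pooled treatment sample is the matched-control mean
times an induction factor times exp Normal(0, noise_sd); noise_sd defaults
to 0.15, a modest pooled-sample measurement noise. The induction factor is
2^Normal(3.0, 0.25) — a mean 8-fold induction — for responsive genes in GTX
cells (and for confounder genes in NGTX cells), 1 elsewhere; five spiked
responsive genes is the default. Centering the pooled sample on the
matched-control mean reflects the averaging effect of pooling several
animals and makes the zero-effect case exact (all ratios 1 when effects and
noise are off).

What the simulator does **not** emulate: probe-level effects and
cross-hybridization, correlated gene modules, timepoint-dependent response
kinetics, batch or array-lot effects, and genuinely biology-driven
down-regulation. Passing recovery tests therefore shows the scoring
machinery behaves correctly under the design's statistical structure, not
that the defaults are optimal for any particular real dataset.

## Problem sizes and numerical choices

The simulation-based checks run the full design (10,000 genes, 44 treatment
conditions, 64 control samples) over 20 seeds — about 1.5 s per seed — and
smaller 300–2,000-gene designs elsewhere; these sizes give stable pass/fail
behaviour for the stochastic properties while keeping the suite quick.
Other numerics: ratios are exact quotients (no pseudocounts; a zero control
mean raises), distance matrices are symmetrized to machine precision before
linkage, and UPGMA tie-breaks follow the deterministic merge order of the
underlying implementation (ties are measure-zero for continuous inputs).

## Known limitations

* The default call criteria and bin tables are reconstructions constrained
  by, and consistent with, the published panel — not the original
  supplementary tables. Both are injectable should the originals be
  available.
* The p-value parameter treats pooled per-condition samples as independent
  observations, as the original analysis appears to; it is a ranking
  heuristic, not an inferential test.
* Scoring only considers up-regulation as the positive signal (reverse
  change aside), mirroring the scheme it implements; a down-regulation
  biomarker would need a mirrored scoring pass.
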