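# Methods

## The screen

The screen operates on probe-level expression matrices in log2 units.
Linear-scale input is log2-transformed at ingestion, with nonpositive
(background-over-corrected) intensities set missing rather than
clamped. Missing values are carried as explicit NA throughout and
excluded pairwise from means, medians and tests, because genes can be
absent from individual platforms and the screen must tolerate that.

Preprocessing order is fixed: per-sample **median centering at probe
level**, then **probe-to-gene collapsing**. Median centering (subtract
each sample column's median; no rescaling of spread) removes per-array
loading offsets before probes are averaged; it is idempotent and makes
every downstream call invariant to per-sample constant shifts.
Collapsing takes the arithmetic mean of a gene's probes on the log2
scale — the geometric mean of intensities — which is the natural
average for multiplicative microarray signals. Whether to center
before or after collapsing is not determined by first principles; both
are available, centering-first is the default, and the two differ only
through probe-composition effects.

For gene *g* in one dataset, with ref(g) the mean (optionally median)
log2 level over ≥ 2 usable reference samples (normal livers by
default, adjacent non-tumorous liver as an alternative):

* per-tumor fold: 2^(x(g,s) − ref(g)); an overexpression **call** when
  the fold is **no less than** the fold threshold F (default 2; the
  threshold is inclusive, read literally);
* **frequency**: calls / tumors with a non-missing measurement (the
  denominator deliberately excludes unmeasured tumors);
* dataset fold: 2^(mean tumor log2 − ref(g)); under the default mean
  reference this is the usual mean-difference fold. The reference
  statistic is shared between calls and the dataset fold so the two
  never disagree about the baseline;
* p value: two-tailed pooled-variance (equal-variance) Student's t on
  log2 values, tumor vs reference.

**The dual gate.** A gene passes in a dataset when it is overexpressed
at ≥ F-fold in at least the frequency threshold (default 30%) of the
patient population — the fold threshold acts per patient, inside the
frequency. An optional stricter mode (`require_dataset_fold`)
additionally demands that the dataset-level mean fold clear F; it is
off by default because a gene strongly overexpressed in a third of
patients can easily have a mean fold below F while being exactly the
heterogeneous target the frequency gate exists to find.

**Cross-dataset consensus.** Per-dataset passes combine under one of
three rules: `all_present` (pass in every dataset where the gene is
measured), `majority_present` (default: pass in more than half of
them — datasets where the gene is missing must not veto), or `pooled`
(fold and frequency recomputed on all tumors pooled after per-dataset
median centering). The choice matters for borderline genes and is
surfaced in the exported per-rule flags.

No multiple-testing correction enters the gate; raw per-dataset p
values are reported, with a Benjamini–Hochberg column
(`min_p_bh`) added to the exported gene list purely as a convenience
for users who want an FDR-controlled view.

Degenerate comparisons are reported, not raised: when the pooled
variance is exactly zero the t test returns p = 1 (means equal) or
p = 0 (means differ) together with a `zero_variance` flag, so
noiseless synthetic inputs pass through the screen rather than
crashing it.

## qPCR relative quantification

Amplification efficiency is fixed at 2 (perfect doubling); no
standard-curve correction. Per observation, replicate Ct values are
averaged arithmetically on the cycle scale, ΔCt = mean Ct(target) −
mean Ct(β-actin), and the relative level is 2^(−ΔCt). A replicate
spread above 1.5 cycles triggers a logged QC warning but is not fatal.
Relative levels are invariant to plate-wide Ct offsets.

Folds between conditions are ratios of mean relative levels. The
reported s.d. is that of the per-observation condition-A levels each
divided by the fixed mean condition-B level — the single-number-per-
cell "fold ± s.d." convention; no error propagation from B is
attempted because the assayed convention reports one spread per cell.
The t test runs on −ΔCt values (log scale), not on ratios, since Ct
differences are far closer to normal.

The paired specimen survey calls a tumor up-regulated at a per-pair
fold 2^(−ΔCt_tumor + ΔCt_adjacent) of at least 2 by default. The
original up-regulation calls in such surveys are made by gel
inspection and have no numeric rule, so the threshold is an explicit
config parameter rather than a validated constant. Percentages are
rounded half-up to one decimal (46 of 53 → 86.8). Box statistics
(median, 25th/75th percentiles, extremes of −ΔCt per group) use linear
interpolation.

Knockdown QC passes only when the remaining mRNA fraction
(mean si level / mean negative-control level) is **strictly** below
the cutoff (default 0.60), and the proliferation hit rule is likewise
strict (<75% relative viability); both thresholds read "less than"
literally, while the screen's "no less than" gates are inclusive.

## Assay statistics

Relative viability is 100 × mean(treated OD450)/mean(vehicle OD450)
with the s.d. of per-replicate treated ratios and a pooled t on raw OD
values. Dose–response tables are emitted as per-concentration
viability summaries with per-dose t tests; no IC50 curve is fitted.
Apoptosis readouts are annexin-positive fractions in [0, 1], summarized
as mean ± s.d. percentages with pairwise t tests. Colony counts are
compared by pooled t; the colony-size inclusion rule (≥ 50 cells) is
applied upstream of counting and carried as metadata. Xenograft
volumes use the caliper ellipsoid approximation π/6 × major × minor²
with millimeters and mm³ fixed as units and integer days from
inoculation; arms must share measurement days, each aligned day gets a
pooled t, and the last day is the endpoint summary.

## Synthetic data

The expression generator draws per-gene log2 baselines μ_g ~
Normal(8, 1), shared across datasets, and emits probe values
μ_g + Δ·carrier + δ_s + ε with per-sample offsets δ_s ~ Normal(0, 0.5),
measurement noise ε ~ Normal(0, 0.5), and 1–3 probes per gene. Spike
carriers are Bernoulli(f) per tumor, drawn independently per dataset —
the inter-patient heterogeneity that makes the frequency gate
meaningful. Five percent of genes are dropped per dataset to emulate
platform gaps. The defaults (3 datasets, 500 genes, 10 spiked genes at
Δ = 1.5 log2 in f = 60% of tumors, 60 tumors / 20 normals per dataset)
are the regime the screen targets: heterogeneous overexpression whose
*mean* fold (2^0.9 ≈ 1.87) sits below the 2-fold line even though most
carriers individually exceed it. Baselines are quantized to a 2⁻²⁰
grid so that in the noiseless limit probe and replicate averages are
exact in floating point and spiked tumors sit at exactly 2^Δ-fold.

The qPCR generator places the β-actin reference at Ct 16 and targets 8
cycles above it, shifting condition A by −log2(true fold); replicate
noise is Normal(0, sd) per well. The cohort generator gives the
up-regulated fraction of pairs folds uniform in [2.5, 12] and the rest
folds in [0.7, 1.4], with small (sd 0.05) replicate noise that cannot
flip a call across the 2-fold line. Assay generators draw OD450,
annexin fractions, integer colony counts and caliper axes (aspect
ratio 1.5, axes recovered from lognormal-perturbed volumes on an
exponential growth curve) around known true effects.

What the generators do **not** emulate: platform-specific probe
affinity effects, batch structure beyond a scalar per-sample offset,
correlated gene modules, copy-number-driven expression, qPCR
efficiency drift, or flow-cytometry gating noise. Passing tests
therefore demonstrate that the statistics recover the effects the
model encodes under realistic noise magnitudes — not that the pipeline
is robust to every artifact of real microarray or assay data.

## Numerical choices and limitations

* Thresholds: screen gates inclusive (≥), QC/hit rules strict (<), per
  the quoted definitions they implement.
* Zero-variance comparisons: p = 1 (or 0) with a flag, pipeline-wide.
* Genes with fewer than two usable reference values in a dataset are
  treated as not evaluable there (`present = False`) by the
  collection-level screen; the single-gene API raises instead, so
  callers probing one gene get an explicit error.
* Percent rounding is decimal half-up; all other numbers are written
  at full float precision, which is what makes rerun outputs
  byte-identical.
* Problem sizes in the test suite and the acceptance script (ten
  replicate collections of 3 × 500 genes; twenty qPCR seeds per
  regime) are chosen to estimate recovery rates with comfortable
  margin while keeping a full run in the order of seconds.
* The GEO series-matrix reader parses local files only and leaves
  tumor/normal annotation to the caller; sample groupings for public
  HCC series are not encoded in the matrix files and must be supplied
  as metadata. Reproducing a published gene list from specific GEO
  accessions additionally depends on the consensus rule chosen, which
  is why the cross-dataset rule is explicit configuration rather than
  a constant.
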