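# Methods

## The model

The pipeline analyses a 2 × 2 design: iris side (dorsal `d`, ventral `v`)
by timepoint (4 and 8 days post-lentectomy), one bulk RNA-seq library per
cell.  All inference is threshold-based rather than model-based: no count
distribution is fitted to the data.  The stages are

1. **Quantification.** `RPKM(t) = 1e9 · C(t) / (N · L(t))` per library,
   where `C` is the unique-read count, `N` the library's total mapped
   reads and `L` the transcript length in bp.  Transcripts without reads
   are retained at RPKM 0; the identity *RPKM = 0 ⇔ C = 0* is relied on
   later by the exclusivity rule, so quantification never drops or
   imputes.  Whether `N` counts all mapped reads or only unique ones is a
   caller decision — the interface takes `N` as given, and the two
   conventions only rescale all RPKM in a library by a common factor.

2. **Detection cutoffs.** Because no genome is available, background
   cannot be read off intergenic coverage.  Instead the threshold comes
   from an independent microarray of the same tissue: spots that are
   structurally valid (valid flag, circularity > 80 %, within-spot
   intensity CV below `cv_max`) yet signal-free (snr < 1; spots with
   signal have snr > 3) mark transcripts present on the array but not
   detectably expressed.  After deduplicating spot→transcript mappings,
   the per-library cutoff is the arithmetic mean RPKM of that null set;
   "expressed" means strictly above it.  The within-spot "very small"
   intensity variation is not quantified by the source procedure; it is
   exposed as `cv_max` (default 0.2, dimensionless CV) and documented as
   a free parameter.  A median estimator is available behind a flag for
   robustness studies, but the default follows the prescribed average.
   Conditions without null coverage raise an error; no threshold is
   invented.

3. **Gradient classification.** Per-day ratios `log2(d/v)` are undefined
   (reported `NA`) when either side is 0.  The combined ranking statistic
   is `log2((d4 + d8) / (v4 + v8))` — the sum-ratio form, which stays
   defined when a single day is zero on one side.  This definition was
   validated against all 100 rows of the two published reference tables
   before being adopted: every defined printed value is reproduced within
   ±0.015 (inputs carry 3-decimal rounding) and every printed
   undefined-value placeholder maps to an undefined recomputation,
   whereas the alternative mean-of-per-day-logs does not reproduce the
   printed column.  Classification: `dorsal_up` requires dorsal RPKM
   above cutoff on both days and `d/v ≥ 2` on both days (inclusive, "at
   least"); `dorsal_exclusive` requires zero ventral *reads* on both days
   (not merely sub-cutoff RPKM) with dorsal expressed on both days;
   symmetric for ventral.  A zero denominator with an expressed numerator
   passes any fold threshold (the ratio diverges).  Temporal
   classification (`day4_up`/`day8_up`) is strict (`> 2`, "more than")
   and demands the fold on *both* sides plus expression above cutoff in
   both day-of-interest libraries.  By default the down-regulated side is
   not required to be expressed (the selection workflows gate only the up
   side); `require_both_sides=True` adds that gate.  Output tables are
   sorted by descending combined fold change, NA last, ties broken by
   transcript id.

4. **GO enrichment.** One 2 × 2 table per GO term annotating at least one
   transcript in the union of the two sets (terms absent from both sets
   are not tested and do not enter the correction burden `m`).  The
   default test is two-sided Fisher by the minimum-likelihood convention;
   a one-sided upper-tail variant is exposed because historical annotation
   tools offered both and the source workflow does not pin the sidedness
   down.  Multiplicity is handled with Benjamini–Hochberg
   (`q(i) = min_{j ≥ rank(i)} p(j)·m/j`, capped at 1) — the source
   procedure says only "corrected for multiple selections", and BH is the
   standard FDR reading of that phrase.  Optional annotation propagation
   closes each transcript's GO set under is_a/part_of ancestors of an OBO
   1.2 graph; it is off by default since shipped annotations may already
   be closed.

5. **qPCR statistics.** Standard curves are OLS fits of Ct on
   log10(amount) (≥ 3 dilution points; slope must be negative; efficiency
   `10^(−1/slope) − 1`, 1.0 = perfect doubling).  Replicate Cts are
   back-transformed to amounts individually and then averaged — averaging
   Cts would estimate the geometric mean amount instead.  Normalization
   divides by the reference gene's condition-mean amount.  The
   dorsoventral ratio estimator is a ratio of two normalized means; its
   delta-method SE propagates the sampling variance of all four group
   means, including the reference gene's — reference noise divides whole
   groups and is invisible in normalized replicate spread, so omitting it
   understates the SE by roughly a factor √2 here.  Group comparisons use
   classic (mean-centred) Levene's test to choose between pooled-variance
   Student and Welch t-tests at Levene p > 0.05 (median centring is
   available behind the Brown–Forsythe-style flag of `scipy.stats.levene`
   but is not the default, since the prescribed test is Levene's).  The
   side × day ANOVA is the standard balanced fixed-effects decomposition;
   unbalanced designs are rejected rather than reweighted, matching the
   triplicate design.  Degenerate inputs are resolved explicitly:
   zero-variance effects report F = 0, p = 1; zero residual variance with
   a real effect reports F = ∞, p = 0; perfectly separated constant
   groups report the smallest positive float with a warning.

## The synthetic-data generator

The generator emulates the study conditions so every stage can be scored
against known truth: 5,000 transcripts (log-normal lengths, median
1.5 kb), four libraries of 2 × 10⁶ mapped reads, and negative-binomial
counts with dispersion 0.2.  Counts are drawn as gamma-mixed multinomials:
each transcript's relative abundance (log-normal, σ = 1.2) is multiplied
per library by a gamma factor with mean 1 and variance equal to the
dispersion, and reads are then allocated multinomially.  Marginally each
count is gamma-Poisson (negative binomial) to an excellent approximation,
while each library's total equals its requested size exactly — which is
what fixed `N` in the RPKM formula assumes.  Planted structure: a 100-
transcript dorsal-up set and a 100-transcript ventral-up set at true fold
8 on both days (the fold scale the strongest published markers show),
5 + 5 side-exclusive transcripts (opposite-side abundance exactly 0), a
60-transcript low-abundance pool backing 120 quality-passing null spots
(with deliberate duplicate and missing spot→transcript mappings, plus 40
decoys each failing exactly one quality rule), a 40-term GO vocabulary
with the cell-cycle term planted into the dorsal-up set at probability
0.8 against a background of 0.01–0.06, and a qPCR panel with a TBX5-like
8:1 dorsal marker, an NTN1-like 1:8 ventral marker and a constant RPL27
reference, Ct noise σ = 0.15 cycles on perfect-efficiency curves.  All
randomness descends from one seed through fixed-order substreams.

What the generator does *not* emulate: GC or length bias, multi-mapping
ambiguity, batch effects between libraries, correlated annotation
structure (real GO terms are hierarchically nested), or qPCR efficiency
differences between genes.  Passing tests therefore demonstrate the
correctness and calibration of the pipeline's rules on data obeying its
assumptions, not robustness of those rules to real-library artefacts.

## Verification design

* Fold-change arithmetic and the exclusivity rule are checked against the
  two shipped published reference tables (100 rows, ±0.02 tolerance
  absorbing 3-decimal input rounding; exactly 3 dorsal-exclusive rows).
* Fisher's exact test is compared to an exact integer-arithmetic
  enumeration oracle over every 2 × 2 table with row sums ≤ 30
  (agreement to 1e-12; ties at the observed likelihood included with the
  conventional 1e-7 relative gate).  BH output is compared with a literal
  step-up implementation.
* Planted-signal recovery on the default generator: dorsal-up
  sensitivity ≥ 0.9; truly-null transcripts admitted to the scored
  dorsal-up call at ≤ 0.05 (sensitivity and false-admission are defined
  on the same binary call); the planted GO term significant at
  FDR < 0.05; under a global null with uniform annotation frequencies
  the mean significant-term fraction over 20 seeds stays ≤ 0.05.
* Statements of the form "within 2 SE" or "within 3 SE" are verified as
  coverage/calibration properties over a batch of fixed seeds rather
  than as a single draw, because one interval is by construction only a
  ~95 %/99.7 % event.

## Problem sizes and defaults

Defaults are chosen so a full simulated run — 5,000 transcripts, four
2M-read libraries, 160 spots, two qPCR genes in triplicate — completes in
seconds, which is also the scale every shipped test uses.  `fold ≥ 2`
(dorsoventral, inclusive) and `fold > 2` (temporal, strict) follow the
source workflows; `alpha = 0.05` throughout; all thresholds are exposed
as parameters.  Known limitations: RPKM inherits the usual
between-library comparability caveats (no TMM-style normalization is
applied, by design fidelity to the original procedure); detection cutoffs
assume the microarray tissue matches the RNA-seq tissue; the exclusivity
rule is sensitive to even one stray read; and Fisher enrichment treats
transcripts as exchangeable units, ignoring length bias in annotation
coverage.
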