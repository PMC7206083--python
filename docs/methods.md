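# Methods

## Paired-fraction somatic calling

Each site is reduced to a biallelic pair of counts per fraction:
(ref_calls, var_calls) in the "normal" sorted fraction and in the "tumor"
(clonally expanded) fraction. The somatic p-value is the one-tailed
Fisher exact / hypergeometric upper tail,

    p = P(X >= tumor_var | margins fixed),

the probability that at least the observed variant support lands in the
tumor fraction when variant reads carry no fraction signal. This is the
convention of VarScan-style somatic callers; it reproduces the printed
panel p-values of the worked-example table to their printed precision at
all 14 sites (0.00178 … 0.41053), which is how the tail convention was
confirmed. A two-sided Fisher test is available behind
`CallerParams(two_tailed=True)` for sensitivity analysis only.

Filters are ordered and exclusive — coverage (tumor depth < 6), then VAF
(< 5%), then known-variant exclusion — so a failing site carries exactly
one label and a site failing coverage is never labelled `filtered_low_vaf`.
The known-variant list is user-supplied (`chrom pos var` TSV); no germline
database ships with the package. `normal_purity` is recorded but does not
modify counts (the reference setting is 1). Coordinates are 1-based;
substitutions only — the two frameshift rows of the packaged panel fixture
are carried as printed for completeness but the count model treats every
site as a biallelic substitution.

VAF display convention: `100 * var / (ref + var)`, rounded half away from
zero — two decimals in panel tables, one decimal in amplicon tables. A
guard of 1e-9 absorbs binary representation error just below a rounding
tie. Tests compare printed values at half a unit in the last printed
decimal or tighter.

## Ultra-deep amplicon calling

A variant is called when both thresholds pass, inclusively:

* reported VAF >= 0.5% of called reads. The comparison uses the
  *one-decimal reported* VAF (the resolution of amplicon tables and of
  the 0.5%-sensitivity claim), so a run drawing 0.452% raw VAF reports
  0.5 and is called. Under the binomial read model below, this choice
  gives detection probability ≈ 0.9999 for a true 0.5% variant at
  100,000x with a 1e-3 error floor, matching the stated assay
  sensitivity; comparing the raw fraction instead would give ≈ 0.93.
* base quality frequency ratio >= 0.9. The ratio is
  `(qsum_var / qsum_all) / (var_calls / depth)` — the mean Phred quality
  of variant-supporting bases relative to the mean quality of all bases
  at the position. Genuine variants cluster near 1 (the accepted rows of
  the validation table span ~0.96–1.03); error-dominated variant support
  carries depressed qualities and falls below 0.9. The phrase defining
  this statistic is ambiguous between the ratio and its reciprocal; the
  default direction is mean-variant-quality over mean-all-quality
  (values below 1 = suspicious), with the reciprocal behind
  `AmpliconThresholds(invert_ratio=True)`. "Quality sum" is taken as raw
  Phred sums. The inclusive ratio boundary is applied with a 1e-12
  tolerance against representation error.

The packaged validation-table fixture marks each row `consistent` when
its printed one-decimal VAF equals the rounding of `100 * var / depth`;
eight printed rows disagree with their own counts (plausibly a
quality-weighted counting upstream, not recoverable from the printed
numbers) and numeric reproduction is asserted only on consistent rows.

Longitudinal series report direction (stable / non-decreasing /
non-increasing / mixed) and a descriptive least-squares slope in %/year.
Confinement classifies compartments by VAF: the maximum is the carrier;
uncalled compartments are absent; called compartments below
`trace_factor * max_vaf` (default 0.5, a pragmatic convention — the
source narrates confinement only qualitatively) are contamination-level
traces with their trace/max ratio reported; the remainder are shared.
Cohort prevalence is carrier-count arithmetic at one decimal.

## TCR clonotype analysis

Orphan pooling requires exact identity of the beta CDR3 nucleotide
sequence and all three V/D/J gene calls, and merges only beta-only
orphans into *paired* clonotypes — the strictest reading of the pooling
rule; fuzzy (1-mismatch) merging and alpha-only orphans are deliberately
out of scope. An orphan matching two or more paired clonotypes is left
unmerged and reported, not guessed. Pooling conserves total cells, never
shrinks the largest clone, and is idempotent.

Diversity uses natural-log Shannon entropy over clone fractions and
normalized clonality `1 - H / ln(richness)` (defined as 1 for a
single-clone repertoire); the flow Vβ-panel covers ~70% of the normal
repertoire, so per-timepoint panel fractions are validated to [0, 1] but
not required to sum to 1. The antibody-family-to-IMGT mapping is an
editable user table, not hard-coded.

## Impedance cytotoxicity

Cell Index and Normalized Cell Index follow the instrument definitions
`CI(t) = (R(f_n,t) - R(f_n,t0)) / Z_n` and `NCI(t) = CI(t) / CI(t_norm)`
with the stated exclusion CI(t_norm) != 0 raised as a dedicated error
(zero tested at 1e-12). t_norm defaults to effector-addition time and the
readout horizon to 21 h after it. Percent cytolysis,
`100 * (NCI_control - NCI_effector) / NCI_control`, is a documented
convention (the source reports curves, not a named scalar); negative
values are reported as-is. Times are matched by nearest sample within the
trace and linearly interpolated across mismatched grids (the reference
design sampled uniformly every 30 min, so interpolation is a fallback).
No numeric cytotoxicity targets exist; this stage is validated by its
identities and by noise-free simulation monotonicity.

## Dose-response and DSS

Inhibition is `100 * (1 - signal / negative-control signal)`. The 4PL is
fitted on the log10 dose axis by bounded least squares (bottom, top in
[0, 100], slope in (0, 20], log10 IC50 within 3 decades of the tested
window) with deterministic initialization from data quantiles and a fixed
grid of four slope starts; tolerances are set to machine level, and
noise-free profiles are recovered to ~1e-15 relative error (the tested
contract is 1e-6). A constant profile is returned as a flagged flat
curve (slope and IC50 undefined) rather than fitted.

DSS integrates the fitted response above the activity threshold t
(default 10%) over the tested log10 window [x_min, x_max] using a Simpson
rule on a fixed 2001-point grid (deterministic bit-for-bit):

* DSS1 = 100 * A / ((100 - t) (x_max - x_min)),
* DSS2 = DSS1 * 100 / top   (default; normalizes by the response ceiling),
* DSS3 = DSS2 * (fraction of the window with response >= t).

A response never exceeding t scores 0; constant 100% inhibition scores
100 (variants 1–2). Which variant the original screen used is not
recorded; variant 2 is the default and all are selectable. Selective DSS
is the per-drug difference sample − reference, sorted by |difference|.

## Synthetic generators

* **Pileups** — `var_calls ~ Binomial(depth, v(1-e) + (1-v)e/3)`:
  miscalls distribute uniformly over the three non-reference bases and
  only the tracked alternate base is counted (the callers are biallelic).
  The default error floor e = 1e-3 is a stand-in for an error model the
  assay description does not pin down. Base qualities are truncated-
  normal Phred integers in [2, 60] per allele class (mean 36, sd 4 by
  default) — chosen so the frequency-ratio statistic is exercisable, not
  claimed to match any instrument.
* **Paired fractions** — carrier at `clone_vaf`; every other compartment
  at `contamination * clone_vaf` (sorting impurity, e.g. double-positive
  cells in a bead-sorted fraction).
* **Repertoires** — a dominant paired clonotype at
  `expanded_clone_fraction` of `n_cells`, with `orphan_split_fraction` of
  it emitted as a beta-only orphan sharing the beta chain and V/D/J
  calls; background clone sizes are geometric (simple and heavy-tailed
  enough for frequency/diversity behaviour), rescaled to conserve the
  total exactly. The defaults of the worked configuration
  (n_cells = 14,111, fraction 0.475, orphan split 0.30) reproduce the
  reference clone structure (4669 + 2038 cells) in expectation.
* **Impedance** — CI grows logistically (rate 0.08/h, carrying capacity
  10 CI units, CI(0) = 1, Euler steps at the 0.5 h sampling interval) and
  decays after effector addition at `killing_rate * E:T`; resistance is
  `r0 + Zn * CI` plus optional Gaussian noise. The default design (E:T =
  4, 8, 16:1, addition at 24 h, 21 h readout) mirrors the reference
  co-culture layout. These are phenomenological kinetics sufficient for
  monotonicity and rescue properties, not a mechanistic killing model.
* **Plates** — viability follows a descending 4PL over the default
  five-dose, 10,000-fold series (1–10,000 nM); inhibition is its
  complement, plus optional noise.

All generators take explicit seeds and touch no global random state;
identical configurations and seeds reproduce outputs exactly.

### What the simulations do and do not show

Passing the property suites shows the implementations are internally
consistent with the stated statistical models (binomial sampling, exact
hypergeometric tails, logistic kinetics, 4PL curves). Real data add
effects these generators omit — alignment and PCR artifacts, strand
bias, overdispersion beyond binomial, UMI/chemistry effects, plate
position effects, instrument drift — so simulated detection rates bound
ideal-case behaviour, not real-assay performance.

## Problem sizes and numerics

Stochastic checks use 200 replicate simulations per condition at depth
100,000 (detection/false-call rates), 1000 replicates at depth 2000 for
mean-recovery, 100 simulated curves for DSS properties, and exhaustive
enumeration of all ~635,000 2×2 tables with total ≤ 60 for the somatic
test oracle — sizes chosen to make the binomial/hypergeometric
predictions sharp while keeping the default suite fast. Oracle
equivalence is asserted at 1e-9 relative; definitional identities
exactly or at 1e-12.

## Known limitations

Substitutions only (no indel model); a single measurement frequency per
RTCA run; no multiple-testing correction across panel sites (the
reference workflow reports raw somatic p-values); cohort prevalence
treats carriers as exchangeable booleans (no per-subject VAF modelling);
DSS assumes a monotone ascending response.
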