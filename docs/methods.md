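# Methods notes

This note records the modeling assumptions, parameter choices and
numerical conventions behind `tedg`, including the places where the
design was genuinely open and what was decided.

## Data model

A cohort is a list of per-sample lesion measurements: patient, sample
time in **months** since first sample, lesion identifier, assay (NGS
mutant-allele frequency or FISH abnormal-nuclei fraction, both in
[0, 1]), FACS tumor-cell fraction in (0, 1], and an optional treatment
annotation attached to the sample it precedes.  Lesion identifiers are
free strings: gene-level and variant-level analyses use the identical
machinery and differ only in the granularity the caller chooses.  A
missing FACS fraction defaults to 1.0 (pure sample) with a logged
warning rather than failing.  Patients with fewer than two distinct
sample times are kept but flagged; they contribute recurrence counts
but no ordering evidence.  Kinetics converts months to years (/12); all
slopes are per year.

## MCF estimation

Three estimators map raw values to mutation cell frequency:

* FISH: `min(fraction / FACS, 1)`.
* Diploid NGS: the Hill curve `K·MAF^n/(1+K·MAF^n)` with (K, n) from
  an exhaustive grid search (K over powers of two up to 512, n in
  1..10) minimizing the squared deviation from the ideal 2·MAF on
  MAF ∈ [0, 0.5].  The integral is evaluated by a fixed midpoint rule
  with 10,000 nodes — deterministic, and accurate far beyond what the
  coarse 10×10 grid can distinguish (the test suite checks agreement
  with a 10⁶-node oracle to 1e-6).  Grid ties would be broken toward
  smaller K then smaller n; at the resolutions involved no tie occurs.
  The optimum for the diploid target is (16, 2).
* Deletion-adjusted NGS: for genes paired with a co-measured deletion
  (pairings are configuration, defaulting to TP53↔del17p and
  BIRC3↔delBIRC3), the target becomes (2 − MCF_del)·MAF and the Hill
  fit is recomputed (and cached) per deletion MCF.  If the named
  deletion is absent from the sample the code warns and falls back to
  the diploid fit.  Copy-neutral LOH and homozygous deletions are not
  modeled.

NGS estimates are divided by the FACS fraction and capped at 1.  The
cap is forced by the definition (a fraction of cells); whether the
purity division applies to diploid lesions as well as deletion-paired
ones is ambiguous in principle, and the package divides in both cases
for consistency with the 2·MAF/purity ≈ 0.57 convention at MAF 0.2,
purity 0.7 (a `divide_purity=False` escape hatch exists).  The
piecewise estimator min(2·MAF, 1) and the simple 2·MAF/purity
approximation are retained for comparison; the Hill curve deviates
from the piecewise form by at most 0.20 (at the saturation point
MAF = 0.5) and by < 0.17 below MAF ≈ 0.4.

## Ordering pipeline

"A before B" is defined by strict comparison of first-presence times,
where presence means MCF strictly above the 5% threshold.  Lesions
that later drop below threshold keep their original first-presence
time; lesions tied at the same first sample contribute no edge.  ISN
edge weights count supporting patients; node recurrence counts
patients ever showing the lesion.  Reciprocal ISN edge pairs (the only
kind of "self-loop" a two-lesion order can produce) are reduced to the
heavier direction with the weight difference; exact ties cancel.

Deconvolution computes `G_obs (I + β G_obs)^-1` on the raw patient-
count adjacency over the sorted node list (results are permutation
invariant; a property test asserts this).  Entries below 1e-9 —
including all negatives, which arise when transitive mass exceeds an
observed weight — are treated as "no direct order" and dropped.  The
matrix is used unnormalized: the useful range of β therefore scales
like 1/N (with patient-count weights the transitive correction term is
β·w², against differences of order w), and the calibration grid is the
tool for choosing β at a given cohort size.  β = 0.2 is the default,
appropriate for cohorts of roughly 30 patients.

Backbone extraction transforms deconvolved weights to costs exp(−w)
and takes the minimum spanning tree with Prim's algorithm on the
undirected projection (parallel reciprocal costs resolved by the
cheaper), then re-orients each tree edge by the surviving directed
edge.  Prim-on-undirected is the default because the ordering graphs
are nearly tree-like once deconvolved; Edmonds' minimum spanning
arborescence (rooted at the node with maximal out-minus-in weighted
degree) is available as the directed-correct alternative and agrees
with the default on all tested inputs.  Disconnected graphs are
handled per weakly-connected component, so the output can be a forest.

## Simulator

Two four-mutation topologies: linear π0 ⊂ π1 ⊂ … ⊂ π4, and branching,
identical through π2 = {x1, x2} with terminal states π3 = {x1,x2,x3}
and π4 = {x1,x2,x4}.  Over an elapsed time dt, with
q = 1 − e^(−f·dt): stay with probability 1 − q, advance k states with
probability q^k(1−q).  Truncation to the finite ladder leaves mass
q^(5−i) in row i of the linear model; it is absorbed into the terminal
state, preserving the off-diagonal ratios while keeping rows
stochastic.  In the branching model the advance mass into each
terminal branch is q^(3−i); the default "split" policy gives each
branch half of it, which makes rows exactly stochastic with both
branches symmetric.  The "renormalize" alternative (full printed mass
to each branch, row rescaled) is kept behind a flag.

The chain is advanced in **unit monthly steps** of this law and read
out at the sampling times (default 10, 20, 30 months).  This matters:
the truncated multi-jump family is not consistent under composition
(Chapman–Kolmogorov residual ~0.007 at monthly steps but ~0.16 at
interval-sized steps — both asserted in the tests), and interval-sized
jumps would tie the first appearance of several mutations at once,
erasing precisely the ordering signal the calibration measures.  With
one transition per 10-month interval the pipeline cannot exceed ~50%
reconstruction accuracy at β = 0.2, N = 30 for any fitness; with
monthly steps and the default fitness f = 0.1/month it reaches ~85%
(linear) and ~90% (branching), the method's intended operating regime.
Default fitness 0.1 per month makes f × interval = 1 per sampling
interval.

Accuracy is the fraction of replicate cohorts whose extracted backbone
edge set equals the generating topology's defining edges exactly.
Replicates and patients draw from counter-derived RNG substreams, so
cohorts are reproducible and grow consistently with N.  Accuracy runs
use 100 replicates by default (the stochastic SE at 0.85 is then
~0.036); a 5 × 2 calibration grid at 20 replicates per cell runs in
about two seconds.

## What the synthetic data does and does not emulate

The fixture generator converts simulated presence trajectories into
raw observations: a lesion is at true MCF 0.5 at its first positive
sample (a newly expanded subclone) and 1.0 afterwards; NGS lesions
report 0.5·MCF, FISH lesions report MCF, with optional truncated
Gaussian noise; FACS purity is 1.0.  This exercises every downstream
module deterministically, but real cohorts differ: purity varies per
sample, MCF trajectories are continuous rather than two-valued,
deletions co-occur with mutations in the same gene, sampling is
irregular, and measurement noise is heteroscedastic in depth.  Passing
tests demonstrate the machinery is correct under its stated model, not
that the biological assumptions hold in any particular cohort.

## Statistical conventions

* Degree ordering test: weighted degrees (each patient contributes an
  arrow); two-sided exact binomial p at 1/2 by doubling the smaller
  tail; labels early/late at p < 0.05 with a second star at 0.01;
  fold change out/in with a 0.5 pseudocount on both sides only when a
  degree is zero; isolated nodes are unlabeled with p = 1.
* Flow test: Σ(d_in − d_out)²/d_out as printed, with zero denominators
  replaced by the 0.5 pseudocount so pure sinks inflate the statistic
  but keep it finite; df = n − 1.  The denominator is the node's
  out-degree, not an expected count — the statistic is used as a
  directional-flow score, not a textbook goodness-of-fit.
* Association test: pairwise hypergeometric upper tail (co-occurrence,
  P(X ≥ k)) and lower tail (exclusivity, P(X ≤ k)); patients missing
  either entry dropped pairwise; Bonferroni over the pairs actually
  tested; degenerate margins (lesion in none or all) reported with
  verdict "none" and excluded from the correction count.
* FEM: the Z-score is Δf standardized by σ·√(f̄(1−f̄)) with f̄ the
  two-sample mean clamped to [1/2000, 1 − 1/2000] (a depth proxy) so
  absent and fixed lesions stay finite.  σ per assay is 1.4826·MAD of
  standardized changes from sample pairs with no recorded intervening
  treatment, floored at 1e-6.  One-sided normal tails of rising
  (falling) lesions are combined with Fisher's method into P_increase
  (P_decrease); an empty side gives 1.  Benjamini–Hochberg at FDR 0.1
  is applied with both axes pooled **per cohort**; a pair rejected on
  both axes is a replacement event and marks the patient branching.
  Per-patient pooling exists (`classify_patient`) but is
  anti-conservative on its own: p-values of sign-selected half-normal
  tails are U(0, 0.5) under the null, so small pooled families reject
  too easily (~10% false branching calls on two-lesion null patients
  versus ~2% with cohort pooling).  The cohort-pooled route is the
  default and the one whose type-I behavior is tested.
* Kinetics: growth rate is the mean of *clipped* slopes per lesion
  (the "average increasing speed"); MMFS is the *unclipped* maximum
  slope per patient, so a patient whose clones only shrink gets a
  negative MMFS.  The subclonal variant drops observations whose
  earlier frequency exceeds 0.20 before averaging.  Group comparisons
  use the two-sided Wilcoxon rank-sum test, exact when both groups
  have ≤ 20 tie-free values.  The early-versus-late comparison is run
  on per-lesion mean growth rates (per-observation pooling is a flag).

## Known limitations

* The deconvolution operates on count-weighted adjacency, so β must be
  rescaled with cohort size; there is no auto-calibration beyond the
  grid tool.
* MCF estimation is per-lesion and point-wise; no subclonal clustering
  or copy-number deconvolution is attempted.
* The simulator is a state-level Markov chain over four mutations; it
  has no subclone frequency dynamics, so FEM's operating
  characteristics are tested on separately constructed frequency-level
  synthetics.
* Replacement detection inherits the selection effect of combining
  sign-selected one-sided p-values; cohort-level FDR pooling keeps the
  false-call rate near nominal but the per-pair p-values themselves
  are not calibrated tail probabilities.
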