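# Methods

## Relative quantification

The quantification model is the Livak 2^-ΔΔCt method with an assumed
amplification efficiency of 2 per cycle (no Pfaffl efficiency correction).
Within each sample — one biological replicate of one cultivar × tissue ×
treatment × timepoint cell — the target is normalized against the reference
gene measured in the same sample, ΔCt = Cq_target − Cq_reference, so
plate/sample effects shared by both genes cancel. Relative quantity against
a calibrator cell is RQ = 2^-(ΔCt − mean ΔCt_calibrator).

Two aggregation conventions exist in practice. The default
(`aggregate="per_replicate"`) calibrates each replicate and averages the
linear RQ values, which is what linear-scale mean ± SE bars over biological
replicates display; `"of_means"` exponentiates the mean ΔΔCt instead
(geometric-mean flavour). The two agree at zero noise and differ by a
Jensen-gap factor otherwise. The self-calibrated cell is pinned to exactly
RQ = 1 — the control bars of a calibrated figure are 1 by construction —
while its replicate scatter still yields a nonzero SE.

The calibrator is the water control of the **same cultivar**, tissue and
timepoint. This makes within-cultivar responses comparable across
genotypes, but it also means calibrated RQ carries no information about
between-genotype baseline differences: both cultivars' controls sit at 1.
Genotype contrasts are therefore computed from ΔCt directly (below).

## Responsiveness calls

A gene is called at a timepoint from its stress and control ΔCt replicate
sets: fold change = 2^-(mean ΔCt_stress − mean ΔCt_control), and
significance from a one-tailed unpaired pooled-variance t-test. The test is
applied on the ΔCt scale by default: ΔCt values are log2-scale quantities,
approximately normal with roughly homogeneous variance, whereas linear RQ
replicates are log-normal and right-skewed with n = 3. A
`test_scale="rq"` switch applies the test to calibrated linear RQ
replicates instead; both modes reproduce the qualitative calls on low-noise
data.

The one-tailed p-value takes its tail in the direction of the observed mean
difference (equivalently, half the two-tailed p), so it never exceeds 0.5.
Degenerate inputs are defined explicitly: identical zero-variance groups
give p = 0.5; zero pooled variance with unequal means gives p = 0 with a
runtime warning (this arises only with noiseless synthetic data).

Call semantics: **up** requires fold ≥ threshold AND p < α; **down**
requires fold ≤ 1/threshold AND p < α; the threshold comparison is
inclusive ("at least two-fold"; default threshold 2.0, α = 0.05). A gene's
overall pattern is up/down when at least one timepoint is called and all
called timepoints agree, **mixed** when both directions occur, and
**unchanged** otherwise. Timepoints are analyzed independently — no
interpolation, no time-course model. No multiple-testing correction is
applied by default, matching how such screens report raw per-gene
p-values; Benjamini–Hochberg is available behind `bh_correct=True`.

## Genotype contrasts

For each gene × tissue × treatment × timepoint the tolerant/sensitive
ratio is 2^-(mean ΔCt_tolerant − mean ΔCt_sensitive) with the same
one-tailed test and 2-fold gate, yielding higher / lower / similar. Each of
the four conditions (2 treatments × 2 timepoints) is contrasted
independently; no cultivar × treatment interaction model is fitted. A
property test asserts that a programmed control-condition baseline gap is
recovered by the contrast while being invisible in calibrated RQ.

## Tissue overlap

The root/leaf partition is per (tissue, direction): two independent two-set
overlaps, one for induced and one for repressed genes. A gene with a mixed
pattern in either tissue is excluded from the partition entirely, even if
cleanly directional in the other tissue — matching how such genes are
dropped from published overlap figures. A consequence of the per-direction
view is that a gene cleanly up in one tissue and cleanly down in the other
legitimately appears in one "-only" set of each family; disjointness holds
within each direction family, not across families.

## Candidate rule engine

The engine runs on a qualitative state matrix: per gene × tissue, the
response pattern of each cultivar plus the contrast call per condition.
The default **paper** profile implements the operational rules:

* **Group 1** ⇔ higher in ≥ 1 condition AND no control condition lower AND
  NOT (tolerant pattern down while sensitive pattern is up or unchanged).
* **Group 2** ⇔ lower in ≥ 1 condition AND higher in none AND neither
  cultivar's pattern is up or mixed.

This operationalization is reverse-engineered from the published
selections, which a literal reading of the stated criteria does not
reproduce: one gene satisfying the "up in both cultivars with a higher
level under dehydration" reading was nevertheless not selected (it is lower
under both control conditions — hence the control-lower veto), and one
selected gene is down-regulated in both cultivars (hence down-in-both does
not disqualify a gene that is higher-in-tolerant and never control-lower).
The "higher in none" clause of Group 2 is not strictly implied by the
published wording but follows from its intent ("lower expression levels in
the tolerant cultivar") and is required for Group 1 and Group 2 to be
mutually exclusive over all possible states — verified by exhaustive
enumeration of the 4 × 4 × 3⁴ single-gene state space.

A **literal** profile implements the stated criteria verbatim
(i: inducible-in-tolerant vs unchanged-in-sensitive with a higher level;
ii: up in both with a higher level in the tolerant cultivar; iii:
up-vs-unchanged or up/unchanged-vs-down), with Group 1 taking precedence
over Group 2. Criterion (ii)'s "higher up-regulated expression change" is
read at the expression-level scale; the induction-fold reading would need
quantitative fold data that the qualitative matrix does not carry. Every
selection carries a trace of the predicates evaluated and the criterion it
instantiates.

## Packaged call matrix

The package ships a transcription of the screen's qualitative results: per
gene × tissue, per-timepoint dehydration directions for both cultivars,
overall patterns, and the four contrast calls. Cells that the published
enumerations do not pin down are flagged `ambiguous` and encoded as
their most conservative value ("similar"): the dehydrated-leaf "lower"
memberships (only counts were reported, except the top negative candidate)
and the dehydrated-root 2 h enumeration, which sits in a sentence whose
condition label contradicts its surrounding counts. Flagged cells are
excluded from truth-recovery comparisons but still feed the rule engine.
Per-timepoint directions for the tolerant cultivar are only partially
enumerable from prose; the fixture records pattern-consistent choices
(up-pattern genes up at both timepoints except the four genes with printed
timepoint-specific behaviour). All overall patterns, overlap counts and
selections — the quantities the analysis reports — are exact
transcriptions.

## Synthetic data generator

The generator draws, per (cultivar, tissue, treatment, timepoint,
replicate) cell, one reference Cq = reference_ct + N(0, σ) shared by all
target genes of the cell, and per target
Cq = Cq_ref + baselineΔCt − true_log2FC·[stress] + N(0, σ). Noise is
additive Gaussian on the Cq scale (multiplicative log-normal on expression,
the standard qPCR error model); sharing the reference draw within a cell
mirrors same-sample normalization, so reference noise cancels in ΔCt.
Defaults mirror the emulated screen: 3 biological replicates,
reference_ct = 20 cycles, σ = 0.25 cycles (a typical biological-replicate
scatter for plant RT-qPCR). Baseline ΔCt is keyed per timepoint so
control-condition genotype contrasts may differ between sampling times, as
the screen reports.

`paper_scenario()` reconstructs a quantitative ground truth from the
qualitative matrix: printed fold magnitudes anchor the cells that report
them (the ~300-/400-fold inductions, the 17.5-/9.2-fold repressions, the
3.8/2.1 mixed pattern, the 3.9/3.3 opposite-tissue gene, and the full
contrast fold sets of the two headline candidates); every other effect is a
|log2FC| = 2 placeholder (0 for unchanged/similar), recorded in
`placeholder_cells`. Because control contrast d, stress contrast s and the
two fold changes are linked (s = d + log2FC_tol − log2FC_sens), a small
deterministic solver adjusts the least-anchored quantity (sensitive fold
first, then whichever of baseline/tolerant fold lacks a printed value)
within the log2 band of its qualitative state (±[1, 12] for
changed/higher/lower states, |x| ≤ 0.9 for sub-threshold states, kept
clear of the inclusive |log2| = 1 boundary). The zero-noise truth table
provably reproduces the packaged matrix on every non-ambiguous cell (tested
end-to-end through the full pipeline).

What the generator does **not** emulate: PCR-efficiency deviations from 2,
plate/batch effects, technical replicates, non-detects, and any
correlation between genes beyond the shared reference draw. Passing tests
therefore demonstrate correctness of the computational chain and its
statistical calibration under the stated noise model — not robustness to
instrument artefacts.

## Statistical calibration (simulated, n = 3, σ = 0.25)

With the screen's nominal design the acceptance suite verifies, at desk
scale: a null (log2FC = 0) up-or-down call rate far below 0.05 over 2,000
genes (the 2-fold gate is ≈ 4.9 σ of the fold estimator, so the gate —
not the t-test — dominates); > 95 % directional recovery at |log2FC| = 3
over 500 genes; mean log2FC estimation bias within ±0.05 (the ΔCt-scale
estimator is unbiased); and recovery monotone over log2FC ∈ {0.5, 1, 1.5,
2, 3} at 400 genes per level.

## Numerical and interface choices

* Reports are TSV with floats at 6 significant digits; re-reading a report
  reproduces values to that precision.
* Fold repression is conventionally narrated as 1/RQ ("17.5-fold down");
  tables always store the linear ratio.
* The pipeline refuses to overwrite existing stage outputs unless forced,
  logs all thresholds at INFO, and is byte-deterministic given (inputs,
  seed).
* Cq validity range (0, 45]; missing replicates or reference rows are
  hard errors — the data model assumes complete replication, and
  non-amplification is out of scope.
* The optional overlap figure uses plain matplotlib circle patches.

## Known limitations

* The rule engine consumes qualitative states only; a magnitude-aware
  ranking (e.g. by contrast fold) is deliberately out of scope.
* Technical (within-plate) replicates are not modelled; `bio_replicate` is
  the only replication level.
* The literal rule profile cannot express the induction-fold reading of
  criterion (ii) (see above).
* With n = 3 the t-test has 4 degrees of freedom; power below ~2-fold
  effects is poor, which the calibration suite quantifies rather than
  hides.
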