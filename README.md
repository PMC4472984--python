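# drqpcr

Reusable pipeline for RT-qPCR screens of dehydration-responsive genes in
contrasting genotypes — from raw quantification-cycle (Cq) tables to
prioritized candidate genes.

The package was built around a chickpea (*Cicer arietinum*) screen of 19
*CaNAC* transcription-factor genes in the drought-tolerant cultivar ILC482
and the drought-sensitive cultivar Hashem: roots and leaves, water control
vs dehydration, 2 h and 5 h, three biological replicates, *IF4a* as the
reference gene. Every step is generic, though: any two-genotype,
two-tissue, multi-timepoint qPCR screen in the same shape works.

## What it computes

1. **Relative quantification (Livak 2^-ΔΔCt).** Within each sample,
   ΔCt = Cq_target − Cq_reference; relative quantity against the
   water-control calibrator of the same cultivar, tissue and timepoint is
   RQ = 2^-ΔΔCt, reported as mean ± SE over biological replicates.
2. **Responsiveness calls.** A gene is dehydration-responsive in a
   cultivar × tissue when, at ≥ 1 timepoint, its stress/control fold change
   is ≥ 2 (or ≤ 1/2) with a one-tailed unpaired equal-variance t-test
   P < 0.05. Opposite calls at different timepoints give a "mixed" pattern.
3. **Genotype contrasts.** Tolerant/sensitive expression ratios per
   condition, computed from ΔCt (never from calibrated RQ, which erases
   between-genotype baselines), with the same 2-fold + P < 0.05 rule for
   higher/lower calls.
4. **Tissue overlap.** Root/leaf Venn partition of responsive genes per
   direction, excluding mixed-pattern genes entirely.
5. **Candidate selection.** A rule engine classifies genes into Group 1
   (overexpression candidates: higher in the tolerant genotype, never lower
   under control conditions, not down-in-tolerant vs not-down-in-sensitive)
   and Group 2 (knock-down candidates: lower in the tolerant genotype,
   never higher, not up-regulated in either genotype).
6. **Synthetic data.** A Cq generator with programmed ground truth
   (baseline ΔCt per genotype plus true log2 fold changes, Gaussian Cq
   noise) makes the whole chain testable end-to-end; `paper_scenario()`
   encodes the published screen's qualitative call matrix and printed fold
   magnitudes.

## Worked example

```sh
drqpcr run-all --simulate --noise-sd 0 --seed 1 --out run/
```

simulates the published design noiselessly and runs every stage. The log
ends with:

```
INFO drqpcr: venn: up_both=10 down_both=1 excluded_mixed=1
INFO drqpcr: select (leaf): group1=['CaNAC04', 'CaNAC05', 'CaNAC16'] group2=['CaNAC02']
INFO drqpcr: select (root): group1=['CaNAC04', 'CaNAC16', 'CaNAC24'] group2=['CaNAC02']
```

i.e. 10 genes induced and 1 repressed in both tissues (the mixed-pattern
gene *CaNAC24* — repressed 3.8-fold at 2 h but induced 2.1-fold at 5 h in
leaves — is excluded from the overlap), three Group-1 candidates per
tissue, and *CaNAC02* as the single Group-2 candidate, five prioritized
genes in total. `run/` contains `relative_expression.tsv`,
`response_calls.tsv`, `contrasts.tsv`, `venn.tsv`, `candidates.tsv` and a
`summary.tsv` of all counts.

The same steps are available as a narrative sequence of scripts under
`analysis/` (`01_simulate.py` … `05_overlap_and_candidates.py`), each a
thin driver over the library that writes its tables to `results/`.

## Library surface

```python
from drqpcr import (
    read_cq_table, compute_delta_ct, relative_expression_table,
    response_table, contrast_table, venn_partition,
    build_state_matrix, select_candidates,
    paper_scenario, simulate_cq, derive_truth_table,
)
```

See `docs/methods.md` for the statistical model, the rule-engine
operationalization, and the synthetic-data assumptions.
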