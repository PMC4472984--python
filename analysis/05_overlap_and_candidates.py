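"""Tissue overlap and Group-1/Group-2 candidate selection.

Partitions the tolerant cultivar's responsive genes across root and leaf
(excluding the mixed-pattern gene), then applies the candidate rule engine to
the combined state matrix. Reproduces the screen's headline result: 10 genes
induced and 1 repressed in both tissues; 3 Group-1 candidates per tissue,
4 in union, plus 1 Group-2 candidate — 5 prioritized genes in total.
"""

from pathlib import Path

import pandas as pd

from drqpcr.design import default_design
from drqpcr.qpcr_io import write_report
from drqpcr.set_analysis import venn_partition
from drqpcr.candidate_selection import build_state_matrix, candidates_frame, select_candidates

OUT = Path(__file__).resolve().parent.parent / "results"
design = default_design()
resp = pd.read_csv(OUT / "response_calls.tsv", sep="\t")
contrasts = pd.read_csv(OUT / "contrasts.tsv", sep="\t")

patterns = resp.drop_duplicates(["gene_id", "cultivar", "tissue"])
tolpat = patterns[patterns["cultivar"] == design.tolerant_cultivar]
root = dict(tolpat[tolpat["tissue"] == "root"][["gene_id", "pattern"]].values)
leaf = dict(tolpat[tolpat["tissue"] == "leaf"][["gene_id", "pattern"]].values)
partition = venn_partition(root, leaf)
write_report(partition.to_frame(), OUT / "venn.tsv")
print(f"overlap: {len(partition.up_both)} up in both tissues, "
      f"{len(partition.down_both)} down in both; "
      f"excluded (mixed): {sorted(partition.excluded_mixed)}")

tol = {(r.gene_id, r.tissue): r.pattern
       for r in tolpat.itertuples()}
sen = {(r.gene_id, r.tissue): r.pattern
       for r in patterns[patterns["cultivar"] == design.sensitive_cultivar].itertuples()}
matrix = build_state_matrix(tol, sen, contrasts)

frames = []
for tissue in matrix.tissues():
    calls = select_candidates(matrix, tissue, design)
    frames.append(candidates_frame(calls))
    g1 = sorted(c.gene_id for c in calls if c.group == "group1")
    g2 = sorted(c.gene_id for c in calls if c.group == "group2")
    print(f"  {tissue}: Group 1 = {g1}, Group 2 = {g2}")
cands = pd.concat(frames, ignore_index=True)
write_report(cands, OUT / "candidates.tsv")
selected = sorted(set(cands[cands["group"] != "none"]["gene_id"]))
print(f"prioritized candidates overall: {selected} (n = {len(selected)})")
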