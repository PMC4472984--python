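"""Independent transcription of the candidate-selection predicates.

Kept separate from the package so acceptance checks compare two
implementations written from the rule statement, not one calling the other.
"""

from drqpcr.candidate_selection import StateMatrix, StateRow

CELLS = [("control", 2.0), ("control", 5.0), ("stress", 2.0), ("stress", 5.0)]


def single_gene_matrix(pattern_tolerant, pattern_sensitive, contrasts):
    row = StateRow(
        gene_id="g",
        tissue="root",
        pattern_tolerant=pattern_tolerant,
        pattern_sensitive=pattern_sensitive,
        contrasts=dict(zip(CELLS, contrasts)),
    )
    return StateMatrix(rows={("g", "root"): row})


def selection_oracle(pattern_tolerant, pattern_sensitive, contrasts):
    cmap = dict(zip(CELLS, contrasts))
    if "higher" in contrasts:
        if any(cmap[c] == "lower" for c in CELLS if c[0] == "control"):
            return "none"
        if pattern_tolerant == "down" and pattern_sensitive in ("up", "unchanged"):
            return "none"
        return "group1"
    if "lower" in contrasts:
        if pattern_tolerant in ("up", "mixed") or pattern_sensitive in ("up", "mixed"):
            return "none"
        return "group2"
    return "none"
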