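"""Group-1 / Group-2 candidate-gene rule engine.

Two candidate classes are distinguished per tissue from the combined
qualitative evidence (dehydration-response pattern of each cultivar plus the
tolerant/sensitive contrast call per treatment × timepoint):

* **Group 1** (overexpression candidates): genes with higher expression in
  the tolerant cultivar in at least one condition, provided no control
  condition shows lower expression and the gene is not down-regulated in the
  tolerant cultivar while the sensitive cultivar is up-regulated or
  unchanged.
* **Group 2** (knock-down / RNAi candidates): genes lower in the tolerant
  cultivar in at least one condition, never higher anywhere, and not
  up-regulated (nor mixed) by dehydration in either cultivar.

This operational "paper" profile is reverse-engineered from the published
selections, which a literal reading of the stated criteria (i)–(iii) does not
reproduce (see docs/methods.md); the literal profile remains available via
``rule_profile="literal"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import pandas as pd

from drqpcr.design import CONTROL, ExperimentDesign
from drqpcr.genotype_comparison import GenotypeContrast
from drqpcr.responsiveness import ResponseCall

Group = Literal["group1", "group2", "none"]
RuleProfile = Literal["paper", "literal"]

#: contrast-cell key: (treatment, timepoint_h)
Cell = tuple[str, float]


@dataclass(frozen=True)
class StateRow:
    """Qualitative state of one gene × tissue."""

    gene_id: str
    tissue: str
    pattern_tolerant: str
    pattern_sensitive: str
    contrasts: Mapping[Cell, str]  # (treatment, timepoint) -> higher/lower/similar
    ambiguous_cells: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class StateMatrix:
    """Per-gene × tissue state rows, keyed by (gene_id, tissue)."""

    rows: Mapping[tuple[str, str], StateRow]
    timepoints: tuple[float, ...] = (2.0, 5.0)

    def genes(self, tissue: str | None = None) -> list[str]:
        return sorted(
            {g for g, t in self.rows if tissue is None or t == tissue}
        )

    def tissues(self) -> list[str]:
        return sorted({t for _, t in self.rows})

    def row(self, gene_id: str, tissue: str) -> StateRow:
        return self.rows[(gene_id, tissue)]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for (g, t), r in sorted(self.rows.items()):
            rec = {
                "gene_id": g,
                "tissue": t,
                "pattern_tolerant": r.pattern_tolerant,
                "pattern_sensitive": r.pattern_sensitive,
            }
            for (trt, tp), call in sorted(r.contrasts.items()):
                rec[f"contrast_{trt}_{tp:g}h"] = call
            records.append(rec)
        return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class CandidateCall:
    """Selection outcome for one gene × tissue with a criteria trace."""

    gene_id: str
    tissue: str
    group: Group
    trace: tuple[str, ...]

    def __post_init__(self):
        if self.group != "none" and not self.trace:
            raise ValueError("non-none group requires a non-empty trace")


def build_state_matrix(
    tolerant_calls: Mapping[tuple[str, str], ResponseCall] | Mapping[tuple[str, str], str],
    sensitive_calls: Mapping[tuple[str, str], ResponseCall] | Mapping[tuple[str, str], str],
    contrasts: Sequence[GenotypeContrast] | pd.DataFrame,
    timepoints: Sequence[float] = (2.0, 5.0),
) -> StateMatrix:
    """Join per-cultivar response patterns and contrast calls into a StateMatrix.

    ``tolerant_calls``/``sensitive_calls`` map (gene_id, tissue) to a
    :class:`ResponseCall` (or a bare pattern string); ``contrasts`` is either
    a sequence of :class:`GenotypeContrast` or the frame from
    :func:`~drqpcr.genotype_comparison.contrast_table`.
    """
    if isinstance(contrasts, pd.DataFrame):
        contrast_map = {
            (r.gene_id, r.tissue, r.treatment, r.timepoint_h): r.call
            for r in contrasts.itertuples()
        }
    else:
        contrast_map = {
            (c.gene_id, c.tissue, c.treatment, c.timepoint_h): c.call
            for c in contrasts
        }
    if set(tolerant_calls) != set(sensitive_calls):
        raise ValueError(
            "cultivar call sets cover different gene×tissue universes: "
            f"{set(tolerant_calls) ^ set(sensitive_calls)}"
        )

    def _pattern(v) -> str:
        return v.pattern if isinstance(v, ResponseCall) else v

    cells: list[Cell] = [
        (trt, float(tp)) for trt in (CONTROL, "stress") for tp in timepoints
    ]
    rows = {}
    missing = []
    for (gene, tissue) in tolerant_calls:
        cmap = {}
        for cell in cells:
            key = (gene, tissue, cell[0], cell[1])
            if key not in contrast_map:
                missing.append(key)
                continue
            cmap[cell] = contrast_map[key]
        rows[(gene, tissue)] = StateRow(
            gene_id=gene,
            tissue=tissue,
            pattern_tolerant=_pattern(tolerant_calls[(gene, tissue)]),
            pattern_sensitive=_pattern(sensitive_calls[(gene, tissue)]),
            contrasts=cmap,
        )
    if missing:
        raise ValueError(f"contrast coverage gaps for cells: {missing[:5]}")
    return StateMatrix(rows=rows, timepoints=tuple(float(t) for t in timepoints))


def _criterion_label(row: StateRow) -> str:
    """Map a selected Group-1 pattern combination onto the stated criteria."""
    pt, ps = row.pattern_tolerant, row.pattern_sensitive
    if pt == "up" and ps == "unchanged":
        return "criterion_i_iii"
    if pt == "up" and ps == "up":
        return "criterion_ii"
    if pt in ("up", "unchanged") and ps == "down":
        return "criterion_iii"
    return "operational_rule"


def _select_paper(row: StateRow) -> tuple[Group, tuple[str, ...]]:
    calls = row.contrasts
    has_higher = any(c == "higher" for c in calls.values())
    has_lower = any(c == "lower" for c in calls.values())
    control_lower = any(
        c == "lower" for (trt, _), c in calls.items() if trt == CONTROL
    )
    pt, ps = row.pattern_tolerant, row.pattern_sensitive
    tol_down_vs_nondown = pt == "down" and ps in ("up", "unchanged")
    trace: list[str] = []
    if has_higher:
        trace.append("higher_in_some_condition:yes")
        trace.append(
            "no_control_condition_lower:" + ("yes" if not control_lower else "no")
        )
        trace.append(
            "tolerant_not_down_while_sensitive_not_down:"
            + ("yes" if not tol_down_vs_nondown else "no")
        )
        if not control_lower and not tol_down_vs_nondown:
            trace.append(_criterion_label(row))
            return "group1", tuple(trace)
        return "none", tuple(trace)
    trace.append("higher_in_some_condition:no")
    if has_lower:
        trace.append("lower_in_some_condition:yes")
        up_like = ("up", "mixed")
        neither_up = pt not in up_like and ps not in up_like
        trace.append("neither_cultivar_up:" + ("yes" if neither_up else "no"))
        if neither_up:
            trace.append("group2_rule")
            return "group2", tuple(trace)
        return "none", tuple(trace)
    trace.append("lower_in_some_condition:no")
    return "none", tuple(trace)


def _select_literal(row: StateRow) -> tuple[Group, tuple[str, ...]]:
    """Literal transcription of the stated criteria (i)–(iii) and Group 2.

    Criterion (ii)'s "higher up-regulated expression change" is read at the
    expression-level scale (a higher contrast call in some condition); the
    induction-fold reading needs quantitative data that the qualitative state
    matrix does not carry. Group 1 takes precedence over Group 2.
    """
    calls = row.contrasts
    has_higher = any(c == "higher" for c in calls.values())
    has_lower = any(c == "lower" for c in calls.values())
    pt, ps = row.pattern_tolerant, row.pattern_sensitive
    crit_i = pt == "up" and ps == "unchanged" and has_higher
    crit_ii = pt == "up" and ps == "up" and has_higher
    crit_iii = (pt == "up" and ps == "unchanged") or (
        pt in ("up", "unchanged") and ps == "down"
    )
    if crit_i or crit_ii or crit_iii:
        trace = tuple(
            name
            for name, ok in (
                ("criterion_i", crit_i),
                ("criterion_ii", crit_ii),
                ("criterion_iii", crit_iii),
            )
            if ok
        )
        return "group1", trace
    if pt in ("down", "unchanged") and ps in ("down", "unchanged") and has_lower:
        return "group2", ("group2_rule",)
    return "none", ("no_criterion_satisfied",)


def select_candidates(
    matrix: StateMatrix,
    tissue: str,
    design: ExperimentDesign,
    rule_profile: RuleProfile = "paper",
) -> list[CandidateCall]:
    """Apply the selection rules to every gene of one tissue.

    Returns one :class:`CandidateCall` per gene, including the non-selected
    ones (group "none"), each with a predicate trace.
    """
    if tissue not in matrix.tissues():
        raise ValueError(f"tissue {tissue!r} not covered by the state matrix")
    select = {"paper": _select_paper, "literal": _select_literal}[rule_profile]
    out = []
    for gene in matrix.genes(tissue):
        row = matrix.row(gene, tissue)
        group, trace = select(row)
        out.append(CandidateCall(gene_id=gene, tissue=tissue, group=group, trace=trace))
    return out


def candidates_frame(calls: Sequence[CandidateCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "tissue": c.tissue,
                "group": c.group,
                "trace": ";".join(c.trace),
            }
            for c in calls
        ]
    )
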