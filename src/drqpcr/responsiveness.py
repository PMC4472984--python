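"""Dehydration-responsiveness calls: ≥ 2-fold change with one-tailed t-test P < 0.05.

A gene is called up (down) at a timepoint when its stress/control fold change
on the linear scale is at least the threshold (at most its reciprocal) AND the
one-tailed unpaired equal-variance t-test on the replicate values gives
P < alpha. A gene is dehydration-responsive when at least one timepoint is
called; opposite calls at different timepoints give the "mixed" pattern.

The test is applied to ΔCt replicates by default (approximately normal on the
log2 scale); ``test_scale="rq"`` applies it to control-calibrated linear RQ
replicates instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from drqpcr.design import CONTROL, STRESS, ExperimentDesign, SampleKey
from drqpcr.relative_quant import DeltaCtSet

TestScale = Literal["delta_ct", "rq"]

Call = Literal["up", "down", "unchanged"]
Pattern = Literal["up", "down", "mixed", "unchanged"]


@dataclass(frozen=True)
class TimepointCall:
    """Stress-vs-control call of one gene × cultivar × tissue × timepoint."""

    key: SampleKey  # stress-side key
    fold_change: float  # linear, stress vs control
    p_value: float
    call: Call


@dataclass(frozen=True)
class ResponseCall:
    """Overall dehydration-response pattern of one gene × cultivar × tissue."""

    gene_id: str
    cultivar: str
    tissue: str
    timepoint_calls: tuple[TimepointCall, ...]
    pattern: Pattern

    @property
    def responsive(self) -> bool:
        return self.pattern != "unchanged"


def one_tailed_t(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """One-tailed p-value of the unpaired pooled-variance t statistic.

    The tail is taken in the direction of the observed mean difference
    (equivalently, half the two-tailed p). Degenerate inputs: identical
    zero-variance groups give 0.5; zero pooled variance with unequal means
    gives 0.0 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.5
        warnings.warn(
            "zero pooled variance with unequal means; returning p = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return float(stats.t.sf(abs(t), na + nb - 2))


def _classify(fold: float, p: float, design: ExperimentDesign) -> Call:
    thr = design.fold_change_threshold
    if p < design.alpha:
        if fold >= thr:
            return "up"
        if fold <= 1.0 / thr:
            return "down"
    return "unchanged"


def call_timepoint(
    stress: DeltaCtSet,
    control: DeltaCtSet,
    design: ExperimentDesign,
    test_scale: TestScale = "delta_ct",
) -> TimepointCall:
    """Call one gene at one timepoint from its stress and control ΔCt sets.

    Fold change = 2^−(mean ΔCt_stress − mean ΔCt_control); note that a LOWER
    ΔCt means MORE transcript, hence the sign flip.
    """
    ks, kc = stress.key, control.key
    if (ks.gene_id, ks.cultivar, ks.tissue, ks.timepoint_h) != (
        kc.gene_id,
        kc.cultivar,
        kc.tissue,
        kc.timepoint_h,
    ):
        raise ValueError("stress and control sets must share gene/cultivar/tissue/timepoint")
    if ks.treatment != STRESS or kc.treatment != CONTROL:
        raise ValueError("expected a (stress, control) pair of ΔCt sets")
    fold = float(2.0 ** -(stress.mean - control.mean))
    if test_scale == "delta_ct":
        p = one_tailed_t(stress.values, control.values)
    elif test_scale == "rq":
        rq_s = 2.0 ** -(stress.values - control.mean)
        rq_c = 2.0 ** -(control.values - control.mean)
        p = one_tailed_t(rq_s, rq_c)
    else:
        raise ValueError(f"unknown test_scale {test_scale!r}")
    return TimepointCall(
        key=ks, fold_change=fold, p_value=p, call=_classify(fold, p, design)
    )


def classify_gene(calls: Sequence[TimepointCall]) -> ResponseCall:
    """Derive the overall pattern from per-timepoint calls.

    up/down when at least one timepoint is called and all calls agree in
    direction; mixed when both directions occur; unchanged when no timepoint
    is called.
    """
    if not calls:
        raise ValueError("need at least one timepoint call")
    k = calls[0].key
    directions = {c.call for c in calls} - {"unchanged"}
    if directions == {"up", "down"}:
        pattern: Pattern = "mixed"
    elif directions == {"up"}:
        pattern = "up"
    elif directions == {"down"}:
        pattern = "down"
    else:
        pattern = "unchanged"
    return ResponseCall(
        gene_id=k.gene_id,
        cultivar=k.cultivar,
        tissue=k.tissue,
        timepoint_calls=tuple(sorted(calls, key=lambda c: c.key.timepoint_h)),
        pattern=pattern,
    )


def _vectorized_calls(delta: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    """Per-timepoint fold changes, p-values and calls for every gene×cell.

    Vectorized equivalent of :func:`call_timepoint` on the ΔCt scale; used by
    the table driver so thousands of simulated genes call in milliseconds.
    """
    grp_cols = ["gene_id", "cultivar", "tissue", "timepoint_h"]
    agg = (
        delta.groupby(grp_cols + ["treatment"])["delta_ct"]
        .agg(["mean", "var", "count"])
        .unstack("treatment")
    )
    mean_s, mean_c = agg[("mean", STRESS)], agg[("mean", CONTROL)]
    var_s, var_c = agg[("var", STRESS)], agg[("var", CONTROL)]
    n_s, n_c = agg[("count", STRESS)], agg[("count", CONTROL)]
    if mean_s.isna().any() or mean_c.isna().any():
        raise ValueError("every gene cell needs both a stress and a control group")
    if (n_s < 2).any() or (n_c < 2).any():
        raise ValueError("each group needs at least 2 replicates")
    sp2 = ((n_s - 1) * var_s + (n_c - 1) * var_c) / (n_s + n_c - 2)
    diff = mean_s - mean_c
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / n_s + 1.0 / n_c))
    p = pd.Series(
        stats.t.sf(np.abs(t.to_numpy()), (n_s + n_c - 2).to_numpy()), index=t.index
    )
    # degenerate zero-variance cells, as in one_tailed_t
    p[(sp2 == 0) & (diff == 0)] = 0.5
    p[(sp2 == 0) & (diff != 0)] = 0.0
    fold = 2.0 ** -diff
    thr = design.fold_change_threshold
    call = np.where(
        (p < design.alpha) & (fold >= thr),
        "up",
        np.where((p < design.alpha) & (fold <= 1.0 / thr), "down", "unchanged"),
    )
    out = pd.DataFrame(
        {"fold_change": fold, "p_value": p, "call": call}
    ).reset_index()
    return out


def response_table(
    delta: pd.DataFrame,
    design: ExperimentDesign,
    test_scale: TestScale = "delta_ct",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-timepoint calls plus the overall pattern for every gene×cultivar×tissue.

    Columns: gene_id, cultivar, tissue, timepoint_h, fold_change, p_value,
    call, pattern. ``bh_correct`` applies Benjamini–Hochberg across all
    per-timepoint tests before calling (off by default: the screen uses raw
    per-gene p-values).
    """
    delta = delta[delta["gene_id"] != design.reference_gene]
    if test_scale == "delta_ct":
        per_tp = _vectorized_calls(delta, design)
    else:
        from drqpcr.relative_quant import delta_ct_sets

        sets = delta_ct_sets(delta)
        records = []
        for key, s in sets.items():
            if key.treatment != STRESS:
                continue
            ctrl = sets[SampleKey(key.gene_id, key.cultivar, key.tissue, CONTROL, key.timepoint_h)]
            tc = call_timepoint(s, ctrl, design, test_scale=test_scale)
            records.append(
                {
                    "gene_id": key.gene_id,
                    "cultivar": key.cultivar,
                    "tissue": key.tissue,
                    "timepoint_h": key.timepoint_h,
                    "fold_change": tc.fold_change,
                    "p_value": tc.p_value,
                    "call": tc.call,
                }
            )
        per_tp = pd.DataFrame.from_records(records)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(per_tp["p_value"], method="fdr_bh")[1]
        per_tp = per_tp.assign(p_value=adj)
        thr = design.fold_change_threshold
        per_tp["call"] = np.where(
            (per_tp["p_value"] < design.alpha) & (per_tp["fold_change"] >= thr),
            "up",
            np.where(
                (per_tp["p_value"] < design.alpha)
                & (per_tp["fold_change"] <= 1.0 / thr),
                "down",
                "unchanged",
            ),
        )

    def _pattern(calls: pd.Series) -> str:
        d = set(calls) - {"unchanged"}
        if d == {"up", "down"}:
            return "mixed"
        if d:
            return d.pop()
        return "unchanged"

    pattern = (
        per_tp.groupby(["gene_id", "cultivar", "tissue"])["call"]
        .apply(_pattern)
        .rename("pattern")
    )
    out = per_tp.merge(pattern.reset_index(), on=["gene_id", "cultivar", "tissue"])
    return out.sort_values(
        ["cultivar", "tissue", "gene_id", "timepoint_h"], kind="mergesort"
    ).reset_index(drop=True)


def response_calls(
    delta: pd.DataFrame,
    design: ExperimentDesign,
    test_scale: TestScale = "delta_ct",
) -> dict[tuple[str, str, str], ResponseCall]:
    """Structured :class:`ResponseCall` objects keyed by (gene, cultivar, tissue)."""
    table = response_table(delta, design, test_scale=test_scale)
    out: dict[tuple[str, str, str], ResponseCall] = {}
    for (gene, cultivar, tissue), grp in table.groupby(
        ["gene_id", "cultivar", "tissue"]
    ):
        calls = tuple(
            TimepointCall(
                key=SampleKey(gene, cultivar, tissue, STRESS, r.timepoint_h),
                fold_change=r.fold_change,
                p_value=r.p_value,
                call=r.call,
            )
            for r in grp.itertuples()
        )
        out[(gene, cultivar, tissue)] = classify_gene(calls)
    return out
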