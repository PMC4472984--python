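"""Tolerant-vs-sensitive expression contrasts per gene × tissue × condition.

Contrasts are computed from reference-normalized ΔCt, never from
control-calibrated RQ: calibration pins both cultivars' controls to 1 and
would erase genuine between-genotype baseline differences (which the screen
reports, e.g. large control-condition ratios). The ratio is

    ratio = 2^−(mean ΔCt_tolerant − mean ΔCt_sensitive)

and a call of higher/lower requires the ratio to reach the fold threshold
with a one-tailed t-test P < alpha on the two ΔCt sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from drqpcr.design import ExperimentDesign
from drqpcr.relative_quant import DeltaCtSet
from drqpcr.responsiveness import one_tailed_t

ContrastCall = Literal["higher", "lower", "similar"]


@dataclass(frozen=True)
class GenotypeContrast:
    """Tolerant/sensitive expression ratio of one gene × tissue × condition."""

    gene_id: str
    tissue: str
    treatment: str
    timepoint_h: float
    ratio: float  # tolerant / sensitive, linear fold
    p_value: float
    call: ContrastCall


def contrast(
    tolerant: DeltaCtSet, sensitive: DeltaCtSet, design: ExperimentDesign
) -> GenotypeContrast:
    """Contrast two cultivars' ΔCt sets for the same gene/tissue/condition."""
    kt, ks = tolerant.key, sensitive.key
    if (kt.gene_id, kt.tissue, kt.treatment, kt.timepoint_h) != (
        ks.gene_id,
        ks.tissue,
        ks.treatment,
        ks.timepoint_h,
    ):
        raise ValueError("sets must share gene, tissue, treatment and timepoint")
    if kt.cultivar == ks.cultivar:
        raise ValueError("sets must come from different cultivars")
    ratio = float(2.0 ** -(tolerant.mean - sensitive.mean))
    p = one_tailed_t(tolerant.values, sensitive.values)
    thr = design.fold_change_threshold
    if p < design.alpha and ratio >= thr:
        call: ContrastCall = "higher"
    elif p < design.alpha and ratio <= 1.0 / thr:
        call = "lower"
    else:
        call = "similar"
    return GenotypeContrast(
        gene_id=kt.gene_id,
        tissue=kt.tissue,
        treatment=kt.treatment,
        timepoint_h=kt.timepoint_h,
        ratio=ratio,
        p_value=p,
        call=call,
    )


def contrast_table(delta: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    """All per-condition contrasts (vectorized over genes).

    Columns: gene_id, tissue, treatment, timepoint_h, ratio, p_value, call.
    Each of the treatment × timepoint conditions is contrasted independently.
    """
    delta = delta[delta["gene_id"] != design.reference_gene]
    grp_cols = ["gene_id", "tissue", "treatment", "timepoint_h"]
    agg = (
        delta.groupby(grp_cols + ["cultivar"])["delta_ct"]
        .agg(["mean", "var", "count"])
        .unstack("cultivar")
    )
    tol, sen = design.tolerant_cultivar, design.sensitive_cultivar
    for cv in (tol, sen):
        if ("mean", cv) not in agg.columns or agg[("mean", cv)].isna().any():
            raise ValueError(f"cultivar {cv!r} missing for some gene cells")
    mt, ms = agg[("mean", tol)], agg[("mean", sen)]
    vt, vs = agg[("var", tol)], agg[("var", sen)]
    nt, ns = agg[("count", tol)], agg[("count", sen)]
    sp2 = ((nt - 1) * vt + (ns - 1) * vs) / (nt + ns - 2)
    diff = mt - ms
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / nt + 1.0 / ns))
    p = pd.Series(
        stats.t.sf(np.abs(t.to_numpy()), (nt + ns - 2).to_numpy()), index=t.index
    )
    p[(sp2 == 0) & (diff == 0)] = 0.5
    p[(sp2 == 0) & (diff != 0)] = 0.0
    ratio = 2.0 ** -diff
    thr = design.fold_change_threshold
    call = np.where(
        (p < design.alpha) & (ratio >= thr),
        "higher",
        np.where((p < design.alpha) & (ratio <= 1.0 / thr), "lower", "similar"),
    )
    out = pd.DataFrame({"ratio": ratio, "p_value": p, "call": call}).reset_index()
    return out.sort_values(grp_cols, kind="mergesort").reset_index(drop=True)
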