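"""Reference-normalized ΔCt and calibrated 2^-ΔΔCt relative quantities.

Within every sample (one biological replicate of one cultivar × tissue ×
treatment × timepoint cell) the target's quantification cycle is normalized
against the reference gene measured in the same sample:

    ΔCt_i = Cq_target,i − Cq_reference,i

Relative quantity against a calibrator sample (here: the water control of the
same cultivar, tissue and timepoint) follows the Livak 2^-ΔΔCt model. By
default each replicate is calibrated individually and the replicate RQ values
are averaged ("per_replicate"), which is what linear-scale mean ± SE bars over
biological replicates report; ``aggregate="of_means"`` instead exponentiates
the mean ΔΔCt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from drqpcr.design import CONTROL, ExperimentDesign, SampleKey
from drqpcr.qpcr_io import CqTable

Aggregate = Literal["per_replicate", "of_means"]


@dataclass(frozen=True)
class DeltaCtSet:
    """Per-replicate ΔCt values of one experimental cell."""

    key: SampleKey
    delta_ct: tuple[float, ...]

    def __post_init__(self):
        if len(self.delta_ct) < 2:
            raise ValueError(
                f"need >= 2 replicates to estimate variance, got {len(self.delta_ct)} "
                f"for {self.key}"
            )

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.delta_ct, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def n(self) -> int:
        return len(self.delta_ct)


@dataclass(frozen=True)
class RelExpression:
    """Calibrated relative quantity of one cell: mean RQ, SE and n."""

    key: SampleKey
    calibrator: SampleKey
    mean_rq: float
    se_rq: float
    n: int

    def __post_init__(self):
        if self.mean_rq <= 0:
            raise ValueError("mean_rq must be positive")
        if self.se_rq < 0:
            raise ValueError("se_rq must be non-negative")


def compute_delta_ct(table: CqTable, design: ExperimentDesign) -> pd.DataFrame:
    """ΔCt per target gene and biological replicate.

    Returns a tidy frame with columns gene_id, cultivar, tissue, treatment,
    timepoint_h, bio_replicate, delta_ct. The reference gene itself appears
    with all-zero ΔCt.
    """
    df = table.df
    cell_cols = ["cultivar", "tissue", "treatment", "timepoint_h", "bio_replicate"]
    ref = df[df["gene_id"] == design.reference_gene][cell_cols + ["cq"]].rename(
        columns={"cq": "cq_ref"}
    )
    merged = df.merge(ref, on=cell_cols, how="left")
    if merged["cq_ref"].isna().any():
        row = merged[merged["cq_ref"].isna()].iloc[0]
        raise ValueError(
            f"reference gene missing for replicate {int(row['bio_replicate'])} of "
            f"{row['cultivar']}/{row['tissue']}/{row['treatment']}/{row['timepoint_h']}h"
        )
    merged["delta_ct"] = merged["cq"] - merged["cq_ref"]
    out = merged[["gene_id"] + cell_cols + ["delta_ct"]]
    return out.sort_values(["gene_id"] + cell_cols, kind="mergesort").reset_index(
        drop=True
    )


def delta_ct_sets(delta: pd.DataFrame) -> dict[SampleKey, DeltaCtSet]:
    """Group a tidy ΔCt frame into per-cell :class:`DeltaCtSet` objects."""
    sets: dict[SampleKey, DeltaCtSet] = {}
    cols = ["gene_id", "cultivar", "tissue", "treatment", "timepoint_h"]
    for key_vals, grp in delta.groupby(cols, sort=True):
        key = SampleKey(*key_vals)
        grp = grp.sort_values("bio_replicate")
        sets[key] = DeltaCtSet(key=key, delta_ct=tuple(grp["delta_ct"]))
    return sets


def compute_rq(
    target: DeltaCtSet,
    calibrator: DeltaCtSet,
    aggregate: Aggregate = "per_replicate",
) -> RelExpression:
    """Calibrated 2^-ΔΔCt relative quantity of ``target`` vs ``calibrator``.

    Per replicate i, rq_i = 2^−(ΔCt_i − mean ΔCt_calibrator). The reported
    mean is the average of the rq_i (or 2^−(mean ΔΔCt) for ``of_means``);
    SE is sd(rq_i)/√n. A self-calibrated cell reports mean_rq = 1 exactly,
    matching the normalized-to-1 convention of control bars.
    """
    if target.key.gene_id != calibrator.key.gene_id:
        raise ValueError("target and calibrator must be the same gene")
    if (target.key.cultivar, target.key.tissue) != (
        calibrator.key.cultivar,
        calibrator.key.tissue,
    ):
        raise ValueError("target and calibrator must share cultivar and tissue")
    rq_i = 2.0 ** -(target.values - calibrator.mean)
    se = float(rq_i.std(ddof=1) / np.sqrt(target.n))
    if target.key == calibrator.key:
        mean = 1.0
    elif aggregate == "per_replicate":
        mean = float(rq_i.mean())
    elif aggregate == "of_means":
        mean = float(2.0 ** -(target.mean - calibrator.mean))
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    return RelExpression(
        key=target.key, calibrator=calibrator.key, mean_rq=mean, se_rq=se, n=target.n
    )


def relative_expression_table(
    delta: pd.DataFrame,
    design: ExperimentDesign,
    aggregate: Aggregate = "per_replicate",
) -> pd.DataFrame:
    """Mean RQ ± SE for every cell, calibrated to the same-cultivar,
    same-tissue, same-timepoint control.

    Columns: gene_id, cultivar, tissue, treatment, timepoint_h, mean_rq,
    se_rq, n.
    """
    sets = delta_ct_sets(delta)
    records = []
    for key, target in sets.items():
        cal_key = SampleKey(
            key.gene_id, key.cultivar, key.tissue, CONTROL, key.timepoint_h
        )
        if cal_key not in sets:
            raise ValueError(f"no control calibrator for {key}")
        rel = compute_rq(target, sets[cal_key], aggregate=aggregate)
        records.append(
            {
                "gene_id": key.gene_id,
                "cultivar": key.cultivar,
                "tissue": key.tissue,
                "treatment": key.treatment,
                "timepoint_h": key.timepoint_h,
                "mean_rq": rel.mean_rq,
                "se_rq": rel.se_rq,
                "n": rel.n,
            }
        )
    return pd.DataFrame.from_records(records)
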