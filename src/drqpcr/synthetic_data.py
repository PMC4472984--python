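"""Synthetic Cq generator with programmed ground truth.

The generator emulates a two-genotype dehydration RT-qPCR screen: for every
(cultivar, tissue, treatment, timepoint, replicate) cell one reference-gene
Cq is sampled and shared by all target genes of that cell (so reference noise
cancels within a replicate, mirroring same-sample normalization), and each
target Cq is

    Cq = Cq_reference + baseline ΔCt [− true_log2fc if stress] + N(0, noise_sd)

Noise is additive Gaussian on the Cq (log2) scale, the standard qPCR error
model. ``paper_scenario`` returns a spec whose noiseless truth table
reproduces the packaged qualitative call matrix, using printed fold
magnitudes where available and |log2FC| = 2 placeholders elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from drqpcr.design import CONTROL, STRESS, ExperimentDesign
from drqpcr.qpcr_io import CQ_COLUMNS, CqTable

#: map key: (gene_id, cultivar, tissue, timepoint_h)
MapKey = tuple[str, str, str, float]


@dataclass(frozen=True)
class ScenarioSpec:
    """Fully specified ground truth for a simulated Cq table.

    ``baseline_ct`` holds the control-condition target ΔCt per gene ×
    cultivar × tissue × timepoint (keeping the timepoint lets control-condition
    genotype contrasts differ between sampling times, as real screens report);
    ``true_log2fc`` the programmed stress-vs-control log2 fold change for the
    same keys. Both maps must cover the full declared design.
    """

    genes: tuple[str, ...]
    cultivars: tuple[str, ...]
    tissues: tuple[str, ...]
    timepoints: tuple[float, ...]
    baseline_ct: Mapping[MapKey, float]
    true_log2fc: Mapping[MapKey, float]
    n_replicates: int = 3
    reference_ct: float = 20.0
    noise_sd: float = 0.25
    seed: int = 0
    reference_gene: str = "IF4a"
    placeholder_cells: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates for variance estimation")
        if self.reference_gene in self.genes:
            raise ValueError("reference gene cannot also be a target gene")
        for name, m in (("baseline_ct", self.baseline_ct), ("true_log2fc", self.true_log2fc)):
            for g in self.genes:
                for cv in self.cultivars:
                    for ti in self.tissues:
                        for tp in self.timepoints:
                            if (g, cv, ti, tp) not in m:
                                raise ValueError(
                                    f"{name} does not cover ({g}, {cv}, {ti}, {tp})"
                                )

    def design(self, **overrides) -> ExperimentDesign:
        """An :class:`ExperimentDesign` matching this scenario."""
        tol = self.cultivars[0]
        sen = self.cultivars[1] if len(self.cultivars) > 1 else tol + "_other"
        kw = dict(
            reference_gene=self.reference_gene,
            tolerant_cultivar=tol,
            sensitive_cultivar=sen,
            timepoints=self.timepoints,
        )
        kw.update(overrides)
        return ExperimentDesign(**kw)

    def to_yaml(self, path: str | Path) -> None:
        def records(m: Mapping[MapKey, float]):
            return [
                {"gene_id": g, "cultivar": cv, "tissue": ti, "timepoint_h": tp, "value": float(v)}
                for (g, cv, ti, tp), v in sorted(m.items())
            ]

        data = {
            "genes": list(self.genes),
            "cultivars": list(self.cultivars),
            "tissues": list(self.tissues),
            "timepoints": [float(t) for t in self.timepoints],
            "n_replicates": self.n_replicates,
            "reference_ct": self.reference_ct,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "reference_gene": self.reference_gene,
            "baseline_ct": records(self.baseline_ct),
            "true_log2fc": records(self.true_log2fc),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        raw = yaml.safe_load(Path(path).read_text())

        def to_map(recs):
            return {
                (r["gene_id"], r["cultivar"], r["tissue"], float(r["timepoint_h"])): float(
                    r["value"]
                )
                for r in recs
            }

        return cls(
            genes=tuple(raw["genes"]),
            cultivars=tuple(raw["cultivars"]),
            tissues=tuple(raw["tissues"]),
            timepoints=tuple(float(t) for t in raw["timepoints"]),
            baseline_ct=to_map(raw["baseline_ct"]),
            true_log2fc=to_map(raw["true_log2fc"]),
            n_replicates=int(raw["n_replicates"]),
            reference_ct=float(raw["reference_ct"]),
            noise_sd=float(raw["noise_sd"]),
            seed=int(raw["seed"]),
            reference_gene=raw["reference_gene"],
        )


def bulk_scenario(
    n_genes: int,
    log2fc: float | Sequence[float],
    noise_sd: float = 0.25,
    seed: int = 0,
    n_replicates: int = 3,
) -> ScenarioSpec:
    """Single-cultivar, single-tissue, single-timepoint scenario for
    statistical calibration runs (null rate, recovery, bias)."""
    genes = tuple(f"g{i:05d}" for i in range(n_genes))
    fcs = np.broadcast_to(np.asarray(log2fc, dtype=float), (n_genes,))
    baseline = {(g, "ILC482", "root", 2.0): 3.0 for g in genes}
    l2fc = {(g, "ILC482", "root", 2.0): float(f) for g, f in zip(genes, fcs)}
    return ScenarioSpec(
        genes=genes,
        cultivars=("ILC482",),
        tissues=("root",),
        timepoints=(2.0,),
        baseline_ct=baseline,
        true_log2fc=l2fc,
        noise_sd=noise_sd,
        seed=seed,
        n_replicates=n_replicates,
    )


def simulate_cq(spec: ScenarioSpec) -> CqTable:
    """Draw a Cq table from the scenario; byte-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    reps = range(1, spec.n_replicates + 1)
    cells = pd.MultiIndex.from_product(
        [spec.cultivars, spec.tissues, (CONTROL, STRESS), spec.timepoints, reps],
        names=["cultivar", "tissue", "treatment", "timepoint_h", "bio_replicate"],
    ).to_frame(index=False)
    cells["ref_cq"] = spec.reference_ct + rng.normal(0.0, spec.noise_sd, len(cells))

    rows = cells.merge(pd.DataFrame({"gene_id": list(spec.genes)}), how="cross")
    key = list(
        zip(rows["gene_id"], rows["cultivar"], rows["tissue"], rows["timepoint_h"])
    )
    rows["baseline"] = [spec.baseline_ct[k] for k in key]
    rows["l2fc"] = [spec.true_log2fc[k] for k in key]
    stress = (rows["treatment"] == STRESS).to_numpy()
    rows["cq"] = (
        rows["ref_cq"]
        + rows["baseline"]
        - np.where(stress, rows["l2fc"], 0.0)
        + rng.normal(0.0, spec.noise_sd, len(rows))
    )
    ref_rows = cells.rename(columns={"ref_cq": "cq"}).assign(gene_id=spec.reference_gene)
    df = pd.concat([rows[CQ_COLUMNS], ref_rows[CQ_COLUMNS]], ignore_index=True)
    df = df.sort_values(CQ_COLUMNS[:-1], kind="mergesort").reset_index(drop=True)
    return CqTable(df, spec.design())


@dataclass(frozen=True)
class TruthTable:
    """Calls implied analytically by a scenario at zero noise.

    p-values are treated as 0 for any nonzero programmed effect and as the
    null value otherwise, so calls are gated by the fold threshold alone.
    """

    timepoint_calls: Mapping[tuple[str, str, str, float], str]
    patterns: Mapping[tuple[str, str, str], str]
    contrast_calls: Mapping[tuple[str, str, str, float], str]

    def state_matrix(self, spec: ScenarioSpec, design: ExperimentDesign):
        from drqpcr.candidate_selection import StateMatrix, StateRow

        rows = {}
        for g in spec.genes:
            for ti in spec.tissues:
                contrasts = {
                    (trt, tp): self.contrast_calls[(g, ti, trt, tp)]
                    for trt in (CONTROL, STRESS)
                    for tp in spec.timepoints
                }
                rows[(g, ti)] = StateRow(
                    gene_id=g,
                    tissue=ti,
                    pattern_tolerant=self.patterns[(g, design.tolerant_cultivar, ti)],
                    pattern_sensitive=self.patterns[(g, design.sensitive_cultivar, ti)],
                    contrasts=contrasts,
                )
        return StateMatrix(rows=rows, timepoints=spec.timepoints)


def derive_truth_table(spec: ScenarioSpec, design: ExperimentDesign) -> TruthTable:
    """Threshold rules applied analytically to the noiseless means."""
    lthr = design.log2_threshold
    tp_calls = {}
    patterns = {}
    for g in spec.genes:
        for cv in spec.cultivars:
            for ti in spec.tissues:
                dirs = set()
                for tp in spec.timepoints:
                    fc = spec.true_log2fc[(g, cv, ti, tp)]
                    if fc >= lthr:
                        call = "up"
                    elif fc <= -lthr:
                        call = "down"
                    else:
                        call = "unchanged"
                    tp_calls[(g, cv, ti, tp)] = call
                    dirs.add(call)
                dirs -= {"unchanged"}
                if dirs == {"up", "down"}:
                    patterns[(g, cv, ti)] = "mixed"
                elif dirs:
                    patterns[(g, cv, ti)] = dirs.pop()
                else:
                    patterns[(g, cv, ti)] = "unchanged"
    contrast_calls = {}
    tol, sen = design.tolerant_cultivar, design.sensitive_cultivar
    if tol in spec.cultivars and sen in spec.cultivars:
        for g in spec.genes:
            for ti in spec.tissues:
                for tp in spec.timepoints:
                    d = spec.baseline_ct[(g, sen, ti, tp)] - spec.baseline_ct[(g, tol, ti, tp)]
                    for trt in (CONTROL, STRESS):
                        s = d
                        if trt == STRESS:
                            s += (
                                spec.true_log2fc[(g, tol, ti, tp)]
                                - spec.true_log2fc[(g, sen, ti, tp)]
                            )
                        if s >= lthr:
                            call = "higher"
                        elif s <= -lthr:
                            call = "lower"
                        else:
                            call = "similar"
                        contrast_calls[(g, ti, trt, tp)] = call
    return TruthTable(
        timepoint_calls=tp_calls, patterns=patterns, contrast_calls=contrast_calls
    )


# ---------------------------------------------------------------------------
# Published-screen scenario
# ---------------------------------------------------------------------------

# printed stress/control fold magnitudes (log2), tolerant cultivar
_L2FC_PRINTED: dict[tuple[str, str, float], float] = {
    ("CaNAC27", "root", 5.0): math.log2(300.0),
    ("CaNAC67", "leaf", 5.0): math.log2(400.0),
    ("CaNAC02", "root", 5.0): -math.log2(17.5),
    ("CaNAC02", "leaf", 5.0): -math.log2(9.2),
    ("CaNAC24", "leaf", 2.0): -math.log2(3.8),
    ("CaNAC24", "leaf", 5.0): math.log2(2.1),
    ("CaNAC46", "root", 5.0): -math.log2(3.9),
    ("CaNAC46", "leaf", 2.0): math.log2(3.3),
}

# printed tolerant/sensitive contrast magnitudes (log2)
_CONTRAST_PRINTED: dict[tuple[str, str, str, float], float] = {
    ("CaNAC16", "root", CONTROL, 2.0): math.log2(20.73),
    ("CaNAC16", "root", CONTROL, 5.0): math.log2(18.68),
    ("CaNAC16", "root", STRESS, 2.0): math.log2(10.15),
    ("CaNAC16", "root", STRESS, 5.0): math.log2(13.55),
    ("CaNAC16", "leaf", CONTROL, 2.0): math.log2(17.31),
    ("CaNAC16", "leaf", CONTROL, 5.0): math.log2(9.51),
    ("CaNAC16", "leaf", STRESS, 2.0): math.log2(86.42),
    ("CaNAC16", "leaf", STRESS, 5.0): math.log2(120.26),
    ("CaNAC02", "root", CONTROL, 2.0): -math.log2(10.36),
    ("CaNAC02", "root", CONTROL, 5.0): -math.log2(6.48),
    ("CaNAC02", "root", STRESS, 2.0): -math.log2(12.27),
    ("CaNAC02", "root", STRESS, 5.0): -math.log2(18.29),
    ("CaNAC02", "leaf", CONTROL, 2.0): -math.log2(13.64),
    ("CaNAC02", "leaf", CONTROL, 5.0): -math.log2(16.87),
    ("CaNAC02", "leaf", STRESS, 2.0): -math.log2(9.38),
    ("CaNAC02", "leaf", STRESS, 5.0): -math.log2(6.48),
}

# log2 ranges each qualitative state may occupy (threshold 2-fold, inclusive;
# sub-threshold states stay below |log2| = 0.9 to keep clear of the boundary)
_RANGES = {
    "up": (1.0, 12.0),
    "down": (-12.0, -1.0),
    "none": (-0.9, 0.9),
    "higher": (1.0, 12.0),
    "lower": (-12.0, -1.0),
    "similar": (-0.9, 0.9),
}
_MID = {"up": 2.0, "down": -2.0, "none": 0.0, "higher": 2.0, "lower": -2.0, "similar": 0.0}


def _in(x: float, state: str) -> bool:
    lo, hi = _RANGES[state]
    return lo <= x <= hi


def _clamp(x: float, state: str) -> float:
    lo, hi = _RANGES[state]
    return min(max(x, lo), hi)


def _solve_cell(
    d0: float,
    lt0: float,
    ls0: float,
    ctrl_call: str,
    stress_call: str,
    dir_tol: str,
    dir_sens: str,
    s_printed: float | None,
    d_printed: bool,
    lt_printed: bool,
) -> tuple[float, float, float]:
    """Find (baseline diff d, tolerant l2fc, sensitive l2fc) consistent with
    the qualitative cell: control contrast = d, stress contrast = d + lt − ls.

    Starts from printed/default magnitudes and adjusts the least-constrained
    quantities first: the (never-printed) sensitive fold, then whichever of
    the baseline diff / tolerant fold is not anchored by a printed value.
    """
    s = d0 + lt0 - ls0
    if s_printed is None and _in(s, stress_call):
        return d0, lt0, ls0
    target = s_printed if s_printed is not None else _MID[stress_call]
    ls = d0 + lt0 - target
    if _in(ls, dir_sens):
        return d0, lt0, ls
    ls = _clamp(ls, dir_sens)
    # preserve printed magnitudes: adjust the non-printed quantity first
    order = ("lt", "d") if d_printed and not lt_printed else ("d", "lt") if lt_printed and not d_printed else ("lt", "d")
    d, lt = d0, lt0
    for quantity in order:
        if quantity == "lt":
            lt = target - d + ls
            if _in(lt, dir_tol):
                return d, lt, ls
            lt = _clamp(lt, dir_tol)
        else:
            d = target - lt + ls
            if _in(d, ctrl_call):
                return d, lt, ls
            d = _clamp(d, ctrl_call)
    if abs((d + lt - ls) - target) < 1e-9 or (
        s_printed is None and _in(d + lt - ls, stress_call)
    ):
        return d, lt, ls
    raise ValueError(
        "no (baseline, fold-change) assignment reproduces the cell "
        f"(ctrl={ctrl_call}, stress={stress_call}, tol={dir_tol}, sens={dir_sens})"
    )


def paper_scenario(noise_sd: float = 0.25, seed: int = 2015) -> ScenarioSpec:
    """Scenario reproducing the packaged 19-gene × 2-tissue call matrix.

    At zero noise the derived truth table matches the packaged qualitative
    matrix on every non-ambiguous cell. Printed fold magnitudes anchor the
    cells that report them; all remaining effects are |log2FC| = 2
    placeholders (0 for unchanged/similar), recorded in
    ``placeholder_cells``.
    """
    from drqpcr.qpcr_io import load_paper_call_table

    table = load_paper_call_table()
    genes = tuple(sorted(table["gene_id"].unique()))
    tol, sen = "ILC482", "Hashem"
    timepoints = (2.0, 5.0)
    baseline: dict[MapKey, float] = {}
    l2fc: dict[MapKey, float] = {}
    placeholders: set[tuple] = set()
    gene_index = {g: i for i, g in enumerate(genes)}
    for _, r in table.iterrows():
        g, ti = r["gene_id"], r["tissue"]
        base_tol = 2.0 + 0.15 * gene_index[g]  # arbitrary absolute level
        for tp, suffix in ((2.0, "2h"), (5.0, "5h")):
            dir_tol = r[f"dir_tol_{suffix}"]
            dir_sens = r[f"dir_sens_{suffix}"]
            ctrl_call = r[f"contrast_control_{suffix}"]
            stress_call = r[f"contrast_stress_{suffix}"]
            d0 = _CONTRAST_PRINTED.get((g, ti, CONTROL, tp), _MID[ctrl_call])
            lt0 = _L2FC_PRINTED.get((g, ti, tp), _MID[dir_tol])
            ls0 = _MID[dir_sens]
            s_printed = _CONTRAST_PRINTED.get((g, ti, STRESS, tp))
            d, lt, ls = _solve_cell(
                d0, lt0, ls0, ctrl_call, stress_call, dir_tol, dir_sens, s_printed,
                d_printed=(g, ti, CONTROL, tp) in _CONTRAST_PRINTED,
                lt_printed=(g, ti, tp) in _L2FC_PRINTED,
            )
            baseline[(g, tol, ti, tp)] = base_tol
            baseline[(g, sen, ti, tp)] = base_tol + d
            l2fc[(g, tol, ti, tp)] = lt
            l2fc[(g, sen, ti, tp)] = ls
            if (g, ti, tp) not in _L2FC_PRINTED:
                placeholders.add(("log2fc", g, tol, ti, tp))
            placeholders.add(("log2fc", g, sen, ti, tp))
            if (g, ti, CONTROL, tp) not in _CONTRAST_PRINTED:
                placeholders.add(("baseline", g, ti, tp))
    return ScenarioSpec(
        genes=genes,
        cultivars=(tol, sen),
        tissues=("leaf", "root"),
        timepoints=timepoints,
        baseline_ct=baseline,
        true_log2fc=l2fc,
        noise_sd=noise_sd,
        seed=seed,
        placeholder_cells=frozenset(placeholders),
    )
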