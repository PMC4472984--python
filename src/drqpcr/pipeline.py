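"""End-to-end orchestration: quantify → respond/contrast → venn → select.

Each stage writes a fixed-name TSV into the output directory so downstream
tooling and tests can rely on stable paths:

    simulated_cq.csv (simulate only), relative_expression.tsv,
    response_calls.tsv, contrasts.tsv, venn.tsv, candidates.tsv, summary.tsv
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from drqpcr.design import ExperimentDesign
from drqpcr.qpcr_io import CqTable, read_cq_table, write_report
from drqpcr.relative_quant import compute_delta_ct, relative_expression_table
from drqpcr.responsiveness import response_table
from drqpcr.genotype_comparison import contrast_table
from drqpcr.set_analysis import venn_partition
from drqpcr.candidate_selection import (
    build_state_matrix,
    candidates_frame,
    select_candidates,
)

log = logging.getLogger("drqpcr")

STAGES = ("simulate", "quantify", "respond", "contrast", "venn", "select")

STAGE_FILES = {
    "simulate": ("simulated_cq.csv",),
    "quantify": ("relative_expression.tsv",),
    "respond": ("response_calls.tsv",),
    "contrast": ("contrasts.tsv",),
    "venn": ("venn.tsv",),
    "select": ("candidates.tsv", "summary.tsv"),
}

_DEPENDS = {
    "quantify": (),
    "respond": (),
    "contrast": (),
    "venn": ("respond",),
    "select": ("respond", "contrast"),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    input: Path | None = None  # Cq CSV; None requires the simulate stage
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    stages: Sequence[str] = STAGES[1:]
    rule_profile: str = "paper"
    test_scale: str = "delta_ct"
    aggregate: str = "per_replicate"
    noise_sd: float = 0.25
    seed: int = 0
    force: bool = False

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        order = {s: i for i, s in enumerate(STAGES)}
        if list(self.stages) != sorted(self.stages, key=order.__getitem__):
            raise ValueError("stages must respect dependency order " + " -> ".join(STAGES))
        for s in self.stages:
            missing = set(_DEPENDS.get(s, ())) - set(self.stages)
            if missing:
                raise ValueError(f"stage {s!r} requires {sorted(missing)}")


def _load_table(config: RunConfig) -> CqTable:
    if "simulate" in config.stages:
        from drqpcr.synthetic_data import paper_scenario, simulate_cq
        from dataclasses import replace

        spec = paper_scenario(noise_sd=config.noise_sd, seed=config.seed)
        log.info("simulating published-design scenario (noise_sd=%g, seed=%d)",
                 config.noise_sd, config.seed)
        table = simulate_cq(spec)
        table.write_csv(config.out_dir / "simulated_cq.csv")
        return table
    if config.input is None:
        raise ValueError("either an input Cq CSV or the simulate stage is required")
    return read_cq_table(config.input, config.design)


def run_all(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the requested stages; returns the stage outputs keyed by name.

    Existing output files abort the run unless ``force`` is set, so partial
    results are never silently overwritten.
    """
    design = config.design
    config.out_dir.mkdir(parents=True, exist_ok=True)
    if not config.force:
        clashes = [
            f
            for s in config.stages
            for f in STAGE_FILES[s]
            if (config.out_dir / f).exists()
        ]
        if clashes:
            raise FileExistsError(
                f"output files exist (use force to overwrite): {clashes}"
            )
    log.info(
        "thresholds: fold_change >= %g, alpha = %g, reference gene = %s",
        design.fold_change_threshold,
        design.alpha,
        design.reference_gene,
    )
    table = _load_table(config)
    delta = compute_delta_ct(table, design)
    outputs: dict[str, pd.DataFrame] = {}

    if "quantify" in config.stages:
        rel = relative_expression_table(delta, design, aggregate=config.aggregate)
        write_report(rel, config.out_dir / "relative_expression.tsv")
        outputs["quantify"] = rel
        log.info("quantify: %d cells", len(rel))

    responses = None
    if "respond" in config.stages:
        responses = response_table(delta, design, test_scale=config.test_scale)
        write_report(responses, config.out_dir / "response_calls.tsv")
        outputs["respond"] = responses
        n_resp = (
            responses.drop_duplicates(["gene_id", "cultivar", "tissue"])["pattern"]
            != "unchanged"
        ).sum()
        log.info("respond: %d responsive gene×cultivar×tissue combinations", n_resp)

    contrasts = None
    if "contrast" in config.stages:
        contrasts = contrast_table(delta, design)
        write_report(contrasts, config.out_dir / "contrasts.tsv")
        outputs["contrast"] = contrasts
        log.info("contrast: %d condition contrasts", len(contrasts))

    if "venn" in config.stages:
        tol = responses[responses["cultivar"] == design.tolerant_cultivar]
        pat = tol.drop_duplicates(["gene_id", "tissue"])
        tissues = set(pat["tissue"])
        if not {"root", "leaf"} <= tissues:
            raise ValueError("venn stage needs both root and leaf tissues")
        root = dict(pat[pat["tissue"] == "root"][["gene_id", "pattern"]].values)
        leaf = dict(pat[pat["tissue"] == "leaf"][["gene_id", "pattern"]].values)
        partition = venn_partition(root, leaf)
        write_report(partition.to_frame(), config.out_dir / "venn.tsv")
        outputs["venn"] = partition.to_frame()
        log.info(
            "venn: up_both=%d down_both=%d excluded_mixed=%d",
            len(partition.up_both),
            len(partition.down_both),
            len(partition.excluded_mixed),
        )

    if "select" in config.stages:
        pat = responses.drop_duplicates(["gene_id", "cultivar", "tissue"])
        tol_calls = {
            (r.gene_id, r.tissue): r.pattern
            for r in pat[pat["cultivar"] == design.tolerant_cultivar].itertuples()
        }
        sen_calls = {
            (r.gene_id, r.tissue): r.pattern
            for r in pat[pat["cultivar"] == design.sensitive_cultivar].itertuples()
        }
        matrix = build_state_matrix(
            tol_calls, sen_calls, contrasts, timepoints=design.timepoints
        )
        frames = []
        for tissue in matrix.tissues():
            calls = select_candidates(
                matrix, tissue, design, rule_profile=config.rule_profile
            )
            frames.append(candidates_frame(calls))
        cands = pd.concat(frames, ignore_index=True)
        write_report(cands, config.out_dir / "candidates.tsv")
        outputs["select"] = cands
        summary = _summary(responses, outputs.get("venn"), cands, design)
        write_report(summary, config.out_dir / "summary.tsv")
        outputs["summary"] = summary
        for tissue in matrix.tissues():
            sel = cands[(cands["tissue"] == tissue) & (cands["group"] != "none")]
            log.info(
                "select (%s): group1=%s group2=%s",
                tissue,
                sorted(sel[sel["group"] == "group1"]["gene_id"]),
                sorted(sel[sel["group"] == "group2"]["gene_id"]),
            )
    return outputs


def _summary(
    responses: pd.DataFrame,
    venn: pd.DataFrame | None,
    candidates: pd.DataFrame,
    design: ExperimentDesign,
) -> pd.DataFrame:
    rows = []
    for (cv, ti, tp), grp in responses.groupby(["cultivar", "tissue", "timepoint_h"]):
        for call in ("up", "down"):
            rows.append(
                {
                    "metric": f"n_{call}",
                    "scope": f"{cv}/{ti}/{tp:g}h",
                    "value": int((grp["call"] == call).sum()),
                }
            )
    pat = responses.drop_duplicates(["gene_id", "cultivar", "tissue"])
    for (cv, ti), grp in pat.groupby(["cultivar", "tissue"]):
        rows.append(
            {
                "metric": "n_responsive",
                "scope": f"{cv}/{ti}",
                "value": int((grp["pattern"] != "unchanged").sum()),
            }
        )
    if venn is not None:
        for label, grp in venn.groupby("partition"):
            rows.append({"metric": f"venn_{label}", "scope": design.tolerant_cultivar,
                         "value": len(grp)})
    for (ti, group), grp in candidates[candidates["group"] != "none"].groupby(
        ["tissue", "group"]
    ):
        rows.append(
            {
                "metric": f"n_{group}",
                "scope": ti,
                "value": len(grp),
            }
        )
    return pd.DataFrame(rows, columns=["metric", "scope", "value"])
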