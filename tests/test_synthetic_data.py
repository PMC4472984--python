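"""Ground-truth generator: determinism, truth tables, published-design scenario."""

import numpy as np
import pandas as pd
import pytest

from drqpcr.design import CONTROL, STRESS
from drqpcr.qpcr_io import CQ_COLUMNS
from drqpcr.relative_quant import compute_delta_ct
from drqpcr.responsiveness import response_table
from drqpcr.genotype_comparison import contrast_table
from drqpcr.synthetic_data import (
    ScenarioSpec,
    bulk_scenario,
    derive_truth_table,
    paper_scenario,
    simulate_cq,
)


def test_same_seed_identical_different_seed_not():
    spec = bulk_scenario(8, log2fc=1.0, noise_sd=0.3, seed=21)
    t1, t2 = simulate_cq(spec), simulate_cq(spec)
    pd.testing.assert_frame_equal(t1.df, t2.df)
    from dataclasses import replace

    t3 = simulate_cq(replace(spec, seed=22))
    assert not t1.df["cq"].equals(t3.df["cq"])


def test_reference_noise_shared_within_cell():
    spec = bulk_scenario(4, log2fc=0.0, noise_sd=0.5, seed=3)
    df = simulate_cq(spec).df
    ref = df[df["gene_id"] == spec.reference_gene]
    # one reference Cq per cell, shared by construction
    assert ref.groupby(["treatment", "bio_replicate"])["cq"].nunique().eq(1).all()


def test_invalid_spec_rejected_before_sampling():
    with pytest.raises(ValueError, match="cover"):
        ScenarioSpec(
            genes=("g1",), cultivars=("A",), tissues=("root",), timepoints=(2.0,),
            baseline_ct={}, true_log2fc={},
        )
    with pytest.raises(ValueError, match="noise_sd"):
        bulk_scenario(2, log2fc=0.0, noise_sd=-1.0)


def test_truth_table_boundary_semantics(design):
    spec = bulk_scenario(2, log2fc=[1.0, 0.0], seed=0)
    truth = derive_truth_table(spec, design)
    assert truth.timepoint_calls[("g00000", "ILC482", "root", 2.0)] == "up"  # inclusive
    assert truth.timepoint_calls[("g00001", "ILC482", "root", 2.0)] == "unchanged"
    assert truth.patterns[("g00001", "ILC482", "root")] == "unchanged"


def test_random_spec_truth_equals_zero_noise_pipeline(design):
    """Analytic truth table vs actually running the pipeline on a noiseless
    draw, over random effects kept away from the decision boundary."""
    rng = np.random.default_rng(17)
    genes = tuple(f"g{i}" for i in range(40))
    cultivars = ("ILC482", "Hashem")

    def eff():
        x = rng.uniform(-4, 4)
        while min(abs(abs(x) - 1.0), abs(x)) < 0.05:  # avoid threshold/null edges
            x = rng.uniform(-4, 4)
        return round(x, 3)

    baseline, l2fc = {}, {}
    for g in genes:
        for cv in cultivars:
            for tp in (2.0, 5.0):
                baseline[(g, cv, "root", tp)] = 3.0 + eff()
                l2fc[(g, cv, "root", tp)] = eff()
    spec = ScenarioSpec(
        genes=genes, cultivars=cultivars, tissues=("root",), timepoints=(2.0, 5.0),
        baseline_ct=baseline, true_log2fc=l2fc, noise_sd=0.0, seed=5,
    )
    truth = derive_truth_table(spec, design)
    delta = compute_delta_ct(simulate_cq(spec), design)
    resp = response_table(delta, design)
    contr = contrast_table(delta, design)
    for row in resp.itertuples():
        assert row.call == truth.timepoint_calls[
            (row.gene_id, row.cultivar, row.tissue, row.timepoint_h)
        ]
        assert row.pattern == truth.patterns[(row.gene_id, row.cultivar, row.tissue)]
    for row in contr.itertuples():
        assert row.call == truth.contrast_calls[
            (row.gene_id, row.tissue, row.treatment, row.timepoint_h)
        ]


def test_recovery_rate_matches_independent_reimplementation(design):
    """Directional-call recovery under noise, cross-checked against a plain
    re-implementation of both the generator and the caller (numpy + scipy
    only, no package code)."""
    n, l2fc, sd, reps = 300, 2.0, 0.25, 3
    spec = bulk_scenario(n, log2fc=l2fc, noise_sd=sd, seed=31)
    delta = compute_delta_ct(simulate_cq(spec), design)
    resp = response_table(delta, design)
    rate_pkg = (resp["call"] == "up").mean()

    from scipy import stats

    rng = np.random.default_rng(131)
    hits = 0
    for _ in range(n):
        dct_c = 3.0 + rng.normal(0, sd, reps)
        dct_s = 3.0 - l2fc + rng.normal(0, sd, reps)
        fold = 2.0 ** -(dct_s.mean() - dct_c.mean())
        t, p2 = stats.ttest_ind(dct_s, dct_c, equal_var=True)
        hits += fold >= 2.0 and p2 / 2 < 0.05
    rate_ind = hits / n
    assert rate_pkg == pytest.approx(rate_ind, abs=0.05)


class TestPaperScenario:
    def test_design_dimensions(self):
        spec = paper_scenario()
        assert len(spec.genes) == 19
        assert spec.cultivars == ("ILC482", "Hashem")
        assert set(spec.tissues) == {"leaf", "root"}
        assert spec.n_replicates == 3

    def test_printed_magnitudes_anchor_the_truth(self):
        spec = paper_scenario()
        assert 2.0 ** spec.true_log2fc[("CaNAC27", "ILC482", "root", 5.0)] >= 299.99
        assert 2.0 ** spec.true_log2fc[("CaNAC67", "ILC482", "leaf", 5.0)] >= 399.99
        assert 2.0 ** -spec.true_log2fc[("CaNAC02", "ILC482", "root", 5.0)] == pytest.approx(17.5)
        # mixed-pattern gene: repressed at 2 h, induced at 5 h
        assert spec.true_log2fc[("CaNAC24", "ILC482", "leaf", 2.0)] == pytest.approx(-np.log2(3.8))
        assert spec.true_log2fc[("CaNAC24", "ILC482", "leaf", 5.0)] == pytest.approx(np.log2(2.1))
        assert spec.placeholder_cells  # unprinted effects are flagged

    def test_truth_table_reproduces_packaged_matrix(self, paper_matrix, design):
        spec = paper_scenario(noise_sd=0.0)
        matrix = derive_truth_table(spec, design).state_matrix(spec, design)
        for (g, t), row in paper_matrix.rows.items():
            got = matrix.row(g, t)
            assert got.pattern_tolerant == row.pattern_tolerant, (g, t)
            assert got.pattern_sensitive == row.pattern_sensitive, (g, t)
            for cell, call in row.contrasts.items():
                tag = f"{cell[0]}_{cell[1]:g}h"
                if tag in row.ambiguous_cells:
                    continue
                assert got.contrasts[cell] == call, (g, t, cell)

    def test_yaml_roundtrip(self, tmp_path):
        spec = paper_scenario()
        path = tmp_path / "scenario.yaml"
        spec.to_yaml(path)
        back = ScenarioSpec.from_yaml(path)
        assert back.genes == spec.genes
        assert back.baseline_ct == dict(spec.baseline_ct)
        assert back.true_log2fc == dict(spec.true_log2fc)
        pd.testing.assert_frame_equal(
            simulate_cq(back).df[CQ_COLUMNS], simulate_cq(spec).df[CQ_COLUMNS]
        )
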