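"""ΔCt arithmetic and 2^-ΔΔCt relative quantities, with brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from drqpcr.design import SampleKey
from drqpcr.qpcr_io import CqTable
from drqpcr.relative_quant import (
    DeltaCtSet,
    compute_delta_ct,
    compute_rq,
    delta_ct_sets,
    relative_expression_table,
)
from drqpcr.synthetic_data import bulk_scenario, paper_scenario, simulate_cq


def _key(treatment="stress", gene="g1"):
    return SampleKey(gene, "ILC482", "root", treatment, 2.0)


def test_delta_ct_definitional(design, tiny_cq):
    table = CqTable(tiny_cq, design)
    delta = compute_delta_ct(table, design)
    target = delta[(delta["gene_id"] == "CaNAC16") & (delta["treatment"] == "control")]
    assert sorted(target["delta_ct"]) == [4.0, 4.5, 5.0]
    ref = delta[delta["gene_id"] == "IF4a"]
    assert (ref["delta_ct"] == 0.0).all()


def test_delta_ct_matches_bruteforce(design):
    """Element-wise subtraction recomputed independently row by row."""
    table = simulate_cq(bulk_scenario(4, log2fc=1.5, noise_sd=0.3, seed=11))
    delta = compute_delta_ct(table, design)
    df = table.df
    expected = {}
    for row in df.itertuples():
        if row.gene_id == design.reference_gene:
            continue
        ref_cq = df[
            (df["gene_id"] == design.reference_gene)
            & (df["cultivar"] == row.cultivar)
            & (df["tissue"] == row.tissue)
            & (df["treatment"] == row.treatment)
            & (df["timepoint_h"] == row.timepoint_h)
            & (df["bio_replicate"] == row.bio_replicate)
        ]["cq"].iloc[0]
        expected[(row.gene_id, row.treatment, row.bio_replicate)] = row.cq - ref_cq
    for row in delta[delta["gene_id"] != design.reference_gene].itertuples():
        assert row.delta_ct == pytest.approx(
            expected[(row.gene_id, row.treatment, row.bio_replicate)], abs=1e-12
        )


def test_rq_self_calibration_is_exactly_one():
    s = DeltaCtSet(_key("control"), (3.0, 3.0, 3.0))
    rel = compute_rq(s, s)
    assert rel.mean_rq == 1.0
    assert rel.se_rq == 0.0


def test_rq_one_cycle_is_twofold():
    target = DeltaCtSet(_key(), (2.0, 2.0, 2.0))
    cal = DeltaCtSet(_key("control"), (3.0, 3.0, 3.0))
    assert compute_rq(target, cal).mean_rq == pytest.approx(2.0)


def test_rq_bruteforce_expansion_oracle():
    # hand-expanded: mean(2^(4.0-1.8), 2^(4.0-2.1), 2^(4.0-2.4))
    target = DeltaCtSet(_key(), (1.8, 2.1, 2.4))
    cal = DeltaCtSet(_key("control"), (4.0, 4.1, 3.9))
    rel = compute_rq(target, cal)
    assert rel.mean_rq == pytest.approx(3.7861195063853885, rel=1e-12)
    assert rel.se_rq == pytest.approx(0.45210980878262275, rel=1e-10)
    of_means = compute_rq(target, cal, aggregate="of_means")
    assert of_means.mean_rq == pytest.approx(2.0 ** (4.0 - 2.1), rel=1e-12)


def test_rq_requires_two_replicates():
    with pytest.raises(ValueError, match="2 replicates"):
        DeltaCtSet(_key(), (1.0,))


@given(
    dcts=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
    cal=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
    c=st.floats(-3, 3),
)
def test_rq_scale_invariance(dcts, cal, c):
    """Adding a constant to every Cq of target AND reference genes leaves
    ΔCt — and hence every RQ — unchanged (the shift cancels in Cq_t − Cq_ref),
    so RQ from identical ΔCt sets is trivially equal; verified through the
    full Cq path below."""
    t = DeltaCtSet(_key(), tuple(dcts))
    k = DeltaCtSet(_key("control"), tuple(cal))
    base = compute_rq(t, k)
    again = compute_rq(t, k)
    assert base.mean_rq == again.mean_rq


def test_scale_equivariance_through_cq_path(design, tiny_cq):
    shifted = tiny_cq.copy()
    shifted["cq"] = shifted["cq"] + 2.5  # every gene, every sample
    d0 = compute_delta_ct(CqTable(tiny_cq, design), design)
    d1 = compute_delta_ct(CqTable(shifted, design), design)
    pd.testing.assert_frame_equal(d0, d1)


def test_reference_shift_multiplies_rq(design, tiny_cq):
    """Adding c = 1 cycle to the reference gene of the stress cell only
    multiplies that cell's RQ by 2^c."""
    base = relative_expression_table(
        compute_delta_ct(CqTable(tiny_cq, design), design), design
    )
    shifted_cq = tiny_cq.copy()
    mask = (shifted_cq["gene_id"] == "IF4a") & (
        shifted_cq["treatment"] == "dehydration"
    )
    shifted_cq.loc[mask, "cq"] += 1.0
    shifted = relative_expression_table(
        compute_delta_ct(CqTable(shifted_cq, design), design), design
    )
    sel = lambda df: df[
        (df["gene_id"] == "CaNAC16") & (df["treatment"] == "stress")
    ]["mean_rq"].iloc[0]
    assert sel(shifted) == pytest.approx(2.0 * sel(base), rel=1e-12)


@given(
    t=st.lists(st.floats(-4, 4), min_size=3, max_size=4),
    c=st.lists(st.floats(-4, 4), min_size=3, max_size=4),
)
def test_reciprocity_on_log_scale(t, c):
    ts = DeltaCtSet(_key(), tuple(t))
    cs = DeltaCtSet(_key("control"), tuple(c))
    fwd = np.mean(np.log2(2.0 ** -(ts.values - cs.mean)))
    rev = np.mean(np.log2(2.0 ** -(cs.values - ts.mean)))
    assert fwd == pytest.approx(-rev, abs=1e-9)


def test_zero_noise_rq_recovers_programmed_truth(design):
    spec = paper_scenario(noise_sd=0.0, seed=7)
    delta = compute_delta_ct(simulate_cq(spec), design)
    rel = relative_expression_table(delta, design)
    rel = rel[rel["gene_id"] != design.reference_gene]
    stress = rel[rel["treatment"] == "stress"]
    for row in stress.itertuples():
        truth = 2.0 ** spec.true_log2fc[
            (row.gene_id, row.cultivar, row.tissue, row.timepoint_h)
        ]
        assert row.mean_rq == pytest.approx(truth, rel=1e-12)
    controls = rel[rel["treatment"] == "control"]
    assert (controls["mean_rq"] == 1.0).all()


def test_missing_calibrator_is_error(design, tiny_cq):
    delta = compute_delta_ct(CqTable(tiny_cq, design), design)
    with pytest.raises(ValueError, match="calibrator"):
        relative_expression_table(delta[delta["treatment"] == "stress"], design)
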