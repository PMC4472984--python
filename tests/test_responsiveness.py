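"""One-tailed t-test, per-timepoint calls, and pattern classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from drqpcr.design import SampleKey
from drqpcr.relative_quant import DeltaCtSet, compute_delta_ct
from drqpcr.responsiveness import (
    TimepointCall,
    call_timepoint,
    classify_gene,
    one_tailed_t,
    response_calls,
    response_table,
)
from drqpcr.synthetic_data import bulk_scenario, simulate_cq


class TestOneTailedT:
    def test_identical_groups_give_half(self):
        assert one_tailed_t([1, 2, 3], [1, 2, 3]) == 0.5

    def test_matches_pooled_t_oracle(self):
        # pooled sd = 1, t = 4/sqrt(2/3) = 4.89898, df = 4
        p = one_tailed_t([5, 6, 7], [1, 2, 3])
        assert p == pytest.approx(0.0040249465504188595, rel=1e-12)
        oracle = stats.ttest_ind([5, 6, 7], [1, 2, 3], alternative="greater").pvalue
        assert p == pytest.approx(oracle, rel=1e-12)

    @given(
        a=st.lists(st.floats(-10, 10), min_size=2, max_size=5),
        b=st.lists(st.floats(-10, 10), min_size=2, max_size=5),
        c=st.floats(-20, 20),
    )
    def test_bounds_and_location_invariance(self, a, b, c):
        p = one_tailed_t(a, b)
        assert 0.0 <= p <= 0.5 + 1e-12  # observed-direction tail never exceeds 0.5
        shifted = one_tailed_t([x + c for x in a], [x + c for x in b])
        assert shifted == pytest.approx(p, abs=1e-9)

    def test_zero_variance_unequal_means_warns(self):
        with pytest.warns(RuntimeWarning, match="zero pooled variance"):
            assert one_tailed_t([1, 1, 1], [2, 2, 2]) == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            one_tailed_t([1], [1, 2])


def _pair(stress_dct, control_dct, gene="g1", tp=2.0):
    ks = SampleKey(gene, "ILC482", "root", "stress", tp)
    kc = SampleKey(gene, "ILC482", "root", "control", tp)
    return DeltaCtSet(ks, tuple(stress_dct)), DeltaCtSet(kc, tuple(control_dct))


class TestCallTimepoint:
    def test_strong_repression_called_down(self, design):
        # 17.5-fold repression: stress ΔCt higher by log2(17.5) cycles
        shift = np.log2(17.5)
        s, c = _pair([shift + 0.05, shift, shift - 0.05], [0.05, 0.0, -0.05])
        call = call_timepoint(s, c, design)
        assert call.call == "down"
        assert call.fold_change == pytest.approx(1 / 17.5, rel=1e-3)

    def test_below_threshold_stays_unchanged_despite_tiny_p(self, design):
        # 1.9-fold induction with almost no noise: significant but sub-threshold
        shift = -np.log2(1.9)
        s, c = _pair([shift + 1e-3, shift, shift - 1e-3], [1e-3, 0.0, -1e-3])
        call = call_timepoint(s, c, design)
        assert call.p_value < design.alpha
        assert call.call == "unchanged"

    def test_zero_noise_twofold_truth_called_up(self, design):
        s, c = _pair([-2.0, -2.0, -2.0], [0.0, 0.0, 0.0])
        with pytest.warns(RuntimeWarning):
            call = call_timepoint(s, c, design)
        assert call.call == "up"
        assert call.fold_change == pytest.approx(4.0)

    def test_rq_scale_agrees_qualitatively_at_low_noise(self, design):
        s, c = _pair([-2.01, -1.99, -2.0], [0.01, -0.01, 0.0])
        assert call_timepoint(s, c, design, test_scale="delta_ct").call == "up"
        assert call_timepoint(s, c, design, test_scale="rq").call == "up"


class TestClassifyGene:
    def _tc(self, call, tp):
        return TimepointCall(
            key=SampleKey("g", "ILC482", "leaf", "stress", tp),
            fold_change=1.0,
            p_value=0.5,
            call=call,
        )

    def test_opposite_directions_are_mixed(self):
        rc = classify_gene([self._tc("down", 2.0), self._tc("up", 5.0)])
        assert rc.pattern == "mixed"

    def test_single_timepoint_hit_is_responsive(self):
        assert classify_gene([self._tc("unchanged", 2.0), self._tc("up", 5.0)]).pattern == "up"

    def test_all_unchanged(self):
        rc = classify_gene([self._tc("unchanged", 2.0), self._tc("unchanged", 5.0)])
        assert rc.pattern == "unchanged"
        assert not rc.responsive

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_gene([])


def test_vectorized_table_matches_scalar_calls(design):
    """The groupby/numpy fast path must agree with call_timepoint exactly."""
    spec = bulk_scenario(30, log2fc=np.linspace(-3, 3, 30), noise_sd=0.4, seed=5)
    delta = compute_delta_ct(simulate_cq(spec), design)
    table = response_table(delta, design)
    from drqpcr.relative_quant import delta_ct_sets

    sets = delta_ct_sets(delta[delta["gene_id"] != design.reference_gene])
    for row in table.itertuples():
        s = sets[SampleKey(row.gene_id, "ILC482", "root", "stress", row.timepoint_h)]
        c = sets[SampleKey(row.gene_id, "ILC482", "root", "control", row.timepoint_h)]
        ref = call_timepoint(s, c, design)
        assert row.fold_change == pytest.approx(ref.fold_change, rel=1e-12)
        assert row.p_value == pytest.approx(ref.p_value, rel=1e-9)
        assert row.call == ref.call


def test_determinism_identical_inputs_identical_calls(design):
    spec = bulk_scenario(10, log2fc=2.0, noise_sd=0.3, seed=9)
    d1 = compute_delta_ct(simulate_cq(spec), design)
    d2 = compute_delta_ct(simulate_cq(spec), design)
    t1, t2 = response_table(d1, design), response_table(d2, design)
    assert t1.equals(t2)


def test_response_calls_structures(design):
    spec = bulk_scenario(3, log2fc=3.0, noise_sd=0.1, seed=2)
    delta = compute_delta_ct(simulate_cq(spec), design)
    calls = response_calls(delta, design)
    assert len(calls) == 3
    for rc in calls.values():
        assert rc.pattern == "up"
        assert len(rc.timepoint_calls) == 1
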