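import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dynmod import (
    ConnectivityMatrix,
    DataValidationError,
    DegenerateInputError,
    InsufficientDataError,
    ModularityTrace,
    aggregate_by_network,
    detect_states,
    q_trace,
    sd_q,
    state_profiles,
    threshold_sweep,
)
from dynmod.temporal_dynamics import group_mean_q
from dynmod.synth_cohort import SimulationConfig, make_labeling


def _trace(q_values, subject_id="s"):
    q_values = np.asarray(q_values, dtype=float)
    return ModularityTrace(q_values=q_values,
                           n_modules_values=np.full(q_values.size, 4),
                           gamma=1.0, subject_id=subject_id)


def _block_matrix(n=12, between=0.1, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n // 2)
    w = np.where(np.equal.outer(labels, labels), 0.8, between)
    w = w + rng.uniform(0, 0.01, (n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


class TestQTrace:
    def test_stationary_matrices_give_near_constant_trace(self):
        mats = [_block_matrix(seed=s) for s in range(6)]
        trace = q_trace(mats, gamma=1.0, n_runs=10)
        assert sd_q(trace) < 0.02

    def test_alternating_coupling_gives_bimodal_trace(self):
        strong = [_block_matrix(between=0.0, seed=s) for s in range(3)]
        weak = [_block_matrix(between=0.6, seed=s + 10) for s in range(3)]
        mats = [m for pair in zip(strong, weak) for m in pair]
        trace = q_trace(mats, gamma=1.0, n_runs=10)
        q = trace.q_values
        assert q[::2].min() > q[1::2].max()  # segregated windows above integrated

    def test_single_window_trace_allowed(self):
        trace = q_trace([_block_matrix()], gamma=1.0, n_runs=5)
        assert trace.n_windows == 1
        with pytest.raises(DegenerateInputError):
            sd_q(trace)

    def test_no_windows_rejected(self):
        with pytest.raises(InsufficientDataError):
            q_trace([], gamma=1.0)


class TestSdQ:
    def test_textbook_example(self):
        assert sd_q(_trace([0.2, 0.3, 0.4])) == pytest.approx(0.1, abs=1e-12)

    def test_constant_trace_is_zero(self):
        assert sd_q(_trace([0.3, 0.3, 0.3])) == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_homogeneity(self, scale):
        base = np.array([0.1, 0.25, 0.3, 0.6])
        assert sd_q(_trace(base * scale)) == pytest.approx(
            scale * sd_q(_trace(base)), rel=1e-12)

    def test_matches_two_pass_computation(self, rng):
        for _ in range(20):
            q = rng.uniform(0, 1, size=int(rng.integers(2, 30)))
            mean = sum(q) / len(q)
            two_pass = np.sqrt(sum((x - mean) ** 2 for x in q) / (len(q) - 1))
            assert sd_q(_trace(q)) == pytest.approx(two_pass, abs=1e-12)


class TestDetectStates:
    def test_forced_arithmetic_example(self):
        trace = _trace([0.10, 0.30, 0.30, 0.50])
        rep = detect_states(trace, "individual", fraction=0.5)
        assert rep.reference_mean == pytest.approx(0.30)
        assert rep.high_threshold == pytest.approx(0.45)
        assert rep.low_threshold == pytest.approx(0.15)
        assert rep.n_high == 1 and rep.n_low == 1
        np.testing.assert_array_equal(rep.high_window_indices, [3])
        np.testing.assert_array_equal(rep.low_window_indices, [0])

    def test_group_convention_with_same_mean_is_identical(self):
        trace = _trace([0.10, 0.30, 0.30, 0.50])
        ind = detect_states(trace, "individual", fraction=0.5)
        grp = detect_states(trace, "group", reference_mean=0.30, fraction=0.5)
        assert (grp.n_high, grp.n_low) == (ind.n_high, ind.n_low)

    def test_exact_threshold_value_not_counted(self):
        # values chosen exactly representable: mean 0.25, thresholds 0.375/0.125
        trace = _trace([0.125, 0.25, 0.375])
        rep = detect_states(trace, "individual", fraction=0.5)
        assert rep.high_threshold == 0.375 and rep.low_threshold == 0.125
        assert rep.n_high == 0 and rep.n_low == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_counts_invariant_to_positive_scaling(self, scale):
        q = np.array([0.05, 0.2, 0.31, 0.9])
        rep1 = detect_states(_trace(q), "individual", fraction=0.5)
        rep2 = detect_states(_trace(q * scale), "individual", fraction=0.5)
        assert (rep1.n_high, rep1.n_low) == (rep2.n_high, rep2.n_low)

    def test_group_convention_requires_reference(self):
        with pytest.raises(DataValidationError):
            detect_states(_trace([0.1, 0.2]), "group")

    def test_non_positive_mean_rejected(self):
        with pytest.raises(DegenerateInputError):
            detect_states(_trace([-0.2, 0.2]), "individual")


class TestGroupMeanQ:
    def test_subjects_first_then_time(self):
        traces = [_trace([0.1, 0.3]), _trace([0.5, 0.7])]
        # avg across subjects: [0.3, 0.5]; then across windows: 0.4
        assert group_mean_q(traces) == pytest.approx(0.4)


class TestThresholdSweep:
    def test_counts_monotone_in_fraction(self, rng):
        traces = [_trace(rng.uniform(0.05, 0.6, 20), subject_id=f"s{i}")
                  for i in range(5)]
        fractions = np.round(np.arange(0.05, 0.95, 0.05), 2)
        table = threshold_sweep(traces, fractions=fractions)
        for _, sub in table.groupby("subject_id"):
            sub = sub.sort_values("fraction")
            assert (np.diff(sub["n_high"]) <= 0).all()
            assert (np.diff(sub["n_low"]) <= 0).all()

    def test_empty_fraction_list_gives_empty_table(self):
        table = threshold_sweep([_trace([0.1, 0.2])], fractions=[])
        assert table.empty

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(DataValidationError):
            threshold_sweep([_trace([0.1, 0.2])], fractions=[1.5])


def _constant_matrix(n, value):
    m = np.full((n, n), value)
    np.fill_diagonal(m, 0.0)
    return ConnectivityMatrix(values=m, window_index=0)


class TestStateProfiles:
    def _labeling(self, n_nodes=14):
        return make_labeling(SimulationConfig(n_subjects=3, n_nodes=n_nodes,
                                              n_timepoints=200, n_modules=7))

    def test_constructed_difference_matrix(self):
        from dynmod import StateReport
        lab = self._labeling()
        # high-Q windows carry -0.2 edges, low-Q windows +0.2
        mats = [_constant_matrix(14, -0.2), _constant_matrix(14, 0.2)]
        rep = StateReport(convention="individual", fraction=0.5,
                          reference_mean=0.3, high_threshold=0.45,
                          low_threshold=0.15,
                          high_window_indices=np.array([0]),
                          low_window_indices=np.array([1]))
        high, low, diff, agg = state_profiles([mats], [rep], lab)
        off = ~np.eye(14, dtype=bool)
        np.testing.assert_allclose(diff[off], -0.4, atol=1e-12)
        assert agg.shape == (7, 7)

    def test_identical_high_and_low_sets_give_zero_difference(self):
        from dynmod import StateReport
        lab = self._labeling()
        mats = [_constant_matrix(14, 0.3)]
        rep = StateReport(convention="individual", fraction=0.5,
                          reference_mean=0.3, high_threshold=0.45,
                          low_threshold=0.15,
                          high_window_indices=np.array([0]),
                          low_window_indices=np.array([0]))
        _, _, diff, _ = state_profiles([mats], [rep], lab)
        np.testing.assert_allclose(diff, 0.0, atol=1e-15)

    def test_no_qualifying_windows_is_informative_error(self):
        from dynmod import StateReport
        lab = self._labeling()
        rep = StateReport(convention="individual", fraction=0.5,
                          reference_mean=0.3, high_threshold=0.45,
                          low_threshold=0.15,
                          high_window_indices=np.array([], dtype=int),
                          low_window_indices=np.array([], dtype=int))
        with pytest.raises(InsufficientDataError, match="0 high"):
            state_profiles([[_constant_matrix(14, 0.1)]], [rep], lab)


class TestAggregateByNetwork:
    def test_constant_matrix_gives_constant_blocks(self):
        lab = make_labeling(SimulationConfig(n_subjects=3, n_nodes=21,
                                             n_timepoints=200, n_modules=7))
        m = np.full((21, 21), 0.37)
        agg = aggregate_by_network(m, lab)
        np.testing.assert_allclose(agg.to_numpy(), 0.37, atol=1e-12)
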