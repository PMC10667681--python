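import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meltplex import (
    CHANNELS,
    NormalizationConfig,
    PartitionTable,
    ZeroDenominatorError,
    call_partitions,
    compute_ratios,
    normalize_ratios,
    qc_well,
)
from meltplex.calling import RatioTable
from meltplex.errors import NormalizationError


def table_from_channel(values, n=1, channel="blue"):
    """PartitionTable with one channel set to `values` (len 4), others flat 1000."""
    F = np.full((n, 4, 4), 1000.0)
    F[:, CHANNELS.index(channel), :] = np.asarray(values, dtype=float)
    return PartitionTable(well_id="T", fluorescence=F)


def ratio_table(raw):
    raw = np.asarray(raw, dtype=float)
    return RatioTable(
        well_id="T",
        raw=raw,
        preliminary_negative=raw <= 1.0,
        valid=np.ones(raw.shape[0], dtype=bool),
    )


class TestComputeRatios:
    def test_constant_signal(self, panel):
        ratios = compute_ratios(table_from_channel([1000, 1000, 1000, 1000]), panel)
        np.testing.assert_allclose(ratios.raw[0, 0], [1.0, 1.0, 1.0])

    def test_arithmetic(self, panel):
        ratios = compute_ratios(table_from_channel([800, 1000, 1000, 1000]), panel)
        np.testing.assert_allclose(ratios.raw[0, 0], [1.25, 1.0, 1.0])

    def test_zero_denominator_raises(self, panel):
        table = table_from_channel([0, 1000, 1000, 1000])
        with pytest.raises(ZeroDenominatorError) as exc:
            compute_ratios(table, panel)
        assert exc.value.partition_indices == [0]

    def test_zero_denominator_exclude_mode(self, panel):
        F = np.full((4, 4, 4), 1000.0)
        F[2, 0, 0] = 0.0
        table = PartitionTable(well_id="T", fluorescence=F)
        ratios = compute_ratios(table, panel, on_zero_denominator="exclude")
        assert ratios.valid.tolist() == [True, True, False, True]
        assert np.isnan(ratios.raw[2]).all()

    def test_preliminary_negative_flag(self, panel):
        ratios = compute_ratios(table_from_channel([800, 1000, 990, 1000]), panel)
        # 1.25 > cutoff 1.0 -> not preliminary negative; 0.99 <= 1.0 -> negative
        assert not ratios.preliminary_negative[0, 0, 0]
        assert ratios.preliminary_negative[0, 0, 1]


class TestNormalizeRatios:
    def test_constant_baseline_divides_out_exactly(self):
        raw = np.full((500, 4, 3), 0.98)
        out = normalize_ratios(ratio_table(raw), NormalizationConfig(window_size=101))
        np.testing.assert_array_equal(out.norm, np.ones_like(raw))

    def test_constant_baseline_mean_mode(self):
        # running-sum evaluation of the mean leaves ~1 ulp of rounding
        raw = np.full((500, 4, 3), 0.98)
        cfg = NormalizationConfig(
            window_size=101, statistic="rolling_mean_of_preliminary_negatives"
        )
        out = normalize_ratios(ratio_table(raw), cfg)
        np.testing.assert_allclose(out.norm, np.ones_like(raw), rtol=1e-12)

    def test_sparse_positives_on_flat_baseline(self, rng):
        # negatives at 0.98 with 1% positives at 1.30: baseline must stay at
        # 0.98, sending positives to 1.30/0.98 = 1.3265...
        n = 4000
        raw = np.full((n, 4, 3), 0.98)
        pos = rng.choice(n, size=n // 100, replace=False)
        raw[pos, 0, 0] = 1.30
        out = normalize_ratios(ratio_table(raw), NormalizationConfig(window_size=401))
        neg = np.setdiff1d(np.arange(n), pos)
        assert np.mean(out.norm[neg, 0, 0]) == pytest.approx(1.0, abs=0.005)
        np.testing.assert_allclose(out.norm[pos, 0, 0], 1.30 / 0.98, rtol=1e-9)

    def test_linear_drift_tracked_per_block(self):
        n = 20480
        drift = np.linspace(0.95, 1.05, n)
        raw = np.tile(drift[:, None, None], (1, 4, 3))
        out = normalize_ratios(ratio_table(raw), NormalizationConfig(window_size=1001))
        for start in range(0, n, 1000):
            block = out.norm[start : start + 1000, 0, 0]
            assert np.mean(block) == pytest.approx(1.0, abs=0.005)

    def test_window_larger_than_table(self):
        raw = np.ones((100, 4, 3))
        with pytest.raises(NormalizationError, match="exceeds"):
            normalize_ratios(ratio_table(raw), NormalizationConfig(window_size=1001))

    def test_all_preliminary_positive_mean_mode(self):
        raw = np.full((500, 4, 3), 1.5)  # everything above cutoff 1.0
        cfg = NormalizationConfig(
            window_size=101, statistic="rolling_mean_of_preliminary_negatives"
        )
        with pytest.raises(NormalizationError, match="preliminary-negative"):
            normalize_ratios(ratio_table(raw), cfg)

    def test_nan_partitions_ignored(self):
        raw = np.full((500, 4, 3), 0.98)
        raw[250] = np.nan
        rt = ratio_table(raw)
        rt.valid[250] = False
        out = normalize_ratios(rt, NormalizationConfig(window_size=101))
        assert np.isnan(out.norm[250]).all()
        ok = np.ones(500, dtype=bool)
        ok[250] = False
        np.testing.assert_array_equal(out.norm[ok], np.ones((499, 4, 3)))


class TestCallPartitions:
    def _norm_table(self, panel, value, probe_id="P1-A"):
        raw = np.ones((10, 4, 3))
        rt = ratio_table(raw)
        rt.norm = raw.copy()
        ci, wi = panel.slot_of(probe_id)
        rt.norm[0, ci, wi] = value
        return rt

    def test_above_threshold_positive(self, panel):
        calls = call_partitions(self._norm_table(panel, 1.08), panel)
        assert calls.positives_for("P1-A") == 1

    def test_tie_is_negative(self, panel):
        calls = call_partitions(self._norm_table(panel, 1.075), panel)
        assert calls.positives_for("P1-A") == 0

    def test_all_ones_no_positives(self, panel):
        rt = ratio_table(np.ones((10, 4, 3)))
        rt.norm = rt.raw.copy()
        calls = call_partitions(rt, panel)
        assert calls.positives.sum() == 0
        assert calls.analyzed == 10

    def test_unnormalized_rejected(self, panel):
        with pytest.raises(ValueError, match="normalized"):
            call_partitions(ratio_table(np.ones((5, 4, 3))), panel)

    @given(seed=st.integers(0, 2**31), n=st.integers(5, 200))
    @settings(max_examples=30, deadline=None)
    def test_brute_force_oracle(self, panel, seed, n):
        rng = np.random.default_rng(seed)
        norm = rng.uniform(0.8, 1.3, (n, 4, 3))
        rt = ratio_table(np.ones((n, 4, 3)))
        rt.norm = norm
        calls = call_partitions(rt, panel)
        for j, probe in enumerate(panel.probes):
            ci, wi = panel.slot_of(probe.probe_id)
            for p in range(n):
                expected = norm[p, ci, wi] > probe.threshold
                assert calls.calls[p, j] == expected

    def test_channel_independence(self, panel, rng):
        n = 300
        F = rng.uniform(900, 1100, (n, 4, 4))
        t1 = PartitionTable(well_id="A", fluorescence=F)
        F2 = F.copy()
        F2[:, CHANNELS.index("green"), :] *= rng.uniform(0.5, 2.0, (n, 4))
        t2 = PartitionTable(well_id="B", fluorescence=F2)
        cfg = NormalizationConfig(window_size=101)
        c1 = call_partitions(normalize_ratios(compute_ratios(t1, panel), cfg), panel)
        c2 = call_partitions(normalize_ratios(compute_ratios(t2, panel), cfg), panel)
        for j, probe in enumerate(panel.probes):
            if probe.channel != "green":
                np.testing.assert_array_equal(c1.calls[:, j], c2.calls[:, j])

    def test_scale_invariance(self, panel, rng):
        n = 300
        F = rng.uniform(900, 1100, (n, 4, 4))
        t1 = PartitionTable(well_id="A", fluorescence=F)
        F2 = F.copy()
        F2[:, 0, :] *= 37.5  # same constant at all four temperatures
        t2 = PartitionTable(well_id="B", fluorescence=F2)
        r1 = compute_ratios(t1, panel)
        r2 = compute_ratios(t2, panel)
        np.testing.assert_allclose(r1.raw[:, 0, :], r2.raw[:, 0, :], rtol=1e-12)

    def test_threshold_monotonicity(self, panel, rng):
        n = 500
        norm = rng.uniform(0.9, 1.2, (n, 4, 3))
        rt = ratio_table(np.ones((n, 4, 3)))
        rt.norm = norm
        base = call_partitions(rt, panel).positives
        raised = panel.model_copy(deep=True)
        for p in raised.probes:
            p.threshold += 0.05
        after = call_partitions(rt, raised).positives
        assert (after <= base).all()


class TestQCWell:
    def test_default_simulated_well_passes(self, small_blank_well, small_panel):
        table, _ = small_blank_well
        report = qc_well(table, small_panel)
        assert report.passed
        assert {c.name for c in report.checks} == {
            "partition_count",
            "finite_fluorescence",
            "reference_channel_signal",
            "zero_denominator_fraction",
        }

    def test_partition_count_mismatch(self, panel):
        table = PartitionTable(well_id="T", fluorescence=np.full((10000, 4, 4), 1000.0))
        report = qc_well(table, panel)
        assert not report.passed
        check = {c.name: c for c in report.checks}["partition_count"]
        assert not check.passed
        assert "10000" in check.message and "20480" in check.message

    def test_dead_reference_channel(self, small_panel):
        F = np.full((2048, 4, 4), 1000.0)
        F[:, CHANNELS.index("red"), :] = 0.0
        report = qc_well(PartitionTable(well_id="T", fluorescence=F), small_panel)
        check = {c.name: c for c in report.checks}["reference_channel_signal"]
        assert not check.passed
        assert report.reference_channel == "red"
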