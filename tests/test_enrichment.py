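"""Count-based enrichment metrics and the spiking-series recovery estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spiralfoil import enrichment as enr
from spiralfoil.exceptions import UndefinedMetricError


class TestBeadMetrics:
    @pytest.mark.parametrize(
        "counts, recovery, purity",
        [
            (enr.BeadCounts(90, 10, 5, 100), 90.0, 100.0 * 90 / 95),
            (enr.BeadCounts(120, 0, 0, 50), 100.0, 100.0),
            (enr.BeadCounts(95, 5, 5, 20), 95.0, 95.0),
            (enr.BeadCounts(40, 40, 40, 0), 50.0, 50.0),
        ],
    )
    def test_recovery_and_purity(self, counts, recovery, purity):
        assert enr.bead_recovery(counts) == pytest.approx(recovery)
        assert enr.bead_purity(counts) == pytest.approx(purity)

    def test_zero_denominators_rejected(self):
        with pytest.raises(UndefinedMetricError):
            enr.bead_recovery(enr.BeadCounts(0, 0, 5, 5))
        with pytest.raises(UndefinedMetricError):
            enr.bead_purity(enr.BeadCounts(0, 10, 0, 5))

    @given(
        a=st.integers(0, 10**6), b=st.integers(0, 10**6),
        c=st.integers(0, 10**6),
    )
    @settings(max_examples=50, deadline=None)
    def test_recovery_matches_enumeration_oracle(self, a, b, c):
        if a + b == 0:
            return
        counts = enr.BeadCounts(a, b, c, 0)
        assert enr.bead_recovery(counts) == pytest.approx(100.0 * a / (a + b))
        assert 0.0 <= enr.bead_recovery(counts) <= 100.0


class TestCycleMetrics:
    def test_depletion_matching_first_cycle_counts(self):
        # 1e6 WBC in, 369k carried to the CTC outlet -> 63.1% removed
        counts = enr.CycleCounts(1_000_000, 369_000, 117_000, 1000, 229, 116)
        assert enr.wbc_depletion(counts, 1) == pytest.approx(63.1)
        assert enr.wbc_depletion(counts, 2) == pytest.approx(88.3)

    def test_depletion_bounds(self):
        counts = enr.CycleCounts(100, 100, 0, 10, 0, 0)
        assert enr.wbc_depletion(counts, 1) == 0.0
        assert enr.wbc_depletion(counts, 2) == 100.0

    def test_recovery_matching_first_cycle_counts(self):
        counts = enr.CycleCounts(10, 5, 1, 1000, 229, 116)
        assert enr.ctc_recovery(counts, 1) == pytest.approx(77.1)
        # cycle 2 counts cumulative escape referenced to the original inlet
        assert enr.ctc_recovery(counts, 2) == pytest.approx(65.5)

    def test_recovery_bounds(self):
        counts = enr.CycleCounts(10, 5, 1, 500, 0, 0)
        assert enr.ctc_recovery(counts, 1) == 100.0
        counts = enr.CycleCounts(10, 5, 1, 500, 500, 0)
        assert enr.ctc_recovery(counts, 1) == 0.0

    def test_implausible_count_ordering_warns(self):
        with pytest.warns(RuntimeWarning):
            enr.CycleCounts(100, 200, 10, 10, 1, 1)


class TestCellLoss:
    def test_no_loss(self):
        v = enr.ViabilityCounts(800, 1000, 800, 1000)
        out = enr.cell_loss(v)
        assert out["viable_loss"] == 0.0
        assert out["total_loss"] == 0.0

    def test_first_cycle_loss_pair(self):
        # viable 843->711, total 1000->847
        out = enr.cell_loss(enr.ViabilityCounts(843, 1000, 711, 847))
        assert out["viable_loss"] == pytest.approx(15.7, abs=0.05)
        assert out["total_loss"] == pytest.approx(15.3, abs=0.05)
        assert out["viability_in"] == pytest.approx(84.3)

    def test_total_viable_loss(self):
        out = enr.cell_loss(enr.ViabilityCounts(843, 1000, 0, 100))
        assert out["viable_loss"] == 100.0


class TestLinearFitRecovery:
    def test_exact_proportional_data(self):
        levels = np.array([100, 500, 1000, 2000])
        series = enr.SpikingSeries(levels, 0.5 * levels)
        out = enr.linear_fit_recovery(series)
        assert out["rate"] == pytest.approx(50.0, rel=1e-12)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.integers(50, 3500, 15).astype(float)
        y = 0.77 * x + rng.normal(0, 20, 15)
        series = enr.SpikingSeries(x, np.maximum(y, 0))
        out = enr.linear_fit_recovery(series)
        slope_oracle = float(np.linalg.lstsq(x[:, None], series.recovered,
                                             rcond=None)[0][0])
        assert out["rate"] == pytest.approx(100 * slope_oracle, rel=1e-12)

    def test_degenerate_series_rejected(self):
        series = enr.SpikingSeries(np.array([100.0, 100, 100]),
                                   np.array([50.0, 51, 49]))
        with pytest.raises(UndefinedMetricError):
            enr.linear_fit_recovery(series)


class TestEnrichmentFactor:
    @pytest.mark.parametrize("dep, fold", [(0.0, 1.0), (50.0, 2.0), (88.3, 8.547)])
    def test_values(self, dep, fold):
        assert enr.enrichment_factor(dep) == pytest.approx(fold, rel=1e-3)

    def test_total_depletion_is_infinite(self):
        assert enr.enrichment_factor(100.0) == float("inf")


class TestBookkeeping:
    def test_two_cycle_protocol_volumes_and_times(self):
        """9 mL at a 2:3 split: 3.6/5.4 mL in 7.5 min; 3.6 mL in 3 min."""
        out1 = enr.cycle_bookkeeping(enr.CycleVolumes(9.0))
        assert out1["ctc_volume_ml"] == pytest.approx(3.6)
        assert out1["waste_volume_ml"] == pytest.approx(5.4)
        assert out1["process_time_min"] == pytest.approx(7.5)
        out2 = enr.cycle_bookkeeping(enr.CycleVolumes(3.6))
        assert out2["process_time_min"] == pytest.approx(3.0)
        out3 = enr.cycle_bookkeeping(enr.CycleVolumes(10.0))
        assert out3["process_time_min"] == pytest.approx(8.333, abs=1e-3)
        assert out3["process_time_min"] < 9.0

    @given(v=st.floats(0.1, 100), c=st.floats(0.1, 10), w=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_volume_conserved_exactly(self, v, c, w):
        out = enr.cycle_bookkeeping(enr.CycleVolumes(v, (c, w)))
        assert out["ctc_volume_ml"] + out["waste_volume_ml"] == pytest.approx(
            v, rel=1e-12
        )
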